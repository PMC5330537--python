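"""PARS scoring, positional quality flags, gene retention, structure calls.

The PARS score at a position is the log ratio of V1 to S1 read-start
counts: positive scores indicate double-stranded (V1-cleaved) conformations,
negative scores single-stranded.  A position is high quality (flag 1) only
when all three libraries have data there and the score magnitude reaches
the threshold (default |score| >= 3, log base 2); genes with at least 80%
high-quality positions are retained.  Calls on quality-1 positions follow
the sign of the score; everything else is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .tally import StartCountTrack

PAIRED = 1
SINGLE = 0
UNKNOWN = -1

__all__ = [
    "PAIRED",
    "SINGLE",
    "UNKNOWN",
    "ParsParams",
    "ParsProfile",
    "pars_score",
    "quality_flag",
    "compute_profile",
    "filter_genes",
    "call_structure",
    "pct_double_stranded",
    "write_profiles_tsv",
    "write_bedgraph",
]


@dataclass(frozen=True)
class ParsParams:
    """Scoring parameters; the defaults implement the standard rules
    (log base 2, no pseudocount, |score| >= 3, 80% retention)."""

    log_base: float = 2.0
    pseudocount: float = 0.0
    score_threshold: float = 3.0
    retention_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.log_base <= 1.0:
            raise ValueError(f"log_base must be > 1, got {self.log_base}")
        if self.pseudocount < 0:
            raise ValueError(f"pseudocount must be >= 0, got {self.pseudocount}")
        if not 0.0 <= self.retention_threshold <= 1.0:
            raise ValueError(
                f"retention_threshold must be in [0, 1], got {self.retention_threshold}"
            )


@dataclass
class ParsProfile:
    """Per-position scores, quality flags and ternary calls for one gene.

    ``score`` is NaN where undefined (a probing count of zero with no
    pseudocount); ``call`` is PAIRED (1), SINGLE (0) or UNKNOWN (-1).
    """

    transcript_id: str
    score: np.ndarray
    quality: np.ndarray
    call: np.ndarray
    pct_high_quality: float
    retained: bool

    @property
    def length(self) -> int:
        return len(self.score)


def pars_score(
    v1: np.ndarray | float, s1: np.ndarray | float, params: ParsParams = ParsParams()
) -> np.ndarray | float:
    """log_base((v1 + pseudocount) / (s1 + pseudocount)); NaN where either
    effective count is zero."""
    v = np.asarray(v1, dtype=float) + params.pseudocount
    s = np.asarray(s1, dtype=float) + params.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((v > 0) & (s > 0), np.log(v / s) / np.log(params.log_base), np.nan)
    if np.isscalar(v1) and np.isscalar(s1):
        return float(out)
    return out


def quality_flag(
    v1: np.ndarray | float,
    s1: np.ndarray | float,
    control: np.ndarray | float,
    params: ParsParams = ParsParams(),
) -> np.ndarray | int:
    """The 0/1 positional quality flag: 0 wherever any of the three
    libraries has no data; otherwise 1 iff |PARS score| >= threshold.

    The absent-data rule is applied to the raw counts and is never
    overridden by a pseudocount.
    """
    v = np.asarray(v1)
    s = np.asarray(s1)
    c = np.asarray(control)
    present = (v > 0) & (s > 0) & (c > 0)
    score = pars_score(v, s, params)
    with np.errstate(invalid="ignore"):
        flag = present & (np.abs(score) >= params.score_threshold)
    flag = np.asarray(flag).astype(np.int8)
    if np.isscalar(v1) and np.isscalar(s1) and np.isscalar(control):
        return int(flag)
    return flag


def call_structure(
    score: np.ndarray, quality: np.ndarray
) -> np.ndarray:
    """Ternary call: sign of the score on quality-1 positions, else unknown."""
    call = np.full(len(np.asarray(score)), UNKNOWN, dtype=np.int8)
    q = np.asarray(quality).astype(bool)
    with np.errstate(invalid="ignore"):
        call[q & (np.asarray(score) > 0)] = PAIRED
        call[q & (np.asarray(score) < 0)] = SINGLE
    return call


def compute_profile(track: StartCountTrack, params: ParsParams = ParsParams()) -> ParsProfile:
    """Score one gene and evaluate its retention status."""
    if track.length == 0:
        raise ValueError(f"{track.transcript_id}: zero-length gene")
    score = pars_score(track.counts_v1, track.counts_s1, params)
    quality = quality_flag(track.counts_v1, track.counts_s1, track.counts_control, params)
    call = call_structure(score, quality)
    pct = float(np.mean(quality))
    return ParsProfile(
        transcript_id=track.transcript_id,
        score=score,
        quality=quality,
        call=call,
        pct_high_quality=pct,
        retained=pct >= params.retention_threshold,
    )


def filter_genes(
    profiles: Iterable[ParsProfile], params: ParsParams = ParsParams()
) -> tuple[list[ParsProfile], pd.DataFrame]:
    """Retention filter: keep genes whose fraction of quality-1 positions is
    at least the retention threshold (boundary inclusive).  Returns the
    retained profiles and a per-gene summary table."""
    profiles = list(profiles)
    for p in profiles:
        if p.length == 0:
            raise ValueError(f"{p.transcript_id}: zero-length gene")
        p.retained = p.pct_high_quality >= params.retention_threshold
    summary = pd.DataFrame(
        {
            "transcript_id": [p.transcript_id for p in profiles],
            "pct_high_quality": [p.pct_high_quality for p in profiles],
            "retained": [p.retained for p in profiles],
        }
    )
    return [p for p in profiles if p.retained], summary


def pct_double_stranded(profile: ParsProfile) -> float:
    """Fraction of called positions that are paired; unknowns are excluded
    from the denominator."""
    n_paired = int(np.sum(profile.call == PAIRED))
    n_single = int(np.sum(profile.call == SINGLE))
    if n_paired + n_single == 0:
        raise ValueError(
            f"{profile.transcript_id}: no called positions; exclude this gene"
        )
    return n_paired / (n_paired + n_single)


# ---------------------------------------------------------------------------
# export

_CALL_LABEL = {PAIRED: "paired", SINGLE: "single", UNKNOWN: "unknown"}


def write_profiles_tsv(
    profiles: Iterable[ParsProfile],
    tracks: dict[str, StartCountTrack],
    path: str | Path,
) -> None:
    rows = []
    for p in sorted(profiles, key=lambda p: p.transcript_id):
        t = tracks[p.transcript_id]
        rows.append(
            pd.DataFrame(
                {
                    "transcript_id": p.transcript_id,
                    "pos": np.arange(1, p.length + 1),
                    "v1": t.counts_v1,
                    "s1": t.counts_s1,
                    "control": t.counts_control,
                    "score": np.round(p.score, 6),
                    "quality": p.quality,
                    "call": [_CALL_LABEL[c] for c in p.call],
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["transcript_id", "pos", "v1", "s1", "control", "score", "quality", "call"]
        )
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_profiles_tsv(path: str | Path) -> list[ParsProfile]:
    label_to_call = {v: k for k, v in _CALL_LABEL.items()}
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"transcript_id": str})
    profiles = []
    for tid, sub in df.groupby("transcript_id", sort=True):
        sub = sub.sort_values("pos")
        quality = sub["quality"].to_numpy(dtype=np.int8)
        pct = float(np.mean(quality))
        profiles.append(
            ParsProfile(
                transcript_id=str(tid),
                score=sub["score"].to_numpy(dtype=float),
                quality=quality,
                call=np.array([label_to_call[c] for c in sub["call"]], dtype=np.int8),
                pct_high_quality=pct,
                retained=False,  # recomputed by filter_genes under the caller's params
            )
        )
    return profiles


def write_bedgraph(profile: ParsProfile, path: str | Path) -> None:
    """Export defined scores as a 0-based half-open bedGraph track."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="PARS_{profile.transcript_id}"\n')
        for i, s in enumerate(profile.score):
            if np.isfinite(s):
                fh.write(f"{profile.transcript_id}\t{i}\t{i + 1}\t{s:.6g}\n")
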