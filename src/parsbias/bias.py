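"""Correlation and regression battery relating depth, GC content and structure.

Per-gene summaries (GC fraction, normalized control depth, percent
double-stranded) feed three families of tests: control depth vs. PARS
score at nucleotide resolution, depth vs. GC pooled and within GC strata
(the default strata are <40%, 35-60% and >60%, overlapping as printed in
the protocols this mirrors), and percent-double-stranded vs. GC.  Depth is
normalized per strain because library size is strain-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .pars import ParsProfile, pct_double_stranded
from .tally import StartCountTrack

__all__ = [
    "CorrelationResult",
    "GcStratum",
    "DEFAULT_STRATA",
    "gene_gc",
    "normalized_depths",
    "pearson",
    "depth_vs_pars",
    "summarize_genes",
    "depth_vs_gc",
    "per_strain_regression",
    "pctds_vs_gc",
]


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    stratum: str = ""
    computable: bool = True
    note: str = ""


@dataclass(frozen=True)
class GcStratum:
    """A labeled GC interval; bounds may be open or closed so the printed
    conventions ("less than 40%" strict, "between 35% and 60%" closed) are
    representable exactly.  Intervals may overlap."""

    label: str
    lo: float = -math.inf
    hi: float = math.inf
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def contains(self, gc: float) -> bool:
        above = gc >= self.lo if self.lo_inclusive else gc > self.lo
        below = gc <= self.hi if self.hi_inclusive else gc < self.hi
        return above and below


DEFAULT_STRATA: tuple[GcStratum, ...] = (
    GcStratum("low", hi=0.40, hi_inclusive=False),
    GcStratum("medium", lo=0.35, hi=0.60),
    GcStratum("high", lo=0.60, lo_inclusive=False),
)


def gene_gc(sequence: str) -> float:
    """GC fraction over unambiguous bases; ambiguity codes are excluded from
    numerator and denominator."""
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return gc / (gc + at)


def normalized_depths(tracks: Iterable[StartCountTrack]) -> dict[str, float]:
    """Per-gene mean control start count relative to the strain-wide mean
    per position.  The length-weighted mean of the result is 1."""
    tracks = list(tracks)
    total = sum(int(t.counts_control.sum()) for t in tracks)
    positions = sum(t.length for t in tracks)
    if total == 0:
        raise ValueError("strain has zero total control counts")
    strain_rate = total / positions
    return {
        t.transcript_id: float(t.counts_control.mean()) / strain_rate for t in tracks
    }


def pearson(x: Sequence[float], y: Sequence[float], stratum: str = "") -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value
    (equivalent to the t transform on n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    res = scipy.stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p_value=float(res.pvalue), n=len(x), stratum=stratum
    )


def depth_vs_pars(profile: ParsProfile, track: StartCountTrack) -> CorrelationResult:
    """Nucleotide-resolution correlation of PARS score with control read
    starts, over positions where the score is defined."""
    if profile.length != track.length:
        raise ValueError(f"{profile.transcript_id}: profile/track length mismatch")
    defined = np.isfinite(profile.score)
    if defined.sum() < 3:
        raise ValueError(
            f"{profile.transcript_id}: fewer than 3 positions with defined scores"
        )
    return pearson(
        profile.score[defined],
        track.counts_control.astype(float)[defined],
        stratum=profile.transcript_id,
    )


def summarize_genes(
    profiles: Iterable[ParsProfile],
    tracks: dict[str, StartCountTrack],
    sequences: dict[str, str],
    strain_id: str = "strain",
) -> pd.DataFrame:
    """Build the per-gene summary table: GC fraction, normalized control
    depth, percent double-stranded (NaN where no positions were called),
    length and retention flag."""
    profiles = list(profiles)
    depth = normalized_depths([tracks[p.transcript_id] for p in profiles])
    rows = []
    for p in profiles:
        try:
            pct_ds = pct_double_stranded(p)
        except ValueError:
            pct_ds = np.nan
        rows.append(
            {
                "transcript_id": p.transcript_id,
                "strain_id": strain_id,
                "gc_fraction": gene_gc(sequences[p.transcript_id]),
                "mean_depth_norm": depth[p.transcript_id],
                "pct_ds": pct_ds,
                "n_positions": p.length,
                "retained": p.retained,
            }
        )
    return pd.DataFrame(rows)


def depth_vs_gc(
    summaries: pd.DataFrame, strata: Sequence[GcStratum] = DEFAULT_STRATA
) -> list[CorrelationResult]:
    """Pooled depth-GC correlation plus one result per GC stratum.  Strata
    with fewer than 3 genes are returned flagged not-computable."""
    if summaries.empty:
        raise ValueError("empty gene summary table")
    results = [
        pearson(summaries["gc_fraction"], summaries["mean_depth_norm"], stratum="pooled")
    ]
    for stratum in strata:
        mask = summaries["gc_fraction"].map(stratum.contains)
        sub = summaries[mask]
        if len(sub) < 3:
            results.append(
                CorrelationResult(
                    r=np.nan,
                    p_value=np.nan,
                    n=len(sub),
                    stratum=stratum.label,
                    computable=False,
                    note=f"only {len(sub)} genes in stratum",
                )
            )
            continue
        results.append(
            pearson(sub["gc_fraction"], sub["mean_depth_norm"], stratum=stratum.label)
        )
    return results


def per_strain_regression(summaries: pd.DataFrame) -> pd.DataFrame:
    """OLS of normalized depth on GC fraction, one fit per strain.
    Returns slope, intercept, slope standard error, two-sided slope p."""
    rows = []
    for strain, sub in summaries.groupby("strain_id", sort=True):
        if len(sub) < 3:
            raise ValueError(f"strain {strain}: need >= 3 genes, got {len(sub)}")
        x = sub["gc_fraction"].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"strain {strain}: constant GC, degenerate design")
        X = sm.add_constant(x)
        fit = sm.OLS(sub["mean_depth_norm"].to_numpy(dtype=float), X).fit()
        rows.append(
            {
                "strain_id": strain,
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "slope_se": float(fit.bse[1]),
                "p_value": float(fit.pvalues[1]),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def pctds_vs_gc(summaries: pd.DataFrame) -> CorrelationResult:
    """Correlation of percent double-stranded with gene GC over retained
    genes that have at least one called position."""
    sub = summaries[summaries["retained"] & summaries["pct_ds"].notna()]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 retained genes with calls, got {len(sub)}")
    return pearson(sub["pct_ds"], sub["gc_fraction"], stratum="retained")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default in
    reporting)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
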