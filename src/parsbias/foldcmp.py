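"""Comparison of PARS calls against thermodynamic fold predictions.

Fold predictions arrive as dot-bracket strings (the standard output of
free-energy folding engines; folding itself is strictly upstream of this
package).  '(' and ')' mark paired bases, '.' unpaired; pseudoknot
brackets [], {} and <> are accepted and treated as paired.  Agreement with
the experimental calls is measured two ways: Pearson correlation of the
PARS score with the folded-state indicator over quality-1 positions, and a
2x2 paired/single contingency table with a two-sided Fisher exact test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats

from .bias import CorrelationResult, pearson
from .pars import PAIRED, SINGLE, ParsProfile

_PAIR_CHARS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSE_TO_OPEN = {v: k for k, v in _PAIR_CHARS.items()}
_VALID = set("().[]{}<>")

__all__ = [
    "DotBracketStructure",
    "FoldComparison",
    "parse_dot_bracket",
    "parse_dot_bracket_file",
    "serialize_dot_bracket",
    "pars_vs_fold",
]


@dataclass
class DotBracketStructure:
    transcript_id: str
    structure: str  # may be empty for objects built directly from a paired vector
    paired: np.ndarray  # 1 where the character is any bracket

    @property
    def length(self) -> int:
        return len(self.paired)


def _validate_brackets(structure: str) -> None:
    stack: list[tuple[str, int]] = []
    for i, ch in enumerate(structure):
        if ch not in _VALID:
            raise ValueError(f"invalid character {ch!r} at position {i + 1}")
        if ch in _PAIR_CHARS:
            stack.append((ch, i))
        elif ch in _CLOSE_TO_OPEN:
            if not stack or stack[-1][0] != _CLOSE_TO_OPEN[ch]:
                raise ValueError(f"unbalanced bracket {ch!r} at position {i + 1}")
            stack.pop()
    if stack:
        ch, i = stack[0]
        raise ValueError(
            f"unbalanced bracket {ch!r} opened at position {i + 1} and never closed"
        )


def parse_dot_bracket(
    structure: str, transcript_id: str = "", sequence: str | None = None
) -> DotBracketStructure:
    """Parse one dot-bracket string, validating bracket balance with a
    stack; a trailing free-energy annotation like ``(-12.30)`` is stripped.
    """
    structure = structure.strip()
    m = re.search(r"\s+\(\s*-?\d+(\.\d+)?\s*\)$", structure)
    if m:
        structure = structure[: m.start()].strip()
    if not structure:
        raise ValueError("empty structure string")
    _validate_brackets(structure)
    if sequence is not None and len(sequence) != len(structure):
        raise ValueError(
            f"structure length {len(structure)} != sequence length {len(sequence)}"
        )
    paired = np.array([1 if ch != "." else 0 for ch in structure], dtype=np.int8)
    return DotBracketStructure(transcript_id=transcript_id, structure=structure, paired=paired)


def parse_dot_bracket_file(path: str | Path) -> dict[str, DotBracketStructure]:
    """Parse fold-output text: per record a '>' header, an optional
    sequence line, and the structure line (with optional energy)."""
    records: dict[str, DotBracketStructure] = {}
    header: str | None = None
    sequence: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0]
                sequence = None
            elif re.fullmatch(r"[ACGTUNacgtun]+", line):
                sequence = line
            else:
                if header is None:
                    raise ValueError(f"{path}: structure line before any '>' header")
                records[header] = parse_dot_bracket(line, header, sequence)
                header, sequence = None, None
    return records


def serialize_dot_bracket(struct: DotBracketStructure) -> str:
    return f">{struct.transcript_id}\n{struct.structure}\n"


@dataclass
class FoldComparison:
    correlation: CorrelationResult
    table: np.ndarray  # rows: PARS call paired/single; cols: fold paired/unpaired
    fisher_odds: float
    fisher_p: float


def pars_vs_fold(profile: ParsProfile, fold: DotBracketStructure) -> FoldComparison:
    """Score-vs-fold correlation and call-vs-fold agreement over quality-1
    positions."""
    if profile.length != fold.length:
        raise ValueError(
            f"{profile.transcript_id}: profile length {profile.length} != "
            f"fold length {fold.length}"
        )
    q = profile.quality.astype(bool)
    if q.sum() < 3:
        raise ValueError(
            f"{profile.transcript_id}: need >= 3 quality-1 positions, got {int(q.sum())}"
        )
    corr = pearson(
        profile.score[q], fold.paired.astype(float)[q], stratum=profile.transcript_id
    )
    table = np.array(
        [
            [
                int(np.sum((profile.call == PAIRED) & (fold.paired == 1) & q)),
                int(np.sum((profile.call == PAIRED) & (fold.paired == 0) & q)),
            ],
            [
                int(np.sum((profile.call == SINGLE) & (fold.paired == 1) & q)),
                int(np.sum((profile.call == SINGLE) & (fold.paired == 0) & q)),
            ],
        ]
    )
    odds, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return FoldComparison(
        correlation=corr, table=table, fisher_odds=float(odds), fisher_p=float(p)
    )
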