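"""Per-position 5'-end read-start tallying.

In the probing protocol the ligated 5' phosphate marks the nuclease cleavage
site, so each accepted alignment contributes exactly one count: at the
read's leftmost reference position for genes on the + strand, and at the
rightmost position (mirrored into transcript coordinates) for genes on the
- strand.  Soft-clipped bases do not shift the start — clipping is an
alignment artifact, not part of the molecule's 5' end.  Replicates merge by
summation.  Internal coordinates are 0-based half-open; files are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

CONDITIONS = ("v1", "s1", "control")

__all__ = [
    "CONDITIONS",
    "GeneModel",
    "StartCountTrack",
    "tally_starts",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_gene_models",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene's location on a reference sequence (1-based inclusive)."""

    transcript_id: str
    reference_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_transcript_pos(self, genomic_pos: int) -> int:
        """Map a 1-based genomic coordinate to a 0-based transcript offset."""
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - genomic_pos


@dataclass
class StartCountTrack:
    """Per-transcript read-start counts for the three library conditions."""

    transcript_id: str
    counts_v1: np.ndarray
    counts_s1: np.ndarray
    counts_control: np.ndarray

    def __post_init__(self) -> None:
        lens = {len(self.counts_v1), len(self.counts_s1), len(self.counts_control)}
        if len(lens) != 1:
            raise ValueError(f"{self.transcript_id}: condition vectors differ in length")
        for name in ("counts_v1", "counts_s1", "counts_control"):
            arr = np.asarray(getattr(self, name))
            if arr.size and arr.min() < 0:
                raise ValueError(f"{self.transcript_id}: negative count in {name}")
            setattr(self, name, arr.astype(np.int64))

    @classmethod
    def zeros(cls, transcript_id: str, length: int) -> "StartCountTrack":
        z = lambda: np.zeros(length, dtype=np.int64)
        return cls(transcript_id, z(), z(), z())

    @property
    def length(self) -> int:
        return len(self.counts_v1)

    def counts(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        return getattr(self, f"counts_{condition}")


def _gene_index(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.reference_id, IntervalTree())[g.start : g.end + 1] = g
    return trees


def tally_starts(
    alignments: str | Path | Sequence[str | Path],
    genes: Iterable[GeneModel],
    condition: str,
    min_mapq: int = 10,
    count_read2: bool = False,
    tracks: dict[str, StartCountTrack] | None = None,
) -> dict[str, StartCountTrack]:
    """Tally 5'-end read starts from one or more SAM/BAM files (replicates
    are summed) into per-gene tracks for one condition.

    Accepted reads are mapped, primary, non-duplicate, non-supplementary,
    with MAPQ >= ``min_mapq``; by default only read 1 of a pair contributes.
    Reads whose 5' end falls outside every gene are ignored.  Raises if an
    alignment references a sequence absent from the gene annotation.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    genes = list(genes)
    trees = _gene_index(genes)
    if tracks is None:
        tracks = {}
    for g in genes:
        tracks.setdefault(g.transcript_id, StartCountTrack.zeros(g.transcript_id, g.length))

    paths = [alignments] if isinstance(alignments, (str, Path)) else list(alignments)
    for path in paths:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for read in af:
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.mapping_quality < min_mapq
                ):
                    continue
                if read.is_paired and read.is_read2 and not count_read2:
                    continue
                ref = read.reference_name
                if ref not in trees:
                    raise ValueError(
                        f"{path}: alignment references unknown sequence {ref!r}"
                    )
                # 1-based genomic coordinate of the biological 5' end, per gene strand
                left = read.reference_start + 1
                right = read.reference_end  # pysam end is exclusive, so this is 1-based rightmost
                for hit in trees[ref][left] | trees[ref][right]:
                    gene: GeneModel = hit.data
                    five_prime = left if gene.strand == "+" else right
                    if not (gene.start <= five_prime <= gene.end):
                        continue
                    pos = gene.to_transcript_pos(five_prime)
                    tracks[gene.transcript_id].counts(condition)[pos] += 1
    return tracks


# ---------------------------------------------------------------------------
# count-table TSV (transcript_id, pos_1based, condition, count)

def write_counts_tsv(tracks: Iterable[StartCountTrack], path: str | Path) -> None:
    """Write every position of every track, all three conditions, 1-based."""
    rows = []
    for t in sorted(tracks, key=lambda t: t.transcript_id):
        for cond in CONDITIONS:
            arr = t.counts(cond)
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": t.transcript_id,
                        "pos": np.arange(1, t.length + 1),
                        "condition": cond,
                        "count": arr,
                    }
                )
            )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["transcript_id", "pos", "condition", "count"])
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> dict[str, StartCountTrack]:
    """Read the 4-column count table; validates counts, positions and
    duplicate rows, reporting the offending line number."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"transcript_id": str, "condition": str},
        comment="#",
    )
    expected = ["transcript_id", "pos", "condition", "count"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    if df.empty:
        return {}
    for col in ("pos", "count"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: line {bad[0] + 2}: non-integer {col!r}")
        df[col] = df[col].astype(np.int64)
    bad = df.index[df["count"] < 0]
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 2}: negative count")
    bad = df.index[df["pos"] < 1]
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 2}: position must be >= 1")
    bad = df.index[~df["condition"].isin(CONDITIONS)]
    if len(bad):
        raise ValueError(
            f"{path}: line {bad[0] + 2}: unknown condition {df.loc[bad[0], 'condition']!r}"
        )
    dup = df.duplicated(subset=["transcript_id", "pos", "condition"])
    if dup.any():
        raise ValueError(
            f"{path}: line {df.index[dup][0] + 2}: duplicate (transcript, pos, condition)"
        )

    tracks: dict[str, StartCountTrack] = {}
    for tid, sub in df.groupby("transcript_id", sort=True):
        length = int(sub["pos"].max())
        track = StartCountTrack.zeros(str(tid), length)
        for cond, csub in sub.groupby("condition"):
            track.counts(str(cond))[csub["pos"].to_numpy() - 1] = csub["count"].to_numpy()
        tracks[str(tid)] = track
    return tracks


# ---------------------------------------------------------------------------
# gene models from GFF3 (CDS features) or 6-column BED

def read_gene_models(path: str | Path, feature_type: str = "CDS") -> list[GeneModel]:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _genes_from_gff3(path, feature_type)
    if path.suffix.lower() == ".bed":
        return _genes_from_bed(path)
    raise ValueError(f"unrecognized annotation format: {path} (expected .gff3/.gff/.bed)")


def _genes_from_gff3(path: Path, feature_type: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        tid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                transcript_id=tid,
                reference_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def _genes_from_bed(path: Path) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GeneModel(
            transcript_id=row["name"],
            reference_id=row["chrom"],
            start=int(row["start"]) + 1,  # BED is 0-based half-open
            end=int(row["end"]),
            strand=row["strand"],
        )
        for _, row in df.iterrows()
    ]
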