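"""YAML run configuration for the command-line interface."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bias import DEFAULT_STRATA, GcStratum
from .pars import ParsParams
from .simulate import SimConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: Path = Path("parsbias_out")
    params: ParsParams = field(default_factory=ParsParams)
    strata: tuple[GcStratum, ...] = DEFAULT_STRATA
    # either real inputs ...
    counts: dict[str, Path] = field(default_factory=dict)  # strain -> counts TSV
    fasta: dict[str, Path] = field(default_factory=dict)  # strain -> FASTA
    dot_bracket: dict[str, Path] = field(default_factory=dict)  # strain -> folds
    # ... or a simulation block (selftest / self-contained runs)
    simulation: list[SimConfig] = field(default_factory=list)


def _parse_strata(items: list[dict]) -> tuple[GcStratum, ...]:
    return tuple(GcStratum(**item) for item in items)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; referenced input paths
    must exist at validation time and the seed propagates to every
    simulated strain that does not set its own."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent
    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", 0))
    cfg.output_dir = Path(raw.get("output_dir", "parsbias_out"))
    if "params" in raw:
        cfg.params = ParsParams(**raw["params"])
    if "strata" in raw:
        cfg.strata = _parse_strata(raw["strata"])
    for section in ("counts", "fasta", "dot_bracket"):
        for strain, p in (raw.get(section) or {}).items():
            full = base / p if not Path(p).is_absolute() else Path(p)
            if not full.exists():
                raise FileNotFoundError(f"{section}[{strain}]: {full} does not exist")
            getattr(cfg, section)[strain] = full
    for block in raw.get("simulation") or []:
        block = dict(block)
        block.setdefault("seed", cfg.seed)
        if "length_range" in block:
            block["length_range"] = tuple(block["length_range"])
        cfg.simulation.append(SimConfig(**block))
    return cfg
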