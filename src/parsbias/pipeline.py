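"""End-to-end orchestration: counts -> profiles -> retention -> bias battery.

One :class:`StrainData` per organism (tracks, sequences, optional fold
predictions); :func:`analyze_study` chains scoring, retention filtering,
the depth/GC/structure correlation battery, the pooled and per-gene
logistic fits, and the per-gene long-format report table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bias, foldcmp, logit as logit_mod, pars
from .bias import DEFAULT_STRATA, CorrelationResult, GcStratum
from .foldcmp import DotBracketStructure
from .pars import ParsParams, ParsProfile
from .simulate import SimConfig, simulate_dataset
from .tally import StartCountTrack

__all__ = ["StrainData", "StudyResults", "analyze_study", "simulate_study", "report"]


@dataclass
class StrainData:
    strain_id: str
    tracks: dict[str, StartCountTrack]
    sequences: dict[str, str]
    folds: dict[str, DotBracketStructure] | None = None


@dataclass
class StudyResults:
    params: ParsParams
    profiles: dict[str, list[ParsProfile]]  # strain -> all profiles
    summaries: pd.DataFrame  # per gene, all strains, retained flag
    retention: pd.DataFrame  # per gene pct_high_quality / retained
    depth_gc: list[CorrelationResult]  # pooled + per stratum, retained genes
    strain_regressions: pd.DataFrame
    pctds_gc: CorrelationResult | None
    pooled_logit: logit_mod.LogitFit | None
    battery: pd.DataFrame  # long format: gene, strain, test, statistic, p_value, flag

    @property
    def retained_counts(self) -> dict[str, int]:
        sub = self.summaries[self.summaries["retained"]]
        return sub.groupby("strain_id").size().to_dict()


def analyze_study(
    strains: list[StrainData],
    params: ParsParams = ParsParams(),
    strata: tuple[GcStratum, ...] = DEFAULT_STRATA,
) -> StudyResults:
    all_profiles: dict[str, list[ParsProfile]] = {}
    summaries = []
    retention_rows = []
    battery_rows = []
    pooled_calls: list[np.ndarray] = []
    pooled_control: list[np.ndarray] = []

    for strain in strains:
        profiles = [
            pars.compute_profile(t, params) for t in strain.tracks.values()
        ]
        retained, ret_table = pars.filter_genes(profiles, params)
        ret_table.insert(1, "strain_id", strain.strain_id)
        retention_rows.append(ret_table)
        all_profiles[strain.strain_id] = profiles
        summaries.append(
            bias.summarize_genes(profiles, strain.tracks, strain.sequences, strain.strain_id)
        )
        for p in retained:
            track = strain.tracks[p.transcript_id]
            pooled_calls.append(p.call)
            pooled_control.append(track.counts_control)
            battery_rows.extend(
                _gene_battery(p, track, strain.folds, strain.strain_id)
            )

    summaries = pd.concat(summaries, ignore_index=True)
    retention = pd.concat(retention_rows, ignore_index=True)
    retained_sum = summaries[summaries["retained"]]

    depth_gc = (
        bias.depth_vs_gc(retained_sum, strata) if len(retained_sum) >= 3 else []
    )
    strain_reg = (
        bias.per_strain_regression(retained_sum)
        if (retained_sum.groupby("strain_id").size() >= 3).all() and len(retained_sum)
        else pd.DataFrame()
    )
    try:
        pctds = bias.pctds_vs_gc(summaries)
    except ValueError:
        pctds = None

    pooled_fit = None
    if pooled_calls:
        calls = np.concatenate(pooled_calls)
        control = np.concatenate(pooled_control)
        try:
            pooled_fit = logit_mod.fit_structure_logit(calls, control)
        except ValueError:
            pooled_fit = None

    battery = pd.DataFrame(
        battery_rows,
        columns=["transcript_id", "strain_id", "test", "statistic", "p_value", "flag"],
    )
    return StudyResults(
        params=params,
        profiles=all_profiles,
        summaries=summaries,
        retention=retention,
        depth_gc=depth_gc,
        strain_regressions=strain_reg,
        pctds_gc=pctds,
        pooled_logit=pooled_fit,
        battery=battery,
    )


def _gene_battery(
    profile: ParsProfile,
    track: StartCountTrack,
    folds: dict[str, DotBracketStructure] | None,
    strain_id: str,
) -> list[dict]:
    """The three per-gene tests: PARS-vs-control depth correlation,
    logistic prediction-vs-control, and (when folds are supplied)
    PARS-vs-fold agreement."""
    rows = []

    def row(test: str, statistic=np.nan, p=np.nan, flag: str = "") -> dict:
        return {
            "transcript_id": profile.transcript_id,
            "strain_id": strain_id,
            "test": test,
            "statistic": statistic,
            "p_value": p,
            "flag": flag,
        }

    try:
        corr = bias.depth_vs_pars(profile, track)
        rows.append(row("pars_control", corr.r, corr.p_value))
    except ValueError as exc:
        rows.append(row("pars_control", flag=str(exc)))

    try:
        fit = logit_mod.fit_structure_logit(profile.call, track.counts_control)
        if fit.converged:
            rows.append(row("prediction_control", fit.beta1, fit.p_value))
        else:
            rows.append(row("prediction_control", flag=fit.diagnostic))
    except ValueError as exc:
        rows.append(row("prediction_control", flag=str(exc)))

    if folds is not None:
        fold = folds.get(profile.transcript_id)
        if fold is None:
            rows.append(row("pars_vienna", flag="no fold prediction supplied"))
        else:
            try:
                cmp = foldcmp.pars_vs_fold(profile, fold)
                rows.append(row("pars_vienna", cmp.correlation.r, cmp.correlation.p_value))
            except ValueError as exc:
                rows.append(row("pars_vienna", flag=str(exc)))
    return rows


def simulate_study(
    configs: list[SimConfig], params: ParsParams = ParsParams()
) -> tuple[list, StudyResults]:
    """Simulate one strain per config and run the full analysis chain."""
    truths = []
    strains = []
    for cfg in configs:
        truth, tracks = simulate_dataset(cfg)
        truths.append(truth)
        strains.append(
            StrainData(
                strain_id=cfg.strain_id,
                tracks={t.transcript_id: t for t in tracks},
                sequences={t.transcript_id: t.sequence for t in truth},
            )
        )
    return truths, analyze_study(strains, params)


def report(results: StudyResults, alpha: float = 0.05) -> tuple[pd.DataFrame, str]:
    """The long-format battery table plus a text summary of significant
    fractions per test per strain."""
    battery = results.battery
    lines = ["Significant fractions (p < %.3g) per test per strain:" % alpha]
    tests_present = battery["test"].unique().tolist()
    for strain in sorted(battery["strain_id"].unique()):
        for test in tests_present:
            sub = battery[(battery["strain_id"] == strain) & (battery["test"] == test)]
            ok = sub[sub["flag"] == ""]
            if len(ok) == 0:
                lines.append(f"  {strain} {test}: no computable genes")
                continue
            frac = float((ok["p_value"] < alpha).mean())
            lines.append(f"  {strain} {test}: {frac:.3f} ({len(ok)} genes)")
    if "pars_vienna" not in tests_present:
        lines.append("  (no fold predictions supplied; pars_vienna rows absent)")
    return battery, "\n".join(lines)
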