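"""Binomial logistic regression of structure state on control read starts.

Models P(position is paired) = logistic(beta0 + beta1 * read_starts), where
the response is the binary structure call (unknown positions excluded) and
the predictor is the raw control read-start count — so exp(beta1) is the
odds multiplier for one additional read start.  Fitting is maximum
likelihood by iteratively reweighted least squares; predicted-probability
curves carry pointwise Wald intervals built on the linear predictor with
the full coefficient covariance, then mapped through the logistic so the
endpoints stay inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import expit

from .pars import PAIRED, SINGLE, UNKNOWN, ParsProfile
from .tally import StartCountTrack

__all__ = [
    "LogitFit",
    "ProbabilityCurve",
    "fit_structure_logit",
    "predict_curve",
    "per_gene_logit_battery",
]


@dataclass
class LogitFit:
    beta0: float
    beta1: float
    se0: float
    se1: float
    cov: np.ndarray  # 2x2 coefficient covariance
    n: int
    converged: bool
    p_value: float = np.nan  # two-sided Wald p for beta1
    x_max: float = np.nan  # largest observed read-start count
    diagnostic: str = ""


@dataclass
class ProbabilityCurve:
    read_starts: np.ndarray
    p_hat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float = 0.95


def _separation_diagnostic(y: np.ndarray, x: np.ndarray) -> str | None:
    """For a single continuous predictor, complete separation is exactly a
    threshold with no overlap between the two classes' predictor ranges."""
    x1, x0 = x[y == 1], x[y == 0]
    if x1.max() < x0.min() or x0.max() < x1.min():
        return (
            "complete separation: predictor ranges of the two classes do not "
            f"overlap (paired in [{x1.min():g}, {x1.max():g}], "
            f"single in [{x0.min():g}, {x0.max():g}])"
        )
    return None


def fit_structure_logit(
    calls: np.ndarray,
    control: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogitFit:
    """Fit the structure-vs-read-starts logistic model.

    ``calls`` is the ternary call vector; unknown positions are dropped.
    Raises if only one class remains.  Complete separation is flagged via
    ``converged=False`` with a diagnostic rather than returning unstable
    coefficients.
    """
    calls = np.asarray(calls)
    control = np.asarray(control, dtype=float)
    if len(calls) != len(control):
        raise ValueError(f"length mismatch: {len(calls)} vs {len(control)}")
    keep = calls != UNKNOWN
    y = (calls[keep] == PAIRED).astype(float)
    x = control[keep]
    n = len(y)
    if n == 0 or y.min() == y.max():
        raise ValueError(
            "logistic fit needs both paired and single calls; "
            f"got {int(y.sum())} paired of {n} called positions"
        )
    diag = _separation_diagnostic(y, x)
    if diag is not None:
        return LogitFit(
            beta0=np.nan, beta1=np.nan, se0=np.nan, se1=np.nan,
            cov=np.full((2, 2), np.nan), n=n, converged=False, diagnostic=diag,
        )

    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        return LogitFit(
            beta0=np.nan, beta1=np.nan, se0=np.nan, se1=np.nan,
            cov=np.full((2, 2), np.nan), n=n, converged=False,
            diagnostic=f"IRLS failed: {exc}",
        )
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        return LogitFit(
            beta0=float(params[0]), beta1=float(params[1]), se0=np.nan, se1=np.nan,
            cov=cov, n=n, converged=False,
            diagnostic="non-finite coefficients or standard errors (quasi-separation?)",
        )
    z = params[1] / bse[1]
    return LogitFit(
        beta0=float(params[0]),
        beta1=float(params[1]),
        se0=float(bse[0]),
        se1=float(bse[1]),
        cov=cov,
        n=n,
        converged=bool(res.converged),
        p_value=float(2 * scipy.stats.norm.sf(abs(z))),
        x_max=float(x.max()),
    )


def predict_curve(
    fit: LogitFit, level: float = 0.95, max_read_starts: int | None = None
) -> ProbabilityCurve:
    """Predicted structure probability on the integer read-start grid with
    pointwise intervals (normal approximation on the linear predictor)."""
    if not fit.converged:
        raise ValueError(f"cannot predict from a non-converged fit: {fit.diagnostic}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if max_read_starts is None:
        if not np.isfinite(fit.x_max):
            raise ValueError("fit carries no observed maximum; pass max_read_starts")
        max_read_starts = int(fit.x_max)
    grid = np.arange(0, max_read_starts + 1)
    eta = fit.beta0 + fit.beta1 * grid
    var_eta = (
        fit.cov[0, 0] + grid**2 * fit.cov[1, 1] + 2 * grid * fit.cov[0, 1]
    )
    se_eta = np.sqrt(np.maximum(var_eta, 0.0))
    z = scipy.stats.norm.ppf(0.5 + level / 2)
    return ProbabilityCurve(
        read_starts=grid,
        p_hat=expit(eta),
        ci_low=expit(eta - z * se_eta),
        ci_high=expit(eta + z * se_eta),
        level=level,
    )


def per_gene_logit_battery(
    profiles: Iterable[ParsProfile],
    tracks: dict[str, StartCountTrack],
) -> pd.DataFrame:
    """One logistic fit per retained gene.  Genes whose data violate the
    fit preconditions (no calls, one class, separation) are flagged in the
    ``flag`` column, never silently dropped."""
    rows = []
    for p in profiles:
        track = tracks[p.transcript_id]
        row = {
            "transcript_id": p.transcript_id,
            "beta1": np.nan,
            "se1": np.nan,
            "p_value": np.nan,
            "n": 0,
            "flag": "",
        }
        try:
            fit = fit_structure_logit(p.call, track.counts_control)
        except ValueError as exc:
            row["flag"] = str(exc)
        else:
            row["n"] = fit.n
            if fit.converged:
                row.update(beta1=fit.beta1, se1=fit.se1, p_value=fit.p_value)
            else:
                row["flag"] = fit.diagnostic
        rows.append(row)
    return pd.DataFrame(rows)


def write_curve_tsv(curve: ProbabilityCurve, path) -> None:
    pd.DataFrame(
        {
            "read_starts": curve.read_starts,
            "p_hat": curve.p_hat,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
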