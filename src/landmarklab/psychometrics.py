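"""Cumulative-logistic psychometric fitting for 2AFC landmark data.

For each subject x condition x block the proportion of "left shorter"
responses at each transector offset is fitted with

    f(mu, x, s) = 1 / (1 + exp((x - mu) / s))

by binomial maximum likelihood.  ``mu`` is the point of subjective
equality (PSE): the offset judged "left shorter" on half the trials,
negative for a leftward (pseudoneglect) bias.  ``s`` is the curve
width: small s means steep, precise judgements; large s, poor
discrimination sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = [
    "ProportionPoint",
    "PsychometricFit",
    "aggregate_proportions",
    "fit_logistic",
    "fit_blocks",
    "exclude_outliers",
    "write_fits",
    "read_fits",
]

FIT_COLUMNS = ["subject", "condition", "block", "pse", "width", "nll", "converged"]

# multi-start grid and bounds for the bounded quasi-Newton optimizer
_MU_STARTS = (-10.0, 0.0, 10.0)
_S_STARTS = (2.0, 6.0, 12.0)
_S_BOUNDS = (0.1, 100.0)
_FTOL = 1e-8


@dataclass(frozen=True)
class ProportionPoint:
    """Response counts at one stimulus offset."""

    offset: float
    n_trials: int
    n_left_shorter: int

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0 <= self.n_left_shorter <= self.n_trials:
            raise ValueError("n_left_shorter must lie in [0, n_trials]")


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted (PSE, width) for one block, with fit diagnostics."""

    subject_id: str
    condition: str
    block: int
    pse: float
    width: float
    neg_log_likelihood: float
    converged: bool


def aggregate_proportions(trials: pd.DataFrame) -> list[ProportionPoint]:
    """Collapse one block's trials into per-offset response counts.

    The input must contain trials from a single subject x condition x
    block; mixed keys raise, as do empty inputs.  Counts are conserved:
    the per-point ``n_trials`` sum to the number of input rows.
    """
    if len(trials) == 0:
        raise ValueError("cannot aggregate an empty trial table")
    for key in ("subject", "condition", "block"):
        if key in trials.columns and trials[key].nunique() > 1:
            raise ValueError(f"trials span multiple values of {key!r}; aggregate one block at a time")
    grouped = trials.groupby("offset", sort=True)["response"].agg(["count", "sum"])
    return [
        ProportionPoint(offset=float(off), n_trials=int(row["count"]), n_left_shorter=int(row["sum"]))
        for off, row in grouped.iterrows()
    ]


def _nll_grad(params: np.ndarray, x: np.ndarray, n: np.ndarray, k: np.ndarray):
    """Binomial negative log-likelihood of the logistic and its gradient."""
    mu, s = params
    # expit(-(x - mu) / s) == 1 / (1 + exp((x - mu) / s)), overflow-safe
    p = np.clip(expit(-(x - mu) / s), 1e-12, 1.0 - 1e-12)
    nll = float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())
    resid = k - n * p  # d(nll)/d(logit) per point, sign flipped
    d_mu = -resid.sum() / s
    d_s = -float((resid * (x - mu)).sum()) / s**2
    return nll, np.array([d_mu, d_s])


def fit_logistic(
    points: list[ProportionPoint],
    subject_id: str = "",
    condition: str = "",
    block: int = 0,
) -> PsychometricFit:
    """Maximum-likelihood fit of the cumulative logistic to count data.

    Runs L-BFGS-B from a 3 x 3 grid of starts (mu in {-10, 0, 10}, s in
    {2, 6, 12}) with s bounded in [0.1, 100] px and keeps the best
    converged optimum.  Degenerate inputs (all responses identical, or
    no optimizer start converging) return ``converged=False`` rather
    than raising, so such blocks can be flagged downstream instead of
    silently vanishing.
    """
    if len({p.offset for p in points}) < 3:
        raise ValueError("need >= 3 distinct offsets to fit a psychometric function")
    x = np.array([p.offset for p in points], dtype=float)
    n = np.array([p.n_trials for p in points], dtype=float)
    k = np.array([p.n_left_shorter for p in points], dtype=float)

    total = k.sum()
    if total == 0 or total == n.sum():
        return PsychometricFit(subject_id, condition, block, float("nan"), float("nan"), float("inf"), False)

    best: optimize.OptimizeResult | None = None
    for mu0 in _MU_STARTS:
        for s0 in _S_STARTS:
            res = optimize.minimize(
                _nll_grad,
                x0=np.array([mu0, s0]),
                args=(x, n, k),
                jac=True,
                method="L-BFGS-B",
                bounds=[(None, None), _S_BOUNDS],
                options={"ftol": _FTOL, "maxiter": 500},
            )
            if res.success and (best is None or res.fun < best.fun):
                best = res
    if best is None:
        return PsychometricFit(subject_id, condition, block, float("nan"), float("nan"), float("inf"), False)
    mu, s = best.x
    return PsychometricFit(subject_id, condition, block, float(mu), float(s), float(best.fun), True)


def fit_blocks(trials: pd.DataFrame) -> pd.DataFrame:
    """Fit every subject x condition x block in a long trial table.

    Returns the fits table (one row per block) with columns
    ``subject, condition, block, pse, width, nll, converged``.
    """
    records = []
    for (subj, cond, block), grp in trials.groupby(["subject", "condition", "block"], sort=True):
        fit = fit_logistic(aggregate_proportions(grp), str(subj), str(cond), int(block))
        records.append(
            {
                "subject": fit.subject_id,
                "condition": fit.condition,
                "block": fit.block,
                "pse": fit.pse,
                "width": fit.width,
                "nll": fit.neg_log_likelihood,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame.from_records(records, columns=FIT_COLUMNS)


def exclude_outliers(baseline_widths: dict[str, float]) -> tuple[set[str], set[str]]:
    """Flag subjects whose baseline curve width is > 3 SD above the group mean.

    The rule is one-sided (only implausibly wide, i.e. poorly
    discriminating, subjects are dropped) and strict: a width exactly
    at mean + 3 SD is kept.  SD is the sample standard deviation over
    all subjects.  Returns ``(kept, excluded)`` sets partitioning the
    input.
    """
    if len(baseline_widths) < 3:
        raise ValueError("need >= 3 subjects to apply the outlier rule")
    widths = np.array(list(baseline_widths.values()), dtype=float)
    cutoff = widths.mean() + 3.0 * widths.std(ddof=1)
    excluded = {s for s, w in baseline_widths.items() if w > cutoff}
    kept = set(baseline_widths) - excluded
    return kept, excluded


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, index=False, columns=FIT_COLUMNS)


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fits table missing columns: {sorted(missing)}")
    df["converged"] = df["converged"].astype(bool)
    return df[FIT_COLUMNS]
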