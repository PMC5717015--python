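"""Block-wise bias transforms, performance splits and summary statistics.

Operates on tidy fits tables (``subject, condition, block, pse, width``)
and implements the analysis chain for a sham-controlled within-subject
stimulation study:

* sham normalization — subtract each subject's sham PSE series
  block-by-block from each active condition;
* baseline correction — subtract the mean pre-stimulation PSE
  (blocks 1-2) from blocks 3-6;
* performance-group allocation — median/mean splits on baseline curve
  width into high/low discrimination sensitivity (HDS/LDS) groups;
* window summaries — online (blocks 3-4) and overall (blocks 3-6)
  mean shifts;
* directional-shift contingency counts, percentile bootstrap CIs and
  the simple t/Spearman statistics used to characterize the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BASELINE_BLOCKS",
    "WINDOWS",
    "baseline_summary",
    "sham_normalize",
    "baseline_correct",
    "allocate_groups",
    "summarize_shifts",
    "count_directional_shifts",
    "bootstrap_ci",
    "one_sample_t",
    "paired_t",
    "spearman",
]

BASELINE_BLOCKS = (1, 2)
WINDOWS: dict[str, tuple[int, ...]] = {"online": (3, 4), "overall": (3, 4, 5, 6)}

SHAM = "sham"


def _check_blocks(table: pd.DataFrame, n_blocks: int = 6) -> None:
    counts = table.groupby(["subject", "condition"])["block"].nunique()
    bad = counts[counts != n_blocks]
    if len(bad):
        subj, cond = bad.index[0]
        raise ValueError(f"subject {subj!r} condition {cond!r} has {bad.iloc[0]} blocks, expected {n_blocks}")


def baseline_summary(table: pd.DataFrame, value: str = "width") -> pd.DataFrame:
    """Per subject x condition mean of ``value`` over the baseline blocks (1-2)."""
    base = table[table["block"].isin(BASELINE_BLOCKS)]
    return base.groupby(["subject", "condition"], sort=True)[value].mean().reset_index()


def sham_normalize(table: pd.DataFrame, sham: str = SHAM) -> pd.DataFrame:
    """Subtract the sham PSE series block-by-block from each condition.

    Active-condition PSEs become (active - sham) per subject and block;
    the sham condition itself maps to identically zero.  Widths are
    carried through untouched.  Raises if any subject lacks a complete
    sham series.
    """
    if sham not in set(table["condition"]):
        raise ValueError(f"no {sham!r} condition in table")
    sham_tbl = table[table["condition"] == sham].set_index(["subject", "block"])["pse"]
    out = table.copy()
    keyed = pd.MultiIndex.from_frame(out[["subject", "block"]])
    missing = ~keyed.isin(sham_tbl.index)
    if missing.any():
        subj = out.loc[missing, "subject"].iloc[0]
        raise ValueError(f"subject {subj!r} is missing sham blocks required for normalization")
    out["pse"] = out["pse"].to_numpy() - sham_tbl.loc[keyed].to_numpy()
    return out


def baseline_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each series' mean of blocks 1-2 from every block.

    After correction the baseline blocks of each subject x condition
    have mean zero by construction, and blocks 3-6 express the shift
    relative to that subject's own pre-stimulation bias.
    """
    out = table.copy()
    base = (
        out[out["block"].isin(BASELINE_BLOCKS)]
        .groupby(["subject", "condition"])["pse"]
        .mean()
    )
    keyed = pd.MultiIndex.from_frame(out[["subject", "condition"]])
    if not keyed.isin(base.index).all():
        raise ValueError("every subject x condition needs baseline blocks 1-2")
    out["pse"] = out["pse"].to_numpy() - base.loc[keyed].to_numpy()
    return out


@dataclass(frozen=True)
class GroupAssignment:
    subject_id: str
    scheme: str
    condition: str | None  # None for pooled / consistent-subset schemes
    label: str  # "HDS" | "LDS"


def _split(widths: pd.Series, center: float) -> pd.Series:
    """Narrow (<= center) -> HDS, wide (> center) -> LDS.

    A subject exactly at the split value goes to HDS, matching the tie
    rule that the median-width subject joins the high-sensitivity group.
    """
    return pd.Series(np.where(widths.to_numpy() <= center, "HDS", "LDS"), index=widths.index)


def allocate_groups(table: pd.DataFrame, scheme: str = "pooled-median") -> list[GroupAssignment]:
    """Split subjects into HDS/LDS performance groups by baseline width.

    Schemes:

    * ``pooled-median`` — baseline width averaged over blocks 1-2 then
      over all conditions; split at the cohort median (at-median
      subject -> HDS);
    * ``per-condition`` — one label per condition, split at that
      condition's mean baseline width;
    * ``consistent-subset`` — the subset of subjects labeled
      identically in every condition under ``per-condition``, with that
      common label.
    """
    base = baseline_summary(table, "width")
    if base["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects to form performance groups")

    if scheme == "pooled-median":
        pooled = base.groupby("subject", sort=True)["width"].mean()
        labels = _split(pooled, float(pooled.median()))
        return [GroupAssignment(str(s), scheme, None, lab) for s, lab in labels.items()]

    if scheme in ("per-condition", "consistent-subset"):
        per_cond: list[GroupAssignment] = []
        for cond, grp in base.groupby("condition", sort=True):
            widths = grp.set_index("subject")["width"]
            labels = _split(widths, float(widths.mean()))
            per_cond.extend(GroupAssignment(str(s), "per-condition", str(cond), lab) for s, lab in labels.items())
        if scheme == "per-condition":
            return per_cond
        by_subject: dict[str, set[str]] = {}
        for a in per_cond:
            by_subject.setdefault(a.subject_id, set()).add(a.label)
        return [
            GroupAssignment(s, scheme, None, labs.pop())
            for s, labs in sorted(by_subject.items())
            if len(labs) == 1
        ]

    raise ValueError(f"unknown allocation scheme {scheme!r}")


def assignments_frame(assignments: list[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject": a.subject_id, "scheme": a.scheme, "condition": a.condition, "label": a.label}
            for a in assignments
        ]
    )


def summarize_shifts(table: pd.DataFrame, window: str, sham: str = SHAM) -> pd.DataFrame:
    """Mean shift over a summary window per subject x active condition.

    ``table`` must already be sham-normalized and baseline-corrected;
    ``window`` is ``"online"`` (blocks 3-4) or ``"overall"`` (blocks
    3-6).  Returns columns ``subject, condition, window, shift``.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}")
    blocks = WINDOWS[window]
    sub = table[(table["condition"] != sham) & table["block"].isin(blocks)]
    out = sub.groupby(["subject", "condition"], sort=True)["pse"].mean().reset_index()
    out = out.rename(columns={"pse": "shift"})
    out.insert(2, "window", window)
    return out


def count_directional_shifts(
    shifts: pd.DataFrame,
    assignments: list[GroupAssignment],
    active_conditions: tuple[str, str] = ("1mA", "2mA"),
) -> dict[str, dict[str, object]]:
    """Per-group counts of rightward shifters and cross-condition orderings.

    For each performance group: how many subjects shifted rightward
    (shift > 0, strict — a zero shift is not rightward) under each
    active condition, and how many shifted further right under one
    condition than the other, with percentages of the group size.
    """
    lab = {a.subject_id: a.label for a in assignments}
    wide = shifts.pivot(index="subject", columns="condition", values="shift")
    a, b = active_conditions
    out: dict[str, dict[str, object]] = {}
    for group in ("HDS", "LDS"):
        members = [s for s in wide.index if lab.get(s) == group]
        sub = wide.loc[members]
        n = len(members)
        counts = {
            "n": n,
            f"rightward_{a}": int((sub[a] > 0).sum()),
            f"rightward_{b}": int((sub[b] > 0).sum()),
            f"{a}_gt_{b}": int((sub[a] > sub[b]).sum()),
            f"{b}_gt_{a}": int((sub[b] > sub[a]).sum()),
        }
        counts[f"pct_{a}_gt_{b}"] = 100.0 * counts[f"{a}_gt_{b}"] / n if n else float("nan")
        counts[f"pct_{b}_gt_{a}"] = 100.0 * counts[f"{b}_gt_{a}"] / n if n else float("nan")
        out[group] = counts
    return out


def bootstrap_ci(
    values,
    n_resamples: int = 20_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean.

    Draws ``n_resamples`` with-replacement resamples of the data,
    computes each resample mean, and returns the central ``level``
    percentile interval.  Deterministic given the seed.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if x.size < 2:
        raise ValueError("need >= 2 values for a bootstrap interval")
    if n_resamples < 1000:
        raise ValueError("n_resamples must be >= 1000")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _require_n(x: np.ndarray, n: int = 3) -> None:
    if x.size < n:
        raise ValueError(f"need >= {n} observations")


def one_sample_t(values, popmean: float = 0.0) -> dict[str, float | None]:
    """One-sample t-test against ``popmean``; zero-variance input is flagged."""
    x = np.asarray(values, dtype=float)
    _require_n(x)
    if np.ptp(x) == 0.0:
        return {"mean": float(x.mean()), "t": None, "p": None, "df": x.size - 1, "degenerate": True}
    res = stats.ttest_1samp(x, popmean)
    return {
        "mean": float(x.mean()),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": x.size - 1,
        "degenerate": False,
    }


def paired_t(x, y) -> dict[str, float | None]:
    """Paired t-test on two matched samples (t-test on the differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    _require_n(x)
    d = x - y
    if np.ptp(d) == 0.0:
        return {"mean_diff": float(d.mean()), "t": None, "p": None, "df": d.size - 1, "degenerate": True}
    res = stats.ttest_rel(x, y)
    return {
        "mean_diff": float(d.mean()),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": d.size - 1,
        "degenerate": False,
    }


def spearman(x, y) -> dict[str, float | None]:
    """Spearman rank correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    _require_n(x)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return {"rho": None, "p": None, "n": x.size, "degenerate": True}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": x.size, "degenerate": False}
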