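"""End-to-end pipeline runner: generate/load -> fit -> transform -> report.

Runs the full analysis chain on a trial table (simulated or loaded):
per-block psychometric fits, the curve-width exclusion rule, sham
normalization, baseline correction, performance-group allocation,
window summaries, directional-shift counts, bootstrap CIs and the
summary t-tests / correlations.  Writes every intermediate table as
CSV plus a JSON run report; identical seeds and inputs give identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline as pl
from . import psychometrics as psy
from . import synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``input_path`` (a trial CSV) or ``cohort`` (a synthetic
    cohort to generate) must be provided.  ``bootstrap_resamples`` and
    ``bootstrap_level`` control the shift CIs; ``seed`` drives every
    stochastic stage (generation uses ``cohort.seed``, which
    :func:`run_pipeline` overrides with ``seed`` when ``reseed`` is
    true, and the bootstrap uses a child of ``seed``).
    """

    cohort: synth.CohortConfig | None = None
    input_path: str | Path | None = None
    out_dir: str | Path | None = None
    schemes: tuple[str, ...] = ("pooled-median", "per-condition", "consistent-subset")
    windows: tuple[str, ...] = ("online", "overall")
    bootstrap_resamples: int = 20_000
    bootstrap_level: float = 0.95
    seed: int = 0
    reseed: bool = True
    sham: str = "sham"
    active_conditions: tuple[str, str] = ("1mA", "2mA")

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_path is None):
            raise ValueError("provide exactly one of cohort / input_path")


def _stage(name: str, t0: float, n: int) -> None:
    logger.info("%s: %d records in %.2fs", name, n, time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain and return the run report.

    The report dict contains cohort bookkeeping, exclusions, baseline
    statistics (per-condition one-sample t-tests and cross-session
    Spearman correlations), per-window shift summaries with bootstrap
    CIs and paired t-tests, directional-shift counts, and the seeds
    used.  If ``config.out_dir`` is set, intermediate tables (trials,
    fits, corrected series, shifts, assignments) and the report JSON
    are written there.
    """
    rng_seed = int(config.seed)
    report: dict = {"seed": rng_seed, "stages": {}}
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- generate or load trials -----------------------------------
    t0 = time.perf_counter()
    if config.cohort is not None:
        cohort_cfg = config.cohort.with_seed(rng_seed) if config.reseed else config.cohort
        observers = synth.draw_cohort(cohort_cfg)
        trials = synth.simulate_trials(observers, cohort_cfg)
        report["source"] = {"kind": "synthetic", "n_subjects": cohort_cfg.n_subjects, "seed": cohort_cfg.seed}
    else:
        trials = synth.read_trials(config.input_path)
        report["source"] = {"kind": "file", "path": str(config.input_path)}
    _stage("trials", t0, len(trials))
    report["stages"]["trials"] = {"n_rows": int(len(trials))}
    if out_dir is not None and config.cohort is not None:
        synth.write_trials(trials, out_dir / "trials.csv")

    # --- psychometric fits -----------------------------------------
    t0 = time.perf_counter()
    fits = psy.fit_blocks(trials)
    _stage("fits", t0, len(fits))
    n_diverged = int((~fits["converged"]).sum())
    report["stages"]["fits"] = {"n_fits": int(len(fits)), "n_not_converged": n_diverged}
    if out_dir is not None:
        psy.write_fits(fits, out_dir / "fits.csv")
    fits = fits[fits["converged"]]

    # --- outlier exclusion on pooled baseline width ----------------
    base_w = pl.baseline_summary(fits, "width").groupby("subject")["width"].mean()
    kept, excluded = psy.exclude_outliers(base_w.to_dict())
    fits = fits[fits["subject"].isin(kept)]
    report["stages"]["exclusion"] = {"n_kept": len(kept), "excluded": sorted(excluded)}

    # --- baseline statistics ---------------------------------------
    base_pse = pl.baseline_summary(fits, "pse").pivot(index="subject", columns="condition", values="pse")
    conditions = list(base_pse.columns)
    report["baseline"] = {
        "pse_t_tests": {c: pl.one_sample_t(base_pse[c].to_numpy()) for c in conditions},
        "pse_spearman": {
            f"{a}_vs_{b}": pl.spearman(base_pse[a].to_numpy(), base_pse[b].to_numpy())
            for i, a in enumerate(conditions)
            for b in conditions[i + 1 :]
        },
    }

    # --- transforms -------------------------------------------------
    corrected = pl.baseline_correct(pl.sham_normalize(fits, sham=config.sham))
    if out_dir is not None:
        corrected.to_csv(out_dir / "corrected.csv", index=False)

    # --- group allocation -------------------------------------------
    assignments = {s: pl.allocate_groups(fits, s) for s in config.schemes}
    if out_dir is not None:
        pd.concat([pl.assignments_frame(a) for a in assignments.values()]).to_csv(
            out_dir / "assignments.csv", index=False
        )
    report["groups"] = {
        s: pd.Series([a.label for a in asg]).value_counts().to_dict() for s, asg in assignments.items()
    }

    # --- shift summaries, CIs, tests --------------------------------
    boot_rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(2)[1])
    all_shifts = []
    report["shifts"] = {}
    a_cond, b_cond = config.active_conditions
    for window in config.windows:
        shifts = pl.summarize_shifts(corrected, window, sham=config.sham)
        all_shifts.append(shifts)
        wide = shifts.pivot(index="subject", columns="condition", values="shift")
        entry: dict = {}
        for cond in (a_cond, b_cond):
            vals = wide[cond].to_numpy()
            lo, hi = pl.bootstrap_ci(vals, config.bootstrap_resamples, config.bootstrap_level, boot_rng)
            entry[cond] = {
                "mean": float(vals.mean()),
                "ci": [lo, hi],
                "t_vs_zero": pl.one_sample_t(vals),
            }
        both = wide[[a_cond, b_cond]].mean(axis=1).to_numpy()
        lo, hi = pl.bootstrap_ci(both, config.bootstrap_resamples, config.bootstrap_level, boot_rng)
        entry["collapsed"] = {"mean": float(both.mean()), "ci": [lo, hi], "t_vs_zero": pl.one_sample_t(both)}
        entry["paired_t_1mA_vs_2mA"] = pl.paired_t(wide[a_cond].to_numpy(), wide[b_cond].to_numpy())
        report["shifts"][window] = entry
    shifts_tbl = pd.concat(all_shifts, ignore_index=True)
    if out_dir is not None:
        shifts_tbl.to_csv(out_dir / "shifts.csv", index=False)

    # --- directional-shift counts (overall window, pooled groups) ---
    overall = shifts_tbl[shifts_tbl["window"] == "overall"]
    pooled = assignments.get("pooled-median")
    if pooled is not None and not overall.empty:
        report["directional_counts"] = pl.count_directional_shifts(
            overall, pooled, active_conditions=config.active_conditions
        )

    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
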