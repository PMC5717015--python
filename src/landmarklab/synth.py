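"""Synthetic landmark-task cohort generator.

Emulates the structure of a within-subject tDCS landmark-task study:
each subject completes three sessions (1 mA, 2 mA, sham), each session
six blocks of 272 two-alternative forced-choice trials over a symmetric
grid of 17 transector offsets (-48..+48 px in steps of 6, 16 repeats
per offset per block).  Subjects carry a stable leftward spatial bias
(pseudoneglect, negative PSE) and a lognormally distributed curve
width; a shared subject random effect induces the cross-session
correlation of both quantities that real observers show.

Sign convention: ``offset`` is the left-minus-right length asymmetry in
pixels, and the response records whether the *left* segment was judged
shorter.  The response probability is logistic and decreasing in the
offset, so a negative fitted PSE denotes a leftward bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CohortConfig",
    "ObserverParams",
    "DEFAULT_CONDITIONS",
    "DEFAULT_OFFSETS",
    "logistic_response_prob",
    "draw_cohort",
    "simulate_trials",
    "true_bias_table",
    "write_trials",
    "read_trials",
]

DEFAULT_CONDITIONS: tuple[str, ...] = ("1mA", "2mA", "sham")
DEFAULT_OFFSETS: tuple[int, ...] = tuple(range(-48, 49, 6))

TRIAL_COLUMNS = ["subject", "condition", "block", "offset", "response"]


@dataclass(frozen=True)
class CohortConfig:
    """Population and design parameters for a simulated cohort.

    Defaults reproduce the study design the analysis pipeline assumes:
    29 subjects x 3 sessions x 6 blocks x 272 trials, group-mean
    baseline PSE near -2 px and median curve width 6.3 px.

    ``injected_shift`` maps ``(condition, block)`` to an additive PSE
    displacement in pixels, used to plant known stimulation effects
    (e.g. a rightward shift during blocks 3-6 of one active condition).
    ``cross_session_icc`` is the fraction of between-subject variance
    shared across sessions, and sets the expected cross-session
    correlation of subject-level PSE (and, on the log scale, width).
    """

    n_subjects: int = 29
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_blocks: int = 6
    offsets: tuple[int, ...] = DEFAULT_OFFSETS
    reps_per_offset: int = 16
    pse_population_mean: float = -2.0
    pse_population_sd: float = 4.0
    pse_block_sd: float = 0.5
    width_population_median: float = 6.3
    width_population_log_sd: float = 0.35
    width_block_log_sd: float = 0.1
    cross_session_icc: float = 0.6
    lapse_rate: float = 0.0
    injected_shift: dict[tuple[str, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        offs = np.asarray(self.offsets, dtype=float)
        if len(offs) < 3 or not np.allclose(np.sort(offs), -np.sort(offs)[::-1]):
            raise ValueError("offsets must be symmetric about zero")
        if 0.0 not in offs:
            raise ValueError("offsets must include zero")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_blocks < 1 or self.reps_per_offset < 1:
            raise ValueError("n_blocks and reps_per_offset must be positive")
        if self.pse_population_sd <= 0 or self.width_population_log_sd <= 0:
            raise ValueError("population scale parameters must be > 0")
        if self.pse_block_sd < 0 or self.width_block_log_sd < 0:
            raise ValueError("block jitter scales must be >= 0")
        if not 0.0 <= self.cross_session_icc <= 1.0:
            raise ValueError("cross_session_icc must lie in [0, 1]")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        for (cond, block) in self.injected_shift:
            if cond not in self.conditions:
                raise ValueError(f"injected_shift references unknown condition {cond!r}")
            if not 1 <= block <= self.n_blocks:
                raise ValueError(f"injected_shift references block {block} outside 1..{self.n_blocks}")

    @property
    def trials_per_block(self) -> int:
        return len(self.offsets) * self.reps_per_offset

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ObserverParams:
    """Generating psychometric parameters for one simulated subject.

    ``pse`` and ``width`` map ``(condition, block)`` to the true mu and
    s of the cumulative logistic that drives that block's responses.
    """

    subject_id: str
    pse: dict[tuple[str, int], float]
    width: dict[tuple[str, int], float]
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.width.values()):
            raise ValueError("all curve widths must be strictly positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if set(self.pse) != set(self.width):
            raise ValueError("pse and width must cover the same (condition, block) keys")


def logistic_response_prob(mu: float, x, s: float, lapse_rate: float = 0.0):
    """P(left judged shorter) at offset ``x`` for a cumulative logistic.

    f(mu, x, s) = 1 / (1 + exp((x - mu) / s)), optionally mixed with a
    lapse floor/ceiling: p = lapse/2 + (1 - lapse) * f.
    """
    x = np.asarray(x, dtype=float)
    f = expit(-(x - mu) / s)  # == 1 / (1 + exp((x - mu) / s)), overflow-safe
    return lapse_rate / 2.0 + (1.0 - lapse_rate) * f


def draw_cohort(config: CohortConfig) -> list[ObserverParams]:
    """Draw per-subject generating parameters from the population model.

    The subject-level PSE in condition c is
    ``mean + u_i + v_ic`` with ``u_i ~ N(0, icc * sd^2)`` shared across
    sessions and ``v_ic ~ N(0, (1 - icc) * sd^2)`` session-specific, so
    that the between-condition correlation of subject-level PSE equals
    ``cross_session_icc`` (attenuated slightly by block jitter).  Log
    curve width follows the same decomposition around
    ``log(width_population_median)``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    icc = config.cross_session_icc
    n, n_cond = config.n_subjects, len(config.conditions)

    u_pse = rng.normal(0.0, np.sqrt(icc) * config.pse_population_sd, size=n)
    v_pse = rng.normal(0.0, np.sqrt(1.0 - icc) * config.pse_population_sd, size=(n, n_cond))
    u_logw = rng.normal(0.0, np.sqrt(icc) * config.width_population_log_sd, size=n)
    v_logw = rng.normal(0.0, np.sqrt(1.0 - icc) * config.width_population_log_sd, size=(n, n_cond))

    pad = len(str(n))
    observers: list[ObserverParams] = []
    for i in range(n):
        pse: dict[tuple[str, int], float] = {}
        width: dict[tuple[str, int], float] = {}
        for j, cond in enumerate(config.conditions):
            level_mu = config.pse_population_mean + u_pse[i] + v_pse[i, j]
            level_logw = np.log(config.width_population_median) + u_logw[i] + v_logw[i, j]
            for block in range(1, config.n_blocks + 1):
                mu = level_mu + rng.normal(0.0, config.pse_block_sd) if config.pse_block_sd else level_mu
                logw = level_logw + rng.normal(0.0, config.width_block_log_sd) if config.width_block_log_sd else level_logw
                mu += config.injected_shift.get((cond, block), 0.0)
                pse[(cond, block)] = float(mu)
                width[(cond, block)] = float(np.exp(logw))
        observers.append(
            ObserverParams(
                subject_id=f"S{i + 1:0{pad}d}",
                pse=pse,
                width=width,
                lapse_rate=config.lapse_rate,
            )
        )
    return observers


def simulate_trials(observers: list[ObserverParams], config: CohortConfig) -> pd.DataFrame:
    """Simulate every 2AFC trial for a cohort as Bernoulli draws.

    Returns a long-format table with one row per trial and columns
    ``subject, condition, block, offset, response`` (response = 1 when
    the left segment was judged shorter).  Exactly
    ``reps_per_offset`` trials are produced per subject x condition x
    block x offset.  Deterministic given ``config.seed`` (a child seed
    distinct from the one used by :func:`draw_cohort`).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    offsets = np.asarray(config.offsets, dtype=float)
    reps = config.reps_per_offset

    rows: list[pd.DataFrame] = []
    for obs in observers:
        for cond, block in itertools.product(config.conditions, range(1, config.n_blocks + 1)):
            mu = obs.pse[(cond, block)]
            s = obs.width[(cond, block)]
            p = logistic_response_prob(mu, offsets, s, obs.lapse_rate)
            resp = (rng.random((reps, offsets.size)) < p).astype(np.int8)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": obs.subject_id,
                        "condition": cond,
                        "block": block,
                        "offset": np.tile(offsets, reps).astype(int),
                        "response": resp.ravel(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def true_bias_table(observers: list[ObserverParams]) -> pd.DataFrame:
    """Tabulate the generating (noise-free) PSE/width per subject x condition x block.

    Shaped exactly like a fits table, so the downstream transforms can
    be exercised on known truth without psychometric fitting.
    """
    records = [
        {
            "subject": obs.subject_id,
            "condition": cond,
            "block": block,
            "pse": obs.pse[(cond, block)],
            "width": obs.width[(cond, block)],
        }
        for obs in observers
        for (cond, block) in sorted(obs.pse)
    ]
    return pd.DataFrame.from_records(records)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df[TRIAL_COLUMNS]
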