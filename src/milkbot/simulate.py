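"""Synthetic test-day cohorts with the study's herd-parity structure.

Emulates a milk-recording (DHIA-style) data set: herds, each with parity
groups (first lactation P1 vs. later lactations P2+) of cows; per-cow
MilkBot parameters drawn from a two-level hierarchy (population mean +
herd effect + cow deviation, truncated to the model's sign constraints);
roughly monthly test-day schedules truncated at 305 DIM; and additive
homoskedastic Gaussian measurement noise on each milk weight, floored at
zero. Every lactation's generating parameters are recorded in a truth
table so parameter-recovery and power experiments can score themselves.

Setting all herd-effect multipliers to zero gives exchangeable "null"
herds — the configuration used to calibrate the divergence score, whose
per-group expectation is then (n_herds - 1) * 0.05. Per-herd mean shifts
and post-DIM step effects can be injected for power and residual tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import P1, P2PLUS, _POPULATION_TABLE, Lactation, TestDay
from .model import MilkBotParams, predict

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "sample_parameters",
    "sample_schedule",
    "simulate_lactation",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("scale", "ramp", "offset", "decay")


def _default_population():
    return {
        parity: {
            "mean": row["mean"],
            "sd": tuple(row["sd"]),
            "noise_sd": row["rmse"],
        }
        for parity, row in _POPULATION_TABLE.items()
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-structure and magnitude settings for cohort simulation.

    Defaults reproduce the reference design: 21 herds x 2 parity groups
    x 50 lactations, monthly tests (30 +/- 3 d jitter, first test uniform
    on 5-35 DIM) capped at 305 DIM with at least 7 tests, population
    parameter means/SDs per parity at the published survey values, and
    noise SDs of 3.7 (P1) / 4.65 (P2+) kg — the scale of typical fitted
    RMSE. ``herd_sd_multiplier`` expresses between-herd SD per parameter
    as a multiple of the within-group SD (0.5 by default; 0 gives
    exchangeable null herds).
    """

    n_herds: int = 21
    n_per_group: int = 50
    parities: tuple[str, ...] = (P1, P2PLUS)
    population: dict = field(default_factory=_default_population)
    herd_sd_multiplier: dict = field(
        default_factory=lambda: {n: 0.5 for n in _PARAM_NAMES}
    )
    first_test_dim: tuple[float, float] = (5.0, 35.0)
    test_interval: float = 30.0  # days
    interval_jitter: float = 3.0  # uniform +/- days
    max_dim: float = 305.0
    min_tests: int = 7
    seed: int = 0
    # optional experiment hooks
    herd_shifts: dict = field(default_factory=dict)  # (herd_id, parity, param) -> delta
    step_effect: tuple[float, float] | None = None  # (dim_threshold, delta kg/day)
    param_correlation: object = None  # 4x4 correlation matrix for cow deviations

    def __post_init__(self):
        if self.n_per_group < 1 or self.n_herds < 1:
            raise ValueError("n_herds and n_per_group must be >= 1")
        for parity, row in self.population.items():
            if any(s < 0 for s in row["sd"]) or row["noise_sd"] < 0:
                raise ValueError(f"negative SD in population row {parity!r}")
        # best-case schedule must be able to reach min_tests
        lo = self.first_test_dim[0]
        step = max(self.test_interval - self.interval_jitter, 1e-6)
        if 1 + np.floor((self.max_dim - lo) / step) < self.min_tests:
            raise ValueError(
                "infeasible schedule: test_interval too long to ever "
                f"reach min_tests={self.min_tests} by {self.max_dim} DIM"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated lactations plus the generating-truth table."""

    lactations: tuple[Lactation, ...]
    truth: pd.DataFrame  # one row per lactation: generating params + effects
    config: GeneratorConfig


def _herd_effects(rng: np.random.Generator, config: GeneratorConfig, parity: str):
    """Additive herd-level deviations of the four parameter means."""
    sds = config.population[parity]["sd"]
    mult = config.herd_sd_multiplier
    return np.array(
        [rng.normal(0.0, mult.get(n, 0.0) * s) if mult.get(n, 0.0) * s > 0 else 0.0
         for n, s in zip(_PARAM_NAMES, sds)]
    )


def sample_parameters(
    rng: np.random.Generator,
    config: GeneratorConfig,
    herd_effect: np.ndarray,
    parity: str,
    shift: np.ndarray | None = None,
    max_resample: int = 1000,
) -> MilkBotParams:
    """Draw one cow's parameters: population mean + herd effect + deviation.

    Cow deviations are Gaussian with the within-group SDs (optionally
    correlated via ``config.param_correlation``) and the draw is resampled
    until scale > 0, ramp > 0 and decay > 0 (truncation to the model's
    sign constraints).
    """
    row = config.population[parity]
    mean = np.array(row["mean"].as_tuple()) + herd_effect
    if shift is not None:
        mean = mean + shift
    sds = np.array(row["sd"], dtype=float)
    corr = config.param_correlation
    cov = None
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        cov = corr * np.outer(sds, sds)
    for _ in range(max_resample):
        if cov is not None:
            draw = rng.multivariate_normal(mean, cov, method="cholesky")
        else:
            draw = mean + rng.normal(0.0, 1.0, 4) * sds
        a, b, c, d = draw
        if a > 0 and b > 0 and d > 0:
            return MilkBotParams(a, b, c, d)
    raise ValueError(
        "could not draw sign-valid parameters after "
        f"{max_resample} attempts; population SDs are implausibly large"
    )


def sample_schedule(
    rng: np.random.Generator, config: GeneratorConfig, max_regen: int = 1000
) -> np.ndarray:
    """Monthly-style DIM schedule: first test uniform in ``first_test_dim``,
    then steps of ``test_interval`` +/- uniform jitter, truncated at
    ``max_dim``. Schedules shorter than ``min_tests`` are regenerated
    (count logged)."""
    n_regen = 0
    for _ in range(max_regen):
        dims = [rng.uniform(*config.first_test_dim)]
        while True:
            step = config.test_interval + rng.uniform(
                -config.interval_jitter, config.interval_jitter
            )
            nxt = dims[-1] + max(step, 1.0)
            if nxt > config.max_dim:
                break
            dims.append(nxt)
        if len(dims) >= config.min_tests:
            if n_regen:
                logger.debug("regenerated %d short schedules", n_regen)
            return np.array(dims)
        n_regen += 1
    raise ValueError("schedule regeneration failed; config likely infeasible")


def simulate_lactation(
    params: MilkBotParams,
    schedule: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    lactation_id: str = "sim",
    herd_id: str = "H0",
    parity_group: str = P1,
    step_effect: tuple[float, float] | None = None,
) -> tuple[Lactation, int]:
    """Noisy test-day observations from known parameters.

    milk_i = predict(params, dim_i) [+ step delta past its DIM threshold]
    + N(0, noise_sd), floored at 0. Returns the lactation and the count
    of floored (negative -> 0) values.
    """
    y = predict(params, schedule)
    if step_effect is not None:
        thr, delta = step_effect
        y = y + np.where(schedule > thr, delta, 0.0)
    milk = y + rng.normal(0.0, noise_sd, size=len(schedule))
    n_floored = int(np.sum(milk < 0))
    if n_floored:
        logger.debug("floored %d negative milk weights at 0", n_floored)
    milk = np.maximum(milk, 0.0)
    lact = Lactation(
        lactation_id=lactation_id,
        herd_id=herd_id,
        parity_group=parity_group,
        tests=tuple(TestDay(float(t), float(m)) for t, m in zip(schedule, milk)),
    )
    return lact, n_floored


def simulate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Full herd x parity x cow cohort, reproducible from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    lactations: list[Lactation] = []
    truth_rows = []
    for h in range(config.n_herds):
        herd_id = f"H{h + 1:02d}"
        for parity in config.parities:
            effect = _herd_effects(rng, config, parity)
            shift_key = [
                config.herd_shifts.get((herd_id, parity, n), 0.0)
                for n in _PARAM_NAMES
            ]
            shift = np.array(shift_key) if any(shift_key) else None
            noise_sd = config.population[parity]["noise_sd"]
            for i in range(config.n_per_group):
                lid = f"{herd_id}-{parity}-{i + 1:03d}"
                params = sample_parameters(rng, config, effect, parity, shift)
                schedule = sample_schedule(rng, config)
                lact, n_floored = simulate_lactation(
                    params,
                    schedule,
                    noise_sd,
                    rng,
                    lactation_id=lid,
                    herd_id=herd_id,
                    parity_group=parity,
                    step_effect=config.step_effect,
                )
                lactations.append(lact)
                truth_rows.append(
                    {
                        "lactation_id": lid,
                        "herd_id": herd_id,
                        "parity_group": parity,
                        "scale": params.scale,
                        "ramp": params.ramp,
                        "offset": params.offset,
                        "decay": params.decay,
                        "noise_sd": noise_sd,
                        "n_tests": lact.n_tests,
                        "n_floored": n_floored,
                        "step_threshold": (
                            config.step_effect[0] if config.step_effect else np.nan
                        ),
                        "step_delta": (
                            config.step_effect[1] if config.step_effect else np.nan
                        ),
                    }
                )
    return SyntheticCohort(
        lactations=tuple(lactations),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )
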