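"""Fitting MilkBot parameters to test-day milk records.

Two engines share one Levenberg-Marquardt core:

* :func:`fit_least_squares` — plain nonlinear least squares. Positivity of
  scale, ramp and decay is enforced by optimizing their logarithms
  (offset stays in natural scale), so the LM steps are unconstrained and
  smooth.
* :func:`fit_map` — maximum a posteriori with independent Gaussian priors
  on the natural parameters and Gaussian residuals of fixed standard
  deviation. With zero observations it returns the prior means; as test
  days accumulate the solution moves from the prior toward the pure
  least-squares fit, which it matches in the flat-prior limit.

Monthly DHIA-style data cannot identify the offset parameter, so the
default policy fixes offset at 0; it can be freed or fixed elsewhere via
:class:`FitConfig` / :class:`PriorSpec`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares as _scipy_least_squares

from .model import MilkBotParams, peak_day, predict

__all__ = [
    "TestDay",
    "Lactation",
    "PriorSpec",
    "FitConfig",
    "FitResult",
    "FilterLog",
    "IdentifiabilityError",
    "fit_least_squares",
    "fit_map",
    "compute_rmse",
    "predict_residuals",
    "apply_study_filters",
    "normalize_parity",
    "POPULATION_PRIORS",
    "P1",
    "P2PLUS",
]

logger = logging.getLogger(__name__)

P1 = "P1"
P2PLUS = "P2plus"


def normalize_parity(value) -> str:
    """Map parity labels/numbers onto the two study groups P1 / P2plus.

    First lactations ("1", "P1", 1) form P1; every later parity
    ("2+", "2plus", any integer >= 2) is pooled into P2plus.
    """
    s = str(value).strip().lower()
    if s in {"1", "p1", "1.0"}:
        return P1
    if s in {"2+", "2plus", "p2+", "p2plus", "p2"}:
        return P2PLUS
    try:
        n = float(s)
    except ValueError:
        raise ValueError(f"unrecognized parity group {value!r}") from None
    if n >= 2:
        return P2PLUS
    if n == 1:
        return P1
    raise ValueError(f"unrecognized parity group {value!r}")


@dataclass(frozen=True)
class TestDay:
    """One milk weight: days in milk and daily yield (kg/day)."""

    dim: float
    milk: float

    def __post_init__(self):
        if not (math.isfinite(self.dim) and 1 <= self.dim <= 999):
            raise ValueError(f"dim must be in [1, 999], got {self.dim}")
        if not (math.isfinite(self.milk) and self.milk >= 0):
            raise ValueError(f"milk must be finite and >= 0, got {self.milk}")


TestDay.__test__ = False  # keep pytest from collecting the domain class


@dataclass(frozen=True)
class Lactation:
    """An identified, DIM-ordered sequence of test-day observations."""

    lactation_id: str
    herd_id: str
    parity_group: str
    tests: tuple[TestDay, ...]

    def __post_init__(self):
        object.__setattr__(self, "parity_group", normalize_parity(self.parity_group))
        object.__setattr__(self, "tests", tuple(self.tests))
        dims = [td.dim for td in self.tests]
        if any(b <= a for a, b in zip(dims, dims[1:])):
            raise ValueError(
                f"lactation {self.lactation_id}: test days must be strictly "
                "increasing in DIM"
            )

    @property
    def dims(self) -> np.ndarray:
        return np.array([td.dim for td in self.tests], dtype=float)

    @property
    def milks(self) -> np.ndarray:
        return np.array([td.milk for td in self.tests], dtype=float)

    @property
    def n_tests(self) -> int:
        return len(self.tests)


# Population-level parameter distributions (means and within-group SDs) for
# Holstein-dominated US DHIA herds, by parity group. These anchor the default
# MAP priors and the synthetic cohort generator.
_POPULATION_TABLE = {
    P1: {
        "mean": MilkBotParams(scale=38.66, ramp=31.43, offset=-0.5, decay=0.000974),
        "sd": (5.87, 2.67, 0.0, 0.000605),
        "rmse": 3.7,
    },
    P2PLUS: {
        "mean": MilkBotParams(scale=53.65, ramp=26.13, offset=-0.37, decay=0.002213),
        "sd": (9.3, 7.66, 0.39, 0.000858),
        "rmse": 4.65,
    },
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors for MAP fitting.

    ``offset_sd = 0`` means the offset is held fixed at its prior mean
    (the monthly-data convention); the other prior SDs must be positive.
    ``residual_sd`` is the Gaussian measurement-noise scale in kg/day.
    """

    mean: MilkBotParams
    scale_sd: float
    ramp_sd: float
    offset_sd: float
    decay_sd: float
    residual_sd: float = 4.0
    offset_policy: str = "free"  # free | fixed_zero | fixed_value
    offset_value: float = 0.0

    def __post_init__(self):
        for name in ("scale_sd", "ramp_sd", "decay_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.offset_sd < 0:
            raise ValueError("offset_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.offset_policy not in {"free", "fixed_zero", "fixed_value"}:
            raise ValueError(f"unknown offset_policy {self.offset_policy!r}")

    @classmethod
    def for_parity(cls, parity_group: str, **overrides) -> "PriorSpec":
        """Default population prior for a parity group (P1 or P2plus)."""
        row = _POPULATION_TABLE[normalize_parity(parity_group)]
        sds = row["sd"]
        kw = dict(
            mean=row["mean"],
            scale_sd=sds[0],
            ramp_sd=sds[1],
            offset_sd=sds[2],
            decay_sd=sds[3],
            residual_sd=4.0,
            offset_policy="free" if sds[2] > 0 else "fixed_value",
            offset_value=row["mean"].offset,
        )
        kw.update(overrides)
        return cls(**kw)


POPULATION_PRIORS = {p: PriorSpec.for_parity(p) for p in (P1, P2PLUS)}


@dataclass(frozen=True)
class FitConfig:
    """Configuration shared by both fitting engines.

    offset_policy: "fixed_zero" (default — monthly data cannot identify
    offset), "free", or "fixed_value" with ``offset_value``.
    """

    offset_policy: str = "fixed_zero"
    offset_value: float = 0.0
    init_scale_factor: float = 1.1  # scale0 = factor * max observed milk
    init_ramp: float = 25.0  # days
    init_decay: float = 0.002  # 1/day
    init_offset: float = 0.0  # days (free-offset start)
    tol: float = 1e-10  # relative objective-change convergence tolerance
    max_iter: int = 200

    def __post_init__(self):
        if self.offset_policy not in {"fixed_zero", "free", "fixed_value"}:
            raise ValueError(f"unknown offset_policy {self.offset_policy!r}")


DEFAULT_CONFIG = FitConfig()


@dataclass(frozen=True)
class FitResult:
    """A fitted lactation: parameters, fit error, and diagnostics."""

    params: MilkBotParams
    rmse: float  # kg/day, divisor n
    residuals: tuple[float, ...]  # observed - predicted, DIM order
    n_tests: int
    engine: str  # "least_squares" | "map"
    converged: bool
    n_iter: int
    diagnostics: tuple[str, ...] = ()
    lactation_id: str = ""
    herd_id: str = ""
    parity_group: str = ""

    @property
    def residual_mean(self) -> float:
        return float(np.mean(self.residuals)) if self.residuals else float("nan")


class IdentifiabilityError(ValueError):
    """Too few test days to identify the free parameters."""


# ---------------------------------------------------------------------------
# Residual/RMSE utilities
# ---------------------------------------------------------------------------

def predict_residuals(lact: Lactation, params: MilkBotParams) -> np.ndarray:
    """Per-test residuals observed - predicted (kg/day), in DIM order."""
    if lact.n_tests < 1:
        raise ValueError("lactation has no tests")
    return lact.milks - predict(params, lact.dims)


def compute_rmse(lact: Lactation, params: MilkBotParams) -> float:
    """Root-mean-square residual (kg/day) with divisor n (no df correction)."""
    r = predict_residuals(lact, params)
    return float(np.sqrt(np.mean(r * r)))


# ---------------------------------------------------------------------------
# Study filters
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    """Exclusion accounting for :func:`apply_study_filters`."""

    n_input: int = 0
    n_retained: int = 0
    n_tests_dropped: int = 0  # test days past the DIM cap
    n_lactations_rejected: int = 0  # too few tests after truncation
    rejected_ids: list = field(default_factory=list)


def apply_study_filters(
    lactations, *, max_dim: float = 305.0, min_tests: int = 7
) -> tuple[list[Lactation], FilterLog]:
    """Standard study filters, applied in order.

    First every test day past ``max_dim`` DIM is dropped, then any
    lactation left with fewer than ``min_tests`` tests is rejected.
    The order matters: late tests cannot rescue a short lactation.
    """
    log = FilterLog()
    kept: list[Lactation] = []
    for lact in lactations:
        log.n_input += 1
        tests = tuple(td for td in lact.tests if td.dim <= max_dim)
        log.n_tests_dropped += lact.n_tests - len(tests)
        if len(tests) < min_tests:
            log.n_lactations_rejected += 1
            log.rejected_ids.append(lact.lactation_id)
            continue
        kept.append(replace(lact, tests=tests) if len(tests) != lact.n_tests else lact)
    log.n_retained = len(kept)
    return kept, log


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core (shared by LS and MAP)
# ---------------------------------------------------------------------------
# Optimizer vector x = [log scale, log ramp, (offset), log decay]; offset is
# present only under the "free" policy. Log-reparameterization keeps the sign
# constraints without bounds, so MINPACK's LM can be used directly.

def _unpack(x: np.ndarray, free_offset: bool, fixed_offset: float):
    if free_offset:
        la, lb, c, ld = x
    else:
        la, lb, ld = x
        c = fixed_offset
    # clip log-parameters so exp stays finite and nonzero even when LM
    # probes a boundary (e.g. ramp -> 0); keeps the Jacobian NaN-free
    la, lb, ld = (min(max(v, -600.0), 600.0) for v in (la, lb, ld))
    return math.exp(la), math.exp(lb), c, math.exp(ld)


def _pack(params: MilkBotParams, free_offset: bool) -> np.ndarray:
    logs = [math.log(params.scale), math.log(params.ramp)]
    if free_offset:
        return np.array(logs + [params.offset, math.log(params.decay)])
    return np.array(logs + [math.log(params.decay)])


def _model_and_jac(x, dim, free_offset, fixed_offset):
    """Predicted milk and its Jacobian w.r.t. the optimizer vector."""
    a, b, c, d = _unpack(x, free_offset, fixed_offset)
    u = np.exp(np.clip((c - dim) / b, -700.0, 700.0))
    g = 1.0 - u / 2.0
    h = np.exp(np.clip(-d * dim, -700.0, 700.0))
    y = a * g * h
    # Natural-parameter partials chained onto log coordinates.
    dy_dloga = y
    dy_dlogb = -a * h * u * (dim - c) / (2.0 * b)
    dy_dlogd = -dim * y * d
    if free_offset:
        dy_dc = -a * h * u / (2.0 * b)
        J = np.column_stack([dy_dloga, dy_dlogb, dy_dc, dy_dlogd])
    else:
        J = np.column_stack([dy_dloga, dy_dlogb, dy_dlogd])
    return y, J


# Plausibility bounds on the natural parameters, used by the robust (trf)
# fallback solver and to flag boundary-pinned solutions.
_NAT_BOUNDS = {"scale": (1e-3, 1e4), "ramp": (1e-2, 1e3), "decay": (1e-8, 1.0)}
_OFFSET_BOUNDS = (-305.0, 305.0)


def _log_bounds(free_offset: bool):
    lo = [math.log(_NAT_BOUNDS["scale"][0]), math.log(_NAT_BOUNDS["ramp"][0])]
    hi = [math.log(_NAT_BOUNDS["scale"][1]), math.log(_NAT_BOUNDS["ramp"][1])]
    if free_offset:
        lo.append(_OFFSET_BOUNDS[0])
        hi.append(_OFFSET_BOUNDS[1])
    lo.append(math.log(_NAT_BOUNDS["decay"][0]))
    hi.append(math.log(_NAT_BOUNDS["decay"][1]))
    return np.array(lo), np.array(hi)


def _run_lm(residual_fun, jac_fun, x0, config: FitConfig, robust: bool = False,
            free_offset: bool = False):
    """One solver run: fast unconstrained LM, or bounded trust-region.

    The LM path is the workhorse; the bounded trust-region path is the
    fallback for degenerate data that drives a parameter toward a
    boundary (e.g. ramp -> 0), where LM's autoscaling can stall on an
    exactly flat direction.
    """
    if robust:
        lo, hi = _log_bounds(free_offset)
        return _scipy_least_squares(
            residual_fun,
            np.clip(x0, lo + 1e-9, hi - 1e-9),
            jac=jac_fun,
            method="trf",
            bounds=(lo, hi),
            x_scale="jac",
            ftol=config.tol,
            xtol=config.tol,
            gtol=config.tol,
            max_nfev=config.max_iter * (len(x0) + 1),
        )
    # Short evaluation budget on purpose: well-posed fits converge in ~20
    # evaluations; fits walking a parameter to a boundary burn the budget,
    # come back flagged, and are finished by the bounded solver instead.
    return _scipy_least_squares(
        residual_fun,
        x0,
        jac=jac_fun,
        method="lm",
        ftol=config.tol,
        xtol=config.tol,
        gtol=config.tol,
        max_nfev=min(config.max_iter * (len(x0) + 1), 80),
    )


def _boundary_active(params: MilkBotParams) -> bool:
    for name, (lo, hi) in _NAT_BOUNDS.items():
        v = getattr(params, name)
        if v <= lo * math.e or v >= hi / math.e:
            return True
    return False


def _diagnostics_for(params: MilkBotParams, dim: np.ndarray) -> tuple[str, ...]:
    flags = []
    try:
        if peak_day(params) < 1.0:
            flags.append("pre_parturition_peak")
    except ValueError:
        flags.append("no_interior_peak")
    if params.decay < 1e-7:
        flags.append("decay_near_zero")
    if _boundary_active(params):
        flags.append("boundary_active")
    if np.any(np.abs((params.offset - dim) / params.ramp) > 700.0) or np.any(
        params.decay * dim > 700.0
    ):
        flags.append("clamped_exponent")
    return tuple(flags)


def _starts(lact: Lactation, config: FitConfig, free_offset: bool):
    """Initial guesses: data-driven default plus population fallbacks."""
    milk_max = max(float(lact.milks.max()), 1e-3)
    primary = MilkBotParams(
        scale=config.init_scale_factor * milk_max,
        ramp=config.init_ramp,
        offset=config.init_offset,
        decay=config.init_decay,
    )
    fallbacks = [_POPULATION_TABLE[p]["mean"] for p in (P1, P2PLUS)]
    return [primary] + fallbacks


def fit_least_squares(
    lact: Lactation, config: FitConfig = DEFAULT_CONFIG
) -> FitResult:
    """Fit one lactation by Levenberg-Marquardt least squares.

    Minimizes the sum of squared residuals over the sign-constrained
    parameter space (log-reparameterized, so effectively unconstrained
    LM). Deterministic for a given lactation and config. If the first
    start ends worse than the best constant curve, population-mean
    starts are tried and the best solution kept. Non-convergence is
    reported through ``converged``/``diagnostics``, not an exception.
    """
    free_offset = config.offset_policy == "free"
    fixed_offset = 0.0 if config.offset_policy == "fixed_zero" else config.offset_value
    n_params = 4 if free_offset else 3
    if lact.n_tests < n_params:
        raise IdentifiabilityError(
            f"lactation {lact.lactation_id}: {lact.n_tests} tests cannot "
            f"identify {n_params} free parameters; use fit_map with a prior"
        )
    dim, milk = lact.dims, lact.milks

    def residual(x):
        y, _ = _model_and_jac(x, dim, free_offset, fixed_offset)
        return milk - y

    def jac(x):
        _, J = _model_and_jac(x, dim, free_offset, fixed_offset)
        return -J

    best = None
    const_sse = float(np.sum((milk - milk.mean()) ** 2))

    def _suspicious(res):
        params = MilkBotParams(*_unpack(res.x, free_offset, fixed_offset))
        return (
            res.status <= 0
            or 2.0 * res.cost > const_sse + 1e-9
            or _boundary_active(params)
        )

    for start in _starts(lact, config, free_offset):
        start = replace(start, offset=config.init_offset if free_offset else fixed_offset)
        res = _run_lm(residual, jac, _pack(start, free_offset), config)
        if _suspicious(res):
            # degenerate or stalled: retry with the bounded robust solver
            res_r = _run_lm(
                residual, jac, _pack(start, free_offset), config,
                robust=True, free_offset=free_offset,
            )
            if res_r.cost < res.cost:
                res = res_r
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, res)
        # extra starts only needed while we do worse than a flat line
        if best[0] <= const_sse + 1e-9:
            break
    sse, res = best
    if sse > const_sse * (1.0 + 1e-6) + 1e-6:
        logger.warning(
            "lactation %s: fit worse than best constant curve", lact.lactation_id
        )
    a, b, c, d = _unpack(res.x, free_offset, fixed_offset)
    params = MilkBotParams(a, b, c, d)
    residuals = milk - predict(params, dim)
    return FitResult(
        params=params,
        rmse=float(np.sqrt(np.mean(residuals**2))),
        residuals=tuple(float(r) for r in residuals),
        n_tests=lact.n_tests,
        engine="least_squares",
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
        diagnostics=_diagnostics_for(params, dim)
        + (() if res.status > 0 else ("not_converged",)),
        lactation_id=lact.lactation_id,
        herd_id=lact.herd_id,
        parity_group=lact.parity_group,
    )


def fit_map(
    lact: Lactation, prior: PriorSpec, config: FitConfig | None = None
) -> FitResult:
    """Fit one lactation by MAP with Gaussian priors.

    Maximizes the Gaussian log-likelihood (residual SD from the prior
    spec) plus independent Gaussian log-priors on the natural
    parameters. With zero test days the optimum is exactly the prior
    mean vector, which is returned directly; as data accumulate the
    solution leaves the prior means, and in the flat-prior limit it
    coincides with :func:`fit_least_squares`. Accepts any number of
    tests, including fewer than the free-parameter count.
    """
    if config is None:
        offset_policy = prior.offset_policy
        if prior.offset_sd == 0 and offset_policy == "free":
            offset_policy = "fixed_value"
        config = FitConfig(
            offset_policy=offset_policy,
            offset_value=(
                0.0 if offset_policy == "fixed_zero"
                else (prior.offset_value if prior.offset_policy == "fixed_value"
                      else prior.mean.offset)
            ),
        )
    free_offset = config.offset_policy == "free"
    if free_offset and prior.offset_sd == 0:
        raise ValueError("offset_sd = 0 requires a fixed offset policy")
    fixed_offset = 0.0 if config.offset_policy == "fixed_zero" else config.offset_value

    mean = prior.mean
    if lact.n_tests == 0:
        params = (
            mean if free_offset else replace(mean, offset=fixed_offset)
        )
        return FitResult(
            params=params,
            rmse=float("nan"),
            residuals=(),
            n_tests=0,
            engine="map",
            converged=True,
            n_iter=0,
            diagnostics=("no_data_prior_mean",),
            lactation_id=lact.lactation_id,
            herd_id=lact.herd_id,
            parity_group=lact.parity_group,
        )

    dim, milk = lact.dims, lact.milks
    sd_data = prior.residual_sd
    prior_sds = [prior.scale_sd, prior.ramp_sd] + (
        [prior.offset_sd] if free_offset else []
    ) + [prior.decay_sd]
    prior_sds = np.array(prior_sds)
    prior_means = [mean.scale, mean.ramp] + ([mean.offset] if free_offset else []) + [
        mean.decay
    ]
    prior_means = np.array(prior_means)

    def natural(x):
        a, b, c, d = _unpack(x, free_offset, fixed_offset)
        return np.array([a, b] + ([c] if free_offset else []) + [d])

    def residual(x):
        y, _ = _model_and_jac(x, dim, free_offset, fixed_offset)
        return np.concatenate([(milk - y) / sd_data, (natural(x) - prior_means) / prior_sds])

    def jac(x):
        _, J = _model_and_jac(x, dim, free_offset, fixed_offset)
        nat = natural(x)
        # d(natural)/d(optimizer coord): exp-params scale by their value,
        # offset coordinate is identity.
        dnat = np.diag(nat) if not free_offset else np.diag([nat[0], nat[1], 1.0, nat[3]])
        return np.vstack([-J / sd_data, dnat / prior_sds[:, None]])

    start = replace(
        mean, offset=mean.offset if free_offset else fixed_offset
    )
    res = _run_lm(residual, jac, _pack(start, free_offset), config)
    if res.status <= 0 or _boundary_active(
        MilkBotParams(*_unpack(res.x, free_offset, fixed_offset))
    ):
        res_r = _run_lm(
            residual, jac, _pack(start, free_offset), config,
            robust=True, free_offset=free_offset,
        )
        if res_r.cost < res.cost:
            res = res_r
    a, b, c, d = _unpack(res.x, free_offset, fixed_offset)
    params = MilkBotParams(a, b, c, d)
    residuals = milk - predict(params, dim)
    return FitResult(
        params=params,
        rmse=float(np.sqrt(np.mean(residuals**2))),
        residuals=tuple(float(r) for r in residuals),
        n_tests=lact.n_tests,
        engine="map",
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
        diagnostics=_diagnostics_for(params, dim)
        + (() if res.status > 0 else ("not_converged",)),
        lactation_id=lact.lactation_id,
        herd_id=lact.herd_id,
        parity_group=lact.parity_group,
    )
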