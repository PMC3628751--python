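"""Group-level summaries and inter-group comparison statistics.

Fitted lactations are grouped by (herd, parity group); each group is
summarized per metric (mean, SD, quartiles, range, a Z-based 95% CI),
groups of matching parity are compared pairwise by two-sided Z-test, and
each group receives a *divergence score*: the number of same-parity peer
groups whose mean differs at p < .05. With G groups per parity the score
ranges 0..G-1 and its expectation under identical groups is
(G-1) * 0.05 — one for the 21-herd design — which is the built-in null
calibration; no multiple-testing correction is applied, deliberately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import model
from .fitting import FitResult

__all__ = [
    "METRICS",
    "GroupKey",
    "GroupSummary",
    "DivergenceResult",
    "summarize_group",
    "z_test",
    "divergence_scores",
    "null_divergence_replicates",
    "build_metric_table",
    "summarize_groups",
    "summary_table",
    "group_boxstats",
]

logger = logging.getLogger(__name__)

#: The per-lactation metrics summarized and compared between groups.
METRICS = ("scale", "ramp", "offset", "decay", "rmse", "m305", "peak_day", "peak_milk")


class GroupKey(NamedTuple):
    herd_id: str
    parity_group: str


@dataclass(frozen=True)
class GroupSummary:
    """Box-whisker-style summary of one metric in one group."""

    n: int
    mean: float
    sd: float  # n-1 divisor
    q1: float
    median: float
    q3: float
    minimum: float
    maximum: float
    ci95_half_width: float  # 1.96 * sd / sqrt(n)


@dataclass(frozen=True)
class DivergenceResult:
    """Divergence scores and the pairwise p-value matrices, per parity."""

    metric: str
    scores: dict  # GroupKey -> int
    p_matrix: dict  # parity -> pd.DataFrame (herd x herd, symmetric)
    mean_score: dict  # parity -> float


def summarize_group(values) -> GroupSummary:
    """Summary statistics for one metric vector (n >= 2).

    Quartiles use linear interpolation between order statistics (numpy's
    default convention); the 95% CI half-width is the Z-based
    ``1.96 * sd / sqrt(n)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 values, got {v.size}")
    sd = float(np.std(v, ddof=1))
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return GroupSummary(
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=sd,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        minimum=float(v.min()),
        maximum=float(v.max()),
        ci95_half_width=1.96 * sd / np.sqrt(v.size),
    )


def z_test(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Two-sample Z-test on summary statistics (unpooled variance).

    ``z = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2)`` with a standard
    normal reference, two-sided p. Degenerate zero-variance pairs: equal
    means give (0, 1) by convention, unequal means give p = 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("z_test requires n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    se = np.sqrt(sd1**2 / n1 + sd2**2 / n2)
    if se == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        logger.warning("z_test: zero variance with unequal means; p = 0")
        return float(np.sign(mean1 - mean2) * np.inf), 0.0
    z = (mean1 - mean2) / se
    return float(z), float(2.0 * _stats.norm.sf(abs(z)))


def divergence_scores(
    groups: Mapping[GroupKey, GroupSummary],
    metric: str,
    alpha: float = 0.05,
) -> DivergenceResult:
    """Count, per group, the same-parity peers that differ at p < alpha."""
    by_parity: dict[str, list[GroupKey]] = {}
    for key in groups:
        by_parity.setdefault(key.parity_group, []).append(key)
    scores: dict[GroupKey, int] = {}
    p_mats: dict[str, pd.DataFrame] = {}
    means: dict[str, float] = {}
    for parity, keys in by_parity.items():
        if len(keys) < 2:
            raise ValueError(f"parity stratum {parity!r} has a single group")
        keys = sorted(keys)
        herds = [k.herd_id for k in keys]
        mean = np.array([groups[k].mean for k in keys])
        var_n = np.array([groups[k].sd ** 2 / groups[k].n for k in keys])
        # vectorized pairwise unpooled Z-tests (identical to z_test)
        se = np.sqrt(var_n[:, None] + var_n[None, :])
        diff = mean[:, None] - mean[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
            p = 2.0 * _stats.norm.sf(np.abs(z))
        p = np.where((se == 0) & (diff != 0), 0.0, p)
        np.fill_diagonal(p, 1.0)
        if np.any((se == 0) & (diff != 0)):
            logger.warning("z_test: zero variance with unequal means; p = 0")
        counts = np.sum(p < alpha, axis=1)
        for ki, c in zip(keys, counts):
            scores[ki] = int(c)
        p_mats[parity] = pd.DataFrame(p, index=herds, columns=herds)
        means[parity] = float(np.mean(counts))
    return DivergenceResult(metric=metric, scores=scores, p_matrix=p_mats, mean_score=means)


def null_divergence_replicates(
    n_replicates: int,
    seed: int,
    *,
    n_herds: int = 21,
    n_per_group: int = 50,
    parity: str = "P1",
    metric: str = "scale",
) -> np.ndarray:
    """Monte-Carlo null calibration of the divergence score.

    Each replicate simulates ``n_herds`` herds of ``n_per_group``
    lactations from one identical parameter distribution (no herd
    effects), fits every lactation by least squares with offset fixed at
    0, and averages the groups' divergence scores for ``metric``. Under
    this exchangeable null the expected mean score is ~(n_herds-1)*0.05.
    Returns the per-replicate mean scores.
    """
    from .fitting import fit_least_squares
    from .simulate import GeneratorConfig, simulate_cohort

    null_mult = {k: 0.0 for k in ("scale", "ramp", "offset", "decay")}
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = GeneratorConfig(
            n_herds=n_herds,
            n_per_group=n_per_group,
            parities=(parity,),
            herd_sd_multiplier=null_mult,
            seed=int((seed + 1000003 * r) % 2**31),
        )
        cohort = simulate_cohort(cfg)
        by_herd: dict[str, list[float]] = {}
        for lact in cohort.lactations:
            fr = fit_least_squares(lact)
            by_herd.setdefault(fr.herd_id, []).append(getattr(fr.params, metric))
        summaries = {
            GroupKey(h, parity): summarize_group(v) for h, v in by_herd.items()
        }
        div = divergence_scores(summaries, metric)
        out[r] = div.mean_score[parity]
    return out


def build_metric_table(fits: Iterable[FitResult]) -> pd.DataFrame:
    """One row per fitted lactation with the eight comparison metrics.

    Derived metrics (m305, peak day, peak milk) are computed in closed
    form from the fitted parameters. Rows from unconverged fits are kept
    but flagged, and excluded from group summaries by default.
    """
    rows = []
    for fr in fits:
        p = fr.params
        try:
            tp, yp = model.peak_day(p), model.peak_milk(p)
        except ValueError:  # decay pinned at ~0: no interior peak
            tp, yp = float("nan"), float("nan")
        rows.append(
            {
                "lactation_id": fr.lactation_id,
                "herd_id": fr.herd_id,
                "parity_group": fr.parity_group,
                "scale": p.scale,
                "ramp": p.ramp,
                "offset": p.offset,
                "decay": p.decay,
                "rmse": fr.rmse,
                "m305": model.m305(p),
                "peak_day": tp,
                "peak_milk": yp,
                "converged": fr.converged,
                "flags": ";".join(fr.diagnostics),
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(
    table: pd.DataFrame, *, include_unconverged: bool = False
) -> dict[GroupKey, dict[str, GroupSummary]]:
    """Per-(herd, parity) summaries of every metric column."""
    t = table if include_unconverged else table[table["converged"]]
    n_dropped = len(table) - len(t)
    if n_dropped:
        logger.info("excluding %d unconverged fits from group summaries", n_dropped)
    out: dict[GroupKey, dict[str, GroupSummary]] = {}
    for (herd, parity), sub in t.groupby(["herd_id", "parity_group"], sort=True):
        out[GroupKey(str(herd), str(parity))] = {
            m: summarize_group(sub[m].to_numpy()) for m in METRICS
        }
    return out


def summary_table(
    summaries: Mapping[GroupKey, Mapping[str, GroupSummary]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Population overview: per metric and parity, the mean of group means,
    mean of group SDs, and the mean divergence score."""
    rows = []
    parities = sorted({k.parity_group for k in summaries})
    for metric in METRICS:
        div = divergence_scores(
            {k: v[metric] for k, v in summaries.items()}, metric, alpha=alpha
        )
        for parity in parities:
            vals = [v[metric] for k, v in summaries.items() if k.parity_group == parity]
            rows.append(
                {
                    "metric": metric,
                    "parity_group": parity,
                    "mean_group_mean": float(np.mean([s.mean for s in vals])),
                    "mean_group_sd": float(np.mean([s.sd for s in vals])),
                    "mean_divergence_score": div.mean_score[parity],
                }
            )
    return pd.DataFrame(rows)


def group_boxstats(
    summaries: Mapping[GroupKey, Mapping[str, GroupSummary]]
) -> pd.DataFrame:
    """Flat per-group box-whisker statistics (one row per group x metric)."""
    rows = []
    for key in sorted(summaries):
        for metric in METRICS:
            s = summaries[key][metric]
            rows.append(
                {
                    "herd_id": key.herd_id,
                    "parity_group": key.parity_group,
                    "metric": metric,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "min": s.minimum,
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "max": s.maximum,
                    "ci95_half_width": s.ci95_half_width,
                }
            )
    return pd.DataFrame(rows)
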