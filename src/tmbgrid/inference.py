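"""Bayesian combination of prior and likelihood, and report-level summaries.

The posterior over true TMB is the point-wise product of a prior (flat, or a
histology-specific KDE) with the normalized binomial likelihood, renormalized
on the shared grid.  Summaries — the central credible interval, the
probability of exceeding a therapeutic threshold, the cohort percentile range
of the interval — are computed by exact summation over the grid; a seeded
sampling mode is provided for parity with Monte-Carlo implementations.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np

from .cohort import CohortTable, empirical_percentile
from .exceptions import (
    DegeneratePosteriorError,
    GridMismatchError,
    InvalidArgumentError,
)
from .grid import (
    GRID_TOL,
    AssayObservation,
    DiscreteTMBDistribution,
    binomial_likelihood,
)

__all__ = [
    "UncertaintyReport",
    "bayes_update",
    "central_interval",
    "prob_above",
    "summarize",
    "sample_distribution",
]


def bayes_update(
    prior: DiscreteTMBDistribution, likelihood: DiscreteTMBDistribution
) -> DiscreteTMBDistribution:
    """Posterior = prior x likelihood, renormalized on the shared grid.

    With a flat prior the posterior equals the likelihood point-wise.
    """
    if prior.grid != likelihood.grid:
        raise GridMismatchError(
            f"prior grid (max={prior.grid.max_tmb}, step={prior.grid.step}) does not "
            f"match likelihood grid (max={likelihood.grid.max_tmb}, "
            f"step={likelihood.grid.step})"
        )
    product = prior.probs * likelihood.probs
    total = product.sum()
    if total <= 0:
        raise DegeneratePosteriorError(
            "prior and likelihood have disjoint support on the grid; "
            "the posterior is undefined"
        )
    return DiscreteTMBDistribution.from_weights(prior.grid, product, kind="posterior")


def central_interval(
    dist: DiscreteTMBDistribution, level: float = 0.90
) -> tuple[float, float]:
    """Equal-tailed central interval on the discrete grid, in mut/Mb.

    The bounds are the smallest grid values at which the cumulative mass
    first reaches (1-level)/2 and (1+level)/2 respectively.
    """
    if not (0 < level < 1):
        raise InvalidArgumentError(f"interval level must be in (0, 1), got {level}")
    lo_target = (1 - level) / 2
    hi_target = (1 + level) / 2
    cdf = dist.cdf
    # searchsorted('left') on the nondecreasing cdf gives the first index with
    # cdf >= target; the 1e-15 guard absorbs rounding in the cumulative sum.
    i_lo = int(np.searchsorted(cdf, lo_target - 1e-15, side="left"))
    i_hi = int(np.searchsorted(cdf, hi_target - 1e-15, side="left"))
    i_hi = min(i_hi, len(cdf) - 1)
    values = dist.grid.tmb_values
    return float(values[i_lo]), float(values[i_hi])


def prob_above(dist: DiscreteTMBDistribution, threshold: float) -> float:
    """Probability that the true TMB strictly exceeds ``threshold`` (mut/Mb).

    Sums the masses at grid points strictly greater than the threshold; a
    grid point numerically equal to the threshold counts as not-greater.
    """
    if threshold < 0 or threshold > dist.grid.max_tmb + GRID_TOL:
        raise InvalidArgumentError(
            f"threshold {threshold} outside the grid range [0, {dist.grid.max_tmb}]"
        )
    return float(dist.probs[dist.grid.tmb_values > threshold + GRID_TOL].sum())


@dataclasses.dataclass(frozen=True)
class UncertaintyReport:
    """Everything a laboratory report needs about one TMB measurement.

    Serializes to a flat JSON object (:meth:`to_json`) or a one-line TSV
    (:meth:`to_tsv`); field names are fixed.  ``percentile_low`` /
    ``percentile_high`` are the cohort percentiles of the interval bounds and
    are present only when a cohort was supplied.
    """

    reported_tmb: float
    mutation_count: int
    panel_size_mb: float
    prior_kind: str  # "flat" or "histology:<label>"
    ci_level: float
    ci_low: float
    ci_high: float
    threshold: float
    p_above_threshold: float
    percentile_low: Optional[float] = None
    percentile_high: Optional[float] = None
    grid_max: float = 200.0
    grid_step: float = 0.1
    bandwidth: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.ci_high <= self.grid_max):
            raise InvalidArgumentError(
                f"interval ({self.ci_low}, {self.ci_high}) violates "
                f"0 <= low <= high <= grid max {self.grid_max}"
            )
        if not (0 <= self.p_above_threshold <= 1):
            raise InvalidArgumentError(
                f"p_above_threshold must be in [0, 1], got {self.p_above_threshold}"
            )
        if (self.percentile_low is None) != (self.percentile_high is None):
            raise InvalidArgumentError(
                "percentile_low and percentile_high must be given together"
            )
        if self.percentile_low is not None and self.percentile_low > self.percentile_high:
            raise InvalidArgumentError("percentile_low must be <= percentile_high")

    FIELDS = (
        "reported_tmb",
        "mutation_count",
        "panel_size_mb",
        "prior_kind",
        "ci_level",
        "ci_low",
        "ci_high",
        "threshold",
        "p_above_threshold",
        "percentile_low",
        "percentile_high",
        "grid_max",
        "grid_step",
        "bandwidth",
    )

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "UncertaintyReport":
        return cls(**json.loads(text))

    def to_tsv(self, header: bool = True) -> str:
        def fmt(v):
            return "" if v is None else (f"{v:.10g}" if isinstance(v, float) else str(v))

        lines = []
        if header:
            lines.append("\t".join(self.FIELDS))
        lines.append("\t".join(fmt(getattr(self, f)) for f in self.FIELDS))
        return "\n".join(lines) + "\n"


def summarize(
    obs: AssayObservation,
    prior: DiscreteTMBDistribution,
    cohort: CohortTable | None = None,
    histology: str | None = None,
    level: float = 0.90,
    threshold: float = 10.0,
    bandwidth: float | None = None,
) -> UncertaintyReport:
    """Full pipeline for one observation: likelihood, posterior, report.

    When a cohort (and histology) is given, the interval bounds are mapped
    through the histology's empirical CDF to give a percentile range.
    """
    if (cohort is None) != (histology is None):
        raise InvalidArgumentError("cohort and histology must be given together")
    likelihood = binomial_likelihood(obs, prior.grid)
    posterior = bayes_update(prior, likelihood)
    ci_low, ci_high = central_interval(posterior, level)
    p_above = prob_above(posterior, threshold)
    pct_low = pct_high = None
    if cohort is not None:
        pct_low = empirical_percentile(ci_low, cohort, histology)
        pct_high = empirical_percentile(ci_high, cohort, histology)
    prior_kind = "flat" if prior.kind == "flat" else f"histology:{histology}"
    return UncertaintyReport(
        reported_tmb=obs.reported_tmb,
        mutation_count=obs.mutation_count,
        panel_size_mb=obs.panel_size_mb,
        prior_kind=prior_kind,
        ci_level=level,
        ci_low=ci_low,
        ci_high=ci_high,
        threshold=threshold,
        p_above_threshold=p_above,
        percentile_low=pct_low,
        percentile_high=pct_high,
        grid_max=prior.grid.max_tmb,
        grid_step=prior.grid.step,
        bandwidth=bandwidth,
    )


def sample_distribution(
    dist: DiscreteTMBDistribution,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """``n`` i.i.d. draws of TMB values from the grid masses (seeded).

    Parity mode for Monte-Carlo implementations of the summaries; the
    deterministic grid sums are the canonical path.
    """
    if n < 1:
        raise InvalidArgumentError(f"number of draws must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.choice(dist.grid.tmb_values, size=n, p=dist.probs)
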