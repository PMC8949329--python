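"""Binomial sampling model for panel-based TMB measurements.

A targeted sequencing panel covers M megabases of the exome.  If somatic
mutations are independent and identically distributed across bases, the
mutation count k observed on the panel is

    k ~ Binomial(n, p),   n = round(M x 1e6) bases,   p = t x 1e-6,

where t is the unobserved true exome-wide TMB in mutations per megabase
(mut/Mb).  This module discretizes t on a uniform grid (default 0-200 mut/Mb
in steps of 0.1, i.e. 2001 points), evaluates the binomial likelihood of the
observed count at every grid point, and normalizes it into a discrete
probability distribution over plausible true TMB values.

The gamma-Poisson identity provides an analytic cross-check: under a flat
prior the posterior of t is (up to truncation at the grid maximum) a
Gamma(k+1, rate=M) density, so

    P(t > c) = P(Poisson(c x M) <= k),

which :func:`flat_prior_threshold_prob_closed_form` evaluates exactly.
"""

from __future__ import annotations

import dataclasses
import math
from functools import cached_property

import numpy as np
from scipy import stats

from .exceptions import (
    DegeneratePosteriorError,
    InvalidArgumentError,
    OutOfGridError,
)

__all__ = [
    "TMBGrid",
    "AssayObservation",
    "DiscreteTMBDistribution",
    "mutation_count_for_target",
    "binomial_likelihood",
    "flat_prior_threshold_prob_closed_form",
    "GRID_TOL",
]

#: Absolute tolerance for comparing TMB values against grid coordinates.
#: Far below the smallest sensible grid step, far above float rounding in
#: ``linspace``; a grid point numerically equal to a threshold is treated as
#: exactly at it.
GRID_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class TMBGrid:
    """Uniform grid of candidate true TMB values.

    Parameters
    ----------
    max_tmb : float, default 200.0
        Upper bound of the grid in mut/Mb.
    step : float, default 0.1
        Grid increment in mut/Mb.  ``max_tmb`` must be at least 10 steps and
        an (approximate) integer multiple of ``step``.
    """

    max_tmb: float = 200.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise InvalidArgumentError(f"grid step must be positive, got {self.step}")
        if self.max_tmb < 10 * self.step:
            raise InvalidArgumentError(
                f"grid max ({self.max_tmb}) must be at least 10 x step ({self.step})"
            )
        n_cells = self.max_tmb / self.step
        if abs(n_cells - round(n_cells)) > 1e-6:
            raise InvalidArgumentError(
                f"grid max ({self.max_tmb}) must be a multiple of step ({self.step})"
            )

    @property
    def n_points(self) -> int:
        return round(self.max_tmb / self.step) + 1

    @cached_property
    def tmb_values(self) -> np.ndarray:
        """Grid coordinates in mut/Mb: 0, step, 2*step, ..., max_tmb."""
        v = np.linspace(0.0, self.max_tmb, self.n_points)
        v.setflags(write=False)
        return v

    @cached_property
    def probabilities(self) -> np.ndarray:
        """Per-base mutation probability at each grid point (TMB x 1e-6)."""
        p = self.tmb_values * 1e-6
        p.setflags(write=False)
        return p

    def __len__(self) -> int:
        return self.n_points


@dataclasses.dataclass(frozen=True)
class AssayObservation:
    """A panel TMB measurement: panel footprint plus integer mutation count.

    ``bases_sequenced`` is ``round(panel_size_mb x 1e6)`` and ``reported_tmb``
    is ``mutation_count / panel_size_mb`` — the number a laboratory would
    print on the report.
    """

    panel_size_mb: float
    mutation_count: int

    def __post_init__(self) -> None:
        if not (self.panel_size_mb > 0):
            raise InvalidArgumentError(
                f"panel size must be positive, got {self.panel_size_mb} Mb"
            )
        if self.mutation_count != int(self.mutation_count) or self.mutation_count < 0:
            raise InvalidArgumentError(
                f"mutation count must be a nonnegative integer, got {self.mutation_count}"
            )
        object.__setattr__(self, "mutation_count", int(self.mutation_count))
        if self.mutation_count > self.bases_sequenced:
            raise InvalidArgumentError(
                f"mutation count {self.mutation_count} exceeds bases sequenced "
                f"{self.bases_sequenced}"
            )

    @property
    def bases_sequenced(self) -> int:
        return max(1, round(self.panel_size_mb * 1e6))

    @property
    def reported_tmb(self) -> float:
        return self.mutation_count / self.panel_size_mb

    @classmethod
    def from_target_tmb(cls, target_tmb: float, panel_size_mb: float) -> "AssayObservation":
        """Observation whose integer count most closely reproduces ``target_tmb``."""
        k = mutation_count_for_target(target_tmb, panel_size_mb)
        return cls(panel_size_mb=panel_size_mb, mutation_count=k)


@dataclasses.dataclass(frozen=True)
class DiscreteTMBDistribution:
    """Probability masses over a :class:`TMBGrid`.

    ``kind`` records provenance: ``"likelihood"``, ``"prior"``, ``"posterior"``
    or ``"flat"``.  Masses must be nonnegative and sum to 1 within 1e-12; use
    :meth:`from_weights` to build one from unnormalized weights.
    """

    grid: TMBGrid
    probs: np.ndarray
    kind: str

    _KINDS = ("likelihood", "prior", "posterior", "flat")

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if self.kind not in self._KINDS:
            raise InvalidArgumentError(
                f"kind must be one of {self._KINDS}, got {self.kind!r}"
            )
        if probs.shape != (len(self.grid),):
            raise InvalidArgumentError(
                f"probs length {probs.shape} does not match grid ({len(self.grid)} points)"
            )
        if np.any(probs < 0):
            raise InvalidArgumentError("probability masses must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise InvalidArgumentError(
                f"probability masses must sum to 1 within 1e-12 (got {probs.sum()!r}); "
                "use DiscreteTMBDistribution.from_weights to normalize"
            )
        probs = probs.copy()
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def from_weights(
        cls, grid: TMBGrid, weights: np.ndarray, kind: str
    ) -> "DiscreteTMBDistribution":
        """Normalize nonnegative weights into a distribution."""
        w = np.asarray(weights, dtype=float)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise DegeneratePosteriorError(
                "weights sum to zero or are non-finite; cannot normalize"
            )
        w = w / total
        # renormalize once more to absorb rounding in the division
        return cls(grid=grid, probs=w / w.sum(), kind=kind)

    @classmethod
    def flat(cls, grid: TMBGrid) -> "DiscreteTMBDistribution":
        """Uniform distribution: every grid point carries mass 1/len(grid)."""
        return cls.from_weights(grid, np.ones(len(grid)), kind="flat")

    @cached_property
    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.probs)
        c.setflags(write=False)
        return c

    def mean(self) -> float:
        """Mean TMB in mut/Mb."""
        return float(self.probs @ self.grid.tmb_values)


def mutation_count_for_target(target_tmb: float, panel_size_mb: float) -> int:
    """Integer mutation count whose implied TMB is closest to ``target_tmb``.

    Minimizes ``|k / panel_size_mb - target_tmb|`` over nonnegative integers
    k; an exact tie is resolved toward the larger count.
    """
    if not (panel_size_mb > 0):
        raise InvalidArgumentError(
            f"panel size must be positive, got {panel_size_mb} Mb"
        )
    if target_tmb < 0 or not math.isfinite(target_tmb):
        raise InvalidArgumentError(f"target TMB must be nonnegative, got {target_tmb}")
    k_lo = math.floor(target_tmb * panel_size_mb)
    k_hi = k_lo + 1
    if abs(k_hi / panel_size_mb - target_tmb) <= abs(k_lo / panel_size_mb - target_tmb):
        return k_hi
    return k_lo


def binomial_likelihood(
    obs: AssayObservation, grid: TMBGrid | None = None
) -> DiscreteTMBDistribution:
    """Normalized binomial likelihood of true TMB given an observed count.

    At each grid point t the mass is proportional to
    ``BinomialPMF(k; n=bases_sequenced, p=t x 1e-6)``, renormalized over the
    grid.  Raises :class:`OutOfGridError` if the reported TMB exceeds the
    grid maximum, where the likelihood would be badly truncated.
    """
    if grid is None:
        grid = TMBGrid()
    if obs.reported_tmb > grid.max_tmb + GRID_TOL:
        raise OutOfGridError(
            f"reported TMB {obs.reported_tmb:.6g} mut/Mb exceeds the grid maximum "
            f"of {grid.max_tmb:g} mut/Mb; enlarge the grid (max_tmb) to cover it"
        )
    pmf = stats.binom.pmf(obs.mutation_count, obs.bases_sequenced, grid.probabilities)
    return DiscreteTMBDistribution.from_weights(grid, pmf, kind="likelihood")


def flat_prior_threshold_prob_closed_form(
    mutation_count: int, panel_size_mb: float, threshold: float
) -> float:
    """Analytic P(true TMB > threshold) under a flat prior, without the grid.

    With a flat prior on the mutation rate the posterior given count k at
    panel size M (Mb) is Gamma(k+1, rate=M) in the Poisson limit, so
    ``P(T > c) = P(Poisson(c*M) <= k)``.  Used as an independent oracle for
    the grid computation.
    """
    if mutation_count < 0 or mutation_count != int(mutation_count):
        raise InvalidArgumentError(
            f"mutation count must be a nonnegative integer, got {mutation_count}"
        )
    if not (panel_size_mb > 0):
        raise InvalidArgumentError(
            f"panel size must be positive, got {panel_size_mb} Mb"
        )
    if threshold < 0:
        raise InvalidArgumentError(f"threshold must be nonnegative, got {threshold}")
    return float(stats.poisson.cdf(mutation_count, threshold * panel_size_mb))
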