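"""Model/Results interface over the grid machinery.

``TMBUncertaintyModel`` bundles one panel observation with a prior choice;
``fit()`` runs likelihood evaluation, Bayes update and summarization and
returns a ``TMBUncertaintyResults`` carrying the posterior, the interval and
threshold probabilities, and a ``summary()`` table, in the style of
statsmodels' model/results split.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortTable, kde_prior, normal_reference_bandwidth
from .exceptions import InvalidArgumentError
from .grid import (
    AssayObservation,
    DiscreteTMBDistribution,
    TMBGrid,
    binomial_likelihood,
)
from .inference import (
    UncertaintyReport,
    bayes_update,
    central_interval,
    prob_above,
    sample_distribution,
    summarize,
)

__all__ = ["TMBUncertaintyModel", "TMBUncertaintyResults"]


class TMBUncertaintyModel:
    """Binomial sampling-error model for one reported TMB value.

    Parameters
    ----------
    reported_tmb : float
        Target TMB in mut/Mb; converted to the integer mutation count whose
        implied TMB is closest (ties toward the larger count).
    panel_size_mb : float
        Panel footprint in megabases.
    prior : {"flat", "histology"}, default "flat"
        Flat prior, or a histology-specific KDE prior built from ``cohort``.
    cohort, histology
        Required when ``prior="histology"``: the cohort table and the label
        whose TMB values form the prior.
    grid : TMBGrid, optional
        Support of true TMB values; defaults to 0-200 mut/Mb in 0.1 steps.
    bandwidth : float, optional
        KDE bandwidth in mut/Mb; defaults to the normal-reference rule.

    Examples
    --------
    >>> res = TMBUncertaintyModel(12, 0.3).fit()
    >>> round(res.p_above_threshold, 2)
    0.81
    """

    def __init__(
        self,
        reported_tmb: float,
        panel_size_mb: float,
        *,
        prior: str = "flat",
        cohort: CohortTable | None = None,
        histology: str | None = None,
        grid: TMBGrid | None = None,
        bandwidth: float | None = None,
    ):
        self.grid = grid if grid is not None else TMBGrid()
        self.observation = AssayObservation.from_target_tmb(reported_tmb, panel_size_mb)
        self.target_tmb = float(reported_tmb)
        if prior not in ("flat", "histology"):
            raise InvalidArgumentError(
                f"prior must be 'flat' or 'histology', got {prior!r}"
            )
        if prior == "histology":
            if cohort is None or histology is None:
                raise InvalidArgumentError(
                    "prior='histology' requires both cohort and histology"
                )
            histology = cohort.resolve_histology(histology)
            if bandwidth is None:
                bandwidth = normal_reference_bandwidth(cohort.values_for(histology))
            self.prior_dist = kde_prior(cohort, histology, self.grid, bandwidth)
        else:
            if histology is not None:
                raise InvalidArgumentError("histology given but prior is 'flat'")
            self.prior_dist = DiscreteTMBDistribution.flat(self.grid)
        self.prior = prior
        self.cohort = cohort
        self.histology = histology
        self.bandwidth = bandwidth

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        reported_tmb: float,
        panel_size_mb: float,
        histology: str,
        **kwargs,
    ) -> "TMBUncertaintyModel":
        """Build a histology-prior model straight from a cohort DataFrame
        with columns ``sample_id``, ``cancer_type``, ``tmb``."""
        return cls(
            reported_tmb,
            panel_size_mb,
            prior="histology",
            cohort=CohortTable(data),
            histology=histology,
            **kwargs,
        )

    def fit(self, ci_level: float = 0.90, threshold: float = 10.0) -> "TMBUncertaintyResults":
        """Evaluate the likelihood, apply the prior, summarize the posterior."""
        likelihood = binomial_likelihood(self.observation, self.grid)
        posterior = bayes_update(self.prior_dist, likelihood)
        report = summarize(
            self.observation,
            self.prior_dist,
            cohort=self.cohort,
            histology=self.histology,
            level=ci_level,
            threshold=threshold,
            bandwidth=self.bandwidth,
        )
        return TMBUncertaintyResults(self, likelihood, posterior, report)


class TMBUncertaintyResults:
    """Fitted posterior and its summaries for one TMB observation.

    Attributes
    ----------
    model : TMBUncertaintyModel
    prior, likelihood, posterior : DiscreteTMBDistribution
    report : UncertaintyReport
        Flat record of every input and summary; serializes to JSON/TSV.
    """

    def __init__(
        self,
        model: TMBUncertaintyModel,
        likelihood: DiscreteTMBDistribution,
        posterior: DiscreteTMBDistribution,
        report: UncertaintyReport,
    ):
        self.model = model
        self.prior = model.prior_dist
        self.likelihood = likelihood
        self.posterior = posterior
        self.report = report

    # convenient scalar views
    @property
    def ci_low(self) -> float:
        return self.report.ci_low

    @property
    def ci_high(self) -> float:
        return self.report.ci_high

    @property
    def p_above_threshold(self) -> float:
        return self.report.p_above_threshold

    @property
    def percentile_range(self) -> Optional[tuple[float, float]]:
        if self.report.percentile_low is None:
            return None
        return (self.report.percentile_low, self.report.percentile_high)

    def conf_int(self, level: float | None = None) -> tuple[float, float]:
        """Central interval at ``level`` (defaults to the fitted level)."""
        if level is None:
            return (self.report.ci_low, self.report.ci_high)
        return central_interval(self.posterior, level)

    def prob_above(self, threshold: float) -> float:
        """P(true TMB > threshold) under the posterior."""
        return prob_above(self.posterior, threshold)

    def sample(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        """Seeded posterior draws (Monte-Carlo parity mode)."""
        return sample_distribution(self.posterior, n, seed)

    def plot(self, ax=None, shade_ci: bool = True):
        """Prior/likelihood/posterior curves with the CI shaded."""
        from .plotting import plot_distributions

        return plot_distributions(self, ax=ax, shade_ci=shade_ci)

    def summary(self) -> str:
        """Human-readable summary table (returns the formatted string)."""
        r = self.report
        rows = [
            ("Reported TMB (mut/Mb)", f"{r.reported_tmb:.4g}"),
            ("Panel size (Mb)", f"{r.panel_size_mb:.4g}"),
            ("Mutation count used", f"{r.mutation_count}"),
            ("Prior", r.prior_kind),
            (f"Central {r.ci_level:.0%} interval (mut/Mb)",
             f"[{r.ci_low:.1f}, {r.ci_high:.1f}]"),
            (f"P(true TMB > {r.threshold:g} mut/Mb)", f"{r.p_above_threshold:.3f}"),
        ]
        if r.percentile_low is not None:
            rows.append(
                ("Cohort percentile range",
                 f"[{r.percentile_low:.1f}, {r.percentile_high:.1f}]")
            )
        if r.bandwidth is not None:
            rows.append(("KDE bandwidth (mut/Mb)", f"{r.bandwidth:.4g}"))
        rows.append(("Grid", f"0-{r.grid_max:g} mut/Mb, step {r.grid_step:g}"))
        width = max(len(k) for k, _ in rows)
        title = "TMB Measurement Uncertainty"
        bar = "=" * (width + 24)
        body = "\n".join(f"{k:<{width}}  {v:>20}" for k, v in rows)
        return f"{bar}\n{title:^{len(bar)}}\n{bar}\n{body}\n{bar}"

    def __repr__(self) -> str:
        r = self.report
        return (
            f"<TMBUncertaintyResults tmb={r.reported_tmb:.4g} "
            f"panel={r.panel_size_mb:g}Mb prior={r.prior_kind} "
            f"ci=[{r.ci_low:.1f},{r.ci_high:.1f}] "
            f"p>{r.threshold:g}={r.p_above_threshold:.3f}>"
        )
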