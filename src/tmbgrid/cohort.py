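"""Cohort TMB tables, histology-specific KDE priors and percentile summaries.

Pan-cancer immunotherapy cohorts report one TMB value per sequenced tumor
together with its histology.  Those per-histology empirical distributions
serve two purposes here: smoothed into a kernel density estimate on the TMB
grid they become an informative prior for the Bayesian update, and their
raw quantiles give the percentile context (deciles, percentile of a CI
bound) that a laboratory report would display.

A deterministic synthetic cohort generator stands in for the real
(accession-gated) patient data in tests and examples; it draws per-histology
TMB values from log-normal distributions, which reproduce the heavy right
tail and strictly positive support of observed TMB data.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CohortSchemaError,
    EmptyCohortError,
    InsufficientDataError,
    InvalidArgumentError,
    UnknownHistologyError,
)
from .grid import DiscreteTMBDistribution, TMBGrid

__all__ = [
    "CohortTable",
    "HistologySpec",
    "SyntheticCohortSpec",
    "read_cohort",
    "kde_prior",
    "empirical_percentile",
    "decile_table",
    "generate_synthetic_cohort",
    "preset_cohort_spec",
    "MELANOMA_LIKE",
    "RCC_LIKE",
    "MIN_KDE_RECORDS",
]

logger = logging.getLogger(__name__)

#: Minimum records per histology for a KDE prior; below this the prior falls
#: back to flat (a 4-point density estimate is noise, not information).
MIN_KDE_RECORDS = 5

REQUIRED_COLUMNS = ("sample_id", "cancer_type", "tmb")


class CohortTable:
    """Per-sample (histology, TMB) records backing priors and percentiles.

    Thin wrapper over a :class:`pandas.DataFrame` with canonical columns
    ``sample_id``, ``cancer_type``, ``tmb`` (mut/Mb).  Histology lookup is
    case-insensitive after trimming; an ambiguous match (two distinct labels
    that collide case-insensitively) raises with the candidates listed.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise CohortSchemaError(
                f"cohort table is missing required column(s): {', '.join(missing)}"
            )
        frame = frame.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        frame["cancer_type"] = frame["cancer_type"].astype(str).str.strip()
        frame["tmb"] = pd.to_numeric(frame["tmb"], errors="coerce")
        bad = frame["tmb"].isna() | (frame["tmb"] < 0) | (frame["cancer_type"] == "")
        if int(bad.sum()):
            raise InvalidArgumentError(
                f"{int(bad.sum())} record(s) have missing/negative TMB or empty "
                "histology; filter before constructing CohortTable (read_cohort does)"
            )
        if len(frame) == 0:
            raise EmptyCohortError("cohort has no records")
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying records as a DataFrame (copy-on-write protected)."""
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def histologies(self) -> list[str]:
        """Distinct histology labels, in first-appearance order."""
        return list(dict.fromkeys(self._frame["cancer_type"]))

    def resolve_histology(self, histology: str) -> str:
        """Map a user-supplied label to the canonical cohort label."""
        want = str(histology).strip()
        labels = self.histologies
        if want in labels:
            return want
        matches = [lab for lab in labels if lab.casefold() == want.casefold()]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            raise UnknownHistologyError(
                f"histology {histology!r} is ambiguous; candidates: "
                + ", ".join(sorted(matches))
            )
        raise UnknownHistologyError(
            f"histology {histology!r} not found; available: "
            + ", ".join(sorted(labels))
        )

    def values_for(self, histology: str) -> np.ndarray:
        """TMB values (mut/Mb) for one histology, as a float array."""
        label = self.resolve_histology(histology)
        return self._frame.loc[
            self._frame["cancer_type"] == label, "tmb"
        ].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self._frame.to_csv(path, sep="\t", index=False)


def read_cohort(
    path: str | Path,
    *,
    sample_col: str = "sample_id",
    type_col: str = "cancer_type",
    tmb_col: str = "tmb",
) -> CohortTable:
    """Read a delimited cohort file (TSV or CSV, sniffed; header required).

    Rows with missing or negative TMB, or an empty histology label, are
    dropped with a logged count.  A missing required column raises
    :class:`CohortSchemaError` naming it; zero valid rows raises
    :class:`EmptyCohortError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    rename = {sample_col: "sample_id", type_col: "cancer_type", tmb_col: "tmb"}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"{path}: missing required column(s): {', '.join(missing)} "
            f"(found: {', '.join(map(str, df.columns))})"
        )
    df = df.rename(columns=rename)
    df["tmb"] = pd.to_numeric(df["tmb"], errors="coerce")
    df["cancer_type"] = df["cancer_type"].astype(str).str.strip()
    keep = df["tmb"].notna() & (df["tmb"] >= 0) & (df["cancer_type"] != "")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_cohort: dropped %d invalid row(s) from %s", n_dropped, path)
    df = df.loc[keep]
    if len(df) == 0:
        raise EmptyCohortError(f"{path}: no valid cohort rows after filtering")
    table = CohortTable(df)
    table.n_dropped = n_dropped  # type: ignore[attr-defined]
    return table


def normal_reference_bandwidth(values: np.ndarray) -> float:
    """Normal-reference (Silverman) bandwidth: 1.06 * sd * n^(-1/5), in mut/Mb."""
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return 1.06 * sd * len(values) ** (-1 / 5)


#: Smallest mass any grid point may carry in a KDE prior.  A Gaussian KDE is
#: numerically zero far from the data; flooring keeps the posterior defined
#: wherever the likelihood has support while perturbing results far below
#: reporting precision.
PRIOR_FLOOR = 1e-12


def kde_prior(
    cohort: CohortTable,
    histology: str,
    grid: TMBGrid | None = None,
    bandwidth: float | None = None,
) -> DiscreteTMBDistribution:
    """Histology-specific prior: Gaussian KDE of cohort TMB values on the grid.

    The density sum(phi((t - x_i)/h)) / (n h) is evaluated at every grid
    point, floored at ``PRIOR_FLOOR`` and renormalized; mass the kernels
    place below 0 or beyond the grid maximum is discarded by the
    renormalization (the grid starts at 0, so there is no boundary
    reflection).  ``bandwidth`` (mut/Mb) defaults to the normal-reference
    rule on the histology's values.  Histologies with fewer than
    ``MIN_KDE_RECORDS`` records fall back to a flat prior with a warning.
    """
    if grid is None:
        grid = TMBGrid()
    values = cohort.values_for(histology)
    if len(values) < MIN_KDE_RECORDS:
        warnings.warn(
            f"histology {histology!r} has only {len(values)} record(s) "
            f"(< {MIN_KDE_RECORDS}); falling back to a flat prior",
            stacklevel=2,
        )
        return DiscreteTMBDistribution.flat(grid)
    if bandwidth is None:
        bandwidth = normal_reference_bandwidth(values)
    if not (bandwidth > 0) or not math.isfinite(bandwidth):
        raise InvalidArgumentError(
            f"KDE bandwidth must be positive and finite, got {bandwidth} "
            "(constant-valued cohorts need an explicit bandwidth)"
        )
    z = (grid.tmb_values[:, None] - values[None, :]) / bandwidth
    density = stats.norm.pdf(z).sum(axis=1) / (len(values) * bandwidth)
    mass = density / density.sum()
    mass = np.maximum(mass, PRIOR_FLOOR)
    return DiscreteTMBDistribution.from_weights(grid, mass, kind="prior")


def empirical_percentile(tmb: float, cohort: CohortTable, histology: str) -> float:
    """Percentile of ``tmb`` within a histology's cohort values, in [0, 100].

    Midpoint convention for ties: 100 * (#below + 0.5 * #equal) / n.
    """
    if tmb < 0:
        raise InvalidArgumentError(f"TMB must be nonnegative, got {tmb}")
    values = cohort.values_for(histology)
    below = np.count_nonzero(values < tmb)
    equal = np.count_nonzero(values == tmb)
    return 100.0 * (below + 0.5 * equal) / len(values)


def decile_table(cohort: CohortTable, histology: str) -> np.ndarray:
    """The 10th..90th percentiles of a histology's TMB values (9 values).

    Linear-interpolation quantiles (numpy's default, R type 7); requires at
    least 10 records.
    """
    values = cohort.values_for(histology)
    if len(values) < 10:
        raise InsufficientDataError(
            f"decile table needs >= 10 records for {histology!r}, found {len(values)}"
        )
    return np.percentile(values, np.arange(10, 100, 10))


@dataclasses.dataclass(frozen=True)
class HistologySpec:
    """Log-normal TMB distribution for one synthetic histology."""

    label: str
    n_samples: int
    log_location: float  # mean of log TMB
    log_spread: float  # sd of log TMB

    def __post_init__(self) -> None:
        if not self.label or not str(self.label).strip():
            raise InvalidArgumentError("histology label must be nonempty")
        if self.n_samples < 1:
            raise InvalidArgumentError(
                f"n_samples must be >= 1, got {self.n_samples} for {self.label!r}"
            )
        if not (self.log_spread > 0):
            raise InvalidArgumentError(
                f"log_spread must be positive, got {self.log_spread} for {self.label!r}"
            )


# Canonical presets: a high-TMB histology (melanoma-like, median 15 mut/Mb on
# the log scale) and a low-TMB one (renal-cell-like, median 2.5 mut/Mb), both
# with ~1 log-unit dispersion — the qualitative contrast seen between
# UV-driven and low-mutation tumor types in pan-cancer cohorts.
MELANOMA_LIKE = "melanoma-like"
RCC_LIKE = "rcc-like"

_PRESETS = (
    HistologySpec(MELANOMA_LIKE, 2000, math.log(15.0), 1.0),
    HistologySpec(RCC_LIKE, 2000, math.log(2.5), 1.0),
)


@dataclasses.dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for a reproducible synthetic cohort (one log-normal per histology)."""

    histologies: tuple[HistologySpec, ...]
    seed: int = 0
    max_tmb: float = 200.0  # draws are capped at the grid maximum

    def __post_init__(self) -> None:
        if len(self.histologies) == 0:
            raise InvalidArgumentError("spec needs at least one histology")
        labels = [h.label for h in self.histologies]
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError(f"duplicate histology labels in spec: {labels}")


def preset_cohort_spec(seed: int = 0) -> SyntheticCohortSpec:
    """The two-preset spec: melanoma-like (high TMB) and rcc-like (low TMB)."""
    return SyntheticCohortSpec(histologies=_PRESETS, seed=seed)


def generate_synthetic_cohort(spec: SyntheticCohortSpec) -> CohortTable:
    """Draw a cohort from the spec; the same spec (incl. seed) gives an
    identical table.  Values are rounded to 4 decimals (sub-0.001 mut/Mb is
    below any assay's resolution) and capped at ``spec.max_tmb``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for h in spec.histologies:
        draws = rng.lognormal(mean=h.log_location, sigma=h.log_spread, size=h.n_samples)
        draws = np.minimum(np.round(draws, 4), spec.max_tmb)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [f"{h.label}-{i:04d}" for i in range(h.n_samples)],
                    "cancer_type": h.label,
                    "tmb": draws,
                }
            )
        )
    return CohortTable(pd.concat(frames, ignore_index=True))
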