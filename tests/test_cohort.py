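"""Cohort ingestion, KDE priors, percentiles and the synthetic generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from tmbgrid import (
    HistologySpec,
    SyntheticCohortSpec,
    TMBGrid,
    decile_table,
    empirical_percentile,
    generate_synthetic_cohort,
    kde_prior,
    preset_cohort_spec,
    prob_above,
    read_cohort,
)
from tmbgrid.cohort import MELANOMA_LIKE, RCC_LIKE, normal_reference_bandwidth
from tmbgrid.exceptions import (
    CohortSchemaError,
    EmptyCohortError,
    InsufficientDataError,
    InvalidArgumentError,
    UnknownHistologyError,
)


class TestReadCohort:
    def test_well_formed_tsv(self, toy_cohort_file):
        cohort = read_cohort(toy_cohort_file)
        assert len(cohort) == 6
        assert set(cohort.histologies) == {"Melanoma", "Renal Cell Carcinoma"}

    def test_csv_dialect_sniffed(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("sample_id,cancer_type,tmb\na,Glioma,1.5\nb,Glioma,2.5\n")
        assert len(read_cohort(path)) == 2

    def test_negative_tmb_rows_dropped_and_counted(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        path.write_text(
            "sample_id\tcancer_type\ttmb\n"
            "a\tGlioma\t1.0\nb\tGlioma\t-2.0\nc\tGlioma\t3.0\nd\tGlioma\t\n"
        )
        cohort = read_cohort(path)
        assert len(cohort) == 2
        assert cohort.n_dropped == 2

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        path.write_text("sample_id\ttmb\na\t1.0\n")
        with pytest.raises(CohortSchemaError, match="cancer_type"):
            read_cohort(path)

    def test_custom_column_names(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("id,histology,muts_per_mb\na,Glioma,1.5\n")
        cohort = read_cohort(
            path, sample_col="id", type_col="histology", tmb_col="muts_per_mb"
        )
        assert cohort.values_for("Glioma").tolist() == [1.5]

    def test_zero_valid_rows(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        path.write_text("sample_id\tcancer_type\ttmb\na\tGlioma\t-1\n")
        with pytest.raises(EmptyCohortError):
            read_cohort(path)

    def test_histology_lookup_case_insensitive(self, toy_cohort_file):
        cohort = read_cohort(toy_cohort_file)
        assert len(cohort.values_for("melanoma")) == 3
        with pytest.raises(UnknownHistologyError, match="Melanoma"):
            cohort.values_for("sarcoma")


class TestKDEPrior:
    def test_concentrates_on_constant_data(self, default_grid):
        import pandas as pd

        from tmbgrid.cohort import CohortTable

        frame = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(20)], "cancer_type": "x", "tmb": 5.0}
        )
        cohort = CohortTable(frame)
        prior = kde_prior(cohort, "x", default_grid, bandwidth=0.3)
        mask = (default_grid.tmb_values >= 4) & (default_grid.tmb_values <= 6)
        assert prior.probs[mask].sum() > 0.99

    def test_auto_bandwidth_requires_spread(self, default_grid):
        from tmbgrid.cohort import CohortTable
        import pandas as pd

        frame = pd.DataFrame(
            {"sample_id": list("abcde"), "cancer_type": "x", "tmb": 5.0}
        )
        with pytest.raises(InvalidArgumentError, match="bandwidth"):
            kde_prior(CohortTable(frame), "x", default_grid)

    def test_normalized_and_strictly_positive(self, preset_cohort, default_grid):
        prior = kde_prior(preset_cohort, MELANOMA_LIKE, default_grid)
        assert abs(prior.probs.sum() - 1.0) <= 1e-12
        assert np.all(prior.probs > 0)  # floor keeps posterior support alive
        assert prior.kind == "prior"

    def test_disjoint_histologies_order_by_mean(self, default_grid):
        spec = SyntheticCohortSpec(
            histologies=(
                HistologySpec("low", 50, math.log(2.0), 0.3),
                HistologySpec("high", 50, math.log(40.0), 0.3),
            ),
            seed=7,
        )
        cohort = generate_synthetic_cohort(spec)
        low = kde_prior(cohort, "low", default_grid)
        high = kde_prior(cohort, "high", default_grid)
        assert high.mean() > low.mean()

    def test_small_histology_falls_back_to_flat(self, default_grid):
        spec = SyntheticCohortSpec(
            histologies=(HistologySpec("tiny", 3, 1.0, 0.5),), seed=2
        )
        cohort = generate_synthetic_cohort(spec)
        with pytest.warns(UserWarning, match="flat prior"):
            prior = kde_prior(cohort, "tiny", default_grid)
        assert prior.kind == "flat"

    def test_matches_statsmodels_kde(self, default_grid):
        """Independent route: statsmodels KDEUnivariate at the same bandwidth."""
        sm = pytest.importorskip("statsmodels.api")
        spec = SyntheticCohortSpec(
            histologies=(HistologySpec("x", 60, math.log(8.0), 0.6),), seed=5
        )
        cohort = generate_synthetic_cohort(spec)
        values = cohort.values_for("x")
        bw = normal_reference_bandwidth(values)
        ours = kde_prior(cohort, "x", default_grid, bandwidth=bw)
        kde = sm.nonparametric.KDEUnivariate(values)
        kde.fit(kernel="gau", bw=bw, fft=False)
        dens = kde.evaluate(default_grid.tmb_values)
        theirs = dens / dens.sum()
        big = theirs > 1e-8
        assert np.allclose(ours.probs[big], theirs[big], rtol=1e-6, atol=1e-12)

    def test_prior_exceedance_ordering_of_presets(self, preset_cohort, default_grid):
        """High-TMB histology prior puts far more mass above 10 mut/Mb."""
        p_mel = prob_above(kde_prior(preset_cohort, MELANOMA_LIKE, default_grid), 10)
        p_rcc = prob_above(kde_prior(preset_cohort, RCC_LIKE, default_grid), 10)
        assert p_mel > p_rcc

    @settings(max_examples=10, deadline=None)
    @given(
        mu=st.floats(min_value=0.0, max_value=3.5),
        sigma=st.floats(min_value=0.2, max_value=1.5),
        n=st.integers(min_value=5, max_value=60),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_valid_distribution_for_random_cohorts(self, mu, sigma, n, seed):
        spec = SyntheticCohortSpec(histologies=(HistologySpec("h", n, mu, sigma),), seed=seed)
        cohort = generate_synthetic_cohort(spec)
        grid = TMBGrid(max_tmb=100, step=0.5)
        prior = kde_prior(cohort, "h", grid)
        assert abs(prior.probs.sum() - 1.0) <= 1e-12
        assert np.all(prior.probs >= 0)


class TestEmpiricalPercentile:
    def test_edge_and_tie_conventions(self, toy_cohort_file):
        cohort = read_cohort(toy_cohort_file)
        assert empirical_percentile(0.1, cohort, "Melanoma") == 0.0
        assert empirical_percentile(100.0, cohort, "Melanoma") == 100.0
        # tie at the single middle value: midpoint convention
        assert empirical_percentile(14.5, cohort, "Melanoma") == pytest.approx(50.0)

    def test_single_record_midpoint(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text("sample_id\tcancer_type\ttmb\na\tGlioma\t3.0\n")
        cohort = read_cohort(path)
        assert empirical_percentile(3.0, cohort, "Glioma") == pytest.approx(50.0)

    @given(st.lists(st.floats(min_value=0, max_value=50), min_size=2, max_size=30))
    def test_nondecreasing_in_tmb(self, tmbs):
        import pandas as pd

        from tmbgrid.cohort import CohortTable

        frame = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(tmbs))],
                "cancer_type": "h",
                "tmb": tmbs,
            }
        )
        cohort = CohortTable(frame)
        queries = sorted(set(tmbs) | {0.0, 25.0, 50.0})
        pcts = [empirical_percentile(q, cohort, "h") for q in queries]
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))


class TestDecileTable:
    def test_interpolated_deciles_of_1_to_10(self, tmp_path):
        path = tmp_path / "ten.tsv"
        rows = "\n".join(f"s{i}\th\t{i}" for i in range(1, 11))
        path.write_text("sample_id\tcancer_type\ttmb\n" + rows + "\n")
        cohort = read_cohort(path)
        expected = [1.9, 2.8, 3.7, 4.6, 5.5, 6.4, 7.3, 8.2, 9.1]
        assert np.allclose(decile_table(cohort, "h"), expected)

    def test_constant_cohort_all_deciles_equal(self, tmp_path):
        import pandas as pd

        from tmbgrid.cohort import CohortTable

        frame = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(12)], "cancer_type": "h", "tmb": 7.0}
        )
        assert np.allclose(decile_table(CohortTable(frame), "h"), 7.0)

    def test_deciles_nondecreasing(self, preset_cohort):
        d = decile_table(preset_cohort, MELANOMA_LIKE)
        assert len(d) == 9
        assert np.all(np.diff(d) >= 0)

    def test_too_few_records(self, toy_cohort_file):
        cohort = read_cohort(toy_cohort_file)
        with pytest.raises(InsufficientDataError):
            decile_table(cohort, "Melanoma")


class TestSyntheticCohort:
    def test_same_seed_identical_tables(self, tmp_path):
        spec = preset_cohort_spec(seed=11)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        generate_synthetic_cohort(spec).to_tsv(a)
        generate_synthetic_cohort(spec).to_tsv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_preset_exceedance_fractions_match_lognormal_cdf(self, preset_cohort):
        """Empirical P(TMB > 10) per preset tracks the log-normal oracle."""
        for label, mu in ((MELANOMA_LIKE, math.log(15.0)), (RCC_LIKE, math.log(2.5))):
            values = preset_cohort.values_for(label)
            assert len(values) == 2000
            frac = float((values > 10).mean())
            oracle = 1 - norm.cdf((math.log(10) - mu) / 1.0)
            assert frac == pytest.approx(oracle, abs=0.04)
        mel = (preset_cohort.values_for(MELANOMA_LIKE) > 10).mean()
        rcc = (preset_cohort.values_for(RCC_LIKE) > 10).mean()
        assert mel > rcc

    def test_single_sample_histology(self):
        spec = SyntheticCohortSpec(
            histologies=(HistologySpec("solo", 1, 1.0, 0.5),), seed=3
        )
        cohort = generate_synthetic_cohort(spec)
        assert len(cohort.values_for("solo")) == 1

    def test_values_capped_at_grid_max(self):
        spec = SyntheticCohortSpec(
            histologies=(HistologySpec("hot", 500, math.log(150.0), 1.0),), seed=4
        )
        cohort = generate_synthetic_cohort(spec)
        assert cohort.values_for("hot").max() <= 200.0

    @pytest.mark.parametrize(
        "bad",
        [
            dict(label="", n_samples=5, log_location=1.0, log_spread=0.5),
            dict(label="x", n_samples=0, log_location=1.0, log_spread=0.5),
            dict(label="x", n_samples=5, log_location=1.0, log_spread=0.0),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            HistologySpec(**bad)
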