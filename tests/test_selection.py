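"""Selection-coefficient estimation, null binning, filters, synonyms."""

import math

import numpy as np
import pytest

from elasticdms.elasticity import selection_from_function
from elasticdms.selection import (
    CountTable,
    InvalidTableError,
    Klass,
    SelectionError,
    VariantId,
    aggregate_synonyms,
    apply_filters,
    epistasis,
    epistasis_table,
    estimate_selection,
    estimate_table,
    log_ratio_series,
    null_like_cutoff,
    refit_null_like,
    run_estimation,
)
from elasticdms.synthetic import build_library, sample_true_function, simulate_bulk_competition


def make_table(counts, wt_counts, timepoints=None, variants=None):
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if timepoints is None:
        timepoints = np.arange(counts.shape[1], dtype=float)
    if variants is None:
        variants = [
            VariantId(position=582, codon=f"AA{b}", aa="K") for b in "ACGT"[: counts.shape[0]]
        ]
    return CountTable(
        construct_name="test",
        timepoints=timepoints,
        variants=variants,
        counts=counts,
        wt_counts=np.asarray(wt_counts, dtype=float),
    )


class TestLogRatio:
    def test_identity_when_tracking_wt(self):
        table = make_table([[50, 100, 200]], [50, 100, 200])
        series = log_ratio_series(table, pseudocount=0.0)
        assert np.allclose(series, 0.0)

    def test_pseudocount_arithmetic(self):
        table = make_table([[100, 0]], [100, 100], timepoints=[0.0, 1.0])
        series = log_ratio_series(table, pseudocount=0.5)
        assert series[0, 1] == pytest.approx(math.log(0.5 / 100.5))

    def test_all_zero_wt_rejected(self):
        table = make_table([[1, 1, 1]], [1, 1, 1])
        table.wt_counts = np.zeros(3)
        with pytest.raises(InvalidTableError):
            log_ratio_series(table)


class TestEstimateSelection:
    def test_non_growing_mutant(self):
        # Mutant constant while WT doubles hourly: slope -ln2, s = -1.
        t = np.arange(4.0)
        table = make_table([[100, 100, 100, 100]], 100 * 2.0**t, timepoints=t)
        series = log_ratio_series(table, pseudocount=0.0)
        est = estimate_selection(series[0], t, g_wt=math.log(2))
        assert est.slope == pytest.approx(-math.log(2), abs=1e-12)
        assert est.s == pytest.approx(-1.0, abs=1e-12)

    def test_wt_tracking_mutant(self):
        t = np.arange(4.0)
        table = make_table([[100, 200, 400, 800]], 100 * 2.0**t, timepoints=t)
        series = log_ratio_series(table, pseudocount=0.0)
        est = estimate_selection(series[0], t, g_wt=math.log(2))
        assert est.s == pytest.approx(0.0, abs=1e-12)

    def test_invalid_normalization(self):
        with pytest.raises(SelectionError):
            estimate_selection(np.zeros(4), np.arange(4.0), g_wt=0.0)

    def test_noise_free_recovery_is_exact(self, params, constructs, library):
        # Without sampling noise the log-linear model is exact, so every
        # estimate equals the generating selection coefficient.
        truth = sample_true_function(library, {"preset": "uniform"}, seed=5)
        gpd = constructs["GPD"]
        table = simulate_bulk_competition(truth, gpd, params, depths=None)
        ests = estimate_table(table, g_wt=gpd.g_wt, pseudocount=0.0)
        f_by_key = {t.variant.key: t.f_true for t in truth}
        for est in ests:
            s_true = selection_from_function(gpd.e, f_by_key[est.variant.key], params)
            assert est.s == pytest.approx(s_true, abs=1e-9)

    def test_sampled_recovery_known_function(self, params, constructs, library):
        # A variant with half wild-type function under the endogenous
        # construct: estimate within 0.05 of the generating model.
        truth = sample_true_function(
            library, {"preset": "planted", "default": 0.5}, seed=0
        )
        gpd = constructs["GPD"]
        table = simulate_bulk_competition(truth, gpd, params, depths=500_000, seed=11)
        ests = estimate_table(table, g_wt=gpd.g_wt)
        s_expected = selection_from_function(1.0, 0.5, params)
        target = [e for e in ests if not e.variant.is_wt_codon and e.variant.aa != "*"
                  and not e.variant.is_synonymous_wt]
        s_hat = np.median([e.s for e in target])
        assert s_hat == pytest.approx(s_expected, abs=0.05)


class TestNullBinning:
    def test_cutoff_zero_spread(self):
        assert null_like_cutoff([-0.30, -0.30]) == pytest.approx(-0.30)

    def test_cutoff_arithmetic(self):
        values = [-0.34, -0.30, -0.26]  # mean -0.30, sd 0.04
        assert null_like_cutoff(values) == pytest.approx(-0.22)

    def test_requires_two_stops(self):
        with pytest.raises(SelectionError):
            null_like_cutoff([-0.3])

    def test_refit_uses_first_three_timepoints(self, params, constructs, library):
        truth = sample_true_function(library, {"preset": "bimodal"}, seed=2)
        gpd = constructs["GPD"]
        table = simulate_bulk_competition(truth, gpd, params, depths=500_000, seed=3)
        ests, cutoff = run_estimation(table, g_wt=gpd.g_wt)
        assert -1.0 < cutoff < -0.2
        nulls = [e for e in ests if e.klass is Klass.NULL_LIKE]
        assert nulls, "expected null-like variants in a bimodal run"
        assert all(e.n_timepoints_used == 3 for e in nulls)
        # Stops sit near s = -1 on the early timepoints.
        stop_s = [e.s for e in nulls if e.variant.aa == "*"]
        assert np.median(stop_s) == pytest.approx(-1.0, abs=0.15)

    def test_refit_idempotent_and_gated(self):
        t = np.arange(3.0)
        wt = 100 * 2.0**t
        table = make_table([[100, 100, 100], [100, 200, 400]], wt, timepoints=t)
        ests = estimate_table(table, g_wt=math.log(2), pseudocount=0.0)
        refit = refit_null_like(table, ests, cutoff=-0.5, g_wt=math.log(2), pseudocount=0.0)
        # Null variant already fitted on 3 points: identical slope, rebinned.
        assert refit[0].slope == pytest.approx(ests[0].slope)
        assert refit[0].klass is Klass.NULL_LIKE
        # WT-like variant above the cutoff is untouched.
        assert refit[1] is ests[1]
        assert refit[1].klass is Klass.NUMERIC


class TestFilters:
    def _est(self, residual, initial_ratio):
        v = VariantId(position=582, codon="AAA", aa="K")
        return estimate_selection(
            np.array([0.0, 0.1, -0.1, 0.0]), np.arange(4.0), 1.0, variant=v,
            initial_ratio=initial_ratio,
        ).__class__(
            variant=v, s=0.0, slope=0.0, residual_per_timepoint=residual,
            initial_ratio=initial_ratio, n_timepoints_used=4,
        )

    def test_residual_boundary_is_strict(self):
        kept = apply_filters([self._est(0.25, 0.1)])[0]
        assert kept.klass is Klass.NUMERIC
        dropped = apply_filters([self._est(0.2500001, 0.1)])[0]
        assert dropped.klass is Klass.FILTERED

    def test_low_initial_abundance(self):
        dropped = apply_filters([self._est(0.0, 0.003)])[0]
        assert dropped.klass is Klass.FILTERED
        kept = apply_filters([self._est(0.0, 0.004)])[0]
        assert kept.klass is Klass.NUMERIC

    def test_clean_synthetic_run_keeps_most_variants(self, params, constructs, library):
        truth = sample_true_function(library, {"preset": "intermediate"}, seed=4)
        gpd = constructs["GPD"]
        table = simulate_bulk_competition(truth, gpd, params, depths=500_000, seed=5)
        ests, _ = run_estimation(table, g_wt=gpd.g_wt)
        frac = np.mean([e.klass is Klass.FILTERED for e in ests])
        assert frac < 0.07

    def test_filters_commute_with_null_refit(self, params, constructs, library):
        truth = sample_true_function(library, {"preset": "bimodal"}, seed=6)
        gpd = constructs["GPD"]
        table = simulate_bulk_competition(truth, gpd, params, depths=500_000, seed=7)
        ests = estimate_table(table, g_wt=gpd.g_wt)
        cutoff = null_like_cutoff([e.s for e in ests if e.variant.aa == "*"])
        a = apply_filters(refit_null_like(table, ests, cutoff, gpd.g_wt))
        b = refit_null_like(table, apply_filters(ests), cutoff, gpd.g_wt)
        b = apply_filters(b)
        assert [e.klass for e in a] == [e.klass for e in b]


class TestSynonyms:
    def test_mean_of_synonyms(self):
        from elasticdms.selection import SelectionEstimate

        ests = [
            SelectionEstimate(VariantId(582, "AAA", "K"), s=-0.10, slope=0, residual_per_timepoint=0,
                              initial_ratio=1, n_timepoints_used=7),
            SelectionEstimate(VariantId(582, "AAG", "K"), s=-0.20, slope=0, residual_per_timepoint=0,
                              initial_ratio=1, n_timepoints_used=7),
            SelectionEstimate(VariantId(582, "TGG", "W"), s=-0.05, slope=0, residual_per_timepoint=0,
                              initial_ratio=1, n_timepoints_used=7),
        ]
        aa_df, dev_df = aggregate_synonyms(ests)
        k = aa_df[aa_df.aa == "K"].iloc[0]
        assert k.s == pytest.approx(-0.15)
        assert k.n_codons == 2
        # Single-codon amino acid keeps its codon's value.
        w = aa_df[aa_df.aa == "W"].iloc[0]
        assert w.s == pytest.approx(-0.05)
        # Persistence gate is strict s > -0.1: both lysine codons fall out,
        # only the tryptophan codon contributes a (zero) deviation.
        assert set(dev_df.aa) == {"W"}
        assert dev_df.deviation.abs().max() == pytest.approx(0.0)

    def test_synonym_deviations_center_on_zero(self, params, constructs, library):
        # Synonyms share true function, so deviations reflect sampling only.
        truth = sample_true_function(library, {"preset": "uniform", "low": 0.5, "high": 1.0}, seed=8)
        gpd = constructs["GPD"]
        table = simulate_bulk_competition(truth, gpd, params, depths=500_000, seed=9)
        ests, cutoff = run_estimation(table, g_wt=gpd.g_wt)
        _, dev_df = aggregate_synonyms(ests, cutoff=cutoff)
        assert len(dev_df) > 100
        assert abs(dev_df.deviation.mean()) < 0.01
        assert dev_df.deviation.std() < 0.05


class TestEpistasis:
    def test_wt_to_null_is_minus_one(self):
        assert epistasis(0.0, -0.6, reduced_null=True) == pytest.approx(-1.0)

    def test_identical_conditions(self):
        assert epistasis(-0.2, -0.2) == pytest.approx(0.0)

    def test_plain_subtraction(self):
        assert epistasis(-0.1, -0.3) == pytest.approx(-0.2)

    def test_table_join(self):
        import pandas as pd

        endog = pd.DataFrame(
            {"position": [582, 582], "aa": ["K", "R"], "s": [0.0, -0.1],
             "n_codons": [2, 2], "klass": ["NUMERIC", "NUMERIC"]}
        )
        reduced = pd.DataFrame(
            {"position": [582], "aa": ["K"], "s": [-0.5],
             "n_codons": [2], "klass": ["NULL_LIKE"]}
        )
        df = epistasis_table(endog, reduced)
        assert len(df) == 1
        assert df.epistasis.iloc[0] == pytest.approx(-1.0)
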