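"""Function inference, bounds, combination, and downstream summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from elasticdms.config import default_config
from elasticdms.elasticity import selection_from_function
from elasticdms.function_inference import (
    Bound,
    blosum_similarity_table,
    combine_across_constructs,
    cross_construct_consistency,
    ddg_function_join,
    dfe_histogram,
    partition_surface_core,
    per_construct_function,
)
from elasticdms.pipeline import run_pipeline
from elasticdms.selection import Klass


class TestPerConstructFunction:
    def test_null_like_gives_lower_bound(self, constructs, params):
        out = per_construct_function(-0.8, Klass.NULL_LIKE, constructs["TEF"], params)
        assert isinstance(out, Bound)
        assert out.kind == "below"
        assert out.value == pytest.approx(0.067, abs=0.0005)

    def test_wt_like_gives_upper_bound(self, constructs, params):
        out = per_construct_function(-0.01, Klass.NUMERIC, constructs["TEFdTer"], params)
        assert isinstance(out, Bound)
        assert out.kind == "above"
        assert out.value == pytest.approx(0.71, abs=0.005)

    def test_numeric_matches_bisection_oracle(self, constructs, params):
        # Independent check: bisect the forward map instead of inverting it.
        s_obs = -0.2
        out = per_construct_function(s_obs, Klass.NUMERIC, constructs["GPD"], params)
        lo, hi = 1e-9, 2.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if selection_from_function(1.0, mid, params) < s_obs:
                lo = mid
            else:
                hi = mid
        assert out == pytest.approx((lo + hi) / 2, abs=1e-9)

    def test_filtered_is_missing(self, constructs, params):
        assert per_construct_function(-0.2, Klass.FILTERED, constructs["GPD"], params) is None


class TestCombine:
    def test_mean_of_numeric_entries(self):
        est = combine_across_constructs(
            582, "K", {"GPD": 0.4, "TEF": 0.6, "CYC": Bound("above", 0.38)}
        )
        assert est.combined_f == pytest.approx(0.5)
        # Population (ddof=0) standard deviation across constructs.
        assert est.sd_across_constructs == pytest.approx(0.1)
        assert est.n_numeric == 2
        assert not est.inconsistent

    def test_only_above_bounds(self):
        est = combine_across_constructs(
            582, "K", {"CYC": Bound("above", 0.38), "ADH": Bound("above", 0.43)}
        )
        assert est.combined_f is None
        assert est.bound == Bound("above", 0.43)

    def test_contradictory_bounds_flagged_not_raised(self):
        est = combine_across_constructs(
            582, "K", {"a": Bound("above", 0.7), "b": Bound("below", 0.1)}
        )
        assert est.inconsistent
        assert est.combined_f is None

    def test_permutation_invariance(self):
        entries = {"GPD": 0.4, "TEF": 0.6, "TEFdTer": 0.55}
        a = combine_across_constructs(582, "K", entries)
        b = combine_across_constructs(582, "K", dict(reversed(list(entries.items()))))
        assert a.combined_f == b.combined_f
        assert a.sd_across_constructs == b.sd_across_constructs


class TestConsistency:
    def _mk(self, per_construct_values):
        ests = []
        for i, vals in enumerate(per_construct_values):
            ests.append(combine_across_constructs(582 + i % 9, "ACDEFGHIK"[i % 9], vals))
        return ests

    def test_identical_vectors(self):
        rng = np.random.default_rng(0)
        fs = rng.uniform(0.1, 0.9, 20)
        ests = self._mk([{"A": f, "B": f} for f in fs])
        out = cross_construct_consistency(ests, ["A", "B"])
        assert out["pairs"][("A", "B")] == pytest.approx(1.0)
        assert out["pooled"] == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        ests = self._mk(
            [{"A": a, "B": b} for a, b in zip(rng.uniform(size=500), rng.uniform(size=500))]
        )
        out = cross_construct_consistency(ests, ["A", "B"])
        assert out["pooled"] < 0.05

    def test_too_few_shared_is_missing(self):
        ests = self._mk([{"A": 0.5, "B": 0.5}, {"A": 0.2}])
        out = cross_construct_consistency(ests, ["A", "B"])
        assert out["pairs"][("A", "B")] is None


class TestPartition:
    def test_positions_fall_in_exactly_one_partition(self):
        for pos in range(582, 591):
            est = combine_across_constructs(pos, "K", {"GPD": 0.5})
            surface, core = partition_surface_core([est])
            assert len(surface) + len(core) == 1

    def test_planted_surface_defect_recovered(self):
        rng = np.random.default_rng(2)
        ests = []
        for pos in range(582, 591):
            for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY"):
                low = pos in (582, 583, 585)
                f = rng.uniform(0.0, 0.4) if low else rng.uniform(0.6, 1.0)
                ests.append(combine_across_constructs(pos, aa, {"GPD": f}))
        surface, core = partition_surface_core(ests)
        assert np.median(surface) < np.median(core)


class TestBlosum:
    def _ests(self, f_by_aa, pos=583):
        return [combine_across_constructs(pos, aa, {"GPD": f}) for aa, f in f_by_aa.items()]

    def test_conservative_substitution_scores_higher(self):
        # From wild-type Phe, tyrosine is closer than aspartate.
        df, _ = blosum_similarity_table({583: "F"}, self._ests({"Y": 0.9, "D": 0.1}))
        y = df[df.aa == "Y"].blosum62.iloc[0]
        d = df[df.aa == "D"].blosum62.iloc[0]
        assert y > d

    def test_self_substitution_excluded_from_correlation(self):
        df, rho = blosum_similarity_table(
            {583: "F"}, self._ests({"F": 1.0, "Y": 0.9, "D": 0.1, "W": 0.7, "K": 0.2})
        )
        assert df[df.aa == "F"].is_self.all()
        assert rho is not None

    def test_planted_similarity_effect_recovered(self):
        # Function increasing with similarity -> positive rank correlation.
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        f_by_aa = {aa: 0.5 + 0.05 * m["F", aa] for aa in "ACDEGHIKLMNPQRSTVWY"}
        _, rho = blosum_similarity_table({583: "F"}, self._ests(f_by_aa))
        assert rho > 0.9

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(ValueError):
            blosum_similarity_table({583: "?"}, self._ests({"Y": 0.9}))


class TestDdgJoin:
    def _ests(self):
        return [
            combine_across_constructs(582, aa, {"GPD": f})
            for aa, f in zip("ACDEFG", [0.1, 0.3, 0.5, 0.6, 0.8, 0.9])
        ]

    def test_zero_variance_reported_missing(self):
        ddg = pd.DataFrame({"position": [582] * 6, "aa": list("ACDEFG"), "ddg_kcal_mol": [1.0] * 6})
        out = ddg_function_join(ddg, self._ests())
        assert out["pearson"] is None

    def test_perfect_anticorrelation(self):
        ests = self._ests()
        ddg = pd.DataFrame(
            {"position": [e.position for e in ests], "aa": [e.aa for e in ests],
             "ddg_kcal_mol": [-e.combined_f for e in ests]}
        )
        out = ddg_function_join(ddg, ests)
        assert out["pearson"] == pytest.approx(-1.0)
        assert out["n_dropped"] == 0

    def test_missing_keys_counted(self):
        ddg = pd.DataFrame(
            {"position": [582, 582, 999], "aa": ["A", "C", "A"], "ddg_kcal_mol": [0.1, 0.5, 1.0]}
        )
        out = ddg_function_join(ddg, self._ests())
        assert out["n_dropped"] == 1


class TestDfeHistogram:
    def test_single_occupied_bin(self):
        hist = dfe_histogram(np.zeros(10), kind="s")
        assert (hist.counts > 0).sum() == 1
        assert hist.shares["wt_like"] == pytest.approx(1.0)

    def test_function_intermediate_band(self):
        vals = np.array([0.05, 0.5, 0.5, 0.95])
        hist = dfe_histogram(vals, kind="f")
        assert hist.shares["intermediate"] == pytest.approx(0.5)
        assert hist.shares["null_like"] == pytest.approx(0.25)
        assert hist.shares["wt_like"] == pytest.approx(0.25)


class TestHiddenDefectProperty:
    def test_hidden_fraction_decreases_with_expression(self, params):
        # Analytic: intermediate defects are invisible at endogenous
        # expression and progressively revealed down the promoter ladder.
        rng = np.random.default_rng(3)
        fs = rng.uniform(0.25, 0.95, size=2000)
        ladder = [1.0, 0.32, 0.094, 0.028, 0.015, 0.014, 0.010]
        fracs = []
        for e in ladder:
            s = np.array([selection_from_function(e, f, params) for f in fs])
            fracs.append(float(np.mean(s > -0.05)))
        assert fracs[0] >= 0.9
        assert all(a > b for a, b in zip(fracs, fracs[1:]))

    def test_pipeline_reveals_hidden_defects(self, params):
        cfg = default_config()
        cfg.synthetic.preset = "uniform"
        cfg.synthetic.dfe = {"low": 0.25, "high": 0.95}
        res = run_pipeline(cfg, seed=13)
        wt_like = {name: shares["wt_like"] for name, shares in res.dfe_shares.items()}
        assert wt_like["GPD"] >= 0.9
        for name in ("TEF", "TEFdTer", "CYC", "CYCdTer", "ADH", "ADHdTer"):
            assert wt_like[name] < wt_like["GPD"]
        # Well-separated expression strengths order strictly.
        assert wt_like["GPD"] > wt_like["TEF"] > wt_like["TEFdTer"] > wt_like["CYC"]


class TestBoundConservation:
    def test_every_entry_is_numeric_or_one_bound(self):
        cfg = default_config()
        res = run_pipeline(cfg, seed=17)
        for est in res.function_estimates:
            for name, entry in est.per_construct.items():
                ok = entry is None or isinstance(entry, float) or (
                    isinstance(entry, Bound) and entry.kind in ("above", "below")
                )
                assert ok, (est.aa_key, name, entry)
                if entry is None:
                    klass = res.aa_tables[name]
                    row = klass[(klass.position == est.position) & (klass.aa == est.aa)]
                    # Missing only when filtered out (or absent entirely).
                    assert row.empty or (row.klass == "FILTERED").all()
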