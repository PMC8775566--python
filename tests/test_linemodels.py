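"""Line-model fits: the factorial ANCOVA, LS-means, method-of-moments
variance components and genetic correlations, checked against hand
calculations and closed-form balanced-design identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from linesense import (
    DataError,
    fit_full_ancova,
    genetic_correlation,
    ls_line_means,
    raw_line_means,
    variance_components,
)


def _balanced_records(rng, n_lines=6, reps=3, blocks=2, line_sd=1.0, noise_sd=0.5):
    rows = []
    line_eff = rng.normal(0, line_sd, n_lines)
    for li in range(n_lines):
        for age in ("young", "old"):
            for tr in ("control", "treated"):
                for r in range(reps):
                    rows.append(
                        {
                            "line_id": f"L{li}",
                            "age": age,
                            "treatment": tr,
                            "block": f"b{r % blocks}",
                            "mass_mg": rng.normal(1.0, 0.1),
                            "trait": "speed",
                            "value": line_eff[li]
                            + 0.5 * (tr == "treated")
                            - 1.0 * (age == "old")
                            + rng.normal(0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


class TestFullAncova:
    def test_partial_ss_additive_on_balanced_design(self):
        rec = _balanced_records(np.random.default_rng(0))
        tab = fit_full_ancova(rec)
        y = rec["value"].to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        # with sum-coded orthogonal terms, partial SS behave sequentially:
        # they and the residual decompose the total SS (mass is the one
        # non-orthogonal column; allow its small covariance slack)
        assert tab["ss"].sum() == pytest.approx(total, rel=0.02)

    def test_detects_treatment_effect_only(self):
        rng = np.random.default_rng(1)
        rec = _balanced_records(rng, n_lines=12, reps=6, line_sd=0.0, noise_sd=0.5)
        tab = fit_full_ancova(rec)
        assert tab.loc["treatment", "p"] < 0.01
        assert tab.loc["age", "p"] < 0.01
        assert tab.loc["line:treatment", "p"] > 0.001  # no planted interaction

    def test_null_genotype_f_near_one(self):
        rng = np.random.default_rng(2)
        fs = []
        for _ in range(20):
            rec = _balanced_records(rng, n_lines=8, reps=3, line_sd=0.0)
            fs.append(fit_full_ancova(rec).loc["line", "F"])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_empty_cell_error_names_cell(self):
        rec = _balanced_records(np.random.default_rng(3))
        rec = rec[~((rec.line_id == "L0") & (rec.age == "old") & (rec.treatment == "treated"))]
        with pytest.raises(DataError, match="L0"):
            fit_full_ancova(rec)

    def test_duplicating_records_keeps_ss_ordering(self):
        rec = _balanced_records(np.random.default_rng(4))
        t1 = fit_full_ancova(rec)
        t2 = fit_full_ancova(pd.concat([rec, rec], ignore_index=True))
        terms = [t for t in t1.index if t != "residual"]
        assert list(t1.loc[terms, "ss"].sort_values().index) == list(
            t2.loc[terms, "ss"].sort_values().index
        )
        assert not np.allclose(t1.loc[terms, "F"], t2.loc[terms, "F"])


class TestLsMeans:
    def test_two_line_mass_worked_example(self, two_line_mass_records):
        lm = ls_line_means(two_line_mass_records, "young", "control")
        assert lm.set_index("line_id").loc["L1", "lsmean"] == pytest.approx(2.0, abs=1e-10)
        assert lm.set_index("line_id").loc["L2", "lsmean"] == pytest.approx(4.0, abs=1e-10)

    def test_identical_mass_equals_raw_means(self):
        rng = np.random.default_rng(5)
        rec = _balanced_records(rng, reps=4, blocks=2)  # blocks balanced
        rec["mass_mg"] = 1.0
        lm = ls_line_means(rec, "young", "control").set_index("line_id")["lsmean"]
        raw = raw_line_means(rec, "young", "control").set_index("line_id")["lsmean"]
        pd.testing.assert_series_equal(lm, raw, atol=1e-9)

    @given(shift=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_mass_translation_invariance(self, shift):
        rec = _balanced_records(np.random.default_rng(6))
        base = ls_line_means(rec, "old", "treated")["lsmean"].to_numpy()
        rec2 = rec.assign(mass_mg=rec["mass_mg"] + shift)
        shifted = ls_line_means(rec2, "old", "treated")["lsmean"].to_numpy()
        np.testing.assert_allclose(base, shifted, atol=1e-8)

    def test_block_relabeling_invariance(self):
        rec = _balanced_records(np.random.default_rng(7))
        base = ls_line_means(rec, "young", "control")["lsmean"].to_numpy()
        relabeled = rec.assign(block=rec["block"].map({"b0": "zz", "b1": "aa"}))
        out = ls_line_means(relabeled, "young", "control")["lsmean"].to_numpy()
        np.testing.assert_allclose(base, out, atol=1e-9)

    def test_missing_line_omitted_with_warning(self):
        rec = _balanced_records(np.random.default_rng(8))
        rec = rec[~((rec.line_id == "L2") & (rec.age == "young") & (rec.treatment == "control"))]
        with pytest.warns(UserWarning, match="omitted"):
            lm = ls_line_means(rec, "young", "control")
        assert "L2" not in set(lm["line_id"])


class TestVarianceComponents:
    def test_two_line_worked_example(self):
        rec = pd.DataFrame(
            {
                "line_id": ["A", "A", "B", "B"],
                "age": "young",
                "treatment": "control",
                "block": "b1",
                "mass_mg": 1.0,
                "value": [0.0, 2.0, 4.0, 6.0],
            }
        )
        vc = variance_components(rec, "young", "control")
        assert vc.ms_within == pytest.approx(2.0)
        assert vc.ms_between == pytest.approx(16.0)
        assert vc.n0 == pytest.approx(2.0)
        assert vc.var_line == pytest.approx(7.0)
        assert vc.var_error == pytest.approx(2.0)

    def test_constant_values_give_zero_components(self):
        rec = pd.DataFrame(
            {
                "line_id": ["A", "A", "B", "B"],
                "age": "y", "treatment": "c", "block": "b", "mass_mg": 1.0,
                "value": 3.0,
            }
        )
        vc = variance_components(rec, "y", "c")
        assert vc.var_line == 0.0
        assert vc.var_error == 0.0

    def test_negative_estimate_truncated_but_raw_kept(self):
        rng = np.random.default_rng(9)
        rec = pd.DataFrame(
            {
                "line_id": np.repeat([f"L{i}" for i in range(4)], 2),
                "age": "y", "treatment": "c", "block": "b", "mass_mg": 1.0,
                "value": [0.0, 10.0, 5.0, 5.2, 4.0, 6.0, 5.0, 5.1],
            }
        )
        vc = variance_components(rec, "y", "c")
        assert vc.var_line == 0.0
        assert vc.var_line_raw < 0.0

    def test_singleton_lines_error(self):
        rec = pd.DataFrame(
            {
                "line_id": ["A", "B"], "age": "y", "treatment": "c",
                "block": "b", "mass_mg": 1.0, "value": [1.0, 2.0],
            }
        )
        with pytest.raises(DataError, match="singleton"):
            variance_components(rec, "y", "c")

    def test_balanced_matches_closed_form(self):
        rng = np.random.default_rng(10)
        rec = _balanced_records(rng, n_lines=10, reps=4)
        rec["mass_mg"] = 1.0  # no adjustment: pure one-way ANOVA
        vc = variance_components(rec, "young", "control")
        sub = rec[(rec.age == "young") & (rec.treatment == "control")]
        means = sub.groupby("line_id")["value"].mean()
        msb = 4 * means.var(ddof=1)
        msw = sub.groupby("line_id")["value"].var(ddof=1).mean()
        assert vc.ms_between == pytest.approx(msb)
        assert vc.ms_within == pytest.approx(msw)
        assert vc.n0 == pytest.approx(4.0)


class TestGeneticCorrelation:
    @staticmethod
    def _means(vals, age="y", tr="c"):
        return pd.DataFrame(
            {
                "line_id": [f"L{i}" for i in range(len(vals))],
                "age": age, "treatment": tr, "lsmean": vals, "se": 0.0, "n": 2,
            }
        )

    @staticmethod
    def _vc(var, age="y", tr="c"):
        from linesense import VarianceComponents

        return VarianceComponents(
            age=age, treatment=tr, var_line=var, var_line_raw=var,
            var_error=1.0, n0=2.0, ms_between=0.0, ms_within=1.0, n_lines=5, n_obs=10,
        )

    def test_perfect_scaling_gives_r_one(self):
        vals = np.array([1.0, 2.0, 4.0, 0.5, 3.0])
        a, b = self._means(vals), self._means(2 * vals, tr="t")
        gc = genetic_correlation(
            a, b, self._vc(vals.var(ddof=1)), self._vc((2 * vals).var(ddof=1), tr="t")
        )
        assert gc.defined
        assert gc.r == pytest.approx(1.0, abs=1e-12)

    def test_independent_permutations_center_on_zero(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=30)
        rs = []
        for _ in range(200):
            perm = rng.permutation(vals)
            gc = genetic_correlation(
                self._means(vals), self._means(perm, tr="t"),
                self._vc(vals.var(ddof=1)), self._vc(vals.var(ddof=1), tr="t"),
            )
            rs.append(gc.r)
        assert abs(np.mean(rs)) < 3 / np.sqrt(200 * 29)

    def test_zero_component_marks_undefined(self):
        gc = genetic_correlation(
            self._means([1, 2, 3]), self._means([1, 2, 3], tr="t"),
            self._vc(0.0), self._vc(1.0, tr="t"),
        )
        assert not gc.defined
        assert gc.r is None
        assert np.isfinite(gc.cov12)

    def test_too_few_shared_lines_error(self):
        with pytest.raises(DataError, match="3"):
            genetic_correlation(
                self._means([1, 2]), self._means([3, 4], tr="t"),
                self._vc(1.0), self._vc(1.0, tr="t"),
            )

    def test_r_above_one_not_clamped(self):
        # sampling noise can push |r| past 1 when the supplied components
        # underestimate the line variance; the estimator must report it
        vals = np.array([1.0, 2.0, 4.0, 0.5, 3.0])
        gc = genetic_correlation(
            self._means(vals), self._means(2 * vals, tr="t"),
            self._vc(0.5 * vals.var(ddof=1)), self._vc((2 * vals).var(ddof=1), tr="t"),
        )
        assert gc.r > 1.0
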