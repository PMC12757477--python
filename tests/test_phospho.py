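"""Differential-phosphorylation core: modified Z, both strategies, consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphodiff import phospho, simulate as sim
from phosphodiff.model import (
    AbundanceTable,
    PhosphopeptideRecord,
    SampleDesign,
    Thresholds,
    ValidationError,
)

from conftest import make_table, small_config


def brute_modified_z(xs: list[float]) -> list[float]:
    """Independent oracle: medians by explicit sort, no numpy."""
    def median(v):
        s = sorted(v)
        n = len(s)
        return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2

    med = median(xs)
    devs = [abs(x - med) for x in xs]
    mad = median(devs)
    if mad > 0:
        return [0.6745 * (x - med) / mad for x in xs]
    mean_ad = sum(devs) / len(devs)
    if mean_ad > 0:
        return [(x - med) / (1.253314 * mean_ad) for x in xs]
    return [0.0] * len(xs)


class TestModifiedZ:
    def test_hand_case(self):
        z = phospho.modified_zscore([1, 2, 3, 4, 100])
        assert z[-1] == pytest.approx(0.6745 * 97 / 1, abs=1e-6)
        assert z[-1] == pytest.approx(65.4265, abs=1e-4)

    def test_all_equal_gives_zeros(self):
        assert phospho.modified_zscore([5, 5, 5, 5]) == pytest.approx([0, 0, 0, 0])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            phospho.modified_zscore([1, 2])

    def test_exhaustive_oracle_small_integer_vectors(self):
        """Equality with a brute-force median/MAD oracle on every vector of
        length <= 5 over {0,1,2,3} (longer lengths spot-checked)."""
        for n in (3, 4, 5):
            for xs in itertools.product((0, 1, 2, 3), repeat=n):
                np.testing.assert_allclose(
                    phospho.modified_zscore(list(xs)), brute_modified_z(list(xs)),
                    atol=1e-12, err_msg=str(xs))

    def test_oracle_spot_checks_length_six_seven(self, rng):
        for n in (6, 7):
            for _ in range(300):
                xs = rng.integers(0, 4, size=n).tolist()
                np.testing.assert_allclose(phospho.modified_zscore(xs),
                                           brute_modified_z(xs), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-100, 100).map(float), min_size=3, max_size=20),
           st.floats(0.1, 5), st.floats(-10, 10))
    def test_affine_invariance(self, xs, a, b):
        z1 = phospho.modified_zscore(xs)
        z2 = phospho.modified_zscore([a * x + b for x in xs])
        np.testing.assert_allclose(z1, z2, atol=1e-6)


class TestPtmrsFilter:
    def test_strictly_greater_than(self, th):
        recs = [PhosphopeptideRecord(f"p{s}", "P1", "S1", s) for s in (49, 50, 51)]
        kept = phospho.filter_ptmrs(recs, th)
        assert [r.peptide_id for r in kept] == ["p51"]

    def test_empty_and_identity_cases(self, th):
        assert phospho.filter_ptmrs([], th) == []
        recs = [PhosphopeptideRecord(f"p{i}", "P1", "S1", 100.0) for i in range(3)]
        assert phospho.filter_ptmrs(recs, th) == recs


class TestNormalize:
    def _records(self):
        return [PhosphopeptideRecord("pep1", "P1", "S3", 80.0),
                PhosphopeptideRecord("pep2", "P2", "T7", 80.0)]

    def test_elementwise_ratio(self):
        pep = make_table([[10.0, 6.0]], features=["pep1"], kind="phosphopeptide")
        prot = make_table([[5.0, 3.0]], features=["P1"])
        norm = phospho.normalize_phospho(pep, prot, self._records()[:1])
        assert norm.values.loc["pep1"].tolist() == pytest.approx([2.0, 2.0])

    def test_scale_invariance_per_sample(self):
        pep = make_table([[10.0, 6.0]], features=["pep1"], kind="phosphopeptide")
        prot = make_table([[5.0, 3.0]], features=["P1"])
        pep7 = make_table([[70.0, 6.0]], features=["pep1"], kind="phosphopeptide")
        prot7 = make_table([[35.0, 3.0]], features=["P1"])
        n1 = phospho.normalize_phospho(pep, prot, self._records()[:1])
        n2 = phospho.normalize_phospho(pep7, prot7, self._records()[:1])
        pd.testing.assert_frame_equal(n1.values, n2.values)

    def test_missing_parent_value_propagates_mask(self):
        pep = make_table([[10.0, 6.0]], features=["pep1"], kind="phosphopeptide")
        prot = make_table([[5.0, np.nan]], features=["P1"])
        norm = phospho.normalize_phospho(pep, prot, self._records()[:1])
        assert norm.values.loc["pep1", "s0"] == 2.0
        assert np.isnan(norm.values.loc["pep1", "s1"])

    def test_absent_parent_drops_peptide_with_log(self):
        pep = make_table([[10.0], [4.0]], features=["pep1", "pep2"],
                         kind="phosphopeptide")
        prot = make_table([[5.0]], features=["P1"])
        norm = phospho.normalize_phospho(pep, prot, self._records())
        assert norm.values.index.tolist() == ["pep1"]
        assert norm.dropped == [("pep2", "parent protein 'P2' absent from protein table")]


class TestStrategy1:
    def test_equal_fold_changes_never_outliers(self, th):
        idx = [f"p{i}" for i in range(6)]
        a = pd.Series([1.0, 2.0, -1.0, 0.5, 1.5, 3.0], index=idx)
        res = phospho.strategy1(a, a.copy(), th)
        # identical A and B: trend line is the identity, D collapses to zero
        assert res["D"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert not res["is_outlier"].any()

    def test_normalized_difference_formula(self, th):
        idx = ["p0", "p1", "p2", "p3"]
        a = pd.Series([1.0, 2.0, 1.0, 4.0], index=idx)
        b = pd.Series([3.0, 2.0, 1.0, 4.0], index=idx)
        res = phospho.strategy1(a, b, th).set_index("peptide_id")
        # intercept of the fitted trend is subtracted before D
        c = res.attrs["intercept"]
        expected = (max(1.0, 3.0 - c) - min(1.0, 3.0 - c)) / (1.0 + 3.0 - c)
        assert res.loc["p0", "D"] == pytest.approx(expected)

    def test_pure_example_d_of_1_and_3_is_half(self):
        # the statistic itself, with no intercept correction needed
        a, b = 1.0, 3.0
        assert (max(a, b) - min(a, b)) / (a + b) == pytest.approx(0.5)

    def test_refit_intercept_is_zero(self, th, rng):
        idx = [f"p{i}" for i in range(40)]
        a = pd.Series(rng.normal(0, 1, 40), index=idx)
        b = pd.Series(a + rng.normal(0.7, 0.3, 40), index=idx)
        res = phospho.strategy1(a, b, th)
        slope, intercept = np.polyfit(res["A"], res["B"], 1)
        assert abs(intercept) < 1e-9

    def test_near_zero_denominator_excluded_not_clamped(self, th):
        idx = [f"p{i}" for i in range(5)]
        a = pd.Series([1.0, 2.0, 3.0, 1.5, 0.5], index=idx)
        b = -a + pd.Series([0.0, 4.0, 6.0, 3.0, 1.0], index=idx)  # p0 has A+B ~ 0
        res = phospho.strategy1(a, b, th, delta=1e-6).set_index("peptide_id")
        if res.loc["p0", "excluded"]:
            assert np.isnan(res.loc["p0", "D"])

    def test_fewer_than_three_peptides_rejected(self, th):
        s = pd.Series([1.0, 2.0], index=["p0", "p1"])
        with pytest.raises(ValidationError):
            phospho.strategy1(s, s, th)


def _two_condition_design():
    rows = [(f"WT_{i}", "WT", i) for i in (1, 2, 3, 4)]
    rows += [(f"M_{i}", "M", i) for i in (1, 2, 3)]
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"]))


def _const_norm_table(mut_val, wt_val, parent="P1"):
    design = _two_condition_design()
    vals = {f"WT_{i}": wt_val for i in (1, 2, 3, 4)}
    vals.update({f"M_{i}": mut_val for i in (1, 2, 3)})
    df = pd.DataFrame(vals, index=["pep1"])
    return phospho.NormalizedPhosphoTable(values=df, parent={"pep1": parent}), design


class TestStrategy2:
    def test_closed_form_worked_example(self, th):
        """Phospho ratios all exactly 3, protein ratios all exactly 1, 3x4
        replicates: 12 ratios per side, log2(3+1)=2 vs log2(1+1)=1, effect 1,
        degenerate zero-variance rule gives p_raw = 0."""
        norm, design = _const_norm_table(3.0, 1.0)
        prot = make_table(np.full((1, 7), 5.0), features=["P1"],
                          samples=design.sample_ids)
        res = phospho.strategy2(norm, prot, design, "M", "WT", th)
        row = res.iloc[0]
        assert row["n_ratios"] == 12
        assert row["log2fc_phospho"] == pytest.approx(2.0)
        assert row["log2fc_tot"] == pytest.approx(1.0)
        assert row["effect"] == pytest.approx(1.0)
        assert row["p_raw"] == 0.0

    def test_equal_ratio_sets_give_p_one(self, th):
        norm, design = _const_norm_table(3.0, 1.0)
        prot_vals = {f"WT_{i}": 1.0 for i in (1, 2, 3, 4)}
        prot_vals.update({f"M_{i}": 3.0 for i in (1, 2, 3)})
        prot = AbundanceTable(pd.DataFrame(prot_vals, index=["P1"]), "protein")
        res = phospho.strategy2(norm, prot, design, "M", "WT", th)
        assert res.iloc[0]["effect"] == pytest.approx(0.0)
        assert res.iloc[0]["p_raw"] == 1.0

    def test_proportional_peptide_effect_vanishes_at_high_abundance(self, th, rng):
        """A phosphopeptide perfectly proportional to its protein has effect
        -> 0 as abundances grow (the +1 pseudocount becomes negligible)."""
        design = _two_condition_design()
        base = 2.0 ** 20
        prot_vals = base * np.exp2(rng.normal(0, 0.2, 7))
        prot = make_table(prot_vals[None, :], features=["P1"],
                          samples=design.sample_ids)
        pep = phospho.NormalizedPhosphoTable(
            values=prot.values.loc[["P1"]].set_axis(["pep1"]) * 0.3,
            parent={"pep1": "P1"})
        res = phospho.strategy2(pep, prot, design, "M", "WT", th)
        assert abs(res.iloc[0]["effect"]) < 0.05

    def test_antisymmetry_under_label_swap_in_small_pseudocount_limit(self, rng):
        """Swapping mutant and control flips the effect's sign once the ratio
        pseudocount is negligible (with the default +1 the transform is not
        antisymmetric: log2(r+1) is not odd in log r)."""
        th_eps = Thresholds(pseudocount_ratio=1e-9)
        design = _two_condition_design()
        base = 2.0 ** 22
        prot = make_table(base * np.exp2(rng.normal(0, 0.2, (1, 7))),
                          features=["P1"], samples=design.sample_ids)
        pepvals = prot.values.loc[["P1"]].set_axis(["pep1"]) * 0.3
        pepvals[design.samples_for("M")] *= 4.0
        pep = phospho.NormalizedPhosphoTable(values=pepvals, parent={"pep1": "P1"})
        fwd = phospho.strategy2(pep, prot, design, "M", "WT", th_eps).iloc[0]["effect"]
        rev = phospho.strategy2(pep, prot, design, "WT", "M", th_eps).iloc[0]["effect"]
        assert fwd == pytest.approx(-rev, abs=1e-6)
        assert fwd == pytest.approx(2.0, abs=1e-6)

    def test_bonferroni_family_is_all_tests(self, th):
        d1 = pd.DataFrame({"peptide_id": ["a", "b"], "condition": "c1",
                           "log2fc_phospho": 1.0, "log2fc_tot": 0.0,
                           "effect": 1.0, "p_raw": [0.01, 0.4], "n_ratios": 12})
        d2 = d1.assign(condition="c2")
        out = phospho.bonferroni_finalize({"c1": d1, "c2": d2}, th)
        assert out["p_adj"].tolist() == pytest.approx([0.04, 1.0, 0.04, 1.0])


class TestConsensus:
    def _s1(self, flagged, cond):
        return pd.DataFrame({"peptide_id": ["a", "b", "c"], "condition": cond,
                             "is_outlier": [p in flagged for p in "abc"]})

    def _s2(self, rows):
        return pd.DataFrame(rows, columns=["peptide_id", "condition", "is_significant"])

    def test_both_strategies_two_conditions_is_high(self):
        calls1 = {"c1": self._s1({"a"}, "c1"), "c2": self._s1({"a"}, "c2")}
        calls2 = self._s2([("a", "c1", True)])
        out = phospho.consensus(calls1, calls2).set_index("peptide_id")
        assert out.loc["a", "confidence"] == "high"

    def test_single_strategy_is_candidate(self):
        calls1 = {"c1": self._s1({"a"}, "c1"), "c2": self._s1({"a"}, "c2")}
        out = phospho.consensus(calls1, self._s2([])).set_index("peptide_id")
        assert out.loc["a", "confidence"] == "candidate"

    def test_no_flags_gives_empty_calls(self):
        calls1 = {"c1": self._s1(set(), "c1")}
        assert phospho.consensus(calls1, self._s2([])).empty

    def test_disjoint_universes_is_error(self):
        calls1 = {"c1": self._s1({"a"}, "c1")}
        calls2 = self._s2([("zzz", "c1", True)])
        calls2["peptide_id"] = ["zzz"]
        with pytest.raises(ValidationError):
            phospho.consensus(calls1, calls2)

    def test_high_confidence_sorted_first(self):
        calls1 = {"c1": self._s1({"a", "b"}, "c1"), "c2": self._s1({"b"}, "c2")}
        calls2 = self._s2([("b", "c1", True)])
        out = phospho.consensus(calls1, calls2)
        assert out.iloc[0]["peptide_id"] == "b"
        assert out.iloc[0]["confidence"] == "high"


class TestRecovery:
    def test_planted_peptides_recovered_single_seed(self, bundle, th):
        res = phospho.run_dphospho(bundle.phosphopeptides, bundle.proteins,
                                   bundle.phospho_records, bundle.design_protein,
                                   th, mutants=list(bundle.config.mutants))
        planted = set(bundle.truth.dphospho_ids)
        flagged1 = set()
        for df in res["strategy1"].values():
            flagged1 |= set(df.loc[df["is_outlier"], "peptide_id"])
        s2 = res["strategy2"]
        flagged2 = set(s2.loc[s2["is_significant"], "peptide_id"])
        union = flagged1 | flagged2
        assert len(union & planted) / len(planted) >= 0.8
        cons = res["consensus"]
        both = set(cons.loc[cons["by_strategy1"] & cons["by_strategy2"], "peptide_id"])
        # the consensus of both strategies is the precise caller
        assert len(both - planted) / max(len(both), 1) <= 0.25
        assert len(both & planted) / len(planted) >= 0.8

    def test_effect_monotonicity(self, th):
        """Doubling the planted effect must not decrease union sensitivity."""
        def union_sens(effect, seed):
            b = sim.simulate(small_config(seed=seed, effect_log2=effect))
            res = phospho.run_dphospho(b.phosphopeptides, b.proteins,
                                       b.phospho_records, b.design_protein, th,
                                       mutants=list(b.config.mutants))
            flagged = set()
            for df in res["strategy1"].values():
                flagged |= set(df.loc[df["is_outlier"], "peptide_id"])
            s2 = res["strategy2"]
            flagged |= set(s2.loc[s2["is_significant"], "peptide_id"])
            planted = set(b.truth.dphospho_ids)
            return len(flagged & planted) / len(planted)

        lo = np.mean([union_sens(1.0, s) for s in range(4)])
        hi = np.mean([union_sens(2.0, s) for s in range(4)])
        assert hi >= lo - 1e-9
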