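"""Domain-type invariants and tabular round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphodiff import io as pio
from phosphodiff.model import (
    AbundanceTable,
    ContrastResult,
    FormatError,
    PhosphopeptideRecord,
    SampleDesign,
    Thresholds,
    ValidationError,
)


class TestDesign:
    def test_read_design_counts_conditions(self, tmp_path):
        p = tmp_path / "design.tsv"
        rows = ["sample_id\tcondition\treplicate"]
        rows += [f"lp{i}\tLP\t{i}" for i in (1, 2, 3)]
        rows += [f"wt{i}\tWT\t{i}" for i in (1, 2, 3, 4)]
        p.write_text("\n".join(rows) + "\n")
        d = pio.read_design(p)
        assert d.condition_sizes() == {"LP": 3, "WT": 4}
        assert d.conditions == ["LP", "WT"]

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(FormatError):
            pio.read_design(p)

    def test_duplicate_sample_id_names_offender(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("sample_id\tcondition\treplicate\ns1\tWT\t1\ns1\tWT\t2\n")
        with pytest.raises(ValidationError, match="s1"):
            pio.read_design(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tcondition\ns1\tWT\n")
        with pytest.raises(FormatError, match="replicate"):
            pio.read_design(p)

    def test_replicate_requirement_enforced(self, toy_design):
        with pytest.raises(ValidationError, match="WT"):
            toy_design.require_replicates(["WT"], minimum=4)


class TestAbundance:
    def test_round_trip_preserves_values_and_missing(self, tmp_path, rng):
        vals = rng.lognormal(10, 1, size=(6, 4))
        df = pd.DataFrame(vals, index=[f"f{i}" for i in range(6)],
                          columns=[f"s{j}" for j in range(4)])
        df.iloc[1, 2] = np.nan
        t = AbundanceTable(df, "protein")
        path = tmp_path / "ab.tsv"
        pio.write_abundance(t, path)
        back = pio.read_abundance(path, "protein")
        pd.testing.assert_frame_equal(back.values, t.values, rtol=1e-11,
                                      check_names=False)
        assert back.values.isna().equals(t.values.isna())

    def test_na_cell_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "ab.tsv"
        p.write_text("feature_id\ts1\ts2\nf1\tNA\t4.0\nf2\t2.0\t8.0\n")
        t = pio.read_abundance(p)
        assert np.isnan(t.values.loc["f1", "s1"])
        # imputing zero for the missing cell must change the mean
        assert t.values.loc["f1"].mean() == 4.0
        assert t.values.loc["f1"].fillna(0.0).mean() == 2.0

    def test_negative_abundance_rejected_with_location(self, tmp_path):
        p = tmp_path / "ab.tsv"
        p.write_text("feature_id\ts1\nf1\t-5.0\n")
        with pytest.raises(ValidationError, match="f1"):
            pio.read_abundance(p)

    def test_non_numeric_cell_is_format_error(self, tmp_path):
        p = tmp_path / "ab.tsv"
        p.write_text("feature_id\ts1\nf1\tabc\n")
        with pytest.raises(FormatError):
            pio.read_abundance(p)

    def test_duplicate_feature_ids_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["f1", "f1"], columns=["s1"])
        with pytest.raises(ValidationError, match="f1"):
            AbundanceTable(df)


class TestContrastIO:
    def _results(self, n=10, seed=0):
        r = np.random.default_rng(seed)
        p_raw = np.sort(r.uniform(0, 1, n))
        p_adj = np.minimum(1.0, p_raw * 1.3)
        return [
            ContrastResult(f"f{i}", float(r.normal()), float(p_raw[i]),
                           float(p_adj[i]), "unchanged")
            for i in range(n)
        ]

    def test_round_trip_12_significant_digits(self, tmp_path):
        results = self._results()
        path = tmp_path / "c.tsv"
        pio.write_contrast(results, path)
        back = pio.read_contrast(path)
        for a, b in zip(results, back):
            assert a.feature_id == b.feature_id
            assert a.log2fc == pytest.approx(b.log2fc, rel=1e-11)
            assert a.p_adj == pytest.approx(b.p_adj, rel=1e-11)

    def test_empty_list_is_error_not_empty_file(self, tmp_path):
        path = tmp_path / "c.tsv"
        with pytest.raises(ValidationError):
            pio.write_contrast([], path)
        assert not path.exists()

    def test_p_adj_below_p_raw_rejected(self):
        with pytest.raises(ValidationError):
            ContrastResult("f1", 0.0, 0.5, 0.1)


class TestMappingAndGmt:
    def test_duplicate_mapping_is_ambiguity_error(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("protein_id\tgene_id\nP1\tG1\nP1\tG2\n")
        with pytest.raises(ValidationError, match="P1"):
            pio.read_mapping(p)

    def test_gmt_round_trip(self, tmp_path):
        sets = {"setA": {"description": "db1", "members": {"g1", "g2"}},
                "setB": {"description": "db2", "members": {"g3"}}}
        p = tmp_path / "x.gmt"
        pio.write_gmt(sets, p)
        back = pio.read_gmt(p)
        assert back == sets

    def test_gmt_short_line_rejected(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("name_only\tdesc\n")
        with pytest.raises(FormatError):
            pio.read_gmt(p)


class TestThresholds:
    def test_defaults_match_published_settings(self):
        t = Thresholds()
        assert (t.alpha_adj, t.log2fc_min) == (0.05, 0.585)
        assert (t.z_dphospho, t.z_concordance, t.ptmrs_min) == (1.0, 3.5, 50.0)

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            Thresholds(alpha_adj=0.0)

    def test_ptmrs_score_range_enforced(self):
        with pytest.raises(ValidationError):
            PhosphopeptideRecord("p", "P", "S5", 101.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(2, 8), st.integers(2, 5), st.integers(0, 10 ** 6))
def test_abundance_round_trip_randomized(tmp_path_factory, n_feat, n_samp, seed):
    """Write-then-read is the identity for arbitrary non-negative tables."""
    r = np.random.default_rng(seed)
    vals = r.lognormal(8, 2, size=(n_feat, n_samp))
    mask = r.random((n_feat, n_samp)) < 0.2
    df = pd.DataFrame(np.where(mask, np.nan, vals),
                      index=[f"f{i}" for i in range(n_feat)],
                      columns=[f"s{j}" for j in range(n_samp)])
    t = AbundanceTable(df, "transcript")
    path = tmp_path_factory.mktemp("rt") / "t.tsv"
    pio.write_abundance(t, path)
    back = pio.read_abundance(path, "transcript")
    pd.testing.assert_frame_equal(back.values, t.values, rtol=1e-11, check_names=False)
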