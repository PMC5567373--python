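import numpy as np
import pandas as pd
import pytest

from metconc.dataio import Dataset, MetaboliteRecord
from metconc.features import (
    FeatureMatrix,
    build_mpf,
    clogp_bin_report,
    filter_near_constant_pathways,
    pathway_deviation_table,
    pathway_variables,
    preprocess,
    read_pathway_membership,
)

MEMBERS = {
    "glu": {"Map02020", "Map00010"},
    "ala": {"Map00010"},
    "x1": set(),
    "x2": {"Map02020", "Map00010"},
}
ROWS = ["glu:eco", "ala:eco", "x1:eco", "x2:eco"]


class TestPathwayVariables:
    def test_binary_membership_columns(self):
        pv = pathway_variables(MEMBERS, {"Map02020", "Map00010"}, ROWS)
        assert pv.frame.loc["glu:eco", "Map02020"] == 1.0
        assert pv.frame.loc["x1:eco"].tolist() == [0.0, 0.0]
        assert set(pv.origin) == {"pathway"}

    def test_identical_membership_identical_rows(self):
        pv = pathway_variables(MEMBERS, {"Map02020", "Map00010"}, ROWS)
        assert pv.frame.loc["glu:eco"].equals(pv.frame.loc["x2:eco"])

    def test_empty_pathway_set_rejected(self):
        with pytest.raises(ValueError):
            pathway_variables(MEMBERS, set(), ROWS)


class TestMPF:
    def test_mpf_is_or_of_pathway_columns(self):
        selected = {"Map02020", "Map00010"}
        pv = pathway_variables(MEMBERS, selected, ROWS)
        mpf = build_mpf(MEMBERS, selected, ROWS)
        expected = (pv.frame.max(axis=1) > 0).astype(float)
        assert mpf.tolist() == expected.tolist()

    def test_member_and_nonmember(self):
        mpf = build_mpf(MEMBERS, {"Map02020"}, ROWS)
        assert mpf["glu:eco"] == 1.0 and mpf["ala:eco"] == 0.0

    def test_or_saturation_with_all_pathways(self):
        mpf = build_mpf(MEMBERS, {"Map02020", "Map00010", "Map09999"}, ROWS)
        assert mpf["x1:eco"] == 0.0
        assert mpf.drop("x1:eco").eq(1.0).all()


class TestPreprocess:
    def _matrix(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "informative": rng.normal(size=20),
                "constant": np.full(20, 3.14),
                "tiny_sd": 1.0 + rng.normal(scale=1e-4, size=20),
                "ok": rng.normal(size=20),
            }
        )
        return FeatureMatrix(frame, {c: "molecular" for c in frame.columns})

    def test_filters_and_report_partition(self):
        fm, rep = preprocess(self._matrix())
        assert rep.removed_constant == ["constant"]
        assert rep.removed_low_sd == ["tiny_sd"]
        assert sorted(rep.kept + rep.removed_constant + rep.removed_low_sd) == sorted(
            ["informative", "constant", "tiny_sd", "ok"]
        )
        assert fm.column_names == rep.kept

    def test_idempotent(self):
        fm1, _ = preprocess(self._matrix())
        fm2, rep2 = preprocess(fm1)
        assert fm2.frame.equals(fm1.frame)
        assert rep2.removed_constant == [] and rep2.removed_low_sd == []

    def test_all_removed_rejected(self):
        frame = pd.DataFrame({"c1": [1.0] * 5, "c2": [2.0] * 5})
        with pytest.raises(ValueError):
            preprocess(FeatureMatrix(frame, {"c1": "molecular", "c2": "molecular"}))

    def test_origin_tags_preserved(self):
        m = self._matrix()
        m = m.join(
            FeatureMatrix(
                pd.DataFrame({"Map1": np.r_[np.zeros(10), np.ones(10)]}, index=m.frame.index),
                {"Map1": "pathway"},
            )
        )
        fm, _ = preprocess(m)
        assert fm.origin["Map1"] == "pathway"
        assert fm.subset(["Map1", "ok"]).origin.tolist() == ["pathway", "molecular"]


def test_near_constant_pathway_filter():
    frame = pd.DataFrame(
        {"common": [1, 1, 0, 0, 1], "rare": [1, 0, 0, 0, 0], "all0": [0, 0, 0, 0, 0]},
        dtype=float,
    )
    pv = FeatureMatrix(frame, {c: "pathway" for c in frame.columns})
    kept, dropped = filter_near_constant_pathways(pv, min_minority=2)
    assert kept.column_names == ["common"]
    assert sorted(dropped) == ["all0", "rare"]


class TestFeatureMatrixIO:
    def test_round_trip_with_origin(self, tmp_path):
        frame = pd.DataFrame(
            {"a": [1.0, 2.0], "Map1": [0.0, 1.0]}, index=["m1:eco", "m2:eco"]
        )
        fm = FeatureMatrix(frame, {"a": "molecular", "Map1": "pathway"})
        fm.to_csv(tmp_path / "fm.csv")
        back = FeatureMatrix.from_csv(tmp_path / "fm.csv")
        assert back.frame.equals(fm.frame)
        assert back.origin.to_dict() == fm.origin.to_dict()

    def test_strict_rejects_missing_lenient_imputes(self, tmp_path):
        (tmp_path / "m.csv").write_text("row_key,a,b\nr1,1.0,2.0\nr2,,4.0\n")
        with pytest.raises(ValueError, match="missing"):
            FeatureMatrix.from_csv(tmp_path / "m.csv")
        fm = FeatureMatrix.from_csv(tmp_path / "m.csv", strict=False)
        assert fm.frame.loc["r2", "a"] == 1.0  # column mean

    def test_duplicate_columns_rejected(self):
        frame = pd.DataFrame([[1.0, 2.0]], columns=["a", "a"])
        with pytest.raises(ValueError):
            FeatureMatrix(frame, {"a": "molecular"})


def test_membership_tsv_and_gmt(tmp_path):
    (tmp_path / "m.tsv").write_text("metabolite_id\tpathway_id\nglu\tMap1\nglu\tMap2\nala\tMap1\n")
    assert read_pathway_membership(tmp_path / "m.tsv") == {"glu": {"Map1", "Map2"}, "ala": {"Map1"}}
    (tmp_path / "m.gmt").write_text("Map1\tdesc\tglu\tala\nMap2\tdesc\tglu\n")
    assert read_pathway_membership(tmp_path / "m.gmt") == {"glu": {"Map1", "Map2"}, "ala": {"Map1"}}


class TestCLogPBins:
    def test_perfectly_linear_gives_r2_one(self):
        clogp = {f"m{i}": -3.0 + 0.5 * i for i in range(12)}
        ds = Dataset(
            [
                MetaboliteRecord(f"m{i}", organism="eco", neg_log_c=2.0 + 0.8 * clogp[f"m{i}"])
                for i in range(12)
            ]
        )
        table, r2 = clogp_bin_report(ds, clogp)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert len(table) >= 3

    def test_single_bin_rejected(self):
        clogp = {f"m{i}": -2.01 - 0.001 * i for i in range(5)}
        ds = Dataset(
            [MetaboliteRecord(f"m{i}", organism="eco", neg_log_c=1.0 + i) for i in range(5)]
        )
        with pytest.raises(ValueError):
            clogp_bin_report(ds, clogp)


class TestPathwayDeviation:
    def test_single_member_means_equal_member(self):
        ds = Dataset(
            [
                MetaboliteRecord("glu", name="Glutamate", organism="eco", neg_log_c=1.02),
                MetaboliteRecord("glu", name="Glutamate", organism="sce", neg_log_c=1.09),
            ]
        )
        table, summary = pathway_deviation_table(ds, ["glu"], {"glu": -2.69})
        assert summary["mean_neg_log_c"] == {"eco": 1.02, "sce": 1.09}
        assert summary["mean_clogp"] == -2.69

    def test_na_entries_excluded_from_means(self):
        ds = Dataset(
            [
                MetaboliteRecord("a", organism="eco", neg_log_c=2.0),
                MetaboliteRecord("a", organism="sce", neg_log_c=4.0),
                MetaboliteRecord("b", organism="eco", neg_log_c=6.0),
            ]
        )
        table, summary = pathway_deviation_table(ds, ["a", "b"], {"a": -1.0, "b": -3.0})
        assert summary["mean_neg_log_c"]["eco"] == pytest.approx(4.0)
        assert summary["mean_neg_log_c"]["sce"] == pytest.approx(4.0)  # only one value
        assert summary["n_non_na"] == {"eco": 2, "sce": 1}

    def test_empty_member_set_rejected(self):
        ds = Dataset([MetaboliteRecord("a", organism="eco", neg_log_c=1.0)])
        with pytest.raises(ValueError):
            pathway_deviation_table(ds, [], {})
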