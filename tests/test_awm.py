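"""AWM construction: nearest-gene annotation, selection rules, z-scoring."""

import numpy as np
import pandas as pd
import pytest

from bfawm.awm import annotate_nearest_gene, select_awm_rows, zscore_matrix

TRAITS = [f"T{i}" for i in range(1, 8)]
KEY = "T1"


def _genes():
    return pd.DataFrame(
        {
            "gene_id": ["GA", "GB", "GC"],
            "chrom": ["1", "1", "2"],
            "start": [100_000, 500_000, 50_000],
            "end": [120_000, 520_000, 80_000],
            "strand": ["+", "-", "+"],
        }
    )


class TestNearestGene:
    def test_snp_inside_gene_is_genic(self):
        mmap = pd.DataFrame({"marker_id": ["M0"], "chrom": ["1"], "pos_bp": [110_000]})
        out = annotate_nearest_gene(mmap, _genes())
        assert out.loc[0, "gene_id"] == "GA"
        assert out.loc[0, "distance_bp"] == 0
        assert out.loc[0, "region_class"] == "genic"

    def test_downstream_distance(self):
        # gene GA ends at 120000; SNP at 123121 sits 3121 bp downstream
        mmap = pd.DataFrame({"marker_id": ["M0"], "chrom": ["1"], "pos_bp": [123_121]})
        out = annotate_nearest_gene(mmap, _genes())
        assert out.loc[0, "gene_id"] == "GA"
        assert out.loc[0, "distance_bp"] == 3121
        assert out.loc[0, "region_class"] == "intergenic"

    def test_equidistant_tie_breaks_to_smaller_start(self):
        # midpoint between GA end (120000) and GB start (500000)
        mmap = pd.DataFrame({"marker_id": ["M0"], "chrom": ["1"], "pos_bp": [310_000]})
        out = annotate_nearest_gene(mmap, _genes())
        assert out.loc[0, "gene_id"] == "GA"

    def test_gene_free_chromosome_unannotated(self):
        mmap = pd.DataFrame({"marker_id": ["M0"], "chrom": ["9"], "pos_bp": [1000]})
        out = annotate_nearest_gene(mmap, _genes())
        assert out.loc[0, "gene_id"] is None
        assert np.isnan(out.loc[0, "distance_bp"])


def _selection_fixture():
    """12 SNPs x 7 traits with hand-set BFs, distances and gene links."""
    markers = [f"M{j:02d}" for j in range(12)]
    bf = pd.DataFrame(0.1, index=pd.Index(markers, name="marker_id"), columns=TRAITS)
    # key-trait significant:
    bf.loc["M00", KEY] = 10.0                      # gene g1, d=5000 -> kept (literal)
    bf.loc["M01", KEY] = 5.0                       # gene g1, d=10000 -> duplicate of g1
    bf.loc["M02", KEY] = 8.0                       # d=1000 -> killed by literal filter
    bf.loc["M03", KEY] = 8.0                       # d=2_000_000 -> killed both modes
    # multi-trait significant (key not significant):
    bf.loc["M04", ["T2", "T3"]] = [6.0, 4.0]       # gene g2, d=3000 -> kept
    bf.loc["M05", "T2"] = 50.0                     # only ONE trait -> dropped at step 1
    bf.loc["M06", ["T2", "T3", "T4"]] = 5.0        # gene g3, d=4000 -> kept (3 traits)
    bf.loc["M07", ["T5", "T6"]] = 5.0              # gene g3, d=2500  -> loses to M06
    # unannotated survivor:
    bf.loc["M08", [KEY, "T7"]] = [4.0, 4.0]        # no gene on its chromosome
    # boundary: BF exactly 3.2 counts as significant (>= bf_min)
    bf.loc["M09", ["T2", "T3"]] = 3.2              # gene g4, d=0 (genic) -> literal kills
    # M10, M11 stay insignificant everywhere
    links = pd.DataFrame(
        {
            "marker_id": markers,
            "gene_id": ["g1", "g1", "g1", "g2", "g2", "g2", "g3", "g3", None,
                        "g4", "g4", "g1"],
            "distance_bp": [5000.0, 10_000.0, 1000.0, 2_000_000.0, 3000.0, 1200.0,
                            4000.0, 2500.0, np.nan, 0.0, 900.0, 800.0],
            "region_class": ["intergenic"] * 8 + ["unannotated", "genic",
                                                  "intergenic", "intergenic"],
        }
    )
    mmap = pd.DataFrame(
        {"marker_id": markers, "chrom": "1", "pos_bp": np.arange(12) * 100_000}
    )
    return bf, links, mmap


class TestSelectRows:
    def test_literal_mode_hand_enumerated(self):
        bf, links, mmap = _selection_fixture()
        out = select_awm_rows(bf, links, mmap, KEY, mode="literal")
        assert set(out["row_id"]) == {"g1", "g2", "g3", "M08"}
        chosen = out.set_index("row_id")["marker_id"]
        assert chosen["g1"] == "M00"   # higher key BF than M01
        assert chosen["g2"] == "M04"
        assert chosen["g3"] == "M06"   # 3 significant traits beat 2

    def test_proximal_mode_hand_enumerated(self):
        bf, links, mmap = _selection_fixture()
        out = select_awm_rows(bf, links, mmap, KEY, mode="proximal")
        # only d <= 2500 survives: M02 (g1, d=1000), M07 (g3, d=2500),
        # M09 (g4, genic) and the unannotated M08
        assert set(out["row_id"]) == {"g1", "g3", "g4", "M08"}
        chosen = out.set_index("row_id")["marker_id"]
        assert chosen["g1"] == "M02"
        assert chosen["g3"] == "M07"
        assert chosen["g4"] == "M09"

    def test_single_nonkey_trait_dropped(self):
        bf, links, mmap = _selection_fixture()
        out = select_awm_rows(bf, links, mmap, KEY, mode="literal")
        assert "M05" not in set(out["marker_id"])

    def test_filter_is_idempotent(self):
        bf, links, mmap = _selection_fixture()
        first = select_awm_rows(bf, links, mmap, KEY, mode="literal")
        bf2 = bf.loc[first["marker_id"]]
        links2 = links[links["marker_id"].isin(first["marker_id"])]
        second = select_awm_rows(bf2, links2, mmap, KEY, mode="literal")
        assert set(second["row_id"]) == set(first["row_id"])

    def test_one_row_per_gene(self):
        bf, links, mmap = _selection_fixture()
        out = select_awm_rows(bf, links, mmap, KEY, mode="literal")
        genes = out["gene_id"].dropna()
        assert genes.is_unique

    def test_missing_key_trait_rejected(self):
        bf, links, mmap = _selection_fixture()
        with pytest.raises(KeyError):
            select_awm_rows(bf, links, mmap, "NOPE")

    def test_unannotated_can_be_excluded(self):
        bf, links, mmap = _selection_fixture()
        out = select_awm_rows(bf, links, mmap, KEY, keep_unannotated=False)
        assert "M08" not in set(out["row_id"])


class TestZScore:
    def _selected(self, markers):
        return pd.DataFrame({"row_id": markers, "marker_id": markers})

    def test_simple_column(self):
        eff = pd.DataFrame({"T1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        z = zscore_matrix(self._selected(["a", "b", "c"]), eff)
        np.testing.assert_allclose(z["T1"], [-1.0, 0.0, 1.0])

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        markers = [f"M{j}" for j in range(40)]
        eff = pd.DataFrame(rng.standard_normal((40, 7)), index=markers, columns=TRAITS)
        z = zscore_matrix(self._selected(markers), eff)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance_per_trait(self):
        rng = np.random.default_rng(1)
        markers = [f"M{j}" for j in range(10)]
        eff = pd.DataFrame(rng.standard_normal((10, 3)), index=markers,
                           columns=["T1", "T2", "T3"])
        z1 = zscore_matrix(self._selected(markers), eff)
        z2 = zscore_matrix(self._selected(markers), eff * 3.5 + 7.0)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_constant_column_rejected_with_trait_name(self):
        eff = pd.DataFrame({"T1": [1.0, 1.0, 1.0], "T2": [1.0, 2.0, 3.0]},
                           index=["a", "b", "c"])
        with pytest.raises(ValueError, match="T1"):
            zscore_matrix(self._selected(["a", "b", "c"]), eff)

    def test_too_few_rows_rejected(self):
        eff = pd.DataFrame({"T1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            zscore_matrix(self._selected(["a", "b"]), eff)
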