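"""Gene-centric annotation: identifier rules, target resolution, channel fusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicstack.annotate import (OmicsMatrix, build_gene_table,
                                normalize_mirna_id, resolve_cpg_genes,
                                resolve_mirna_targets)


class TestMirnaNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("hsa-miR-21-5p", "hsa-mir-21"),
        ("hsa-mir-21", "hsa-mir-21"),
        ("HSA-MIR-155.1", "hsa-mir-155"),
        ("hsa-miR-7-3p.2", "hsa-mir-7"),
        ("  hsa-miR-99a  ", "hsa-mir-99a"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_mirna_id(raw) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_mirna_id("   ")

    @given(st.text(alphabet="abcdefghij-0123456789.RpP", min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_idempotent(self, raw):
        try:
            once = normalize_mirna_id(raw)
        except ValueError:
            return
        assert normalize_mirna_id(once) == once


class TestTargetResolution:
    def test_strict_maximum_wins(self):
        table = pd.DataFrame([("m1", "G1", 5), ("m1", "G2", 3)],
                             columns=["mirna_id", "target_gene", "report_count"])
        assert resolve_mirna_targets(table) == {"m1": "G1"}

    def test_tie_breaks_lexicographically(self):
        table = pd.DataFrame([("m1", "G2", 4), ("m1", "G1", 4)],
                             columns=["mirna_id", "target_gene", "report_count"])
        assert resolve_mirna_targets(table) == {"m1": "G1"}

    def test_counts_summed_over_duplicate_rows(self):
        table = pd.DataFrame(
            [("m1", "G2", 3), ("m1", "G2", 3), ("m1", "G1", 5)],
            columns=["mirna_id", "target_gene", "report_count"])
        assert resolve_mirna_targets(table) == {"m1": "G2"}

    def test_empty_table(self):
        table = pd.DataFrame(columns=["mirna_id", "target_gene", "report_count"])
        assert resolve_mirna_targets(table) == {}

    def test_ids_normalized_before_grouping(self):
        table = pd.DataFrame(
            [("hsa-miR-21-5p", "G1", 2), ("hsa-mir-21", "G1", 2),
             ("hsa-mir-21", "G2", 3)],
            columns=["mirna_id", "target_gene", "report_count"])
        assert resolve_mirna_targets(table) == {"hsa-mir-21": "G1"}


class TestCpgResolution:
    def test_duplicates_merged_preserving_order(self):
        table = pd.DataFrame([("cg1", "GENE1;GENE1;GENE2")],
                             columns=["probe_id", "gene_list"])
        assert resolve_cpg_genes(table) == {"cg1": ("GENE1", "GENE2")}

    def test_single_gene_uppercased(self):
        table = pd.DataFrame([("cg1", "gene1")], columns=["probe_id", "gene_list"])
        assert resolve_cpg_genes(table) == {"cg1": ("GENE1",)}

    def test_empty_list_dropped(self):
        table = pd.DataFrame([("cg1", ""), ("cg2", "G1")],
                             columns=["probe_id", "gene_list"])
        assert resolve_cpg_genes(table) == {"cg2": ("G1",)}


def _matrix(values, samples, features, modality):
    return OmicsMatrix(np.asarray(values, dtype=float), samples, features, modality)


class TestGeneTable:
    samples = ["s1", "s2"]

    def _mrna(self):
        return _matrix([[1.0, 2.0], [3.0, 4.0]], self.samples, ["GA", "GB"], "mrna")

    def test_zero_fill_for_unmapped_channels(self):
        gt = build_gene_table(self._mrna(), None, None)
        j = gt.genes.index("GA")
        assert np.array_equal(gt.channels["mrna"][:, j], [1.0, 3.0])
        assert np.all(gt.channels["meth"] == 0)
        assert np.all(gt.channels["mirna"] == 0)

    def test_multiple_cpgs_averaged(self):
        meth = _matrix([[0.2, 0.6], [0.4, 0.8]], self.samples, ["cg1", "cg2"], "meth")
        gt = build_gene_table(self._mrna(), None, meth,
                              cpg_genes={"cg1": ("GA",), "cg2": ("GA",)})
        j = gt.genes.index("GA")
        assert np.allclose(gt.channels["meth"][:, j], [0.4, 0.6])

    def test_empty_mirna_layer_gives_zero_channel(self):
        mirna = _matrix(np.zeros((2, 0)), self.samples, [], "mirna")
        gt = build_gene_table(self._mrna(), mirna, None)
        assert np.all(gt.channels["mirna"] == 0)

    def test_sample_mismatch_rejected_with_ids(self):
        meth = _matrix([[0.1], [0.2]], ["s1", "s3"], ["cg1"], "meth")
        with pytest.raises(ValueError, match="s3"):
            build_gene_table(self._mrna(), None, meth, cpg_genes={"cg1": ("GA",)})

    def test_feature_order_permutation_invariant(self):
        mrna_a = _matrix([[1, 2], [3, 4]], self.samples, ["GA", "GB"], "mrna")
        mrna_b = _matrix([[2, 1], [4, 3]], self.samples, ["GB", "GA"], "mrna")
        ga = build_gene_table(mrna_a, None, None)
        gb = build_gene_table(mrna_b, None, None)
        assert ga.genes == gb.genes
        assert np.array_equal(ga.channels["mrna"], gb.channels["mrna"])

    def test_nonzero_meth_channels_match_mapped_genes(self):
        meth = _matrix([[0.2, 0.6], [0.4, 0.8]], self.samples, ["cg1", "cg2"], "meth")
        gt = build_gene_table(self._mrna(), None, meth,
                              cpg_genes={"cg1": ("GA",), "cg2": ("GC",)})
        nonzero = (gt.channels["meth"] != 0).any(axis=0)
        assert {gt.genes[i] for i in np.flatnonzero(nonzero)} == {"GA", "GC"}

    def test_sample_order_follows_mrna_layer(self):
        meth = _matrix([[0.9], [0.1]], ["s2", "s1"], ["cg1"], "meth")
        gt = build_gene_table(self._mrna(), None, meth, cpg_genes={"cg1": ("GA",)})
        j = gt.genes.index("GA")
        assert np.allclose(gt.channels["meth"][:, j], [0.1, 0.9])

    def test_universe_includes_map_only_genes(self):
        gt = build_gene_table(self._mrna(), None, None,
                              mirna_targets={"hsa-mir-1": "GZ"})
        assert "GZ" in gt.genes
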