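"""Network construction, serialization and degree-preserving randomization."""
import numpy as np
import pandas as pd
import pytest

from regulead import ParseError, ValidationError
from regulead.interactomes import (Interactome, Regulon, kd_regulons,
                                   randomize_interactome, read_aracne_adjacency,
                                   read_chea_sets, read_regulons,
                                   read_string_links, regulons_from_edges,
                                   write_regulons)
from regulead.signatures import ExpressionMatrix, GeneSignature
from regulead.synthetic import make_network

from conftest import build_regulon


class TestRegulonValidation:
    def test_rejects_out_of_range_mode_self_loop_and_duplicates(self):
        with pytest.raises(ValidationError):
            build_regulon("R", ["a"], [1.5], [1.0])
        with pytest.raises(ValidationError):
            build_regulon("R", ["R"], [1.0], [1.0])
        with pytest.raises(ValidationError):
            build_regulon("R", ["a", "a"], [1, 1], [1, 1])
        with pytest.raises(ValidationError):
            build_regulon("R", ["a"], [0.5], [-0.1])

    def test_summary_counts(self, small_interactome):
        s = small_interactome.summary()
        assert (s["regulators"], s["targets"], s["interactions"]) == (3, 36, 36)


class TestAracneReader:
    def test_adj_line_expands_to_target_mi_pairs(self, tmp_path):
        path = tmp_path / "net.adj"
        path.write_text(">header comment\nR1\tT1\t0.5\tT2\t0.3\n")
        assert read_aracne_adjacency(path, "adj") == [
            ("R1", "T1", 0.5), ("R1", "T2", 0.3)]

    def test_three_column_duplicates_keep_max_mi(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("R1\tT1\t0.2\nR1\tT1\t0.4\nR1\tT2\t0.1\n")
        assert read_aracne_adjacency(path, "three_column") == [
            ("R1", "T1", 0.4), ("R1", "T2", 0.1)]

    def test_empty_file_gives_empty_edge_list(self, tmp_path):
        path = tmp_path / "empty.adj"
        path.write_text("")
        assert read_aracne_adjacency(path, "adj") == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.adj"
        path.write_text("R1\tT1\t0.5\nR2\tT1\n")
        with pytest.raises(ParseError, match=":2"):
            read_aracne_adjacency(path, "adj")

    def test_negative_mi_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("R1\tT1\t-0.2\n")
        with pytest.raises(ValidationError, match="negative"):
            read_aracne_adjacency(path, "three_column")


class TestRegulonsFromEdges:
    def test_monotone_target_gets_mode_one(self):
        rows = {"R": (1.0, 2.0, 3.0, 4.0), "T": (10.0, 20.0, 30.0, 40.0)}
        expr = ExpressionMatrix(data=pd.DataFrame(rows, index=list("abcd")).T)
        net = regulons_from_edges([("R", "T", 0.5)], expr, min_targets=1)
        assert net.regulons["R"].table.loc["T", "mode"] == pytest.approx(1.0)

    def test_spearman_mode_matches_rank_correlation(self):
        rows = {"R": (1.0, 2.0, 3.0, 4.0), "T": (2.0, 1.0, 4.0, 3.0)}
        expr = ExpressionMatrix(data=pd.DataFrame(rows, index=list("abcd")).T)
        net = regulons_from_edges([("R", "T", 0.5)], expr, min_targets=1)
        assert net.regulons["R"].table.loc["T", "mode"] == pytest.approx(0.6)

    def test_single_target_weight_is_max_normalized_to_one(self):
        rows = {"R": (1.0, 2.0, 3.0, 4.0), "T": (2.0, 1.0, 4.0, 3.0)}
        expr = ExpressionMatrix(data=pd.DataFrame(rows, index=list("abcd")).T)
        net = regulons_from_edges([("R", "T", 0.5)], expr, min_targets=1)
        assert net.regulons["R"].table.loc["T", "weight"] == 1.0

    def test_zero_variance_gene_gives_mode_zero(self):
        rows = {"R": (1.0, 2.0, 3.0, 4.0), "T": (5.0, 5.0, 5.0, 5.0)}
        expr = ExpressionMatrix(data=pd.DataFrame(rows, index=list("abcd")).T)
        net = regulons_from_edges([("R", "T", 0.5)], expr, min_targets=1)
        assert net.regulons["R"].table.loc["T", "mode"] == 0.0

    def test_small_regulons_dropped_and_absent_genes_skipped(self, rng):
        genes = [f"g{i}" for i in range(20)] + ["R"]
        expr = ExpressionMatrix(data=pd.DataFrame(
            rng.standard_normal((21, 5)), index=genes))
        edges = [("R", f"g{i}", 0.5) for i in range(5)] + [("R", "missing", 0.9)]
        net = regulons_from_edges(edges, expr, min_targets=10)
        assert net.regulons == {}

    def test_weight_max_normalized_within_every_regulon(self, rng):
        genes = [f"g{i}" for i in range(30)] + ["R1", "R2"]
        expr = ExpressionMatrix(data=pd.DataFrame(
            rng.standard_normal((32, 6)), index=genes))
        edges = [("R1", f"g{i}", 0.1 * (i + 1)) for i in range(15)]
        edges += [("R2", f"g{i}", 0.01 * (i + 1)) for i in range(15, 30)]
        net = regulons_from_edges(edges, expr, min_targets=10)
        for reg in net.regulons.values():
            assert reg.table["weight"].max() == pytest.approx(1.0)


class TestStringReader:
    def test_threshold_is_strict_and_links_are_bidirectional(self, tmp_path):
        path = tmp_path / "links.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\n"
                        "A\tB\t0.71\nC\tD\t0.70\n")
        net = read_string_links(path)
        assert set(net.regulons) == {"A", "B"}
        assert net.regulons["A"].table.loc["B", "weight"] == pytest.approx(0.71)
        assert net.regulons["A"].table.loc["B", "mode"] == 0.0
        assert net.regulons["B"].table.loc["A", "weight"] == pytest.approx(0.71)

    def test_thousand_scale_scores_rescaled(self, tmp_path):
        path = tmp_path / "links.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\nA\tB\t710\n")
        net = read_string_links(path)
        assert net.regulons["A"].table.loc["B", "weight"] == pytest.approx(0.71)

    def test_score_outside_range_rejected(self, tmp_path):
        path = tmp_path / "links.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\nA\tB\t-5\n")
        with pytest.raises(ValidationError):
            read_string_links(path)


class TestCheaReader:
    def test_duplicate_tf_records_merged_by_union(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("X\tdesc\ta\tb\nX\tdesc2\tb\tc\n")
        net = read_chea_sets(path)
        assert set(net.regulons["X"].targets) == {"a", "b", "c"}
        assert (net.regulons["X"].table["mode"] == 0).all()
        assert (net.regulons["X"].table["weight"] == 1).all()

    def test_record_with_no_targets_skipped(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("X\tdesc\ta\nY\tdesc\n")
        net = read_chea_sets(path)
        assert set(net.regulons) == {"X"}

    def test_modes_from_expression_when_supplied(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("X\tdesc\ta\n")
        expr = ExpressionMatrix(data=pd.DataFrame(
            {"S1": [1, 1], "S2": [2, 2], "S3": [3, 3], "S4": [4, 4]},
            index=["X", "a"], dtype=float))
        net = read_chea_sets(path, expression=expr)
        assert net.regulons["X"].table.loc["a", "mode"] == pytest.approx(1.0)


class TestKdRegulons:
    def _sig(self, mapping, label):
        return GeneSignature(values=pd.Series(mapping, dtype=float), label=label)

    def test_sign_logic_threshold_and_weights(self):
        z = {f"t{i}": -4.0 for i in range(10)}
        z.update({"up": 4.0, "weak": 2.9, "g": -8.0, "strong": -8.0})
        net = kd_regulons({"g": self._sig(z, "kd_g")}, z_min=3.0, min_targets=5)
        table = net.regulons["g"].table
        assert "weak" not in table.index          # below |z| threshold
        assert "g" not in table.index             # silenced gene excluded
        assert table.loc["t0", "mode"] == 1.0     # fell on silencing -> activated
        assert table.loc["up", "mode"] == -1.0    # rose on silencing -> repressed
        assert table.loc["strong", "weight"] == 1.0
        assert table.loc["t0", "weight"] == pytest.approx(0.5)

    def test_max_targets_cap_keeps_largest_z(self):
        z = {f"t{i}": -(3.0 + i) for i in range(30)}
        z["g"] = -9.0
        net = kd_regulons({"g": self._sig(z, "kd")}, max_targets=10, min_targets=5)
        assert len(net.regulons["g"]) == 10
        assert "t29" in net.regulons["g"].table.index

    def test_sparse_knockdown_dropped(self):
        z = {"t0": -4.0, "g": -9.0}
        net = kd_regulons({"g": self._sig(z, "kd")}, min_targets=10)
        assert net.regulons == {}


class TestRandomization:
    def test_fraction_zero_is_identity(self, small_interactome):
        out = randomize_interactome(small_interactome, 0.0, seed=1)
        assert out.equals(small_interactome)

    @pytest.mark.parametrize("fraction", [0.25, 0.5, 1.0])
    def test_degree_sequences_preserved_exactly(self, fraction):
        net = make_network(20, 15, 300, seed=3)
        out = randomize_interactome(net, fraction, seed=7)
        assert sorted(len(r) for r in out.regulons.values()) == \
            sorted(len(r) for r in net.regulons.values())
        in_deg = lambda n: sorted(
            pd.Series([t for r in n.regulons.values() for t in r.targets])
            .value_counts().to_list())
        assert in_deg(out) == in_deg(net)

    def test_full_randomization_leaves_low_edge_overlap(self):
        net = make_network(20, 50, 1000, seed=5)  # 1000 edges
        out = randomize_interactome(net, 1.0, seed=11)
        orig = set((r, t) for r in net.regulons for t in net.regulons[r].targets)
        new = set((r, t) for r in out.regulons for t in out.regulons[r].targets)
        assert len(orig & new) / len(orig) < 0.20
        assert out.meta["realized_fraction"] > 0.8

    def test_deterministic_given_seed(self, small_interactome):
        a = randomize_interactome(small_interactome, 0.5, seed=42)
        b = randomize_interactome(small_interactome, 0.5, seed=42)
        assert a.equals(b)

    def test_invalid_fraction_rejected(self, small_interactome):
        with pytest.raises(ValidationError):
            randomize_interactome(small_interactome, 1.5, seed=0)

    def test_attributes_travel_with_regulator_stub(self):
        net = make_network(10, 20, 200, seed=9)
        out = randomize_interactome(net, 1.0, seed=13)
        for rid in net.regulons:
            orig = net.regulons[rid].table
            new = out.regulons[rid].table
            assert sorted(new["mode"]) == sorted(orig["mode"])
            assert sorted(new["weight"]) == sorted(orig["weight"])


class TestSerialization:
    def test_round_trip_preserves_interactome(self, small_interactome, tmp_path):
        path = tmp_path / "net.tsv"
        write_regulons(small_interactome, path)
        back = read_regulons(path)
        assert back.equals(small_interactome)
        assert back.name == small_interactome.name

    def test_out_of_range_mode_in_file_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("regulator\ttarget\tmode\tweight\nR\ta\t1.5\t1.0\n")
        with pytest.raises(ValidationError):
            read_regulons(path)

    def test_header_only_file_gives_empty_interactome(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("# name=x\nregulator\ttarget\tmode\tweight\n")
        assert read_regulons(path).regulons == {}

    def test_missing_column_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("regulator\ttarget\tmode\nR\ta\t1.0\n")
        with pytest.raises(ParseError):
            read_regulons(path)
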