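"""3-tail enrichment core, calibration, pleiotropy and network integration."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.base import clone

from regulead import ValidationError
from regulead.activity import (ActivityMatrix, RegulonActivity,
                               infer_activity_matrix, integrate_networks,
                               nes_analytic, nes_empirical, rank_transform,
                               regulon_es)
from regulead.interactomes import Interactome
from regulead.signatures import GeneSignature
from regulead.synthetic import make_network, simulate_perturbation_experiment

from conftest import build_regulon


def brute_force_es(signature_values: pd.Series, table: pd.DataFrame) -> float:
    """Independent re-derivation of the 3-tail weighted mean, step by step."""
    n = len(signature_values)
    v = signature_values
    t2 = pd.Series(stats.norm.ppf(v.rank(method="average") / (n + 1)), index=v.index)
    t1 = pd.Series(stats.norm.ppf(0.5 + v.abs().rank(method="average") / (2 * (n + 1))),
                   index=v.index)
    present = [t for t in table.index if t in v.index]
    wsum = sum(table.loc[t, "weight"] for t in present)
    es = 0.0
    for t in present:
        w = table.loc[t, "weight"] / wsum
        m = table.loc[t, "mode"]
        es += w * (m * t2[t] + (1 - abs(m)) * t1[t])
    return es


class TestRankTransform:
    def test_probit_scores_match_hand_computed_quantiles(self):
        sig = GeneSignature(values=pd.Series({"a": 2.0, "b": 0.0, "c": -1.5}))
        out = rank_transform(sig)
        assert list(out.t2) == pytest.approx([0.674, 0.0, -0.674], abs=1e-3)
        assert list(out.t1) == pytest.approx([1.150, 0.319, 0.674], abs=1e-3)

    def test_negation_flips_t2_and_preserves_t1(self, gaussian_signature):
        fwd = rank_transform(gaussian_signature)
        neg = rank_transform(GeneSignature(values=-gaussian_signature.values))
        assert np.allclose(fwd.t2, -neg.t2)
        assert np.allclose(fwd.t1, neg.t1)

    def test_monotone_in_statistic_and_magnitude(self, gaussian_signature):
        out = rank_transform(gaussian_signature)
        order = gaussian_signature.values.sort_values().index
        assert out.t2.loc[order].is_monotonic_increasing
        order_abs = gaussian_signature.values.abs().sort_values().index
        assert out.t1.loc[order_abs].is_monotonic_increasing

    def test_constant_signature_rejected(self):
        sig = GeneSignature(values=pd.Series(np.ones(50)))
        with pytest.raises(ValidationError):
            rank_transform(sig)


class TestRegulonEs:
    def test_reduces_to_single_target_scores(self, gaussian_signature):
        t = rank_transform(gaussian_signature)
        top = t.t2.idxmax()
        reg = build_regulon("R", [top], [1.0], [1.0])
        es, n = regulon_es(t, reg, min_targets=1)
        assert es == pytest.approx(t.t2[top])
        reg0 = build_regulon("R", [top], [0.0], [1.0])
        es0, _ = regulon_es(t, reg0, min_targets=1)
        assert es0 == pytest.approx(t.t1[top])

    def test_three_target_mixed_mode_sum(self):
        # modes (1, -1, 0), equal weights: es = (t2_a - t2_b + t1_c) / 3
        sig = GeneSignature(values=pd.Series(
            np.concatenate([np.linspace(-3, 3, 97), [2.5, -2.5, 1.0]]),
            index=[f"g{i}" for i in range(97)] + ["a", "b", "c"]))
        t = rank_transform(sig)
        reg = build_regulon("R", ["a", "b", "c"], [1, -1, 0], [1, 1, 1])
        es, n = regulon_es(t, reg, min_targets=3)
        assert n == 3
        assert es == pytest.approx((t.t2["a"] - t.t2["b"] + t.t1["c"]) / 3)

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        genes = [f"g{i}" for i in range(300)]
        for _ in range(25):
            sig = GeneSignature(values=pd.Series(rng.standard_normal(300),
                                                 index=genes))
            t = rank_transform(sig)
            targets = list(rng.choice(genes, size=15, replace=False))
            reg = build_regulon("R", targets,
                                rng.choice([-1.0, 0.0, 1.0], size=15),
                                rng.uniform(0.1, 1.0, size=15))
            es, _ = regulon_es(t, reg)
            assert es == pytest.approx(brute_force_es(sig.values, reg.table),
                                       abs=1e-12)

    def test_too_few_present_targets_is_untestable(self, gaussian_signature):
        t = rank_transform(gaussian_signature)
        reg = build_regulon("R", ["missing1", "missing2"], [1, 1], [1, 1])
        with pytest.raises(ValidationError):
            regulon_es(t, reg)


class TestCalibration:
    def test_analytic_scaling_identities(self):
        nes, p = nes_analytic(0.5, np.full(25, 1 / 25))
        assert nes == pytest.approx(2.5)
        nes0, p0 = nes_analytic(0.0, np.array([0.5, 0.5]))
        assert (nes0, p0) == (0.0, pytest.approx(1.0))
        nes2, _ = nes_analytic(1.0, np.array([0.5, 0.5]))
        assert nes2 == pytest.approx(np.sqrt(2.0))

    def test_empirical_standardizes_against_null_distribution(self, rng):
        genes = [f"g{i}" for i in range(300)]
        reg = build_regulon("R", list(rng.choice(genes, 20, replace=False)),
                            rng.choice([-1.0, 1.0], 20), np.ones(20))
        nulls = [rank_transform(GeneSignature(
            values=pd.Series(rng.standard_normal(300), index=genes)))
            for _ in range(150)]
        null_es = np.array([regulon_es(t, reg)[0] for t in nulls])
        nes, p = nes_empirical(float(null_es.mean()), reg, nulls)
        assert nes == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        nes2, p2 = nes_empirical(
            float(null_es.mean() + 1.96 * null_es.std(ddof=1)), reg, nulls)
        assert nes2 == pytest.approx(1.96)
        assert p2 == pytest.approx(0.05, abs=1e-3)

    def test_empirical_agrees_with_analytic_on_gaussian_signatures(self, rng):
        """Median |NES_emp - NES_ana| stays small for signed-mode regulons."""
        net = make_network(50, 20, n_genes=1000, mode_mix=(0.5, 0.5, 0.0),
                           seed=1)
        genes = sorted(net.gene_universe)
        nulls = pd.DataFrame(rng.standard_normal((400, len(genes))),
                             columns=genes)
        tests = pd.DataFrame(rng.standard_normal((50, len(genes))),
                             columns=genes)
        emp = RegulonActivity(interactome=net, calibration="empirical")
        emp.fit(nulls)
        ana = RegulonActivity(interactome=net, calibration="analytic")
        ana.fit(tests)
        gap = np.abs(emp.transform(tests) - ana.transform(tests))
        assert np.median(gap) < 0.15


class TestEstimatorApi:
    def test_get_params_clone_and_feature_names(self, small_interactome, rng):
        genes = sorted(small_interactome.gene_universe)
        X = pd.DataFrame(rng.standard_normal((5, len(genes))), columns=genes)
        est = RegulonActivity(interactome=small_interactome, min_targets=5)
        cloned = clone(est)
        assert cloned.get_params()["min_targets"] == 5
        est.fit(X)
        assert list(est.get_feature_names_out()) == est.regulators_
        out = est.transform(X)
        assert out.shape == (5, len(est.regulators_))

    def test_transform_rejects_mismatched_genes(self, small_interactome, rng):
        genes = sorted(small_interactome.gene_universe)
        X = pd.DataFrame(rng.standard_normal((4, len(genes))), columns=genes)
        est = RegulonActivity(interactome=small_interactome, min_targets=5).fit(X)
        bad = X.rename(columns={genes[0]: "other"})
        with pytest.raises(ValidationError):
            est.transform(bad)

    def test_single_sample_inference(self, small_interactome, rng):
        genes = sorted(small_interactome.gene_universe)
        X = pd.DataFrame(rng.standard_normal((1, len(genes))), columns=genes,
                         index=["only"])
        est = RegulonActivity(interactome=small_interactome, min_targets=5).fit(X)
        matrix = est.infer(X)
        assert matrix.perturbations == ["only"]
        assert matrix.nes.notna().all().all()


class TestInferActivityMatrix:
    def test_planted_top_ranked_regulon_has_largest_positive_nes(
            self, small_interactome, rng):
        genes = sorted(small_interactome.gene_universe)
        values = pd.Series(rng.standard_normal(len(genes)), index=genes)
        ra = small_interactome.regulons["RA"]
        values[ra.targets] = 10.0 + rng.random(len(ra.targets))  # force to top
        sig = GeneSignature(values=values, label="planted")
        matrix = infer_activity_matrix([sig], small_interactome, min_targets=5)
        assert matrix.nes["planted"].idxmax() == "RA"
        assert matrix.nes.at["RA", "planted"] > 1.96

    def test_empty_interactome_rejected(self, gaussian_signature):
        with pytest.raises(ValidationError):
            infer_activity_matrix([gaussian_signature],
                                  Interactome(name="x", regulons={}))

    def test_long_form_round_trip(self, small_interactome, rng, tmp_path):
        genes = sorted(small_interactome.gene_universe)
        sigs = [GeneSignature(values=pd.Series(rng.standard_normal(len(genes)),
                                               index=genes), label=f"c{i}")
                for i in range(3)]
        matrix = infer_activity_matrix(sigs, small_interactome, min_targets=5)
        path = tmp_path / "activity.tsv"
        matrix.write_long(path)
        back = ActivityMatrix.read_long(path)
        pd.testing.assert_frame_equal(back.nes, matrix.nes, check_names=False)


class TestPleiotropy:
    def test_disjoint_regulons_unchanged(self, small_interactome, rng):
        genes = sorted(small_interactome.gene_universe)
        sigs = [GeneSignature(values=pd.Series(rng.standard_normal(len(genes)),
                                               index=genes), label="c")]
        plain = infer_activity_matrix(sigs, small_interactome, min_targets=5)
        adj = infer_activity_matrix(sigs, small_interactome, min_targets=5,
                                    pleiotropy=True)
        pd.testing.assert_frame_equal(plain.nes, adj.nes)

    def _shadow_net(self, overlap_frac=0.5):
        genes = [f"g{i}" for i in range(40)]
        k = int(20 * overlap_frac)
        a = build_regulon("A", genes[:20], [1] * 20, np.ones(20))
        b = build_regulon("B", genes[20 - k: 40 - k], [1] * 20, np.ones(20))
        return Interactome(name="shadow", regulons={"A": a, "B": b}), genes

    def test_identical_regulons_shrunk_identically(self, rng):
        genes = [f"g{i}" for i in range(200)]
        a = build_regulon("A", genes[:20], [1] * 20, np.ones(20))
        b = build_regulon("B", genes[:20], [1] * 20, np.ones(20))
        net = Interactome(name="twin", regulons={"A": a, "B": b})
        values = pd.Series(rng.standard_normal(200), index=genes)
        values[genes[:20]] = 5.0 + rng.random(20)
        sig = GeneSignature(values=values, label="c")
        plain = infer_activity_matrix([sig], net, min_targets=5)
        adj = infer_activity_matrix([sig], net, min_targets=5, pleiotropy=True)
        assert adj.nes.at["A", "c"] == pytest.approx(adj.nes.at["B", "c"])
        assert abs(adj.nes.at["A", "c"]) < abs(plain.nes.at["A", "c"])
        assert np.sign(adj.nes.at["A", "c"]) in (0, np.sign(plain.nes.at["A", "c"]))

    def test_planted_regulator_kept_shadow_shrunk(self, rng):
        net = make_network(10, 40, n_genes=600, overlap=0.5,
                           mode_mix=(1.0, 0.0, 0.0), seed=4)
        regs = net.regulators
        planted, shadow = regs[0], regs[1]  # shadow partners by construction
        _, sigs, _ = simulate_perturbation_experiment(
            net, {"c": {planted: 3.0}}, n_reps=10, noise_sd=1.0, seed=5)
        plain = infer_activity_matrix(list(sigs.values()), net)
        adj = infer_activity_matrix(list(sigs.values()), net, pleiotropy=True)
        assert abs(adj.nes.at[shadow, "c"]) < abs(plain.nes.at[shadow, "c"])
        loss = 1 - abs(adj.nes.at[planted, "c"]) / abs(plain.nes.at[planted, "c"])
        assert loss < 0.10


class TestIntegration:
    def _matrix(self, nes_frame, network):
        p = 2 * stats.norm.sf(np.abs(nes_frame))
        return ActivityMatrix(
            es=nes_frame.copy(), nes=nes_frame,
            pvalue=pd.DataFrame(p, index=nes_frame.index,
                                columns=nes_frame.columns),
            n_targets=pd.Series(10, index=nes_frame.index), network=network)

    def test_identity_on_duplicated_matrices(self, rng):
        nes = pd.DataFrame(rng.standard_normal((4, 3)),
                           index=list("abcd"), columns=list("xyz"))
        out = integrate_networks([self._matrix(nes, "n1"),
                                  self._matrix(nes.copy(), "n2"),
                                  self._matrix(nes.copy(), "n3")])
        pd.testing.assert_frame_equal(out.nes, nes, check_names=False)

    def test_self_weighted_average_example(self):
        m1 = self._matrix(pd.DataFrame({"x": [2.0]}, index=["a"]), "n1")
        m2 = self._matrix(pd.DataFrame({"x": [-1.0]}, index=["a"]), "n2")
        out = integrate_networks([m1, m2])
        assert out.nes.at["a", "x"] == pytest.approx(1.0)
        assert out.networks.at["a", "x"] == "n1,n2"

    def test_partial_coverage_passes_through(self):
        m1 = self._matrix(pd.DataFrame({"x": [2.0]}, index=["a"]), "n1")
        m2 = self._matrix(pd.DataFrame({"x": [0.5]}, index=["b"]), "n2")
        out = integrate_networks([m1, m2])
        assert out.nes.at["a", "x"] == 2.0
        assert out.nes.at["b", "x"] == 0.5

    def test_all_zero_cells_integrate_to_zero(self):
        m1 = self._matrix(pd.DataFrame({"x": [0.0]}, index=["a"]), "n1")
        m2 = self._matrix(pd.DataFrame({"x": [0.0]}, index=["a"]), "n2")
        assert integrate_networks([m1, m2]).nes.at["a", "x"] == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            integrate_networks([])

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=1,
                    max_size=6))
    def test_bound_and_formula_on_fuzzed_cells(self, cells):
        mats = [self._matrix(pd.DataFrame({"x": [v]}, index=["a"]), f"n{i}")
                for i, v in enumerate(cells)]
        out = integrate_networks(mats).nes.at["a", "x"]
        den = sum(abs(v) for v in cells)
        expected = sum(v * abs(v) for v in cells) / den if den > 0 else 0.0
        assert out == pytest.approx(expected, abs=1e-12)
        assert abs(out) <= max(abs(v) for v in cells) + 1e-12
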