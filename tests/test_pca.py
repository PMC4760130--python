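import numpy as np
import pytest

from _oracles import dense_variance_fractions
from roma.containers import ModuleDefinition, ModuleGene
from roma.exceptions import DegenerateModuleError, RomaError
from roma.pca import DEFAULT_Z_MAX, fit_pc1, orient_pc1, robust_filter


class TestFitPC1:
    def test_anticorrelated_pair_is_rank_one(self):
        X = np.array([[2.0, -2.0], [-2.0, 2.0]])
        fit = fit_pc1(X, mode="standard", seed=0)
        assert fit.L1 == pytest.approx(1.0, abs=1e-12)
        expected = np.array([1.0, -1.0]) / np.sqrt(2)
        assert (
            np.allclose(fit.loadings, expected, atol=1e-9)
            or np.allclose(fit.loadings, -expected, atol=1e-9)
        )

    def test_weight_scale_invariance(self, rng):
        X = rng.standard_normal((12, 8))
        f1 = fit_pc1(X, np.ones(12), mode="standard", seed=4)
        f2 = fit_pc1(X, np.full(12, 7.3), mode="standard", seed=4)
        np.testing.assert_allclose(f1.loadings, f2.loadings, atol=1e-10)
        np.testing.assert_allclose(f1.activity, f2.activity, atol=1e-10)
        assert f1.L1 == pytest.approx(f2.L1, abs=1e-10)
        assert f1.L2 == pytest.approx(f2.L2, abs=1e-10)

    @pytest.mark.parametrize("mode", ["standard", "fixed_center"])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_oracle_equivalence_random_matrices(self, mode, weighted):
        """Engine L1/L2 must match a dense eigensolver on the exact covariance."""
        seed = {"standard": 10, "fixed_center": 20}[mode] + int(weighted)
        rng = np.random.default_rng(seed)
        for _ in range(30):
            g = int(rng.integers(3, 41))
            s = int(rng.integers(3, 26))
            X = rng.standard_normal((g, s))
            w = rng.uniform(0.2, 5.0, g) if weighted else None
            center = rng.standard_normal(s) if mode == "fixed_center" else None
            fit = fit_pc1(X, w, mode=mode, center=center, seed=int(rng.integers(2**31)))
            fr = dense_variance_fractions(X, w, mode=mode, center=center)
            assert abs(fit.L1 - fr[0]) < 1e-8
            assert abs(fit.L2 - fr[1]) < 1e-8

    def test_invariants(self, rng):
        X = rng.standard_normal((15, 10))
        fit = fit_pc1(X, mode="standard", seed=1)
        assert np.linalg.norm(fit.loadings) == pytest.approx(1.0, abs=1e-9)
        # zero-sum loadings under uniform weights (centered model constraint)
        assert abs(fit.loadings.sum()) < 1e-7
        assert 0.0 <= fit.L2 <= fit.L1 <= 1.0
        assert fit.L1 + fit.L2 <= 1.0 + 1e-9

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((10, 8))
        fit = fit_pc1(X, mode="standard", seed=2)
        pg = rng.permutation(10)
        ps = rng.permutation(8)
        fit_p = fit_pc1(X[pg][:, ps], mode="standard", seed=2)
        assert fit_p.L1 == pytest.approx(fit.L1, abs=1e-10)
        assert fit_p.L2 == pytest.approx(fit.L2, abs=1e-10)
        sign = np.sign(fit_p.loadings @ fit.loadings[pg])
        np.testing.assert_allclose(fit_p.loadings, sign * fit.loadings[pg], atol=1e-7)
        np.testing.assert_allclose(fit_p.activity, sign * fit.activity[ps], atol=1e-6)

    def test_two_seeds_agree_on_direction(self, rng):
        X = rng.standard_normal((20, 12))
        f1 = fit_pc1(X, seed=101)
        f2 = fit_pc1(X, seed=202)
        assert abs(f1.loadings @ f2.loadings) == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_is_degenerate(self):
        X = np.zeros((4, 5))
        with pytest.raises(DegenerateModuleError):
            fit_pc1(X, mode="standard", seed=0)

    def test_too_small_input_rejected(self):
        with pytest.raises(RomaError):
            fit_pc1(np.ones((1, 5)))

    def test_fixed_center_requires_center(self, rng):
        with pytest.raises(RomaError, match="center"):
            fit_pc1(rng.standard_normal((4, 4)), mode="fixed_center")


class TestOrientPC1:
    @staticmethod
    def _fit_for(module, loadings, activity):
        X = np.outer(loadings, activity)
        fit = fit_pc1(X, mode="standard", seed=0, gene_names=module.gene_names)
        return fit

    def test_signed_gene_rule_negates(self):
        module = ModuleDefinition(
            "M", "", [ModuleGene("E2F1", 1.0, True), ModuleGene("X"), ModuleGene("Y")]
        )
        a = np.array([-0.5, 0.6, -0.1])
        a -= a.mean()
        a /= np.linalg.norm(a)
        fit = self._fit_for(module, a, np.array([3.0, -1.0, -2.0, 0.0]))
        if fit.loadings[0] > 0:  # force the E2F1 loading negative first
            fit.loadings *= -1
            fit.activity *= -1
        oriented = orient_pc1(fit, module)
        assert oriented.loadings[0] > 0

    def test_already_oriented_fit_unchanged(self):
        module = ModuleDefinition("M", "", [ModuleGene("A", 2.0, True), ModuleGene("B")])
        a = np.array([0.8, -0.6])
        fit = self._fit_for(module, a, np.array([1.0, 2.0, -3.0]))
        if fit.loadings[0] < 0:
            fit.loadings *= -1
            fit.activity *= -1
        oriented = orient_pc1(fit, module)
        np.testing.assert_array_equal(oriented.loadings, fit.loadings)
        np.testing.assert_array_equal(oriented.activity, fit.activity)

    def test_unsigned_fallback_aligns_with_module_mean(self, rng):
        # loadings all one sign: module mean expression tracks the activity
        module = ModuleDefinition("M", "", [ModuleGene(f"g{i}") for i in range(5)])
        loadings = np.full(5, 1 / np.sqrt(5))
        activity = rng.standard_normal(8) * 3
        X = np.outer(loadings, activity) + 0.01 * rng.standard_normal((5, 8))
        fit = fit_pc1(X, mode="fixed_center", center=np.zeros(8), seed=0,
                      gene_names=module.gene_names)
        oriented = orient_pc1(fit, module)
        mean_prof = X.mean(axis=0)
        corr = np.corrcoef(oriented.activity, mean_prof)[0, 1]
        assert corr > 0

    def test_involution(self, rng):
        module = ModuleDefinition(
            "M", "", [ModuleGene("A", 1.0, True), ModuleGene("B", -2.0, True), ModuleGene("C")]
        )
        X = rng.standard_normal((3, 6))
        fit = fit_pc1(X, mode="standard", seed=0, gene_names=module.gene_names)
        once = orient_pc1(fit, module)
        twice = orient_pc1(once, module)
        np.testing.assert_array_equal(once.loadings, twice.loadings)
        np.testing.assert_array_equal(once.activity, twice.activity)

    def test_negating_all_signs_negates_activity(self, rng):
        genes = [ModuleGene(f"g{i}", float((-1) ** i) or 1.0, True) for i in range(6)]
        module = ModuleDefinition("M", "", genes)
        flipped = ModuleDefinition(
            "M", "", [ModuleGene(g.name, -g.weight, True) for g in genes]
        )
        X = rng.standard_normal((6, 7))
        fit = fit_pc1(X, mode="standard", seed=0, gene_names=module.gene_names)
        a = orient_pc1(fit, module)
        b = orient_pc1(fit, flipped)
        np.testing.assert_array_equal(a.activity, -b.activity)


class TestRobustFilter:
    def test_infinite_threshold_removes_nothing(self, rng):
        X = rng.standard_normal((8, 6))
        keep, report = robust_filter(X, z_max=np.inf, seed=0)
        assert keep.tolist() == list(range(8))
        assert report.removed_genes == []

    def test_default_threshold(self):
        assert DEFAULT_Z_MAX == 3.0

    def test_aberrant_amplitude_gene_removed(self, rng):
        """20 coherent planted-factor genes + one 100x-amplitude gene."""
        activity = rng.standard_normal(15)
        coherent = np.outer(np.ones(20) / np.sqrt(20), activity)
        coherent += 0.05 * rng.standard_normal(coherent.shape)
        aberrant = 100.0 * rng.standard_normal((1, 15))
        X = np.vstack([coherent, aberrant])
        names = [f"g{i}" for i in range(20)] + ["ABERRANT"]
        keep, report = robust_filter(X, z_max=3.0, seed=0, gene_names=names)
        assert report.removed_genes == ["ABERRANT"]
        assert keep.tolist() == list(range(20))
        # direct inspection: the leave-one-out L1 values single out the gene
        z = (report.loo_L1 - report.loo_L1.mean()) / report.loo_L1.std(ddof=1)
        assert abs(z[20]) > 3.0
        assert np.all(np.abs(z[:20]) <= 3.0)

    def test_loo_values_match_independent_refits(self, rng):
        X = rng.standard_normal((6, 9))
        _, report = robust_filter(X, z_max=np.inf, seed=5)
        for i in range(6):
            sub = np.delete(X, i, axis=0)
            fr = dense_variance_fractions(sub, mode="standard")
            assert report.loo_L1[i] == pytest.approx(fr[0], abs=1e-8)

    def test_fewer_than_three_genes_skips(self, rng, caplog):
        X = rng.standard_normal((2, 5))
        keep, report = robust_filter(X, seed=0)
        assert keep.tolist() == [0, 1]
        assert report.removed_genes == []

    def test_constant_loo_distribution_removes_nothing(self):
        # perfectly symmetric rank-1 structure: all LOO L1 values equal 1
        X = np.outer(np.array([1.0, -1.0, 1.0, -1.0]), np.array([1.0, -1.0, 2.0, -2.0]))
        keep, _ = robust_filter(X, z_max=0.1, seed=0)
        assert keep.size == 4
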