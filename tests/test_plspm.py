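"""PLS path model: recovery on simulated SEMs, effects algebra, pruning, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecostoichnet.plspm import PLSPathModel, PLSPMSpec, total_effects
from ecostoichnet.simulate import generate_sem_data


def _chain_spec(names, coefs):
    """Strictly lower-triangular coefficient matrix for a chain DAG."""
    B = pd.DataFrame(0.0, index=names, columns=names)
    for (src, dst), c in coefs.items():
        B.loc[dst, src] = c
    return B


def _single_indicator_model(data, names, paths, **kwargs):
    blocks = {n: [n] for n in names}
    return PLSPathModel.from_dataframe(data, blocks, paths, **kwargs)


class TestFit:
    def test_noise_free_single_edge_recovers_coefficient(self):
        B = _chain_spec(["X", "Y"], {("X", "Y"): 0.8})
        data, _ = generate_sem_data(B, n=10_000, noise_sd=0.0, seed=1)
        fit = _single_indicator_model(data, ["X", "Y"], [("X", "Y")]).fit()
        assert fit.converged
        assert fit.path_coefficients.loc["Y", "X"] == pytest.approx(0.8, abs=0.02)

    def test_chain_equals_ols_slopes(self):
        """Single-indicator chain: path coefficients equal standardized OLS slopes."""
        B = _chain_spec(["X", "M", "Y"], {("X", "M"): 0.6, ("M", "Y"): 0.5})
        data, _ = generate_sem_data(B, n=500, noise_sd=0.0, seed=2)
        fit = _single_indicator_model(
            data, ["X", "M", "Y"], [("X", "M"), ("M", "Y")]
        ).fit()

        def std_slope(y, x):
            xs = (x - x.mean()) / x.std(ddof=1)
            ys = (y - y.mean()) / y.std(ddof=1)
            return float((xs * ys).sum() / (xs**2).sum())

        assert fit.path_coefficients.loc["M", "X"] == pytest.approx(
            std_slope(data["M"], data["X"]), abs=1e-10
        )
        assert fit.path_coefficients.loc["Y", "M"] == pytest.approx(
            std_slope(data["Y"], data["M"]), abs=1e-10
        )

    def test_single_indicator_loading_is_one(self):
        B = _chain_spec(["X", "Y"], {("X", "Y"): 0.5})
        data, _ = generate_sem_data(B, n=200, noise_sd=0.1, seed=3)
        fit = _single_indicator_model(data, ["X", "Y"], [("X", "Y")]).fit()
        assert fit.loadings["X"] == pytest.approx(1.0, abs=1e-12)
        assert fit.loadings["Y"] == pytest.approx(1.0, abs=1e-12)

    def test_scores_unit_variance(self):
        B = _chain_spec(["X", "M", "Y"], {("X", "M"): 0.6, ("M", "Y"): 0.5})
        data, _ = generate_sem_data(B, n=300, noise_sd=0.3, seed=4)
        fit = _single_indicator_model(
            data, ["X", "M", "Y"], [("X", "M"), ("M", "Y")]
        ).fit()
        assert np.allclose(fit.scores.std(ddof=1), 1.0, atol=1e-10)

    def test_indicator_sign_flip_flips_only_signs(self):
        rng = np.random.default_rng(5)
        lat = rng.normal(size=400)
        data = pd.DataFrame(
            {
                "x1": lat + 0.3 * rng.normal(size=400),
                "x2": lat + 0.3 * rng.normal(size=400),
                "y1": 0.7 * lat + 0.5 * rng.normal(size=400),
            }
        )
        blocks = {"X": ["x1", "x2"], "Y": ["y1"]}
        fit = PLSPathModel.from_dataframe(data, blocks, [("X", "Y")]).fit()
        flipped = data.assign(x1=-data["x1"])
        fit2 = PLSPathModel.from_dataframe(flipped, blocks, [("X", "Y")]).fit()
        assert abs(fit2.loadings["x1"]) == pytest.approx(abs(fit.loadings["x1"]), abs=1e-6)
        assert abs(fit2.path_coefficients.loc["Y", "X"]) == pytest.approx(
            abs(fit.path_coefficients.loc["Y", "X"]), abs=1e-6
        )

    @pytest.mark.parametrize("scheme", ["centroid", "factorial", "path"])
    def test_schemes_agree_on_strong_simple_model(self, scheme):
        B = _chain_spec(["X", "Y"], {("X", "Y"): 0.8})
        data, _ = generate_sem_data(B, n=2000, noise_sd=0.05, seed=6)
        fit = _single_indicator_model(data, ["X", "Y"], [("X", "Y")], scheme=scheme).fit()
        assert fit.path_coefficients.loc["Y", "X"] == pytest.approx(0.8, abs=0.05)

    def test_cyclic_path_matrix_rejected(self):
        pm = pd.DataFrame(
            [[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"]
        )
        data = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 2)), columns=["A", "B"])
        with pytest.raises(ValueError, match="lower-triangular"):
            PLSPathModel(data, {"A": ["A"], "B": ["B"]}, pm)

    def test_duplicate_indicator_rejected(self):
        data = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 2)), columns=["a", "b"])
        pm = pd.DataFrame(np.zeros((2, 2), dtype=int), index=["X", "Y"], columns=["X", "Y"])
        pm.loc["Y", "X"] = 1
        with pytest.raises(ValueError, match="appears in blocks"):
            PLSPathModel(data, {"X": ["a"], "Y": ["a"]}, pm)


class TestRecoveryProperty:
    def test_dag_recovery_low_noise(self):
        """Estimated paths converge to generating coefficients as noise vanishes."""
        names = ["A", "B", "C", "D"]
        B = _chain_spec(
            names,
            {("A", "B"): 0.7, ("A", "C"): 0.3, ("B", "C"): 0.4, ("C", "D"): -0.6},
        )
        ests = []
        for seed in range(5):
            data, _ = generate_sem_data(B, n=10_000, noise_sd=0.0, seed=50 + seed)
            fit = _single_indicator_model(
                data, names, [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")]
            ).fit()
            ests.append(fit.path_coefficients)
        mean_est = sum(ests) / len(ests)
        for dst in names:
            for src in names:
                if B.loc[dst, src] != 0:
                    assert mean_est.loc[dst, src] == pytest.approx(
                        B.loc[dst, src], abs=0.02
                    )


class TestTotalEffects:
    def test_single_edge_equals_direct(self):
        B = _chain_spec(["X", "Y"], {("X", "Y"): 0.4})
        pd.testing.assert_frame_equal(total_effects(B), B)

    def test_chain_product(self):
        B = _chain_spec(["X", "M", "Y"], {("X", "M"): 0.5, ("M", "Y"): 0.4})
        tot = total_effects(B)
        assert tot.loc["Y", "X"] == pytest.approx(0.20, abs=1e-12)

    def test_against_path_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        names = list("ABCDE")
        B = pd.DataFrame(0.0, index=names, columns=names)
        for i in range(5):
            for j in range(i):
                if rng.random() < 0.6:
                    B.iloc[i, j] = rng.uniform(-0.9, 0.9)

        def paths_total(src, dst):
            # sum over all directed paths of the product of edge coefficients
            total = 0.0
            stack = [(src, 1.0)]
            while stack:
                node, prod = stack.pop()
                for nxt in names:
                    c = B.loc[nxt, node]
                    if c != 0:
                        if nxt == dst:
                            total += prod * c
                        stack.append((nxt, prod * c))
            return total

        tot = total_effects(B)
        for src, dst in itertools.permutations(names, 2):
            assert tot.loc[dst, src] == pytest.approx(
                paths_total(src, dst), abs=1e-12
            )

    def test_non_triangular_rejected(self):
        B = pd.DataFrame(
            [[0.0, 0.2], [0.3, 0.0]], index=["A", "B"], columns=["A", "B"]
        )
        with pytest.raises(ValueError):
            total_effects(B)


class TestGoF:
    def _fit(self, noise, seed=9, n=400):
        B = _chain_spec(["X", "Y"], {("X", "Y"): 0.8})
        data, _ = generate_sem_data(B, n=n, noise_sd=noise, seed=seed)
        return _single_indicator_model(data, ["X", "Y"], [("X", "Y")]).fit()

    def test_saturated_deterministic_model_gof_one(self):
        B = _chain_spec(["X", "Y"], {("X", "Y"): 0.999})
        data, _ = generate_sem_data(B, n=2000, noise_sd=0.0, seed=10)
        fit = _single_indicator_model(data, ["X", "Y"], [("X", "Y")]).fit()
        assert fit.gof == pytest.approx(1.0, abs=0.01)

    def test_gof_formula_arithmetic(self):
        fit = self._fit(noise=0.3)
        expected = np.sqrt(fit.communalities.mean() * fit.r_squared.mean())
        assert fit.gof == pytest.approx(expected, abs=1e-12)

    def test_r_squared_matches_squared_correlation(self):
        fit = self._fit(noise=0.2)
        r = np.corrcoef(fit.scores["X"], fit.scores["Y"])[0, 1]
        assert fit.r_squared["Y"] == pytest.approx(r**2, abs=1e-10)


class TestPruning:
    def _two_block_fit(self, weak_noise):
        rng = np.random.default_rng(11)
        n = 500
        lat = rng.normal(size=n)
        data = pd.DataFrame(
            {
                "x1": lat + 0.2 * rng.normal(size=n),
                "x2": lat + 0.2 * rng.normal(size=n),
                "weak": 0.1 * lat + weak_noise * rng.normal(size=n),
                "y1": 0.7 * lat + 0.5 * rng.normal(size=n),
            }
        )
        blocks = {"X": ["x1", "x2", "weak"], "Y": ["y1"]}
        return PLSPathModel.from_dataframe(data, blocks, [("X", "Y")]).fit()

    def test_weak_indicator_dropped(self):
        fit = self._two_block_fit(weak_noise=2.0)
        assert fit.loadings["weak"] < 0.6
        spec = fit.prune(0.6)
        assert spec.blocks["X"] == ["x1", "x2"]

    def test_boundary_loading_retained(self):
        fit = self._two_block_fit(weak_noise=2.0)
        at_boundary = float(fit.loadings["weak"])
        spec = fit.prune(loading_min=at_boundary)  # loading == threshold kept
        assert "weak" in spec.blocks["X"]

    def test_all_loadings_above_threshold_spec_unchanged(self):
        fit = self._two_block_fit(weak_noise=2.0)
        below_all = float(fit.loadings.min()) - 0.01
        spec = fit.prune(loading_min=below_all)
        assert spec.blocks == {"X": ["x1", "x2", "weak"], "Y": ["y1"]}

    def test_emptied_block_names_latent(self):
        fit = self._two_block_fit(weak_noise=2.0)
        with pytest.raises(ValueError, match="X"):
            fit.prune(loading_min=1.5)

    def test_refit_after_pruning(self):
        fit = self._two_block_fit(weak_noise=2.0)
        refit = fit.refit_pruned(0.6)
        assert "weak" not in refit.loadings.index
        assert refit.converged


class TestBootstrap:
    def _fit(self):
        B = _chain_spec(["X", "Y"], {("X", "Y"): 0.8})
        data, _ = generate_sem_data(B, n=120, noise_sd=0.2, seed=12)
        return _single_indicator_model(data, ["X", "Y"], [("X", "Y")]).fit()

    def test_same_seed_identical(self):
        fit = self._fit()
        a = fit.bootstrap(n_boot=150, seed=3)
        b = fit.bootstrap(n_boot=150, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            self._fit().bootstrap(n_boot=10)

    def test_strong_signal_covered_and_significant(self):
        fit = self._fit()
        out = fit.bootstrap(n_boot=200, seed=4)
        row = out.iloc[0]
        assert row["ci_low"] < 0.8 < row["ci_high"] or abs(row["estimate"] - 0.8) < 0.1
        assert row["p"] < 0.05

    def test_coverage_over_replications(self):
        """95% CI contains the generating coefficient in >= 90% of replications."""
        B = _chain_spec(["X", "Y"], {("X", "Y"): 0.6})
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            data, _ = generate_sem_data(B, n=200, noise_sd=0.0, seed=100 + rep)
            fit = _single_indicator_model(data, ["X", "Y"], [("X", "Y")]).fit()
            out = fit.bootstrap(n_boot=199, seed=rep)
            row = out.iloc[0]
            if row["ci_low"] <= 0.6 <= row["ci_high"]:
                hits += 1
        assert hits >= int(0.9 * n_rep)
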