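"""Kernel construction and the Gibbs-sampled kernel mixed models."""

import numpy as np
import pytest

import sparsemet as sm


def toy_cells(n_geno=3, n_env=2, masked=(), seed=0):
    rng = np.random.default_rng(seed)
    genos = [f"g{i}" for i in range(n_geno)]
    cells = [(g, f"E{l}") for l in range(n_env) for g in genos]
    y = rng.normal(size=len(cells))
    observed = np.array([c not in masked for c in cells])
    return sm.CellFrame(
        genotypes=[c[0] for c in cells],
        environments=[c[1] for c in cells],
        y=y,
        observed=observed,
    )


def toy_grm(n_geno=3, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_geno, 50))
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    return sm.GRM([f"g{i}" for i in range(n_geno)], x @ x.T / 50)


class TestBuildKernels:
    def test_model_kernel_sets(self):
        cells = toy_cells()
        g = toy_grm()
        assert [k.label for k in sm.build_kernels(cells, None, "M1")] == \
            ["env", "line"]
        assert [k.label for k in sm.build_kernels(cells, g, "M2")] == \
            ["env", "line", "genomic"]
        assert [k.label for k in sm.build_kernels(cells, g, "M3")] == \
            ["env", "line", "genomic", "gxe"]

    def test_line_kernel_is_genotype_indicator(self):
        cells = toy_cells()
        line = sm.build_kernels(cells, None, "M1")[1].values
        for i in range(len(cells)):
            for j in range(len(cells)):
                same = cells.genotypes[i] == cells.genotypes[j]
                assert line[i, j] == (1.0 if same else 0.0)

    def test_interaction_kernel_zero_across_environments(self):
        cells = toy_cells()
        g = toy_grm()
        gxe = sm.build_kernels(cells, g, "M3")[3].values
        across = cells.environments[:, None] != cells.environments[None, :]
        assert np.all(gxe[across] == 0.0)

    def test_interaction_matches_brute_force_hadamard(self):
        """6-cell toy: the interaction kernel equals the elementwise
        product of the two full grids computed independently."""
        cells = toy_cells(n_geno=3, n_env=2)
        g = toy_grm(3)
        kernels = {k.label: k.values for k in sm.build_kernels(cells, g, "M3")}
        idx = {f"g{i}": i for i in range(3)}
        n = len(cells)
        expected = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                gen_cov = g.values[idx[cells.genotypes[i]], idx[cells.genotypes[j]]]
                env_ind = float(cells.environments[i] == cells.environments[j])
                expected[i, j] = gen_cov * env_ind
        np.testing.assert_allclose(kernels["gxe"], expected, atol=1e-12)
        # and the Hadamard of two PSD grids stays PSD
        assert np.linalg.eigvalsh(expected).min() >= -1e-10

    def test_missing_genotype_is_named(self):
        cells = toy_cells(n_geno=4)
        with pytest.raises(ValueError, match="g3"):
            sm.build_kernels(cells, toy_grm(3), "M2")


class TestFitModel:
    def test_fixed_variance_matches_direct_solve(self):
        """With the variance components pinned, posterior-mean predictions
        must match Henderson's closed-form solution computed by a direct
        linear solve on a 20-genotype toy."""
        n = 20
        g = toy_grm(n, seed=3)
        rng = np.random.default_rng(4)
        u_true = np.linalg.cholesky(g.values + 1e-8 * np.eye(n)) @ rng.normal(size=n)
        y = 1.5 + u_true + rng.normal(0, 0.3, size=n)
        masked = {(f"g{i}", "E0") for i in range(15, 20)}
        cells = sm.CellFrame(
            genotypes=[f"g{i}" for i in range(n)],
            environments=["E0"] * n,
            y=y,
            observed=np.array([(f"g{i}", "E0") not in masked for i in range(n)]),
        )
        kernels = [k for k in sm.build_kernels(cells, g, "M2") if k.label == "genomic"]
        s2u, s2e = 1.0, 0.09
        fit = sm.fit_model(
            cells, kernels,
            sm.SamplerConfig(n_iter=24000, burn_in=4000, thin=2, seed=7,
                             fixed_components={"genomic": s2u, "error": s2e}),
        )
        # oracle: GLS intercept and conditional-mean random effects
        obs = cells.observed
        k_oo = kernels[0].values[np.ix_(obs, obs)]
        v = s2u * k_oo + s2e * np.eye(obs.sum())
        ones = np.ones(obs.sum())
        vinv_y = np.linalg.solve(v, y[obs])
        vinv_1 = np.linalg.solve(v, ones)
        beta = float(ones @ vinv_y / (ones @ vinv_1))
        u_all = s2u * kernels[0].values[:, obs] @ np.linalg.solve(
            v, y[obs] - beta * ones
        )
        expected = beta + u_all
        assert np.abs(fit.predictions - expected).max() < 0.01 * y.std()

    def test_interpolation_limit_reproduces_observations(self):
        """All cells observed with the error variance pinned near zero:
        fitted values reproduce the data (one environment, so the line
        kernel is full rank over the cells and can interpolate)."""
        cells = toy_cells(n_geno=16, n_env=1, seed=5)
        kernels = [k for k in sm.build_kernels(cells, None, "M1")
                   if k.label == "line"]
        var_y = cells.y.var()
        fit = sm.fit_model(
            cells, kernels,
            sm.SamplerConfig(n_iter=3000, burn_in=500, thin=2, seed=8,
                             fixed_components={"line": 50.0 * var_y,
                                               "error": 1e-6 * var_y}),
        )
        assert np.abs(fit.predictions - cells.y).max() < 0.01 * cells.y.std()

    def test_no_interaction_data_shrinks_m3_toward_m2(self, small_grm):
        """Data simulated without G x E: M3's interaction component stays
        a small share of the genetic variance and its predictions track
        M2's (median over 20 replicates)."""
        shares, corrs = [], []
        for rep in range(20):
            cfg = sm.SimConfig(
                n_genotypes=40, n_environments=5, n_markers=200, seed=300 + rep,
                variance_components={"t": dict(g=2.0, gxe=0.0, block_in_rep=0.0,
                                               error=0.4)},
            )
            markers, sig, plots = sm.simulate_dataset(cfg)
            g = sm.grm(markers)
            blups = sm.adjusted_phenotypes(plots)
            cells = sm.CellFrame.from_blups(
                blups, "t",
                {(gn, e) for gn, e in zip(blups["genotype"], blups["env"])},
            )
            cfg_s = sm.SamplerConfig(n_iter=1500, burn_in=500, thin=5, seed=rep)
            m2 = sm.fit_model(cells, sm.build_kernels(cells, g, "M2"), cfg_s)
            m3 = sm.fit_model(cells, sm.build_kernels(cells, g, "M3"), cfg_s)
            genetic = m3.components["line"] + m3.components["genomic"] \
                + m3.components["gxe"]
            shares.append(m3.components["gxe"] / genetic)
            corrs.append(np.corrcoef(m2.predictions, m3.predictions)[0, 1])
        assert np.median(shares) < 0.10
        assert np.median(corrs) > 0.99

    def test_nesting_never_worsens_in_sample_fit(self, small_blups, small_grm):
        observed = {
            (g, e) for g, e in zip(small_blups["genotype"], small_blups["env"])
        }
        cells = sm.CellFrame.from_blups(small_blups, "t", observed)
        cfg = sm.SamplerConfig(n_iter=2000, burn_in=500, thin=5, seed=3)
        fits = {
            m: sm.fit_model(
                cells,
                sm.build_kernels(cells, small_grm if m != "M1" else None, m),
                cfg,
            )
            for m in sm.MODELS
        }
        in_mse = {m: np.mean((f.predictions - cells.y) ** 2)
                  for m, f in fits.items()}
        slack = 0.02 * cells.y.var()
        assert in_mse["M2"] <= in_mse["M1"] + slack
        assert in_mse["M3"] <= in_mse["M2"] + slack

    def test_permuting_cells_permutes_predictions(self):
        """Kernels are exactly permutation-equivariant; fixed-component
        posterior-mean predictions agree within Monte Carlo noise."""
        cells = toy_cells(n_geno=6, n_env=2, masked={("g0", "E1")}, seed=9)
        g = toy_grm(6, seed=2)
        perm = np.random.default_rng(0).permutation(len(cells))
        permuted = sm.CellFrame(
            genotypes=cells.genotypes[perm],
            environments=cells.environments[perm],
            y=cells.y[perm],
            observed=cells.observed[perm],
        )
        k1 = sm.build_kernels(cells, g, "M3")
        k2 = sm.build_kernels(permuted, g, "M3")
        for a, b in zip(k1, k2):
            np.testing.assert_allclose(
                a.values[np.ix_(perm, perm)], b.values, atol=1e-12
            )
        cfg = dict(n_iter=42000, burn_in=2000, thin=2,
                   fixed_components={"env": 1.0, "line": 1.0, "genomic": 1.0,
                                     "gxe": 1.0, "error": 0.5})
        f1 = sm.fit_model(cells, k1, sm.SamplerConfig(seed=1, **cfg))
        f2 = sm.fit_model(permuted, k2, sm.SamplerConfig(seed=2, **cfg))
        assert np.abs(f1.predictions[perm] - f2.predictions).max() \
            < 0.05 * cells.y.std()

    def test_same_seed_reproducible(self):
        cells = toy_cells(n_geno=5, n_env=2, seed=6)
        kernels = sm.build_kernels(cells, None, "M1")
        cfg = sm.SamplerConfig(n_iter=500, burn_in=100, thin=2, seed=11)
        a = sm.fit_model(cells, kernels, cfg)
        b = sm.fit_model(cells, kernels, cfg)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_component_estimates_nonnegative_and_finite(self, small_blups,
                                                        small_grm):
        observed = {
            (g, e) for g, e in zip(small_blups["genotype"], small_blups["env"])
        }
        cells = sm.CellFrame.from_blups(small_blups, "t", observed)
        fit = sm.fit_model(
            cells, sm.build_kernels(cells, small_grm, "M3"),
            sm.SamplerConfig(n_iter=800, burn_in=300, thin=5, seed=4),
        )
        assert all(v >= 0 for v in fit.components.values())
        assert np.isfinite(fit.predictions).all()
        assert fit.n_samples == (800 - 300 + 4) // 5


class TestValidation:
    def test_chain_shorter_than_burn_in_rejected(self):
        with pytest.raises(ValueError, match="burn-in"):
            sm.SamplerConfig(n_iter=100, burn_in=100)

    def test_non_psd_kernel_rejected(self):
        cells = toy_cells(n_geno=2, n_env=1)
        bad = sm.Kernel("env", np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="PSD"):
            sm.fit_model(cells, [bad],
                         sm.SamplerConfig(n_iter=200, burn_in=50))

    def test_asymmetric_kernel_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sm.Kernel("env", np.array([[1.0, 0.5], [0.0, 1.0]]))
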