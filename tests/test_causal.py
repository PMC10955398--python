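"""Node-pair table construction and the diachronic causal models."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, linalg, stats

from geophylocausal import causal
from geophylocausal.causal import (
    ModelSpec,
    NodePairTable,
    build_node_pair_table,
    elpd_compare,
    fit_model,
    gp_kernel_geo,
    gp_kernel_phylo,
    interpolate_lineage_value,
    latent_measurement_layers,
    loglik_model_lin,
    sample_latents,
    savage_dickey,
)
from geophylocausal.core import cophenetic_matrix, greatcircle_matrix
from geophylocausal.reconstruct import NodeReconstruction, asr_brownian
from geophylocausal.simulate import SimulationConfig, TraitModelConfig, simulate_dataset

from conftest import humidity_of, trait_of


class TestInterpolation:
    def test_worked_example(self):
        assert interpolate_lineage_value(0.5, 5.0, 2.0) == 3.5

    def test_endpoints(self):
        assert interpolate_lineage_value(0.0, 5.0, 2.0) == 5.0
        assert interpolate_lineage_value(1.0, 5.0, 2.0) == 2.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpolate_lineage_value(1.2, 5.0, 2.0)


class TestNodePairTable:
    def test_hand_computed_worksheet(self, worksheet_tree):
        tree = worksheet_tree
        table = build_node_pair_table(
            tree, trait_of(tree), humidity_of(tree),
            geo_radius_km=500.0, phylo_radius=2.5, scale=False)
        df = table.df.set_index("desc")
        assert len(df) == 4
        # H = mean of endpoint humidities
        assert df.loc["A", "H"] == pytest.approx(1.5)
        assert df.loc["B", "H"] == pytest.approx(0.5)
        assert df.loc["C", "H"] == pytest.approx(2.25)
        assert df.loc["D", "H"] == pytest.approx(1.75)
        # dA = edge durations
        assert df.loc["A", "dA"] == pytest.approx(2.0)
        assert df.loc["B", "dA"] == pytest.approx(3.0)
        # Gt: interpolated contemporaneous neighbours within 500 km
        assert df.loc["A", "Gt_MEAN"] == pytest.approx(4.0 / 3.0)  # R->B at p=2/3
        assert df.loc["A", "Gt_SD"] == pytest.approx(0.0)
        assert df.loc["B", "Gt_MEAN"] == pytest.approx(3.0)  # leaves C=4, D=2
        assert df.loc["B", "Gt_SD"] == pytest.approx(1.0)
        assert df.loc["C", "Gt_MEAN"] == pytest.approx(1.5)  # B=1, D=2
        assert df.loc["C", "Gt_SD"] == pytest.approx(0.5)
        assert df.loc["D", "Gt_MEAN"] == pytest.approx(2.5)  # B=1, C=4
        assert df.loc["D", "Gt_SD"] == pytest.approx(1.5)
        # Pt: cophenetic radius 2.5, excluding self and own ancestor
        assert df.loc["A", "Pt_MEAN"] == pytest.approx(3.0)  # C=4, D=2
        assert df.loc["A", "Pt_SD"] == pytest.approx(1.0)
        assert bool(df.loc["B", "pt_empty"]) is True
        assert df.loc["B", "Pt_MEAN"] == 0.0
        assert df.loc["C", "Pt_MEAN"] == pytest.approx(2.0)  # D only
        assert df.loc["D", "Pt_MEAN"] == pytest.approx(4.0)  # C only

    def test_zscaling_unit_sd_and_recoverable(self, worksheet_tree):
        tree = worksheet_tree
        raw = build_node_pair_table(tree, trait_of(tree), humidity_of(tree),
                                    geo_radius_km=500.0, phylo_radius=2.5,
                                    scale=False)
        scaled = build_node_pair_table(tree, trait_of(tree), humidity_of(tree),
                                       geo_radius_km=500.0, phylo_radius=2.5)
        assert np.std(scaled.df["H"], ddof=1) == pytest.approx(1.0)
        # dividing by the stored factor recovers the raw column
        np.testing.assert_allclose(
            scaled.df["H"] * scaled.scale_factors["H"], raw.df["H"])
        np.testing.assert_allclose(
            scaled.df["Gt_MEAN"] * scaled.scale_factors["Gt"], raw.df["Gt_MEAN"])
        # scaling divides, never centres: signs and zeros preserved
        assert (np.sign(scaled.df["Pt_MEAN"]) == np.sign(raw.df["Pt_MEAN"])).all()

    def test_single_location_all_contemporaries_are_neighbours(self):
        cfg = SimulationConfig(n_tips=12, seed=1, dispersal_sd=0.0)
        tree = simulate_dataset(cfg)
        table = build_node_pair_table(tree, trait_of(tree), humidity_of(tree),
                                      phylo_radius_mode="fraction_of_depth")
        from geophylocausal.core import lineages_at_time

        for _, row in table.df.iterrows():
            n_contemp = len(lineages_at_time(tree, tree.nodes[row["desc"]].age)) - 1
            assert bool(row["gt_empty"]) == (n_contemp == 0)

    def test_zero_length_edges_dropped_and_logged(self, worksheet_tree):
        from conftest import make_tree

        tree = make_tree({"A": "R", "B": "R", "C": "A", "D": "A"},
                         {"R": 2.0, "A": 2.0, "B": 0.0, "C": 0.0, "D": 0.0})
        tree.set_trait("h", {n: 1.0 + i for i, n in enumerate(tree.node_ids)})
        traits = {n: float(i) for i, n in enumerate(tree.node_ids)}
        h = {n: tree.nodes[n].traits["h"] for n in tree.node_ids}
        table = build_node_pair_table(tree, traits, h, phylo_radius=0.5,
                                      scale=False)
        assert table.dropped_edges == ["A"]
        assert "A" not in set(table.df["desc"])


class TestLoglikModelLin:
    def _table(self, n=5, seed=0, se=0.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "anc": [f"a{i}" for i in range(n)],
            "desc": [f"d{i}" for i in range(n)],
            "T_anc": rng.normal(2, 1, n), "T_desc": rng.normal(2, 1, n),
            "T_anc_SE": np.zeros(n), "T_desc_SE": np.full(n, se),
            "dA": rng.uniform(0.5, 2.0, n), "H": rng.normal(0, 1, n),
            "Gt_MEAN": rng.normal(0, 1, n), "Gt_SD": np.zeros(n),
            "Pt_MEAN": rng.normal(0, 1, n), "Pt_SD": np.zeros(n),
            "gt_empty": False, "pt_empty": False,
        })
        return NodePairTable(df=df, scale_factors={"H": 1, "Gt": 1, "Pt": 1})

    def test_beta_zero_matches_iid_normal(self):
        table = self._table()
        params = dict(alpha=0.3, eta=0.5, gamma=-0.2, rho=0.1, sigma0=0.7,
                      beta=0.0)
        ll = loglik_model_lin(params, table)
        df = table.df
        mu = (params["alpha"] + params["eta"] * df["H"]
              + params["gamma"] * df["Gt_MEAN"]
              + params["rho"] * df["Pt_MEAN"]) * df["dA"]
        direct = stats.norm.logpdf(df["T_desc"] - df["T_anc"], mu, 0.7).sum()
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_one_row_closed_form(self):
        table = self._table(n=1, seed=3)
        row = table.df.iloc[0]
        params = dict(alpha=0.1, eta=0.4, gamma=0.0, rho=0.0, sigma0=0.5,
                      beta=0.2)
        mu = (0.1 + 0.4 * row["H"]) * row["dA"]
        sd = 0.5 + 0.2 * row["dA"]
        expect = stats.norm.logpdf(row["T_desc"] - row["T_anc"], mu, sd)
        assert loglik_model_lin(params, table) == pytest.approx(expect, abs=1e-12)

    def test_doubling_da_doubles_mean_via_alpha(self):
        table = self._table(n=1, seed=4)
        t2 = self._table(n=1, seed=4)
        t2.df["dA"] *= 2
        alpha = 0.7
        y = float(table.df["T_desc"].iloc[0] - table.df["T_anc"].iloc[0])
        p = dict(alpha=alpha, eta=0, gamma=0, rho=0, sigma0=1.0, beta=0.0)
        mu1 = alpha * float(table.df["dA"].iloc[0])
        mu2 = alpha * float(t2.df["dA"].iloc[0])
        assert mu2 == 2 * mu1
        assert loglik_model_lin(p, table) == pytest.approx(
            stats.norm.logpdf(y, mu1, 1.0))
        assert loglik_model_lin(p, t2) == pytest.approx(
            stats.norm.logpdf(y, mu2, 1.0))

    def test_nonpositive_scale_soft_rejection(self):
        table = self._table()
        p = dict(alpha=0, eta=0, gamma=0, rho=0, sigma0=0.1, beta=-1.0)
        assert loglik_model_lin(p, table) == -np.inf

    def test_outcome_difference_equals_offset_formulation(self):
        # fitting dT ~ predictors is the same density as T_desc ~ T_anc+mu
        table = self._table(seed=5)
        params = dict(alpha=0.2, eta=-0.3, gamma=0.0, rho=0.0, sigma0=0.6,
                      beta=0.1)
        df = table.df
        mu = (params["alpha"] + params["eta"] * df["H"]) * df["dA"]
        sd = params["sigma0"] + params["beta"] * df["dA"]
        offset_form = stats.norm.logpdf(df["T_desc"], df["T_anc"] + mu, sd).sum()
        assert loglik_model_lin(params, table) == pytest.approx(offset_form,
                                                                abs=1e-10)

    def test_null_model_equivalence_on_single_edge(self):
        # all coefficients 0, beta=0, sigma0 = branch length: the increment
        # density is the null model's Normal(0, B)
        table = self._table(n=1, seed=6)
        b = float(table.df["dA"].iloc[0])
        y = float(table.df["T_desc"].iloc[0] - table.df["T_anc"].iloc[0])
        p = dict(alpha=0, eta=0, gamma=0, rho=0, sigma0=b, beta=0.0)
        assert loglik_model_lin(p, table) == pytest.approx(
            stats.norm.logpdf(y, 0.0, b), abs=1e-12)


class TestLatentLayers:
    def test_all_se_zero_only_gt_pt_terms(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "anc": ["a"], "desc": ["d"], "T_anc": [2.0], "T_desc": [2.5],
            "T_anc_SE": [0.0], "T_desc_SE": [0.0], "dA": [1.0], "H": [0.5],
            "Gt_MEAN": [1.0], "Gt_SD": [0.5], "Pt_MEAN": [2.0], "Pt_SD": [0.0],
            "gt_empty": [False], "pt_empty": [False],
        })
        table = NodePairTable(df=df, scale_factors={"H": 1, "Gt": 1, "Pt": 1})
        rec = NodeReconstruction(mean={"a": 2.0, "d": 2.5},
                                 se={"a": 0.0, "d": 0.0})
        gt = np.array([1.3])
        pt = np.array([2.0])  # zero-SD: must equal the mean
        lp = latent_measurement_layers(rec, table, {}, gt, pt)
        assert lp == pytest.approx(stats.norm.logpdf(1.3, 1.0, 0.5))
        with pytest.raises(ValueError, match="zero SD"):
            latent_measurement_layers(rec, table, {}, gt, np.array([2.5]))

    def test_single_latent_marginal_matches_numeric_convolution(self):
        # two edges R->A->C share latent A; the closed-form marginal must
        # equal numerical integration over T_A
        df = pd.DataFrame({
            "anc": ["R", "A"], "desc": ["A", "C"],
            "T_anc": [2.0, 2.6], "T_desc": [2.6, 3.1],
            "T_anc_SE": [0.0, 0.4], "T_desc_SE": [0.4, 0.0],
            "dA": [1.0, 1.5], "H": [0.2, -0.1],
            "Gt_MEAN": [0.0, 0.0], "Gt_SD": [0.0, 0.0],
            "Pt_MEAN": [0.0, 0.0], "Pt_SD": [0.0, 0.0],
            "gt_empty": [True, True], "pt_empty": [True, True],
        })
        table = NodePairTable(df=df, scale_factors={"H": 1, "Gt": 1, "Pt": 1})
        spec = ModelSpec(variant="lin")
        model = causal._MarginalModel(spec, table)
        theta = np.array([0.1, 0.3, 0.0, 0.0, 0.6, 0.05])  # alpha eta gamma rho sigma0 beta
        ll = model.log_likelihood(theta)

        a, e, s0, b = 0.1, 0.3, 0.6, 0.05
        mu = (a + e * df["H"].to_numpy()) * df["dA"].to_numpy()
        sd = s0 + b * df["dA"].to_numpy()

        def integrand(t_a):
            # T_A = 2.6 + eps, prior N(2.6, 0.4)
            d1 = stats.norm.pdf(t_a - 2.0, mu[0], sd[0])
            d2 = stats.norm.pdf(3.1 - t_a, mu[1], sd[1])
            return stats.norm.pdf(t_a, 2.6, 0.4) * d1 * d2

        val, _ = integrate.quad(integrand, 2.6 - 6, 2.6 + 6)
        assert ll == pytest.approx(np.log(val), abs=1e-6)


class TestKernels:
    def test_zero_distance_values(self):
        assert gp_kernel_geo(np.array(0.0), 2.0, 100.0, jitter=0.1) == pytest.approx(4.1)
        assert gp_kernel_phylo(np.array(0.0), 1.5, 3.0) == pytest.approx(2.25)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 2000, 50)
        kg = gp_kernel_geo(d, 1.0, 300.0, jitter=0.0)
        kp = gp_kernel_phylo(d / 100, 1.0, 5.0)
        assert np.all(np.diff(kg) < 0)
        assert np.all(np.diff(kp) < 0)

    def test_cholesky_succeeds_on_random_distance_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = rng.uniform(-10, 10, size=(30, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)) * 111.0
            amp = float(rng.uniform(0.2, 3.0))
            ls = float(rng.uniform(50, 2000))
            linalg.cholesky(gp_kernel_geo(d, amp, ls))
            linalg.cholesky(gp_kernel_phylo(d / 500, amp, ls / 500)
                            + 1e-10 * np.eye(30))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            gp_kernel_geo(np.array(1.0), -1.0, 2.0)
        with pytest.raises(ValueError):
            gp_kernel_phylo(np.array(1.0), 1.0, 0.0)


def _synthetic_fit(seed=0, eta=0.5, n_tips=40, **spec_kw):
    cfg = SimulationConfig(n_tips=n_tips, seed=seed,
                           trait=TraitModelConfig(kind="causal", eta=eta))
    tree = simulate_dataset(cfg)
    table = build_node_pair_table(tree, trait_of(tree), humidity_of(tree),
                                  phylo_radius_mode="fraction_of_depth")
    spec = ModelSpec(variant="lin", seed=seed, **spec_kw)
    return tree, table, fit_model(spec, table)


class TestFitModel:
    def test_prior_predictive_moments_match_priors(self):
        cfg = SimulationConfig(n_tips=20, seed=2,
                               trait=TraitModelConfig(kind="causal"))
        tree = simulate_dataset(cfg)
        table = build_node_pair_table(tree, trait_of(tree), humidity_of(tree),
                                      phylo_radius_mode="fraction_of_depth")
        fit = fit_model(ModelSpec(variant="lin", seed=3, nsteps=4000,
                                  burn=1000, thin=4), table, prior_only=True)
        eta = fit.samples("eta")
        sigma0 = fit.samples("sigma0")
        assert np.mean(eta) == pytest.approx(0.0, abs=0.1)
        assert np.std(eta) == pytest.approx(1.0, abs=0.15)
        assert np.mean(sigma0) == pytest.approx(1.0, abs=0.15)

    def test_recovers_eta_and_reports_diagnostics(self):
        tree, table, fit = _synthetic_fit(seed=7, eta=0.5, nsteps=3000,
                                          burn=1500)
        assert fit.acceptance_fraction > 0.1
        assert set(fit.param_names) == {"alpha", "eta", "gamma", "rho",
                                        "sigma0", "beta"}
        eta_raw = fit.raw_coefficient("eta")
        lo, hi = np.quantile(eta_raw, [0.025, 0.975])
        assert lo < 0.5 < hi
        assert all(np.isfinite(v) for v in fit.rhat.values())

    def test_confound_subsets_change_parameter_vector(self):
        cfg = SimulationConfig(n_tips=20, seed=4,
                               trait=TraitModelConfig(kind="causal"))
        tree = simulate_dataset(cfg)
        table = build_node_pair_table(tree, trait_of(tree), humidity_of(tree),
                                      phylo_radius_mode="fraction_of_depth")
        spec = ModelSpec(variant="lin", include_geography=False,
                         include_phylogeny=False, seed=5, nsteps=2000,
                         burn=1000)
        fit = fit_model(spec, table)
        assert fit.param_names == ["alpha", "eta", "sigma0", "beta"]

    def test_gp_variant_runs_and_latents_sampled(self):
        cfg = SimulationConfig(n_tips=25, seed=6,
                               trait=TraitModelConfig(kind="causal", eta=0.3))
        tree = simulate_dataset(cfg)
        table = build_node_pair_table(tree, trait_of(tree), humidity_of(tree),
                                      phylo_radius_mode="fraction_of_depth")
        dm = {"geographic": greatcircle_matrix(tree),
              "cophenetic": cophenetic_matrix(tree)}
        fit = fit_model(ModelSpec(variant="gp", seed=6, nsteps=2000,
                                  burn=1000), table, dm)
        assert set(fit.param_names) == {"alpha", "eta", "sigma0", "beta",
                                        "amp_g", "ls_g", "amp_p", "ls_p"}
        lat = sample_latents(fit, table, dm, n_draws=10)
        assert lat["gp_effect"].shape == (10, len(table))

    def test_gp_variant_requires_distances(self):
        tree, table, _fit = None, None, None
        cfg = SimulationConfig(n_tips=10, seed=8,
                               trait=TraitModelConfig(kind="causal"))
        tree = simulate_dataset(cfg)
        table = build_node_pair_table(tree, trait_of(tree), humidity_of(tree),
                                      phylo_radius_mode="fraction_of_depth")
        with pytest.raises(ValueError, match="distance matrices"):
            fit_model(ModelSpec(variant="gp", seed=1), table)

    def test_latent_interior_nodes_sampled_when_reconstructed(self):
        cfg = SimulationConfig(n_tips=20, seed=9,
                               trait=TraitModelConfig(kind="causal", eta=0.2))
        tree = simulate_dataset(cfg)
        rec = asr_brownian(tree, tree.leaf_trait_map("trait"), root_fossil=2.0)
        table = build_node_pair_table(tree, rec, humidity_of(tree),
                                      phylo_radius_mode="fraction_of_depth")
        fit = fit_model(ModelSpec(variant="lin", seed=9, nsteps=2000,
                                  burn=1000), table)
        lat = sample_latents(fit, table, n_draws=15)
        assert "T_interior" in lat
        assert lat["T_interior"].shape[0] == 15
        assert lat["Gt"].shape == (15, len(table))


class TestSavageDickey:
    def _fake_fit(self, samples, prior_sd=1.0):
        import arviz as az

        idata = az.from_dict(posterior={"eta": samples.reshape(4, -1)})
        spec = ModelSpec(variant="lin", coef_prior_sd=prior_sd)
        return causal.PosteriorFit(
            idata=idata, spec=spec, param_names=["eta"],
            scale_factors={"H": 1.0, "Gt": 1.0, "Pt": 1.0}, rhat={"eta": 1.0},
            ess={"eta": 1000.0}, converged=True, seed=0,
            acceptance_fraction=0.5)

    def test_posterior_equals_prior_gives_bf_one(self):
        rng = np.random.default_rng(0)
        fit = self._fake_fit(rng.normal(0, 1, 40_000))
        res = savage_dickey(fit, "eta")
        assert res["bf10"] == pytest.approx(1.0, rel=0.1)

    def test_matches_closed_form_normal_ratio(self):
        # the tail density is exponentially sensitive to the moment
        # estimates, so a large draw count keeps the ratio within 15%
        rng = np.random.default_rng(1)
        fit = self._fake_fit(rng.normal(1.0, 0.1, 500_000))
        res = savage_dickey(fit, "eta")
        expect = stats.norm.pdf(0, 0, 1) / stats.norm.pdf(0, 1.0, 0.1)
        assert res["bf10"] == pytest.approx(expect, rel=0.15)

    def test_lindley_widening_prior_favours_null_monotonically(self):
        # widening the alternative's prior lowers its density at 0, so the
        # point null gains support: BF10 = prior(0)/posterior(0) decreases
        rng = np.random.default_rng(2)
        samples = rng.normal(0.5, 0.2, 20_000)
        bfs = []
        for prior_sd in (0.5, 1.0, 2.0, 4.0):
            fit = self._fake_fit(samples, prior_sd=prior_sd)
            bfs.append(savage_dickey(fit, "eta")["bf10"])
        assert bfs == sorted(bfs, reverse=True)
        expect = [stats.norm.pdf(0, 0, s) / stats.norm.pdf(0, 0.5, 0.2)
                  for s in (0.5, 1.0, 2.0, 4.0)]
        np.testing.assert_allclose(bfs, expect, rtol=0.2)


class TestElpd:
    def test_model_compared_with_itself_zero_difference(self):
        _, _, fit = _synthetic_fit(seed=10, eta=0.3, n_tips=25, nsteps=2000,
                                   burn=1000)
        table = elpd_compare({"a": fit, "b": fit})
        assert table["elpd_diff"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_true_model_beats_no_humidity_model_on_strong_effect(self):
        wins = 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_tips=60, seed=40 + seed,
                trait=TraitModelConfig(kind="causal", eta=1.5, sigma0=0.3))
            tree = simulate_dataset(cfg)
            table = build_node_pair_table(tree, trait_of(tree),
                                          humidity_of(tree),
                                          phylo_radius_mode="fraction_of_depth")
            common = dict(nsteps=2000, burn=1000, seed=seed)
            full = fit_model(ModelSpec(variant="lin", **common), table)
            # misspecified: humidity excluded by pinning its prior to zero
            nohum = fit_model(ModelSpec(variant="lin", coef_prior_sd=1.0,
                                        **common), _strip_humidity(table))
            cmp_table = elpd_compare({"full": full, "nohum": nohum})
            if cmp_table.index[0] == "full":
                diff = cmp_table.loc["nohum", "elpd_diff"]
                dse = cmp_table.loc["nohum", "dse"]
                wins += diff > 2 * dse
        assert wins >= 4

    def test_mismatched_observation_sets_rejected(self):
        _, table, fit = _synthetic_fit(seed=11, eta=0.0, n_tips=20,
                                       nsteps=1500, burn=750)
        df_small = table.df.iloc[:-2].reset_index(drop=True)
        small = NodePairTable(df=df_small, scale_factors=table.scale_factors)
        fit_small = fit_model(ModelSpec(variant="lin", seed=11, nsteps=1500,
                                        burn=750), small)
        with pytest.raises(ValueError, match="mismatched"):
            elpd_compare({"a": fit, "b": fit_small})


def _strip_humidity(table: NodePairTable) -> NodePairTable:
    df = table.df.copy()
    df["H"] = 0.0
    return NodePairTable(df=df, scale_factors=dict(table.scale_factors))
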