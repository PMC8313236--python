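import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from monoculture.bpmm import ChainConfig, PhyloMetaRegression, fit_bpmm
from monoculture.phylo import grafen_lengths, phylo_correlation, tree_from_taxonomy
from monoculture.simulate import SyntheticTruth, random_taxonomy, simulate_effect_table


def _weighted_fixture(seed=0, n=50, mu=0.3, s2e=0.05):
    rng = np.random.default_rng(seed)
    v = 1.0 / (rng.integers(4, 30, n) - 3)
    y = mu + rng.normal(0.0, np.sqrt(v + s2e))
    return y, v


class TestConjugateOracle:
    def test_intercept_matches_precision_weighted_normal(self):
        """With no random effects and sigma2_e fixed, the intercept's
        posterior is the closed-form precision-weighted normal."""
        s2e = 0.05
        y, v = _weighted_fixture(seed=3, s2e=s2e)
        model = PhyloMetaRegression(
            random_terms=(), iterations=11_000, burn_in=1_000, thin=10,
            n_chains=2, fix_residual_variance=s2e, random_state=11,
        )
        model.fit(np.ones((y.size, 1)), y, v)
        w = 1.0 / (v + s2e)
        prior_prec = 1.0 / model.fixed_effect_variance
        mean_cf = (w * y).sum() / (w.sum() + prior_prec)
        var_cf = 1.0 / (w.sum() + prior_prec)
        draws = model.beta_pooled_[:, 0]
        mcse = draws.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(mean_cf, abs=3 * mcse)
        assert draws.var() == pytest.approx(var_cf, rel=0.10)

    def test_duplicating_data_halves_posterior_variance(self):
        s2e = 0.05
        y, v = _weighted_fixture(seed=4, s2e=s2e)
        kwargs = dict(random_terms=(), iterations=11_000, burn_in=1_000,
                      thin=10, n_chains=2, fix_residual_variance=s2e,
                      random_state=5)
        single = PhyloMetaRegression(**kwargs).fit(np.ones((y.size, 1)), y, v)
        y2, v2 = np.tile(y, 2), np.tile(v, 2)
        double = PhyloMetaRegression(**kwargs).fit(np.ones((y2.size, 1)), y2, v2)
        ratio = double.beta_pooled_[:, 0].var() / single.beta_pooled_[:, 0].var()
        assert ratio == pytest.approx(0.5, rel=0.15)


class TestDenseMvnOracle:
    def test_fixed_variance_posterior_matches_marginal_closed_form(self):
        """Small instance: with every variance component held fixed, the
        Gibbs posterior of beta must match the dense multivariate-normal
        marginal computed by direct linear algebra."""
        rng = np.random.default_rng(9)
        n, species_of = 12, np.array([0, 0, 1, 1, 2, 2, 3, 3, 0, 1, 2, 3])
        study_of = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 4, 4])
        tax = pd.DataFrame({
            "class": ["c1"] * 4,
            "genus": ["g1", "g1", "g2", "g2"],
            "species": ["s0", "s1", "s2", "s3"],
        })
        corr = phylo_correlation(grafen_lengths(tree_from_taxonomy(tax)))
        A = corr.loc[[f"s{i}" for i in range(4)], [f"s{i}" for i in range(4)]].to_numpy()
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        v = np.full(n, 0.2)
        s2 = {"study": 0.10, "species": 0.05, "phylo": 0.08}
        s2e = 0.04
        Zs = np.eye(5)[study_of]
        Zp = np.eye(4)[species_of]
        V = (s2["study"] * Zs @ Zs.T + s2["species"] * Zp @ Zp.T
             + s2["phylo"] * Zp @ A @ Zp.T + np.diag(v + s2e))
        y = rng.multivariate_normal(X @ [0.2, -0.4], V)

        Vinv = np.linalg.inv(V)
        B = 1e10
        post_prec = X.T @ Vinv @ X + np.eye(2) / B
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ X.T @ Vinv @ y

        model = PhyloMetaRegression(
            iterations=31_000, burn_in=1_000, thin=10, n_chains=2,
            fix_residual_variance=s2e, fix_variance_components=s2,
            random_state=21,
        )
        model.fit(
            X, y, v,
            study=[f"st{j}" for j in study_of],
            species=[f"s{i}" for i in species_of],
            phylo_corr=corr,
        )
        draws = model.beta_pooled_
        for j in range(2):
            mcse = draws[:, j].std() / np.sqrt(draws.shape[0] / 5)
            assert draws[:, j].mean() == pytest.approx(post_mean[j], abs=3 * mcse)
            assert draws[:, j].std() == pytest.approx(
                np.sqrt(post_cov[j, j]), rel=0.15
            )


class TestModelBehaviour:
    def test_row_order_invariance(self, small_dataset, smoke_cfg):
        records, corr, _ = small_dataset
        rec = records[records["effect_type"] == "Zr"]
        shuffled = rec.sample(frac=1.0, random_state=7)
        out = []
        for data in (rec, shuffled):
            model = PhyloMetaRegression(
                iterations=smoke_cfg.iterations, burn_in=smoke_cfg.burn_in,
                thin=smoke_cfg.thin, n_chains=1, random_state=17,
            )
            model.fit(
                np.ones((len(data), 1)), data["value"],
                data["sampling_variance"], study=data["study_id"],
                species=data["species_id"], phylo_corr=corr,
            )
            out.append(model.beta_samples_)
        assert np.array_equal(out[0], out[1])

    def test_engines_agree(self, small_dataset):
        """The compiled sweep and the numpy reference implement the same
        conditional draws in the same order."""
        records, corr, _ = small_dataset
        rec = records[records["effect_type"] == "Zr"]
        out = {}
        for engine in ("numpy", "numba"):
            model = PhyloMetaRegression(
                iterations=2_000, burn_in=500, thin=5, n_chains=1,
                engine=engine, random_state=23,
            )
            model.fit(
                np.ones((len(rec), 1)), rec["value"],
                rec["sampling_variance"], study=rec["study_id"],
                species=rec["species_id"], phylo_corr=corr,
            )
            out[engine] = (model.beta_samples_, model.variance_samples_)
        assert np.allclose(out["numpy"][0], out["numba"][0], atol=1e-10)
        assert np.allclose(out["numpy"][1], out["numba"][1], atol=1e-10)

    def test_identity_corr_recovers_species_plus_phylo_sum(self):
        """With an identity species correlation the species and phylo
        variances are jointly unidentifiable, but their sum is
        recoverable."""
        truth = SyntheticTruth(
            n_species=50, n_studies=60, n_effects=200, n_lncvr=0,
            s2_species=0.1, s2_phylo=0.1,
        )
        ident = pd.DataFrame(
            np.eye(50),
            index=[f"sp{i:03d}" for i in range(50)],
            columns=[f"sp{i:03d}" for i in range(50)],
        )
        rec, corr, _ = simulate_effect_table(truth, tree_or_S=ident, seed=5)
        model = PhyloMetaRegression(
            iterations=33_000, burn_in=3_000, thin=30, n_chains=2,
            random_state=3,
        )
        model.fit(
            np.ones((len(rec), 1)), rec["value"], rec["sampling_variance"],
            study=rec["study_id"], species=rec["species_id"], phylo_corr=corr,
        )
        vs = model.variance_pooled_
        names = model.variance_names_
        total = (vs[:, names.index("species")] + vs[:, names.index("phylo")])
        assert 0.1 < total.mean() < 0.4  # truth: 0.2

    def test_variance_fractions_sum_to_hundred(self, small_dataset, smoke_cfg):
        records, corr, _ = small_dataset
        rec = records[records["effect_type"] == "Zr"]
        model = fit_bpmm(
            rec, pd.DataFrame({"intercept": np.ones(len(rec))}, index=rec.index),
            corr, profile=smoke_cfg, seed=2,
        )
        total = sum(
            100.0 * model.variance_pooled_[:, j] / model.variance_pooled_.sum(axis=1)
            for j in range(len(model.variance_names_))
        )
        assert np.allclose(total, 100.0)
        frac = model.variance_fraction("phylo")
        assert 0 <= frac.ci_low <= frac.ci_high <= 100

    def test_exchangeable_components_have_matching_fractions(self):
        """Species and phylo terms are exchangeable under an identity
        correlation, so their variance-fraction posteriors must agree."""
        truth = SyntheticTruth(
            n_species=50, n_studies=60, n_effects=200, n_lncvr=0,
            s2_species=0.1, s2_phylo=0.1,
        )
        ident = pd.DataFrame(
            np.eye(50),
            index=[f"sp{i:03d}" for i in range(50)],
            columns=[f"sp{i:03d}" for i in range(50)],
        )
        rec, corr, _ = simulate_effect_table(truth, tree_or_S=ident, seed=8)
        model = PhyloMetaRegression(
            iterations=33_000, burn_in=3_000, thin=30, n_chains=2,
            random_state=6,
        )
        model.fit(
            np.ones((len(rec), 1)), rec["value"], rec["sampling_variance"],
            study=rec["study_id"], species=rec["species_id"], phylo_corr=corr,
        )
        vs = model.variance_pooled_
        names = model.variance_names_
        sp = vs[:, names.index("species")]
        ph = vs[:, names.index("phylo")]
        # the split between the two unidentified components mixes slowly,
        # so subsample to near-independence before the KS comparison
        assert ks_2samp(sp[::20], ph[::20]).pvalue > 0.01

    def test_summary_and_samples_layout(self, small_dataset, smoke_cfg):
        records, corr, _ = small_dataset
        rec = records[records["effect_type"] == "Zr"]
        model = fit_bpmm(
            rec, pd.DataFrame({"intercept": np.ones(len(rec))}, index=rec.index),
            corr, profile=smoke_cfg, seed=1,
        )
        frame = model.samples_frame()
        assert len(frame) == smoke_cfg.n_keep * smoke_cfg.n_chains
        assert set(frame["chain"]) == {0, 1}
        summary = model.summary()
        assert set(summary["kind"]) == {"fixed", "variance"}
        assert (model.variance_pooled_ > 0).all()
        assert set(model.psrf_) == {
            "intercept", "var:study", "var:species", "var:phylo", "var:residual"
        }


class TestValidation:
    def test_rank_deficient_design(self, small_dataset):
        records, corr, _ = small_dataset
        rec = records[records["effect_type"] == "Zr"]
        X = np.ones((len(rec), 2))  # duplicated column
        model = PhyloMetaRegression(iterations=2000, burn_in=500, thin=5,
                                    n_chains=1)
        with pytest.raises(ValueError, match="rank"):
            model.fit(X, rec["value"], rec["sampling_variance"],
                      study=rec["study_id"], species=rec["species_id"],
                      phylo_corr=corr)

    def test_nonpositive_sampling_variance(self):
        model = PhyloMetaRegression(random_terms=(), iterations=2000,
                                    burn_in=500, thin=5, n_chains=1)
        with pytest.raises(ValueError, match="variance"):
            model.fit(np.ones((4, 1)), np.zeros(4), np.array([0.1, 0.2, 0.0, 0.3]))

    def test_non_psd_corr_rejected(self):
        bad = pd.DataFrame(
            [[1.0, 2.0], [2.0, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        model = PhyloMetaRegression(random_terms=("phylo",), iterations=2000,
                                    burn_in=500, thin=5, n_chains=1)
        with pytest.raises(ValueError, match="PSD"):
            model.fit(np.ones((4, 1)), np.zeros(4), np.full(4, 0.1),
                      species=["a", "a", "b", "b"], phylo_corr=bad)

    def test_missing_species_in_corr(self):
        corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        model = PhyloMetaRegression(random_terms=("phylo",), iterations=2000,
                                    burn_in=500, thin=5, n_chains=1)
        with pytest.raises(ValueError, match="missing"):
            model.fit(np.ones((2, 1)), np.zeros(2), np.full(2, 0.1),
                      species=["a", "b"], phylo_corr=corr)

    def test_sklearn_params_round_trip(self):
        model = PhyloMetaRegression(iterations=5000, burn_in=1000, thin=4)
        params = model.get_params()
        clone = PhyloMetaRegression(**params)
        assert clone.get_params() == params
        model.set_params(thin=8)
        assert model.thin == 8
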