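"""Bayesian phylogenetic multilevel meta-regression (BPMM).

The model for an effect size :math:`y_i` (Zr or LnCVR) is

.. math::

    y_i = x_i^T \\beta + u_{study(i)} + u_{species(i)} + u_{phylo(i)}
          + m_i + e_i

with independent study and species effects, phylogenetic species
effects :math:`u_{phylo} \\sim N(0, \\sigma^2_{phylo} A)` for the
species correlation matrix :math:`A`, a residual
:math:`e_i \\sim N(0, \\sigma^2_e)`, and a *known-variance* measurement
term :math:`m_i \\sim N(0, v_i)` whose per-observation variance
:math:`v_i` is the effect size's sampling variance.  The measurement
term is sampled in the Gibbs sweep but its scale is never updated —
this is exactly how inverse-sampling-variance weighting enters a
Bayesian meta-analysis.

Priors: fixed effects N(0, 1e10); every free variance component an
inverse-gamma with V = 1, nu = 0.002, parameterised as shape = nu/2 and
rate = V * nu / 2 (both 0.001).

Sampling is plain conjugate Gibbs: a blocked multivariate-normal draw
for the fixed effects, level-wise normal draws for each random term
(a joint S-dimensional draw for the phylogenetic term), per-observation
normals for the measurement deviates, and inverse-gamma draws for the
variances, in the fixed order beta -> study -> species -> phylo ->
measurement -> variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from sklearn.base import BaseEstimator

from .posterior import PosteriorSummary, gelman_rubin, summarize

__all__ = ["ChainConfig", "PROFILES", "PhyloMetaRegression", "fit_bpmm",
           "variance_fraction"]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule: total iterations, burn-in, thinning, chain count."""

    iterations: int = 110_000
    burn_in: int = 10_000
    thin: int = 100
    n_chains: int = 3

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if (self.iterations - self.burn_in) % self.thin:
            raise ValueError("thin must divide iterations - burn_in")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_keep(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: ``paper`` is the published schedule (1.1M iterations); ``desk`` keeps
#: the same retained-draw count at a tenth of the cost and is the
#: default for interactive work; ``smoke`` is a quick-look schedule for
#: pipeline checks where Monte-Carlo error is not the concern.
PROFILES: dict[str, ChainConfig] = {
    "paper": ChainConfig(1_100_000, 100_000, 1_000, 3),
    "desk": ChainConfig(110_000, 10_000, 100, 3),
    "smoke": ChainConfig(11_000, 1_000, 10, 2),
}


@dataclass
class _Term:
    name: str
    idx: np.ndarray          # (n,) level index per observation
    q: int                   # number of levels
    labels: list
    a_inv: np.ndarray | None = None   # phylo precision-shaping matrix
    fixed_variance: float | None = None
    counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.bincount(self.idx, minlength=self.q).astype(float)


def _encode(labels) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    if (codes < 0).any():
        raise ValueError("grouping labels contain missing values")
    return codes.astype(np.intp), list(uniques)


class PhyloMetaRegression(BaseEstimator):
    """Gibbs-sampled Gaussian multilevel meta-regression.

    Parameters
    ----------
    random_terms : sequence of str
        Which random terms to include.  ``"study"`` and ``"species"``
        are independent intercepts over the corresponding labels,
        ``"phylo"`` is a species-level term with covariance
        ``sigma2_phylo * A`` for the correlation matrix ``A`` passed to
        :meth:`fit`; any other name must appear in ``extra_random``.
    iterations, burn_in, thin, n_chains :
        MCMC schedule (see :data:`PROFILES` for the two stock
        schedules).  Retained draws per chain:
        ``(iterations - burn_in) / thin``.
    fixed_effect_variance : float
        Prior variance of each fixed effect (default 1e10, effectively
        flat).
    prior_v, prior_nu : float
        Inverse-gamma hyperparameters for every free variance
        component: shape ``nu/2``, rate ``V * nu / 2``.
    fix_residual_variance : float, optional
        Hold the residual variance at this value instead of sampling it
        (testing hook; enables closed-form cross-checks).
    fix_variance_components : mapping, optional
        Hold named random-term variances fixed, e.g. ``{"study": 0.05}``.
    random_state : int or numpy SeedSequence, optional
        Seed; chains get independent spawned streams.

    Attributes
    ----------
    coef_names_ : list of str
    beta_samples_ : ndarray, shape (n_chains, n_keep, p)
    variance_names_ : list of str  (random terms then ``"residual"``)
    variance_samples_ : ndarray, shape (n_chains, n_keep, k)
    psrf_ : dict
        Gelman-Rubin potential scale reduction factor per parameter
        (requires >= 2 chains).
    """

    def __init__(
        self,
        *,
        random_terms: Sequence[str] = ("study", "species", "phylo"),
        iterations: int = 110_000,
        burn_in: int = 10_000,
        thin: int = 100,
        n_chains: int = 3,
        fixed_effect_variance: float = 1e10,
        prior_v: float = 1.0,
        prior_nu: float = 0.002,
        fix_residual_variance: float | None = None,
        fix_variance_components: Mapping[str, float] | None = None,
        engine: str = "auto",
        random_state=None,
    ):
        self.random_terms = random_terms
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.fixed_effect_variance = fixed_effect_variance
        self.prior_v = prior_v
        self.prior_nu = prior_nu
        self.fix_residual_variance = fix_residual_variance
        self.fix_variance_components = fix_variance_components
        self.engine = engine
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(
        self,
        X,
        y,
        sampling_variance,
        *,
        study=None,
        species=None,
        phylo_corr: pd.DataFrame | None = None,
        extra_random: Mapping[str, Sequence] | None = None,
    ):
        """Draw from the posterior given a design and known variances.

        ``X`` is the fixed-effect design (DataFrame or array); ``y``
        the effect sizes; ``sampling_variance`` the known per-effect
        variances ``v_i > 0``.  ``study``/``species`` supply grouping
        labels for the corresponding random terms, ``phylo_corr`` the
        species correlation matrix (rows/columns labelled by species
        id), and ``extra_random`` labels for any additional iid term
        named in ``random_terms``.
        """
        cfg = ChainConfig(self.iterations, self.burn_in, self.thin, self.n_chains)
        if isinstance(X, pd.DataFrame):
            coef_names = [str(c) for c in X.columns]
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            coef_names = [f"beta{j}" for j in range(Xa.shape[1])]
        ya = np.asarray(y, dtype=float).ravel()
        va = np.asarray(sampling_variance, dtype=float).ravel()
        n = ya.size
        if Xa.shape[0] != n or va.size != n:
            raise ValueError("X, y and sampling_variance lengths disagree")
        if not np.all(np.isfinite(ya)):
            raise ValueError("non-finite response values")
        if np.any(va <= 0):
            raise ValueError("sampling variances must be strictly positive")
        if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

        fixed_vars = dict(self.fix_variance_components or {})
        terms: list[_Term] = []
        for name in self.random_terms:
            if name == "study":
                labels = study
            elif name in ("species", "phylo"):
                labels = species
            else:
                if not extra_random or name not in extra_random:
                    raise ValueError(f"no labels supplied for random term {name!r}")
                labels = extra_random[name]
            if labels is None:
                raise ValueError(f"no labels supplied for random term {name!r}")
            idx, uniq = _encode(labels)
            a_inv = None
            if name == "phylo":
                if phylo_corr is None:
                    raise ValueError("phylo term requires phylo_corr")
                missing = [s for s in uniq if s not in phylo_corr.index]
                if missing:
                    raise ValueError(f"species missing from phylo_corr: {missing}")
                A = phylo_corr.loc[uniq, uniq].to_numpy(dtype=float)
                A = 0.5 * (A + A.T)
                w = np.linalg.eigvalsh(A)
                if w.min() < -1e-10:
                    raise ValueError("phylo correlation matrix is not PSD")
                jitter = 0.0
                while True:
                    try:
                        cf = cho_factor(A + jitter * np.eye(len(A)), lower=True)
                        break
                    except np.linalg.LinAlgError:
                        jitter = max(jitter * 10, 1e-12)
                ident = np.eye(len(A))
                a_inv = cho_solve(cf, ident)
                a_inv = 0.5 * (a_inv + a_inv.T)
            terms.append(
                _Term(name, idx, len(uniq), uniq, a_inv=a_inv,
                      fixed_variance=fixed_vars.get(name))
            )

        # canonical observation order: results depend only on the data
        # multiset, not the row order the caller happened to use
        keys = [t.idx for t in terms] + [Xa[:, j] for j in range(Xa.shape[1])]
        keys += [va, ya]
        order = np.lexsort(tuple(keys))
        Xs, ys, vs = Xa[order], ya[order], va[order]
        sorted_terms = [
            _Term(t.name, t.idx[order], t.q, t.labels, a_inv=t.a_inv,
                  fixed_variance=t.fixed_variance)
            for t in terms
        ]

        runner = _select_engine(self.engine)
        if isinstance(self.random_state, np.random.SeedSequence):
            seed = self.random_state
        else:
            seed = np.random.SeedSequence(self.random_state)
        streams = seed.spawn(cfg.n_chains)
        p = Xs.shape[1]
        beta_out = np.empty((cfg.n_chains, cfg.n_keep, p))
        var_out = np.empty((cfg.n_chains, cfg.n_keep, len(sorted_terms) + 1))
        for c, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            beta_out[c], var_out[c] = runner(
                rng, Xs, ys, vs, sorted_terms, cfg,
                prior_b=self.fixed_effect_variance,
                prior_shape=self.prior_nu / 2.0,
                prior_rate=self.prior_v * self.prior_nu / 2.0,
                fix_resid=self.fix_residual_variance,
            )

        self.coef_names_ = coef_names
        self.variance_names_ = [t.name for t in sorted_terms] + ["residual"]
        self.beta_samples_ = beta_out
        self.variance_samples_ = var_out
        self.n_obs_ = n
        self.term_labels_ = {t.name: t.labels for t in terms}
        self.psrf_ = self._compute_psrf() if cfg.n_chains >= 2 else {}
        return self

    # ------------------------------------------------------------------
    def _compute_psrf(self) -> dict[str, float]:
        out = {}
        for j, name in enumerate(self.coef_names_):
            out[name] = gelman_rubin(self.beta_samples_[:, :, j])
        for j, name in enumerate(self.variance_names_):
            out[f"var:{name}"] = gelman_rubin(self.variance_samples_[:, :, j])
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "beta_samples_"):
            raise RuntimeError("model is not fitted")

    @property
    def beta_pooled_(self) -> np.ndarray:
        """Fixed-effect draws pooled over chains, shape (chains*keep, p)."""
        self._check_fitted()
        return self.beta_samples_.reshape(-1, self.beta_samples_.shape[-1])

    @property
    def variance_pooled_(self) -> np.ndarray:
        self._check_fitted()
        return self.variance_samples_.reshape(-1, self.variance_samples_.shape[-1])

    def coef_draws(self, name: str) -> np.ndarray:
        self._check_fitted()
        return self.beta_pooled_[:, self.coef_names_.index(name)]

    def predict(self, X) -> np.ndarray:
        """Fixed-effect (marginal) prediction at the posterior mean."""
        self._check_fitted()
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        return Xa @ self.beta_pooled_.mean(axis=0)

    def variance_fraction(self, component: str) -> PosteriorSummary:
        """Posterior of the % of random + residual variance in one term.

        Per draw, ``100 * sigma2_component / sum(all sampled variance
        components including the residual)``; the fixed measurement
        variances ``v_i`` are not part of the denominator.
        """
        self._check_fitted()
        if component not in self.variance_names_:
            raise ValueError(f"component {component!r} not in model")
        vs = self.variance_pooled_
        frac = 100.0 * vs[:, self.variance_names_.index(component)] / vs.sum(axis=1)
        return summarize(frac)

    def samples_frame(self) -> pd.DataFrame:
        """All retained draws as a tidy frame, one row per draw."""
        self._check_fitted()
        chains, keep, p = self.beta_samples_.shape
        recs = {"chain": np.repeat(np.arange(chains), keep)}
        for j, name in enumerate(self.coef_names_):
            recs[name] = self.beta_samples_[:, :, j].ravel()
        for j, name in enumerate(self.variance_names_):
            recs[f"var:{name}"] = self.variance_samples_[:, :, j].ravel()
        return pd.DataFrame(recs)

    def summary(self) -> pd.DataFrame:
        """PM, 95% HPD and pMCMC for each coefficient and variance."""
        self._check_fitted()
        rows = []
        for j, name in enumerate(self.coef_names_):
            s = summarize(self.beta_pooled_[:, j])
            rows.append(("fixed", name, s))
        for j, name in enumerate(self.variance_names_):
            s = summarize(self.variance_pooled_[:, j])
            rows.append(("variance", name, s))
        return pd.DataFrame(
            [
                {
                    "kind": kind,
                    "parameter": name,
                    "pm": s.pm,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "pmcmc": s.pmcmc,
                }
                for kind, name, s in rows
            ]
        )


def _select_engine(engine: str):
    """Pick the chain runner: compiled sweep when available, else numpy.

    Both engines implement identical conditional distributions and
    update order; draws differ only through their RNG call sequences.
    """
    if engine not in {"auto", "numba", "numpy"}:
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "numpy":
        return _run_chain
    try:
        from ._gibbs_fast import run_chain_fast
        return run_chain_fast
    except ImportError:
        if engine == "numba":
            raise
        return _run_chain


def _run_chain(rng, X, y, v, terms, cfg, *, prior_b, prior_shape, prior_rate,
               fix_resid):
    n, p = X.shape
    XtX = X.T @ X
    prior_prec = np.eye(p) / prior_b

    beta = np.zeros(p)
    m = np.zeros(n)
    u = [np.zeros(t.q) for t in terms]
    y_var = max(float(np.var(y)), 1e-6)
    s2 = np.array([t.fixed_variance if t.fixed_variance is not None else y_var
                   for t in terms], dtype=float) if terms else np.empty(0)
    s2e = fix_resid if fix_resid is not None else y_var

    resid = y - m  # running y - X beta - sum_k u_k[idx_k] - m
    keep_beta = np.empty((cfg.n_keep, p))
    keep_var = np.empty((cfg.n_keep, len(terms) + 1))
    kept = 0

    for it in range(cfg.iterations):
        # --- fixed effects (blocked draw)
        resid += X @ beta
        prec = XtX / s2e + prior_prec
        L = np.linalg.cholesky(prec)
        mean = cho_solve((L, True), X.T @ resid / s2e)
        beta = mean + solve_triangular(L.T, rng.standard_normal(p),
                                       lower=False, check_finite=False)
        resid -= X @ beta

        # --- random terms, fixed update order
        for k, t in enumerate(terms):
            resid += u[k][t.idx]
            b = np.bincount(t.idx, weights=resid, minlength=t.q) / s2e
            if t.a_inv is None:
                prec_k = t.counts / s2e + 1.0 / s2[k]
                uk = b / prec_k + rng.standard_normal(t.q) / np.sqrt(prec_k)
            else:
                P = t.a_inv / s2[k]
                P[np.diag_indices_from(P)] += t.counts / s2e
                Lk = np.linalg.cholesky(P)
                mean_k = cho_solve((Lk, True), b)
                uk = mean_k + solve_triangular(
                    Lk.T, rng.standard_normal(t.q), lower=False,
                    check_finite=False)
            u[k] = uk
            resid -= uk[t.idx]

        # --- measurement deviates with fixed variances v_i
        resid += m
        prec_m = 1.0 / v + 1.0 / s2e
        m = resid / (s2e * prec_m) + rng.standard_normal(n) / np.sqrt(prec_m)
        resid -= m

        # --- variance components
        for k, t in enumerate(terms):
            if t.fixed_variance is not None:
                continue
            if t.a_inv is None:
                quad = u[k] @ u[k]
            else:
                quad = u[k] @ (t.a_inv @ u[k])
            s2[k] = (prior_rate + 0.5 * quad) / rng.standard_gamma(
                prior_shape + 0.5 * t.q)
        if fix_resid is None:
            s2e = (prior_rate + 0.5 * (resid @ resid)) / rng.standard_gamma(
                prior_shape + 0.5 * n)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == cfg.thin - 1:
            keep_beta[kept] = beta
            keep_var[kept, : len(terms)] = s2
            keep_var[kept, -1] = s2e
            kept += 1

    return keep_beta, keep_var


def fit_bpmm(
    records: pd.DataFrame,
    design: pd.DataFrame,
    phylo_corr: pd.DataFrame | None = None,
    *,
    random_terms: Sequence[str] = ("study", "species", "phylo"),
    profile: str | ChainConfig = "desk",
    seed=None,
    extra_random: Mapping[str, Sequence] | None = None,
    **kwargs,
) -> PhyloMetaRegression:
    """Convenience wrapper: fit a BPMM from an effect-size table.

    ``records`` must carry ``value``, ``sampling_variance``,
    ``study_id`` and ``species_id`` columns; ``design`` is the
    fixed-effect design aligned to it row-for-row.
    """
    cfg = PROFILES[profile] if isinstance(profile, str) else profile
    model = PhyloMetaRegression(
        random_terms=random_terms,
        iterations=cfg.iterations,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
        n_chains=cfg.n_chains,
        random_state=seed,
        **kwargs,
    )
    return model.fit(
        design,
        records["value"],
        records["sampling_variance"],
        study=records["study_id"],
        species=records["species_id"],
        phylo_corr=phylo_corr,
        extra_random=extra_random,
    )


def variance_fraction(model: PhyloMetaRegression, component: str) -> PosteriorSummary:
    """Module-level alias for :meth:`PhyloMetaRegression.variance_fraction`."""
    return model.variance_fraction(component)
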