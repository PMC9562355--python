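"""Hierarchical multi-species site-occupancy model with imperfect detection.

The model separates true presence from observation.  For fish species k at
site i the latent occupancy state is

    z_ik ~ Bernoulli(psi_ik),
    logit(psi_ik) = alpha_k + beta1_k * coral_i + beta2_k * turf_i,

with coral and turf cover standardized to mean 0, SD 1 across sites, so the
slopes are standardized effect sizes (units of covariate SD).  Conditional
on presence, each 10-minute video plot j is an independent sampling
occasion ("time-for-space substitution"):

    y_ijk ~ Bernoulli(z_ik * p_ijk),
    logit(p_ijk) = a_k + delta_depth * [site i is deep] + u_ij,

where u_ij is a per-plot random effect.  Species coefficients are partially
pooled through community hyperdistributions, e.g.
alpha_k ~ N(mu_alpha, sd_alpha^2); species with many detections thereby
stabilize the estimates for rarely detected species.

The latent z is marginalized out of the likelihood (see
:func:`site_marginal_likelihood`), which makes the posterior a smooth
function of continuous parameters only; z is recoverable post hoc from its
conditional distribution.  Sampling uses an adaptive Metropolis-within-Gibbs
scheme: component-wise random-walk updates vectorized across species,
conjugate Gibbs draws for hyper-means, log-scale random-walk updates for
hyper-SDs, and per-site block updates for the plot effects.  Proposal
scales adapt during warmup only, so the post-warmup chains are valid MCMC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_expit

from .data_io import DetectionHistory, SiteCovariates

__all__ = [
    "ModelConfig",
    "PriorConfig",
    "PosteriorSamples",
    "FitDiagnostics",
    "standardize",
    "site_marginal_likelihood",
    "fit",
    "rhat",
    "assemblage_mean",
]

SPECIES_PARAMS = ("alpha", "beta1", "beta2", "p_intercept")


# ---------------------------------------------------------------------------
# small operations
# ---------------------------------------------------------------------------


def standardize(x, name: str = "covariate") -> tuple[np.ndarray, tuple[float, float]]:
    """Center and scale to sample SD 1 (n-1 denominator).

    Returns the standardized vector and the (mean, sd) pair needed to map
    effect sizes back to the covariate's native units.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"{name}: need at least 2 values to standardize")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError(f"{name}: zero variance, cannot standardize")
    return (x - mean) / sd, (mean, sd)


def site_marginal_likelihood(psi: float, p, y) -> float:
    """Marginal likelihood of one species' detection history at one site.

    With at least one detection the site is surely occupied:
    psi * prod_j p_j^y_j (1-p_j)^(1-y_j).  An all-zero history mixes
    occupied-but-missed with truly absent:
    psi * prod_j (1-p_j) + (1 - psi).
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("p and y must be 1-D of equal length >= 1")
    if not (0 <= psi <= 1) or (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary")
    obs = np.prod(np.where(y == 1, p, 1 - p))
    if y.any():
        return float(psi * obs)
    return float(psi * obs + (1 - psi))


def rhat(chains) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half, and
    R-hat = sqrt(((n-1)/n * W + B/n) / W) over the resulting 2*n_chains
    sequences.  A single chain is accepted (its two halves are compared)
    with a warning.  Zero-variance draws give exactly 1.0.
    """
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    if x.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    if x.shape[0] == 1:
        warnings.warn("single chain: R-hat computed on its two halves")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    chain_vars = splits.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def assemblage_mean(ps: "PosteriorSamples", which: str = "beta1") -> np.ndarray:
    """Posterior draws of the across-species average coefficient.

    The per-draw arithmetic mean over the K species summarizes the
    assemblage-wide response to the covariate; with the default settings it
    returns 3000 values (3 chains x 1000 saved draws).
    """
    if which not in ("beta1", "beta2"):
        raise ValueError("which must be 'beta1' or 'beta2'")
    draws = ps.stacked(which)  # (n_total, K)
    return draws.mean(axis=1)


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Weakly informative priors on the logit scale.

    Hyper-means ~ N(0, mu_sd^2); hyper-SDs ~ half-Normal(hyper_sd_scale);
    depth effect ~ N(0, delta_sd^2); with ``pooling='fixed'`` every species
    coefficient instead gets an independent N(0, fixed_sd^2) prior.
    """

    mu_sd: float = 1.5
    hyper_sd_scale: float = 1.0
    delta_sd: float = 1.5
    fixed_sd: float = 1.5


@dataclass
class ModelConfig:
    """Sampler and model settings for one (coral taxon, life stage) run."""

    coral_taxon: str | None = None  # default: first non-turf taxon
    life_stage: str = "adult"
    n_chains: int = 3
    n_saved_per_chain: int = 1000
    warmup: int = 2000
    thin: int = 1
    ci_levels: tuple[float, ...] = (0.90, 0.50)
    seed: int = 0
    pooling: str = "hierarchical"  # or "fixed"
    plot_effect: bool = True
    shared_detection: bool = False
    compute_bpv: bool = True
    bpv_draws: int = 500
    plot_update_repeats: int = 3
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least 1 chain")
        if self.pooling not in ("hierarchical", "fixed"):
            raise ValueError("pooling must be 'hierarchical' or 'fixed'")

    @property
    def n_total_draws(self) -> int:
        return self.n_chains * self.n_saved_per_chain


HYPER_KEYS = (
    "mu_alpha", "sd_alpha", "mu_beta1", "sd_beta1",
    "mu_beta2", "sd_beta2", "mu_p", "sd_p",
)


@dataclass
class PosteriorSamples:
    """MCMC draws, indexable by parameter name and species.

    ``params[name]`` has shape (n_chains, n_draws, K) for species-level
    parameters (alpha, beta1, beta2, p_intercept), (n_chains, n_draws) for
    scalars (hypers, delta_depth, sd_plot) and (n_chains, n_draws, n_occ)
    for the plot effects.
    """

    species: list[tuple[str, str]]
    params: dict[str, np.ndarray]
    config: ModelConfig
    coral_taxon: str
    covariate_scales: dict[str, tuple[float, float]]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains concatenated: (n_chains*n_draws, ...)."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def species_draws(self, name: str, species_ix: int) -> np.ndarray:
        return self.stacked(name)[:, species_ix]

    def summary(self, ci_level: float | None = None) -> pd.DataFrame:
        """Per-species posterior mean, median and equal-tailed CI bounds for
        the occupancy coefficients."""
        lev = ci_level or self.config.ci_levels[0]
        lo, hi = (1 - lev) / 2, 1 - (1 - lev) / 2
        rows = []
        for k, (sp, stage) in enumerate(self.species):
            row = {"species_id": sp, "stage": stage}
            for name in ("alpha", "beta1", "beta2"):
                d = self.species_draws(name, k)
                row[f"{name}_mean"] = d.mean()
                row[f"{name}_median"] = np.median(d)
                row[f"{name}_lo"] = np.quantile(d, lo)
                row[f"{name}_hi"] = np.quantile(d, hi)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format draws (chain, iter, parameter, value) for archiving."""
        frames = []
        for name, a in self.params.items():
            if a.ndim == 2:
                c, d = a.shape
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": np.repeat(np.arange(c), d),
                            "iter": np.tile(np.arange(d), c),
                            "parameter": name,
                            "value": a.reshape(-1),
                        }
                    )
                )
            elif name in SPECIES_PARAMS:
                for k, (sp, stage) in enumerate(self.species):
                    c, d = a.shape[:2]
                    frames.append(
                        pd.DataFrame(
                            {
                                "chain": np.repeat(np.arange(c), d),
                                "iter": np.tile(np.arange(d), c),
                                "parameter": f"{name}[{sp}|{stage}]",
                                "value": a[:, :, k].reshape(-1),
                            }
                        )
                    )
        return pd.concat(frames, ignore_index=True)


@dataclass
class FitDiagnostics:
    """Convergence and goodness-of-fit summaries for one fitted model."""

    rhat: dict[str, np.ndarray | float]
    max_rhat: float
    bpv: float | None
    acceptance: dict[str, float]
    converged: bool

    def to_dict(self) -> dict:
        return {
            "max_rhat": self.max_rhat,
            "bpv": self.bpv,
            "converged": self.converged,
            "acceptance": self.acceptance,
        }


# ---------------------------------------------------------------------------
# internal sampler machinery
# ---------------------------------------------------------------------------


class _Data:
    """Flattened, occasion-major view of a detection history."""

    def __init__(self, dh: DetectionHistory, cov: SiteCovariates, coral_taxon: str):
        order = [cov.sites.index(s) for s in dh.sites]  # align covariates
        x1_raw = cov.coral_cover(coral_taxon).values[order]
        x2_raw = cov.turf_cover.values[order]
        self.x1, self.x1_scale = standardize(x1_raw, f"coral cover ({coral_taxon})")
        self.x2, self.x2_scale = standardize(x2_raw, "turf cover")
        self.deep = cov.is_deep()[order]

        J = dh.n_occasions
        self.n_sites = dh.n_sites
        self.n_species = dh.n_species
        self.occ_site = np.repeat(np.arange(self.n_sites), J)
        self.n_occ = int(J.sum())
        self.site_starts = np.concatenate([[0], np.cumsum(J)[:-1]])
        y = []
        for i in range(self.n_sites):
            y.append(dh.y[i, : J[i], :])
        self.y_occ = np.concatenate(y, axis=0)  # (n_occ, K)
        self.det = (
            np.add.reduceat(self.y_occ, self.site_starts, axis=0) > 0
        )  # (n_sites, K)
        self.ndet = np.add.reduceat(self.y_occ, self.site_starts, axis=0)
        self.deep_occ = self.deep[self.occ_site]


def _psi_caches(data: _Data, alpha, beta1, beta2):
    logit = (
        alpha[None, :]
        + beta1[None, :] * data.x1[:, None]
        + beta2[None, :] * data.x2[:, None]
    )
    return log_expit(logit), log_expit(-logit)


def _p_caches(data: _Data, a, delta, u):
    logit = a[None, :] + delta * data.deep_occ[:, None] + u[:, None]
    logp = log_expit(logit)
    log1mp = log_expit(-logit)
    term = data.y_occ * logp + (1.0 - data.y_occ) * log1mp
    s1 = np.add.reduceat(term, data.site_starts, axis=0)
    logq0 = np.add.reduceat(log1mp, data.site_starts, axis=0)
    return s1, logq0


def _ll_matrix(data: _Data, logpsi, log1mpsi, s1, logq0):
    return np.where(
        data.det,
        logpsi + s1,
        np.logaddexp(logpsi + logq0, log1mpsi),
    )


def _norm_logpdf(x, mu, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _halfnorm_logpdf(x, scale):
    if x <= 0:
        return -np.inf
    return (
        0.5 * np.log(2 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2
    )


class _AdaptiveScale:
    """Robbins-Monro adaptation of log proposal scales toward a target
    acceptance rate; frozen once warmup ends."""

    def __init__(self, shape, init=0.3, target=0.44):
        self.log_scale = np.full(shape, np.log(init))
        self.target = target
        self.accepted = np.zeros(shape)
        self.count = 0
        self.batch = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self, accepted, adapting: bool):
        self.accepted += accepted
        self.count += 1
        if adapting and self.count >= 25:
            self.batch += 1
            rate = self.accepted / self.count
            self.log_scale += (rate - self.target) / np.sqrt(self.batch)
            np.clip(self.log_scale, np.log(1e-3), np.log(10.0), out=self.log_scale)
            self.accepted = np.zeros_like(self.accepted)
            self.count = 0


class _ChainState:
    def __init__(self, data: _Data, mc: ModelConfig, rng: np.random.Generator):
        K = data.n_species
        naive = data.det.mean(axis=0)
        p_naive = data.ndet.sum(axis=0) / np.maximum(
            (data.det * np.diff(np.append(data.site_starts, data.n_occ))[:, None]).sum(axis=0),
            1,
        )
        self.alpha = _logit(np.clip(naive, 0.05, 0.95)) + 0.3 * rng.standard_normal(K)
        self.beta1 = 0.1 * rng.standard_normal(K)
        self.beta2 = 0.1 * rng.standard_normal(K)
        self.p_intercept = _logit(np.clip(p_naive, 0.05, 0.95)) + 0.3 * rng.standard_normal(K)
        if mc.shared_detection:
            self.p_intercept[:] = self.p_intercept.mean()
        self.delta = 0.1 * rng.standard_normal()
        self.u = np.zeros(data.n_occ)
        self.sd_plot = 0.3
        self.hyper = {}
        for name, vec in (
            ("alpha", self.alpha),
            ("beta1", self.beta1),
            ("beta2", self.beta2),
            ("p", self.p_intercept),
        ):
            self.hyper[f"mu_{name}"] = float(vec.mean())
            self.hyper[f"sd_{name}"] = float(max(vec.std(), 0.3))
        self.logpsi, self.log1mpsi = _psi_caches(data, self.alpha, self.beta1, self.beta2)
        self.s1, self.logq0 = _p_caches(data, self.p_intercept, self.delta, self.u)

    def ll(self, data):
        return _ll_matrix(data, self.logpsi, self.log1mpsi, self.s1, self.logq0)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _species_prior(mc: ModelConfig, st: _ChainState, name: str):
    if mc.pooling == "fixed":
        return 0.0, mc.priors.fixed_sd
    key = "p" if name == "p_intercept" else name
    return st.hyper[f"mu_{key}"], st.hyper[f"sd_{key}"]


def _run_chain(data: _Data, mc: ModelConfig, rng: np.random.Generator,
               store_every: int, n_store: int):
    K = data.n_species
    st = _ChainState(data, mc, rng)
    scales = {
        name: _AdaptiveScale(K, init=0.2)
        for name in ("alpha", "beta1", "beta2", "p_intercept")
    }
    scales["delta"] = _AdaptiveScale((), init=0.2)
    scales["u"] = _AdaptiveScale(data.n_sites, init=0.3, target=0.30)
    scales["hyper_sd"] = {
        k: _AdaptiveScale((), init=0.3) for k in ("alpha", "beta1", "beta2", "p")
    }
    scales["rescale"] = {
        k: _AdaptiveScale((), init=0.2) for k in ("alpha", "beta1", "beta2", "p")
    }
    scales["sd_plot"] = _AdaptiveScale((), init=0.3)
    scales["u_rescale"] = _AdaptiveScale((), init=0.3)

    out = {
        name: np.empty((n_store, K)) for name in SPECIES_PARAMS
    }
    out["delta_depth"] = np.empty(n_store)
    if mc.plot_effect:
        out["plot_effect"] = np.empty((n_store, data.n_occ))
        out["sd_plot"] = np.empty(n_store)
    if mc.pooling == "hierarchical":
        for k in HYPER_KEYS:
            out[k] = np.empty(n_store)

    ll_cur = st.ll(data)
    ll_species = ll_cur.sum(axis=0)
    n_iter = mc.warmup + n_store * store_every
    stored = 0
    acc_totals = {k: [0.0, 0] for k in ("species", "delta", "u")}

    for it in range(n_iter):
        adapting = it < mc.warmup

        # --- occupancy-side species parameters (vectorized across species)
        for name in ("alpha", "beta1", "beta2"):
            cur = getattr(st, name)
            sc = scales[name]
            prop = cur + sc.scale * rng.standard_normal(K)
            trial = {n: getattr(st, n) for n in ("alpha", "beta1", "beta2")}
            trial[name] = prop
            logpsi_p, log1mpsi_p = _psi_caches(
                data, trial["alpha"], trial["beta1"], trial["beta2"]
            )
            ll_prop = _ll_matrix(data, logpsi_p, log1mpsi_p, st.s1, st.logq0)
            ll_prop_sp = ll_prop.sum(axis=0)
            m, s = _species_prior(mc, st, name)
            logr = (
                ll_prop_sp - ll_species
                + _norm_logpdf(prop, m, s) - _norm_logpdf(cur, m, s)
            )
            accept = np.log(rng.random(K)) < logr
            if accept.any():
                cur[accept] = prop[accept]
                st.logpsi[:, accept] = logpsi_p[:, accept]
                st.log1mpsi[:, accept] = log1mpsi_p[:, accept]
                ll_species[accept] = ll_prop_sp[accept]
            sc.update(accept.astype(float), adapting)
            acc_totals["species"][0] += accept.mean()
            acc_totals["species"][1] += 1

        # --- detection intercepts
        sc = scales["p_intercept"]
        if mc.shared_detection:
            prop_val = st.p_intercept[0] + float(sc.scale.mean()) * rng.standard_normal()
            prop = np.full(K, prop_val)
        else:
            prop = st.p_intercept + sc.scale * rng.standard_normal(K)
        s1_p, logq0_p = _p_caches(data, prop, st.delta, st.u)
        ll_prop = _ll_matrix(data, st.logpsi, st.log1mpsi, s1_p, logq0_p)
        ll_prop_sp = ll_prop.sum(axis=0)
        m, s = _species_prior(mc, st, "p_intercept")
        logr = (
            ll_prop_sp - ll_species
            + _norm_logpdf(prop, m, s) - _norm_logpdf(st.p_intercept, m, s)
        )
        if mc.shared_detection:
            take = np.log(rng.random()) < logr.sum()
            accept = np.full(K, take)
        else:
            accept = np.log(rng.random(K)) < logr
        if accept.any():
            st.p_intercept[accept] = prop[accept]
            st.s1[:, accept] = s1_p[:, accept]
            st.logq0[:, accept] = logq0_p[:, accept]
            ll_species[accept] = ll_prop_sp[accept]
        sc.update(accept.astype(float), adapting)

        # --- depth effect on detection
        sc = scales["delta"]
        prop_d = st.delta + float(sc.scale) * rng.standard_normal()
        s1_p, logq0_p = _p_caches(data, st.p_intercept, prop_d, st.u)
        ll_prop = _ll_matrix(data, st.logpsi, st.log1mpsi, s1_p, logq0_p)
        logr = (
            ll_prop.sum() - ll_species.sum()
            + _norm_logpdf(prop_d, 0.0, mc.priors.delta_sd)
            - _norm_logpdf(st.delta, 0.0, mc.priors.delta_sd)
        )
        acc = np.log(rng.random()) < logr
        if acc:
            st.delta = prop_d
            st.s1, st.logq0 = s1_p, logq0_p
            ll_species = ll_prop.sum(axis=0)
        sc.update(float(acc), adapting)
        acc_totals["delta"][0] += float(acc)
        acc_totals["delta"][1] += 1

        # --- plot random effects, block-updated per site
        if mc.plot_effect:
            # the plot-effect scale is the slowest-mixing parameter; its
            # update block is repeated within each sweep
            for _ in range(mc.plot_update_repeats):
                step = scales["u"].scale[data.occ_site]
                prop_u = st.u + step * rng.standard_normal(data.n_occ)
                s1_p, logq0_p = _p_caches(data, st.p_intercept, st.delta, prop_u)
                ll_prop = _ll_matrix(data, st.logpsi, st.log1mpsi, s1_p, logq0_p)
                d_ll = (ll_prop - _ll_matrix(data, st.logpsi, st.log1mpsi, st.s1, st.logq0)).sum(axis=1)
                prior_term = _norm_logpdf(prop_u, 0.0, st.sd_plot) - _norm_logpdf(
                    st.u, 0.0, st.sd_plot
                )
                d_prior = np.add.reduceat(prior_term, data.site_starts)
                logr_site = d_ll + d_prior
                accept_site = np.log(rng.random(data.n_sites)) < logr_site
                if accept_site.any():
                    occ_acc = accept_site[data.occ_site]
                    st.u[occ_acc] = prop_u[occ_acc]
                    st.s1[accept_site] = s1_p[accept_site]
                    st.logq0[accept_site] = logq0_p[accept_site]
                    ll_species = _ll_matrix(
                        data, st.logpsi, st.log1mpsi, st.s1, st.logq0
                    ).sum(axis=0)
                scales["u"].update(accept_site.astype(float), adapting)
                acc_totals["u"][0] += accept_site.mean()
                acc_totals["u"][1] += 1

                # sd of the plot effect (half-normal prior, log-scale walk)
                sc = scales["sd_plot"]
                prop_sd = st.sd_plot * np.exp(float(sc.scale) * rng.standard_normal())
                logr = (
                    _norm_logpdf(st.u, 0.0, prop_sd).sum()
                    - _norm_logpdf(st.u, 0.0, st.sd_plot).sum()
                    + _halfnorm_logpdf(prop_sd, mc.priors.hyper_sd_scale)
                    - _halfnorm_logpdf(st.sd_plot, mc.priors.hyper_sd_scale)
                    + np.log(prop_sd) - np.log(st.sd_plot)
                )
                acc = np.log(rng.random()) < logr
                if acc:
                    st.sd_plot = prop_sd
                sc.update(float(acc), adapting)

                # joint rescale of (u, sd_plot): breaks the funnel coupling
                # between the effects and their SD (interweaving move); the
                # u-prior term cancels against the Jacobian up to one log c.
                sc = scales["u_rescale"]
                c = np.exp(float(sc.scale) * rng.standard_normal())
                prop_u = c * st.u
                prop_sd = c * st.sd_plot
                s1_p, logq0_p = _p_caches(data, st.p_intercept, st.delta, prop_u)
                ll_prop = _ll_matrix(data, st.logpsi, st.log1mpsi, s1_p, logq0_p)
                logr = (
                    ll_prop.sum() - ll_species.sum()
                    + _halfnorm_logpdf(prop_sd, mc.priors.hyper_sd_scale)
                    - _halfnorm_logpdf(st.sd_plot, mc.priors.hyper_sd_scale)
                    + np.log(c)
                )
                acc = np.log(rng.random()) < logr
                if acc:
                    st.u = prop_u
                    st.sd_plot = prop_sd
                    st.s1, st.logq0 = s1_p, logq0_p
                    ll_species = ll_prop.sum(axis=0)
                sc.update(float(acc), adapting)

        # --- community hyperparameters
        if mc.pooling == "hierarchical":
            for key, vec in (
                ("alpha", st.alpha),
                ("beta1", st.beta1),
                ("beta2", st.beta2),
                ("p", st.p_intercept),
            ):
                sd_h = st.hyper[f"sd_{key}"]
                # conjugate normal draw for the hyper-mean
                prec = len(vec) / sd_h**2 + 1.0 / mc.priors.mu_sd**2
                mean_post = (vec.sum() / sd_h**2) / prec
                st.hyper[f"mu_{key}"] = mean_post + rng.standard_normal() / np.sqrt(prec)
                # log-scale random walk for the hyper-SD
                sc = scales["hyper_sd"][key]
                prop_sd = sd_h * np.exp(float(sc.scale) * rng.standard_normal())
                mu_h = st.hyper[f"mu_{key}"]
                logr = (
                    _norm_logpdf(vec, mu_h, prop_sd).sum()
                    - _norm_logpdf(vec, mu_h, sd_h).sum()
                    + _halfnorm_logpdf(prop_sd, mc.priors.hyper_sd_scale)
                    - _halfnorm_logpdf(sd_h, mc.priors.hyper_sd_scale)
                    + np.log(prop_sd) - np.log(sd_h)
                )
                acc = np.log(rng.random()) < logr
                if acc:
                    st.hyper[f"sd_{key}"] = prop_sd
                sc.update(float(acc), adapting)

                # joint rescale of (theta_k - mu, sd): the interweaving move
                # that keeps mixing healthy when the hyper-SD approaches 0
                name = "p_intercept" if key == "p" else key
                sc = scales["rescale"][key]
                c = np.exp(float(sc.scale) * rng.standard_normal())
                vec = getattr(st, name)
                mu_h = st.hyper[f"mu_{key}"]
                sd_h = st.hyper[f"sd_{key}"]
                prop_vec = mu_h + c * (vec - mu_h)
                prop_sd = c * sd_h
                if name == "p_intercept":
                    s1_p, logq0_p = _p_caches(data, prop_vec, st.delta, st.u)
                    ll_prop = _ll_matrix(data, st.logpsi, st.log1mpsi, s1_p, logq0_p)
                else:
                    trial = {n: getattr(st, n) for n in ("alpha", "beta1", "beta2")}
                    trial[name] = prop_vec
                    logpsi_p, log1mpsi_p = _psi_caches(
                        data, trial["alpha"], trial["beta1"], trial["beta2"]
                    )
                    ll_prop = _ll_matrix(data, logpsi_p, log1mpsi_p, st.s1, st.logq0)
                logr = (
                    ll_prop.sum() - ll_species.sum()
                    + _halfnorm_logpdf(prop_sd, mc.priors.hyper_sd_scale)
                    - _halfnorm_logpdf(sd_h, mc.priors.hyper_sd_scale)
                    + np.log(c)
                )
                acc = np.log(rng.random()) < logr
                if acc:
                    vec[:] = prop_vec
                    st.hyper[f"sd_{key}"] = prop_sd
                    if name == "p_intercept":
                        st.s1, st.logq0 = s1_p, logq0_p
                    else:
                        st.logpsi, st.log1mpsi = logpsi_p, log1mpsi_p
                    ll_species = ll_prop.sum(axis=0)
                sc.update(float(acc), adapting)

        # --- store
        if it >= mc.warmup and (it - mc.warmup) % store_every == 0 and stored < n_store:
            for name in SPECIES_PARAMS:
                out[name][stored] = getattr(st, name)
            out["delta_depth"][stored] = st.delta
            if mc.plot_effect:
                out["plot_effect"][stored] = st.u
                out["sd_plot"][stored] = st.sd_plot
            if mc.pooling == "hierarchical":
                out["mu_alpha"][stored] = st.hyper["mu_alpha"]
                out["sd_alpha"][stored] = st.hyper["sd_alpha"]
                out["mu_beta1"][stored] = st.hyper["mu_beta1"]
                out["sd_beta1"][stored] = st.hyper["sd_beta1"]
                out["mu_beta2"][stored] = st.hyper["mu_beta2"]
                out["sd_beta2"][stored] = st.hyper["sd_beta2"]
                out["mu_p"][stored] = st.hyper["mu_p"]
                out["sd_p"][stored] = st.hyper["sd_p"]
            stored += 1

    acc_rates = {k: v[0] / max(v[1], 1) for k, v in acc_totals.items()}
    return out, acc_rates


# ---------------------------------------------------------------------------
# public fit
# ---------------------------------------------------------------------------


def fit(
    dh: DetectionHistory,
    cov: SiteCovariates,
    mc: ModelConfig | None = None,
) -> tuple[PosteriorSamples, FitDiagnostics]:
    """Fit the multi-species occupancy model by MCMC.

    Runs ``mc.n_chains`` independent chains (default 3 x 1000 saved draws =
    3000 total, mirroring the sampling design of the original analysis),
    then computes split-R-hat for every stored parameter and, if requested,
    the posterior-predictive Bayesian p-value.  Non-convergence (any
    R-hat >= 1.1) triggers a warning but results are still returned.
    """
    mc = mc or ModelConfig()
    if dh.n_species == 0:
        raise ValueError("empty detection history")
    if (dh.detections_per_species() < 1).any():
        raise ValueError("every species must have at least one detection; "
                         "run filter_species first")
    taxa = [c for c in cov.covers.columns if c != cov.turf_taxon]
    coral = mc.coral_taxon or taxa[0]

    data = _Data(dh, cov, coral)
    ss = np.random.SeedSequence(mc.seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(mc.n_chains)]

    chains_out = []
    acc = None
    for rng in chain_rngs:
        out, acc = _run_chain(data, mc, rng, mc.thin, mc.n_saved_per_chain)
        chains_out.append(out)

    params = {
        name: np.stack([c[name] for c in chains_out], axis=0)
        for name in chains_out[0]
    }
    ps = PosteriorSamples(
        species=list(dh.species),
        params=params,
        config=mc,
        coral_taxon=coral,
        covariate_scales={"coral": data.x1_scale, "turf": data.x2_scale},
    )

    rhats: dict[str, np.ndarray | float] = {}
    for name, a in params.items():
        if name == "plot_effect":
            continue
        if a.ndim == 3:
            rhats[name] = np.array([rhat(a[:, :, k]) for k in range(a.shape[2])])
        else:
            rhats[name] = rhat(a)
    max_rhat = float(
        max(np.max(np.atleast_1d(v)) for v in rhats.values())
    )
    converged = max_rhat < 1.1
    if not converged:
        warnings.warn(
            f"possible non-convergence: max split-R-hat = {max_rhat:.3f} >= 1.1"
        )

    bpv = None
    if mc.compute_bpv:
        from .diagnostics import bayesian_p_value

        bpv = bayesian_p_value(ps, dh, cov, n_draws=mc.bpv_draws, seed=mc.seed + 1)

    diag = FitDiagnostics(
        rhat=rhats,
        max_rhat=max_rhat,
        bpv=bpv,
        acceptance=acc or {},
        converged=converged,
    )
    return ps, diag
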