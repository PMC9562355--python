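"""Synthetic communities with the statistical structure the occupancy model
assumes, plus known ground truth for recovery tests.

The default configuration emulates the Southwestern Atlantic field design:
~36 sites spanning shallow (1-7 m) and deep (8-15 m) reefs, 1-12 ten-minute
video plots per site, site-level coral cover that is strongly right-skewed
with many zeros (mean ~4%, maxima near 19%), turf-algae cover between 15 and
81% (mean ~57%), and a community of ~113 species whose occupancy intercepts
and cover slopes are draws from community-level hyperdistributions.
Detection probability declines with body size and differs between depth
categories.

All generators are pure functions of (config, seed): identical inputs give
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import DetectionHistory, SiteCovariates

__all__ = [
    "CommunityHyperparams",
    "SpeciesParams",
    "CoverConfig",
    "SyntheticTruth",
    "simulate_covariates",
    "default_occasions",
    "simulate_species_params",
    "simulate_detection_history",
    "simulate_traits",
]


@dataclass
class CommunityHyperparams:
    """Hyperparameters of the community (logit scale).

    Species-level occupancy intercepts alpha_k ~ N(mu_alpha, sd_alpha^2),
    coral slopes beta1_k ~ N(mu_beta1, sd_beta1^2), turf slopes
    beta2_k ~ N(mu_beta2, sd_beta2^2), and detection intercepts around mu_p
    with between-species spread sd_p plus a body-length trend
    (length_effect per SD of log body length; negative: larger fish are
    detected less often).  delta_depth shifts detection on deep reefs and
    sd_plot is the SD of the per-video-plot random effect.
    """

    mu_alpha: float = 0.0
    sd_alpha: float = 1.0
    mu_beta1: float = 0.3
    sd_beta1: float = 0.7
    mu_beta2: float = 0.0
    sd_beta2: float = 0.5
    mu_p: float = -0.5
    sd_p: float = 0.6
    length_effect: float = -0.4
    delta_depth: float = 0.4
    sd_plot: float = 0.3

    def __post_init__(self) -> None:
        for name in ("sd_alpha", "sd_beta1", "sd_beta2", "sd_p", "sd_plot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SpeciesParams:
    """Per-species ground truth drawn from :class:`CommunityHyperparams`."""

    species_id: list[str]
    alpha: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    p_intercept: np.ndarray
    body_length: np.ndarray  # cm

    @property
    def n_species(self) -> int:
        return len(self.species_id)


@dataclass
class CoverConfig:
    """Zero-inflated Beta family for coral cover and a shifted Beta for turf.

    Coral cover (%) is 0 with probability ``coral_zero_prob`` and otherwise
    ``coral_scale`` * Beta(a, b).  The defaults give an expected cover of
    (1 - 0.25) * 22 * 1.3 / (1.3 + 4.0625) = 4.0% with maxima near 20%,
    matching low-coral marginal reefs.  Turf (%) is
    ``turf_min + Beta(a, b) * (turf_max - turf_min)`` with expectation 57%.
    """

    coral_zero_prob: float = 0.25
    coral_scale: float = 22.0
    coral_a: float = 1.3
    coral_b: float = 4.0625
    turf_min: float = 15.0
    turf_max: float = 81.0
    turf_a: float = 3.5
    turf_b: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.coral_zero_prob <= 1:
            raise ValueError("coral_zero_prob must be in [0,1]")
        if min(self.coral_scale, self.coral_a, self.coral_b) <= 0:
            raise ValueError("coral cover parameters must be positive")
        if self.turf_max <= self.turf_min:
            raise ValueError("turf_max must exceed turf_min")

    @classmethod
    def from_targets(
        cls,
        mean: float = 4.0,
        max_cover: float = 22.0,
        zero_prob: float = 0.25,
        coral_b: float = 4.0625,
        **kwargs,
    ) -> "CoverConfig":
        """Solve the Beta shape for a requested overall mean and maximum.

        Rejects configurations whose maximum cannot support the mean
        (``max_cover * (1 - zero_prob) <= mean``)."""
        m = mean / ((1 - zero_prob) * max_cover) if zero_prob < 1 else np.inf
        if not 0 < m < 1:
            raise ValueError(
                "degenerate config: requested max cover below the requested mean"
            )
        a = coral_b * m / (1 - m)
        return cls(
            coral_zero_prob=zero_prob,
            coral_scale=max_cover,
            coral_a=a,
            coral_b=coral_b,
            **kwargs,
        )

    @property
    def coral_mean(self) -> float:
        """Exact expectation of the zero-inflated coral cover (%)"""
        return (
            (1 - self.coral_zero_prob)
            * self.coral_scale
            * self.coral_a
            / (self.coral_a + self.coral_b)
        )


@dataclass
class SyntheticTruth:
    """Latent state returned alongside a simulated detection history."""

    psi: np.ndarray  # (n_sites, K) occupancy probabilities
    z: np.ndarray  # (n_sites, K) true presence
    p: np.ndarray  # (n_sites, max_J, K) detection probabilities (NaN padded)
    plot_effect: np.ndarray  # (n_sites, max_J)
    params: SpeciesParams
    hyper: CommunityHyperparams


def simulate_covariates(
    n_sites: int,
    cover_config: CoverConfig | None = None,
    seed: int | np.random.Generator = 0,
    coral_taxa: tuple[str, ...] = ("coral",),
) -> SiteCovariates:
    """Draw per-site coral cover(s), turf cover and depth class.

    Each coral taxon is drawn independently from the zero-inflated law;
    depth class is Bernoulli(0.5).
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    cfg = cover_config or CoverConfig()
    rng = np.random.default_rng(seed)
    sites = [f"site{i:04d}" for i in range(n_sites)]
    covers = {}
    for taxon in coral_taxa:
        pos = cfg.coral_scale * rng.beta(cfg.coral_a, cfg.coral_b, size=n_sites)
        zero = rng.random(n_sites) < cfg.coral_zero_prob
        covers[taxon] = np.where(zero, 0.0, pos)
    covers["turf"] = cfg.turf_min + rng.beta(
        cfg.turf_a, cfg.turf_b, size=n_sites
    ) * (cfg.turf_max - cfg.turf_min)
    depth = pd.Series(
        np.where(rng.random(n_sites) < 0.5, "deep", "shallow"), index=sites
    )
    return SiteCovariates(
        covers=pd.DataFrame(covers, index=pd.Index(sites, name="site_id")),
        depth_class=depth,
        turf_taxon="turf",
    )


def simulate_species_params(
    n_species: int,
    hyper: CommunityHyperparams | None = None,
    seed: int | np.random.Generator = 0,
    species_id: list[str] | None = None,
    body_length: np.ndarray | None = None,
) -> SpeciesParams:
    """Draw species-level coefficients i.i.d. from the community
    hyperdistributions; detection intercepts include the body-length trend.

    ``species_id``/``body_length`` can be passed to re-draw coefficients for
    an existing species pool (e.g. juvenile-stage parameters for a subset of
    the adult community)."""
    hyper = hyper or CommunityHyperparams()
    rng = np.random.default_rng(seed)
    ids = species_id or [f"sp{k:04d}" for k in range(n_species)]
    if len(ids) != n_species:
        raise ValueError("species_id length mismatch")
    body = (
        np.asarray(body_length, dtype=float)
        if body_length is not None
        else np.exp(rng.normal(np.log(20.0), 0.6, size=n_species))
    )
    log_len = np.log(body)
    zlen = (log_len - log_len.mean()) / log_len.std(ddof=1) if n_species > 1 else 0.0
    return SpeciesParams(
        species_id=ids,
        alpha=rng.normal(hyper.mu_alpha, hyper.sd_alpha, n_species),
        beta1=rng.normal(hyper.mu_beta1, hyper.sd_beta1, n_species),
        beta2=rng.normal(hyper.mu_beta2, hyper.sd_beta2, n_species),
        p_intercept=hyper.mu_p
        + hyper.length_effect * zlen
        + rng.normal(0.0, hyper.sd_p, n_species),
        body_length=body,
    )


def default_occasions(
    n_sites: int, seed: int | np.random.Generator = 0,
    mean: float = 4.84, sd: float = 2.56,
) -> np.ndarray:
    """Per-site occasion counts: rounded normal clipped to the 1-12 plots of
    the field design."""
    rng = np.random.default_rng(seed)
    j = np.rint(rng.normal(mean, sd, size=n_sites))
    return np.clip(j, 1, 12).astype(int)


def simulate_detection_history(
    sp: SpeciesParams,
    cov: SiteCovariates,
    J_per_site: np.ndarray | list[int],
    hyper: CommunityHyperparams | None = None,
    seed: int | np.random.Generator = 0,
    coral_taxon: str | None = None,
    stage: str = "adult",
) -> tuple[DetectionHistory, SyntheticTruth]:
    """Simulate detection histories under the single-season occupancy model.

    Occupancy: z_ik ~ Bernoulli(psi_ik) with
    logit psi_ik = alpha_k + beta1_k * coral_i^std + beta2_k * turf_i^std.
    Detection: y_ijk ~ Bernoulli(z_ik * p_ijk) with
    logit p_ijk = p_intercept_k + delta_depth * [deep_i] + plot_effect_ij.
    Covariates are standardized internally (mean 0, SD 1 over sites).

    Returns the history together with the full latent truth.
    """
    if sp.n_species == 0:
        raise ValueError("species list is empty")
    hyper = hyper or CommunityHyperparams()
    J = np.asarray(J_per_site, dtype=int)
    if J.shape != (len(cov.sites),):
        raise ValueError("J_per_site must have one entry per site")
    if (J < 1).any() or (J > 12).any():
        raise ValueError("occasion counts must lie in [1, 12]")
    rng = np.random.default_rng(seed)

    taxa = [c for c in cov.covers.columns if c != cov.turf_taxon]
    coral_taxon = coral_taxon or taxa[0]
    from .occupancy import standardize  # local import avoids a cycle

    x1 = standardize(cov.coral_cover(coral_taxon).values)[0]
    x2 = standardize(cov.turf_cover.values)[0]
    deep = cov.is_deep()

    logit_psi = (
        sp.alpha[None, :]
        + sp.beta1[None, :] * x1[:, None]
        + sp.beta2[None, :] * x2[:, None]
    )
    psi = expit(logit_psi)
    z = (rng.random(psi.shape) < psi).astype(float)

    S, K = psi.shape
    max_j = int(J.max())
    plot_effect = np.full((S, max_j), np.nan)
    p = np.full((S, max_j, K), np.nan)
    y = np.full((S, max_j, K), np.nan)
    for i in range(S):
        u = rng.normal(0.0, hyper.sd_plot, size=J[i])
        plot_effect[i, : J[i]] = u
        logit_p = (
            sp.p_intercept[None, :]
            + hyper.delta_depth * deep[i]
            + u[:, None]
        )
        pi = expit(logit_p)
        p[i, : J[i], :] = pi
        y[i, : J[i], :] = (
            rng.random(pi.shape) < pi * z[i][None, :]
        ).astype(float)

    occasions = [[f"plot{j:02d}" for j in range(J[i])] for i in range(S)]
    dh = DetectionHistory(
        sites=cov.sites,
        occasions=occasions,
        species=[(sid, stage) for sid in sp.species_id],
        y=y,
    )
    truth = SyntheticTruth(
        psi=psi, z=z, p=p, plot_effect=plot_effect, params=sp, hyper=hyper
    )
    return dh, truth


#: ordered levels for the group-size trait, solitary lowest
GROUP_SIZE_LEVELS = ("solitary", "pair", "small_group", "medium_group", "school")


def simulate_traits(
    n_species: int,
    seed: int | np.random.Generator = 0,
    species_id: list[str] | None = None,
    body_length: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a species x 6 trait table (no missing values).

    Quantitative traits: total length (cm, lognormal), trophic level,
    aspect ratio, maximum preferred temperature (degC), maximum depth (m).
    Group size is an ordered categorical with levels
    :data:`GROUP_SIZE_LEVELS`.  ``body_length`` can be supplied to keep the
    trait table consistent with simulated detection parameters.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species for a non-degenerate hull")
    rng = np.random.default_rng(seed)
    ids = species_id or [f"sp{k:04d}" for k in range(n_species)]
    if len(ids) != n_species:
        raise ValueError("species_id length mismatch")
    length = (
        np.asarray(body_length, dtype=float)
        if body_length is not None
        else np.exp(rng.normal(np.log(20.0), 0.6, n_species))
    )
    df = pd.DataFrame(
        {
            "total_length": np.round(length, 1),
            "trophic_level": np.round(np.clip(rng.normal(2.9, 0.6, n_species), 2.0, 4.5), 2),
            "aspect_ratio": np.round(np.clip(rng.normal(1.6, 0.5, n_species), 0.3, None), 2),
            "group_size": rng.choice(
                GROUP_SIZE_LEVELS, size=n_species, p=(0.35, 0.2, 0.2, 0.15, 0.1)
            ),
            "max_pref_temperature": np.round(rng.normal(27.0, 1.5, n_species), 1),
            "max_depth": np.round(np.exp(rng.normal(np.log(40.0), 0.7, n_species)), 0),
        },
        index=pd.Index(ids, name="species_id"),
    )
    if df.drop(columns="group_size").std(ddof=1).min() == 0:
        # degenerate (all-identical) tables are allowed but flagged
        import warnings

        warnings.warn("degenerate trait table: a trait has zero variance")
    return df
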