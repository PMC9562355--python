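"""Classify species' responses to coral and turf cover from posterior CIs.

A species responds positively to a covariate when the lower bound of the
equal-tailed credible interval of its slope is above zero, negatively when
the upper bound is below zero, and neutrally otherwise.  A species is
"coral-associated" when its coral slope (beta1) is credibly positive and
its turf response (beta2) is non-positive; these are the species removed in
the coral-loss scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy import PosteriorSamples

__all__ = [
    "classify_response",
    "identify_coral_associated",
    "classify_fit",
    "associated_sets",
    "AssociatedSets",
]

MIN_DRAWS = 100


def classify_response(draws, ci_level: float = 0.90) -> str:
    """'positive' / 'negative' / 'neutral' from an equal-tailed quantile CI."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no posterior draws")
    if draws.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws, got {draws.size}")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    lo = np.quantile(draws, (1 - ci_level) / 2)
    hi = np.quantile(draws, 1 - (1 - ci_level) / 2)
    if lo > 0:
        return "positive"
    if hi < 0:
        return "negative"
    return "neutral"


def identify_coral_associated(
    beta1_draws,
    beta2_draws,
    ci_level: float = 0.90,
    turf_rule: str = "mean",
) -> bool:
    """True iff the coral slope is credibly positive and the turf response is
    non-positive.

    ``turf_rule`` selects how "beta2 <= 0" is read: 'mean' (posterior mean
    non-positive, the default) or 'upper' (the CI upper bound non-positive,
    a stricter reading).
    """
    beta1_draws = np.asarray(beta1_draws, dtype=float)
    beta2_draws = np.asarray(beta2_draws, dtype=float)
    if beta1_draws.shape != beta2_draws.shape:
        raise ValueError("beta1 and beta2 must have the same number of draws")
    if classify_response(beta1_draws, ci_level) != "positive":
        return False
    if turf_rule == "mean":
        return bool(beta2_draws.mean() <= 0)
    if turf_rule == "upper":
        hi = np.quantile(beta2_draws, 1 - (1 - ci_level) / 2)
        return bool(hi <= 0)
    raise ValueError(f"unknown turf_rule {turf_rule!r}")


def classify_fit(
    ps: PosteriorSamples,
    ci_level: float = 0.90,
    turf_rule: str = "mean",
) -> pd.DataFrame:
    """One classification row per species for a single (coral, stage) fit."""
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    for k, (sp, stage) in enumerate(ps.species):
        b1 = ps.species_draws("beta1", k)
        b2 = ps.species_draws("beta2", k)
        rows.append(
            {
                "species_id": sp,
                "stage": stage,
                "coral_taxon": ps.coral_taxon,
                "beta1_mean": b1.mean(),
                "beta1_lo": np.quantile(b1, lo_q),
                "beta1_hi": np.quantile(b1, hi_q),
                "beta2_mean": b2.mean(),
                "beta2_lo": np.quantile(b2, lo_q),
                "beta2_hi": np.quantile(b2, hi_q),
                "response_coral": classify_response(b1, ci_level),
                "response_turf": classify_response(b2, ci_level),
                "coral_associated": identify_coral_associated(
                    b1, b2, ci_level, turf_rule
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AssociatedSets:
    """Coral-associated species, per coral taxon and pooled."""

    per_coral: dict[str, dict[str, set[str]]]  # stage -> coral -> species
    union: dict[str, set[str]]  # stage -> species
    counts: pd.DataFrame  # response-category counts per (stage, coral, covariate)


def associated_sets(
    classifications: pd.DataFrame,
    expected_corals: list[str] | None = None,
) -> AssociatedSets:
    """Aggregate per-fit classifications into loss-scenario species sets.

    The union across the per-coral models (deduplicated by species id)
    defines the 'total loss' set per life stage.  ``expected_corals`` makes
    missing (coral, stage) runs a hard error.
    """
    if classifications.empty:
        return AssociatedSets(per_coral={}, union={}, counts=pd.DataFrame())
    stages = sorted(classifications["stage"].unique())
    if expected_corals is not None:
        missing = []
        for stage in stages:
            have = set(
                classifications.loc[classifications["stage"] == stage, "coral_taxon"]
            )
            missing += [
                f"{c}/{stage}" for c in expected_corals if c not in have
            ]
        if missing:
            raise ValueError(f"missing coral runs: {missing}")

    per_coral: dict[str, dict[str, set[str]]] = {}
    union: dict[str, set[str]] = {}
    for stage in stages:
        sub = classifications[classifications["stage"] == stage]
        per_coral[stage] = {
            coral: set(
                grp.loc[grp["coral_associated"], "species_id"]
            )
            for coral, grp in sub.groupby("coral_taxon")
        }
        union[stage] = set().union(*per_coral[stage].values())

    count_rows = []
    for (stage, coral), grp in classifications.groupby(["stage", "coral_taxon"]):
        for covariate, col in (("coral", "response_coral"), ("turf", "response_turf")):
            vc = grp[col].value_counts()
            count_rows.append(
                {
                    "stage": stage,
                    "coral_taxon": coral,
                    "covariate": covariate,
                    "positive": int(vc.get("positive", 0)),
                    "neutral": int(vc.get("neutral", 0)),
                    "negative": int(vc.get("negative", 0)),
                }
            )
    return AssociatedSets(
        per_coral=per_coral, union=union, counts=pd.DataFrame(count_rows)
    )
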