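"""Tabular input/output, inclusion filters and site-level aggregation.

The raw inputs are tidy CSV tables:

``detections.csv``
    One row per (site, plot, species, stage) with a binary ``detected``
    column.  A sampling occasion is a 10-minute video plot; occasions that
    were never deployed at a site are encoded by row absence, never by 0.

``benthic.csv``
    Photoquadrat point counts -- one row per (site, quadrat, subunit, taxon)
    with ``points_on_taxon`` out of ``total_points`` (50 random points per
    25 cm^2 subunit) -- or pre-aggregated per-site cover fractions.

``traits.csv``
    One row per species with six traits (five quantitative, one ordered
    categorical: group size, schooling species ranking above solitary ones).

A "site" is the unique combination of locality, place and depth category
(shallow: 1-7 m, deep: 8-15 m); the ``site_id`` key is expected to encode
that combination already.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionHistory",
    "SiteCovariates",
    "FilterReport",
    "LifeStageRuleGap",
    "TRAIT_COLUMNS",
    "ORDERED_TRAITS",
    "aggregate_cover",
    "select_corals",
    "assign_life_stage",
    "filter_species",
    "read_detections",
    "write_detections",
    "read_benthic",
    "read_traits",
    "validate_traits",
    "read_site_covariates",
    "write_site_covariates",
]

STAGES = ("adult", "juvenile")
DEPTH_CLASSES = ("shallow", "deep")

#: canonical trait columns: five quantitative + one ordered categorical
TRAIT_COLUMNS = (
    "total_length",
    "trophic_level",
    "aspect_ratio",
    "group_size",
    "max_pref_temperature",
    "max_depth",
)
ORDERED_TRAITS = ("group_size",)


class LifeStageRuleGap(UserWarning):
    """Raised as a warning for species whose maximum total length falls in
    the [5, 8) cm band, for which no published life-stage cut-off exists."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DetectionHistory:
    """Binary detection/non-detection histories with a ragged occasion design.

    Attributes
    ----------
    sites:
        Ordered site identifiers (length S).
    occasions:
        Per-site list of plot identifiers; ``len(occasions[i])`` is the
        number of sampling occasions J_i at site i (1..12 in the field
        design).
    species:
        Ordered list of ``(species_id, life_stage)`` pairs (length K).
    y:
        Float array of shape (S, max_J, K); entries are 0.0, 1.0 or NaN for
        occasion slots a site does not have.
    """

    sites: list[str]
    occasions: list[list[str]]
    species: list[tuple[str, str]]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        S, J, K = self.y.shape
        if S != len(self.sites) or K != len(self.species):
            raise ValueError("y shape inconsistent with site/species lists")
        for i, occ in enumerate(self.occasions):
            if len(occ) < 1:
                raise ValueError(f"site {self.sites[i]!r} has no occasions")
            if np.isnan(self.y[i, : len(occ)]).any():
                raise ValueError("NaN inside the occasion range")
            if not np.isnan(self.y[i, len(occ) :]).all():
                raise ValueError("non-NaN outside the occasion range")
        vals = self.y[~np.isnan(self.y)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("detections must be binary")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_occasions(self) -> np.ndarray:
        """J_i per site."""
        return np.array([len(o) for o in self.occasions])

    def detections_per_species(self) -> np.ndarray:
        """Total detections per (species, stage), summed over sites/occasions."""
        return np.nansum(self.y, axis=(0, 1))

    def subset_species(self, keep: Sequence[int]) -> "DetectionHistory":
        keep = list(keep)
        return DetectionHistory(
            sites=list(self.sites),
            occasions=[list(o) for o in self.occasions],
            species=[self.species[k] for k in keep],
            y=self.y[:, :, keep].copy(),
        )

    # -- long-format round trip ------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, site in enumerate(self.sites):
            for j, plot in enumerate(self.occasions[i]):
                for k, (sp, stage) in enumerate(self.species):
                    rows.append((site, plot, sp, stage, int(self.y[i, j, k])))
        return pd.DataFrame(
            rows, columns=["site", "plot", "species", "stage", "detected"]
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "DetectionHistory":
        required = {"site", "plot", "species", "stage", "detected"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"detections table missing columns: {sorted(missing)}")
        bad = set(df["stage"].unique()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown life stages: {sorted(bad)}")
        df = df.copy()
        df["detected"] = df["detected"].astype(int)
        if not df["detected"].isin((0, 1)).all():
            raise ValueError("detected must be 0/1")

        sites = sorted(df["site"].astype(str).unique())
        occasions = [
            sorted(df.loc[df["site"].astype(str) == s, "plot"].astype(str).unique())
            for s in sites
        ]
        species = sorted(
            set(zip(df["species"].astype(str), df["stage"].astype(str)))
        )
        max_j = max(len(o) for o in occasions)
        y = np.full((len(sites), max_j, len(species)), np.nan)
        for i, occ in enumerate(occasions):
            y[i, : len(occ), :] = 0.0
        site_ix = {s: i for i, s in enumerate(sites)}
        occ_ix = {
            (s, p): j for i, s in enumerate(sites) for j, p in enumerate(occasions[i])
        }
        sp_ix = {sp: k for k, sp in enumerate(species)}
        for row in df.itertuples(index=False):
            i = site_ix[str(row.site)]
            j = occ_ix[(str(row.site), str(row.plot))]
            k = sp_ix[(str(row.species), str(row.stage))]
            y[i, j, k] = max(y[i, j, k], float(row.detected))
        return cls(sites=sites, occasions=occasions, species=species, y=y)


@dataclass
class SiteCovariates:
    """Per-site benthic covers (percent) and depth category.

    ``covers`` is a site x taxon DataFrame of percent cover in [0, 100];
    ``depth_class`` maps each site to 'shallow' or 'deep'.  The turf taxon
    is identified by name (``turf_taxon``).
    """

    covers: pd.DataFrame
    depth_class: pd.Series | None = None
    turf_taxon: str = "turf"

    def __post_init__(self) -> None:
        if (self.covers.values < 0).any():
            raise ValueError("negative cover")
        if (self.covers.values > 100).any():
            raise ValueError("cover above 100%")
        if self.depth_class is not None:
            self.depth_class = self.depth_class.reindex(self.covers.index)
            bad = set(self.depth_class.dropna().unique()) - set(DEPTH_CLASSES)
            if bad:
                raise ValueError(f"unknown depth classes: {sorted(bad)}")
            if self.depth_class.isna().any():
                miss = list(self.covers.index[self.depth_class.isna()])
                raise ValueError(f"sites without depth class: {miss}")

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.covers.index]

    def coral_cover(self, taxon: str) -> pd.Series:
        if taxon not in self.covers.columns:
            raise KeyError(f"unknown taxon {taxon!r}")
        return self.covers[taxon]

    @property
    def turf_cover(self) -> pd.Series:
        return self.coral_cover(self.turf_taxon)

    def is_deep(self) -> np.ndarray:
        if self.depth_class is None:
            raise ValueError("no depth classes recorded")
        return (self.depth_class.values == "deep").astype(float)


@dataclass
class FilterReport:
    """Bookkeeping emitted by :func:`filter_species`."""

    n_input: int
    n_kept: int
    dropped_zero_detections: list[tuple[str, str]] = field(default_factory=list)
    dropped_unresolved: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def aggregate_cover(
    benthic: pd.DataFrame,
    depth_class: pd.Series | None = None,
    known_sites: Iterable[str] | None = None,
    turf_taxon: str = "turf",
) -> SiteCovariates:
    """Aggregate photoquadrat point counts to site-level percent cover.

    The hierarchy of means is fixed: point fraction per subunit, then mean
    over the (up to five) subunits of a photoquadrat, then mean over the
    photoquadrats of a site.  A taxon not scored in a subunit contributes 0
    there.  Pre-aggregated input (columns site_id, taxon, cover with cover a
    fraction in [0, 1]) is passed through unchanged apart from conversion to
    percent, which makes the operation idempotent on its own output divided
    by 100.
    """
    benthic = benthic.copy()
    if known_sites is not None:
        known = set(map(str, known_sites))
        unknown = set(benthic["site_id"].astype(str)) - known
        if unknown:
            raise ValueError(f"unknown site_id in benthic rows: {sorted(unknown)}")

    if "cover" in benthic.columns:  # pre-aggregated
        if ((benthic["cover"] < 0) | (benthic["cover"] > 1)).any():
            raise ValueError("pre-aggregated cover must be a fraction in [0,1]")
        wide = benthic.pivot_table(
            index="site_id", columns="taxon", values="cover", aggfunc="mean"
        ).fillna(0.0)
        covers = wide * 100.0
    else:
        required = {"site_id", "quadrat_id", "subunit_id", "taxon",
                    "points_on_taxon", "total_points"}
        missing = required - set(benthic.columns)
        if missing:
            raise ValueError(f"benthic table missing columns: {sorted(missing)}")
        if (benthic["total_points"] <= 0).any():
            raise ValueError("total_points must be positive")
        if (benthic["points_on_taxon"] > benthic["total_points"]).any():
            raise ValueError("points_on_taxon exceeds total_points")
        benthic["frac"] = benthic["points_on_taxon"] / benthic["total_points"]
        # subunit level: absent taxa are zeros, so pivot on the full taxon set
        sub = benthic.pivot_table(
            index=["site_id", "quadrat_id", "subunit_id"],
            columns="taxon",
            values="frac",
            aggfunc="sum",
        ).fillna(0.0)
        quad = sub.groupby(level=["site_id", "quadrat_id"]).mean()
        covers = quad.groupby(level="site_id").mean() * 100.0

    covers.index = covers.index.astype(str)
    covers = covers.sort_index()
    covers.columns.name = None
    covers.index.name = "site_id"
    return SiteCovariates(covers=covers, depth_class=depth_class, turf_taxon=turf_taxon)


def select_corals(
    cov: SiteCovariates,
    min_sites: int = 4,
    exclude: Sequence[str] = (),
) -> list[str]:
    """Coral taxa with non-zero cover in at least ``min_sites`` sites.

    Returns taxa sorted by number of occupied sites (descending; ties broken
    alphabetically).  The turf taxon and any ``exclude`` entries are never
    returned.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    skip = set(exclude) | {cov.turf_taxon}
    counts = (cov.covers > 0).sum(axis=0)
    kept = [
        (int(n), t)
        for t, n in counts.items()
        if t not in skip and n >= min_sites
    ]
    kept.sort(key=lambda x: (-x[0], x[1]))
    return [t for _, t in kept]


def assign_life_stage(
    length_obs: float,
    species_max_TL: float,
    gap_policy: str = "midband",
) -> str:
    """Assign 'adult' or 'juvenile' from an observed length and the species'
    maximum total length (TL), both in cm.

    Rules: species with TL < 5 cm are adults at any length; species with
    8 <= TL <= 16 cm split at 5 cm (adult if > 5); species with TL > 16 cm
    split at 10 cm (adult if > 10).  The published rules leave the band
    5 <= TL < 8 undefined; ``gap_policy`` controls the fallback ('midband'
    applies the 8-16 cm rule, 'adult' treats every individual as adult,
    'error' raises) and a :class:`LifeStageRuleGap` warning is always
    emitted for that band.
    """
    if length_obs <= 0 or species_max_TL <= 0:
        raise ValueError("lengths must be positive")
    TL = species_max_TL
    if TL < 5:
        return "adult"
    if 5 <= TL < 8:
        warnings.warn(
            f"species max TL {TL} cm falls in the undefined 5-8 cm band; "
            f"applying gap policy {gap_policy!r}",
            LifeStageRuleGap,
            stacklevel=2,
        )
        if gap_policy == "midband":
            return "adult" if length_obs > 5 else "juvenile"
        if gap_policy == "adult":
            return "adult"
        raise ValueError(f"no life-stage rule for max TL {TL} cm")
    if TL <= 16:
        return "adult" if length_obs > 5 else "juvenile"
    return "adult" if length_obs > 10 else "juvenile"


def filter_species(
    dh: DetectionHistory,
    unresolved: Iterable[str] = (),
) -> tuple[DetectionHistory, FilterReport]:
    """Drop species-stage rows that were never detected or whose taxonomy is
    unresolved (``unresolved`` lists species_ids not identified to species
    level).  Errors if nothing survives."""
    unresolved = set(unresolved)
    totals = dh.detections_per_species()
    keep, zero, unres = [], [], []
    for k, (sp, stage) in enumerate(dh.species):
        if sp in unresolved:
            unres.append((sp, stage))
        elif totals[k] < 1:
            zero.append((sp, stage))
        else:
            keep.append(k)
    if not keep:
        raise ValueError("species filter removed the entire assemblage")
    report = FilterReport(
        n_input=dh.n_species,
        n_kept=len(keep),
        dropped_zero_detections=zero,
        dropped_unresolved=unres,
    )
    return dh.subset_species(keep), report


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------


def read_detections(path: str | Path) -> DetectionHistory:
    return DetectionHistory.from_long(pd.read_csv(path))


def write_detections(dh: DetectionHistory, path: str | Path) -> None:
    dh.to_long().to_csv(path, index=False)


def read_benthic(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def validate_traits(traits: pd.DataFrame, require: Sequence[str] = TRAIT_COLUMNS) -> None:
    missing_cols = set(require) - set(traits.columns)
    if missing_cols:
        raise ValueError(f"trait table missing columns: {sorted(missing_cols)}")
    na = traits[list(require)].isna()
    if na.values.any():
        bad = list(traits.index[na.any(axis=1)])
        raise ValueError(f"missing trait values for species: {bad}")


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="species_id")
    validate_traits(df)
    return df


def read_site_covariates(path: str | Path, turf_taxon: str = "turf") -> SiteCovariates:
    df = pd.read_csv(path, index_col="site_id")
    df.index = df.index.astype(str)
    depth = None
    if "depth_class" in df.columns:
        depth = df.pop("depth_class")
    return SiteCovariates(covers=df, depth_class=depth, turf_taxon=turf_taxon)


def write_site_covariates(cov: SiteCovariates, path: str | Path) -> None:
    out = cov.covers.copy()
    if cov.depth_class is not None:
        out["depth_class"] = cov.depth_class
    out.to_csv(path, index_label="site_id")
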