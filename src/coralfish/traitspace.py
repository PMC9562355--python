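"""Functional trait space: Gower dissimilarity, PCoA and convex-hull areas.

Species are embedded in a low-dimensional ordination space built from mixed
trait types.  Gower's coefficient range-normalizes quantitative traits and
scores ordered categorical traits by ranks, giving pairwise dissimilarities
in [0, 1].  Principal coordinates analysis (PCoA) embeds the distance
matrix into Euclidean axes; because Gower distances are generally
non-Euclidean, negative eigenvalues are handled by the Cailliez correction
(default), the Lingoes correction, or by dropping them.  Functional
richness of a species set is the area of the 2-D convex hull of its
coordinates; the reduction in functional space after removing a set R is

    RFS = (1 - FS_reduced / FS_complete) * 100  (percent),

0% meaning the remaining species span the full trait space (functional
redundancy of the removed set) and 100% a complete collapse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import rankdata
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .data_io import TRAIT_COLUMNS
from .synthetic import GROUP_SIZE_LEVELS

__all__ = [
    "TraitSpace",
    "gower_distance",
    "pcoa",
    "hull_area",
    "hull_vertices",
    "rfs",
    "build_trait_space",
    "SIX_TRAITS",
    "FOUR_TRAITS",
]

#: full trait set and the reduced 4-trait alternative (group size, maximum
#: body size, trophic level, aspect ratio); which set is used is a config
#: choice surfaced to the caller, not resolved here.
SIX_TRAITS = tuple(TRAIT_COLUMNS)
FOUR_TRAITS = ("group_size", "total_length", "trophic_level", "aspect_ratio")

DEFAULT_ORDERED_LEVELS: dict[str, tuple[str, ...]] = {
    "group_size": GROUP_SIZE_LEVELS
}


def gower_distance(
    traits: pd.DataFrame,
    columns: Sequence[str] | None = None,
    ordered_levels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Pairwise Gower dissimilarities between species.

    Quantitative traits contribute |x_a - x_b| / range; ordered categorical
    traits are converted to (tie-averaged) ranks first and then treated the
    same way.  The result is the unweighted mean over traits: symmetric,
    zero-diagonal, bounded by [0, 1].  Missing values are rejected, naming
    the offending species.
    """
    columns = list(columns or traits.columns)
    ordered_levels = dict(DEFAULT_ORDERED_LEVELS, **(ordered_levels or {}))
    if len(traits) < 2:
        raise ValueError("need at least 2 species")
    sub = traits[columns]
    if sub.isna().values.any():
        bad = list(sub.index[sub.isna().any(axis=1)])
        raise ValueError(f"missing trait values for species: {bad}")

    n = len(sub)
    parts = np.zeros((n, n))
    for col in columns:
        if col in ordered_levels:
            levels = list(ordered_levels[col])
            codes = sub[col].map({lv: i for i, lv in enumerate(levels)})
            if codes.isna().any():
                bad = sorted(sub.loc[codes.isna(), col].unique())
                raise ValueError(f"{col}: values outside declared order: {bad}")
            x = rankdata(codes.values)
        else:
            x = sub[col].to_numpy(dtype=float)
        rng = x.max() - x.min()
        if rng == 0:
            continue  # invariant trait: no contribution to dissimilarity
        parts += np.abs(x[:, None] - x[None, :]) / rng
    d = parts / len(columns)
    return pd.DataFrame(d, index=sub.index, columns=sub.index)


def _center(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ mat @ j


def cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant c such that d_ij + c (i != j) is
    Euclidean-embeddable: the largest real eigenvalue of the classical
    2n x 2n companion problem."""
    n = d.shape[0]
    delta1 = _center(-0.5 * d**2)
    delta2 = _center(-0.5 * d)
    top = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    bottom = np.hstack([-np.eye(n), -4.0 * delta2])
    eigs = np.linalg.eigvals(np.vstack([top, bottom]))
    return float(np.max(eigs.real))


def pcoa(
    d: pd.DataFrame | np.ndarray,
    n_axes: int = 2,
    correction: str = "cailliez",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-coordinate embedding of a distance matrix.

    Returns (coordinates, eigenvalues); coordinates keep the input row
    labels when given a DataFrame.  ``correction`` in
    {'cailliez', 'lingoes', 'none'} governs negative eigenvalues; with
    'none', axes with negative eigenvalues are simply dropped.  Rejects a
    request for more axes than there are positive eigenvalues.
    """
    if n_axes < 2:
        raise ValueError("n_axes must be >= 2")
    if isinstance(d, pd.DataFrame):
        ids = [str(i) for i in d.index]
        mat = d.to_numpy(dtype=float)
    else:
        mat = np.asarray(d, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0):
        raise ValueError("distance matrix must have a zero diagonal")

    gram = _center(-0.5 * mat**2)
    if correction != "none" and np.linalg.eigvalsh(gram).min() < -1e-8 * mat.shape[0]:
        if correction == "cailliez":
            c = cailliez_constant(mat)
            mat = mat + c * (1 - np.eye(mat.shape[0]))
        elif correction == "lingoes":
            c = -float(np.linalg.eigvalsh(gram).min())
            off = 1 - np.eye(mat.shape[0])
            mat = np.sqrt(mat**2 + 2.0 * c * off)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        gram = _center(-0.5 * mat**2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about tiny negatives
        res = _skbio_pcoa(DistanceMatrix(mat, ids=ids), method="eigh")
    # availability from the true Gram spectrum (skbio clamps negatives to 0)
    eigvals = np.sort(np.linalg.eigvalsh(gram))[::-1]
    tol = 1e-8 * max(np.abs(eigvals).max(), 1.0)
    n_pos = int((eigvals > tol).sum())
    n_zero = int((np.abs(eigvals) <= tol).sum())
    # zero-eigenvalue axes are legitimate (exact embedding in fewer
    # dimensions, coordinates 0); axes backed by negative eigenvalues are not
    if n_axes > n_pos + n_zero:
        raise ValueError(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues"
        )
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = ids
    coords.columns = [f"axis{i+1}" for i in range(n_axes)]
    return coords, eigvals


def hull_vertices(coords: np.ndarray) -> np.ndarray:
    """Indices of points on the convex hull; empty for degenerate clouds."""
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 3:
        return np.arange(len(pts))
    try:
        return np.sort(ConvexHull(pts).vertices)
    except QhullError:  # collinear
        return np.arange(len(pts))


def hull_area(coords: np.ndarray, subset: Sequence[int] | None = None) -> float:
    """Area of the 2-D convex hull of a point subset.

    Fewer than 3 points, or a collinear set, spans zero area (degenerate
    hull, flagged with a warning).  ``subset`` indexes rows of ``coords``.
    """
    pts = np.asarray(coords, dtype=float)
    if subset is not None:
        subset = np.asarray(list(subset), dtype=int)
        if subset.size and (subset.min() < 0 or subset.max() >= len(pts)):
            raise IndexError("subset indexes species absent from the space")
        pts = pts[subset]
    if pts.shape[0] < 3:
        warnings.warn("degenerate hull: fewer than 3 points, area = 0")
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D: volume is the area
    except QhullError:
        warnings.warn("degenerate hull: collinear points, area = 0")
        return 0.0


def rfs(area_reduced: float, area_complete: float) -> float:
    """Percent reduction in functional trait space,
    (1 - FS_reduced / FS_complete) * 100."""
    if area_complete <= 0:
        raise ValueError("degenerate complete space: area_complete must be > 0")
    if not 0 <= area_reduced <= area_complete * (1 + 1e-12):
        raise ValueError("area_reduced must lie in [0, area_complete]")
    return float((1.0 - area_reduced / area_complete) * 100.0)


@dataclass
class TraitSpace:
    """Species coordinates in ordination space with hull bookkeeping."""

    species_id: list[str]
    coordinates: np.ndarray  # (n_species, n_axes)
    eigenvalues: np.ndarray
    hull_vertex_ids: list[str]
    area_complete: float

    def __post_init__(self) -> None:
        self._ix = {s: i for i, s in enumerate(self.species_id)}

    @property
    def n_species(self) -> int:
        return len(self.species_id)

    def indices(self, species: Iterable[str]) -> np.ndarray:
        missing = [s for s in species if s not in self._ix]
        if missing:
            raise KeyError(f"species absent from the trait space: {missing}")
        return np.array(sorted(self._ix[s] for s in set(species)), dtype=int)

    def area_of(self, keep: Iterable[str]) -> float:
        return hull_area(self.coordinates, self.indices(keep))

    def rfs_of_removal(self, removed: Iterable[str]) -> float:
        removed = set(removed)
        keep = [s for s in self.species_id if s not in removed]
        if not keep:
            return 100.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reduced = self.area_of(keep)
        return rfs(min(reduced, self.area_complete), self.area_complete)

    def coordinates_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.species_id, name="species_id"),
            columns=[f"axis{i+1}" for i in range(self.coordinates.shape[1])],
        )


def build_trait_space(
    traits: pd.DataFrame,
    trait_set: str | Sequence[str] = "six",
    n_axes: int = 2,
    correction: str = "cailliez",
    ordered_levels: Mapping[str, Sequence[str]] | None = None,
) -> TraitSpace:
    """Build the complete functional trait space from a trait table.

    One common space is built from all species; stage- or scenario-specific
    removals are applied to this shared embedding.  ``trait_set`` is 'six'
    (default), 'four', or an explicit column list.
    """
    if trait_set == "six":
        columns = [c for c in SIX_TRAITS if c in traits.columns]
    elif trait_set == "four":
        columns = list(FOUR_TRAITS)
    else:
        columns = list(trait_set)
    d = gower_distance(traits, columns=columns, ordered_levels=ordered_levels)
    coords, eigvals = pcoa(d, n_axes=n_axes, correction=correction)
    xy = coords.to_numpy()
    verts = hull_vertices(xy)
    ids = [str(s) for s in traits.index]
    return TraitSpace(
        species_id=ids,
        coordinates=xy,
        eigenvalues=eigvals,
        hull_vertex_ids=[ids[v] for v in verts],
        area_complete=hull_area(xy),
    )
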