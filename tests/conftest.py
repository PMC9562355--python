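import numpy as np
import pandas as pd
import pytest

from coralfish.traitspace import TraitSpace, hull_area, hull_vertices


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def square_space():
    """Unit-square hull (4 vertex species) plus two interior species."""
    coords = np.array(
        [
            [0.0, 0.0],
            [1.0, 0.0],
            [1.0, 1.0],
            [0.0, 1.0],
            [0.5, 0.5],
            [0.2, 0.4],
        ]
    )
    ids = [f"s{i}" for i in range(len(coords))]
    verts = hull_vertices(coords)
    return TraitSpace(
        species_id=ids,
        coordinates=coords,
        eigenvalues=np.array([1.0, 1.0]),
        hull_vertex_ids=[ids[v] for v in verts],
        area_complete=hull_area(coords),
    )


def shoelace(points: np.ndarray) -> float:
    """Independent polygon-area oracle: shoelace formula on hull vertices
    ordered by angle around the centroid (points must form a convex set)."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
    p = pts[order]
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@pytest.fixture
def tiny_traits():
    return pd.DataFrame(
        {
            "total_length": [10.0, 25.0, 60.0, 14.0, 90.0],
            "trophic_level": [2.0, 3.1, 4.2, 2.5, 3.9],
            "aspect_ratio": [1.1, 1.8, 2.4, 0.9, 3.0],
            "group_size": ["solitary", "pair", "school", "small_group", "solitary"],
            "max_pref_temperature": [25.0, 27.5, 28.8, 26.1, 24.2],
            "max_depth": [20.0, 45.0, 120.0, 35.0, 200.0],
        },
        index=pd.Index([f"sp{i}" for i in range(5)], name="species_id"),
    )
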