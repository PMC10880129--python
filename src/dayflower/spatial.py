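"""Geographic and landscape-composition distance matrices.

Geographic distances are great-circle (haversine) on the WGS84 mean Earth
radius 6371.0088 km; at the sub-100-km extent of a metropolitan study the
difference from a geodesic is far below what rank-based Mantel inference
can resolve.

Landscape distances are Bray-Curtis dissimilarities of land-cover area
vectors around each site: BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i) over
the selected classes.  The default excludes grassland (developed +
agricultural + forest) and uses the 500 m buffer.  Bray-Curtis is a
semimetric bounded in [0, 1]; downstream PCoA must tolerate negative
eigenvalues.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .datatypes import DistMatrix, PopulationMeta

EARTH_RADIUS_KM: float = 6371.0088

#: Classes entering the landscape dissimilarity by default (grassland excluded).
DEFAULT_BC_CLASSES: tuple[str, ...] = ("developed", "agricultural", "forest")
DEFAULT_BC_RADIUS: int = 500


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance(meta: Mapping[str, PopulationMeta]) -> DistMatrix:
    """All-pairs great-circle distance matrix (km), labels in mapping order."""
    labels = list(meta)
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        mi = meta[labels[i]]
        for j in range(i + 1, n):
            mj = meta[labels[j]]
            vals[i, j] = vals[j, i] = haversine_km(mi.lat, mi.lon, mj.lat, mj.lon)
    return DistMatrix(labels, vals, kind="geographic")


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC(x, y) = sum|x - y| / sum(x + y); NaN if both vectors are all-zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0.0:
        return float("nan")
    return float(np.abs(x - y).sum() / denom)


def landscape_distance(
    meta: Mapping[str, PopulationMeta],
    radius: int = DEFAULT_BC_RADIUS,
    classes: Sequence[str] = DEFAULT_BC_CLASSES,
) -> DistMatrix:
    """All-pairs Bray-Curtis dissimilarity of land-cover composition.

    Raises KeyError if any population lacks the requested radius; a pair of
    all-zero composition vectors yields NaN with a warning via DistMatrix
    consumers (kept, not dropped).
    """
    if not classes:
        raise ValueError("class subset must be non-empty")
    labels = list(meta)
    vecs = [meta[l].landcover_vector(radius, classes) for l in labels]
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = bray_curtis(vecs[i], vecs[j])
    return DistMatrix(labels, vals, kind="braycurtis")
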