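"""Mantel-family permutation tests and habitat-pair resampling inference.

All routines are driven by an explicit integer seed (no hidden global
state) and report a :class:`ResamplingResult` holding the observed
statistic, the replicate distribution, percentile CI bounds and — where the
procedure defines one — a permutation p-value.

Contents
--------
mantel
    Pearson correlation of upper-triangle entries; null by joint
    row+column permutation of one matrix; one-sided "greater" p-value by
    default (the vegan convention), (hits + 1)/(n_perm + 1).
partial_mantel
    First-order partial correlation r_xy.z from the three pairwise
    entry correlations, permuting x's labels.
cross_group_correlation_ci
    Correlation between two distance matrices restricted to
    between-habitat pairs, with a label-permutation null and its 95% CI;
    significance means the observed r falls outside the null CI.  (Plain
    Mantel tests cannot address pairs that straddle two groups.)
habitat_pair_resample
    Per habitat-pair category, repeatedly draw one pair at random and
    summarise the sampled distances (mean and percentile CI) — the basis
    of the same/different-habitat distance comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datatypes import HABITATS, DistMatrix


@dataclass
class ResamplingResult:
    """Observed statistic with its resampled/permuted distribution."""

    observed: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    p: float | None
    n_reps: int
    seed: int
    statistic: str = ""

    @property
    def significant(self) -> bool:
        """Observed value outside the replicate 95% interval."""
        return bool(self.observed < self.ci_low or self.observed > self.ci_high)


@dataclass
class PairSet:
    """A named set of unordered population pairs (one habitat-pair category)."""

    label: str
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"{self.label}: self-pair ({a}, {b})")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"{self.label}: duplicate pair ({a}, {b})")
            seen.add(key)


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _check_pair(
    x: DistMatrix, y: DistMatrix
) -> tuple[list[str], np.ndarray, np.ndarray]:
    if set(x.labels) != set(y.labels):
        raise ValueError("distance matrices have different label sets")
    # canonical (sorted) label order so results are invariant to input order
    order = sorted(x.labels)
    x = x.reorder(order)
    y = y.reorder(order)
    if x.has_nonfinite() or y.has_nonfinite():
        raise ValueError("Mantel-family tests require finite matrices")
    return order, x.values, y.values


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float((a * b).sum() / denom)


def mantel(
    x: DistMatrix, y: DistMatrix, n_perm: int = 999, seed: int = 0,
    *, alternative: str = "greater",
) -> ResamplingResult:
    """Mantel test of matrix correlation.

    Observed r is the Pearson correlation over off-diagonal upper-triangle
    entries; the null permutes rows and columns of `y` jointly.  One-sided
    "greater" p by default; "two-sided" compares |r|.
    """
    _, xv, yv = _check_pair(x, y)
    r_obs = _pearson(_upper(xv), _upper(yv))
    rng = np.random.default_rng(seed)
    n = xv.shape[0]
    xu = _upper(xv)
    reps = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        reps[k] = _pearson(xu, _upper(yv[np.ix_(perm, perm)]))
    if alternative == "greater":
        hits = int((reps >= r_obs).sum())
    elif alternative == "two-sided":
        hits = int((np.abs(reps) >= abs(r_obs)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (hits + 1) / (n_perm + 1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return ResamplingResult(r_obs, reps, float(lo), float(hi), p, n_perm, seed, "mantel_r")


def _partial_r(rxy: float, rxz: float, ryz: float) -> float:
    denom = (1 - rxz ** 2) * (1 - ryz ** 2)
    if denom <= 0.0:
        raise ValueError("degenerate covariate: |r_xz| or |r_yz| is 1")
    return (rxy - rxz * ryz) / np.sqrt(denom)


def partial_mantel(
    x: DistMatrix, y: DistMatrix, z: DistMatrix, n_perm: int = 999, seed: int = 0,
) -> ResamplingResult:
    """Partial Mantel test of x ~ y given covariate z (x-permutation null)."""
    _, xv, yv = _check_pair(x, y)
    _, _, zv = _check_pair(x, z)
    xu, yu, zu = _upper(xv), _upper(yv), _upper(zv)
    ryz = _pearson(yu, zu)
    r_obs = _partial_r(_pearson(xu, yu), _pearson(xu, zu), ryz)
    rng = np.random.default_rng(seed)
    n = xv.shape[0]
    reps = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        xp = _upper(xv[np.ix_(perm, perm)])
        reps[k] = _partial_r(_pearson(xp, yu), _pearson(xp, zu), ryz)
    p = (int((reps >= r_obs).sum()) + 1) / (n_perm + 1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return ResamplingResult(
        r_obs, reps, float(lo), float(hi), p, n_perm, seed, "partial_mantel_r"
    )


# ---------------------------------------------------------------------------
# Cross-habitat pair correlations
# ---------------------------------------------------------------------------

def _between_pairs_r(
    xv: np.ndarray, yv: np.ndarray, idx1: Sequence[int], idx2: Sequence[int]
) -> float:
    xs = [xv[a, b] for a in idx1 for b in idx2]
    ys = [yv[a, b] for a in idx1 for b in idx2]
    return _pearson(np.asarray(xs), np.asarray(ys))


def cross_group_correlation_ci(
    x: DistMatrix,
    y: DistMatrix,
    groups: Mapping[str, str],
    g1: str,
    g2: str,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    method: str = "permutation",
) -> ResamplingResult:
    """Correlation of x vs y over between-group population pairs, with a CI.

    Observed r is the Pearson correlation of (x_ab, y_ab) over exactly the
    pairs {a in g1, b in g2}.  With ``method="permutation"`` (default) the
    replicate distribution permutes population labels within g1 U g2
    (group sizes preserved) and recomputes r on the induced between-group
    pairs; the reported CI is of that null and `significant` means the
    observed r lies outside it.  ``method="bootstrap"`` instead resamples
    the between-group pairs with replacement, giving a CI of the observed r.
    """
    if g1 == g2:
        raise ValueError("g1 and g2 must differ")
    labels, xv, yv = _check_pair(x, y)
    members1 = [i for i, l in enumerate(labels) if groups.get(l) == g1]
    members2 = [i for i, l in enumerate(labels) if groups.get(l) == g2]
    if len(members1) < 2 or len(members2) < 2:
        raise ValueError("need at least 2 populations per group")
    if len(members1) * len(members2) < 3:
        raise ValueError("fewer than 3 between-group pairs: correlation ill-defined")
    r_obs = _between_pairs_r(xv, yv, members1, members2)
    rng = np.random.default_rng(seed)
    union = np.asarray(members1 + members2)
    n1 = len(members1)
    reps = np.empty(n_perm)
    if method == "permutation":
        for k in range(n_perm):
            perm = rng.permutation(union)
            reps[k] = _between_pairs_r(xv, yv, perm[:n1], perm[n1:])
    elif method == "bootstrap":
        pairs = [(a, b) for a in members1 for b in members2]
        m = len(pairs)
        for k in range(n_perm):
            take = rng.integers(0, m, m)
            xs = np.array([xv[pairs[t][0], pairs[t][1]] for t in take])
            ys = np.array([yv[pairs[t][0], pairs[t][1]] for t in take])
            try:
                reps[k] = _pearson(xs, ys)
            except ValueError:
                reps[k] = np.nan
        reps = reps[np.isfinite(reps)]
    else:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return ResamplingResult(
        r_obs, reps, float(lo), float(hi), None, len(reps), seed, "cross_group_r"
    )


# ---------------------------------------------------------------------------
# Habitat-pair categories and resampling CIs
# ---------------------------------------------------------------------------

def build_pair_sets(groups: Mapping[str, str]) -> list[PairSet]:
    """The 11 habitat-pair categories: 4 within, 3 rural-urban, 3 urban-urban, ALL.

    Category sizes follow the obvious combinatorics: |within H| = C(n_H, 2),
    |H1_H2| = n_H1 * n_H2, |ALL| = C(sum n_H, 2).
    """
    unknown = sorted({h for h in groups.values() if h not in HABITATS})
    if unknown:
        raise ValueError(f"unknown habitat code(s): {unknown}")
    by_hab: dict[str, list[str]] = {h: [] for h in HABITATS}
    for pop, hab in groups.items():
        by_hab[hab].append(pop)
    out: list[PairSet] = []
    for h in HABITATS:
        out.append(PairSet(h, list(itertools.combinations(by_hab[h], 2))))
    cross = [("RA", "UA"), ("RA", "UP"), ("RA", "UR"), ("UA", "UP"), ("UA", "UR"), ("UP", "UR")]
    for h1, h2 in cross:
        out.append(
            PairSet(f"{h1}_{h2}", [(a, b) for a in by_hab[h1] for b in by_hab[h2]])
        )
    out.append(PairSet("ALL", list(itertools.combinations(groups, 2))))
    return out


def habitat_pair_resample(
    d: DistMatrix,
    categories: Sequence[PairSet],
    n_reps: int = 1000,
    seed: int = 0,
) -> dict[str, ResamplingResult]:
    """Resample one pair per category per replicate; report mean and 95% CI.

    Infinite entries are excluded from a category with a warning; an empty
    category raises.  The CI-overlap comparison across categories is the
    caller's (reporting) concern; this returns the per-category summaries.
    """
    import warnings

    rng = np.random.default_rng(seed)
    out: dict[str, ResamplingResult] = {}
    for cat in categories:
        vals = np.array([d.pair_value(a, b) for a, b in cat.pairs])
        finite = np.isfinite(vals)
        if not finite.all():
            warnings.warn(
                f"{cat.label}: {int((~finite).sum())} non-finite pair distances excluded",
                RuntimeWarning, stacklevel=2,
            )
            vals = vals[finite]
        if vals.size == 0:
            raise ValueError(f"category {cat.label} has no usable pairs")
        draws = vals[rng.integers(0, vals.size, n_reps)]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        out[cat.label] = ResamplingResult(
            float(draws.mean()), draws, float(lo), float(hi), None, n_reps, seed,
            "resampled_distance",
        )
    return out


def ci_overlap_matrix(results: Mapping[str, ResamplingResult]) -> "np.ndarray":
    """Boolean matrix: do the 95% CIs of category i and j overlap?"""
    labels = list(results)
    n = len(labels)
    out = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            ra, rb = results[a], results[b]
            out[i, j] = ra.ci_low <= rb.ci_high and rb.ci_low <= ra.ci_high
    return out
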