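"""Pairwise genetic differentiation (Nei's D, F_ST) and PCoA ordination.

Nei's (1972) standard genetic distance is D = -ln I with
I = J_AB / sqrt(J_A * J_B), where J_A, J_B and J_AB are means over shared
loci of sum(p_A^2), sum(p_B^2) and sum(p_A * p_B).  Loci undefined in either
population are excluded pairwise.  When I = 0 (populations fixed for
disjoint alleles at every shared locus) the distance is +inf, propagated as
a sentinel rather than capped.

F_ST defaults to the Nei / G_ST-style estimator (H_T - H_S)/H_T computed as
a ratio of locus sums, with H_S the mean within-population expected
heterozygosity and H_T from the mean allele frequencies; Weir & Cockerham's
theta is available for sensitivity analysis.

PCoA is classical metric MDS: Gower double-centering of squared distances
followed by an eigendecomposition; axes with positive eigenvalues are
retained and the negative-eigenvalue mass is reported (semimetric inputs
such as Bray-Curtis can produce negative eigenvalues).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import DistMatrix
from .diversity import AlleleFreqTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------

def _pair_freqs(
    f: AlleleFreqTable, popA: str, popB: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """ALT freqs and copy counts at loci defined in both populations."""
    ia, ib = f.pop_index(popA), f.pop_index(popB)
    shared = f.defined()[ia] & f.defined()[ib]
    if not shared.any():
        raise ValueError(f"no shared loci between {popA} and {popB}")
    pa = f.alt_copies[ia, shared] / f.total_copies[ia, shared]
    pb = f.alt_copies[ib, shared] / f.total_copies[ib, shared]
    return pa, pb, f.total_copies[ia, shared], f.total_copies[ib, shared]


def nei_distance(f: AlleleFreqTable, popA: str, popB: str) -> float:
    """Nei (1972) standard distance D = -ln(J_AB / sqrt(J_A J_B)); +inf if I = 0."""
    pa, pb, _, _ = _pair_freqs(f, popA, popB)
    ja = np.mean(pa ** 2 + (1 - pa) ** 2)
    jb = np.mean(pb ** 2 + (1 - pb) ** 2)
    jab = np.mean(pa * pb + (1 - pa) * (1 - pb))
    if jab == 0.0:
        return float("inf")
    return float(-np.log(jab / np.sqrt(ja * jb)))


def fst_pairwise(
    f: AlleleFreqTable, popA: str, popB: str, *, method: str = "nei"
) -> float:
    """Pairwise multilocus F_ST.

    ``method="nei"`` (default): (sum H_T - sum H_S) / sum H_T over shared
    loci.  ``method="wc"``: Weir & Cockerham (1984) theta (ratio of summed
    variance components), which uses the per-population heterozygote counts.
    If there is no variation at any shared locus, 0.0 is returned with a
    warning (F_ST is undefined).
    """
    if method == "nei":
        pa, pb, _, _ = _pair_freqs(f, popA, popB)
        hs = 0.5 * (2 * pa * (1 - pa) + 2 * pb * (1 - pb))
        pbar = 0.5 * (pa + pb)
        ht = 2 * pbar * (1 - pbar)
        sum_ht = ht.sum()
        if sum_ht == 0.0:
            warnings.warn(
                f"F_ST undefined for ({popA}, {popB}): no variation at shared loci; "
                "reporting 0.0",
                RuntimeWarning, stacklevel=2,
            )
            return 0.0
        return float((sum_ht - hs.sum()) / sum_ht)
    if method == "wc":
        return _weir_cockerham_theta(f, popA, popB)
    raise ValueError(f"unknown F_ST method {method!r}")


def _weir_cockerham_theta(f: AlleleFreqTable, popA: str, popB: str) -> float:
    """Weir & Cockerham (1984) theta for two populations, summed over loci."""
    ia, ib = f.pop_index(popA), f.pop_index(popB)
    shared = f.defined()[ia] & f.defined()[ib]
    if not shared.any():
        raise ValueError(f"no shared loci between {popA} and {popB}")
    r = 2.0
    n_i = np.stack(
        [f.called_genotypes[ia, shared], f.called_genotypes[ib, shared]]
    ).astype(float)  # (2, L) sample sizes in diploids
    p_i = np.stack(
        [
            f.alt_copies[ia, shared] / f.total_copies[ia, shared],
            f.alt_copies[ib, shared] / f.total_copies[ib, shared],
        ]
    )
    h_i = np.stack(
        [
            f.het_calls[ia, shared] / f.called_genotypes[ia, shared],
            f.het_calls[ib, shared] / f.called_genotypes[ib, shared],
        ]
    )
    nbar = n_i.mean(axis=0)
    nc = (n_i.sum(axis=0) - (n_i ** 2).sum(axis=0) / n_i.sum(axis=0)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / n_i.sum(axis=0)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / n_i.sum(axis=0)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = (a + b + c).sum()
    if denom == 0.0:
        warnings.warn(
            f"theta undefined for ({popA}, {popB}): no variation; reporting 0.0",
            RuntimeWarning, stacklevel=2,
        )
        return 0.0
    return float(a.sum() / denom)


def distance_matrix(f: AlleleFreqTable, metric: str = "nei", **kwargs) -> DistMatrix:
    """All-pairs genetic distance matrix; metric is "nei" or "fst"."""
    pops = f.populations
    n = len(pops)
    vals = np.zeros((n, n))
    fn = {"nei": nei_distance, "fst": fst_pairwise}.get(metric)
    if fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = fn(f, pops[i], pops[j], **kwargs)
    if not np.isfinite(vals).all():
        log.warning("distance_matrix: %d infinite entries (disjoint fixation)",
                    int((~np.isfinite(vals)).sum() // 2))
    return DistMatrix(list(pops), vals, kind=metric)


# ---------------------------------------------------------------------------
# Principal coordinate analysis
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Eigenvalues (descending), coordinates on positive axes, variance shares."""

    labels: list[str]
    eigenvalues: np.ndarray          # all eigenvalues, descending
    coordinates: np.ndarray          # (n, n_positive_axes)
    percent_variance: np.ndarray     # per retained axis, of positive mass
    negative_mass: float             # |sum of negative eigenvalues|
    correction: str = "none"

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(d: DistMatrix, correction: str = "none") -> PcoaResult:
    """Classical PCoA by Gower double-centering.

    B = -1/2 * C * D^2 * C with C the centering projector; axes with
    eigenvalues > tol are retained; percent variance is relative to the sum
    of positive eigenvalues.  `correction` in {"none", "lingoes",
    "cailliez"} makes semimetric inputs Euclidean-embeddable by adding a
    constant to squared distances (Lingoes) or distances (Cailliez).
    """
    if d.has_nonfinite():
        raise ValueError("PCoA requires finite distances; drop infinite pairs first")
    D = d.values.copy()
    n = d.n

    def center(dist: np.ndarray) -> np.ndarray:
        A = -0.5 * dist ** 2
        C = np.eye(n) - np.ones((n, n)) / n
        return C @ A @ C

    B = center(D)
    evals = np.linalg.eigvalsh(B)
    if correction == "lingoes":
        c1 = max(0.0, -evals.min())
        if c1 > 0:
            D2 = D ** 2 + 2 * c1
            np.fill_diagonal(D2, 0.0)
            B = -0.5 * (np.eye(n) - np.ones((n, n)) / n) @ D2 @ (
                np.eye(n) - np.ones((n, n)) / n
            )
    elif correction == "cailliez":
        # smallest root of the special eigenproblem (Cailliez 1983)
        A1 = -0.5 * D ** 2
        A2 = -0.5 * D
        zero = np.zeros((n, n))
        eye = np.eye(n)
        M = np.block([[zero, 2 * A1], [-eye, -4 * A2]])
        c2 = float(np.max(np.linalg.eigvals(M).real))
        if c2 > 0:
            Dc = D + c2
            np.fill_diagonal(Dc, 0.0)
            B = center(Dc)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * max(abs(evals[0]), 1.0)) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pos_sum = evals[pos].sum()
    pct = 100.0 * evals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    neg_mass = float(-evals[evals < -tol].sum())
    return PcoaResult(list(d.labels), evals, coords, pct, neg_mass, correction)
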