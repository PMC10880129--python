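"""Core in-memory containers shared by every analysis stage.

Genotypes are diploid and biallelic: each call is an unordered pair of
allele indices drawn from {0, 1} (REF/ALT), or missing.  Internally a call
is stored as the count of ALT copies (0, 1, 2) with ``MISSING = -1`` as the
sentinel, which makes every per-locus statistic a cheap masked-array
reduction.  Nothing downstream depends on nucleotide identity — all
statistics in this package are invariant to allele relabelling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel for a missing diploid genotype (both gene copies absent together).
MISSING: int = -1

#: The four habitat classes: rural agricultural, urban agricultural,
#: urban park and urban roadside.
HABITATS: tuple[str, ...] = ("RA", "UA", "UP", "UR")

#: Land-cover classes tabulated around each site.
LANDCOVER_CLASSES: tuple[str, ...] = ("developed", "agricultural", "forest", "grassland")

#: Buffer radii (metres) at which land-cover composition is tabulated.
RADII: tuple[int, ...] = (250, 500, 1000)


class ConsistencyError(ValueError):
    """Cross-file or cross-object inconsistency (unknown individual, bad label...)."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid biallelic genotype calls.

    Parameters
    ----------
    individual_ids
        Unique labels, one per row of `calls`.
    locus_ids
        Unique labels, one per column of `calls`.
    calls
        ``int8`` array of shape (n_individuals, n_loci); entries are ALT-copy
        counts 0/1/2 or :data:`MISSING`.
    pop_of
        Map individual id -> population id; every individual must be present.
    locus_groups
        Optional map locus id -> group tag (e.g. the assembly locus a SNP
        came from), used by the single-SNP-per-group filter.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    pop_of: dict[str, str]
    locus_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_ind, n_loc = self.calls.shape
        if len(self.individual_ids) != n_ind or len(self.locus_ids) != n_loc:
            raise ValueError("calls shape does not match id lists")
        if len(set(self.individual_ids)) != n_ind:
            raise ConsistencyError("duplicate individual ids")
        if len(set(self.locus_ids)) != n_loc:
            raise ConsistencyError("duplicate locus ids")
        missing_pop = [i for i in self.individual_ids if i not in self.pop_of]
        if missing_pop:
            raise ConsistencyError(f"individuals without a population: {missing_pop[:5]}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1, 2 or MISSING")

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        """Population ids in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.pop_of[ind], None)
        return list(seen)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each population's individuals."""
        out: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individual_ids):
            out.setdefault(self.pop_of[ind], []).append(i)
        return {p: np.asarray(v, dtype=int) for p, v in out.items()}

    def missing_fraction_per_individual(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def called_fraction_per_locus(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given individuals/loci (order kept)."""
        ind = list(individuals) if individuals is not None else self.individual_ids
        loc = list(loci) if loci is not None else self.locus_ids
        ind_idx = [self.individual_ids.index(i) for i in ind]
        loc_idx = [self.locus_ids.index(l) for l in loc]
        return GenotypeMatrix(
            individual_ids=ind,
            locus_ids=loc,
            calls=self.calls[np.ix_(ind_idx, loc_idx)].copy(),
            pop_of={i: self.pop_of[i] for i in ind},
            locus_groups={l: self.locus_groups[l] for l in loc if l in self.locus_groups},
        )


@dataclass
class PopulationMeta:
    """Site-level metadata: habitat class, coordinates, land-cover composition.

    `landcover` maps radius (m) -> dict of class -> area (m^2); a radius is
    either fully present (all four classes) or absent.
    """

    pop_id: str
    habitat: str
    lat: float
    lon: float
    landcover: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}; expected one of {HABITATS}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        for radius, areas in self.landcover.items():
            if int(radius) not in RADII:
                raise ValueError(f"unknown radius {radius}")
            if set(areas) != set(LANDCOVER_CLASSES):
                raise ValueError(
                    f"radius {radius} of {self.pop_id} must provide all classes "
                    f"{LANDCOVER_CLASSES}, got {sorted(areas)}"
                )
            for cls, a in areas.items():
                if a < 0:
                    raise ValueError(f"negative area {cls}_{radius} for {self.pop_id}")

    def landcover_vector(self, radius: int, classes: Sequence[str]) -> np.ndarray:
        if radius not in self.landcover:
            raise KeyError(f"population {self.pop_id} has no land cover at {radius} m")
        return np.array([self.landcover[radius][c] for c in classes], dtype=float)


@dataclass
class DistMatrix:
    """Labelled symmetric distance matrix with zero diagonal.

    `kind` records the metric ("nei", "fst", "geographic", "braycurtis", ...)
    so writers can annotate units.  Infinite entries are legal (the Nei-D
    sentinel for non-overlapping fixed alleles) and are propagated, not
    truncated; consumers that require finite input must drop those pairs.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ConsistencyError("duplicate labels")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        sym_ok = np.array_equal(finite, finite.T) and np.allclose(
            self.values[finite & finite.T],
            self.values.T[finite & finite.T],
            rtol=1e-9, atol=1e-12,
        )
        if not sym_ok:
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (row-major), the vector Mantel statistics use."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair_value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: Sequence[str]) -> "DistMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return DistMatrix(list(labels), self.values[np.ix_(idx, idx)].copy(), self.kind)

    def has_nonfinite(self) -> bool:
        return bool(~np.isfinite(self.condensed()).all())

    def drop_nonfinite_pairs(self) -> tuple["DistMatrix", list[str]]:
        """Drop the fewest labels needed to make all entries finite.

        Greedy: repeatedly remove the label involved in the most non-finite
        pairs.  Returns the reduced matrix and the dropped labels.
        """
        vals = self.values.copy()
        keep = list(range(self.n))
        dropped: list[str] = []
        while True:
            sub = vals[np.ix_(keep, keep)]
            bad = ~np.isfinite(sub)
            np.fill_diagonal(bad, False)
            if not bad.any():
                break
            counts = bad.sum(axis=1)
            worst = keep[int(np.argmax(counts))]
            dropped.append(self.labels[worst])
            keep.remove(worst)
        labels = [self.labels[i] for i in keep]
        return DistMatrix(labels, vals[np.ix_(keep, keep)], self.kind), dropped


def check_consistency(
    g: GenotypeMatrix, meta: Mapping[str, PopulationMeta]
) -> None:
    """Raise ConsistencyError if any genotyped population lacks metadata."""
    unknown = sorted(set(g.pop_of.values()) - set(meta))
    if unknown:
        raise ConsistencyError(f"populations without metadata: {unknown}")
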