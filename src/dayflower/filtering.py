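"""Genotype-matrix filters mirroring the Stacks *populations* stage.

Two entry points: :func:`drop_high_missing_samples` removes individuals with
too much missing data (strictly greater than the threshold), and
:func:`apply_locus_filters` applies the locus-level filters in the fixed
order coverage -> single-SNP-per-group -> minor-allele frequency ->
observed heterozygosity.  MAF and H_obs are computed over all individuals
pooled (global filtering, the p=1 convention), not per population.

Thresholds keep a locus when coverage >= r and maf >= min_maf and
H_obs <= max_obs_het; a sample is removed when its missing fraction is
> max_sample_missing.  Sample exclusion is intended to run before locus
filters (see :func:`filter_pipeline`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import MISSING, GenotypeMatrix


class EmptyResultError(ValueError):
    """Every sample or every locus was removed."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the locus/sample filters.

    Defaults replicate a Stacks run with -r 0.8 --min-maf 0.01
    --max-obs-het 0.95 --write-single-snp plus >40% sample exclusion.
    """

    min_maf: float = 0.01
    max_obs_het: float = 0.95
    min_locus_coverage: float = 0.8
    max_sample_missing: float = 0.40
    single_snp_per_locus_group: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        for name in ("max_obs_het", "min_locus_coverage", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-filter removal bookkeeping; removed + retained = input at each step."""

    order: list[str] = field(default_factory=list)
    removed: dict[str, list[str]] = field(default_factory=dict)
    n_input_individuals: int = 0
    n_input_loci: int = 0
    retained_individuals: list[str] = field(default_factory=list)
    retained_loci: list[str] = field(default_factory=list)

    def record(self, step: str, removed: list[str]) -> None:
        self.order.append(step)
        self.removed[step] = list(removed)

    @property
    def counts(self) -> dict[str, int]:
        return {step: len(ids) for step, ids in self.removed.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "order": self.order,
                "removed": self.removed,
                "counts": self.counts,
                "n_input_individuals": self.n_input_individuals,
                "n_input_loci": self.n_input_loci,
                "n_retained_individuals": len(self.retained_individuals),
                "n_retained_loci": len(self.retained_loci),
                "retained_individuals": self.retained_individuals,
                "retained_loci": self.retained_loci,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def drop_high_missing_samples(
    g: GenotypeMatrix, max_sample_missing: float = 0.40
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove individuals whose missing-call fraction exceeds the threshold.

    Strict inequality: a sample at exactly the threshold is retained.
    """
    if g.n_individuals == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    frac = g.missing_fraction_per_individual()
    keep_mask = frac <= max_sample_missing
    removed = [ind for ind, k in zip(g.individual_ids, keep_mask) if not k]
    kept = [ind for ind, k in zip(g.individual_ids, keep_mask) if k]
    if not kept:
        raise EmptyResultError("all samples exceed the missingness threshold")
    report = FilterReport(
        n_input_individuals=g.n_individuals, n_input_loci=g.n_loci,
        retained_loci=list(g.locus_ids),
    )
    report.record("sample_missing", removed)
    out = g.subset(individuals=kept)
    report.retained_individuals = list(out.individual_ids)
    return out, report


def apply_locus_filters(
    g: GenotypeMatrix, cfg: FilterConfig = FilterConfig()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply locus filters in the order coverage -> single-SNP -> maf -> het."""
    if g.n_individuals == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport(
        n_input_individuals=g.n_individuals, n_input_loci=g.n_loci,
        retained_individuals=list(g.individual_ids),
    )
    keep = list(g.locus_ids)
    calls = g.calls

    def col(lid: str) -> np.ndarray:
        return calls[:, g.locus_ids.index(lid)]

    # 1. coverage: called-genotype fraction across all individuals
    removed = [
        lid for lid in keep
        if (col(lid) != MISSING).mean() < cfg.min_locus_coverage
    ]
    report.record("coverage", removed)
    keep = [l for l in keep if l not in set(removed)]

    # 2. one SNP per locus group (keep first in input order)
    if cfg.single_snp_per_locus_group and g.locus_groups:
        seen: set[str] = set()
        removed = []
        kept2 = []
        for lid in keep:
            grp = g.locus_groups.get(lid, lid)
            if grp in seen:
                removed.append(lid)
            else:
                seen.add(grp)
                kept2.append(lid)
        report.record("single_snp", removed)
        keep = kept2
    else:
        report.record("single_snp", [])

    # 3. global minor-allele frequency over called gene copies
    removed = []
    for lid in keep:
        c = col(lid)
        called = c[c != MISSING]
        if called.size == 0:
            removed.append(lid)
            continue
        p_alt = called.sum() / (2 * called.size)
        if min(p_alt, 1.0 - p_alt) < cfg.min_maf:
            removed.append(lid)
    report.record("maf", removed)
    keep = [l for l in keep if l not in set(removed)]

    # 4. global observed heterozygosity
    removed = []
    for lid in keep:
        c = col(lid)
        called = c[c != MISSING]
        if called.size and (called == 1).mean() > cfg.max_obs_het:
            removed.append(lid)
    report.record("obs_het", removed)
    keep = [l for l in keep if l not in set(removed)]

    if not keep:
        raise EmptyResultError("no loci survived the filters")
    report.retained_loci = keep
    return g.subset(loci=keep), report


def filter_pipeline(
    g: GenotypeMatrix, cfg: FilterConfig = FilterConfig()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Sample exclusion first, then locus filters; one merged report."""
    g1, rep_s = drop_high_missing_samples(g, cfg.max_sample_missing)
    g2, rep_l = apply_locus_filters(g1, cfg)
    merged = FilterReport(
        n_input_individuals=g.n_individuals, n_input_loci=g.n_loci,
    )
    merged.record("sample_missing", rep_s.removed["sample_missing"])
    for step in rep_l.order:
        merged.record(step, rep_l.removed[step])
    merged.retained_individuals = list(g2.individual_ids)
    merged.retained_loci = list(g2.locus_ids)
    return g2, merged
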