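"""Readers and writers for the external formats the pipeline consumes.

Formats
-------
* VCF 4.x, GT field only, biallelic records (via cyvcf2).
* A genotype CSV dialect: rows are individuals, first two columns are
  ``individual_id`` and ``pop_id``, remaining columns one locus each with
  cells ``a/b`` (a, b in {0, 1}) or ``NA``.
* Metadata CSV: ``pop_id, habitat, lat, lon`` plus area columns named
  ``<class>_<radius>`` (e.g. ``developed_500``), areas in m^2.
* Distance matrices as labelled square TSV.

The CSV dialect is fixed (comma-separated, UTF-8, "NA" missing), not
sniffed.  Half-called VCF genotypes (one allele missing) are demoted to
MISSING and counted in the module logger.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    HABITATS,
    LANDCOVER_CLASSES,
    MISSING,
    RADII,
    ConsistencyError,
    DistMatrix,
    GenotypeMatrix,
    PopulationMeta,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message names the offending line/record."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    pop_of: Mapping[str, str],
    *,
    split_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    One locus per record; the record id (or "CHROM:POS" when id is missing)
    becomes the locus id and CHROM the locus group.  Multiallelic records
    raise ParseError unless `split_multiallelic` is set, in which case each
    ALT becomes its own pseudo-biallelic locus (non-matching alleles
    missing).  Phased and unphased separators are treated identically;
    half calls become MISSING.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_of]
    if unknown:
        raise ConsistencyError(f"VCF samples absent from metadata: {unknown}")

    locus_ids: list[str] = []
    groups: dict[str, str] = {}
    columns: list[np.ndarray] = []
    n_half = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if not split_multiallelic:
                raise ParseError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS} "
                    f"(ALT={','.join(rec.ALT)}); enable splitting or pre-split"
                )
            alts = list(rec.ALT)
        else:
            alts = [rec.ALT[0] if rec.ALT else None]
        gts = rec.genotypes  # [a0, a1, phased] per sample
        for alt_idx, _alt in enumerate(alts, start=1):
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, gt in enumerate(gts):
                a0, a1 = gt[0], gt[1]
                if a0 < 0 or a1 < 0:
                    if (a0 < 0) != (a1 < 0):
                        n_half += 1
                    continue
                col[i] = int(a0 == alt_idx) + int(a1 == alt_idx)
            base = rec.ID if rec.ID not in (None, ".", "") else f"{rec.CHROM}:{rec.POS}"
            lid = base if len(alts) == 1 else f"{base}_alt{alt_idx}"
            locus_ids.append(lid)
            groups[lid] = rec.CHROM
            columns.append(col)
    if n_half:
        log.info("read_vcf: %d half-called genotypes treated as MISSING", n_half)
    calls = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        individual_ids=samples,
        locus_ids=locus_ids,
        calls=calls,
        pop_of={s: pop_of[s] for s in samples},
        locus_groups=groups,
    )


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (REF=A, ALT=T placeholders; alleles are labels)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = {g.locus_groups.get(l, "1") for l in g.locus_ids}
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, lid in enumerate(g.locus_ids):
            chrom = g.locus_groups.get(lid, "1")
            cells = "\t".join(gt_str[int(c)] for c in g.calls[:, j])
            fh.write(f"{chrom}\t{j + 1}\t{lid}\tA\tT\t.\t.\t.\tGT\t{cells}\n")


# ---------------------------------------------------------------------------
# Genotype CSV dialect
# ---------------------------------------------------------------------------

_CELL_TO_CALL = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "NA": MISSING}


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read the genotype CSV dialect (see module docstring)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "individual_id" or header[1] != "pop_id":
            raise ParseError(
                f"{path}: header must start with individual_id,pop_id; got {header[:3]}"
            )
        locus_ids = header[2:]
        individual_ids: list[str] = []
        pop_of: dict[str, str] = {}
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            ind, pop = row[0], row[1]
            if ind in pop_of:
                raise ParseError(f"{path}:{lineno}: duplicate individual_id {ind!r}")
            calls_row = []
            for lid, cell in zip(locus_ids, row[2:]):
                try:
                    calls_row.append(_CELL_TO_CALL[cell.strip()])
                except KeyError:
                    raise ParseError(
                        f"{path}:{lineno}: bad genotype cell {cell!r} at locus {lid}"
                    ) from None
            individual_ids.append(ind)
            pop_of[ind] = pop
            rows.append(calls_row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return GenotypeMatrix(
        individual_ids=individual_ids,
        locus_ids=list(locus_ids),
        calls=np.array(rows, dtype=np.int8),
        pop_of=pop_of,
    )


def write_genotype_csv(g: GenotypeMatrix, path: str | Path) -> None:
    call_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "NA"}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id", "pop_id"] + g.locus_ids)
        for i, ind in enumerate(g.individual_ids):
            writer.writerow(
                [ind, g.pop_of[ind]] + [call_str[int(c)] for c in g.calls[i]]
            )


# ---------------------------------------------------------------------------
# Metadata CSV
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, PopulationMeta]:
    """Read the population metadata table.

    Area columns are named ``<class>_<radius>``; a radius with any class
    present must provide all four classes.
    """
    df = pd.read_csv(path, dtype={"pop_id": str, "habitat": str})
    required = {"pop_id", "habitat", "lat", "lon"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    area_cols: dict[int, dict[str, str]] = {}
    for col in df.columns:
        if "_" not in col:
            continue
        cls, _, rad = col.rpartition("_")
        if cls in LANDCOVER_CLASSES and rad.isdigit():
            area_cols.setdefault(int(rad), {})[cls] = col
    for rad, cols in area_cols.items():
        if rad not in RADII:
            raise ParseError(f"{path}: unknown radius column(s) for {rad} m")
        if set(cols) != set(LANDCOVER_CLASSES):
            raise ParseError(
                f"{path}: radius {rad} has columns for {sorted(cols)} only; "
                f"all of {LANDCOVER_CLASSES} are required"
            )
    out: dict[str, PopulationMeta] = {}
    for _, row in df.iterrows():
        pid = str(row["pop_id"])
        if pid in out:
            raise ParseError(f"{path}: duplicate pop_id {pid!r}")
        landcover = {
            rad: {cls: float(row[col]) for cls, col in cols.items()}
            for rad, cols in area_cols.items()
            if not any(pd.isna(row[col]) for col in cols.values())
        }
        out[pid] = PopulationMeta(
            pop_id=pid,
            habitat=str(row["habitat"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            landcover=landcover,
        )
    return out


def write_metadata(meta: Mapping[str, PopulationMeta], path: str | Path) -> None:
    radii = sorted({r for m in meta.values() for r in m.landcover})
    cols = ["pop_id", "habitat", "lat", "lon"] + [
        f"{cls}_{rad}" for rad in radii for cls in LANDCOVER_CLASSES
    ]
    rows = []
    for m in meta.values():
        row: dict[str, object] = {
            "pop_id": m.pop_id, "habitat": m.habitat, "lat": m.lat, "lon": m.lon,
        }
        for rad in radii:
            for cls in LANDCOVER_CLASSES:
                row[f"{cls}_{rad}"] = m.landcover.get(rad, {}).get(cls, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def write_distmatrix(d: DistMatrix, path: str | Path, *, comment: str = "") -> None:
    """Write a labelled square TSV; `comment` (e.g. radius/classes) goes in a # header."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"# kind={d.kind}\n")
        fh.write("\t" + "\t".join(d.labels) + "\n")
        for i, lab in enumerate(d.labels):
            fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in d.values[i]) + "\n")


def read_distmatrix(path: str | Path) -> DistMatrix:
    kind = "generic"
    with open(path, encoding="utf-8") as fh:
        lines = []
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("kind="):
                    kind = stripped[5:]
                continue
            lines.append(line.rstrip("\n"))
    labels = lines[0].split("\t")[1:]
    values = np.array(
        [[float(x) for x in line.split("\t")[1:]] for line in lines[1:]], dtype=float
    )
    return DistMatrix(labels, values, kind)
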