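"""Config-driven orchestration of the full analysis sequence.

:func:`run_pipeline` executes, in order: input loading (or simulation) ->
sample/locus filtering -> per-population diversity and Hardy-Weinberg
testing -> Nei/F_ST distance matrices and their Mantel agreement -> PCoA ->
geographic and landscape distance matrices -> within-habitat Mantel tests
(with a partial-Mantel geographic covariate for the landscape analyses) ->
cross-habitat correlation CIs for all six habitat pairings -> all-pairs
landscape Mantel tests at the three buffer radii with best-radius selection
by Mantel r -> habitat-pair resampling CIs -> GLM habitat comparisons and
AIC landscape-scale selection.

Every artifact is written into the run directory as CSV/TSV/JSON along
with a manifest (config, seed, input hashes, stage log) sufficient to
reproduce the run exactly.  Stages that need the land-cover table are
skipped with a warning when it is absent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import HABITATS, RADII, DistMatrix, GenotypeMatrix, check_consistency
from .differentiation import distance_matrix, pcoa
from .diversity import allele_frequencies, diversity_table, hwe_exact_test
from .filtering import FilterConfig, filter_pipeline
from .glm import fit_gaussian_glm, select_landscape_scale, selection_report
from .io import (
    read_genotype_csv,
    read_metadata,
    read_vcf,
    write_distmatrix,
    write_genotype_csv,
    write_metadata,
)
from .resampling import (
    build_pair_sets,
    cross_group_correlation_ci,
    habitat_pair_resample,
    mantel,
    partial_mantel,
)
from .spatial import DEFAULT_BC_CLASSES, geographic_distance, landscape_distance

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "scenario": None,          # name in the scenario library, or None
    "genotype_csv": None,
    "vcf": None,
    "metadata_csv": None,
    "seed": 0,
    "n_perm": 999,
    "n_resample": 1000,
    "rarefaction_copies": 5,
    "filters": {},             # overrides for FilterConfig fields
    "bc_classes": list(DEFAULT_BC_CLASSES),
    "bc_radius": 500,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _res_row(name: str, r) -> dict[str, Any]:
    return {
        "test": name,
        "statistic": r.statistic,
        "observed": r.observed,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "p": r.p if r.p is not None else np.nan,
        "significant": r.significant,
        "n_reps": r.n_reps,
        "seed": r.seed,
    }


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory path."""
    import yaml

    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict[str, Any]] = []
    input_hashes: dict[str, str] = {}

    def stage(name: str, **info: Any) -> None:
        log.info("stage %s: %s", name, info)
        stages.append({"stage": name, **info})

    # ---- inputs ----------------------------------------------------------
    try:
        if cfg["scenario"]:
            from .simulate import scenario_library, simulate

            scn = scenario_library(cfg["scenario"], seed)
            g, meta, truth = simulate(scn)
            write_genotype_csv(g, out / "genotypes.csv")
            write_metadata(meta, out / "metadata.csv")
            (out / "truth.json").write_text(json.dumps(truth), encoding="utf-8")
            stage("simulate", scenario=cfg["scenario"],
                  n_individuals=g.n_individuals, n_loci=g.n_loci)
        else:
            if not cfg["metadata_csv"]:
                raise PipelineError("inputs: metadata_csv required without a scenario")
            meta = read_metadata(cfg["metadata_csv"])
            input_hashes["metadata_csv"] = _sha256(Path(cfg["metadata_csv"]))
            if cfg["genotype_csv"]:
                g = read_genotype_csv(cfg["genotype_csv"])
                input_hashes["genotype_csv"] = _sha256(Path(cfg["genotype_csv"]))
            elif cfg["vcf"]:
                pop_of = _pop_of_from_samples_file(cfg)
                g = read_vcf(cfg["vcf"], pop_of)
                input_hashes["vcf"] = _sha256(Path(cfg["vcf"]))
            else:
                raise PipelineError("inputs: provide genotype_csv or vcf")
            stage("load", n_individuals=g.n_individuals, n_loci=g.n_loci)
        check_consistency(g, meta)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"inputs: {exc}") from exc

    has_landcover = all(
        all(r in meta[p].landcover for r in RADII) for p in set(g.pop_of.values())
    )
    if not has_landcover:
        log.warning("land-cover table incomplete: landscape stages will be skipped")

    # ---- filtering -------------------------------------------------------
    try:
        fcfg = FilterConfig(**cfg["filters"])
        g_f, report = filter_pipeline(g, fcfg)
        report.to_json(out / "filter_report.json")
        write_genotype_csv(g_f, out / "genotypes_filtered.csv")
        stage("filter", loci_in=g.n_loci, loci_out=g_f.n_loci,
              individuals_in=g.n_individuals, individuals_out=g_f.n_individuals)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"filter: {exc}") from exc

    pops = g_f.populations
    groups = {p: meta[p].habitat for p in pops}

    # ---- diversity + HWE -------------------------------------------------
    try:
        div = diversity_table(g_f, rarefaction_copies=int(cfg["rarefaction_copies"]))
        div_out = div.copy()
        div_out.insert(0, "habitat", [groups[p] for p in div.index])
        div_out.to_csv(out / "diversity.csv")
        hwe = hwe_exact_test(g_f)
        hwe_rows = [
            {
                "population": pop,
                "deviating_fraction": res.deviating_fraction,
                "n_testable": int((~res.monomorphic & np.isfinite(res.p_two_sided)).sum()),
                "homozygote_excess_fraction": float(
                    res.homozygote_excess[~res.monomorphic].mean()
                ) if (~res.monomorphic).any() else np.nan,
            }
            for pop, res in hwe.items()
        ]
        pd.DataFrame(hwe_rows).to_csv(out / "hwe.csv", index=False)
        stage("diversity", n_populations=len(div))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"diversity: {exc}") from exc

    # ---- genetic distances ----------------------------------------------
    try:
        freqs = allele_frequencies(g_f)
        nei = distance_matrix(freqs, "nei")
        fst = distance_matrix(freqs, "fst")
        write_distmatrix(nei, out / "nei.tsv")
        write_distmatrix(fst, out / "fst.tsv")
        nei_use, dropped = (
            nei.drop_nonfinite_pairs() if nei.has_nonfinite() else (nei, [])
        )
        if dropped:
            log.warning("dropped %s from matrix analyses (infinite Nei D)", dropped)
        mantel_rows = []
        r_nei_fst = mantel(
            nei_use, fst.reorder(nei_use.labels), int(cfg["n_perm"]), seed
        )
        mantel_rows.append(_res_row("nei_vs_fst", r_nei_fst))
        stage("distances", dropped=dropped, nei_vs_fst_r=r_nei_fst.observed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"distances: {exc}") from exc

    # ---- PCoA ------------------------------------------------------------
    try:
        ord_ = pcoa(nei_use)
        pd.DataFrame(
            ord_.coordinates, index=ord_.labels,
            columns=[f"Axis{i + 1}" for i in range(ord_.n_axes)],
        ).to_csv(out / "pcoa_coordinates.csv")
        pd.DataFrame(
            {"eigenvalue": ord_.eigenvalues[: ord_.n_axes],
             "percent_variance": ord_.percent_variance}
        ).to_csv(out / "pcoa_eigen.csv", index=False)
        stage("pcoa", axes=ord_.n_axes,
              axis1_pct=float(ord_.percent_variance[0]) if ord_.n_axes else np.nan)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"pcoa: {exc}") from exc

    # ---- spatial matrices ------------------------------------------------
    try:
        meta_used = {p: meta[p] for p in nei_use.labels}
        geo = geographic_distance(meta_used)
        write_distmatrix(geo, out / "geographic.tsv")
        bc_by_radius: dict[int, DistMatrix] = {}
        if has_landcover:
            for radius in RADII:
                bc = landscape_distance(meta_used, radius, cfg["bc_classes"])
                bc_by_radius[radius] = bc
                write_distmatrix(
                    bc, out / f"landscape_{radius}.tsv",
                    comment=f"radius={radius}m classes={','.join(cfg['bc_classes'])}",
                )
        stage("spatial", radii=sorted(bc_by_radius))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"spatial: {exc}") from exc

    # ---- within-habitat tests -------------------------------------------
    try:
        for hab in HABITATS:
            members = [p for p in nei_use.labels if groups[p] == hab]
            if len(members) < 4:
                continue
            sub_nei = _submatrix(nei_use, members)
            sub_geo = _submatrix(geo, members)
            res = mantel(sub_nei, sub_geo, int(cfg["n_perm"]), seed)
            mantel_rows.append(_res_row(f"within_{hab}_ibd", res))
            if bc_by_radius:
                sub_bc = _submatrix(bc_by_radius[int(cfg["bc_radius"])], members)
                res = partial_mantel(sub_nei, sub_bc, sub_geo, int(cfg["n_perm"]), seed)
                mantel_rows.append(_res_row(f"within_{hab}_landscape_partial", res))
        stage("within_habitat", n_tests=len(mantel_rows) - 1)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"within_habitat: {exc}") from exc

    # ---- cross-habitat correlation CIs ----------------------------------
    try:
        cross_rows = []
        pairings = [("RA", "UA"), ("RA", "UP"), ("RA", "UR"),
                    ("UA", "UP"), ("UA", "UR"), ("UP", "UR")]
        for g1, g2 in pairings:
            for label, mat in [("geographic", geo)] + (
                [("landscape", bc_by_radius[int(cfg["bc_radius"])])] if bc_by_radius else []
            ):
                try:
                    res = cross_group_correlation_ci(
                        nei_use, mat, groups, g1, g2, int(cfg["n_resample"]), seed
                    )
                except ValueError as ve:
                    log.warning("cross-group %s_%s (%s) skipped: %s", g1, g2, label, ve)
                    continue
                row = _res_row(f"{g1}_{g2}_{label}", res)
                cross_rows.append(row)
        pd.DataFrame(cross_rows).to_csv(out / "cross_group.csv", index=False)
        stage("cross_group", n_tests=len(cross_rows))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"cross_group: {exc}") from exc

    # ---- landscape scale by Mantel r ------------------------------------
    try:
        best_radius = None
        if bc_by_radius:
            radius_rows = []
            for radius, bc in bc_by_radius.items():
                res = mantel(nei_use, bc, int(cfg["n_perm"]), seed)
                radius_rows.append({"radius": radius, **_res_row(f"landscape_{radius}", res)})
                mantel_rows.append(_res_row(f"landscape_all_pairs_{radius}", res))
            best_radius = max(radius_rows, key=lambda r: r["observed"])["radius"]
            pd.DataFrame(radius_rows).to_csv(out / "landscape_scale_mantel.csv", index=False)
        pd.DataFrame(mantel_rows).to_csv(out / "mantel.csv", index=False)
        stage("landscape_scale", best_radius=best_radius)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"landscape_scale: {exc}") from exc

    # ---- habitat-pair resampling CIs ------------------------------------
    try:
        categories = build_pair_sets({p: groups[p] for p in nei_use.labels})
        categories = [c for c in categories if c.pairs]
        resample = habitat_pair_resample(
            nei_use, categories, int(cfg["n_resample"]), seed
        )
        pd.DataFrame(
            [
                {"category": lab, "mean": r.observed,
                 "ci_low": r.ci_low, "ci_high": r.ci_high, "n_pairs": len(c.pairs)}
                for (lab, r), c in zip(resample.items(), categories)
            ]
        ).to_csv(out / "pair_resample.csv", index=False)
        stage("pair_resample", n_categories=len(resample))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"pair_resample: {exc}") from exc

    # ---- GLMs ------------------------------------------------------------
    try:
        habitats = [groups[p] for p in div.index]
        glm_rows = []
        for metric in div.columns:
            y = div[metric].to_numpy(dtype=float)
            if np.isnan(y).any():
                log.warning("GLM: metric %s has NaN values; those rows dropped", metric)
            ok = np.isfinite(y)
            fit = fit_gaussian_glm(
                y[ok], habitat=[h for h, k in zip(habitats, ok) if k], response=metric
            )
            for name in fit.coefficients.index:
                glm_rows.append(
                    {"metric": metric, "term": name,
                     "estimate": fit.coefficients[name], "se": fit.std_errors[name],
                     "t": fit.t_values[name], "p": fit.p_values[name]}
                )
        pd.DataFrame(glm_rows).to_csv(out / "glm_habitat.csv", index=False)
        if has_landcover:
            sel = select_landscape_scale(div.dropna(), {p: meta[p] for p in div.index})
            selection_report(sel).to_csv(out / "glm_scale_selection.csv")
        stage("glm", n_metrics=len(div.columns))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"glm: {exc}") from exc

    # ---- manifest --------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "input_hashes": input_hashes,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str),
                                       encoding="utf-8")
    return out


def _pop_of_from_samples_file(cfg: Mapping[str, Any]) -> dict[str, str]:
    path = cfg.get("samples_csv")
    if not path:
        raise PipelineError("inputs: samples_csv (individual_id,pop_id) required with a VCF")
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["individual_id"], df["pop_id"]))


def _submatrix(d: DistMatrix, labels: list[str]) -> DistMatrix:
    idx = [d.labels.index(l) for l in labels]
    return DistMatrix(labels, d.values[np.ix_(idx, idx)].copy(), d.kind)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(run_dir: str | Path, *, plots: bool = False) -> Path:
    """Assemble a markdown summary from a completed run directory."""
    run = Path(run_dir)
    required = ["diversity.csv", "mantel.csv", "pair_resample.csv", "manifest.json"]
    missing = [f for f in required if not (run / f).exists()]
    if missing:
        raise PipelineError(f"report: incomplete run, missing {missing}")
    manifest = json.loads((run / "manifest.json").read_text(encoding="utf-8"))
    lines = [
        "# Pipeline run summary",
        "",
        f"Seed: {manifest['seed']}  |  Version: {manifest['version']}",
        "",
        "## Genetic diversity per population",
        "",
        pd.read_csv(run / "diversity.csv", index_col=0).round(4).to_markdown(),
        "",
        "## Mantel tests",
        "",
        pd.read_csv(run / "mantel.csv").round(4).to_markdown(index=False),
        "",
        "## Habitat-pair resampled Nei distances (means with 95% CIs)",
        "",
        pd.read_csv(run / "pair_resample.csv").round(4).to_markdown(index=False),
    ]
    if (run / "pcoa_eigen.csv").exists():
        eig = pd.read_csv(run / "pcoa_eigen.csv")
        lines += ["", "## PCoA variance explained", ""]
        lines.append(eig.head(5).round(3).to_markdown(index=False))
    if (run / "cross_group.csv").exists():
        lines += ["", "## Cross-habitat correlations", "",
                  pd.read_csv(run / "cross_group.csv").round(4).to_markdown(index=False)]
    if (run / "glm_scale_selection.csv").exists():
        lines += ["", "## Landscape-scale AIC selection", "",
                  pd.read_csv(run / "glm_scale_selection.csv").round(3).to_markdown(index=False)]
    if plots:
        _report_plots(run)
        lines += ["", "Plots written alongside this summary."]
    out = run / "summary.md"
    out.write_text("\n".join(lines), encoding="utf-8")
    return out


def _report_plots(run: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    div = pd.read_csv(run / "diversity.csv", index_col=0)
    metrics = [c for c in div.columns if c != "habitat"]
    fig, axes = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 3))
    for ax, col in zip(np.atleast_1d(axes), metrics):
        if "habitat" in div.columns:
            habs = [h for h in ("RA", "UA", "UP", "UR") if (div["habitat"] == h).any()]
            ax.boxplot([div.loc[div["habitat"] == h, col].dropna() for h in habs],
                       tick_labels=habs)
        else:
            ax.boxplot(div[col].dropna())
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(run / "diversity_boxplots.png", dpi=100)
    plt.close(fig)
    if (run / "pcoa_coordinates.csv").exists():
        coords = pd.read_csv(run / "pcoa_coordinates.csv", index_col=0)
        if coords.shape[1] >= 2:
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1])
            for lab, row in coords.iterrows():
                ax.annotate(str(lab), (row.iloc[0], row.iloc[1]), fontsize=6)
            ax.set_xlabel("Axis 1")
            ax.set_ylabel("Axis 2")
            fig.tight_layout()
            fig.savefig(run / "pcoa.png", dpi=100)
            plt.close(fig)
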