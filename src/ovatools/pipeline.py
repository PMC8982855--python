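"""End-to-end analyses: ovary transcriptome, knockdown-cell transcriptome,
and ChIP interval/repeat analysis.

Each runner is a pure composition of module operations: filter -> normalize
-> DE (consistency contract) -> shrink -> RPKM -> ectopic calls -> tissue
classification joins -> percentile enrichment -> cluster summary for the
transcriptome runs; mock subtraction -> merge -> TSS annotation -> density
profile -> bin coverage -> randomized overlap enrichment -> repeat
enrichment for ChIP. Every run writes its tables as TSV plus a JSON
manifest recording the seed, thresholds and per-stage feature counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .de import (
    DEConfig,
    consistent_de_call,
    repeat_enrichment,
    rpkm,
    size_factors_median_of_ratios,
    DesignSpec,
    NBDifferentialExpression,
)
from .ectopic import EctopicConfig, EctopicExpressionModel
from .enrichment import GeneSetCollection, cluster_lfc_summary, percentile_enrichment, set_overlap
from .intervals import (
    Workspace,
    annotate_tss,
    bin_coverage,
    density_profile,
    merge_intervals,
    randomized_overlap_enrichment,
    subtract_whole,
)
from .io import CountMatrix, write_peaks
from .normalize import normalize_counts
from .tau import ExpressionAtlas, TauConfig, TissueSpecificityModel


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


def run_ovary_analysis(
    cm: CountMatrix,
    atlas: ExpressionAtlas,
    cluster: pd.DataFrame | None,
    outdir: str | Path,
    seed: int = 0,
    tau_config: TauConfig | None = None,
    de_config: DEConfig | None = None,
    ectopic_config: EctopicConfig | None = None,
    pct: float = 0.01,
    genotype_factor: str = "genotype",
    age_factor: str = "age",
    wt_level: str = "WT",
) -> dict:
    """Full 2x2 ovary transcriptome analysis. Returns the report bundle.

    ``cluster``: optional frame indexed by gene id with start/end columns
    (the co-located testis-like gene cluster of interest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de_config = de_config or DEConfig(alpha=0.01)
    tau_config = tau_config or TauConfig()
    ectopic_config = ectopic_config or EctopicConfig()
    manifest: dict = {
        "analysis": "ovary",
        "version": __version__,
        "seed": seed,
        "thresholds": {
            "de_alpha": de_config.alpha,
            "tau": tau_config.tau_threshold,
            "ectopic_q": ectopic_config.ectopic_q_max,
            "pct": pct,
        },
        "stages": {},
    }
    manifest["stages"]["input"] = {"features": cm.shape[0], "samples": cm.shape[1]}

    kept, norm = _stage("normalize")(normalize_counts)(cm)
    manifest["stages"]["low_count_filter"] = {"kept": kept.shape[0]}

    de_table = _stage("differential_expression")(consistent_de_call)(
        kept, offsets=norm.offsets, genotype_factor=genotype_factor,
        age_factor=age_factor, alpha=de_config.alpha, config=de_config,
    )
    de_table.to_csv(outdir / "de_genes.tsv", sep="\t", index_label="feature_id")
    manifest["stages"]["de"] = {
        "tested": int(de_table["wald_p"].notna().sum()),
        "called": int(de_table["called"].sum()),
    }

    # RPKM without low-count removal; WT/mutant split over all ages
    sf = size_factors_median_of_ratios(cm.counts)
    rpkm_all = _stage("rpkm")(rpkm)(cm.counts, cm.feature_meta["length"], sf)
    meta = cm.sample_meta
    wt_samples = meta.index[meta[genotype_factor].astype(str) == wt_level]
    mut_samples = meta.index[meta[genotype_factor].astype(str) != wt_level]
    ect = _stage("ectopic")(
        lambda: EctopicExpressionModel(
            rpkm_all[list(wt_samples)], rpkm_all[list(mut_samples)], ectopic_config
        ).fit()
    )()
    ect.frame.to_csv(outdir / "ectopic_calls.tsv", sep="\t", index_label="gene_id")
    manifest["stages"]["ectopic"] = {
        "silent_in_wt": int(ect.frame["silent_in_wt"].sum()),
        "bh_family": ect.bh_family_size,
        "ectopic": int(ect.frame["is_ectopic"].sum()),
    }

    tc = _stage("tissue_classification")(
        lambda: TissueSpecificityModel(atlas, tau_config).fit()
    )()
    tc.to_frame().to_csv(outdir / "tissue_classes.tsv", sep="\t")
    manifest["stages"]["tissue_classification"] = {
        k: int(v) for k, v in tc.status_counts.items()
    }

    universe = set(kept.feature_ids)
    sets = GeneSetCollection(tc.gene_sets(), universe)
    lfc = de_table["lfc_shrunk"].dropna()
    enr = _stage("percentile_enrichment")(percentile_enrichment)(lfc, sets, pct)
    enr.to_csv(outdir / "percentile_enrichment.tsv", sep="\t", index=False)

    bundle = {
        "de": de_table,
        "ectopic": ect,
        "tissue_classification": tc,
        "enrichment": enr,
        "rpkm": rpkm_all,
        "normalization": norm,
    }
    if cluster is not None and len(cluster):
        summary = _stage("cluster_summary")(cluster_lfc_summary)(
            lfc, cluster, ectopic_genes=set(ect.ectopic_genes), lfc_all=lfc
        )
        bundle["cluster_summary"] = summary
        manifest["stages"]["cluster"] = {
            "n_genes": summary["n_genes"],
            "mean_lfc": summary["mean_lfc"],
            "genome_mean_lfc": summary["genome_mean_lfc"],
        }
    _write_manifest(outdir, manifest)
    bundle["manifest"] = manifest
    return bundle


def run_s2_analysis(
    cm: CountMatrix,
    outdir: str | Path,
    seed: int = 0,
    de_config: DEConfig | None = None,
    ectopic_config: EctopicConfig | None = None,
    condition_factor: str = "genotype",
    control_level: str = "WT",
    other_ectopic: set[str] | None = None,
) -> dict:
    """Two-condition (knockdown vs control) transcriptome analysis.

    Same stages as the ovary run minus the age factor; when
    ``other_ectopic`` is supplied the overlap of the two ectopic gene sets
    is reported.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de_config = de_config or DEConfig(alpha=0.01)
    ectopic_config = ectopic_config or EctopicConfig()
    meta = cm.sample_meta
    levels = meta[condition_factor].astype(str)
    if min((levels == lv).sum() for lv in levels.unique()) < 2:
        raise PipelineError("stage 'input' failed: need >= 2 replicates per condition")

    manifest: dict = {
        "analysis": "s2",
        "version": __version__,
        "seed": seed,
        "thresholds": {"de_alpha": de_config.alpha,
                       "ectopic_q": ectopic_config.ectopic_q_max},
        "stages": {"input": {"features": cm.shape[0], "samples": cm.shape[1]}},
    }
    kept, norm = _stage("normalize")(normalize_counts)(cm)
    manifest["stages"]["low_count_filter"] = {"kept": kept.shape[0]}

    model = NBDifferentialExpression(
        kept,
        DesignSpec(condition_factor, reference_levels={condition_factor: control_level}),
        offsets=norm.offsets,
        config=de_config,
    )
    res = _stage("differential_expression")(model.fit)()
    res.frame.to_csv(outdir / "de_genes.tsv", sep="\t", index_label="feature_id")
    manifest["stages"]["de"] = {"called": int((res.frame["fdr"] < de_config.alpha).sum())}

    sf = size_factors_median_of_ratios(cm.counts)
    rpkm_all = rpkm(cm.counts, cm.feature_meta["length"], sf)
    ctrl = meta.index[levels == control_level]
    treat = meta.index[levels != control_level]
    ect = _stage("ectopic")(
        lambda: EctopicExpressionModel(
            rpkm_all[list(ctrl)], rpkm_all[list(treat)], ectopic_config
        ).fit()
    )()
    ect.frame.to_csv(outdir / "ectopic_calls.tsv", sep="\t", index_label="gene_id")
    manifest["stages"]["ectopic"] = {"ectopic": int(ect.frame["is_ectopic"].sum())}

    bundle = {"de": res, "ectopic": ect, "rpkm": rpkm_all}
    if other_ectopic is not None:
        ov = set_overlap(set(ect.ectopic_genes), set(other_ectopic))
        bundle["ectopic_overlap"] = ov
        manifest["stages"]["ectopic_overlap"] = ov
    _write_manifest(outdir, manifest)
    bundle["manifest"] = manifest
    return bundle


def run_chip_analysis(
    ip_peaks: dict,
    mock_peaks: list,
    gene_models: list,
    workspace: Workspace,
    repeat_counts: CountMatrix | None,
    outdir: str | Path,
    seed: int = 0,
    tss_window: int = 1000,
    profile_flank: int = 2000,
    profile_bin: int = 50,
    coverage_bin: int = 100_000,
    n_sims: int = 1000,
    reference_peaks: dict | None = None,
) -> dict:
    """ChIP peak/interval analysis from post-IDR peak sets.

    ``ip_peaks`` maps (antibody, replicate) -> peak list; peaks overlapping
    any mock peak are removed whole, the survivors merged into the final
    union peak set, then annotated and profiled. ``reference_peaks``
    optionally maps name -> peak list for randomized overlap enrichment.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "analysis": "chip",
        "version": __version__,
        "seed": seed,
        "thresholds": {"tss_window": tss_window, "coverage_bin": coverage_bin},
        "stages": {},
    }
    blacklist = [p for mock in mock_peaks for p in mock]
    filtered = {}
    for key, peaks in ip_peaks.items():
        filtered[key] = _stage("mock_subtraction")(subtract_whole)(peaks, blacklist)
    manifest["stages"]["mock_subtraction"] = {
        f"{k[0]}_rep{k[1]}": {"in": len(ip_peaks[k]), "out": len(filtered[k])}
        for k in ip_peaks
    }
    union = _stage("merge")(merge_intervals)(
        [p for peaks in filtered.values() for p in peaks]
    )
    write_peaks(union, outdir / "final_peaks.bed", dialect="bed6")
    manifest["stages"]["merge"] = {"final_peaks": len(union)}

    ann = _stage("tss_annotation")(annotate_tss)(union, gene_models, tss_window)
    ann.to_csv(outdir / "tss_annotation.tsv", sep="\t")
    manifest["stages"]["tss_annotation"] = {"bound_genes": int(ann["bound"].sum())}

    # profile summits of the per-replicate filtered peaks (the union merge
    # discards summits)
    all_filtered = [p for peaks in filtered.values() for p in peaks]
    profile = _stage("density_profile")(density_profile)(
        all_filtered, gene_models, flank=profile_flank, bin_size=profile_bin
    )
    profile.to_csv(outdir / "tss_profile.tsv", sep="\t", index=False)
    modal = profile.loc[profile["count"].idxmax()]
    manifest["stages"]["density_profile"] = {
        "modal_bin": [int(modal["bin_start"]), int(modal["bin_end"])]
    }

    cov = _stage("bin_coverage")(bin_coverage)(union, workspace, coverage_bin)
    cov.to_csv(outdir / "bin_coverage.tsv", sep="\t", index=False)

    bundle = {
        "final_peaks": union,
        "tss_annotation": ann,
        "profile": profile,
        "bin_coverage": cov,
    }
    if reference_peaks:
        enrich = {}
        for name, ref in reference_peaks.items():
            enrich[name] = _stage("overlap_enrichment")(
                randomized_overlap_enrichment
            )(union, ref, workspace, n_sims=n_sims, seed=seed)
        bundle["overlap_enrichment"] = enrich
        manifest["stages"]["overlap_enrichment"] = {
            name: {
                "observed": e.observed_overlap,
                "expected": e.expected_overlap,
                "fold": e.fold_enrichment,
                "p": e.empirical_p,
            }
            for name, e in enrich.items()
        }
    if repeat_counts is not None:
        rep = _stage("repeat_enrichment")(repeat_enrichment)(repeat_counts)
        rep.to_csv(outdir / "repeat_enrichment.tsv", sep="\t",
                   index_label="feature_id")
        bundle["repeat_enrichment"] = rep
        manifest["stages"]["repeat_enrichment"] = {
            "repeats": len(rep),
            "enriched": int(rep["enriched"].sum()),
        }
    _write_manifest(outdir, manifest)
    bundle["manifest"] = manifest
    return bundle
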