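"""Synthetic data with planted ground truth.

Generates the three kinds of input the analysis consumes — a tissue
expression atlas, ovary-style 2x2 RNA-seq count matrices, and a ChIP
experiment (peaks, gene models, repeat/bin counts) — with known planted
structure so every downstream stage can be tested by parameter recovery:

* atlas: log-normal background expression roughly even across tissues,
  planted tissue-specific genes elevated ~16-fold in one tissue over a low
  baseline, and a planted NotExpressed fraction below RPKM 2 everywhere;
* ovary counts: NB(mu * depth * gc_bias, alpha) with per-sample smooth
  quadratic GC bias, planted genotype DE at the same log2 fold-change in
  both ages, planted ectopic genes (WT RPKM < 0.5, mutant > 4) including an
  adjacent co-located testis-like cluster, and a disjoint age main effect;
* ChIP: promoter-proximal peak summits at TSS - 150 bp (strand-aware,
  sigma = 50 bp jitter), uniform background peaks, mock peaks as a small
  IP subset plus noise, and repeat counts with planted sub-2-fold IP
  enrichment anchored by unenriched genomic 1-kb bins.

All draws come from a single integer-seeded generator per call, so a fixed
seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneModel, GenomicInterval
from .tau import ExpressionAtlas

__all__ = [
    "SimulationConfig",
    "nb_counts",
    "generate_atlas",
    "generate_ovary_counts",
    "generate_chip_experiment",
    "ChipExperiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: 2 genotypes x 2 ages with 3
    replicates per group, a 34-gene co-located testis-like cluster, planted
    |log2FC| = 2 for DE genes, NB dispersion 0.05 (variance = mu + alpha
    mu^2), and 60% of ChIP peaks promoter-proximal with summits 150 bp
    upstream of the TSS.
    """

    seed: int = 0
    n_genes: int = 2000
    n_tissues: int = 10
    n_samples_per_group: int = 3
    frac_tissue_specific: float = 0.10
    frac_not_expressed: float = 0.10
    frac_de: float = 0.10
    frac_ectopic: float = 0.05
    frac_age_de: float = 0.05
    frac_silent: float = 0.05
    cluster_size: int = 34
    lfc_effect: float = 2.0
    dispersion: float = 0.05
    gc_bias_amplitude: float = 0.5
    genome_length: int = 5_000_000
    peak_frac_promoter: float = 0.6
    tissue_specific_fold: float = 16.0
    base_depth: float = 2e7
    n_peaks_per_sample: int = 400
    peak_width: int = 500
    summit_jitter_sd: float = 50.0
    n_repeats: int = 60
    n_repeats_enriched: int = 20
    repeat_ip_fold: float = 1.5
    repeat_dispersion: float = 0.02
    n_genomic_bins: int = 2000

    def __post_init__(self) -> None:
        for name in (
            "frac_tissue_specific", "frac_not_expressed", "frac_de",
            "frac_ectopic", "frac_age_de", "frac_silent", "peak_frac_promoter",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if self.dispersion < 0 or self.repeat_dispersion < 0:
            raise ValueError("dispersions must be >= 0")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _tissue_names(n: int) -> list[str]:
    base = ["testis", "ovary", "head", "gut", "carcass", "fatbody",
            "salivary", "imaginal", "cns", "tubule"]
    if n <= len(base):
        return base[:n]
    return base + [f"tissue_{i:02d}" for i in range(len(base), n)]


def nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Draw NB counts with variance mu + alpha mu^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# atlas


def generate_atlas(
    config: SimulationConfig,
    gene_ids: list[str] | None = None,
    specific_genes: dict[str, str] | None = None,
) -> tuple[ExpressionAtlas, pd.DataFrame]:
    """Synthetic tissue atlas with planted truth.

    ``specific_genes`` optionally pins given gene ids to given enriched
    tissues (used to co-plant the ovary experiment's testis-like genes);
    the remaining tissue-specific quota is assigned to random genes and
    tissues. Returns (atlas, truth frame with is_tissue_specific,
    enriched_tissue, is_not_expressed).
    """
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_genes
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n)
    if len(genes) != n:
        raise ValueError("gene_ids length must equal n_genes")
    tissues = _tissue_names(config.n_tissues)

    specific: dict[str, str] = dict(specific_genes or {})
    unknown = set(specific) - set(genes)
    if unknown:
        raise ValueError(f"specific_genes not in atlas: {sorted(unknown)[:5]}")
    n_ts = round(config.frac_tissue_specific * n)
    pool = [g for g in genes if g not in specific]
    extra = max(0, n_ts - len(specific))
    for g in rng.choice(len(pool), size=min(extra, len(pool)), replace=False):
        specific[pool[g]] = tissues[rng.integers(0, len(tissues))]

    n_ne = round(config.frac_not_expressed * n)
    ne_pool = [g for g in genes if g not in specific]
    not_expressed = set(
        ne_pool[i] for i in rng.choice(len(ne_pool), size=min(n_ne, len(ne_pool)),
                                       replace=False)
    )

    log2_fold = np.log2(config.tissue_specific_fold)
    rows = np.empty((n, len(tissues)))
    for i, g in enumerate(genes):
        if g in not_expressed:
            rows[i] = np.log2(np.clip(rng.uniform(0.05, 1.8, len(tissues)), 1e-6, None))
        elif g in specific:
            base = rng.normal(0.6, 0.3)
            vals = base + rng.normal(0.0, 0.25, len(tissues))
            vals[tissues.index(specific[g])] = base + log2_fold + rng.normal(0.0, 0.25)
            rows[i] = vals
        else:
            mean = rng.normal(4.3, 1.2)
            rows[i] = mean + rng.normal(0.0, 0.25, len(tissues))
    rpkm = pd.DataFrame(2.0 ** rows, index=genes, columns=tissues)
    atlas = ExpressionAtlas(rpkm)
    truth = pd.DataFrame(
        {
            "is_tissue_specific": [g in specific for g in genes],
            "enriched_tissue": [specific.get(g, "") for g in genes],
            "is_not_expressed": [g in not_expressed for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return atlas, truth


# ---------------------------------------------------------------------------
# ovary counts


def generate_ovary_counts(
    config: SimulationConfig,
    two_factor: bool = True,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Synthetic 2x2 (genotype x age) ovary count matrix with planted truth.

    With ``two_factor=False`` a single-age, two-condition design is
    generated instead (the cell-culture knockdown layout). Truth columns:
    is_de, true_lfc, is_ectopic, in_cluster, is_age_de, is_testis_like,
    wt_rpkm, mut_rpkm.
    """
    if config.n_samples_per_group < 2:
        raise ValueError("n_samples_per_group must be >= 2")
    rng = np.random.default_rng([config.seed, 22])
    n = config.n_genes
    genes = _gene_ids(n)

    # --- planted categories --------------------------------------------
    n_ect = max(round(config.frac_ectopic * n), config.cluster_size)
    n_de = round(config.frac_de * n)
    n_age = round(config.frac_age_de * n)
    n_sil = round(config.frac_silent * n)
    perm = rng.permutation(n)
    ect_idx = perm[:n_ect]
    cluster_idx = ect_idx[: config.cluster_size]
    de_idx = perm[n_ect : n_ect + n_de]
    age_idx = perm[n_ect + n_de : n_ect + n_de + n_age]
    sil_idx = perm[n_ect + n_de + n_age : n_ect + n_de + n_age + n_sil]

    is_ect = np.zeros(n, bool); is_ect[ect_idx] = True
    in_cluster = np.zeros(n, bool); in_cluster[cluster_idx] = True
    is_de = np.zeros(n, bool); is_de[de_idx] = True
    is_age = np.zeros(n, bool); is_age[age_idx] = True
    is_sil = np.zeros(n, bool); is_sil[sil_idx] = True

    true_lfc = np.zeros(n)
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    true_lfc[de_idx] = signs * config.lfc_effect

    # --- feature geometry -----------------------------------------------
    lengths = np.round(2.0 ** rng.uniform(9.0, 12.3, n)).astype(int)  # ~0.5-5 kb
    gc = np.clip(rng.normal(0.45, 0.08, n), 0.25, 0.70)
    chrom = np.where(rng.random(n) < 0.5, "chr2L_sim", "chr3L_sim").astype(object)
    start = rng.integers(0, config.genome_length, n)
    # cluster genes adjacent on one chromosome, ~2 kb apart
    pos = 1_000_000
    for j, gi in enumerate(cluster_idx):
        chrom[gi] = "chr2R_sim"
        start[gi] = pos
        pos += lengths[gi] + 2000
    end = start + lengths
    feature_meta = pd.DataFrame(
        {
            "length": lengths,
            "gc_fraction": gc,
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            "class": "gene",
        },
        index=pd.Index(genes, name="feature_id"),
    )

    # --- expression programme (RPKM scale) ------------------------------
    base = 2.0 ** rng.normal(4.5, 1.5, n)  # background expression level
    wt_e = base.copy()
    mut_e = base.copy()
    wt_e[ect_idx] = rng.uniform(0.1, 0.45, n_ect)
    mut_e[ect_idx] = rng.uniform(5.0, 12.0, n_ect)
    mut_e[de_idx] = wt_e[de_idx] * 2.0 ** true_lfc[de_idx]
    # silent-in-both genes (no true change) exercise the null path of the
    # ectopic test: sampling noise alone pushes some past the fold filter
    wt_e[sil_idx] = rng.uniform(0.1, 0.45, n_sil)
    mut_e[sil_idx] = wt_e[sil_idx]
    age_lfc = np.zeros(n)
    age_lfc[age_idx] = np.where(rng.random(n_age) < 0.5, 1.0, -1.0)

    # the expression levels are RPKM targets; since sum(rpkm * kb) = 1e6 by
    # construction in real libraries, rescale the non-planted programme so a
    # small synthetic panel reproduces the planted RPKM values on measurement
    fixed = is_ect | is_sil
    kb = lengths / 1e3
    budget = 1e6 - (wt_e[fixed] * kb[fixed]).sum()
    lam = budget / (wt_e[~fixed] * kb[~fixed]).sum()
    wt_e[~fixed] *= lam
    mut_e[~fixed] *= lam

    # --- samples ---------------------------------------------------------
    reps = config.n_samples_per_group
    ages = ["0d", "2d"] if two_factor else ["na"]
    samples, meta_rows = [], []
    for geno in ("WT", "mutant"):
        for age in ages:
            for r in range(1, reps + 1):
                sid = f"{geno}_{age}_r{r}" if two_factor else f"{geno}_r{r}"
                samples.append(sid)
                meta_rows.append({"sample_id": sid, "genotype": geno,
                                  "age": age, "replicate": r})
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")

    depth = config.base_depth * rng.uniform(0.8, 1.2, len(samples))
    gc_a = rng.uniform(-1.0, 1.0, len(samples))
    gc_b = rng.uniform(-1.0, 1.0, len(samples))
    gcc = gc - 0.5

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        geno = sample_meta.loc[sid, "genotype"]
        age = sample_meta.loc[sid, "age"]
        e = wt_e if geno == "WT" else mut_e
        e = e * 2.0 ** (age_lfc if age == "2d" else 0.0)
        bias = 2.0 ** (
            config.gc_bias_amplitude * (gc_a[j] * gcc + gc_b[j] * (gcc**2 - gcc.var()))
        )
        mu = e * (lengths / 1e3) * (depth[j] / 1e6) * bias
        counts[:, j] = nb_counts(rng, mu, config.dispersion)
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), sample_meta, feature_meta
    )
    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "true_lfc": true_lfc,
            "is_ectopic": is_ect,
            "in_cluster": in_cluster,
            "is_age_de": is_age,
            "is_silent": is_sil,
            "is_testis_like": is_ect,  # planted ectopic programme is testis-like
            "wt_rpkm": wt_e,
            "mut_rpkm": mut_e,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# ChIP experiment


@dataclass
class ChipExperiment:
    """Everything a ChIP interval/repeat analysis consumes."""

    ip_peaks: dict[tuple[str, int], list[GenomicInterval]]  # (antibody, rep)
    mock_peaks: list[list[GenomicInterval]]
    gene_models: list[GeneModel]
    repeat_counts: CountMatrix
    chrom_sizes: dict[str, int]
    peak_truth: pd.DataFrame
    repeat_truth: pd.DataFrame


def generate_chip_experiment(config: SimulationConfig) -> ChipExperiment:
    """Synthetic ChIP experiment: 2 antibodies x 2 replicates of IP peaks,
    2 mock peak sets, gene models, and repeat + genomic-bin counts."""
    rng = np.random.default_rng([config.seed, 33])
    W = config.genome_length
    chrom_sizes = {"chr2_sim": W, "chr3_sim": W}
    if W < 10 * config.n_peaks_per_sample * config.peak_width:
        raise ValueError("genome_length must be >= 10x the total peak span")

    # gene models every ~10 kb
    models: list[GeneModel] = []
    gid = 0
    for chrom in chrom_sizes:
        for s in range(5000, W - 5000, 10_000):
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(GeneModel(f"cg{gid:05d}", chrom, s, s + 2000, strand))
            gid += 1

    half = config.peak_width // 2
    antibodies = ("ab76", "ab77")

    def make_ip(rep_rng: np.random.Generator):
        peaks, truth_rows = [], []
        n_prom = round(config.peak_frac_promoter * config.n_peaks_per_sample)
        gene_pick = rep_rng.choice(len(models), size=n_prom, replace=False)
        for gi in gene_pick:
            g = models[gi]
            shift = -150.0 + rep_rng.normal(0.0, config.summit_jitter_sd)
            summit = g.tss + int(round(shift if g.strand == "+" else -shift))
            summit = int(np.clip(summit, half, chrom_sizes[g.chrom] - half - 1))
            peaks.append(
                GenomicInterval(g.chrom, summit - half, summit + half,
                                score=float(rep_rng.uniform(2, 6)),
                                summit_offset=half)
            )
            truth_rows.append(True)
        for _ in range(config.n_peaks_per_sample - n_prom):
            chrom = list(chrom_sizes)[rep_rng.integers(0, len(chrom_sizes))]
            s = int(rep_rng.integers(0, chrom_sizes[chrom] - config.peak_width))
            peaks.append(
                GenomicInterval(chrom, s, s + config.peak_width,
                                score=float(rep_rng.uniform(1.2, 3)),
                                summit_offset=half)
            )
            truth_rows.append(False)
        return peaks, truth_rows

    ip_peaks = {}
    truth_frames = []
    for ab in antibodies:
        for rep in (1, 2):
            peaks, prox = make_ip(rng)
            ip_peaks[(ab, rep)] = peaks
            truth_frames.append(
                pd.DataFrame(
                    {
                        "antibody": ab,
                        "replicate": rep,
                        "chrom": [p.chrom for p in peaks],
                        "start": [p.start for p in peaks],
                        "end": [p.end for p in peaks],
                        "is_promoter_proximal": prox,
                    }
                )
            )
    peak_truth = pd.concat(truth_frames, ignore_index=True)

    # mock peaks: a small subset of one IP set plus uniform noise
    mock_sets = []
    for _ in range(2):
        source = ip_peaks[(antibodies[0], 1)]
        keep = rng.choice(len(source), size=max(1, len(source) // 20), replace=False)
        mock = [source[i] for i in keep]
        for _ in range(20):
            chrom = list(chrom_sizes)[rng.integers(0, len(chrom_sizes))]
            s = int(rng.integers(0, chrom_sizes[chrom] - config.peak_width))
            mock.append(GenomicInterval(chrom, s, s + config.peak_width))
        mock_sets.append(mock)

    # repeat + genomic-bin counts: antibody x condition x replicate
    n_rep_feat, n_bins = config.n_repeats, config.n_genomic_bins
    feat_ids = [f"rep{i:03d}" for i in range(n_rep_feat)] + [
        f"bin{i:05d}" for i in range(n_bins)
    ]
    classes = ["repeat"] * n_rep_feat + ["genomic_bin"] * n_bins
    base = np.concatenate(
        [
            2.0 ** rng.normal(11.0, 1.0, n_rep_feat),  # deep repeat coverage
            2.0 ** rng.normal(7.6, 0.8, n_bins),
        ]
    )
    true_fold = np.ones(n_rep_feat + n_bins)
    true_fold[: config.n_repeats_enriched] = config.repeat_ip_fold

    samples, meta_rows = [], []
    for ab in antibodies:
        for cond in ("IP", "mock"):
            for r in (1, 2):
                sid = f"{ab}_{cond}_r{r}"
                samples.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "antibody": ab, "condition": cond,
                     "replicate": r}
                )
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    depth = rng.uniform(0.7, 1.3, len(samples))
    counts = np.empty((len(feat_ids), len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        fold = true_fold if sample_meta.loc[sid, "condition"] == "IP" else 1.0
        mu = base * fold * depth[j]
        counts[:, j] = nb_counts(rng, mu, config.repeat_dispersion)
    feature_meta = pd.DataFrame(
        {
            "length": [5000] * n_rep_feat + [1000] * n_bins,
            "gc_fraction": 0.45,
            "class": classes,
        },
        index=pd.Index(feat_ids, name="feature_id"),
    )
    repeat_counts = CountMatrix(
        pd.DataFrame(counts, index=feat_ids, columns=samples),
        sample_meta,
        feature_meta,
    )
    repeat_truth = pd.DataFrame(
        {"class": classes, "true_ip_fold": true_fold},
        index=pd.Index(feat_ids, name="feature_id"),
    )
    return ChipExperiment(
        ip_peaks=ip_peaks,
        mock_peaks=mock_sets,
        gene_models=models,
        repeat_counts=repeat_counts,
        chrom_sizes=chrom_sizes,
        peak_truth=peak_truth,
        repeat_truth=repeat_truth,
    )
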