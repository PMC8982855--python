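"""Tissue-specificity classification with the tau index.

tau (Yanai et al. 2005) summarises how concentrated a gene's expression is
across a tissue panel:

    tau = sum_i (1 - x_hat_i) / (n - 1),   x_hat_i = x_i / max_i(x_i)

computed on log2(RPKM) values, so tau = 0 for perfectly uniform expression
and tau = 1 for expression confined to a single tissue. Genes with
tau >= 0.7 are treated as tissue-specific; the enriched tissue(s) are those
whose log2(RPKM) exceeds the across-tissue mean by more than 1.5 sample
standard deviations. Genes with RPKM <= 2 in every tissue are classed
NotExpressed without a tau value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TauConfig",
    "ExpressionAtlas",
    "compute_tau",
    "assign_enriched_tissues",
    "TissueSpecificityModel",
    "TissueClassificationResults",
    "classify_genes",
]

STATUS_NOT_EXPRESSED = "NotExpressed"
STATUS_NOT_ENRICHED = "NotEnriched"
STATUS_ENRICHED = "Enriched"


@dataclass(frozen=True)
class TauConfig:
    """Thresholds of the tissue-specificity classifier.

    tau_threshold
        Minimum tau for a gene to be considered tissue-specific (0.70).
    expression_floor_log2
        log2(RPKM) at or below which a tissue counts as not expressed
        (1.0, i.e. RPKM <= 2).
    enrichment_k
        SD multiplier of the enriched-tissue rule (1.5).
    not_expressed_rule
        "all": NotExpressed requires RPKM <= 2 in every tissue (default);
        "any": the stricter alternative reading, failure in at least one
        tissue.
    """

    tau_threshold: float = 0.70
    expression_floor_log2: float = 1.0
    enrichment_k: float = 1.5
    not_expressed_rule: str = "all"

    def __post_init__(self) -> None:
        if not (0 < self.tau_threshold <= 1):
            raise ValueError("tau_threshold must be in (0, 1]")
        if self.enrichment_k <= 0:
            raise ValueError("enrichment_k must be > 0")
        if self.not_expressed_rule not in {"all", "any"}:
            raise ValueError("not_expressed_rule must be 'all' or 'any'")


class ExpressionAtlas:
    """Genes x tissue-groups RPKM matrix with optional raw->group mapping.

    Zero-RPKM cells are excluded from the log2 transform (held as NaN in
    ``log_expr``) but enter tau as x_hat = 0; negative log2 values (RPKM < 1)
    are clipped to 0 inside tau so that x_hat stays in [0, 1].
    """

    def __init__(
        self,
        rpkm: pd.DataFrame,
        tissue_groups: dict[str, str] | None = None,
    ) -> None:
        if rpkm.shape[1] < 2:
            raise ValueError("atlas needs at least 2 tissue columns")
        if (rpkm.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")
        if rpkm.index.duplicated().any():
            raise ValueError("duplicate gene ids in atlas")
        if tissue_groups:
            grouped = rpkm.T.groupby(
                rpkm.columns.map(lambda c: tissue_groups.get(c, c))
            ).max().T
            rpkm = grouped
        self.rpkm = rpkm.astype(float)
        with np.errstate(divide="ignore"):
            le = np.log2(self.rpkm.to_numpy())
        le[~np.isfinite(le)] = np.nan  # zero RPKM excluded from log transform
        self.log_expr = pd.DataFrame(le, index=rpkm.index, columns=rpkm.columns)

    @property
    def tissues(self) -> pd.Index:
        return self.rpkm.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.rpkm.index


def compute_tau(log_expr: np.ndarray) -> float:
    """tau of one gene's per-tissue log2 expression vector.

    NaN cells (zero RPKM) and negative values are treated as 0 expression.
    Returns NaN (undefined) when no tissue has strictly positive expression.
    """
    x = np.asarray(log_expr, dtype=float).copy()
    if x.size < 2:
        raise ValueError("tau needs at least 2 tissues")
    x[np.isnan(x)] = 0.0
    x = np.clip(x, 0.0, None)
    mx = x.max()
    if mx <= 0:
        return float("nan")
    xhat = x / mx
    return float(np.sum(1.0 - xhat) / (x.size - 1))


def assign_enriched_tissues(
    log_expr: pd.Series | np.ndarray,
    k: float = 1.5,
    tissues: pd.Index | None = None,
) -> list[str]:
    """Tissues whose log2 expression exceeds mean + k * sample SD.

    NaN cells (zero RPKM) count as 0 expression; the SD uses the n-1
    denominator. A constant vector (zero SD) yields the empty set.
    """
    if isinstance(log_expr, pd.Series):
        tissues = log_expr.index
        x = log_expr.to_numpy(dtype=float)
    else:
        x = np.asarray(log_expr, dtype=float)
        if tissues is None:
            tissues = pd.Index(range(x.size))
    x = np.where(np.isnan(x), 0.0, x)
    if x.size < 2:
        raise ValueError("need at least 2 tissues")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return []
    thr = mean + k * sd
    return [str(t) for t, v in zip(tissues, x) if v > thr]


class TissueSpecificityModel:
    """Classify every atlas gene as NotExpressed / NotEnriched / Enriched."""

    def __init__(self, atlas: ExpressionAtlas, config: TauConfig | None = None):
        self.atlas = atlas
        self.config = config or TauConfig()

    def fit(self) -> "TissueClassificationResults":
        cfg = self.config
        le = self.atlas.log_expr
        tissues = self.atlas.tissues
        x = le.to_numpy(dtype=float)
        x0 = np.where(np.isnan(x), 0.0, x)

        below_floor = np.isnan(x) | (x <= cfg.expression_floor_log2)
        if cfg.not_expressed_rule == "all":
            not_expressed = below_floor.all(axis=1)
        else:
            not_expressed = below_floor.any(axis=1)

        records = []
        for i, gene in enumerate(self.atlas.gene_ids):
            if not_expressed[i]:
                records.append((gene, np.nan, STATUS_NOT_EXPRESSED, ()))
                continue
            tau = compute_tau(x0[i])
            enriched: tuple[str, ...] = ()
            status = STATUS_NOT_ENRICHED
            if not np.isnan(tau) and tau >= cfg.tau_threshold:
                enriched = tuple(
                    assign_enriched_tissues(x0[i], cfg.enrichment_k, tissues)
                )
                if enriched:
                    status = STATUS_ENRICHED
            records.append((gene, tau, status, enriched))
        frame = pd.DataFrame(
            records, columns=["gene_id", "tau", "status", "enriched_tissues"]
        ).set_index("gene_id")
        return TissueClassificationResults(frame, tissues, cfg)


class TissueClassificationResults:
    """Per-gene tau, status and enriched tissue set, plus summary counts."""

    def __init__(self, frame: pd.DataFrame, tissues: pd.Index, config: TauConfig):
        self.frame = frame
        self.tissues = tissues
        self.config = config

    @property
    def status_counts(self) -> pd.Series:
        return self.frame["status"].value_counts().reindex(
            [STATUS_NOT_EXPRESSED, STATUS_NOT_ENRICHED, STATUS_ENRICHED], fill_value=0
        )

    @property
    def fraction_tissue_specific(self) -> float:
        """Fraction of all atlas genes with Enriched status."""
        return float((self.frame["status"] == STATUS_ENRICHED).mean())

    def per_tissue_counts(self) -> pd.Series:
        counts = {str(t): 0 for t in self.tissues}
        for ts in self.frame.loc[
            self.frame["status"] == STATUS_ENRICHED, "enriched_tissues"
        ]:
            for t in ts:
                counts[t] += 1
        return pd.Series(counts, name="n_enriched_genes")

    def gene_sets(self) -> dict[str, set[str]]:
        """Per-tissue Enriched gene sets, keyed by tissue name."""
        sets: dict[str, set[str]] = {str(t): set() for t in self.tissues}
        enr = self.frame[self.frame["status"] == STATUS_ENRICHED]
        for gene, ts in enr["enriched_tissues"].items():
            for t in ts:
                sets[t].add(gene)
        return sets

    def summary(self) -> str:
        lines = ["Tissue-specificity classification"]
        n = len(self.frame)
        lines.append(f"  genes: {n}")
        for status, count in self.status_counts.items():
            lines.append(f"  {status}: {count} ({100 * count / max(n, 1):.1f}%)")
        lines.append(
            f"  tissue-specific fraction: {100 * self.fraction_tissue_specific:.1f}%"
        )
        lines.append("  per-tissue enriched gene counts:")
        for t, c in self.per_tissue_counts().items():
            lines.append(f"    {t}: {c}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["enriched_tissues"] = out["enriched_tissues"].map(";".join)
        return out


def classify_genes(
    atlas: ExpressionAtlas, config: TauConfig | None = None
) -> TissueClassificationResults:
    """Functional wrapper around :class:`TissueSpecificityModel`."""
    return TissueSpecificityModel(atlas, config).fit()
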