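"""Count-level normalization: low-count filtering, within-lane GC
full-quantile normalization, between-lane full-quantile normalization, and
log-offset generation for the NB GLM.

The within-lane step removes sample-specific GC-content bias: features are
binned into equal-occupancy GC strata and each stratum's count distribution
is mapped onto the sample's pooled count distribution by matching order
statistics (quantile matching with linear interpolation; ties share the
mean of their positions). Between-lane normalization then equalises
sequencing depth by mapping every sample's sorted counts onto the mean
sorted vector. Offsets log((raw + 0.1)/(normalized + 0.1)) let the GLM run
on raw counts while reproducing inference on the normalized scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "NormalizationResult",
    "filter_low_count",
    "within_lane_gc_fqn",
    "between_lane_fqn",
    "compute_offsets",
    "normalize_counts",
]

OFFSET_PSEUDOCOUNT = 0.1


@dataclass
class NormalizationResult:
    """Normalized counts plus the GLM offsets that reproduce them.

    ``offsets`` are natural-log scale: raw expectation = exp(offset) * mu.
    """

    normalized_counts: pd.DataFrame
    offsets: pd.DataFrame | None = None
    strata_bounds: np.ndarray | None = None
    kept_features: pd.Index | None = None

    def __post_init__(self) -> None:
        if self.offsets is not None and not np.isfinite(
            self.offsets.to_numpy()
        ).all():
            raise ValueError("offsets must be finite for all kept features")


def filter_low_count(cm: CountMatrix, min_mean: float = 10.0) -> CountMatrix:
    """Drop features whose mean count across all samples is <= min_mean."""
    means = cm.counts.mean(axis=1)
    keep = means > min_mean
    if not keep.any():
        warnings.warn("low-count filter removed every feature", UserWarning)
    return cm.subset_features(cm.counts.index[keep])


def _gc_strata(gc: np.ndarray, n_strata: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign each feature to one of n_strata equal-occupancy GC bins.

    Returns (assignment, bounds) where bounds partitions [0, 1].
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    qs = np.quantile(gc, np.linspace(0, 1, n_strata + 1))
    bounds = qs.copy()
    bounds[0], bounds[-1] = 0.0, 1.0
    # searchsorted on interior edges; right-closed last bin
    assign = np.searchsorted(bounds[1:-1], gc, side="right")
    return assign, bounds


def _quantile_match(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map ``values`` onto ``reference``'s distribution by matching quantiles.

    Ranks use midranks for ties so tied inputs map to the same output;
    quantile lookup interpolates linearly between reference order statistics.
    """
    m = values.size
    if m == 0:
        return values.copy()
    if m == 1:
        return np.array([np.quantile(reference, 0.5)])
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(m)
    ranks[order] = np.arange(m, dtype=float)
    # midranks for ties
    sv = values[order]
    i = 0
    while i < m:
        j = i
        while j + 1 < m and sv[j + 1] == sv[i]:
            j += 1
        if j > i:
            mid = (i + j) / 2.0
            ranks[order[i : j + 1]] = mid
        i = j + 1
    probs = ranks / (m - 1)
    return np.quantile(reference, probs)


def within_lane_gc_fqn(cm: CountMatrix, n_strata: int = 10) -> NormalizationResult:
    """Full-quantile normalize GC strata within each sample independently.

    Within each of ``n_strata`` equal-occupancy GC bins, a sample's counts
    are replaced by the values at matching quantiles of that sample's pooled
    (all-strata) count distribution; rank order within a stratum is
    preserved.
    """
    fm = cm.feature_meta
    if "gc_fraction" not in fm.columns or fm["gc_fraction"].isna().any():
        missing = (
            fm.index[fm["gc_fraction"].isna()].tolist()
            if "gc_fraction" in fm.columns
            else list(fm.index)
        )
        raise ValueError(f"gc_fraction missing for features: {missing[:5]}")
    gc = fm["gc_fraction"].to_numpy(dtype=float)
    assign, bounds = _gc_strata(gc, n_strata)
    counts = cm.counts.to_numpy(dtype=float)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        pooled = counts[:, j]
        for s in range(n_strata):
            idx = np.flatnonzero(assign == s)
            if idx.size == 0:
                continue
            out[idx, j] = _quantile_match(pooled[idx], pooled)
    norm = pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)
    return NormalizationResult(norm, strata_bounds=bounds, kept_features=cm.counts.index)


def between_lane_fqn(counts: pd.DataFrame) -> NormalizationResult:
    """Map each sample's sorted counts onto the mean sorted vector.

    After normalization all samples share the same sorted count vector (up
    to ties, which receive the mean of their positions' reference values).
    """
    if counts.shape[1] < 2:
        raise ValueError("between-lane normalization needs >= 2 samples")
    arr = counts.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = reference
        # ties share the mean of their positions' reference values
        sv = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sv[k + 1] == sv[i]:
                k += 1
            if k > i:
                mapped[order[i : k + 1]] = reference[i : k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    norm = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return NormalizationResult(norm, kept_features=counts.index)


def compute_offsets(
    raw: pd.DataFrame, normalized: pd.DataFrame
) -> pd.DataFrame:
    """Natural-log offsets log((raw + 0.1) / (normalized + 0.1)).

    Supplying these with raw counts to the NB GLM reproduces inference on
    the normalized counts.
    """
    if raw.shape != normalized.shape or not raw.index.equals(normalized.index):
        raise ValueError("raw and normalized matrices must be aligned")
    off = np.log(
        (raw.to_numpy(dtype=float) + OFFSET_PSEUDOCOUNT)
        / (normalized.to_numpy(dtype=float) + OFFSET_PSEUDOCOUNT)
    )
    return pd.DataFrame(off, index=raw.index, columns=raw.columns)


def normalize_counts(
    cm: CountMatrix,
    min_mean: float = 10.0,
    n_strata: int = 10,
    stratified_between_lane: bool = False,
) -> tuple[CountMatrix, NormalizationResult]:
    """Run the full chain: filter -> within-lane GC FQN -> between-lane FQN
    -> offsets. Returns the filtered CountMatrix and the final result.

    ``stratified_between_lane`` applies the between-lane step per GC stratum
    instead of globally (depth normalization is conventionally unstratified,
    which is the default).
    """
    kept = filter_low_count(cm, min_mean=min_mean)
    within = within_lane_gc_fqn(kept, n_strata=n_strata)
    if stratified_between_lane:
        gc = kept.feature_meta["gc_fraction"].to_numpy(dtype=float)
        assign, _ = _gc_strata(gc, n_strata)
        parts = []
        for s in range(n_strata):
            idx = kept.counts.index[assign == s]
            if len(idx) < 1:
                continue
            parts.append(between_lane_fqn(within.normalized_counts.loc[idx]).normalized_counts)
        norm = pd.concat(parts).loc[kept.counts.index]
        between = NormalizationResult(norm, kept_features=kept.counts.index)
    else:
        between = between_lane_fqn(within.normalized_counts)
    offsets = compute_offsets(kept.counts, between.normalized_counts)
    return kept, NormalizationResult(
        between.normalized_counts,
        offsets=offsets,
        strata_bounds=within.strata_bounds,
        kept_features=kept.counts.index,
    )
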