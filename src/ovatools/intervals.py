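"""Interval algebra and ChIP-peak analytics.

All operations work on 0-based half-open :class:`~ovatools.io.GenomicInterval`
records: mock-peak subtraction, union merging (book-ended intervals merge,
scores max-aggregate), TSS-window annotation (+-1 kb by default), strand-
oriented promoter density profiles, per-bin genome coverage, and a
segment-randomization overlap-enrichment test that rewrites the query peaks
at uniform random positions in the workspace to build the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, GenomicInterval

__all__ = [
    "Workspace",
    "OverlapEnrichment",
    "merge_intervals",
    "subtract_whole",
    "subtract_portion",
    "annotate_tss",
    "density_profile",
    "bin_coverage",
    "randomized_overlap_enrichment",
]


@dataclass(frozen=True)
class Workspace:
    """Chromosome names/lengths plus optional excluded regions (the
    mappable genome available for randomization)."""

    chrom_sizes: dict[str, int]
    excluded: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be > 0")
        for iv in self.excluded:
            if iv.chrom not in self.chrom_sizes:
                raise ValueError(f"excluded region on unknown chromosome {iv.chrom}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class OverlapEnrichment:
    """Observed vs simulated-expected overlap of two peak sets."""

    observed_overlap: float
    expected_overlap: float
    fold_enrichment: float
    empirical_p: float
    n_sims: int
    seed: int
    mode: str
    sim_overlaps: np.ndarray = field(repr=False, default=None)


def _by_chrom(intervals) -> dict[str, list]:
    out: dict[str, list] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(peaks) -> list[GenomicInterval]:
    """Minimal disjoint set covering exactly the union of the input.

    Book-ended intervals ([a,b) followed by [b,c)) merge; the merged score
    is the max over constituents. Output is sorted by (chrom, start).
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(peaks)):
        ivs = sorted(_by_chrom(peaks)[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end, cur_score = ivs[0].start, ivs[0].end, ivs[0].score
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
                cur_score = max(cur_score, iv.score)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end,
                                              score=cur_score))
                cur_start, cur_end, cur_score = iv.start, iv.end, iv.score
        merged.append(GenomicInterval(chrom, cur_start, cur_end, score=cur_score))
    return merged


def subtract_whole(peaks, blacklist) -> list[GenomicInterval]:
    """Remove every peak with >= 1 bp overlap with any blacklist interval."""
    black = {c: sorted((iv.start, iv.end) for iv in ivs)
             for c, ivs in _by_chrom(blacklist).items()}
    out = []
    for p in peaks:
        spans = black.get(p.chrom, [])
        if not any(s < p.end and p.start < e for s, e in spans):
            out.append(p)
    return out


def subtract_portion(peaks, blacklist) -> list[GenomicInterval]:
    """Remove only the covered portions, splitting peaks where needed.

    Resulting fragments inherit the original peak's score and strand; any
    summit falling inside a removed portion is dropped.
    """
    black = {c: [(iv.start, iv.end) for iv in merge_intervals(ivs)]
             for c, ivs in _by_chrom(blacklist).items()}
    out = []
    for p in peaks:
        pieces = [(p.start, p.end)]
        for bs, be in black.get(p.chrom, []):
            nxt = []
            for s, e in pieces:
                if be <= s or e <= bs:
                    nxt.append((s, e))
                    continue
                if s < bs:
                    nxt.append((s, bs))
                if be < e:
                    nxt.append((be, e))
            pieces = nxt
        for s, e in pieces:
            summit = p.summit
            so = summit - s if (summit is not None and s <= summit < e) else None
            out.append(GenomicInterval(p.chrom, s, e, p.name, p.score, p.strand, so))
    return out


# ---------------------------------------------------------------------------
# TSS annotation


def annotate_tss(
    peaks,
    gene_models,
    window: int = 1000,
) -> pd.DataFrame:
    """Annotate genes whose TSS lies within ``window`` bp of a peak.

    A gene is bound iff some peak intersects [tss - window, tss + window + 1).
    ``distance`` is the signed bp from the TSS to the nearest covered base of
    the nearest peak on the gene's chromosome (0 when the TSS is inside a
    peak); negative means the peak is upstream of the TSS relative to gene
    strand. Genes on peak-free chromosomes get NaN distance.
    """
    peaks_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in _by_chrom(peaks).items():
        ivs = sorted(ivs, key=lambda p: p.start)
        peaks_by_chrom[chrom] = (
            np.array([p.start for p in ivs]),
            np.array([p.end for p in ivs]),
        )
    rows = []
    for g in gene_models:
        tss = g.tss
        bound, dist = False, np.nan
        if g.chrom in peaks_by_chrom:
            starts, ends = peaks_by_chrom[g.chrom]
            # candidate: nearest by insertion point; scan both sides since
            # sorted starts do not bound ends
            inside = (starts <= tss) & (tss < ends)
            if inside.any():
                dist = 0.0
            else:
                gaps = np.where(
                    ends <= tss,
                    tss - (ends - 1),  # peak upstream in genome coords
                    np.where(starts > tss, starts - tss, 0),
                )
                i = int(np.argmin(gaps))
                gap = int(gaps[i])
                genome_upstream = ends[i] <= tss
                five_prime = genome_upstream == (g.strand == "+")
                dist = -gap if five_prime else gap
            lo, hi = tss - window, tss + window + 1
            bound = bool(((starts < hi) & (ends > lo)).any())
        rows.append({"gene_id": g.gene_id, "bound": bound, "distance": dist})
    return pd.DataFrame(rows).set_index("gene_id")


def bound_genes(peaks, gene_models, window: int = 1000) -> set[str]:
    ann = annotate_tss(peaks, gene_models, window)
    return set(ann.index[ann["bound"]])


# ---------------------------------------------------------------------------
# density profile


def density_profile(
    peaks,
    gene_models,
    flank: int = 2000,
    bin_size: int = 50,
    anchor: str = "summit",
) -> pd.DataFrame:
    """Strand-oriented frequency profile of peak anchors around TSSs.

    Each peak anchor (summit by default, midpoint otherwise) within
    +-``flank`` of a TSS contributes one count to the bin of its
    strand-oriented offset (negative = upstream of the TSS). Bins cover
    [-flank, flank) in ``bin_size`` steps; ``frequency`` is the count
    normalized to sum to 1 over the window.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    if anchor not in {"summit", "midpoint"}:
        raise ValueError("anchor must be 'summit' or 'midpoint'")
    anchors: dict[str, list[int]] = {}
    for p in peaks:
        if anchor == "summit":
            if p.summit is None:
                raise ValueError(
                    f"peak {p.chrom}:{p.start}-{p.end} lacks a summit; "
                    "use anchor='midpoint'"
                )
            pos = p.summit
        else:
            pos = p.midpoint
        anchors.setdefault(p.chrom, []).append(pos)
    for chrom in anchors:
        anchors[chrom] = np.sort(np.asarray(anchors[chrom]))

    n_bins = 2 * flank // bin_size
    counts = np.zeros(n_bins, dtype=int)
    for g in gene_models:
        pos = anchors.get(g.chrom)
        if pos is None:
            continue
        tss = g.tss
        lo = np.searchsorted(pos, tss - flank, side="left")
        hi = np.searchsorted(pos, tss + flank, side="left")
        for a in pos[lo:hi]:
            offset = (a - tss) if g.strand == "+" else (tss - a)
            if -flank <= offset < flank:
                counts[(offset + flank) // bin_size] += 1
    edges = np.arange(-flank, flank + 1, bin_size)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
            "frequency": counts / total if total else np.zeros(n_bins),
        }
    )


# ---------------------------------------------------------------------------
# bin coverage


def bin_coverage(
    peaks, workspace: Workspace, bin_size: int = 100_000
) -> pd.DataFrame:
    """Percent of each genomic bin covered by the merged peak set.

    Peaks are merged first so overlapping peaks count once; a final partial
    bin is normalized by its true width. Peaks running past a chromosome
    end are clipped with a warning.
    """
    merged = merge_intervals(peaks) if peaks else []
    by_chrom = _by_chrom(merged)
    rows = []
    for chrom, length in workspace.chrom_sizes.items():
        ivs = by_chrom.get(chrom, [])
        clipped = []
        for iv in ivs:
            if iv.end > length:
                warnings.warn(
                    f"peak {chrom}:{iv.start}-{iv.end} extends past chromosome "
                    f"end {length}; clipped",
                    UserWarning,
                )
                if iv.start >= length:
                    continue
                clipped.append((iv.start, length))
            else:
                clipped.append((iv.start, iv.end))
        n_bins = (length + bin_size - 1) // bin_size
        covered = np.zeros(n_bins)
        for s, e in clipped:
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo, hi = b * bin_size, min((b + 1) * bin_size, length)
                covered[b] += max(0, min(e, hi) - max(s, lo))
        for b in range(n_bins):
            width = min((b + 1) * bin_size, length) - b * bin_size
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b * bin_size,
                    "bin_end": min((b + 1) * bin_size, length),
                    "pct_covered": 100.0 * covered[b] / width,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# randomized overlap enrichment


def _overlap_bp(a_by_chrom, b_by_chrom) -> int:
    total = 0
    for chrom, a_spans in a_by_chrom.items():
        b_spans = b_by_chrom.get(chrom)
        if not b_spans:
            continue
        for s, e in a_spans:
            for bs, be in b_spans:
                total += max(0, min(e, be) - max(s, bs))
    return total


def _overlap_count(a_by_chrom, b_by_chrom) -> int:
    total = 0
    for chrom, a_spans in a_by_chrom.items():
        b_spans = b_by_chrom.get(chrom)
        if not b_spans:
            continue
        for s, e in a_spans:
            if any(bs < e and s < be for bs, be in b_spans):
                total += 1
    return total


def _spans(intervals) -> dict[str, list[tuple[int, int]]]:
    return {
        c: [(iv.start, iv.end) for iv in ivs]
        for c, ivs in _by_chrom(intervals).items()
    }


def randomized_overlap_enrichment(
    query,
    reference,
    workspace: Workspace,
    n_sims: int = 1000,
    seed: int = 0,
    mode: str = "bp",
) -> OverlapEnrichment:
    """Segment-randomization overlap enrichment.

    Each simulation rewrites every query interval at an independent uniform
    random position in the workspace (lengths preserved, excluded regions
    avoided by rejection, overlaps among placed intervals permitted) and
    records the overlap with the fixed reference set. ``mode`` is "bp"
    (total overlapping bases) or "count" (query intervals with >= 1 bp
    overlap). The empirical p uses the (1 + #sims >= observed)/(1 + n_sims)
    estimator, so it is always positive.
    """
    if mode not in {"bp", "count"}:
        raise ValueError("mode must be 'bp' or 'count'")
    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} < 100: p-value resolution is coarse",
                      UserWarning)
    chroms = list(workspace.chrom_sizes)
    sizes = np.array([workspace.chrom_sizes[c] for c in chroms], dtype=np.int64)
    lengths = np.array([len(q) for q in query], dtype=np.int64)
    if len(lengths) and lengths.max() > sizes.max():
        raise ValueError("a query interval is longer than every chromosome")
    excluded = _spans(workspace.excluded)
    ref_spans = _spans(reference)
    overlap_fn = _overlap_bp if mode == "bp" else _overlap_count

    observed = overlap_fn(_spans(query), ref_spans)
    rng = np.random.default_rng(seed)

    # merged reference per chromosome with prefix coverage sums, so the
    # covered bases below any coordinate come from one searchsorted
    ref_merged: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for ci, chrom in enumerate(chroms):
        ivs = merge_intervals(
            [GenomicInterval(chrom, s, e) for s, e in ref_spans.get(chrom, [])]
        ) if ref_spans.get(chrom) else []
        rs = np.array([iv.start for iv in ivs], dtype=np.int64)
        re_ = np.array([iv.end for iv in ivs], dtype=np.int64)
        ref_merged[ci] = (rs, re_, np.concatenate([[0], np.cumsum(re_ - rs)]))

    def covered_below(ci: int, x: np.ndarray) -> np.ndarray:
        rs, re_, cum = ref_merged[ci]
        if rs.size == 0:
            return np.zeros(x.shape, dtype=np.int64)
        k = np.searchsorted(rs, x, side="right")
        out = cum[k]
        nz = k > 0
        out[nz] -= np.maximum(re_[k[nz] - 1] - x[nz], 0)
        return out

    # per-interval chromosome weights: number of valid start positions
    valid = np.maximum(sizes[None, :] - lengths[:, None] + 1, 0)  # (nq, nc)
    cdf = np.cumsum(valid, axis=1)
    totals = cdf[:, -1].astype(float)

    def place(n_query: int) -> tuple[np.ndarray, np.ndarray]:
        u = rng.random(n_query) * totals
        ci = (u[:, None] >= cdf).sum(axis=1)
        starts = (rng.random(n_query) * valid[np.arange(n_query), ci]).astype(np.int64)
        return ci, starts

    nq = len(lengths)
    sims = np.empty(n_sims)
    for s in range(n_sims):
        ci, starts = place(nq)
        if excluded:
            for i in range(nq):
                exc = excluded.get(chroms[ci[i]], [])
                tries = 0
                while any(bs < starts[i] + lengths[i] and starts[i] < be
                          for bs, be in exc):
                    tries += 1
                    if tries > 1000:
                        raise RuntimeError(
                            "could not place interval outside excluded regions"
                        )
                    c1, s1 = place(1)
                    ci[i], starts[i] = c1[0], s1[0]
                    exc = excluded.get(chroms[ci[i]], [])
        ends = starts + lengths
        total = 0
        for c in np.unique(ci):
            m = ci == c
            ov = covered_below(int(c), ends[m]) - covered_below(int(c), starts[m])
            total += int((ov > 0).sum()) if mode == "count" else int(ov.sum())
        sims[s] = total
    expected = float(sims.mean())
    fold = observed / expected if expected > 0 else np.inf
    emp_p = (1.0 + float((sims >= observed).sum())) / (1.0 + n_sims)
    return OverlapEnrichment(
        observed_overlap=float(observed),
        expected_overlap=expected,
        fold_enrichment=float(fold),
        empirical_p=emp_p,
        n_sims=n_sims,
        seed=seed,
        mode=mode,
        sim_overlaps=sims,
    )
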