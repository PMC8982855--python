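"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are held 0-based half-open internally (BED-native).
GTF input (1-based inclusive) is converted on read and back on write, so a
round trip through any supported dialect is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "CountMatrix",
    "FormatError",
    "read_count_table",
    "write_count_table",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "write_gene_models",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

VALID_FEATURE_CLASSES = {"gene", "repeat", "genomic_bin"}

PEAK_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "broadPeak": 9, "narrowPeak": 10}


class FormatError(ValueError):
    """A file violated the contract of its declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an enrichment score.

    ``summit_offset`` (narrowPeak column 10) is the point-source position in
    bp from ``start``; ``None`` when absent (encoded as -1 on disk).
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.score < 0:
            raise FormatError(f"negative score {self.score} on {self.chrom}:{self.start}")
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise FormatError(
                f"summit_offset {self.summit_offset} outside interval of length "
                f"{self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit(self) -> int | None:
        """Absolute summit coordinate, or None when no summit is recorded."""
        if self.summit_offset is None:
            return None
        return self.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    """A gene body span plus its strand-derived transcription start site.

    The TSS is ``body_start`` on the + strand and ``body_end - 1`` on the -
    strand (the last covered base in 0-based half-open coordinates).
    """

    gene_id: str
    chrom: str
    body_start: int
    body_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r} "
                "(TSS undefined otherwise)"
            )
        if not (0 <= self.body_start < self.body_end):
            raise FormatError(
                f"gene {self.gene_id}: invalid span [{self.body_start},{self.body_end})"
            )

    @property
    def tss(self) -> int:
        return self.body_start if self.strand == "+" else self.body_end - 1


class CountMatrix:
    """Features x samples integer counts with sample and feature metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = feature ids,
        columns = sample ids.
    sample_meta
        DataFrame indexed by sample id carrying factor levels
        (genotype, age, condition, antibody, replicate, ...).
    feature_meta
        DataFrame indexed by feature id. Recognised columns: ``length`` (bp,
        > 0), ``gc_fraction`` (in [0, 1]), ``chrom``/``start``/``end``/
        ``strand`` and ``class`` (one of gene/repeat/genomic_bin).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sample_meta: pd.DataFrame,
        feature_meta: pd.DataFrame,
    ) -> None:
        counts = counts.copy()
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count table")
        arr = counts.to_numpy()
        if arr.size:
            if not np.isfinite(arr.astype(float)).all():
                raise FormatError("counts contain non-finite values")
            frac, _ = np.modf(arr.astype(float))
            if (frac != 0).any():
                i, j = np.argwhere(frac != 0)[0]
                raise FormatError(
                    f"non-integer count {arr[i, j]!r} at feature "
                    f"{counts.index[i]!r}, sample {counts.columns[j]!r}"
                )
            if (arr < 0).any():
                i, j = np.argwhere(arr < 0)[0]
                raise FormatError(
                    f"negative count at feature {counts.index[i]!r}, "
                    f"sample {counts.columns[j]!r}"
                )
        self.counts = counts.astype(np.int64)

        missing = [s for s in counts.columns if s not in sample_meta.index]
        if missing:
            raise FormatError(f"samples missing from sample metadata: {missing}")
        missing_f = [f for f in counts.index if f not in feature_meta.index]
        if missing_f:
            raise FormatError(
                f"features missing from feature metadata: {missing_f[:5]}"
            )
        self.sample_meta = sample_meta.loc[counts.columns].copy()
        self.feature_meta = feature_meta.loc[counts.index].copy()
        self._validate_feature_meta()

    def _validate_feature_meta(self) -> None:
        fm = self.feature_meta
        if "gc_fraction" in fm.columns:
            gc = fm["gc_fraction"].astype(float)
            bad = gc[(gc < 0) | (gc > 1) | gc.isna()]
            if len(bad):
                raise FormatError(
                    f"gc_fraction outside [0,1] for features {bad.index[:5].tolist()}"
                )
        if "length" in fm.columns:
            ln = fm["length"].astype(float)
            if (ln <= 0).any():
                raise FormatError("feature length must be > 0")
        if "class" in fm.columns:
            bad_cls = set(fm["class"].dropna()) - VALID_FEATURE_CLASSES
            if bad_cls:
                raise FormatError(f"unknown feature classes: {sorted(bad_cls)}")

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[feature_ids],
            self.sample_meta,
            self.feature_meta.loc[feature_ids],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)], self.sample_meta, self.feature_meta
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.shape[0]} features x {self.shape[1]} samples)"


# ---------------------------------------------------------------------------
# count tables


def read_count_table(
    path: str | Path,
    sample_meta_path: str | Path,
    feature_meta_path: str | Path,
) -> CountMatrix:
    """Read a TSV count table plus its sample and feature metadata tables.

    The count table has a header row of sample ids and feature ids in the
    first column. Metadata tables are TSV keyed by their first column
    (sample id / feature id respectively). Validation errors name the
    offending cell or id.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids in {path}: {dups[:5]}")
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            bad = raw.index[vals.isna()][0]
            raise FormatError(
                f"{path}: non-numeric count {raw.loc[bad, col]!r} at feature "
                f"{bad!r}, sample {col!r}"
            )
        frac = vals % 1
        if (frac != 0).any():
            bad = raw.index[frac != 0][0]
            raise FormatError(
                f"{path}: non-integer count {raw.loc[bad, col]!r} at feature "
                f"{bad!r}, sample {col!r}"
            )
        if (vals < 0).any():
            bad = raw.index[vals < 0][0]
            raise FormatError(f"{path}: negative count at feature {bad!r}, sample {col!r}")
        numeric[col] = vals.astype(np.int64)
    sample_meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
    feature_meta = pd.read_csv(feature_meta_path, sep="\t", index_col=0)
    return CountMatrix(numeric, sample_meta, feature_meta)


def write_count_table(
    cm: CountMatrix,
    path: str | Path,
    sample_meta_path: str | Path | None = None,
    feature_meta_path: str | Path | None = None,
) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")
    if sample_meta_path is not None:
        cm.sample_meta.to_csv(sample_meta_path, sep="\t", index_label="sample_id")
    if feature_meta_path is not None:
        cm.feature_meta.to_csv(feature_meta_path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# peak files


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[GenomicInterval]:
    """Read a BED3/BED6/broadPeak/narrowPeak file into intervals.

    narrowPeak column 10 is mapped to ``summit_offset`` (-1 means absent);
    broadPeak/narrowPeak column 7 (signalValue, the fold-enrichment over
    input) is mapped to ``score``; BED6 uses its score column.
    """
    if dialect not in PEAK_DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    want = PEAK_DIALECT_COLUMNS[dialect]
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != want:
                raise FormatError(
                    f"{path}:{lineno}: expected {want} columns for {dialect}, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name, score, strand, summit = ".", 0.0, ".", None
            if want >= 6:
                name = fields[3]
                strand = fields[5] if fields[5] in {"+", "-", "."} else "."
            if dialect == "bed6":
                score = float(fields[4])
            elif dialect in {"broadPeak", "narrowPeak"}:
                score = float(fields[6])
            if dialect == "narrowPeak":
                s = int(fields[9])
                summit = None if s == -1 else s
            try:
                out.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_peaks(
    peaks: Iterable[GenomicInterval], path: str | Path, dialect: str = "narrowPeak"
) -> None:
    if dialect not in PEAK_DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "bed3":
                fields = [p.chrom, p.start, p.end]
            elif dialect == "bed6":
                fields = [p.chrom, p.start, p.end, p.name, _fmt(p.score), p.strand]
            else:
                fields = [
                    p.chrom, p.start, p.end, p.name, 0, p.strand,
                    _fmt(p.score), -1, -1,
                ]
                if dialect == "narrowPeak":
                    fields.append(-1 if p.summit_offset is None else p.summit_offset)
            fh.write("\t".join(str(f) for f in fields) + "\n")


def _fmt(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a minimal GTF (gene features) or a 5-column TSV.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    A TSV must carry the header ``gene_id chrom start end strand`` with
    0-based half-open coordinates.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        return _read_gene_models_gtf(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    models = []
    for row in df.itertuples(index=False):
        if row.end <= row.start:
            raise FormatError(f"{path}: gene {row.gene_id}: end <= start")
        models.append(GeneModel(row.gene_id, row.chrom, int(row.start), int(row.end), row.strand))
    return models


def _read_gene_models_gtf(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = (
                fields[0], int(fields[3]), int(fields[4]), fields[6], fields[8]
            )
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split(None, 1)[1].strip().strip('"')
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature lacks gene_id")
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            # GTF is 1-based inclusive
            models.append(GeneModel(gene_id, chrom, start1 - 1, end1, strand))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "start": m.body_start,
                "end": m.body_end,
                "strand": m.strand,
            }
            for m in models
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# chromosome sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length")
            if name in sizes:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name}")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")
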