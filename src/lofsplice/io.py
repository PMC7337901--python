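"""Readers and writers for the external formats the pipeline consumes.

Tab-separated count matrices and sample sheets, BED6 CLIP-cluster tracks,
GTF transcript annotation and bedGraph conservation tracks all pass through
here; each reader returns objects in the package's internal convention
(0-based half-open intervals, ``chr``-stripped chromosome names) so the rest
of the code never sees a raw file format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ScoredInterval, TranscriptModel

GENOTYPES = ("WT", "HET", "HOM")
ARMS = ("KO", "NLS")

SHEET_COLUMNS = ("sample_id", "dataset", "genotype", "arm")


@dataclass
class CountMatrix:
    """Gene-level counts, genes x samples, with non-negative integer entries."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleSheet:
    """Per-sample metadata: dataset of origin, genotype and comparison arm."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        bad_gt = set(self.table["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValueError(f"unknown genotype values {sorted(bad_gt)}; expected {GENOTYPES}")
        bad_arm = set(self.table["arm"]) - set(ARMS)
        if bad_arm:
            raise ValueError(f"unknown arm values {sorted(bad_arm)}; expected {ARMS}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, sample_ids) -> "SampleSheet":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep.copy())

    def select_comparison(self, arm: str, genotype: str = "HOM") -> "SampleSheet":
        """Samples for one two-group comparison: WT plus one mutant genotype
        of one arm."""
        t = self.table
        keep = t[(t["arm"] == arm) & (t["genotype"].isin(["WT", genotype]))]
        return SampleSheet(keep.copy())


def validate_design(sheet: SampleSheet, min_per_group: int = 2) -> None:
    """Check every (dataset, arm) stratum has enough WT and non-WT samples."""
    for (dataset, arm), grp in sheet.table.groupby(["dataset", "arm"]):
        n_wt = int((grp["genotype"] == "WT").sum())
        n_mut = int((grp["genotype"] != "WT").sum())
        if n_wt < min_per_group or n_mut < min_per_group:
            raise ValueError(
                f"stratum ({dataset}, {arm}) has {n_wt} WT / {n_mut} non-WT "
                f"samples; >= {min_per_group} of each required for model fitting"
            )


def read_counts(path, sheet_path) -> tuple[CountMatrix, SampleSheet]:
    """Read a gene x sample count TSV and its sample sheet, cross-validated.

    The count file has a header of sample ids and gene ids in the first
    column.  Every sample in the matrix must appear exactly once in the
    sheet; counts must be non-negative integers.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    sheet_df = pd.read_csv(sheet_path, sep="\t", dtype=str)
    sheet = SampleSheet(sheet_df)
    missing = [s for s in raw.columns if s not in set(sheet.sample_ids)]
    if missing:
        raise ValueError(
            f"sample(s) {missing} present in count matrix {path} but absent "
            f"from sample sheet {sheet_path}"
        )
    # fail with coordinates rather than a dtype error
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.round(vals.fillna(0)))
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"invalid count {raw.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
    cm = CountMatrix(raw.astype(np.int64))
    return cm, sheet.subset(cm.sample_ids)


def read_bed(path, min_score: int | None = None) -> list[GenomicInterval]:
    """Read a BED6 file of CLIP clusters.

    The score column is the number of supporting reads; rows scoring below
    ``min_score`` are dropped (CLIP clusters are conventionally filtered to
    a minimum of two supporting reads).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6, got {len(fields)} fields")
            chrom, start, end, _name, score, strand = fields[:6]
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            if min_score is not None and float(score) < min_score:
                continue
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals, path, scores=None, names=None) -> None:
    scores = scores if scores is not None else [2] * len(intervals)
    names = names if names is not None else [f"c{i}" for i in range(len(intervals))]
    with open(path, "w") as fh:
        for iv, name, score in zip(intervals, names, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def _parse_gtf_attributes(block: str) -> dict[str, list[str]]:
    """Parse a GTF attribute block into key -> list of values (``tag`` may
    repeat)."""
    attrs: dict[str, list[str]] = {}
    for part in block.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            key, value = part.split(None, 1)
        except ValueError:
            raise ValueError(f"unparseable GTF attribute {part!r}") from None
        attrs.setdefault(key, []).append(value.strip().strip('"'))
    return attrs


def read_gtf(path, excluded_tags: set[str] | frozenset[str] = frozenset()) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    GTF coordinates (1-based, closed) are converted to 0-based half-open.
    Transcripts carrying any tag or transcript_type in ``excluded_tags``
    (e.g. ``retained_intron``, ``nonsense_mediated_decay``, ``cds_end_NF``)
    are dropped.  Exons falling outside a declared transcript span are
    clamped with a warning.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    tags: dict[str, set[str]] = {}
    spans: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_block = fields
            if feature not in ("exon", "CDS", "transcript"):
                continue
            try:
                attrs = _parse_gtf_attributes(attr_block)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            if "transcript_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: missing transcript_id attribute")
            tid = attrs["transcript_id"][0]
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            genes.setdefault(tid, attrs.get("gene_id", [tid])[0])
            t = tags.setdefault(tid, set())
            t.update(attrs.get("tag", []))
            t.update(attrs.get("transcript_type", []))
            t.update(attrs.get("transcript_biotype", []))
            if feature == "transcript":
                spans[tid] = iv
            elif feature == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feature == "CDS":
                cds.setdefault(tid, []).append(iv)

    models = []
    for tid, ex in exons.items():
        if tags[tid] & set(excluded_tags):
            continue
        if tid in spans:
            span = spans[tid]
            clamped = []
            for iv in ex:
                if iv.start < span.start or iv.end > span.end:
                    warnings.warn(
                        f"{tid}: exon [{iv.start}, {iv.end}) outside declared span "
                        f"[{span.start}, {span.end}); clamping"
                    )
                    iv = GenomicInterval(
                        iv.chrom,
                        max(iv.start, span.start),
                        min(iv.end, span.end),
                        iv.strand,
                    )
                clamped.append(iv)
            ex = clamped
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=genes[tid],
                exons=ex,
                cds=cds.get(tid),
                tags=tags[tid],
            )
        )
    return models


def write_gtf(models, path) -> None:
    """Write transcript models as GTF (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for m in models:
            attr = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for tag in sorted(m.tags):
                attr += f' tag "{tag}";'
            span = m.span
            fh.write(
                f"{span.chrom}\tlofsplice\ttranscript\t{span.start + 1}\t{span.end}"
                f"\t.\t{span.strand}\t.\t{attr}\n"
            )
            for iv in m.exons:
                fh.write(
                    f"{iv.chrom}\tlofsplice\texon\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{iv.strand}\t.\t{attr}\n"
                )
            for iv in m.cds or []:
                fh.write(
                    f"{iv.chrom}\tlofsplice\tCDS\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{iv.strand}\t.\t{attr}\n"
                )


def read_bedgraph(path) -> list[ScoredInterval]:
    """Read a bedGraph conservation track (chrom, start, end, value).

    Intervals must not overlap within a chromosome — a per-base score would
    otherwise be ambiguous.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            iv = GenomicInterval(chrom, int(start), int(end), ".")
            out.append(ScoredInterval(iv, float(value)))
    by_chrom: dict[str, list[ScoredInterval]] = {}
    for si in out:
        by_chrom.setdefault(si.interval.chrom, []).append(si)
    for chrom, sis in by_chrom.items():
        sis = sorted(sis, key=lambda s: s.interval.start)
        for a, b in zip(sis, sis[1:]):
            if b.interval.start < a.interval.end:
                raise ValueError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at "
                    f"{b.interval.start} (per-base score ambiguous)"
                )
    return out


def write_bedgraph(scored, path) -> None:
    with open(path, "w") as fh:
        for si in scored:
            fh.write(
                f"{si.interval.chrom}\t{si.interval.start}\t{si.interval.end}"
                f"\t{_fmt(si.score)}\n"
            )


def _fmt(x) -> str:
    """Format one value for a results TSV: floats at 12 significant digits,
    NaN as NA."""
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return "NA"
        return f"{x:.12g}"
    if x is None:
        return "NA"
    return str(x)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV with a stable column order.

    Floats are written at 12 significant digits (lossless round-trip for the
    statistics produced here); NaN p-values become ``NA``.  An empty table
    yields a header-only file with a warning.
    """
    if len(table) == 0:
        warnings.warn(f"writing empty results table to {path}")
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, table.columns)) + "\n")
        for row in table.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)
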