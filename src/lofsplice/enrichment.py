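"""CLIP-cluster and conservation enrichment with matched nulls.

Because CLIP-cluster overlap scales with region length and transcript
abundance, every enrichment test here compares a test set of regions
against a null set matched on both: null candidates must show no evidence
of change (p > 0.05 in both joint models) and fall within the test set's
interquartile range of length and expression.  Proportions are compared
with a two-proportion chi-square test (no continuity correction) and
Bonferroni-corrected within each family of tests.  All overlaps are
strand-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .intervals import GenomicInterval, ScoredInterval, TranscriptModel

FEATURE_LABELS = (
    "five_prime_utr",
    "cds",
    "intron",
    "three_prime_utr_ext",
    "promoter_antisense",
)

UTR_EXTENSION = 5_000
PROMOTER_FLANK = 5_000


@dataclass
class EnrichmentResult:
    test_name: str
    n_test: int
    n_null: int
    prop_test: float
    prop_null: float
    chi2: float
    p: float
    p_bonferroni: float = np.nan


@dataclass
class FeaturePartition:
    """Per-gene genomic feature intervals with CDS > UTR > intron precedence."""

    genes: dict[str, dict[str, list[GenomicInterval]]] = field(default_factory=dict)

    def regions(self, label: str, gene_ids=None) -> list[GenomicInterval]:
        """All intervals of one feature class, optionally restricted to a
        gene set."""
        ids = self.genes.keys() if gene_ids is None else gene_ids
        out = []
        for g in ids:
            out.extend(self.genes.get(g, {}).get(label, []))
        return out


def _merge(spans):
    spans = sorted(spans)
    out = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a_spans, b_spans):
    """Set difference of merged (start, end) span lists."""
    b = _merge(b_spans)
    out = []
    for s, e in _merge(a_spans):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def build_partition(
    models: list[TranscriptModel],
    polya: list[GenomicInterval] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> FeaturePartition:
    """Partition each gene into 5'UTR / CDS / intron / extended 3'UTR /
    promoter-antisense intervals.

    UTR exonic sequence is split into 5' and 3' sides by overlap with
    annotated polyadenylation sites when given, else by position relative
    to the CDS.  The 3'UTR is extended 5 kb downstream (clamped to the
    contig) to capture unannotated sequence; the promoter-antisense region
    flanks the 5' end by 5 kb upstream with the strand inverted.  Genes
    without any coding transcript are skipped (the UTR split is undefined).
    """
    contig_lengths = contig_lengths or {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    part = FeaturePartition()
    for gene_id, txs in by_gene.items():
        coding = [t for t in txs if t.cds]
        if not coding:
            warnings.warn(f"gene {gene_id!r} has no coding transcript; skipped")
            continue
        chrom, strand = coding[0].chrom, coding[0].strand
        cds_spans = _merge([(iv.start, iv.end) for t in coding for iv in t.cds])
        cds_lo = min(s for s, _ in cds_spans)
        cds_hi = max(e for _, e in cds_spans)

        utr5_spans, utr3_spans, intron_spans = [], [], []
        for t in coding:
            exon_spans = [(iv.start, iv.end) for iv in t.exons]
            utr = _subtract(exon_spans, cds_spans)
            for s, e in utr:
                iv = GenomicInterval(chrom, s, e, strand)
                if polya is not None and any(
                    iv.overlaps(pa, stranded=False) for pa in polya
                ):
                    utr3_spans.append((s, e))
                elif (strand == "+" and e <= cds_lo) or (strand == "-" and s >= cds_hi):
                    utr5_spans.append((s, e))
                else:
                    utr3_spans.append((s, e))
            intron_spans.extend((iv.start, iv.end) for iv in t.introns())

        # precedence on collision across transcripts: CDS > UTR > intron
        utr5_spans = _subtract(utr5_spans, cds_spans)
        utr3_spans = _subtract(utr3_spans, cds_spans)
        intron_spans = _subtract(intron_spans, cds_spans + utr5_spans + utr3_spans)

        clen = contig_lengths.get(chrom)
        tx_lo = min(t.span.start for t in coding)
        tx_hi = max(t.span.end for t in coding)
        if strand == "+":
            ext = (tx_hi, tx_hi + UTR_EXTENSION if clen is None else min(tx_hi + UTR_EXTENSION, clen))
            prom = (max(tx_lo - PROMOTER_FLANK, 0), tx_lo)
            prom_strand = "-"
        else:
            ext = (max(tx_lo - UTR_EXTENSION, 0), tx_lo)
            prom = (tx_hi, tx_hi + PROMOTER_FLANK if clen is None else min(tx_hi + PROMOTER_FLANK, clen))
            prom_strand = "+"

        feats = {
            "five_prime_utr": [GenomicInterval(chrom, s, e, strand) for s, e in utr5_spans],
            "cds": [GenomicInterval(chrom, s, e, strand) for s, e in cds_spans],
            "intron": [GenomicInterval(chrom, s, e, strand) for s, e in intron_spans],
            "three_prime_utr_ext": [GenomicInterval(chrom, s, e, strand) for s, e in utr3_spans]
            + ([GenomicInterval(chrom, ext[0], ext[1], strand)] if ext[1] > ext[0] else []),
            "promoter_antisense": (
                [GenomicInterval(chrom, prom[0], prom[1], prom_strand)] if prom[1] > prom[0] else []
            ),
        }
        part.genes[gene_id] = feats
    return part


@dataclass
class NullMatchSpec:
    """How the null pool is filtered and matched to a test set."""

    p_threshold: float = 0.05
    lower_q: float = 0.25
    upper_q: float = 0.75


def match_null(
    test_ids,
    ko_results,
    nls_results,
    lengths: dict,
    expression: dict,
    spec: NullMatchSpec = NullMatchSpec(),
) -> list:
    """Select null features matched to a test set on length and expression.

    Candidates must have p > ``spec.p_threshold`` in both joint models (no
    evidence of change) and length and expression within the closed
    [Q1, Q3] bounds of the test set.  Test features themselves are never
    returned.
    """
    test_ids = list(test_ids)
    # event tables carry both event_id and gene_id; the event is the feature
    id_col = "event_id" if "event_id" in ko_results.columns else "gene_id"
    ko_p = ko_results.set_index(id_col)["p"]
    nls_p = nls_results.set_index(id_col)["p"]

    t_len = np.array([lengths[t] for t in test_ids], dtype=float)
    t_expr = np.array([expression[t] for t in test_ids], dtype=float)
    len_lo, len_hi = np.quantile(t_len, [spec.lower_q, spec.upper_q])
    expr_lo, expr_hi = np.quantile(t_expr, [spec.lower_q, spec.upper_q])

    test_set = set(test_ids)
    null = []
    for fid in ko_p.index.intersection(nls_p.index):
        if fid in test_set:
            continue
        pk, pn = ko_p.loc[fid], nls_p.loc[fid]
        if not (np.isfinite(pk) and np.isfinite(pn)):
            continue
        if pk <= spec.p_threshold or pn <= spec.p_threshold:
            continue
        if fid not in lengths or fid not in expression:
            continue
        if not (len_lo <= lengths[fid] <= len_hi):
            continue
        if not (expr_lo <= expression[fid] <= expr_hi):
            continue
        null.append(fid)
    if not null:
        raise ValueError(
            "no null features satisfy the matching bounds; relax the "
            "quartile bounds or p threshold"
        )
    if len(null) < len(test_ids):
        warnings.warn(
            f"matched null set ({len(null)}) smaller than test set ({len(test_ids)})"
        )
    return null


def _cluster_trees(clusters) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for c in clusters:
        trees.setdefault((c.chrom, c.strand), IntervalTree()).addi(c.start, c.end)
    return trees


def _overlap_flags(regions, trees) -> np.ndarray:
    return np.array(
        [bool(trees.get((r.chrom, r.strand), IntervalTree()).overlap(r.start, r.end))
         for r in regions]
    )


def two_proportion_chi2(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Chi-square test of equal proportions on a 2x2 table, no continuity
    correction.  Degenerate margins give chi2 = 0, p = 1."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def overlap_test(test_regions, null_regions, clusters, test_name: str = "overlap") -> EnrichmentResult:
    """Compare CLIP-cluster overlap proportions between test and matched
    null regions.

    A region overlaps iff at least one same-strand cluster intersects it by
    one or more bases.
    """
    if not test_regions:
        raise ValueError("empty test region set")
    trees = _cluster_trees(clusters)
    t_hit = _overlap_flags(test_regions, trees)
    n_hit = _overlap_flags(null_regions, trees)
    chi2, p = two_proportion_chi2(int(t_hit.sum()), len(t_hit), int(n_hit.sum()), len(n_hit))
    return EnrichmentResult(
        test_name=test_name,
        n_test=len(t_hit),
        n_null=len(n_hit),
        prop_test=float(t_hit.mean()),
        prop_null=float(n_hit.mean()) if len(n_hit) else np.nan,
        chi2=chi2,
        p=p,
    )


def bonferroni(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    m = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p * m)
    return results


def feature_profile(
    up_ids, down_ids, null_ids, partition: FeaturePartition, clusters
) -> list[EnrichmentResult]:
    """CLIP overlap tests per genomic feature class for up- and
    down-regulated gene sets against a matched null, Bonferroni-corrected
    over the whole family."""
    results = []
    for direction, ids in (("up", up_ids), ("down", down_ids)):
        for label in FEATURE_LABELS:
            test_regions = partition.regions(label, ids)
            null_regions = partition.regions(label, null_ids)
            if not test_regions or not null_regions:
                continue
            results.append(
                overlap_test(test_regions, null_regions, clusters,
                             test_name=f"{label}/{direction}")
            )
    return bonferroni(results)


def median_conservation(regions, scores: list[ScoredInterval]) -> np.ndarray:
    """Median per-base conservation score within each region.

    Bases without a score are excluded (missing, not zero); a region with
    no scored base gets NaN.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int, float]]] = {}
    for si in scores:
        tmp.setdefault(si.interval.chrom, []).append(
            (si.interval.start, si.interval.end, si.score)
        )
    for chrom, rows in tmp.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        by_chrom[chrom] = (arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2])

    out = np.full(len(regions), np.nan)
    for i, r in enumerate(regions):
        if r.chrom not in by_chrom:
            continue
        starts, ends, vals = by_chrom[r.chrom]
        lo = np.searchsorted(ends, r.start, side="right")
        hi = np.searchsorted(starts, r.end, side="left")
        if hi <= lo:
            continue
        s = np.maximum(starts[lo:hi], r.start)
        e = np.minimum(ends[lo:hi], r.end)
        w = (e - s).astype(int)
        keep = w > 0
        if keep.any():
            out[i] = float(np.median(np.repeat(vals[lo:hi][keep], w[keep])))
    return out


def conservation_test(
    test_regions, null_regions, scores, threshold: float = 0.5,
    test_name: str = "conservation",
) -> EnrichmentResult:
    """Compare the proportion of regions with median phyloP above a
    threshold (strictly greater) between test and null sets; NA medians are
    excluded from both sides."""
    t_med = median_conservation(test_regions, scores)
    n_med = median_conservation(null_regions, scores)
    t_ok, n_ok = t_med[~np.isnan(t_med)], n_med[~np.isnan(n_med)]
    if len(t_ok) == 0 and len(n_ok) == 0:
        raise ValueError("all region medians are NA; no scored bases")
    t_hit = (t_ok > threshold).sum()
    n_hit = (n_ok > threshold).sum()
    chi2, p = two_proportion_chi2(int(t_hit), len(t_ok), int(n_hit), len(n_ok))
    return EnrichmentResult(
        test_name=test_name,
        n_test=len(t_ok),
        n_null=len(n_ok),
        prop_test=float(t_hit / len(t_ok)) if len(t_ok) else np.nan,
        prop_null=float(n_hit / len(n_ok)) if len(n_ok) else np.nan,
        chi2=chi2,
        p=p,
    )


def proximity_flag(regions, clusters, distance: int = 1_000) -> list[str]:
    """Flag each region as ``overlapping`` a same-strand cluster,
    ``within_distance`` of one (no direct overlap but a cluster within
    ``distance`` bases of either end), or ``none``."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    trees = _cluster_trees(clusters)
    flags = []
    for r in regions:
        tree = trees.get((r.chrom, r.strand))
        if tree is None:
            flags.append("none")
            continue
        if tree.overlap(r.start, r.end):
            flags.append("overlapping")
        elif tree.overlap(max(r.start - distance, 0), r.end + distance):
            flags.append("within_distance")
        else:
            flags.append("none")
    return flags
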