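"""Ground-truth simulator for the joint-model analyses.

Emulates the statistical structure of a multi-dataset FUS loss-of-function
study: three independent datasets, each with a knockout (KO) arm and an
NLS-mutant arm against wild-type controls; negative-binomial gene counts
whose NLS effects are an attenuated multiple of the KO effects; splicing
events with genotype-dependent PSI shifts concentrated in retained
introns; CLIP-cluster tracks enriched over regulated introns; and a
conservation track elevated over the same introns.  Heterozygotes carry
half the homozygote log2 effect (an additive dose model on the log scale).

Everything is driven by one `numpy` Generator seeded from
``SimulationConfig.seed``: a fixed seed reproduces the whole bundle
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .intervals import GenomicInterval, ScoredInterval, TranscriptModel
from .io import (
    CountMatrix,
    SampleSheet,
    write_bed,
    write_bedgraph,
    write_counts,
    write_gtf,
    write_sample_sheet,
)
from .splicing import SpliceEventTable, write_events

DATASET_NAMES = ("fratta", "dupuis", "bozzoni")
CHROM = "S1"

# gene architecture: 3 exons of 200 bp separated by 400 bp introns,
# CDS from mid-exon1 to mid-exon3, loci spaced so 5 kb flanks never collide
EXON_LEN = 200
INTRON_LEN = 400
GENE_LEN = 3 * EXON_LEN + 2 * INTRON_LEN
GENE_SPACING = GENE_LEN + 11_000
GENE_OFFSET = 6_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Fractions partition the gene universe into shared, KO-specific and
    NLS-specific differentially expressed genes; ``attenuation`` is the
    exact ratio of NLS to KO log2 effects for shared genes (and of logit
    PSI shifts for splicing), matching the loss-of-function structure the
    analysis is designed to detect.
    """

    n_genes: int = 2_000
    n_datasets: int = 3
    samples_per_group: int = 3
    baseline_mean_log: tuple[float, float] = (5.0, 1.5)  # ln-scale mean/sd of gene means
    dispersion: float = 0.05  # NB alpha, Var = mu + alpha mu^2
    frac_shared_de: float = 0.10
    frac_ko_specific: float = 0.05
    frac_nls_specific: float = 0.01
    attenuation: float = 0.76
    effect_sd: float = 1.0
    n_events: int = 1_000
    frac_ir_regulated: float = 0.10
    psi_shift: float = 2.0  # logit-scale shift for regulated events
    event_depth: int = 100
    clip_enrichment: float = 5.0
    clip_background: float = 0.15  # baseline cluster placement probability per intron
    conservation_shift: float = 2.0
    conservation_tile: int = 20  # bp per bedGraph segment
    het_datasets: tuple[str, ...] = ("fratta",)
    event_type_props: tuple[tuple[str, float], ...] = (
        ("retained_intron", 0.30),
        ("complex", 0.30),
        ("cassette_exon", 0.18),
        ("alt5", 0.15),
        ("alt3", 0.07),
    )
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_shared_de, self.frac_ko_specific, self.frac_nls_specific,
                 self.frac_ir_regulated)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must be in [0, 1]")
        if self.frac_shared_de + self.frac_ko_specific + self.frac_nls_specific > 1:
            raise ValueError("DE fractions must sum to <= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must be in (0, 1]")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2 (models unfittable otherwise)")
        if self.n_events == 0:
            raise ValueError("n_events must be > 0")
        if self.n_datasets < 1 or self.n_datasets > len(DATASET_NAMES):
            raise ValueError(f"n_datasets must be in [1, {len(DATASET_NAMES)}]")

    @property
    def datasets(self) -> tuple[str, ...]:
        return DATASET_NAMES[: self.n_datasets]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {CHROM: GENE_OFFSET + self.n_genes * GENE_SPACING}


@dataclass
class GroundTruth:
    """True parameters behind a simulated bundle (the oracle for recovery
    tests)."""

    genes: pd.DataFrame  # gene_id, category, ko_log2fc, nls_log2fc
    samples: SampleSheet
    size_factors: pd.Series
    events: pd.DataFrame | None = None  # event_id, gene_id, type, regulated, shifts
    cluster_flags: pd.DataFrame | None = None  # one row per intron, has_cluster


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for ds in config.datasets:
        genotypes = ["WT", "HOM"] + (["HET"] if ds in config.het_datasets else [])
        for arm in ("KO", "NLS"):
            for gt in genotypes:
                for i in range(config.samples_per_group):
                    rows.append((f"{ds}_{arm}_{gt}{i}", ds, gt, arm))
    return pd.DataFrame(rows, columns=["sample_id", "dataset", "genotype", "arm"])


def simulate_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, tuple[CountMatrix, SampleSheet]], GroundTruth]:
    """Draw per-dataset NB count matrices with known true effects.

    Counts follow NB(mean = sizefactor * baseline * 2^(effect * dose),
    dispersion) with dose 1 for homozygotes, 0.5 for heterozygotes and 0
    for wild type; size factors are log-uniform in [0.5, 2] per sample.
    For shared genes the NLS effect equals attenuation x KO effect exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n = config.n_genes

    n_shared = round(config.frac_shared_de * n)
    n_ko = round(config.frac_ko_specific * n)
    n_nls = round(config.frac_nls_specific * n)
    category = np.array(
        ["shared"] * n_shared + ["ko_specific"] * n_ko + ["nls_specific"] * n_nls
        + ["null"] * (n - n_shared - n_ko - n_nls)
    )
    ko_eff = np.zeros(n)
    nls_eff = np.zeros(n)
    base_eff = rng.normal(0.0, config.effect_sd, size=n)
    ko_eff[category == "shared"] = base_eff[category == "shared"]
    nls_eff[category == "shared"] = config.attenuation * base_eff[category == "shared"]
    ko_eff[category == "ko_specific"] = base_eff[category == "ko_specific"]
    nls_eff[category == "nls_specific"] = base_eff[category == "nls_specific"]

    mu_log, sd_log = config.baseline_mean_log
    baseline = rng.lognormal(mu_log, sd_log, size=n)

    sheet_df = _sample_frame(config)
    sf = pd.Series(
        np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(sheet_df))),
        index=sheet_df["sample_id"].to_numpy(),
        name="size_factor",
    )
    dose = sheet_df["genotype"].map({"WT": 0.0, "HET": 0.5, "HOM": 1.0}).to_numpy()
    arm_eff = np.where(sheet_df["arm"].to_numpy() == "KO", 1, 0)

    effects = np.where(arm_eff[None, :] == 1, ko_eff[:, None], nls_eff[:, None])
    mu = (
        baseline[:, None]
        * sf.to_numpy()[None, :]
        * np.power(2.0, effects * dose[None, :])
    )
    alpha = config.dispersion
    counts = rng.negative_binomial(n=1.0 / alpha, p=1.0 / (1.0 + alpha * mu))

    all_counts = pd.DataFrame(counts, index=genes, columns=sheet_df["sample_id"])
    sheet = SampleSheet(sheet_df)
    per_dataset = {}
    for ds in config.datasets:
        ids = sheet_df.loc[sheet_df["dataset"] == ds, "sample_id"]
        per_dataset[ds] = (
            CountMatrix(all_counts[list(ids)].copy()),
            sheet.subset(ids),
        )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {"gene_id": genes, "category": category, "ko_log2fc": ko_eff,
             "nls_log2fc": nls_eff}
        ),
        samples=sheet,
        size_factors=sf,
    )
    return per_dataset, truth


def combine_datasets(per_dataset) -> tuple[CountMatrix, SampleSheet]:
    """Concatenate per-dataset matrices/sheets into one joint pair."""
    mats = [cm.counts for cm, _ in per_dataset.values()]
    sheets = [sh.table for _, sh in per_dataset.values()]
    return (
        CountMatrix(pd.concat(mats, axis=1)),
        SampleSheet(pd.concat(sheets, ignore_index=True)),
    )


def simulate_annotation(config: SimulationConfig) -> list[TranscriptModel]:
    """One synthetic chromosome with non-overlapping three-exon gene loci.

    Each gene has a CDS spanning mid-exon1 to mid-exon3 so 5' and 3' UTRs
    and two introns exist and the feature partition is non-degenerate.
    Strand alternates between genes to exercise strand handling.
    """
    models = []
    for i, gid in enumerate(_gene_ids(config.n_genes)):
        g0 = GENE_OFFSET + i * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        e1 = (g0, g0 + EXON_LEN)
        e2 = (g0 + EXON_LEN + INTRON_LEN, g0 + 2 * EXON_LEN + INTRON_LEN)
        e3 = (g0 + 2 * EXON_LEN + 2 * INTRON_LEN, g0 + GENE_LEN)
        if strand == "+":
            cds = [(e1[0] + EXON_LEN // 2, e1[1]), e2, (e3[0], e3[0] + EXON_LEN // 2)]
        else:
            cds = [(e1[1] - EXON_LEN // 2, e1[1]), e2, (e3[0], e3[1] - EXON_LEN // 2)]
        models.append(
            TranscriptModel(
                transcript_id=f"{gid}_t1",
                gene_id=gid,
                exons=[GenomicInterval(CHROM, s, e, strand) for s, e in (e1, e2, e3)],
                cds=[GenomicInterval(CHROM, s, e, strand) for s, e in cds],
            )
        )
    return models


def _descriptor_for(etype: str, intron: GenomicInterval, flank: GenomicInterval | None):
    """Build a junction descriptor of the requested type around an intron."""
    d, a = intron.start, intron.end
    if etype == "retained_intron":
        return {"inclusion": [], "exclusion": [[d, a]]}
    if etype == "cassette_exon":
        # flank is the second intron; the exon between is the cassette
        d2, a2 = flank.start, flank.end
        return {"inclusion": [[d, a], [d2, a2]], "exclusion": [[d, a2]]}
    if etype == "alt5":
        return {"inclusion": [[d, a]], "exclusion": [[d + 30, a]]}
    if etype == "alt3":
        return {"inclusion": [[d, a]], "exclusion": [[d, a - 30]]}
    if etype == "complex":
        d2, a2 = flank.start, flank.end
        return {"inclusion": [[d, a]], "exclusion": [[d + 15, a - 15], [d2, a2]]}
    raise ValueError(f"unknown event type {etype!r}")


def simulate_events(
    config: SimulationConfig,
    truth: GroundTruth,
    annotation: list[TranscriptModel] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, SpliceEventTable]:
    """Draw per-dataset splice-event tables with known PSI shifts.

    Per event and sample, total reads ~ Poisson(event_depth x size factor)
    and inclusion ~ Binomial(total, psi) with psi = logistic(logit(base)
    + shift x dose).  Regulated events are retained introns whose KO-arm
    logit shift is ±psi_shift (predominantly negative: retention drops when
    FUS is lost) and whose NLS-arm shift is attenuation x the KO shift.
    Updates ``truth.events`` in place.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if annotation is None:
        annotation = simulate_annotation(config)
    by_gene = {m.gene_id: m for m in annotation}
    gene_ids = list(by_gene)
    if config.n_events > len(gene_ids):
        # several events per gene once the universe is exhausted
        hosts = [gene_ids[i % len(gene_ids)] for i in range(config.n_events)]
    else:
        hosts = gene_ids[: config.n_events]

    n_reg = round(config.frac_ir_regulated * config.n_events)
    types, props = zip(*config.event_type_props)
    props = np.asarray(props) / np.sum(props)
    drawn_types = rng.choice(types, size=config.n_events, p=props)
    drawn_types[:n_reg] = "retained_intron"

    base_psi = rng.uniform(0.3, 0.7, size=config.n_events)
    sign = np.where(rng.random(config.n_events) < 0.8, -1.0, 1.0)
    ko_shift = np.where(np.arange(config.n_events) < n_reg, sign * config.psi_shift, 0.0)
    nls_shift = config.attenuation * ko_shift

    sheet = truth.samples.table
    sf = truth.size_factors
    dose = sheet["genotype"].map({"WT": 0.0, "HET": 0.5, "HOM": 1.0}).to_numpy()
    is_ko = (sheet["arm"] == "KO").to_numpy()

    meta_rows = []
    for i in range(config.n_events):
        model = by_gene[hosts[i]]
        introns = model.introns()
        intron = introns[i % len(introns)] if drawn_types[i] != "cassette_exon" else introns[0]
        flank = introns[1] if len(introns) > 1 else introns[0]
        desc = _descriptor_for(drawn_types[i], intron, flank)
        meta_rows.append(
            (f"e{i:05d}", hosts[i], desc, intron.chrom, intron.start, intron.end,
             intron.strand)
        )
    meta = pd.DataFrame(
        meta_rows,
        columns=["event_id", "gene_id", "descriptor", "chrom", "start", "end", "strand"],
    )

    shift = np.where(is_ko[None, :], ko_shift[:, None], nls_shift[:, None])
    logit_psi = special.logit(base_psi)[:, None] + shift * dose[None, :]
    psi = special.expit(logit_psi)
    lam = config.event_depth * sf.loc[sheet["sample_id"]].to_numpy()[None, :]
    total = rng.poisson(np.broadcast_to(lam, psi.shape))
    inclusion = rng.binomial(total, psi)
    exclusion = total - inclusion

    inc = pd.DataFrame(inclusion, columns=sheet["sample_id"])
    exc = pd.DataFrame(exclusion, columns=sheet["sample_id"])

    truth.events = meta.drop(columns="descriptor").assign(
        type=drawn_types,
        regulated=np.arange(config.n_events) < n_reg,
        base_psi=base_psi,
        ko_shift=ko_shift,
        nls_shift=nls_shift,
    )

    out = {}
    for ds in config.datasets:
        ids = list(sheet.loc[sheet["dataset"] == ds, "sample_id"])
        out[ds] = SpliceEventTable(meta.copy(), inc[ids].copy(), exc[ids].copy())
    out["all"] = SpliceEventTable(meta, inc, exc)
    return out


def simulate_tracks(
    config: SimulationConfig,
    truth: GroundTruth,
    annotation: list[TranscriptModel],
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomicInterval], list[ScoredInterval]]:
    """Place CLIP clusters and a conservation track over the annotation.

    Each intron receives a cluster with probability ``clip_background``,
    multiplied by ``clip_enrichment`` (capped at 0.95) when the intron
    hosts a regulated event.  Conservation scores are Normal(0, 0.5) per
    tile, raised by ``conservation_shift`` over regulated introns.
    Clusters inherit the host gene's strand.  Updates
    ``truth.cluster_flags``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    regulated = set()
    if truth.events is not None:
        reg = truth.events[truth.events["regulated"]]
        regulated = {(r.chrom, r.start, r.end) for r in reg.itertuples()}

    clusters, scored, flag_rows = [], [], []
    for m in annotation:
        for intron in m.introns():
            key = (intron.chrom, intron.start, intron.end)
            is_reg = key in regulated
            p = config.clip_background * (config.clip_enrichment if is_reg else 1.0)
            p = min(p, 0.95)
            has_cluster = rng.random() < p
            if has_cluster:
                width = int(rng.integers(20, 61))
                start = int(rng.integers(intron.start, max(intron.end - width, intron.start) + 1))
                clusters.append(
                    GenomicInterval(intron.chrom, start, min(start + width, intron.end),
                                    m.strand)
                )
            flag_rows.append((m.gene_id, *key, is_reg, has_cluster))

            shift = config.conservation_shift if is_reg else 0.0
            pos = intron.start
            while pos < intron.end:
                end = min(pos + config.conservation_tile, intron.end)
                scored.append(
                    ScoredInterval(GenomicInterval(intron.chrom, pos, end, "."),
                                   float(rng.normal(shift, 0.5)))
                )
                pos = end
    truth.cluster_flags = pd.DataFrame(
        flag_rows,
        columns=["gene_id", "chrom", "start", "end", "regulated", "has_cluster"],
    )
    return clusters, scored


def simulate_attenuation_pairs(
    n: int,
    ratio: float,
    r_squared: float | None = None,
    sigma: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired effect sizes with a known attenuation ratio.

    KO effects x ~ N(0, 1); NLS/heterozygote effects y = ratio * x + e.
    The noise scale comes either from ``sigma`` directly or from the target
    coefficient of determination: with Var(ratio * x) = ratio^2, expected
    R^2 = ratio^2 / (ratio^2 + sigma^2), so sigma^2 = ratio^2 (1 - R^2)/R^2.
    """
    if (r_squared is None) == (sigma is None):
        raise ValueError("give exactly one of r_squared or sigma")
    rng = rng if rng is not None else np.random.default_rng(0)
    if sigma is None:
        sigma = abs(ratio) * np.sqrt((1.0 - r_squared) / r_squared)
    x = rng.normal(0.0, 1.0, size=n)
    y = ratio * x + rng.normal(0.0, sigma, size=n)
    return x, y


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["event_type_props"] = [list(t) for t in config.event_type_props]
    d["het_datasets"] = list(config.het_datasets)
    d["baseline_mean_log"] = list(config.baseline_mean_log)
    return d


def write_fixture_bundle(config: SimulationConfig, out_dir, force: bool = False) -> dict:
    """Generate and write the full fixture bundle; returns the manifest.

    The manifest records the config, seed and a checksum per file so a
    rerun with the same seed can be verified byte-identical.  Refuses to
    write into a non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")

    rng = np.random.default_rng(config.seed)
    annotation = simulate_annotation(config)
    per_dataset, truth = simulate_counts(config, rng)
    events = simulate_events(config, truth, annotation, rng)
    clusters, scored = simulate_tracks(config, truth, annotation, rng)

    files = {}
    for ds, (cm, sh) in per_dataset.items():
        files[f"counts_{ds}"] = f"counts_{ds}.tsv"
        write_counts(cm, out / f"counts_{ds}.tsv")
        files[f"samples_{ds}"] = f"samples_{ds}.tsv"
        write_sample_sheet(sh, out / f"samples_{ds}.tsv")
        files[f"events_{ds}"] = f"events_{ds}.tsv"
        write_events(events[ds], out / f"events_{ds}.tsv")
    files["annotation"] = "annotation.gtf"
    write_gtf(annotation, out / "annotation.gtf")
    files["clusters"] = "clusters.bed"
    write_bed(clusters, out / "clusters.bed")
    files["conservation"] = "conservation.bedgraph"
    write_bedgraph(scored, out / "conservation.bedgraph")
    files["truth_genes"] = "truth_genes.tsv"
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    files["truth_events"] = "truth_events.tsv"
    truth.events.to_csv(out / "truth_events.tsv", sep="\t", index=False)
    files["truth_introns"] = "truth_introns.tsv"
    truth.cluster_flags.to_csv(out / "truth_introns.tsv", sep="\t", index=False)

    checksums = {}
    for key, name in sorted(files.items()):
        h = hashlib.sha256((out / name).read_bytes()).hexdigest()
        checksums[name] = h
    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "datasets": list(config.datasets),
        "arms": ["KO", "NLS"],
        "files": files,
        "checksums": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
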