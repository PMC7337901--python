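"""End-to-end orchestration: simulate -> de -> splice -> overlap -> enrich.

Each stage is a plain function over files in a run directory, so every
stage can be run standalone with identical outputs; ``run_all`` chains them
and records a JSON manifest (config, seed, stage status, output files) so
a run is self-describing and a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, overlap, splicing
from .io import (
    SampleSheet,
    read_bed,
    read_bedgraph,
    read_counts,
    read_results,
    write_results,
)
from .simulate import SimulationConfig, write_fixture_bundle
from .splicing import read_events

log = logging.getLogger("lofsplice")

STAGES = ("simulate", "de", "splice", "overlap", "enrich")


@dataclass
class RunConfig:
    out_dir: str
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    min_total: int = 10
    min_cluster_reads: int = 2
    conservation_threshold: float = 0.5
    proximity_distance: int = 1_000
    force: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def bundle_dir(self) -> Path:
        return Path(self.out_dir) / "bundle"

    @property
    def results_dir(self) -> Path:
        return Path(self.out_dir) / "results"


def _load_bundle(config: RunConfig):
    bundle = config.bundle_dir
    with open(bundle / "manifest.json") as fh:
        manifest = json.load(fh)
    datasets = manifest["datasets"]
    mats, sheets = [], []
    for ds in datasets:
        cm, sh = read_counts(bundle / f"counts_{ds}.tsv", bundle / f"samples_{ds}.tsv")
        mats.append(cm.counts)
        sheets.append(sh.table)
    from .io import CountMatrix

    counts = CountMatrix(pd.concat(mats, axis=1))
    sheet = SampleSheet(pd.concat(sheets, ignore_index=True))
    ev_meta = None
    inc, exc = [], []
    for ds in datasets:
        tab = read_events(bundle / f"events_{ds}.tsv")
        ev_meta = tab.events
        inc.append(tab.inclusion)
        exc.append(tab.exclusion)
    events = splicing.SpliceEventTable(
        ev_meta, pd.concat(inc, axis=1), pd.concat(exc, axis=1)
    )
    return counts, sheet, events, manifest


def stage_simulate(config: RunConfig) -> dict:
    return write_fixture_bundle(config.sim, config.bundle_dir, force=config.force)


def stage_de(config: RunConfig) -> dict:
    counts, sheet, _, _ = _load_bundle(config)
    out = {}
    config.results_dir.mkdir(parents=True, exist_ok=True)
    for arm in ("KO", "NLS"):
        sub = sheet.select_comparison(arm, "HOM")
        res = diffexpr.fit_de(counts, sub, joint=True)
        path = config.results_dir / f"de_{arm}.tsv"
        write_results(res, path)
        out[f"de_{arm}"] = str(path)
    return out


def stage_splice(config: RunConfig) -> dict:
    _, sheet, events, _ = _load_bundle(config)
    out = {}
    config.results_dir.mkdir(parents=True, exist_ok=True)
    for arm in ("KO", "NLS"):
        sub = sheet.select_comparison(arm, "HOM")
        res = splicing.fit_usage(events, sub, joint=True, min_total=config.min_total)
        path = config.results_dir / f"splice_{arm}.tsv"
        write_results(res, path)
        out[f"splice_{arm}"] = str(path)
    # heterozygote comparisons (where available) for the dosage regression
    het_ds = [ds for ds in sheet.table["dataset"].unique()
              if (sheet.table["dataset"].eq(ds) & sheet.table["genotype"].eq("HET")).any()]
    for arm in ("KO", "NLS"):
        for ds in het_ds:
            sub = SampleSheet(sheet.table[sheet.table["dataset"] == ds]).select_comparison(arm, "HET")
            res = splicing.fit_usage(events, sub, joint=False, min_total=config.min_total)
            path = config.results_dir / f"splice_{arm}_het_{ds}.tsv"
            write_results(res, path)
            out[f"splice_{arm}_het_{ds}"] = str(path)
    return out


def _fit_to_row(name: str, fit: overlap.AttenuationFit) -> dict:
    return {
        "comparison": name,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "f_p": fit.f_p,
        "n": fit.n,
        "slope_through_origin": fit.slope_through_origin,
    }


def stage_overlap(config: RunConfig) -> dict:
    rd = config.results_dir
    out = {}
    fits = []
    for kind, id_col, eff in (("de", "gene_id", "log2fc"),
                              ("splice", "event_id", "log2_usage_fc")):
        ko = read_results(rd / f"{kind}_KO.tsv")
        nls = read_results(rd / f"{kind}_NLS.tsv")
        labels = overlap.classify_overlap(ko, nls, alpha=config.alpha, id_col=id_col)
        path = rd / f"overlap_{kind}.tsv"
        write_results(labels, path)
        out[f"overlap_{kind}"] = str(path)
        n_conc, n_disc, disc = overlap.direction_concordance(labels, ko, nls,
                                                            effect_col=eff, id_col=id_col)
        shared = overlap.shared_ids(labels)
        if len(shared) >= 3:
            k = ko.set_index(id_col).loc[shared, eff]
            n = nls.set_index(id_col).loc[shared, eff]
            try:
                fit = overlap.fit_attenuation(k, n)
                fits.append(_fit_to_row(f"{kind}_attenuation", fit))
            except ValueError as e:
                log.warning("attenuation fit skipped for %s: %s", kind, e)
        out[f"concordance_{kind}"] = {"concordant": n_conc, "discordant": n_disc,
                                      "discordant_ids": list(map(str, disc))}
    # dosage: heterozygote vs homozygote splicing effects
    for arm in ("KO", "NLS"):
        hom = read_results(rd / f"splice_{arm}.tsv")
        for het_path in sorted(rd.glob(f"splice_{arm}_het_*.tsv")):
            het = read_results(het_path)
            labels = overlap.classify_overlap(hom, het, alpha=config.alpha, id_col="event_id")
            shared = overlap.shared_ids(labels)
            if len(shared) >= 3:
                h = het.set_index("event_id").loc[shared, "log2_usage_fc"]
                m = hom.set_index("event_id").loc[shared, "log2_usage_fc"]
                try:
                    fit = overlap.fit_dosage(h, m)
                    fits.append(_fit_to_row(f"dosage_{arm}_{het_path.stem}", fit))
                except ValueError as e:
                    log.warning("dosage fit skipped for %s: %s", arm, e)
    fit_df = pd.DataFrame(fits) if fits else pd.DataFrame(
        columns=["comparison", "slope", "intercept", "r_squared", "f_p", "n",
                 "slope_through_origin"])
    path = rd / "attenuation_fits.tsv"
    write_results(fit_df, path)
    out["attenuation_fits"] = str(path)
    return out


def stage_enrich(config: RunConfig) -> dict:
    rd = config.results_dir
    bundle = config.bundle_dir
    counts, sheet, events, _ = _load_bundle(config)
    clusters = read_bed(bundle / "clusters.bed", min_score=config.min_cluster_reads)
    scores = read_bedgraph(bundle / "conservation.bedgraph")

    splice_ko = read_results(rd / "splice_KO.tsv")
    splice_nls = read_results(rd / "splice_NLS.tsv")
    labels = read_results(rd / "overlap_splice.tsv")
    shared = set(labels.loc[labels["label"].isin(
        ["shared_strict", "shared_relaxed_only"]), "feature_id"])
    ir_ids = [e for e in splice_ko.loc[splice_ko["type"] == "retained_intron", "event_id"]
              if e in shared]
    if not ir_ids:  # fall back to KO-significant retained introns
        ir_ids = list(splice_ko.loc[(splice_ko["type"] == "retained_intron")
                                    & (splice_ko["fdr"] < config.alpha), "event_id"])

    ev = events.events.set_index("event_id")
    lengths = {e: int(r["end"] - r["start"]) for e, r in ev.iterrows()}
    # event "expression" = mean normalized total count in control samples
    sf = diffexpr.size_factors(counts)
    wt = [s for s in sheet.sample_ids
          if sheet.table.set_index("sample_id").loc[s, "genotype"] == "WT"]
    totals = (events.inclusion[wt] + events.exclusion[wt]).div(sf.loc[wt], axis=1)
    expression = dict(zip(events.event_ids, totals.mean(axis=1)))

    null_ids = enrichment.match_null(ir_ids, splice_ko, splice_nls, lengths, expression)

    def regions(ids):
        return [events.intron(e) for e in ids]

    results = [
        enrichment.overlap_test(regions(ir_ids), regions(null_ids), clusters,
                                test_name="retained_intron/clip"),
        enrichment.conservation_test(regions(ir_ids), regions(null_ids), scores,
                                     threshold=config.conservation_threshold,
                                     test_name="retained_intron/conservation"),
    ]
    enrichment.bonferroni(results)
    table = pd.DataFrame([dataclasses.asdict(r) for r in results])
    path = rd / "enrichment.tsv"
    write_results(table, path)

    prox = enrichment.proximity_flag(regions(ir_ids), clusters,
                                     distance=config.proximity_distance)
    prox_df = pd.DataFrame({"event_id": ir_ids, "proximity": prox})
    prox_path = rd / "proximity.tsv"
    write_results(prox_df, prox_path)
    return {"enrichment": str(path), "proximity": str(prox_path),
            "n_test": len(ir_ids), "n_null": len(null_ids)}


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order, recording a manifest; raises on stage
    failure after marking later outputs stale."""
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "alpha": config.alpha,
            "min_total": config.min_total,
            "min_cluster_reads": config.min_cluster_reads,
            "conservation_threshold": config.conservation_threshold,
            "proximity_distance": config.proximity_distance,
            "seed": config.sim.seed,
            "sim": dataclasses.asdict(config.sim),
        },
        "stages": {},
    }
    funcs = {
        "simulate": stage_simulate,
        "de": stage_de,
        "splice": stage_splice,
        "overlap": stage_overlap,
        "enrich": stage_enrich,
    }
    manifest_path = Path(config.out_dir) / "run_manifest.json"
    for stage in STAGES:
        log.info("stage %s: starting", stage)
        try:
            result = funcs[stage](config)
            manifest["stages"][stage] = {"status": "completed", "outputs": _jsonable(result)}
        except Exception as e:
            log.error("stage %s failed: %s", stage, e)
            manifest["stages"][stage] = {
                "status": "failed",
                "error": f"{type(e).__name__}: {e}",
                "traceback": traceback.format_exc(),
            }
            for later in STAGES[STAGES.index(stage) + 1:]:
                manifest["stages"][later] = {"status": "stale"}
            _write_manifest(manifest, manifest_path)
            raise
        log.info("stage %s: completed", stage)
    _write_manifest(manifest, manifest_path)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_manifest(manifest: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)


def report(manifest: dict, results_dir=None) -> str:
    """Human-readable run summary: overlap label counts, attenuation and
    dosage fits, discordant counts and the enrichment table."""
    lines = ["lofsplice run report", "===================="]
    incomplete = [s for s, st in manifest["stages"].items()
                  if st.get("status") != "completed"]
    if incomplete:
        lines.append(f"WARNING: incomplete stages: {', '.join(incomplete)}")
    ov = manifest["stages"].get("overlap", {})
    if ov.get("status") == "completed":
        outputs = ov["outputs"]
        for kind in ("de", "splice"):
            path = outputs.get(f"overlap_{kind}")
            if path and Path(path).exists():
                labels = read_results(path)["label"].value_counts()
                lines.append(f"\n{kind} overlap labels:")
                for lab, cnt in labels.items():
                    lines.append(f"  {lab:>20}: {cnt}")
            conc = outputs.get(f"concordance_{kind}")
            if conc:
                lines.append(
                    f"  {kind}: {conc['concordant']} concordant, "
                    f"{conc['discordant']} discordant shared features"
                )
        fits_path = outputs.get("attenuation_fits")
        if fits_path and Path(fits_path).exists():
            fits = read_results(fits_path)
            if len(fits):
                lines.append("\nattenuation / dosage fits (beta = slope):")
                for r in fits.itertuples(index=False):
                    lines.append(
                        f"  {r.comparison}: beta={r.slope:.3f} "
                        f"(R2={r.r_squared:.3f}, n={int(r.n)})"
                    )
            else:
                lines.append("\nno shared features: regressions skipped")
    en = manifest["stages"].get("enrich", {})
    if en.get("status") == "completed":
        path = en["outputs"].get("enrichment")
        if path and Path(path).exists():
            table = read_results(path)
            lines.append("\nenrichment tests:")
            for r in table.itertuples(index=False):
                lines.append(
                    f"  {r.test_name}: {r.prop_test:.3f} vs {r.prop_null:.3f} "
                    f"(chi2={r.chi2:.2f}, p_bonf={r.p_bonferroni:.3g})"
                )
    return "\n".join(lines) + "\n"
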