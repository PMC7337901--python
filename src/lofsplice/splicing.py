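"""Splicing-event quantification and differential usage.

Events arrive as inclusion/exclusion read-count tables with a junction
descriptor and the coordinates of the encompassing intron.  PSI (percent
spliced in) is inclusion / (inclusion + exclusion).  Differential usage is
tested per event with a beta-binomial regression on the logit scale — the
natural model for an inclusion count out of a total — with a dataset
covariate in the joint model and a likelihood-ratio test on genotype,
falling back to plain binomial when there is no evidence of
overdispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .intervals import GenomicInterval
from .io import SampleSheet

EVENT_TYPES = ("retained_intron", "cassette_exon", "alt5", "alt3", "complex", "other")


@dataclass
class SpliceEventTable:
    """Per-event inclusion/exclusion counts plus structural descriptors.

    ``events`` holds one row per event (event_id, gene_id, descriptor dict,
    encompassing-intron coordinates); ``inclusion`` and ``exclusion`` are
    events x samples integer count frames sharing the event index.
    """

    events: pd.DataFrame
    inclusion: pd.DataFrame
    exclusion: pd.DataFrame

    def __post_init__(self):
        if self.events["event_id"].duplicated().any():
            raise ValueError("duplicate event ids")
        for name, df in (("inclusion", self.inclusion), ("exclusion", self.exclusion)):
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative {name} count")
        if not self.inclusion.columns.equals(self.exclusion.columns):
            raise ValueError("inclusion and exclusion sample columns differ")

    @property
    def event_ids(self) -> list[str]:
        return list(self.events["event_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.inclusion.columns)

    def intron(self, event_id: str) -> GenomicInterval:
        row = self.events.set_index("event_id").loc[event_id]
        return GenomicInterval(
            str(row["chrom"]), int(row["start"]), int(row["end"]), row["strand"]
        )


def _junctions(descriptor: dict, form: str) -> set[tuple[int, int]]:
    return {tuple(j) for j in descriptor.get(form, [])}


def classify_event(descriptor: dict) -> str:
    """Assign exactly one splicing-event type from the junction descriptor.

    * retained_intron — the inclusion form is the unspliced intron of a
      single donor-acceptor pair (no inclusion junction, one exclusion
      junction).
    * cassette_exon — one internal exon present/absent; the two inclusion
      junctions share their outer coordinates with the single exclusion
      junction.
    * alt5 / alt3 — a single alternative donor / acceptor.
    * complex — more than one elementary alternative at the locus.
    * other — none of the above (degenerate descriptors).
    """
    inc = _junctions(descriptor, "inclusion")
    exc = _junctions(descriptor, "exclusion")
    if not inc and not exc:
        raise ValueError("empty descriptor: no junctions in either form")
    if inc == exc:
        return "other"
    if not inc and len(exc) == 1:
        return "retained_intron"
    if len(inc) == 2 and len(exc) == 1:
        (d1, a1), (d2, a2) = sorted(inc)
        (de, ae) = next(iter(exc))
        if a1 <= d2 and de == d1 and ae == a2:
            return "cassette_exon"
    if len(inc) == 1 and len(exc) == 1:
        (di, ai) = next(iter(inc))
        (de, ae) = next(iter(exc))
        if ai == ae and di != de:
            return "alt5"
        if di == de and ai != ae:
            return "alt3"
        return "complex"  # both splice sites differ: two elementary alternatives
    if len(inc) + len(exc) >= 3:
        return "complex"
    return "other"


def compute_psi(events: SpliceEventTable, min_total: int = 10) -> pd.DataFrame:
    """PSI per event and sample: inclusion / (inclusion + exclusion).

    Returns a long frame (event_id, sample_id, psi, total, low_coverage);
    psi is NaN where the total is zero, and totals below ``min_total`` are
    flagged low-coverage.
    """
    inc = events.inclusion.to_numpy(dtype=float)
    exc = events.exclusion.to_numpy(dtype=float)
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, inc / np.where(total > 0, total, 1), np.nan)
    rows = []
    for i, eid in enumerate(events.event_ids):
        for j, sid in enumerate(events.sample_ids):
            rows.append((eid, sid, psi[i, j], int(total[i, j]), total[i, j] < min_total))
    return pd.DataFrame(rows, columns=["event_id", "sample_id", "psi", "total", "low_coverage"])


def delta_psi(psi: pd.DataFrame, sheet: SampleSheet) -> pd.Series:
    """Mean mutant PSI minus mean wild-type PSI per event, NA-aware."""
    gt = sheet.table.set_index("sample_id")["genotype"]
    sub = psi[psi["sample_id"].isin(gt.index)].copy()
    sub["is_wt"] = sub["sample_id"].map(gt).eq("WT")
    out = {}
    for eid, grp in sub.groupby("event_id", sort=False):
        wt = grp.loc[grp["is_wt"], "psi"].dropna()
        mut = grp.loc[~grp["is_wt"], "psi"].dropna()
        out[eid] = np.nan if (wt.empty or mut.empty) else float(mut.mean() - wt.mean())
    return pd.Series(out, name="delta_psi")


def classify_cryptic_skiptic(
    results: pd.DataFrame,
    psi: pd.DataFrame,
    sheet: SampleSheet,
    low_thr: float = 0.05,
    high_thr: float = 0.95,
    min_gain: float = 0.10,
) -> pd.Series:
    """Label cassette exons as cryptic, skiptic or neither from group PSI.

    Cryptic: essentially absent in wild type (mean WT PSI <= ``low_thr``)
    but gaining inclusion under perturbation.  Skiptic: constitutively
    included in wild type (>= ``high_thr``) but skipped under perturbation.
    """
    if (results["type"] != "cassette_exon").any():
        bad = results.loc[results["type"] != "cassette_exon", "event_id"].iloc[0]
        raise ValueError(f"non-cassette event {bad!r} passed to cryptic/skiptic classifier")
    gt = sheet.table.set_index("sample_id")["genotype"]
    sub = psi[psi["sample_id"].isin(gt.index)].copy()
    sub["is_wt"] = sub["sample_id"].map(gt).eq("WT")
    labels = {}
    for eid in results["event_id"]:
        grp = sub[sub["event_id"] == eid]
        wt = grp.loc[grp["is_wt"], "psi"].dropna().mean()
        mut = grp.loc[~grp["is_wt"], "psi"].dropna().mean()
        if np.isnan(wt) or np.isnan(mut):
            labels[eid] = "neither"
        elif wt <= low_thr and mut >= low_thr + min_gain:
            labels[eid] = "cryptic"
        elif wt >= high_thr and mut <= high_thr - min_gain:
            labels[eid] = "skiptic"
        else:
            labels[eid] = "neither"
    return pd.Series(labels, name="cryptic_skiptic")


def _bb_negll(beta, X, k, m, rho):
    """Negative beta-binomial log-likelihood, mean on the logit scale, fixed
    intra-class correlation rho."""
    p = special.expit(X @ beta)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    nu = (1.0 - rho) / rho
    return -np.sum(stats.betabinom.logpmf(k, m, p * nu, (1.0 - p) * nu))


def _fit_binomial(X, k, m):
    """Binomial logistic fit by Newton scoring; returns (beta, loglik)."""
    import statsmodels.api as sm

    resp = np.column_stack([k, m - k])
    model = sm.GLM(resp, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    return np.asarray(res.params), float(res.llf), res


def fit_usage(
    events: SpliceEventTable,
    sheet: SampleSheet,
    joint: bool = True,
    min_total: int = 10,
) -> pd.DataFrame:
    """Differential splicing usage per event.

    For each event, inclusion counts given totals are modelled on the logit
    scale with a genotype indicator (plus dataset covariates when
    ``joint``).  Overdispersion is estimated per event by the method of
    moments (Pearson dispersion of the binomial fit); when it exceeds 1 the
    likelihood is beta-binomial with that intra-class correlation, else
    plain binomial.  A likelihood-ratio chi-square on the genotype
    coefficient gives the p-value; BH adjustment runs across testable
    events.  ``log2_usage_fc`` is the genotype log-odds coefficient / ln 2.
    """
    from .diffexpr import bh_adjust

    sheet_samples = [s for s in events.sample_ids if s in set(sheet.sample_ids)]
    meta = sheet.table.set_index("sample_id").loc[sheet_samples]
    genotype = (meta["genotype"] != "WT").to_numpy(dtype=float)
    datasets = sorted(meta["dataset"].unique())
    cols = [np.ones(len(sheet_samples)), genotype]
    if joint and len(datasets) > 1:
        for ds in datasets[1:]:
            cols.append((meta["dataset"] == ds).to_numpy(dtype=float))
    X_alt = np.column_stack(cols)
    X_null = np.delete(X_alt, 1, axis=1)

    inc = events.inclusion[sheet_samples].to_numpy(dtype=float)
    exc = events.exclusion[sheet_samples].to_numpy(dtype=float)
    total = inc + exc

    psi_long = compute_psi(events, min_total=min_total)
    dpsi = delta_psi(psi_long[psi_long["sample_id"].isin(sheet_samples)], sheet)

    records = []
    for i, eid in enumerate(events.event_ids):
        m, k = total[i], inc[i]
        use = m > 0
        row = events.events.iloc[i]
        etype = classify_event(row["descriptor"])
        if (m < min_total).all() or use.sum() < X_alt.shape[1] + 1:
            records.append((eid, row["gene_id"], etype, np.nan, np.nan, dpsi.get(eid, np.nan)))
            continue
        Xa, Xn, kk, mm = X_alt[use], X_null[use], k[use], m[use]
        try:
            beta_alt, ll_alt, res_alt = _fit_binomial(Xa, kk, mm)
            beta_null, ll_null, _ = _fit_binomial(Xn, kk, mm)
            df_resid = len(kk) - Xa.shape[1]
            phi = res_alt.pearson_chi2 / df_resid if df_resid > 0 else 1.0
            # switch to beta-binomial only on evidence of lack of fit
            # (Pearson X^2 significant at 5%); fitting noise-level
            # overdispersion would deflate the LRT on binomial data
            overdispersed = (
                df_resid > 0
                and phi > 1.0
                and stats.chi2.sf(res_alt.pearson_chi2, df_resid) < 0.05
            )
            if overdispersed:
                # method-of-moments intra-class correlation from the
                # variance inflation, then beta-binomial ML at fixed rho
                rho = float(np.clip((phi - 1.0) / max(mm.mean() - 1.0, 1.0), 1e-6, 0.95))
                opt_alt = optimize.minimize(
                    _bb_negll, beta_alt, args=(Xa, kk, mm, rho), method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
                opt_null = optimize.minimize(
                    _bb_negll, beta_null, args=(Xn, kk, mm, rho), method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
                ll_alt, ll_null = -opt_alt.fun, -opt_null.fun
                coef = opt_alt.x[1]
            else:
                coef = beta_alt[1]
            lrt = max(0.0, 2.0 * (ll_alt - ll_null))
            p = float(stats.chi2.sf(lrt, df=1))
            records.append((eid, row["gene_id"], etype, coef / np.log(2), p, dpsi.get(eid, np.nan)))
        except Exception:
            records.append((eid, row["gene_id"], etype, np.nan, np.nan, dpsi.get(eid, np.nan)))

    out = pd.DataFrame(
        records,
        columns=["event_id", "gene_id", "type", "log2_usage_fc", "p", "delta_psi"],
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["model"] = "joint" if joint else "per-dataset"
    return out[["event_id", "gene_id", "type", "log2_usage_fc", "p", "fdr", "delta_psi", "model"]]


def write_events(events: SpliceEventTable, path) -> None:
    """Serialise an event table as TSV with a JSON descriptor column."""
    df = events.events.copy()
    df["descriptor"] = df["descriptor"].map(lambda d: json.dumps(d, sort_keys=True))
    for s in events.sample_ids:
        df[f"inc__{s}"] = events.inclusion[s].to_numpy()
        df[f"exc__{s}"] = events.exclusion[s].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> SpliceEventTable:
    df = pd.read_csv(path, sep="\t")
    df["descriptor"] = df["descriptor"].map(json.loads)
    inc_cols = [c for c in df.columns if c.startswith("inc__")]
    exc_cols = [c for c in df.columns if c.startswith("exc__")]
    samples = [c[len("inc__"):] for c in inc_cols]
    inclusion = df[inc_cols].astype(np.int64)
    inclusion.columns = samples
    exclusion = df[exc_cols].astype(np.int64)
    exclusion.columns = samples
    meta = df[[c for c in df.columns if not (c.startswith("inc__") or c.startswith("exc__"))]]
    return SpliceEventTable(meta.reset_index(drop=True), inclusion, exclusion)
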