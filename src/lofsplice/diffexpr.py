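"""Negative-binomial differential expression with a dataset covariate.

A deliberately compact engine in the DESeq2 mould: median-of-ratios size
factors, per-gene method-of-moments dispersion shrunk toward a mean trend,
and a per-gene NB log-link GLM (offset = log size factor) with a Wald test
on the genotype coefficient.  The joint model pools the datasets of one
comparison arm and adds a dataset indicator; with a single dataset it
reduces exactly to the per-dataset model.  No Bayesian fold-change
shrinkage: effect estimates here are plain MLEs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleSheet

DISPERSION_FLOOR = 1e-8


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios normalisation factors, one per sample.

    factor_j = median over genes of count_gj / geometric-mean_g, using only
    genes with a positive geometric mean (i.e. expressed in every sample).
    """
    arr = counts.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(arr).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter the matrix "
            "or merge samples before normalisation"
        )
    ratios = arr[usable] / np.exp(log_geo[usable])[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def normalized_counts(counts: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    return counts.counts / sf.reindex(counts.sample_ids).to_numpy()


def estimate_dispersion(
    counts: CountMatrix, sf: pd.Series, design: SampleSheet
) -> pd.Series:
    """Per-gene NB dispersion alpha (Var = mu + alpha mu^2).

    Method of moments on normalized counts within design groups
    (dataset x genotype), pooled across groups by residual degrees of
    freedom, then shrunk 50/50 toward a mean-dispersion trend
    alpha_trend(mu) = a/mu + b fit by least squares.  Floored at 1e-8;
    all-zero genes sit at the floor.
    """
    norm = normalized_counts(counts, sf)
    meta = design.table.set_index("sample_id").loc[counts.sample_ids]
    groups = meta.groupby(["dataset", "genotype"]).groups

    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for _, idx in groups.items():
        sub = norm[list(idx)].to_numpy()
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
        w = sub.shape[1] - 1
        num += w * np.nan_to_num(a)
        den += w
    raw = np.maximum(num / np.maximum(den, 1), 0.0)

    mu_all = norm.to_numpy().mean(axis=1)
    expressed = mu_all > 0
    if expressed.sum() >= 2:
        # least-squares fit of alpha ~ a/mu + b over expressed genes
        A = np.column_stack([1.0 / mu_all[expressed], np.ones(expressed.sum())])
        coef, *_ = np.linalg.lstsq(A, raw[expressed], rcond=None)
        with np.errstate(divide="ignore"):
            trend = np.where(mu_all > 0, coef[0] / np.where(mu_all > 0, mu_all, 1) + coef[1], 0.0)
        trend = np.maximum(trend, 0.0)
        alpha = 0.5 * raw + 0.5 * trend
    else:
        alpha = raw
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    alpha[~expressed] = DISPERSION_FLOOR
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaN entries propagate unadjusted."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        bad = p[ok][(p[ok] < 0) | (p[ok] > 1)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _design_matrix(meta: pd.DataFrame, joint: bool) -> np.ndarray:
    genotype = (meta["genotype"] != "WT").to_numpy(dtype=float)
    cols = [np.ones(len(meta)), genotype]
    if joint:
        datasets = sorted(meta["dataset"].unique())
        for ds in datasets[1:]:
            cols.append((meta["dataset"] == ds).to_numpy(dtype=float))
    return np.column_stack(cols)


def filter_genes(counts: CountMatrix, sheet: SampleSheet, min_group_nonzero: int = 1) -> CountMatrix:
    """Drop genes with zero counts across all samples of any design group
    (GLM stability)."""
    meta = sheet.table.set_index("sample_id").loc[counts.sample_ids]
    keep = np.ones(counts.shape[0], dtype=bool)
    for _, idx in meta.groupby(["dataset", "genotype"]).groups.items():
        sub = counts.counts[list(idx)].to_numpy()
        keep &= (sub > 0).sum(axis=1) >= min_group_nonzero
    return CountMatrix(counts.counts.loc[keep])


def fit_de(
    counts: CountMatrix,
    sheet: SampleSheet,
    joint: bool = True,
    sf: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB GLM differential expression, WT vs non-WT.

    Returns one row per gene with log2 fold change, standard error, Wald
    statistic, p and BH FDR; genes failing convergence get NA and are
    excluded from the BH adjustment.  ``sheet`` should already be subset to
    one comparison (one arm, WT plus one mutant genotype) via
    ``SampleSheet.select_comparison``.
    """
    samples = [s for s in counts.sample_ids if s in set(sheet.sample_ids)]
    cm = CountMatrix(counts.counts[samples])
    meta = sheet.table.set_index("sample_id").loc[samples]
    if joint and meta["dataset"].nunique() < 1:
        raise ValueError("joint model requires >= 1 dataset")
    if sf is None:
        sf = size_factors(cm)
    sf = sf.reindex(samples)
    if dispersion is None:
        dispersion = estimate_dispersion(cm, sf, SampleSheet(meta.reset_index()))
    X = _design_matrix(meta, joint)
    offset = np.log(sf.to_numpy())
    norm_mean = normalized_counts(cm, sf).mean(axis=1)

    log2 = np.log(2.0)
    # small-sample calibration: refer the Wald statistic to a t distribution
    # with residual degrees of freedom rather than the normal
    df_resid = max(X.shape[0] - X.shape[1], 1)
    n_failed = 0
    records = []
    for gene, y in cm.counts.iterrows():
        alpha = float(dispersion.loc[gene])
        yv = y.to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
                res = sm.GLM(yv, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
            coef, se = float(res.params[1]), float(res.bse[1])
            if not (np.isfinite(coef) and np.isfinite(se) and se > 0 and se < 1e3):
                raise RuntimeError("non-finite or degenerate Wald components")
            z = coef / se
            p = 2.0 * stats.t.sf(abs(z), df_resid)
            records.append((gene, coef / log2, se / log2, z, p))
        except Exception:
            n_failed += 1
            records.append((gene, np.nan, np.nan, np.nan, np.nan))
    if n_failed:
        warnings.warn(f"{n_failed} gene model(s) failed to converge; reported as NA")

    out = pd.DataFrame(records, columns=["gene_id", "log2fc", "se", "wald_stat", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["mean_expr"] = norm_mean.to_numpy()
    out["model"] = "joint" if joint else "per-dataset"
    return out


def relative_expression(
    counts: CountMatrix, sf: pd.Series, sheet: SampleSheet
) -> pd.DataFrame:
    """Normalized counts rescaled to the per-dataset wild-type mean.

    The WT mean maps to 1.0 within each dataset; genes whose WT mean is zero
    get NA for that dataset.
    """
    norm = normalized_counts(counts, sf)
    meta = sheet.table.set_index("sample_id").loc[counts.sample_ids]
    out = norm.copy().astype(float)
    for ds, idx in meta.groupby("dataset").groups.items():
        ds_samples = list(idx)
        wt = [s for s in ds_samples if meta.loc[s, "genotype"] == "WT"]
        if not wt:
            raise ValueError(f"dataset {ds!r} has no WT sample")
        wt_mean = norm[wt].mean(axis=1)
        denom = wt_mean.replace(0.0, np.nan)
        out[ds_samples] = norm[ds_samples].div(denom, axis=0)
    return out
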