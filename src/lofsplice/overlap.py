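"""Comparing the knockout and NLS-mutant joint models.

Features (genes or splicing events) tested in both arms are classified as
shared, arm-specific or unchanged under a strict rule (FDR < alpha in both
models) or a relaxed rule (FDR < alpha in one and raw p < alpha in the
other).  Shared features feed the attenuation regression — an OLS fit of
the mutant-arm effect sizes on the knockout-arm effect sizes whose slope
below one quantifies a partial loss of function — and the analogous
heterozygote-on-homozygote dosage regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

LABELS = ("shared_strict", "shared_relaxed_only", "ko_specific", "nls_specific", "neither")


@dataclass
class AttenuationFit:
    """OLS fit of y on x with intercept; slope < 1 means attenuation."""

    slope: float
    intercept: float
    r_squared: float
    f_p: float
    n: int
    slope_through_origin: float  # reported alongside for transparency

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("attenuation fit needs n >= 3")


def classify_overlap(ko: pd.DataFrame, nls: pd.DataFrame, alpha: float = 0.05,
                     id_col: str | None = None) -> pd.DataFrame:
    """Label every feature by its significance pattern across the two arms.

    Strict sharing: FDR < alpha in both models.  Relaxed-only sharing: FDR
    < alpha in exactly one model and raw p < alpha in the other.
    Arm-specific: FDR < alpha on one side, raw p >= alpha on the other.
    Ties at exactly FDR = alpha are non-significant.  Features present in
    only one model are excluded with a warning.
    """
    if id_col is None:
        id_col = "event_id" if "event_id" in ko.columns else "gene_id"
    k = ko.set_index(id_col)
    n = nls.set_index(id_col)
    common = k.index.intersection(n.index)
    dropped = len(k.index.symmetric_difference(n.index))
    if dropped:
        warnings.warn(f"{dropped} feature(s) present in only one model; excluded")
    rows = []
    for fid in common:
        kf, nf = k.loc[fid], n.loc[fid]
        ko_sig = kf["fdr"] < alpha
        nls_sig = nf["fdr"] < alpha
        ko_nom = kf["p"] < alpha
        nls_nom = nf["p"] < alpha
        if ko_sig and nls_sig:
            label = "shared_strict"
        elif ko_sig and nls_nom:
            label = "shared_relaxed_only"
        elif nls_sig and ko_nom:
            label = "shared_relaxed_only"
        elif ko_sig:
            label = "ko_specific"
        elif nls_sig:
            label = "nls_specific"
        else:
            label = "neither"
        rows.append((fid, label, kf["p"], kf["fdr"], nf["p"], nf["fdr"]))
    return pd.DataFrame(
        rows, columns=["feature_id", "label", "ko_p", "ko_fdr", "nls_p", "nls_fdr"]
    )


def shared_ids(overlap: pd.DataFrame) -> list:
    """Strict plus relaxed shared features (the set used for regressions)."""
    m = overlap["label"].isin(["shared_strict", "shared_relaxed_only"])
    return list(overlap.loc[m, "feature_id"])


def direction_concordance(
    overlap: pd.DataFrame, ko: pd.DataFrame, nls: pd.DataFrame,
    effect_col: str | None = None, id_col: str | None = None,
) -> tuple[int, int, list]:
    """Count shared features whose effects agree/disagree in sign.

    Discordant means sign(ko effect) * sign(nls effect) < 0; exact zeros
    count as concordant.
    """
    if id_col is None:
        id_col = "event_id" if "event_id" in ko.columns else "gene_id"
    if effect_col is None:
        effect_col = "log2fc" if "log2fc" in ko.columns else "log2_usage_fc"
    k = ko.set_index(id_col)[effect_col]
    n = nls.set_index(id_col)[effect_col]
    discordant = []
    n_conc = 0
    for fid in shared_ids(overlap):
        if np.sign(k.loc[fid]) * np.sign(n.loc[fid]) < 0:
            discordant.append(fid)
        else:
            n_conc += 1
    return n_conc, len(discordant), discordant


def fit_attenuation(ko_lfc, nls_lfc) -> AttenuationFit:
    """OLS of NLS effects on KO effects (intercept included).

    The slope is the attenuation coefficient beta; the F-test p is for
    slope = 0.  A through-origin slope is reported alongside since the
    no-intercept variant is sometimes preferred for fold-change pairs.
    """
    x = np.asarray(ko_lfc, dtype=float)
    y = np.asarray(nls_lfc, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"attenuation fit needs >= 3 paired finite values, got {len(x)}")
    if np.var(x) == 0:
        raise ValueError("zero variance in KO effects; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    origin = float(np.sum(x * y) / np.sum(x * x))
    return AttenuationFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        f_p=float(res.f_pvalue),
        n=int(len(x)),
        slope_through_origin=origin,
    )


def fit_dosage(het_lfc, hom_lfc) -> AttenuationFit:
    """OLS of heterozygote effects on homozygote effects (dose response)."""
    return fit_attenuation(hom_lfc, het_lfc)


def intersect_sets(set_a, set_b, universe) -> tuple[int, float, float]:
    """Fisher's exact test for the overlap of two feature sets.

    Returns (overlap count, odds ratio, two-sided p) for the 2x2 table of
    membership in ``set_a`` x membership in ``set_b`` over ``universe``.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    stray = (a | b) - universe
    if stray:
        raise ValueError(f"features outside universe: {sorted(stray)[:10]}")
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(universe) - both - a_only - b_only
    odds, p = stats.fisher_exact([[both, a_only], [b_only, neither]], alternative="two-sided")
    return both, float(odds), float(p)
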