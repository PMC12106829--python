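"""Trait summaries, BLUP correlations, class comparisons and metabolite stats.

Complements the mixed-model stage: arithmetic genotypic means for ordinal or
binary traits where BLUP modelling is inappropriate, Pearson correlations
between trait BLUPs with a significance mask, pooled-variance t-tests between
grain-colour classes, and differential-abundance testing for metabolite
feature tables (log10 transform, Pareto scaling, per-feature t-tests with
Benjamini-Hochberg FDR, and volcano fold-change classification).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def genotypic_means(table: pd.DataFrame, trait: str) -> pd.Series:
    """Arithmetic mean of plot values per genotype (ordinal/binary traits)."""
    if trait not in table.columns:
        raise ValueError(f"trait {trait!r} not in table")
    return table.groupby("accession")[trait].mean()


def correlate_blups(blups: pd.DataFrame, alpha: float = 0.05):
    """Pearson correlations between trait columns on pairwise-complete values.

    Returns ``(r, p, significant)`` DataFrames; constant traits (or pairs
    with fewer than 3 complete observations) are NaN and masked out.
    """
    traits = list(blups.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = blups[[traits[i], traits[j]]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    sig = (pdf < alpha) & pdf.notna()
    return rdf, pdf, sig


def class_ttest(values, classes) -> tuple[float, float]:
    """Pooled-variance two-sample t-test between two classes.

    Returns ``(t, two-sided p)``.  With zero pooled variance, identical class
    means give ``(0, 1)`` and different means give ``(inf-signed, 0)``.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    levels = pd.unique(classes)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(levels)}")
    a = values[classes == levels[0]]
    b = values[classes == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("class_ttest: zero within-class variance with "
                       "different means; p -> 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def pareto_scale(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Centre then divide by the square root of the standard deviation."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x - mu) / np.sqrt(sd)


def differential_features(intensities: pd.DataFrame, classes,
                          fdr: float = 0.05, fc_lo: float = 0.83,
                          fc_hi: float = 1.2) -> pd.DataFrame:
    """Two-class differential test per metabolite feature.

    ``intensities`` is samples x features (strictly positive).  Each feature
    is log10-transformed and Pareto-scaled across samples, then tested with a
    pooled-variance t-test; p-values get Benjamini-Hochberg q-values.  Fold
    change is mean(class1 raw) / mean(class2 raw), where class1 is the first
    label encountered (by convention the brown-grain class); the volcano
    class compares log2 FC against log2(fc_lo) and log2(fc_hi).

    Returns a per-feature table with columns ``log2_fc``, ``t``, ``p``,
    ``q``, ``differential`` and ``volcano``.  Zero-variance features are
    skipped (logged) and appear with NaN statistics.
    """
    X = intensities.to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("intensities must be strictly positive")
    classes = np.asarray(classes)
    levels = list(pd.unique(classes))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 classes, got {levels}")
    m1, m2 = classes == levels[0], classes == levels[1]
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("each class needs n >= 3 samples")

    Z = pareto_scale(np.log10(X), axis=0)
    nfeat = X.shape[1]
    tvals = np.full(nfeat, np.nan)
    pvals = np.full(nfeat, np.nan)
    skipped = 0
    for j in range(nfeat):
        a, b = Z[m1, j], Z[m2, j]
        if np.ptp(Z[:, j]) == 0 or not np.isfinite(Z[:, j]).all():
            skipped += 1
            continue
        res = stats.ttest_ind(a, b, equal_var=True)
        tvals[j], pvals[j] = res.statistic, res.pvalue
    if skipped:
        logger.info("differential_features: skipped %d zero-variance features",
                    skipped)
    tested = np.isfinite(pvals)
    qvals = np.full(nfeat, np.nan)
    if tested.any():
        qvals[tested] = stats.false_discovery_control(pvals[tested], method="bh")

    fc = X[m1].mean(axis=0) / X[m2].mean(axis=0)
    log2fc = np.log2(fc)
    lo, hi = np.log2(fc_lo), np.log2(fc_hi)
    volcano = np.where(log2fc <= lo, "down",
                       np.where(log2fc >= hi, "up", "inside"))
    return pd.DataFrame({
        "feature": list(intensities.columns),
        "log2_fc": log2fc,
        "t": tvals,
        "p": pvals,
        "q": qvals,
        "differential": (qvals < fdr) & tested,
        "volcano": volcano,
    }).set_index("feature")
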