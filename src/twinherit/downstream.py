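"""Gene-list enrichment and heritability/feature correlations.

Enrichment uses Fisher's exact test on the 2x2 (in-list x significant) table
over a declared background gene universe, reporting the conditional
maximum-likelihood odds ratio with its exact 95% CI — the convention of R's
``fisher.test`` — rather than the sample cross-product ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .errors import ValidationError

__all__ = ["EnrichmentResult", "FeatureCorrelation", "fisher_exact_2x2",
           "fisher_enrichment", "feature_correlation"]

#: relative tolerance guard against floating-point ties in the two-sided rule
_P_TIE_GUARD = 1.0 + 1e-7


@dataclass
class EnrichmentResult:
    table: np.ndarray  # [[sig&list, sig&!list], [!sig&list, !sig&!list]]
    odds_ratio: float
    or_ci_lo: float
    or_ci_hi: float
    pvalue: float
    n_background: int
    n_list_dropped: int = 0


@dataclass
class FeatureCorrelation:
    feature: str
    n: int
    r: float
    pvalue: float
    n_dropped: int = 0


def fisher_exact_2x2(table: np.ndarray, level: float = 0.95):
    """Two-sided Fisher exact p and conditional-ML odds ratio with exact CI.

    The p-value sums hypergeometric point probabilities not exceeding the
    observed one (with a small relative tolerance guard). Zero-margin tables
    give p = 1 and an undefined (1.0) odds ratio.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("fisher test needs a 2x2 table of non-negative counts")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0, 1.0, 0.0, np.inf

    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    pvalue = float(min(1.0, pmf[pmf <= p_obs * _P_TIE_GUARD].sum()))

    res = _odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    or_hat = float(res.statistic)
    return pvalue, or_hat, float(ci.low), float(ci.high)


def fisher_enrichment(significant_genes, list_genes, background_genes,
                      level: float = 0.95) -> EnrichmentResult:
    """Enrichment of ``significant_genes`` for ``list_genes`` within a background.

    List genes absent from the background are dropped (their count is
    recorded); significant genes must be a subset of the background.
    """
    background = set(background_genes)
    significant = set(significant_genes)
    if not background:
        raise ValidationError("empty background gene set")
    if not significant:
        raise ValidationError("empty significant gene set")
    outside = significant - background
    if outside:
        raise ValidationError(
            f"significant gene {sorted(outside)[0]!r} absent from background")
    raw_list = set(list_genes)
    in_list = raw_list & background
    n_dropped = len(raw_list) - len(in_list)

    a = len(significant & in_list)
    b = len(significant) - a
    c = len(in_list) - a
    d = len(background) - len(significant) - c
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    pvalue, or_hat, lo, hi = fisher_exact_2x2(table, level=level)
    return EnrichmentResult(table=table, odds_ratio=or_hat, or_ci_lo=lo,
                            or_ci_hi=hi, pvalue=pvalue,
                            n_background=len(background),
                            n_list_dropped=n_dropped)


def feature_correlation(gene_results: pd.DataFrame, annotation: pd.DataFrame,
                        feature: str, only_significant: bool = True,
                        q_threshold: float = 0.05) -> FeatureCorrelation:
    """Pearson correlation of gene-level h2 with an annotation feature.

    Genes lacking the feature are dropped with a recorded count; two-sided
    p from the t transform (scipy's default).
    """
    if feature not in ("gc_percent", "gene_length"):
        raise ValidationError(f"unsupported feature {feature!r}")
    df = gene_results.copy()
    if only_significant:
        df = df[df["q"] < q_threshold]
    feat = (annotation.drop_duplicates("gene_symbol")
            .set_index("gene_symbol")[feature])
    merged = df.assign(feature=pd.to_numeric(df["gene_symbol"].map(feat),
                                             errors="coerce"))
    n_before = len(merged)
    merged = merged[np.isfinite(merged["feature"]) & np.isfinite(merged["h2"])]
    n_dropped = n_before - len(merged)
    if len(merged) < 3:
        raise ValidationError("feature correlation needs at least 3 genes with data")
    x = merged["h2"].to_numpy(float)
    y = merged["feature"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in h2 or feature: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return FeatureCorrelation(feature=feature, n=len(merged), r=float(r),
                              pvalue=float(p), n_dropped=n_dropped)
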