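"""Genome-wide heritability scan: per-probe model fits, FDR, gene aggregation.

For each retained probe the pipeline residualizes expression on the sample
covariates, applies the rank inverse-normal transform, fits the ACE, AE, CE
and E models, selects the best model by AIC and tests heritability by the
AE-vs-E likelihood ratio. Benjamini-Hochberg adjustment is applied across
probes; gene-level results take the probe with the highest h2 and a fresh BH
pass over the selected probes' p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import StudyBundle
from .errors import NumericalError, ValidationError
from .preprocess import (build_design, detection_filter, rank_inverse_normal,
                         residualize)
from .twin_model import (TwinPairSet, bootstrap_ci, compare_models,
                         fit_all_models, heritability_test)

__all__ = ["ScanConfig", "scan", "bh_adjust", "aggregate_genes",
           "chromosome_summary"]

PROBE_RESULT_COLUMNS = ["probe_id", "gene_symbol", "chromosome", "best_model",
                        "h2", "ci_lo", "ci_hi", "pvalue", "q"]
GENE_RESULT_COLUMNS = ["gene_symbol", "ensembl_id", "selected_probe_id", "h2",
                       "ci_lo", "ci_hi", "pvalue", "q", "n_probes",
                       "n_significant_probes"]


@dataclass
class ScanConfig:
    detection_alpha: float = 0.05
    detection_min_samples: int = 3
    skip_detection_filter: bool = False
    covariates: tuple[str, ...] = ("age", "sex", "batch", "rin", "wbc")
    use_covariates: bool = True
    q_threshold: float = 0.05
    bootstrap: bool = False
    bootstrap_b: int = 1000
    seed: int = 0
    counts: dict = field(default_factory=dict)  # filled by scan() for logging


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    ``q_i = min_{j >= i} p_(j) * m / j`` after ascending sort, capped at 1.
    Values outside (0, 1] are a hard error; exclude missing entries first.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d array")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[~(np.isfinite(p) & (p > 0) & (p <= 1))][0]
        raise ValidationError(f"p-value {bad!r} outside (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pair_indices(pair_table: pd.DataFrame, sample_order: list[str]):
    pos = {s: i for i, s in enumerate(sample_order)}
    mz = pair_table[pair_table["zygosity"] == "MZ"]
    dz = pair_table[pair_table["zygosity"] == "DZ"]
    idx = lambda df: (df["sample_1"].map(pos).to_numpy(),
                      df["sample_2"].map(pos).to_numpy())
    return idx(mz), idx(dz)


def scan(bundle: StudyBundle, cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Run the full per-probe analysis; returns the probe result table.

    Probes whose fits fail numerically are flagged (``converged`` False, NaN
    p/q) and excluded from the FDR pass but kept in the output.
    """
    cfg = cfg or ScanConfig()
    counts = {"probes_in": bundle.n_probes, "samples_in": bundle.n_samples}

    if cfg.skip_detection_filter or bundle.detection is None:
        if not cfg.skip_detection_filter:
            raise ValidationError(
                "no detection matrix in study; set skip_detection_filter to "
                "analyze all probes explicitly")
        retained = list(bundle.expression.index)
    else:
        retained = detection_filter(bundle, cfg.detection_alpha,
                                    cfg.detection_min_samples)
    counts["probes_retained"] = len(retained)
    if not retained:
        raise ValidationError("no probes pass the detection filter")

    samples = bundle.samples_in_expression_order()
    design = build_design(samples, cfg.covariates) if cfg.use_covariates else None
    expr = bundle.expression.loc[retained]
    resid = residualize(expr.to_numpy(float), design)
    # probes with (residual-)constant values carry no ordering information:
    # flag them as failed instead of aborting the scan
    degenerate = np.ptp(resid, axis=1) <= 1e-12
    values = np.zeros_like(resid)
    if (~degenerate).any():
        values[~degenerate] = rank_inverse_normal(resid[~degenerate])

    pair_table, n_singletons = bundle.complete_pairs()
    counts["singletons_dropped"] = n_singletons
    (mz1, mz2), (dz1, dz2) = _pair_indices(pair_table, list(expr.columns))
    if len(mz1) < 2 or len(dz1) < 2:
        raise ValidationError("need at least 2 complete pairs per zygosity")
    counts["mz_pairs"] = len(mz1)
    counts["dz_pairs"] = len(dz1)

    annot = bundle.annotation.set_index("probe_id")
    rows = []
    n_failed = 0
    for i, probe in enumerate(retained):
        y = values[i]
        try:
            if degenerate[i]:
                raise NumericalError("constant residuals")
            pairs = TwinPairSet(np.column_stack([y[mz1], y[mz2]]),
                                np.column_stack([y[dz1], y[dz2]]))
            fits = fit_all_models(pairs)
            comparison = compare_models(fits)
            ht = heritability_test(pairs)
            converged = ht.converged and all(f.converged for f in fits.values())
        except Exception:
            converged = False
            comparison = ht = None
        if not converged:
            n_failed += 1
            rows.append({"probe_id": probe, "best_model": "NA", "h2": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "pvalue": np.nan,
                         "converged": False})
            continue
        row = {"probe_id": probe, "best_model": comparison.best_model,
               "h2": ht.h2, "ci_lo": ht.ci_lo, "ci_hi": ht.ci_hi,
               "pvalue": ht.pvalue, "converged": True}
        if cfg.bootstrap:
            row["boot_lo"], row["boot_hi"] = bootstrap_ci(
                pairs, B=cfg.bootstrap_b, seed=cfg.seed + i)
        rows.append(row)
    counts["probes_failed"] = n_failed

    result = pd.DataFrame(rows)
    result["gene_symbol"] = result["probe_id"].map(annot["gene_symbol"])
    result["chromosome"] = result["probe_id"].map(annot["chromosome"]).astype(str)
    result["q"] = np.nan
    ok = result["converged"].to_numpy()
    if ok.any():
        result.loc[ok, "q"] = bh_adjust(result.loc[ok, "pvalue"].to_numpy())
    counts["probes_significant"] = int((result["q"] < cfg.q_threshold).sum())
    cfg.counts = counts

    lead = [c for c in PROBE_RESULT_COLUMNS if c in result.columns]
    extra = [c for c in result.columns if c not in lead]
    return result[lead + extra]


def aggregate_genes(probe_results: pd.DataFrame, annotation: pd.DataFrame,
                    q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene results: the max-h2 probe represents the gene.

    Ties on h2 break toward the smaller p-value, then the lexicographically
    smaller probe id. Gene-level q is a fresh BH pass over the selected
    probes' p-values.
    """
    annot = annotation.set_index("probe_id")
    missing = [p for p in probe_results["probe_id"] if p not in annot.index]
    if missing:
        raise ValidationError(f"probe {missing[0]!r} missing from annotation")

    df = probe_results.copy()
    df["ensembl_id"] = df["probe_id"].map(annot["ensembl_id"])
    df["gene_symbol"] = df["probe_id"].map(annot["gene_symbol"])
    if "converged" in df.columns:
        df = df[df["converged"]]
    df = df[np.isfinite(df["h2"])]

    df = df.sort_values(["gene_symbol", "h2", "pvalue", "probe_id"],
                        ascending=[True, False, True, True], kind="stable")
    rows = []
    for gene, grp in df.groupby("gene_symbol", sort=True):
        top = grp.iloc[0]
        rows.append({
            "gene_symbol": gene,
            "ensembl_id": top["ensembl_id"],
            "selected_probe_id": top["probe_id"],
            "h2": top["h2"],
            "ci_lo": top["ci_lo"],
            "ci_hi": top["ci_hi"],
            "pvalue": top["pvalue"],
            "n_probes": len(grp),
            "n_significant_probes": int((grp["q"] < q_threshold).sum()),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["q"] = np.nan
    return out[[c for c in GENE_RESULT_COLUMNS if c in out.columns]]


def chromosome_summary(gene_results: pd.DataFrame, annotation: pd.DataFrame | None = None,
                       q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-chromosome counts and mean h2 among FDR-significant genes."""
    df = gene_results.copy()
    if "chromosome" not in df.columns:
        if annotation is None:
            raise ValidationError("chromosome_summary needs annotation when "
                                  "gene results lack a chromosome column")
        chrom = annotation.drop_duplicates("gene_symbol").set_index("gene_symbol")["chromosome"]
        df["chromosome"] = df["gene_symbol"].map(chrom).astype(str)
    rows = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        sig = grp[grp["q"] < q_threshold]
        rows.append({
            "chromosome": chrom,
            "n_genes": len(grp),
            "n_significant": len(sig),
            "proportion_significant": len(sig) / len(grp) if len(grp) else 0.0,
            "mean_h2_significant": float(sig["h2"].mean()) if len(sig) else np.nan,
        })
    return pd.DataFrame(rows, columns=["chromosome", "n_genes", "n_significant",
                                       "proportion_significant",
                                       "mean_h2_significant"])
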