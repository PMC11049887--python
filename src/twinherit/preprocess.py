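"""Probe filtering, covariate residualization and rank inverse-normal transform.

The analyzed phenotype for each probe is the rank-based inverse-normal
transform of the ordinary-least-squares residuals of log-expression on the
sample covariates (age, sex, batch, RIN, white-blood-cell count).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm, rankdata

from .errors import ValidationError

__all__ = [
    "detection_filter",
    "build_design",
    "residualize",
    "rank_inverse_normal",
    "transform_matrix",
]

DEFAULT_COVARIATES = ("age", "sex", "batch", "rin", "wbc")


def detection_filter(bundle, alpha: float = 0.05, min_samples: int = 3) -> list[str]:
    """Probes detected (p strictly below ``alpha``) in >= ``min_samples`` samples.

    Returns retained probe ids in input order. The inequality is strict, so a
    sample at exactly ``p == alpha`` does not count as detected.
    """
    if bundle.detection is None:
        raise ValidationError(
            "no detection p-value matrix present; pass detection_filter=False "
            "(CLI: skip_detection_filter: true) to analyze all probes"
        )
    detected = (bundle.detection.to_numpy() < alpha).sum(axis=1)
    keep = detected >= min_samples
    return list(bundle.detection.index[keep])


def build_design(samples: pd.DataFrame,
                 covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Full-rank design matrix with intercept.

    Sex is coded F=0 / M=1; batch is expanded into dummy columns dropping the
    first (sorted) level as reference; numeric covariates enter as-is.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (samples["sex"].astype(str).str.upper() == "M").to_numpy(float)
        elif cov == "batch":
            levels = sorted(samples["batch"].astype(str).unique())
            for lv in levels[1:]:
                cols[f"batch_{lv}"] = (samples["batch"].astype(str) == lv).to_numpy(float)
        else:
            vals = pd.to_numeric(samples[cov], errors="coerce")
            if vals.isna().any():
                bad = samples.loc[vals.isna(), "sample_id"].iloc[0]
                raise ValidationError(f"non-numeric {cov} for sample {bad!r}")
            cols[cov] = vals.to_numpy(float)
    return pd.DataFrame(cols, index=samples.index)


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, _, pivots = linalg.qr(x, mode="economic", pivoting=True)
        culprits = [design.columns[p] for p in pivots[rank:]]
        raise ValidationError(
            f"design matrix is rank-deficient; collinear column(s): {culprits}"
        )


def residualize(y: np.ndarray, covariates: pd.DataFrame | np.ndarray | None = None
                ) -> np.ndarray:
    """Ordinary-least-squares residuals of ``y`` on the design columns.

    An intercept is always included (prepended unless the design already has a
    constant column named ``intercept``). Residuals are orthogonal to every
    design column. A rank-deficient design is a hard error naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None:
        return y - np.mean(y)
    if isinstance(covariates, np.ndarray):
        covariates = pd.DataFrame(
            covariates, columns=[f"x{i}" for i in range(np.atleast_2d(covariates.T).shape[0])]
            if covariates.ndim > 1 else ["x0"],
        )
    design = covariates.copy()
    if "intercept" not in design.columns:
        design.insert(0, "intercept", 1.0)
    if len(design) != y.shape[-1] if y.ndim > 1 else len(design) != len(y):
        raise ValidationError("covariate rows do not match phenotype length")
    _check_full_rank(design)
    x = design.to_numpy(float)
    beta, *_ = np.linalg.lstsq(x, y.T if y.ndim > 1 else y, rcond=None)
    resid = (y.T if y.ndim > 1 else y) - x @ beta
    return resid.T if y.ndim > 1 else resid


def rank_inverse_normal(v: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse normal transform with average ranks for ties.

    Maps value with rank ``r`` (1-based, ties averaged) among ``n`` to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``. Order-preserving; requires
    at least two distinct values.
    """
    v = np.asarray(v, dtype=float)
    n = v.shape[-1] if v.ndim > 1 else v.size
    if n < 3:
        raise ValidationError("rank inverse normal transform requires n >= 3")
    if v.ndim == 1:
        if np.all(v == v[0]):
            raise ValidationError("all values identical: no ordering information")
        ranks = rankdata(v)
    else:
        if np.any(np.all(v == v[:, :1], axis=1)):
            raise ValidationError("a probe has all-identical values: no ordering information")
        ranks = rankdata(v, axis=1)
    return norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def transform_matrix(expr: pd.DataFrame, design: pd.DataFrame | None,
                     offset: float = 3.0 / 8.0) -> pd.DataFrame:
    """Residualize + INT every probe row of a probe x sample matrix at once."""
    resid = residualize(expr.to_numpy(float), design)
    return pd.DataFrame(rank_inverse_normal(resid, offset=offset),
                        index=expr.index, columns=expr.columns)
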