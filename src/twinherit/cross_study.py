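"""Harmonization of per-gene heritability summaries across cohorts.

Studies are joined on version-stripped, case-normalized Ensembl ids; the
false-discovery-rate adjustment is recomputed per study within the common
gene set, then Venn-style overlap counts and pairwise h2 correlations are
reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .scan import bh_adjust

__all__ = ["OverlapReport", "normalize_ensembl", "prepare_study", "harmonize",
           "overlap_fdr", "overlap_report"]


@dataclass
class OverlapReport:
    n_common: int
    flags: pd.DataFrame            # gene x study booleans (q < threshold)
    venn_counts: dict[str, int]    # "A&B" -> count significant in exactly {A,B}
    pairwise_r: pd.DataFrame       # study x study Pearson r of h2
    top_common: pd.DataFrame       # genes significant everywhere, by 1st-study h2


def normalize_ensembl(ids: pd.Series) -> pd.Series:
    """Strip '.N' version suffixes and upper-case Ensembl gene ids."""
    return ids.astype(str).str.split(".").str[0].str.upper()


def prepare_study(df: pd.DataFrame, study_label: str | None = None) -> pd.DataFrame:
    """Normalize ids; collapse multi-record genes to the highest-h2 record."""
    label = study_label or df.attrs.get("study_label", "study")
    out = df.copy()
    out["ensembl_id"] = normalize_ensembl(out["ensembl_id"])
    n_before = len(out)
    out = (out.sort_values(["ensembl_id", "h2"], ascending=[True, False],
                           kind="stable")
           .drop_duplicates("ensembl_id", keep="first")
           .reset_index(drop=True))
    out.attrs["study_label"] = label
    out.attrs["n_collapsed"] = n_before - len(out)
    return out


def harmonize(studies: list[pd.DataFrame],
              labels: list[str] | None = None) -> pd.DataFrame:
    """Intersect >= 2 studies on normalized Ensembl ids.

    Returns a gene-indexed table with columns ``<label>_h2`` / ``<label>_p``.
    Duplicate post-strip ids within a study are a hard error (collapse them
    first with :func:`prepare_study`).
    """
    if len(studies) < 2:
        raise ValidationError("harmonization needs at least 2 studies")
    if labels is None:
        labels = [s.attrs.get("study_label", f"study{i + 1}")
                  for i, s in enumerate(studies)]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate study labels: {labels}")

    normed = []
    for label, s in zip(labels, studies):
        s = s.copy()
        s["ensembl_id"] = normalize_ensembl(s["ensembl_id"])
        dups = s["ensembl_id"][s["ensembl_id"].duplicated()].unique()
        if len(dups):
            raise ValidationError(
                f"study {label!r} has duplicate Ensembl ids after version "
                f"stripping: {sorted(dups)[:5]}")
        normed.append(s.set_index("ensembl_id"))

    common = sorted(set.intersection(*(set(s.index) for s in normed)))
    if not common:
        warnings.warn("no genes common to all studies", stacklevel=2)
    out = pd.DataFrame(index=pd.Index(common, name="ensembl_id"))
    for label, s in zip(labels, normed):
        out[f"{label}_h2"] = s.loc[common, "h2"]
        out[f"{label}_p"] = s.loc[common, "pvalue"]
    out.attrs["labels"] = list(labels)
    return out


def _labels_of(common: pd.DataFrame) -> list[str]:
    labels = common.attrs.get("labels")
    if not labels:
        labels = [c[:-3] for c in common.columns if c.endswith("_h2")]
    return labels


def overlap_fdr(common: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-study BH flags recomputed within the common gene set only."""
    if len(common) < 2:
        raise ValidationError("need at least 2 common genes to recompute FDR")
    flags = pd.DataFrame(index=common.index)
    for label in _labels_of(common):
        p = common[f"{label}_p"]
        if p.isna().any():
            gene = p.index[p.isna()][0]
            raise ValidationError(f"missing p-value for common gene {gene!r} "
                                  f"in study {label!r}")
        q = bh_adjust(p.to_numpy(float))
        flags[label] = q < q_threshold
        flags[f"{label}_q"] = q
    return flags


def overlap_report(flags: pd.DataFrame, common: pd.DataFrame,
                   top_k: int = 10) -> OverlapReport:
    """Venn counts, pairwise h2 correlations and the all-significant top table."""
    labels = _labels_of(common)
    bool_flags = flags[labels]

    venn: dict[str, int] = {}
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            in_combo = bool_flags[list(combo)].all(axis=1)
            out_combo = ~bool_flags[[l for l in labels if l not in combo]].any(axis=1) \
                if len(combo) < len(labels) else pd.Series(True, index=bool_flags.index)
            venn["&".join(combo)] = int((in_combo & out_combo).sum())

    r = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        if len(common) >= 3:
            rv = stats.pearsonr(common[f"{a}_h2"], common[f"{b}_h2"])[0]
        else:
            rv = np.nan
        r.loc[a, b] = r.loc[b, a] = rv

    everywhere = bool_flags.all(axis=1)
    first = labels[0]
    top = (common.loc[everywhere]
           .sort_values(f"{first}_h2", ascending=False)
           .head(top_k)
           .reset_index())
    return OverlapReport(n_common=len(common), flags=flags, venn_counts=venn,
                         pairwise_r=r, top_common=top)
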