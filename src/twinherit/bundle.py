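"""Validated in-memory representation of one twin expression study."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

SAMPLE_COLUMNS = ["sample_id", "pair_id", "zygosity", "age", "sex", "batch", "rin", "wbc"]
ANNOTATION_COLUMNS = ["probe_id", "gene_symbol", "ensembl_id", "chromosome",
                      "gc_percent", "gene_length"]
ZYGOSITIES = {"MZ", "DZ"}


def _first_dup(values) -> str | None:
    seen = set()
    for v in values:
        if v in seen:
            return str(v)
        seen.add(v)
    return None


@dataclass
class StudyBundle:
    """Expression matrix + optional detection p-values + metadata + annotation.

    ``expression`` and ``detection`` are probe x sample DataFrames indexed by
    probe id; ``samples`` has one row per sample id; ``annotation`` one row
    per probe id.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame
    detection: pd.DataFrame | None = None

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        expr = self.expression
        dup = _first_dup(expr.index)
        if dup is not None:
            raise ValidationError(f"duplicated probe row {dup!r} in expression matrix")
        dup = _first_dup(expr.columns)
        if dup is not None:
            raise ValidationError(f"duplicated sample column {dup!r} in expression matrix")
        if expr.isna().to_numpy().any():
            probe = expr.index[expr.isna().any(axis=1)][0]
            raise ValidationError(f"missing expression value for probe {probe!r}")

        samples = self.samples
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing_cols:
            raise ValidationError(f"sample table missing column(s): {missing_cols}")
        dup = _first_dup(samples["sample_id"])
        if dup is not None:
            raise ValidationError(f"duplicated sample id {dup!r} in sample table")
        meta_ids = set(samples["sample_id"])
        for sid in expr.columns:
            if sid not in meta_ids:
                raise ValidationError(
                    f"sample {sid!r} present in expression but absent from metadata"
                )
        analyzed = samples[samples["sample_id"].isin(set(expr.columns))]
        counts = analyzed["pair_id"].value_counts()
        over = counts[counts > 2]
        if len(over):
            raise ValidationError(
                f"pair {over.index[0]!r} has {int(over.iloc[0])} members (max 2)"
            )
        zyg = analyzed["zygosity"].astype(str).str.upper()
        bad = analyzed.loc[~zyg.isin(ZYGOSITIES), "zygosity"]
        if len(bad):
            raise ValidationError(f"invalid zygosity label {bad.iloc[0]!r} (expected MZ or DZ)")
        # both members of a pair share zygosity
        nzyg = analyzed.assign(_z=zyg).groupby("pair_id")["_z"].nunique()
        mixed = nzyg[nzyg > 1]
        if len(mixed):
            raise ValidationError(f"pair {mixed.index[0]!r} mixes MZ and DZ labels")
        for cov in ("age", "sex", "batch", "rin", "wbc", "zygosity", "pair_id"):
            if analyzed[cov].isna().any():
                sid = analyzed.loc[analyzed[cov].isna(), "sample_id"].iloc[0]
                raise ValidationError(f"missing {cov} for analyzed sample {sid!r}")

        if self.detection is not None:
            det = self.detection
            if list(det.index) != list(expr.index) or list(det.columns) != list(expr.columns):
                # allow same sets in different order by realigning
                if set(det.index) != set(expr.index) or set(det.columns) != set(expr.columns):
                    raise ValidationError(
                        "detection matrix probe/sample ids differ from expression matrix"
                    )
                self.detection = det = det.loc[expr.index, expr.columns]
            vals = det.to_numpy(float)
            if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
                raise ValidationError("detection p-values must lie in [0, 1]")

        annot = self.annotation
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
        if missing_cols:
            raise ValidationError(f"annotation table missing column(s): {missing_cols}")
        dup = _first_dup(annot["probe_id"])
        if dup is not None:
            raise ValidationError(f"duplicated probe id {dup!r} in annotation table")

    # -- convenience --------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def samples_in_expression_order(self) -> pd.DataFrame:
        """Sample metadata reindexed to the expression column order."""
        s = self.samples.set_index("sample_id", drop=False)
        return s.loc[list(self.expression.columns)].reset_index(drop=True)

    def complete_pairs(self) -> tuple[pd.DataFrame, int]:
        """(pair table, n singletons dropped).

        The pair table has columns pair_id, zygosity, sample_1, sample_2 with
        members ordered by sample id for determinism.
        """
        s = self.samples_in_expression_order()
        rows = []
        n_singletons = 0
        for pid, grp in s.groupby("pair_id", sort=True):
            if len(grp) != 2:
                n_singletons += len(grp)
                continue
            sids = sorted(grp["sample_id"])
            rows.append({
                "pair_id": pid,
                "zygosity": str(grp["zygosity"].iloc[0]).upper(),
                "sample_1": sids[0],
                "sample_2": sids[1],
            })
        return pd.DataFrame(rows, columns=["pair_id", "zygosity", "sample_1", "sample_2"]), n_singletons
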