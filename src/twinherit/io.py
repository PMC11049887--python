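"""Tab-delimited readers and writers for every table the pipeline touches.

File dialect: UTF-8, tab-separated, '.' decimal, mandatory header row. The
first column of matrix files is ``probe_id``. Floats are serialized with 8
significant digits so a write/read round trip reproduces values at that
precision.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import pandas as pd

from .bundle import StudyBundle
from .errors import ValidationError

FLOAT_FORMAT = "%.8g"

__all__ = [
    "load_study",
    "load_matrix",
    "load_table",
    "write_results",
    "write_study",
    "read_gene_list",
    "write_gene_list",
    "read_study_summary",
    "write_provenance",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except Exception as exc:  # malformed file -> validation failure
        raise ValidationError(f"could not parse {path}: {exc}") from exc


def load_matrix(path) -> pd.DataFrame:
    """Probe x sample matrix; first column is probe_id (kept as index)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"matrix file {path} needs a probe_id column plus samples")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df


def load_table(path) -> pd.DataFrame:
    return _read_tsv(path, dtype=str).apply(_maybe_numeric)


def _maybe_numeric(col: pd.Series) -> pd.Series:
    if col.name in ("sample_id", "pair_id", "probe_id", "gene_symbol", "gene_id",
                    "ensembl_id", "chromosome", "batch", "sex", "zygosity",
                    "study_label"):
        return col
    try:
        return pd.to_numeric(col)
    except (ValueError, TypeError):
        return col


def load_study(expr_path, samples_path, annot_path, detect_path=None) -> StudyBundle:
    """Read and validate a full study (see :class:`~twinherit.bundle.StudyBundle`)."""
    expression = load_matrix(expr_path)
    samples = load_table(samples_path)
    annotation = load_table(annot_path)
    detection = load_matrix(detect_path) if detect_path is not None else None
    return StudyBundle(expression=expression, samples=samples,
                       annotation=annotation, detection=detection)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from exc


def write_results(results: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each named result table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out_dir}: {exc}") from exc
    if not os.access(out_dir, os.W_OK):
        raise ValidationError(f"output directory not writable: {out_dir}")
    written = []
    for name, df in results.items():
        path = out_dir / f"{name}.tsv"
        write_table(df, path)
        written.append(path)
    return written


def write_study(bundle: StudyBundle, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df, index in [
        ("expression", bundle.expression, True),
        ("samples", bundle.samples, False),
        ("annotation", bundle.annotation, False),
    ]:
        path = out_dir / f"{name}.tsv"
        write_table(df, path, index=index)
        written.append(path)
    if bundle.detection is not None:
        path = out_dir / "detection.tsv"
        write_table(bundle.detection, path, index=True)
        written.append(path)
    return written


def read_gene_list(path) -> list[str]:
    """One gene symbol/id per line; blank lines and '#' comments ignored."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gene list not found: {path}")
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    dup = {g for g in genes if genes.count(g) > 1} if len(genes) < 5000 else set()
    if dup:
        raise ValidationError(f"duplicated gene(s) in list {path}: {sorted(dup)[:5]}")
    return genes


def write_gene_list(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


def read_study_summary(path, study_label: str | None = None) -> pd.DataFrame:
    """External per-gene summary with columns (ensembl_id, h2, pvalue)."""
    df = load_table(path)
    required = ["ensembl_id", "h2", "pvalue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"study summary {path} missing column(s): {missing}")
    df = df[required].copy()
    df["h2"] = pd.to_numeric(df["h2"])
    df["pvalue"] = pd.to_numeric(df["pvalue"])
    if df[["h2", "pvalue"]].isna().any().any() or \
            not df["h2"].between(0, 1).all() or \
            not ((df["pvalue"] > 0) & (df["pvalue"] <= 1)).all():
        raise ValidationError(
            f"study summary {path}: h2 must be in [0,1] and pvalue in (0,1]"
        )
    df.attrs["study_label"] = study_label or Path(path).stem
    return df


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(path, *, command: str, seed, config: dict,
                     counts: dict) -> None:
    """Provenance block: seed, config hash, per-stage in/out counts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"command: {command}",
        f"seed: {seed}",
        f"config_hash: {config_hash(config)}",
        "config:",
    ]
    lines += [f"  {k}: {config[k]}" for k in sorted(config)]
    lines.append("counts:")
    lines += [f"  {k}: {v}" for k, v in counts.items()]
    path.write_text("\n".join(lines) + "\n")
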