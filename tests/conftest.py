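"""Shared fixtures: direct pair simulators and tiny hand-written studies."""

import numpy as np
import pandas as pd
import pytest

from twinherit.bundle import StudyBundle
from twinherit.twin_model import TwinPairSet


def simulate_pairs(n_mz: int, n_dz: int, a2: float, c2: float,
                   rng: np.random.Generator, mu: float = 0.0) -> TwinPairSet:
    """Independent oracle simulator for twin pairs (unit residual variance)."""
    e2 = 1.0 - a2 - c2
    n = n_mz + n_dz
    a1 = rng.standard_normal(n)
    a_second = np.where(np.arange(n) < n_mz, a1,
                        0.5 * a1 + np.sqrt(0.75) * rng.standard_normal(n))
    c = rng.standard_normal(n)
    y1 = mu + np.sqrt(a2) * a1 + np.sqrt(c2) * c + np.sqrt(e2) * rng.standard_normal(n)
    y2 = mu + np.sqrt(a2) * a_second + np.sqrt(c2) * c + np.sqrt(e2) * rng.standard_normal(n)
    return TwinPairSet(np.column_stack([y1[:n_mz], y2[:n_mz]]),
                       np.column_stack([y1[n_mz:], y2[n_mz:]]))


@pytest.fixture
def pair_factory():
    return simulate_pairs


def make_tiny_bundle(n_probes=3, n_mz=2, n_dz=2, seed=0, detection=True):
    """Minimal valid StudyBundle built by hand (not via the simulator)."""
    rng = np.random.default_rng(seed)
    pair_ids = [f"MZ{i}" for i in range(n_mz)] + [f"DZ{i}" for i in range(n_dz)]
    zyg = ["MZ"] * n_mz + ["DZ"] * n_dz
    rows = []
    for pid, z in zip(pair_ids, zyg):
        for m in (1, 2):
            rows.append(dict(sample_id=f"{pid}_{m}", pair_id=pid, zygosity=z,
                             age=75.0 + rng.uniform(-3, 3), sex="F",
                             batch="B1" if rng.random() < 0.5 else "B2",
                             rin=8.0, wbc=6.0))
    samples = pd.DataFrame(rows)
    sample_ids = list(samples["sample_id"])
    probes = [f"P{i:03d}" for i in range(n_probes)]
    expr = pd.DataFrame(rng.normal(size=(n_probes, len(sample_ids))),
                        index=pd.Index(probes, name="probe_id"),
                        columns=sample_ids)
    det = pd.DataFrame(rng.uniform(0, 0.01, size=expr.shape),
                       index=expr.index, columns=expr.columns) if detection else None
    annot = pd.DataFrame({
        "probe_id": probes,
        "gene_symbol": [f"G{i // 2}" for i in range(n_probes)],
        "ensembl_id": [f"ENSG{i // 2:011d}" for i in range(n_probes)],
        "chromosome": [str(i % 3 + 1) for i in range(n_probes)],
        "gc_percent": rng.uniform(30, 70, n_probes).round(2),
        "gene_length": rng.integers(1000, 100000, n_probes),
    })
    return StudyBundle(expression=expr, samples=samples, annotation=annot,
                       detection=det)


@pytest.fixture
def tiny_bundle():
    return make_tiny_bundle()
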