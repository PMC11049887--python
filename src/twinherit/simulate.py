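"""Synthetic twin expression studies with known variance-component truth.

Generative rule per probe and pair: draw standard-normal factors A, C, E.
Both MZ members receive the identical A draw; DZ member 2 receives
``0.5 * A_1 + sqrt(0.75) * A_new`` (genetic correlation exactly 0.5). C is
identical within a pair, E independent per individual. The covariate-free
residual is ``sqrt(a2) * A + sqrt(c2) * C + sqrt(e2) * E`` with
``a2 + c2 + e2 = 1``, so its expected within-pair correlation is
``a2 + c2`` (MZ) and ``0.5 * a2 + c2`` (DZ). The phenotype adds a linear
covariate predictor on (age, sex, batch index, RIN, WBC).

Covariate structure: age, sex and batch are shared within a pair (same-sex
design); RIN and WBC vary per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .bundle import StudyBundle
from .errors import ValidationError

__all__ = ["SimConfig", "simulate_study", "plant_gene_lists", "random_probe_truth"]

COVARIATE_NAMES = ("age", "sex", "batch", "rin", "wbc")
DEFAULT_PROBES_PER_GENE = {1: 0.50, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.05}


@dataclass
class SimConfig:
    n_mz_pairs: int
    n_dz_pairs: int
    n_probes: int
    probe_truth: np.ndarray  # (n_probes, 3) fractions (a2, c2, e2), rows sum to 1
    covariate_betas: np.ndarray | None = None  # (n_probes, 5) for COVARIATE_NAMES
    probes_per_gene: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROBES_PER_GENE))
    age_range: tuple[float, float] = (69.4, 93.5)
    n_batches: int = 3
    undetected_probes: int = 0
    seed: int = 0

    def __post_init__(self):
        self.probe_truth = np.asarray(self.probe_truth, dtype=float)
        if self.n_mz_pairs < 2 or self.n_dz_pairs < 2:
            raise ValidationError("need at least 2 pairs per zygosity")
        if self.probe_truth.shape != (self.n_probes, 3):
            raise ValidationError(
                f"probe_truth must have shape ({self.n_probes}, 3), "
                f"got {self.probe_truth.shape}")
        if np.any(self.probe_truth < 0):
            raise ValidationError("variance fractions must be non-negative")
        if not np.allclose(self.probe_truth.sum(axis=1), 1.0, atol=1e-8):
            bad = int(np.argmax(np.abs(self.probe_truth.sum(axis=1) - 1.0)))
            raise ValidationError(
                f"variance fractions of probe {bad} sum to "
                f"{self.probe_truth[bad].sum():.6f}, expected 1")
        if self.covariate_betas is not None:
            self.covariate_betas = np.asarray(self.covariate_betas, dtype=float)
            if self.covariate_betas.shape != (self.n_probes, len(COVARIATE_NAMES)):
                raise ValidationError(
                    f"covariate_betas must have shape ({self.n_probes}, "
                    f"{len(COVARIATE_NAMES)})")
        total = sum(self.probes_per_gene.values())
        if total <= 0 or any(k not in (1, 2, 3, 4, 5) for k in self.probes_per_gene):
            raise ValidationError("probes_per_gene must weight sizes 1..5")
        if not 0 <= self.undetected_probes <= self.n_probes:
            raise ValidationError("undetected_probes out of range")
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError("age_range must be (lo, hi) with lo < hi")


def random_probe_truth(n_probes: int, rng: np.random.Generator,
                       a2_range=(0.0, 0.9), c2_range=(0.0, 0.2),
                       frac_null: float = 0.0) -> np.ndarray:
    """Convenience generator of per-probe (a2, c2, e2) fraction rows."""
    a2 = rng.uniform(*a2_range, size=n_probes)
    c2 = rng.uniform(*c2_range, size=n_probes)
    if frac_null > 0:
        null = rng.random(n_probes) < frac_null
        a2[null] = 0.0
        c2[null] = 0.0
    # keep e2 strictly positive
    scale = np.maximum(a2 + c2, 1e-12)
    over = a2 + c2 > 0.95
    a2[over] *= 0.95 / scale[over]
    c2[over] *= 0.95 / scale[over]
    return np.column_stack([a2, c2, 1.0 - a2 - c2])


def _gene_map(n_probes: int, probes_per_gene: dict[int, float],
              rng: np.random.Generator) -> pd.DataFrame:
    sizes, weights = zip(*sorted(probes_per_gene.items()))
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    gene_ids, probe_ids = [], []
    g = 0
    assigned = 0
    while assigned < n_probes:
        k = int(rng.choice(sizes, p=weights))
        k = min(k, n_probes - assigned)
        g += 1
        for j in range(k):
            probe_ids.append(f"P{assigned + j + 1:06d}")
            gene_ids.append(g)
        assigned += k
    return pd.DataFrame({
        "probe_id": probe_ids,
        "gene_symbol": [f"GENE{i:05d}" for i in gene_ids],
        "ensembl_id": [f"ENSG{i:011d}" for i in gene_ids],
    })


def simulate_study(cfg: SimConfig) -> tuple[StudyBundle, pd.DataFrame]:
    """Generate a :class:`StudyBundle` plus its ground-truth table.

    Deterministic for a fixed config (``cfg.seed`` drives all randomness).
    The truth table has one row per probe with columns probe_id, gene_symbol,
    ensembl_id, a2, c2, e2, h2_true (= a2).
    """
    rng = np.random.default_rng(cfg.seed)
    n_mz, n_dz, n_probes = cfg.n_mz_pairs, cfg.n_dz_pairs, cfg.n_probes
    n_pairs = n_mz + n_dz

    # --- samples -----------------------------------------------------------
    pair_ids = [f"MZ{i + 1:04d}" for i in range(n_mz)] + \
               [f"DZ{i + 1:04d}" for i in range(n_dz)]
    zygosity = ["MZ"] * n_mz + ["DZ"] * n_dz
    age = rng.uniform(*cfg.age_range, size=n_pairs)
    sex = np.where(rng.random(n_pairs) < 0.5, "F", "M")
    batch = rng.integers(0, cfg.n_batches, size=n_pairs)

    rows = []
    for i, pid in enumerate(pair_ids):
        for member in (1, 2):
            rows.append({
                "sample_id": f"{pid}_{member}",
                "pair_id": pid,
                "zygosity": zygosity[i],
                "age": round(float(age[i]), 2),
                "sex": str(sex[i]),
                "batch": f"B{int(batch[i]) + 1}",
                "rin": round(float(rng.uniform(6.0, 10.0)), 2),
                "wbc": round(float(np.clip(rng.normal(6.41, 1.66), 1.0, None)), 2),
            })
    samples = pd.DataFrame(rows)

    # --- residuals ---------------------------------------------------------
    a2 = cfg.probe_truth[:, 0:1]
    c2 = cfg.probe_truth[:, 1:2]
    e2 = cfg.probe_truth[:, 2:3]
    a1 = rng.standard_normal((n_probes, n_pairs))
    a_new = rng.standard_normal((n_probes, n_pairs))
    a2_member = np.where(
        np.arange(n_pairs) < n_mz, a1, 0.5 * a1 + np.sqrt(0.75) * a_new)
    c_shared = rng.standard_normal((n_probes, n_pairs))
    e_1 = rng.standard_normal((n_probes, n_pairs))
    e_2 = rng.standard_normal((n_probes, n_pairs))

    sqa, sqc, sqe = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)
    resid_1 = sqa * a1 + sqc * c_shared + sqe * e_1
    resid_2 = sqa * a2_member + sqc * c_shared + sqe * e_2

    # --- covariate effects -------------------------------------------------
    cov_by_sample = samples[list(COVARIATE_NAMES)].copy()
    cov_by_sample["sex"] = (samples["sex"] == "M").astype(float)
    cov_by_sample["batch"] = samples["batch"].str[1:].astype(float) - 1.0
    cov_mat = cov_by_sample.to_numpy(float)  # (2*n_pairs, 5)
    if cfg.covariate_betas is not None:
        predictor = cfg.covariate_betas @ cov_mat.T  # (n_probes, 2*n_pairs)
    else:
        predictor = np.zeros((n_probes, 2 * n_pairs))

    expr = np.empty((n_probes, 2 * n_pairs))
    expr[:, 0::2] = resid_1
    expr[:, 1::2] = resid_2
    expr += predictor

    sample_ids = list(samples["sample_id"])
    expression = pd.DataFrame(expr, index=None, columns=sample_ids)

    # --- annotation + truth ------------------------------------------------
    gene_map = _gene_map(n_probes, cfg.probes_per_gene, rng)
    expression.index = pd.Index(gene_map["probe_id"], name="probe_id")
    n_genes = gene_map["gene_symbol"].nunique()
    per_gene = pd.DataFrame({
        "gene_symbol": gene_map["gene_symbol"].unique(),
        "chromosome": rng.integers(1, 23, size=n_genes).astype(str),
        "gc_percent": np.round(rng.uniform(30.0, 70.0, size=n_genes), 2),
        "gene_length": rng.integers(500, 200_000, size=n_genes),
    })
    annotation = gene_map.merge(per_gene, on="gene_symbol")

    # --- detection p-values ------------------------------------------------
    detection = rng.uniform(0.0, 0.04, size=(n_probes, 2 * n_pairs))
    if cfg.undetected_probes:
        und = rng.choice(n_probes, size=cfg.undetected_probes, replace=False)
        detection[und, :] = rng.uniform(0.5, 1.0, size=(cfg.undetected_probes,
                                                        2 * n_pairs))
        detection[und, :2] = rng.uniform(0.0, 0.04, size=(cfg.undetected_probes, 2))
    detection = pd.DataFrame(detection, index=expression.index, columns=sample_ids)

    truth = pd.DataFrame({
        "probe_id": gene_map["probe_id"],
        "gene_symbol": gene_map["gene_symbol"],
        "ensembl_id": gene_map["ensembl_id"],
        "a2": cfg.probe_truth[:, 0],
        "c2": cfg.probe_truth[:, 1],
        "e2": cfg.probe_truth[:, 2],
    })
    truth["h2_true"] = truth["a2"]

    bundle = StudyBundle(expression=expression, samples=samples,
                         annotation=annotation, detection=detection)
    return bundle, truth


# ---------------------------------------------------------------------------
# planted gene lists
# ---------------------------------------------------------------------------

def _sample_or(k: float, L: int, n1: int, n0: int) -> float:
    """Sample odds ratio of the 2x2 (in-list x heritable) table at count k."""
    b = L - k          # in list, not heritable
    c = n1 - k         # heritable, not in list
    d = n0 - b         # neither
    if b <= 0 or c <= 0:
        return np.inf
    return (k * d) / (b * c)


def plant_gene_lists(truth: pd.DataFrame, list_size: int,
                     target_enrichment: float, seed: int | None = None,
                     h2_cutoff: float = 0.0) -> list[str]:
    """Draw a gene list over-representing truly heritable genes.

    A gene counts as truly heritable when its maximum probe ``a2`` exceeds
    ``h2_cutoff``. The number of heritable genes in the list is chosen so
    that the expected sample odds ratio of the (in-list x heritable) table
    equals ``target_enrichment``; the remaining slots are uniform draws.
    """
    if target_enrichment < 1:
        raise ValidationError("target_enrichment must be >= 1")
    gene_h2 = truth.groupby("gene_symbol")["a2"].max()
    heritable = gene_h2[gene_h2 > h2_cutoff].index.to_numpy()
    non_heritable = gene_h2[gene_h2 <= h2_cutoff].index.to_numpy()
    n1, n0 = len(heritable), len(non_heritable)
    n_genes = n1 + n0
    if not 0 < list_size < n_genes:
        raise ValidationError(
            f"list_size must be in (0, {n_genes}) exclusive: no enrichment is "
            "possible when the list covers every gene")
    if n1 == 0 or n0 == 0:
        raise ValidationError("need both heritable and non-heritable genes to plant a list")

    k_lo = max(0.0, list_size - n0) + 1e-9
    k_hi = min(list_size, n1) - 1e-9
    if k_hi <= k_lo:
        raise ValidationError("list size infeasible for the gene composition")
    if _sample_or(k_hi, list_size, n1, n0) < target_enrichment:
        raise ValidationError(
            f"target enrichment {target_enrichment} infeasible: even an "
            "all-heritable list falls short")
    rng = np.random.default_rng(seed)
    if target_enrichment == 1.0:
        # null case: plain uniform draw over all genes
        all_genes = np.concatenate([heritable, non_heritable])
        chosen = rng.choice(all_genes, size=list_size, replace=False)
        return sorted(str(g) for g in chosen)
    k_star = optimize.brentq(
            lambda k: _sample_or(k, list_size, n1, n0) - target_enrichment,
            k_lo, k_hi)
    k = int(np.floor(k_star))
    if rng.random() < (k_star - k):
        k += 1
    k = int(np.clip(k, max(0, list_size - n0), min(list_size, n1)))
    chosen = np.concatenate([
        rng.choice(heritable, size=k, replace=False),
        rng.choice(non_heritable, size=list_size - k, replace=False),
    ])
    return sorted(str(g) for g in chosen)
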