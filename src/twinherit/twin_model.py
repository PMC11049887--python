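"""Variance-component models for twin pairs.

A pair of phenotype values ``(y1, y2)`` is modelled as bivariate normal with
common mean ``mu`` and covariance

    Sigma_MZ = [[v, a2 + c2],        Sigma_DZ = [[v, 0.5*a2 + c2],
                [a2 + c2, v]]                    [0.5*a2 + c2, v]]

where ``v = a2 + c2 + e2`` is the total variance, ``a2`` the additive-genetic,
``c2`` the shared-environment and ``e2`` the unique-environment component.
The total log-likelihood is the sum over independent pairs.

Fitting exploits the fact that for fixed within-pair correlations
``(r_mz, r_dz)`` the profile over ``(mu, v)`` is available in closed form, so
each model reduces to a 0-, 1- or 2-dimensional search:

    E   : r_mz = r_dz = 0                      (closed form)
    AE  : r_mz = h2,  r_dz = h2 / 2            (1-d)
    CE  : r_mz = r_dz = r                      (1-d)
    ACE : r_mz / 2 <= r_dz <= r_mz             (2-d)

An alternative optimizer over unconstrained path coefficients (squared into
variances) is provided as ``method="paths"`` and is tested to agree with the
profile route.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import NumericalError, ValidationError

__all__ = [
    "TwinPairSet",
    "VarianceComponents",
    "ModelFit",
    "ModelComparison",
    "HeritabilityTest",
    "MODELS",
    "N_FREE_PARAMS",
    "pair_negloglik",
    "fit_model",
    "fit_all_models",
    "compare_models",
    "heritability_test",
    "profile_ci",
    "bootstrap_ci",
    "falconer_h2",
]

#: Free components of each model (``mu`` is always free).
MODELS = {
    "ACE": ("a2", "c2", "e2"),
    "AE": ("a2", "e2"),
    "CE": ("c2", "e2"),
    "E": ("e2",),
}

#: Number of free parameters, counting the mean.
N_FREE_PARAMS = {"ACE": 4, "AE": 3, "CE": 3, "E": 2}

#: Nested model pairs compared by likelihood ratio, with df.
LRT_PAIRS = [
    ("ACE", "AE", 1),
    ("ACE", "CE", 1),
    ("AE", "E", 1),
    ("CE", "E", 1),
    ("ACE", "E", 2),
]

_R_MAX = 1.0 - 1e-9
_LOG_2PI = float(np.log(2.0 * np.pi))


class ZygStats(NamedTuple):
    """Sufficient statistics of one zygosity group for the pair likelihood."""

    n: int
    s1: float  # sum of y1 + y2
    s2: float  # sum of y1^2 + y2^2
    s12: float  # sum of y1 * y2


def _zyg_stats(pairs: np.ndarray) -> ZygStats:
    if pairs.size == 0:
        return ZygStats(0, 0.0, 0.0, 0.0)
    y1, y2 = pairs[:, 0], pairs[:, 1]
    return ZygStats(
        pairs.shape[0],
        float(np.sum(y1) + np.sum(y2)),
        float(np.sum(y1 * y1) + np.sum(y2 * y2)),
        float(np.sum(y1 * y2)),
    )


class TwinPairSet:
    """Complete MZ and DZ twin pairs for a single phenotype.

    Parameters
    ----------
    mz_pairs, dz_pairs
        Sequences of ``(y1, y2)`` value pairs; converted to ``(n, 2)`` arrays.
    strict
        Require at least 2 pairs per zygosity (needed for fitting). Pass
        ``False`` for pure likelihood evaluation on toy configurations.
    """

    def __init__(self, mz_pairs, dz_pairs, *, strict: bool = True):
        self.mz = np.atleast_2d(np.asarray(mz_pairs, dtype=float)).reshape(-1, 2) \
            if np.size(mz_pairs) else np.empty((0, 2))
        self.dz = np.atleast_2d(np.asarray(dz_pairs, dtype=float)).reshape(-1, 2) \
            if np.size(dz_pairs) else np.empty((0, 2))
        for name, arr in (("MZ", self.mz), ("DZ", self.dz)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite phenotype value in {name} pairs")
        if strict and (self.mz.shape[0] < 2 or self.dz.shape[0] < 2):
            raise ValidationError(
                "need at least 2 complete pairs per zygosity "
                f"(got {self.mz.shape[0]} MZ, {self.dz.shape[0]} DZ)"
            )
        self._stats: tuple[ZygStats, ZygStats] | None = None

    @property
    def n_mz(self) -> int:
        return self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return self.dz.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_mz + self.n_dz

    def stats(self) -> tuple[ZygStats, ZygStats]:
        if self._stats is None:
            self._stats = (_zyg_stats(self.mz), _zyg_stats(self.dz))
        return self._stats

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.mz).tobytes())
        h.update(b"|")
        h.update(np.ascontiguousarray(self.dz).tobytes())
        return h.hexdigest()

    def pooled_values(self) -> np.ndarray:
        return np.concatenate([self.mz.ravel(), self.dz.ravel()])


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components and mean of one fitted (or hypothesized) model."""

    a2: float
    c2: float
    e2: float
    mu: float = 0.0

    @property
    def total(self) -> float:
        return self.a2 + self.c2 + self.e2

    @property
    def h2(self) -> float:
        return self.a2 / self.total if self.total > 0 else 0.0


@dataclass
class ModelFit:
    model: str
    components: VarianceComponents
    loglik: float
    n_free: int
    converged: bool
    fingerprint: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free


@dataclass
class ModelComparison:
    """AIC table, likelihood-ratio tests and the selected model."""

    aic: dict[str, float]
    lrt: list[dict]
    best_model: str


@dataclass
class HeritabilityTest:
    """AE-model heritability with its AE-vs-E likelihood-ratio p-value."""

    h2: float
    lam: float
    pvalue: float
    ci_lo: float
    ci_hi: float
    converged: bool = True
    ae_fit: ModelFit | None = field(default=None, repr=False)
    e_fit: ModelFit | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _negloglik_direct(pairs: np.ndarray, cov: float, v: float, mu: float) -> float:
    """Sum of bivariate-normal negative log-densities over pairs."""
    if pairs.size == 0:
        return 0.0
    det = v * v - cov * cov
    if v <= 0 or det <= 0:
        return np.inf
    d1 = pairs[:, 0] - mu
    d2 = pairs[:, 1] - mu
    quad = (v * (d1 * d1 + d2 * d2) - 2.0 * cov * d1 * d2) / det
    n = pairs.shape[0]
    return float(n * _LOG_2PI + 0.5 * n * np.log(det) + 0.5 * np.sum(quad))


def pair_negloglik(pairs: TwinPairSet, vc: VarianceComponents, model: str = "ACE") -> float:
    """Total negative log-likelihood of all pairs under ``vc``.

    Components that the requested model fixes at zero must be zero in ``vc``.
    A non-positive-definite covariance yields ``inf`` (optimizer-safe), never
    an exception.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    free = MODELS[model]
    for comp in ("a2", "c2", "e2"):
        val = getattr(vc, comp)
        if comp not in free and val != 0.0:
            raise ValidationError(f"model {model} fixes {comp}=0 but got {val}")
        if val < 0:
            raise ValidationError(f"negative variance component {comp}={val}")
    v = vc.total
    nll = _negloglik_direct(pairs.mz, vc.a2 + vc.c2, v, vc.mu)
    nll += _negloglik_direct(pairs.dz, 0.5 * vc.a2 + vc.c2, v, vc.mu)
    return nll


def _profile_negloglik(r_mz, r_dz, smz: ZygStats, sdz: ZygStats):
    """Negative log-likelihood minimized over (mu, v) at fixed correlations.

    Broadcasts over array-valued ``r_mz`` / ``r_dz``. Returns
    ``(nll, mu_star, v_star)``.
    """
    r_mz = np.asarray(r_mz, dtype=float)
    r_dz = np.asarray(r_dz, dtype=float)
    t = smz.n + sdz.n
    a = 2.0 * smz.n / (1.0 + r_mz) + 2.0 * sdz.n / (1.0 + r_dz)
    b = -2.0 * smz.s1 / (1.0 + r_mz) - 2.0 * sdz.s1 / (1.0 + r_dz)
    c = (smz.s2 - 2.0 * r_mz * smz.s12) / (1.0 - r_mz * r_mz) \
        + (sdz.s2 - 2.0 * r_dz * sdz.s12) / (1.0 - r_dz * r_dz)
    mu = -b / (2.0 * a)
    q = c - b * b / (4.0 * a)
    v = q / (2.0 * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        nll = np.where(
            v > 0,
            t * _LOG_2PI + t * np.log(np.maximum(v, 1e-300)) + t
            + 0.5 * smz.n * np.log1p(-r_mz * r_mz)
            + 0.5 * sdz.n * np.log1p(-r_dz * r_dz),
            np.inf,
        )
    return nll, mu, v


def _components_from(r_mz, r_dz, v, mu) -> VarianceComponents:
    a2 = max(2.0 * v * (r_mz - r_dz), 0.0)
    c2 = max(v * (2.0 * r_dz - r_mz), 0.0)
    e2 = max(v * (1.0 - r_mz), 0.0)
    return VarianceComponents(a2=a2, c2=c2, e2=e2, mu=mu)


def _refine_1d(fun, lo: float, hi: float, n_grid: int = 65, rounds: int = 3):
    """Coarse grid followed by zooming grids; robust to flat likelihoods."""
    best_x, best_f = lo, np.inf
    width = hi - lo
    for _ in range(rounds):
        grid = np.linspace(lo, hi, n_grid)
        vals = fun(grid)
        i = int(np.argmin(vals))
        if vals[i] < best_f:
            best_f, best_x = float(vals[i]), float(grid[i])
        width = (hi - lo) / (n_grid - 1) * 2.0
        lo = max(grid[0], best_x - width)
        hi = min(grid[-1], best_x + width)
    return best_x, best_f


def _fit_e(pairs: TwinPairSet, fingerprint: str) -> ModelFit:
    # under E all 2n observations are i.i.d. normal: closed-form MLE
    y = pairs.pooled_values()
    mu = float(np.mean(y))
    e2 = float(np.mean((y - mu) ** 2))
    if e2 <= 0:
        return ModelFit("E", VarianceComponents(0, 0, 0, mu), -np.inf,
                        N_FREE_PARAMS["E"], False, fingerprint)
    n = y.size
    ll = -0.5 * n * (_LOG_2PI + np.log(e2) + 1.0)
    return ModelFit("E", VarianceComponents(0.0, 0.0, e2, mu), float(ll),
                    N_FREE_PARAMS["E"], True, fingerprint)


def _fit_1d_profile(pairs: TwinPairSet, model: str, fingerprint: str) -> ModelFit:
    smz, sdz = pairs.stats()

    if model == "AE":
        def fun(h2):
            return _profile_negloglik(h2, 0.5 * np.asarray(h2), smz, sdz)[0]
    else:  # CE
        def fun(r):
            return _profile_negloglik(r, np.asarray(r), smz, sdz)[0]

    x, f = _refine_1d(fun, 0.0, _R_MAX)
    res = optimize.minimize_scalar(
        lambda t: float(fun(np.array([t]))[0]),
        bounds=(max(0.0, x - 0.02), min(_R_MAX, x + 0.02)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if res.fun <= f:
        x, f = float(res.x), float(res.fun)
    r_mz = x
    r_dz = 0.5 * x if model == "AE" else x
    _, mu, v = _profile_negloglik(r_mz, r_dz, smz, sdz)
    vc = _components_from(r_mz, r_dz, float(v), float(mu))
    converged = np.isfinite(f)
    return ModelFit(model, vc, -f, N_FREE_PARAMS[model], bool(converged), fingerprint)


def _fit_ace_profile(pairs: TwinPairSet, fingerprint: str,
                     seeds: Sequence[tuple[float, float]] = ()) -> ModelFit:
    smz, sdz = pairs.stats()

    # parameterize r_dz = r_mz * (1 + s) / 2 with s in [0, 1]
    def fun_rs(r, s):
        return _profile_negloglik(r, r * (1.0 + s) / 2.0, smz, sdz)[0]

    r_grid = np.linspace(0.0, _R_MAX, 61)
    s_grid = np.linspace(0.0, 1.0, 21)
    rr, ss = np.meshgrid(r_grid, s_grid, indexing="ij")
    vals = fun_rs(rr, ss)
    i, j = np.unravel_index(int(np.argmin(vals)), vals.shape)
    best = (float(rr[i, j]), float(ss[i, j]), float(vals[i, j]))

    # local zoom
    for _ in range(2):
        r0, s0, _ = best
        r_loc = np.clip(np.linspace(r0 - 0.03, r0 + 0.03, 31), 0.0, _R_MAX)
        s_loc = np.clip(np.linspace(s0 - 0.1, s0 + 0.1, 21), 0.0, 1.0)
        rr, ss = np.meshgrid(r_loc, s_loc, indexing="ij")
        vals = fun_rs(rr, ss)
        i, j = np.unravel_index(int(np.argmin(vals)), vals.shape)
        if vals[i, j] < best[2]:
            best = (float(rr[i, j]), float(ss[i, j]), float(vals[i, j]))

    # Nelder-Mead polish from the grid optimum and any supplied seeds
    def penalized(x):
        r, s = x
        if not (0.0 <= r <= _R_MAX and 0.0 <= s <= 1.0):
            return np.inf
        return float(fun_rs(np.array([r]), np.array([s]))[0])

    # candidate starts: grid optimum plus the AE/CE optima (seeds); polishing
    # from the best candidate keeps loglik(ACE) >= max(loglik(AE), loglik(CE))
    candidates = [(best[0], best[1], best[2])]
    for st in seeds:
        st = tuple(np.clip(st, [0, 0], [_R_MAX, 1]))
        candidates.append((st[0], st[1], penalized(st)))
    bx0, bx1, bf = min(candidates, key=lambda c: c[2])
    bx = (bx0, bx1)
    res = optimize.minimize(penalized, np.array(bx), method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-10,
                                     "maxiter": 600})
    if res.fun < bf:
        bf, bx = float(res.fun), (float(res.x[0]), float(res.x[1]))
    r_mz = bx[0]
    r_dz = r_mz * (1.0 + bx[1]) / 2.0
    _, mu, v = _profile_negloglik(r_mz, r_dz, smz, sdz)
    vc = _components_from(r_mz, r_dz, float(v), float(mu))
    return ModelFit("ACE", vc, -bf, N_FREE_PARAMS["ACE"], bool(np.isfinite(bf)),
                    fingerprint)


def _fit_paths(pairs: TwinPairSet, model: str, fingerprint: str,
               rng: np.random.Generator | None) -> ModelFit:
    """Spec-style optimizer over unconstrained path coefficients + mean."""
    free = [c for c in ("a2", "c2", "e2") if c in MODELS[model]]
    y = pairs.pooled_values()
    sd = float(np.std(y)) or 1.0
    mean = float(np.mean(y))

    def unpack(x):
        comps = {"a2": 0.0, "c2": 0.0, "e2": 0.0}
        for name, coef in zip(free, x[:-1]):
            comps[name] = coef * coef
        return VarianceComponents(mu=float(x[-1]), **comps)

    def objective(x):
        vc = unpack(x)
        v = vc.total
        cov_mz = vc.a2 + vc.c2
        cov_dz = 0.5 * vc.a2 + vc.c2
        nll = _negloglik_direct(pairs.mz, cov_mz, v, vc.mu)
        nll += _negloglik_direct(pairs.dz, cov_dz, v, vc.mu)
        return nll

    k = len(free)
    fracs = [
        np.full(k, 1.0 / k),
        np.linspace(0.8, 0.2, k) / np.sum(np.linspace(0.8, 0.2, k)),
        np.linspace(0.2, 0.8, k) / np.sum(np.linspace(0.2, 0.8, k)),
        np.r_[np.full(k - 1, 0.05), 0.95 - 0.05 * (k - 1)] if k > 1 else np.array([1.0]),
        np.r_[0.95 - 0.05 * (k - 1), np.full(k - 1, 0.05)] if k > 1 else np.array([1.0]),
    ]
    starts = [np.r_[np.sqrt(f) * sd, mean] for f in fracs]
    if rng is None:
        rng = np.random.default_rng(0)
    for _ in range(3):
        f = rng.dirichlet(np.ones(k))
        starts.append(np.r_[np.sqrt(f) * sd, mean + rng.normal(0, 0.1 * sd)])

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-9,
                                         "maxiter": 2000, "maxfev": 4000})
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    if best_x is None or not np.isfinite(best_f):
        return ModelFit(model, VarianceComponents(0, 0, 0, mean), -np.inf,
                        N_FREE_PARAMS[model], False, fingerprint)
    return ModelFit(model, unpack(best_x), -best_f, N_FREE_PARAMS[model], True,
                    fingerprint)


def fit_model(pairs: TwinPairSet, model: str, *, method: str = "profile",
              rng: np.random.Generator | None = None) -> ModelFit:
    """Maximum-likelihood fit of one model.

    ``method="profile"`` (default) profiles ``(mu, v)`` analytically and
    searches the remaining correlation parameters — exact and fast.
    ``method="paths"`` runs multi-start Nelder-Mead over unconstrained path
    coefficients; the two agree to optimizer tolerance.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    if pairs.n_mz < 2 or pairs.n_dz < 2:
        raise ValidationError("fitting requires at least 2 pairs per zygosity")
    fp = pairs.fingerprint()
    if method == "paths":
        return _fit_paths(pairs, model, fp, rng)
    if method != "profile":
        raise ValidationError(f"unknown fit method {method!r}")
    if model == "E":
        return _fit_e(pairs, fp)
    if model in ("AE", "CE"):
        return _fit_1d_profile(pairs, model, fp)
    return _fit_ace_profile(pairs, fp, seeds=_ace_seeds(pairs))


def _ace_seeds(pairs: TwinPairSet) -> list[tuple[float, float]]:
    """Seed the ACE search from the AE and CE optima (guarantees nesting)."""
    seeds = []
    for sub in ("AE", "CE"):
        f = _fit_1d_profile(pairs, sub, "")
        v = f.components.total
        if v > 0:
            r_mz = min((f.components.a2 + f.components.c2) / v, _R_MAX)
            seeds.append((r_mz, 0.0 if sub == "AE" else 1.0))
    return seeds


def fit_all_models(pairs: TwinPairSet, *, method: str = "profile") -> dict[str, ModelFit]:
    if method != "profile":
        return {m: fit_model(pairs, m, method=method) for m in MODELS}
    # fit sub-models first and reuse their optima to seed the ACE search
    fits = {m: fit_model(pairs, m) for m in ("E", "AE", "CE")}
    seeds = []
    for sub in ("AE", "CE"):
        vc = fits[sub].components
        v = vc.total
        if v > 0:
            seeds.append((min((vc.a2 + vc.c2) / v, _R_MAX),
                          0.0 if sub == "AE" else 1.0))
    fits["ACE"] = _fit_ace_profile(pairs, pairs.fingerprint(), seeds=seeds)
    return {m: fits[m] for m in MODELS}


def compare_models(fits: dict[str, ModelFit] | Sequence[ModelFit]) -> ModelComparison:
    """AIC table, nested LRTs, and lowest-AIC model selection.

    Ties in AIC are broken toward fewer free parameters, then by the fixed
    preference order E, AE, CE, ACE.
    """
    if not isinstance(fits, dict):
        fits = {f.model: f for f in fits}
    missing = set(MODELS) - set(fits)
    if missing:
        raise ValidationError(f"missing model fits: {sorted(missing)}")
    fps = {f.fingerprint for f in fits.values() if f.fingerprint}
    if len(fps) > 1:
        raise ValidationError("model fits come from different datasets")

    aic = {m: fits[m].aic for m in MODELS}
    lrt = []
    for full, reduced, df in LRT_PAIRS:
        lam = max(0.0, 2.0 * (fits[full].loglik - fits[reduced].loglik))
        lrt.append({
            "full": full, "reduced": reduced, "df": df, "lambda": lam,
            "pvalue": float(stats.chi2.sf(lam, df)) if lam > 0 else 1.0,
        })
    order = {"E": 0, "AE": 1, "CE": 2, "ACE": 3}
    best = min(MODELS, key=lambda m: (round(aic[m], 9), fits[m].n_free, order[m]))
    return ModelComparison(aic=aic, lrt=lrt, best_model=best)


# ---------------------------------------------------------------------------
# heritability test, profile CI, bootstrap
# ---------------------------------------------------------------------------

def profile_ci(pairs: TwinPairSet, level: float = 0.95,
               ae_fit: ModelFit | None = None) -> tuple[float, float]:
    """Profile-likelihood CI for h2 under the AE model, clipped to [0, 1]."""
    if ae_fit is None:
        ae_fit = fit_model(pairs, "AE")
    smz, sdz = pairs.stats()
    h2_hat = ae_fit.components.h2
    nll_min = -ae_fit.loglik
    thr = nll_min + 0.5 * float(stats.chi2.ppf(level, 1))

    def excess(h2):
        nll, _, _ = _profile_negloglik(h2, 0.5 * h2, smz, sdz)
        return float(nll) - thr

    lo = 0.0
    if excess(0.0) > 0 and h2_hat > 0:
        lo = float(optimize.brentq(excess, 0.0, h2_hat, xtol=1e-8))
    hi = 1.0
    if excess(_R_MAX) > 0 and h2_hat < _R_MAX:
        hi = float(optimize.brentq(excess, h2_hat, _R_MAX, xtol=1e-8))
    return max(0.0, lo), min(1.0, hi)


def heritability_test(pairs: TwinPairSet, level: float = 0.95) -> HeritabilityTest:
    """AE-model h2 estimate with AE-vs-E LRT p-value and profile CI."""
    ae = fit_model(pairs, "AE")
    e = fit_model(pairs, "E")
    lam = max(0.0, 2.0 * (ae.loglik - e.loglik))
    pvalue = float(stats.chi2.sf(lam, 1)) if lam > 0 else 1.0
    h2 = ae.components.h2
    if ae.converged and e.converged:
        ci_lo, ci_hi = profile_ci(pairs, level=level, ae_fit=ae)
    else:
        ci_lo, ci_hi = 0.0, 1.0
    ci_lo, ci_hi = min(ci_lo, h2), max(ci_hi, h2)
    return HeritabilityTest(h2=h2, lam=lam, pvalue=pvalue, ci_lo=ci_lo,
                            ci_hi=ci_hi, converged=ae.converged and e.converged,
                            ae_fit=ae, e_fit=e)


def _batched_stats(y: np.ndarray, idx: np.ndarray):
    """Per-replicate sufficient statistics. y: (n, 2); idx: (B, n)."""
    y1 = y[:, 0][idx]
    y2 = y[:, 1][idx]
    return (
        idx.shape[1],
        (y1 + y2).sum(axis=1),
        (y1 * y1 + y2 * y2).sum(axis=1),
        (y1 * y2).sum(axis=1),
    )


def _batched_ae_h2(stats_mz, stats_dz, grid_coarse=None) -> np.ndarray:
    """Vectorized AE-model h2 MLE for B bootstrap replicates.

    ``stats_*`` are (n, s1, s2, s12) with array-valued sums of shape (B,).
    Two-stage grid over h2; resolution ~2.5e-4.
    """
    n_mz, s1_mz, s2_mz, s12_mz = stats_mz
    n_dz, s1_dz, s2_dz, s12_dz = stats_dz
    t = n_mz + n_dz

    def nll(h2):  # h2: (B, G)
        r_mz = h2
        r_dz = 0.5 * h2
        a = 2.0 * n_mz / (1.0 + r_mz) + 2.0 * n_dz / (1.0 + r_dz)
        b = (-2.0 * s1_mz[:, None] / (1.0 + r_mz)
             - 2.0 * s1_dz[:, None] / (1.0 + r_dz))
        c = ((s2_mz[:, None] - 2.0 * r_mz * s12_mz[:, None]) / (1.0 - r_mz ** 2)
             + (s2_dz[:, None] - 2.0 * r_dz * s12_dz[:, None]) / (1.0 - r_dz ** 2))
        q = c - b * b / (4.0 * a)
        v = q / (2.0 * t)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                v > 0,
                t * np.log(np.maximum(v, 1e-300))
                + 0.5 * n_mz * np.log1p(-r_mz ** 2)
                + 0.5 * n_dz * np.log1p(-r_dz ** 2),
                np.inf,
            )
        return out

    if grid_coarse is None:
        grid_coarse = np.linspace(0.0, _R_MAX, 81)
    vals = nll(np.broadcast_to(grid_coarse, (len(s1_mz), grid_coarse.size)))
    best = grid_coarse[np.argmin(vals, axis=1)]
    step = grid_coarse[1] - grid_coarse[0]
    local = np.linspace(-step, step, 41)
    h2_loc = np.clip(best[:, None] + local, 0.0, _R_MAX)
    vals = nll(h2_loc)
    return h2_loc[np.arange(h2_loc.shape[0]), np.argmin(vals, axis=1)]


def bootstrap_ci(pairs: TwinPairSet, B: int = 1000, level: float = 0.95,
                 seed: int | None = None,
                 return_samples: bool = False):
    """Percentile bootstrap CI for AE-model h2, stratified by zygosity.

    Pairs are resampled with replacement within zygosity; the AE model is
    refitted on each replicate and the (1-level)/2 percentile interval of the
    h2 estimates is returned, clipped to [0, 1].
    """
    if B < 100:
        raise ValidationError("bootstrap requires B >= 100")
    rng = np.random.default_rng(seed)
    idx_mz = rng.integers(0, pairs.n_mz, size=(B, pairs.n_mz))
    idx_dz = rng.integers(0, pairs.n_dz, size=(B, pairs.n_dz))
    stats_mz = _batched_stats(pairs.mz, idx_mz)
    stats_dz = _batched_stats(pairs.dz, idx_dz)
    h2 = _batched_ae_h2(stats_mz, stats_dz)
    ok = np.isfinite(h2)
    if np.mean(~ok) > 0.10:
        raise NumericalError(
            f"{int(np.sum(~ok))}/{B} bootstrap replicates failed to fit; "
            "increase B or flag this probe"
        )
    h2 = h2[ok]
    alpha = (1.0 - level) / 2.0
    lo = float(np.clip(np.quantile(h2, alpha), 0.0, 1.0))
    hi = float(np.clip(np.quantile(h2, 1.0 - alpha), 0.0, 1.0))
    if return_samples:
        return lo, hi, h2
    return lo, hi


def falconer_h2(pairs: TwinPairSet) -> float:
    """Moment estimator 2 * (r_MZ - r_DZ); large-sample consistency check."""
    r_mz = float(np.corrcoef(pairs.mz[:, 0], pairs.mz[:, 1])[0, 1])
    r_dz = float(np.corrcoef(pairs.dz[:, 0], pairs.dz[:, 1])[0, 1])
    return 2.0 * (r_mz - r_dz)
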