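"""Causal-mixture (MiXeR-style) estimation of polygenicity and polygenic overlap.

Univariate model: each variant is causal with probability ``pi1``; causal
effects are N(0, sigma_b_sq).  The z-score of variant ``j`` aggregates the
effects of its LD neighborhood plus inflated null noise, giving the
characteristic function

    phi_j(t) = exp(-sigma0^2 t^2 / 2)
               * prod_{i in nbr(j)} [1 - pi1 + pi1 exp(-N sigma_b_sq r_ij^2 t^2 / 2)]

whose density is evaluated by inverse Fourier transform on a symmetric grid.
The bivariate model replaces the per-neighbor factor with a four-component
mixture (neither trait / trait 1 only / trait 2 only / shared, the shared
component carrying effect correlation ``rho12``) and a correlated-noise term
(``rho0``, sample overlap).

Fitting follows the resampling scheme of the causal-mixture literature:
repeated subsampling of variants with random LD pruning at r^2 = 0.8,
derivative-free likelihood maximization on transformed scales, and
iteration mean/SD as the reported estimate and its uncertainty.  The
bivariate stage keeps each trait's univariate parameters fixed and fits only
(pi12, rho12, rho0).  Model support is summarized by AIC against a
minimal-overlap (pi12 = 0) and a maximal-overlap (pi12 = min of the totals)
reference.

Variants are grouped by the multiset of squared correlations in their LD
neighborhood; the density grid is computed once per distinct neighborhood
profile, which makes genome-template-scale likelihoods cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.fft import ifft, ifft2
from scipy import optimize, stats
from scipy.ndimage import map_coordinates
from scipy.special import expit, logit

from ._prune import random_prune
from .sumstats_io import LDStructure, MergedPair, VariantTable

__all__ = [
    "UnivariateParams",
    "BivariateParams",
    "GridSpec",
    "FitConfig",
    "FitResult",
    "univariate_loglik",
    "bivariate_loglik",
    "fit_univariate",
    "fit_bivariate",
    "n90",
    "genetic_correlation",
    "concordant_fraction",
]

LOG_FLOOR = 1e-300


@dataclass
class UnivariateParams:
    """Single-trait mixture parameters."""

    pi1: float  # causal-variant proportion
    sigma_b_sq: float  # effect-size variance (discoverability)
    sigma0: float  # null z-score scale (inflation)

    def __post_init__(self) -> None:
        if not (0 <= self.pi1 <= 1):
            raise ValueError("pi1 must be in [0, 1]")
        if self.sigma_b_sq < 0:
            raise ValueError("sigma_b_sq must be nonnegative")
        if self.sigma0 < 0.5:
            raise ValueError("sigma0 must be >= 0.5")


@dataclass
class BivariateParams:
    """Four-component bivariate mixture parameters.

    ``pi1``/``pi2`` are the *unique* (trait-only) proportions; ``pi12`` the
    shared proportion; ``pi0`` is implied.
    """

    pi1: float
    pi2: float
    pi12: float
    sigma_b1_sq: float
    sigma_b2_sq: float
    rho12: float
    rho0: float = 0.0
    sigma01: float = 1.0
    sigma02: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pi1, self.pi2, self.pi12) < 0 or self.pi0 < -1e-12:
            raise ValueError("component proportions must be nonnegative")
        if abs(self.rho12) > 1 or abs(self.rho0) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.sigma_b1_sq < 0 or self.sigma_b2_sq < 0:
            raise ValueError("effect-size variances must be nonnegative")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1 - self.pi2 - self.pi12

    def swapped(self) -> "BivariateParams":
        return BivariateParams(
            pi1=self.pi2,
            pi2=self.pi1,
            pi12=self.pi12,
            sigma_b1_sq=self.sigma_b2_sq,
            sigma_b2_sq=self.sigma_b1_sq,
            rho12=self.rho12,
            rho0=self.rho0,
            sigma01=self.sigma02,
            sigma02=self.sigma01,
        )


@dataclass
class GridSpec:
    """Fourier grid: n points spanning |z| <= zmax (zmax defaults to
    max(20, observed max |z| + 5)); n2 points per axis for the bivariate grid."""

    n: int = 2048
    n2: int = 128
    zmax: float | None = None

    def resolve_zmax(self, z_abs_max: float) -> float:
        zmax = self.zmax if self.zmax is not None else max(20.0, z_abs_max + 5.0)
        if zmax < z_abs_max:
            raise ValueError(
                f"grid zmax {zmax} does not cover observed max |z| {z_abs_max:.2f}"
            )
        return zmax


@dataclass
class FitConfig:
    """Resampling-fit configuration (desk-scale defaults)."""

    n_iterations: int = 20
    subsample: int = 20_000
    prune_r2: float = 0.8
    n_starts: int = 3
    seed: int = 0
    maxfev_first: int = 250
    maxfev_warm: int = 80
    min_pruned: int = 1_000


@dataclass
class FitResult:
    """Point estimates with per-iteration resampling spread and model support."""

    mean: dict[str, float]
    sd: dict[str, float]
    iterations: pd.DataFrame
    loglik: float
    aic: dict[str, float]
    derived: dict[str, float]
    m: int


# ---------------------------------------------------------------------------
# profile-grouped Fourier likelihood machinery


def _profiles(ids: np.ndarray, ld: LDStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group variants by the multiset of r^2 values in their LD neighborhood.

    Returns (u, C, prof) where ``u`` is the global vector of distinct r^2
    values, ``C[p, k]`` counts occurrences of ``u[k]`` in profile ``p`` and
    ``prof[j]`` is variant j's profile index.  Neighborhoods include the
    variant itself (r = 1) and truncate at |r| < 0.05.
    """
    key_of: dict[tuple, int] = {}
    prof = np.empty(len(ids), dtype=np.int64)
    keys: list[tuple] = []
    for j, v in enumerate(ids):
        r2 = np.round(ld.r2_profile(v, min_r2=0.0025), 8)
        key = tuple(r2)
        p = key_of.get(key)
        if p is None:
            p = len(keys)
            key_of[key] = p
            keys.append(key)
        prof[j] = p
    u = np.unique(np.concatenate([np.asarray(k) for k in keys]))
    C = np.zeros((len(keys), len(u)), dtype=float)
    for p, key in enumerate(keys):
        vals, counts = np.unique(np.asarray(key), return_counts=True)
        C[p, np.searchsorted(u, vals)] = counts
    return u, C, prof


def _segment(prof: np.ndarray, n_prof: int, idx: np.ndarray) -> list[np.ndarray]:
    """Indices of ``idx`` split by profile."""
    sub = prof[idx]
    return [idx[sub == p] for p in range(n_prof)]


class _UnivariateModel:
    """Precomputed Fourier-likelihood evaluator for one trait."""

    def __init__(self, z: np.ndarray, n_eff: float, ids: np.ndarray, ld: LDStructure, grid: GridSpec):
        self.z = np.asarray(z, float)
        if not np.isfinite(self.z).all():
            raise ValueError("z-scores must be finite")
        self.n_eff = float(n_eff)
        self.grid = grid
        self.zmax = grid.resolve_zmax(np.abs(self.z).max() if len(self.z) else 0.0)
        n = grid.n
        self.dz = 2 * self.zmax / n
        self.t = 2 * np.pi * np.fft.fftfreq(n, d=self.dz)
        self.t2 = self.t**2
        self.phase = (-1.0) ** np.arange(n)
        self.u, self.C, self.prof = _profiles(ids, ld)

    def segments(self, idx: np.ndarray) -> list[np.ndarray]:
        return _segment(self.prof, self.C.shape[0], idx)

    def _log_density_rows(self, params: UnivariateParams) -> np.ndarray:
        pi1, sb2, s0 = params.pi1, params.sigma_b_sq, params.sigma0
        # U x n factor grid; 1 - pi + pi*exp(...) = 1 + pi*(exp(...) - 1)
        E = np.exp(-0.5 * self.n_eff * sb2 * np.outer(self.u, self.t2))
        G = np.log1p(pi1 * (E - 1.0))
        logphi = self.C @ G - 0.5 * s0**2 * self.t2
        phi = np.exp(logphi) * self.phase
        f = np.real(ifft(phi, axis=1)) / self.dz
        return np.log(np.clip(f, LOG_FLOOR, None))

    def loglik(self, params: UnivariateParams, segments: list[np.ndarray]) -> float:
        logf = self._log_density_rows(params)
        total = 0.0
        for p, seg in enumerate(segments):
            if len(seg) == 0:
                continue
            coords = (self.z[seg] + self.zmax) / self.dz
            total += map_coordinates(logf[p], coords[None, :], order=3, mode="nearest").sum()
        return float(total)


class _BivariateModel:
    """Precomputed Fourier-likelihood evaluator for a harmonized trait pair."""

    def __init__(self, pair: MergedPair, ld: LDStructure, grid: GridSpec):
        d = pair.df
        self.z1 = d["Z1"].to_numpy(float)
        self.z2 = d["Z2"].to_numpy(float)
        self.n1 = float(np.median(d["N1"]))
        self.n2_eff = float(np.median(d["N2"]))
        self.grid = grid
        zam = max(np.abs(self.z1).max(), np.abs(self.z2).max()) if len(d) else 0.0
        self.zmax = grid.resolve_zmax(zam)
        n2 = grid.n2
        self.dz = 2 * self.zmax / n2
        self.t = 2 * np.pi * np.fft.fftfreq(n2, d=self.dz)
        self.t2 = self.t**2
        self.phase2 = np.outer((-1.0) ** np.arange(n2), (-1.0) ** np.arange(n2))
        self.tt = np.outer(self.t, self.t)
        self.u, self.C, self.prof = _profiles(pair.ids, ld)

    def segments(self, idx: np.ndarray) -> list[np.ndarray]:
        return _segment(self.prof, self.C.shape[0], idx)

    def _log_density_rows(self, params: BivariateParams) -> np.ndarray:
        n2 = self.grid.n2
        c1 = self.n1 * params.sigma_b1_sq
        c2 = self.n2_eff * params.sigma_b2_sq
        a1 = np.exp(-0.5 * c1 * np.outer(self.u, self.t2))  # U x n2 (t1 axis)
        a2 = np.exp(-0.5 * c2 * np.outer(self.u, self.t2))  # U x n2 (t2 axis)
        c12 = params.rho12 * np.sqrt(c1 * c2)
        # shared-component quadratic form kept in one exponent: the cross term
        # alone would overflow even though the PSD form is bounded
        quad = c1 * self.t2[:, None] + c2 * self.t2[None, :] + 2 * c12 * self.tt
        shared = np.exp(-0.5 * self.u[:, None, None] * quad[None, :, :])
        mix = (
            params.pi0
            + params.pi1 * a1[:, :, None]
            + params.pi2 * a2[:, None, :]
            + params.pi12 * shared
        )
        G = np.log(mix).reshape(len(self.u), n2 * n2)
        noise = -0.5 * (
            params.sigma01**2 * self.t2[:, None]
            + params.sigma02**2 * self.t2[None, :]
            + 2 * params.rho0 * params.sigma01 * params.sigma02 * self.tt
        )
        logphi = (self.C @ G).reshape(-1, n2, n2) + noise[None, :, :]
        phi = np.exp(logphi) * self.phase2[None, :, :]
        f = np.real(ifft2(phi, axes=(1, 2))) / self.dz**2
        return np.log(np.clip(f, LOG_FLOOR, None))

    def loglik(self, params: BivariateParams, segments: list[np.ndarray]) -> float:
        logf = self._log_density_rows(params)
        total = 0.0
        for p, seg in enumerate(segments):
            if len(seg) == 0:
                continue
            coords = np.vstack(
                [
                    (self.z1[seg] + self.zmax) / self.dz,
                    (self.z2[seg] + self.zmax) / self.dz,
                ]
            )
            total += map_coordinates(logf[p], coords, order=3, mode="nearest").sum()
        return float(total)


# ---------------------------------------------------------------------------
# public likelihoods


def univariate_loglik(
    params: UnivariateParams,
    merged: VariantTable | pd.DataFrame,
    ld: LDStructure,
    grid: GridSpec | None = None,
) -> float:
    """Summed log density of the observed z-scores under the univariate mixture."""
    df = merged.df if isinstance(merged, VariantTable) else merged
    model = _UnivariateModel(
        df["Z"].to_numpy(float),
        float(np.median(df["N"])),
        df["SNP"].to_numpy(),
        ld,
        grid or GridSpec(),
    )
    return model.loglik(params, model.segments(np.arange(len(df))))


def bivariate_loglik(
    params: BivariateParams,
    pair: MergedPair,
    ld: LDStructure,
    grid: GridSpec | None = None,
) -> float:
    """Summed joint log density of (z1, z2) under the four-component mixture."""
    model = _BivariateModel(pair, ld, grid or GridSpec())
    return model.loglik(params, model.segments(np.arange(len(pair))))


# ---------------------------------------------------------------------------
# fitting


def _minimize(fun, x0: np.ndarray, maxfev: int) -> optimize.OptimizeResult:
    return optimize.minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 2e-3, "fatol": 0.05, "adaptive": False},
    )


def _sigma0_from_x(x: float) -> float:
    return 0.5 + np.exp(np.clip(x, -30, 5))


def fit_univariate(
    merged: VariantTable | pd.DataFrame,
    ld: LDStructure,
    m: int,
    config: FitConfig | None = None,
    grid: GridSpec | None = None,
) -> FitResult:
    """Resampling maximum-likelihood fit of (pi1, sigma_b_sq, sigma0).

    Each iteration subsamples variants, randomly prunes at
    ``r^2 > config.prune_r2`` and maximizes the Fourier likelihood with a
    simplex search on (logit pi1, log sigma_b_sq, log(sigma0 - 0.5)).  The
    first iteration uses ``n_starts`` starting points (one moment-matched,
    the rest perturbed); later iterations warm-start from the previous
    optimum.  Reported estimates are iteration means with iteration SDs.
    """
    config = config or FitConfig()
    df = merged.df if isinstance(merged, VariantTable) else merged
    ids = df["SNP"].to_numpy()
    model = _UnivariateModel(
        df["Z"].to_numpy(float), float(np.median(df["N"])), ids, ld, grid or GridSpec()
    )
    mv = len(ids)
    indptr, indices = ld.adjacency(ids, min_r2=config.prune_r2)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(11,)))

    # moment-matched start: E z^2 = sigma0^2 + pi1 * N sb2 * mean profile r^2 sum
    mean_r2sum = float(np.mean((model.C @ model.u)[model.prof]))
    excess = max(float(np.mean(model.z**2)) - 1.0, 0.05)

    def start_for(pi1: float) -> np.ndarray:
        sb2 = excess / (pi1 * model.n_eff * mean_r2sum)
        return np.array([logit(pi1), np.log(sb2), np.log(0.5)])

    def unpack(x: np.ndarray) -> UnivariateParams:
        return UnivariateParams(
            pi1=float(expit(x[0])),
            sigma_b_sq=float(np.exp(np.clip(x[1], -60, 10))),
            sigma0=float(_sigma0_from_x(x[2])),
        )

    rows = []
    ref_segments = None
    x_prev = None
    for it in range(config.n_iterations):
        it_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(12, it))
        )
        sub = it_rng.choice(mv, size=min(config.subsample, mv), replace=False)
        keep = random_prune(indptr, indices, sub, it_rng)
        if len(keep) < config.min_pruned:
            warnings.warn(
                f"only {len(keep)} variants after pruning (< {config.min_pruned})"
            )
        segments = model.segments(keep)
        if ref_segments is None:
            ref_segments = segments

        def neg(x: np.ndarray) -> float:
            return -model.loglik(unpack(x), segments)

        if x_prev is None:
            starts = [start_for(p) for p in (0.003, 0.01, 0.03)][: config.n_starts]
            while len(starts) < config.n_starts:
                base = starts[len(starts) % 3]
                starts.append(base + it_rng.normal(0, 1.0, size=3))
            best = None
            for x0 in starts:
                res = _minimize(neg, x0, config.maxfev_first)
                if best is None or res.fun < best.fun:
                    best = res
        else:
            best = _minimize(neg, x_prev, config.maxfev_warm)
        x_prev = best.x
        prm = unpack(best.x)
        rows.append(
            {
                "iteration": it,
                "pi1": prm.pi1,
                "sigma_b_sq": prm.sigma_b_sq,
                "sigma0": prm.sigma0,
                "loglik": -best.fun,
                "n_variants": len(keep),
            }
        )

    iters = pd.DataFrame(rows)
    mean = {k: float(iters[k].mean()) for k in ("pi1", "sigma_b_sq", "sigma0")}
    sd = {k: float(iters[k].std(ddof=1)) for k in ("pi1", "sigma_b_sq", "sigma0")}
    fitted = UnivariateParams(**mean)
    ll = model.loglik(fitted, ref_segments)

    # null reference: pi1 = 0, sigma0 free (closed-form MLE on the reference set)
    ref_idx = np.concatenate([s for s in ref_segments if len(s)]) if ref_segments else np.array([], int)
    z_ref = model.z[ref_idx]
    s0_null = max(np.sqrt(float(np.mean(z_ref**2))), 0.5)
    ll_null = float(np.sum(stats.norm.logpdf(z_ref, scale=s0_null)))
    aic = {"fitted": 2 * 3 - 2 * ll, "null": 2 * 1 - 2 * ll_null}

    derived = {
        "n_causal": mean["pi1"] * m,
        "n_causal_sd": sd["pi1"] * m,
        "n90": float(n90(mean["pi1"], m)),
        "heritability_scale": m * mean["pi1"] * mean["sigma_b_sq"] * model.n_eff,
    }
    return FitResult(mean=mean, sd=sd, iterations=iters, loglik=ll, aic=aic, derived=derived, m=m)


def fit_bivariate(
    pair: MergedPair,
    ld: LDStructure,
    fit1: FitResult,
    fit2: FitResult,
    m: int,
    config: FitConfig | None = None,
    grid: GridSpec | None = None,
) -> FitResult:
    """Resampling fit of the shared component given both univariate fits.

    Univariate totals (pi_total, sigma_b_sq, sigma0) are held fixed per
    trait; only (pi12, rho12, rho0) are free, with
    ``pi1' = pi1_total - pi12 >= 0`` enforced through the parameterization
    ``pi12 = min(totals) * sigmoid(x)``.  AIC is reported against the
    minimal-overlap (pi12 = 0) and maximal-overlap (pi12 = min of totals)
    references.
    """
    config = config or FitConfig()
    model = _BivariateModel(pair, ld, grid or GridSpec())
    tot1, sb1, s01 = fit1.mean["pi1"], fit1.mean["sigma_b_sq"], fit1.mean["sigma0"]
    tot2, sb2, s02 = fit2.mean["pi1"], fit2.mean["sigma_b_sq"], fit2.mean["sigma0"]
    min_tot = min(tot1, tot2)
    mv = len(pair)
    indptr, indices = ld.adjacency(pair.ids, min_r2=config.prune_r2)

    def unpack(x: np.ndarray) -> BivariateParams:
        pi12 = min_tot * float(expit(x[0]))
        return BivariateParams(
            pi1=max(tot1 - pi12, 0.0),
            pi2=max(tot2 - pi12, 0.0),
            pi12=pi12,
            sigma_b1_sq=sb1,
            sigma_b2_sq=sb2,
            rho12=float(np.tanh(x[1])),
            rho0=float(np.tanh(x[2])),
            sigma01=s01,
            sigma02=s02,
        )

    # moment heuristics for starting points
    quiet = (np.abs(model.z1) < 1.5) & (np.abs(model.z2) < 1.5)
    rho0_init = float(np.corrcoef(model.z1[quiet], model.z2[quiet])[0, 1]) if quiet.sum() > 10 else 0.0
    r_all = float(np.corrcoef(model.z1, model.z2)[0, 1])
    rho12_init = np.clip(2 * (r_all - rho0_init), -0.95, 0.95)

    rows = []
    ref_segments = None
    x_prev = None
    for it in range(config.n_iterations):
        it_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(13, it))
        )
        sub = it_rng.choice(mv, size=min(config.subsample, mv), replace=False)
        keep = random_prune(indptr, indices, sub, it_rng)
        segments = model.segments(keep)
        if ref_segments is None:
            ref_segments = segments

        def neg(x: np.ndarray) -> float:
            return -model.loglik(unpack(x), segments)

        if x_prev is None:
            starts = [
                np.array([logit(f), np.arctanh(rho12_init), np.arctanh(np.clip(rho0_init, -0.9, 0.9))])
                for f in (0.5, 0.25, 0.9)
            ][: config.n_starts]
            while len(starts) < config.n_starts:
                base = starts[len(starts) % 3]
                starts.append(base + it_rng.normal(0, 0.8, size=3))
            best = None
            for x0 in starts:
                res = _minimize(neg, x0, config.maxfev_first)
                if best is None or res.fun < best.fun:
                    best = res
        else:
            best = _minimize(neg, x_prev, config.maxfev_warm)
        x_prev = best.x
        prm = unpack(best.x)
        rows.append(
            {
                "iteration": it,
                "pi12": prm.pi12,
                "pi1_unique": prm.pi1,
                "pi2_unique": prm.pi2,
                "rho12": prm.rho12,
                "rho0": prm.rho0,
                "loglik": -best.fun,
                "n_variants": len(keep),
            }
        )

    iters = pd.DataFrame(rows)
    keys = ("pi12", "pi1_unique", "pi2_unique", "rho12", "rho0")
    mean = {k: float(iters[k].mean()) for k in keys}
    sd = {k: float(iters[k].std(ddof=1)) for k in keys}

    fitted = BivariateParams(
        pi1=max(tot1 - mean["pi12"], 0.0),
        pi2=max(tot2 - mean["pi12"], 0.0),
        pi12=mean["pi12"],
        sigma_b1_sq=sb1,
        sigma_b2_sq=sb2,
        rho12=np.clip(mean["rho12"], -1, 1),
        rho0=np.clip(mean["rho0"], -1, 1),
        sigma01=s01,
        sigma02=s02,
    )
    ll = model.loglik(fitted, ref_segments)

    # reference models on the same subsample for AIC comparison
    def neg_zero(x: np.ndarray) -> float:
        p = BivariateParams(
            pi1=tot1, pi2=tot2, pi12=0.0, sigma_b1_sq=sb1, sigma_b2_sq=sb2,
            rho12=0.0, rho0=float(np.tanh(x[0])), sigma01=s01, sigma02=s02,
        )
        return -model.loglik(p, ref_segments)

    def neg_max(x: np.ndarray) -> float:
        p = BivariateParams(
            pi1=tot1 - min_tot, pi2=tot2 - min_tot, pi12=min_tot,
            sigma_b1_sq=sb1, sigma_b2_sq=sb2,
            rho12=float(np.tanh(x[0])), rho0=float(np.tanh(x[1])),
            sigma01=s01, sigma02=s02,
        )
        return -model.loglik(p, ref_segments)

    res_zero = _minimize(neg_zero, np.array([np.arctanh(np.clip(rho0_init, -0.9, 0.9))]), 100)
    res_max = _minimize(
        neg_max,
        np.array([np.arctanh(rho12_init), np.arctanh(np.clip(rho0_init, -0.9, 0.9))]),
        150,
    )
    aic = {
        "fitted": 2 * 3 - 2 * ll,
        "pi12_zero": 2 * 1 + 2 * res_zero.fun,
        "pi12_max": 2 * 2 + 2 * res_max.fun,
    }

    derived = {
        "n_shared": mean["pi12"] * m,
        "n_shared_sd": sd["pi12"] * m,
        "n1_unique": mean["pi1_unique"] * m,
        "n2_unique": mean["pi2_unique"] * m,
        "n1_total": tot1 * m,
        "n2_total": tot2 * m,
        "rg": genetic_correlation(fitted),
        "concordant_fraction": concordant_fraction(fitted.rho12),
        "n90_shared": float(n90(mean["pi12"], m)),
        "n90_trait1": float(n90(tot1, m)),
        "n90_trait2": float(n90(tot2, m)),
    }
    return FitResult(mean=mean, sd=sd, iterations=iters, loglik=ll, aic=aic, derived=derived, m=m)


# ---------------------------------------------------------------------------
# derived quantities


def n90(pi: float, m: int, sigma_b_sq: float | None = None) -> int:
    """Number of causal variants whose largest effects explain 90% of heritability.

    With squared effects proportional to chi-square(1), the threshold ``t``
    solving ``E[X 1{X > t}] = 0.9 E[X]`` satisfies ``P(chi2_3 > t) = 0.9``,
    and the answer is ``round(pi * m * P(chi2_1 > t))``; the ratio
    ``n90 / (pi m)`` is a universal constant (~0.444), independent of the
    effect-size variance.
    """
    if not (0 <= pi <= 1):
        raise ValueError("pi must be in [0, 1]")
    t = stats.chi2.isf(0.9, df=3)
    frac = stats.chi2.sf(t, df=1)
    return int(round(pi * m * frac))


def genetic_correlation(params: BivariateParams) -> float:
    """rg = rho12 * pi12 / sqrt(pi1_total * pi2_total) (equal within-trait
    effect variance across components); 0 if either total is 0."""
    tot1 = params.pi1 + params.pi12
    tot2 = params.pi2 + params.pi12
    if tot1 <= 0 or tot2 <= 0:
        return 0.0
    return float(params.rho12 * params.pi12 / np.sqrt(tot1 * tot2))


def concordant_fraction(rho12: float) -> float:
    """Probability that a shared causal variant has same-signed effects:
    the bivariate-normal orthant probability 1/2 + arcsin(rho12)/pi."""
    if abs(rho12) > 1:
        raise ValueError("|rho12| must be <= 1")
    return float(0.5 + np.arcsin(rho12) / np.pi)
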