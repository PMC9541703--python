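"""Conditional QQ curves and conditional/conjunctional FDR lookup tables.

The conditional FDR of a primary-trait p-value given a conditioning-trait
threshold is estimated stratum-wise as ``condFDR(p1 | p2 <= T) = p1 /
Fhat(p1 | p2 <= T)`` where ``Fhat`` is the empirical cdf of primary p-values
within the stratum (the null proportion is conservatively set to 1).  The
lookup is built on a grid over (-log10 p1, -log10 p2), interpolating between
nested conditioning strata, averaged over random LD-pruning iterations
(clusters at r^2 > 0.1), and regularized to be monotone: non-decreasing in
p1 along each conditioning slice and non-increasing as the conditioning
p-value sharpens.  The conjunctional FDR of a variant is the maximum of the
two mutual conditional FDR values; calls use a single significance threshold
(default 0.05).

Regions of long-range atypical LD (extended MHC chr6:25-34 Mb and the chr8
inversion chr8:7-12 Mb by default) are excluded from cdf construction but
still receive interpolated values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._prune import random_prune
from .sumstats_io import LDStructure, MergedPair, clamp_p

__all__ = [
    "StratumSpec",
    "FDRConfig",
    "FDRLookup",
    "conditional_qq",
    "build_fdr_lookup",
    "cond_fdr",
    "conj_fdr",
    "conjfdr_table",
    "CONJ_FDR_SIGNIFICANCE",
]

#: single significance threshold used everywhere downstream
CONJ_FDR_SIGNIFICANCE = 0.05

#: (chromosome, start, end) regions excluded from cdf construction
DEFAULT_EXCLUSIONS: tuple[tuple[int, int, int], ...] = (
    (6, 25_000_000, 34_000_000),   # extended MHC
    (8, 7_000_000, 12_000_000),    # 8p23 inversion
)


@dataclass
class StratumSpec:
    """Descending p-value thresholds for the conditioning trait."""

    thresholds: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001)

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, float)
        if (t <= 0).any() or (t > 1).any():
            raise ValueError("thresholds must lie in (0, 1]")
        if (np.diff(t) >= 0).any():
            raise ValueError("thresholds must be strictly decreasing")


@dataclass
class FDRConfig:
    """Grid, pruning and exclusion settings for lookup construction."""

    strata: StratumSpec = field(default_factory=StratumSpec)
    n_q1: int = 101
    n_q2: int = 41
    q_max: float = 10.0
    n_prune_iterations: int = 20
    prune_r2: float = 0.1
    exclusions: tuple[tuple[int, int, int], ...] = DEFAULT_EXCLUSIONS
    seed: int = 0


@dataclass
class FDRLookup:
    """Gridded condFDR values over (-log10 p_primary, -log10 p_conditioning)."""

    q1: np.ndarray  # primary axis nodes, ascending
    q2: np.ndarray  # conditioning axis nodes, ascending
    grid: np.ndarray  # (len(q1), len(q2)) condFDR values in (0, 1]
    primary: int  # which trait of the pair is primary (1 or 2)
    n_iterations: int
    exclusions: tuple[tuple[int, int, int], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid, index=self.q1, columns=self.q2)
        df.index.name = "neglog10_p_primary"
        df.columns.name = "neglog10_p_conditioning"
        return df

    def write(self, path) -> None:
        """TSV grid with a '#' metadata header (primary trait, iterations)."""
        with open(path, "w") as fh:
            fh.write(f"# primary={self.primary} iterations={self.n_iterations}\n")
            fh.write(
                "# exclusions="
                + ";".join(f"{c}:{s}-{e}" for c, s, e in self.exclusions)
                + "\n"
            )
            self.to_frame().to_csv(fh, sep="\t", float_format="%.10g")

    @classmethod
    def read(cls, path) -> "FDRLookup":
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k, _, v = tok.partition("=")
                        meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        exclusions = tuple(
            (int(c), int(s), int(e))
            for part in meta.get("exclusions", "").split(";")
            if part
            for c, rest in [part.split(":")]
            for s, e in [rest.split("-")]
        )
        return cls(
            q1=df.index.to_numpy(float),
            q2=np.asarray([float(c) for c in df.columns]),
            grid=df.to_numpy(float),
            primary=int(meta.get("primary", 1)),
            n_iterations=int(meta.get("iterations", 0)),
            exclusions=exclusions,
        )


def _neglog10(p: np.ndarray) -> np.ndarray:
    return -np.log10(clamp_p(np.asarray(p, float)))


def conditional_qq(
    pair: MergedPair, strata: StratumSpec | None = None, direction: int = 1
) -> dict[float, dict]:
    """Stratified QQ curves of the primary trait given conditioning thresholds.

    For each stratum threshold ``T``, the curve pairs the expected uniform
    quantiles with the observed ``-log10 p`` of primary-trait p-values among
    variants whose conditioning p-value is ``<= T``.  Strata with fewer than
    100 variants are flagged unstable but still returned.
    """
    if len(pair) == 0:
        raise ValueError("empty merged pair")
    strata = strata or StratumSpec()
    d = pair.df
    p_primary = d[f"P{direction}"].to_numpy(float)
    p_cond = d[f"P{2 if direction == 1 else 1}"].to_numpy(float)
    curves: dict[float, dict] = {}
    for thr in strata.thresholds:
        sel = p_cond <= thr
        obs = np.sort(_neglog10(p_primary[sel]))[::-1]
        n = len(obs)
        expected = _neglog10((np.arange(1, n + 1)) / (n + 1.0))
        curves[thr] = {
            "expected": expected,
            "observed": obs,
            "n": n,
            "unstable": n < 100,
        }
    return curves


def qq_quantile_point(curve: dict, quantile: float = 0.01) -> float:
    """Observed -log10 p at the given upper quantile of a QQ curve."""
    n = curve["n"]
    if n == 0:
        return np.nan
    k = min(max(int(np.ceil(quantile * n)) - 1, 0), n - 1)
    return float(curve["observed"][k])


def _exclusion_mask(
    chrom: np.ndarray, bp: np.ndarray, regions: tuple[tuple[int, int, int], ...]
) -> np.ndarray:
    """True for variants inside any exclusion region."""
    mask = np.zeros(len(chrom), dtype=bool)
    for c, s, e in regions:
        mask |= (chrom == c) & (bp >= s) & (bp <= e)
    return mask


def build_fdr_lookup(
    pair: MergedPair, ld: LDStructure, primary: int, config: FDRConfig | None = None
) -> FDRLookup:
    """Build the stratified empirical condFDR lookup for one direction.

    Per pruning iteration one random variant per LD cluster (r^2 > 0.1) is
    kept; per conditioning stratum the empirical cdf of primary p-values is
    evaluated on the grid and ``condFDR = p1 / Fhat``; grids are averaged
    over iterations, interpolated along the conditioning axis between
    stratum coordinates, and monotone-regularized.
    """
    if primary not in (1, 2):
        raise ValueError("primary must be 1 or 2")
    config = config or FDRConfig()
    d = pair.df
    p1 = d[f"P{primary}"].to_numpy(float)
    p2 = d[f"P{2 if primary == 1 else 1}"].to_numpy(float)
    chrom = d["CHR"].to_numpy()
    bp = d["BP"].to_numpy()
    excluded = _exclusion_mask(chrom, bp, config.exclusions)

    thresholds = np.asarray(config.strata.thresholds, float)
    q1 = np.linspace(0.0, config.q_max, config.n_q1)
    p1_grid = 10.0**(-q1)
    q2 = np.linspace(0.0, config.q_max, config.n_q2)
    q_strata = -np.log10(thresholds)

    indptr, indices = ld.adjacency(pair.ids, min_r2=config.prune_r2)
    eligible = np.flatnonzero(~excluded)
    acc = np.zeros((len(thresholds), len(q1)))
    for it in range(config.n_prune_iterations):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(21, it)))
        keep = random_prune(indptr, indices, eligible, rng)
        kept_p1, kept_p2 = p1[keep], p2[keep]
        prev_sorted = None
        for si, thr in enumerate(thresholds):
            vals = np.sort(kept_p1[kept_p2 <= thr])
            if len(vals) == 0:
                warnings.warn(f"empty conditioning stratum p <= {thr}; merged with parent")
                vals = prev_sorted if prev_sorted is not None else np.sort(kept_p1)
            prev_sorted = vals
            counts = np.searchsorted(vals, p1_grid, side="right")
            # empirical cdf floored by the uniform cdf: cross-trait enrichment
            # implies F(p) >= p, and the floor keeps grid nodes beyond the
            # observed p range conservative (condFDR ~ 1) instead of
            # extrapolating the last observed rank
            fhat = np.maximum(counts / len(vals), p1_grid)
            acc[si] += np.clip(p1_grid / fhat, None, 1.0)
    acc /= config.n_prune_iterations

    # interpolate stratum curves along the conditioning axis, clamped beyond
    grid = np.empty((len(q1), len(q2)))
    for j, q in enumerate(q2):
        if q <= q_strata[0]:
            grid[:, j] = acc[0]
        elif q >= q_strata[-1]:
            grid[:, j] = acc[-1]
        else:
            k = np.searchsorted(q_strata, q) - 1
            w = (q - q_strata[k]) / (q_strata[k + 1] - q_strata[k])
            grid[:, j] = (1 - w) * acc[k] + w * acc[k + 1]

    # monotone regularization: condFDR falls as p1 falls (q1 rises) and as
    # the conditioning p-value sharpens (q2 rises)
    grid = np.minimum.accumulate(grid, axis=0)
    grid = np.minimum.accumulate(grid, axis=1)
    grid = np.clip(grid, np.finfo(float).tiny, 1.0)
    return FDRLookup(
        q1=q1,
        q2=q2,
        grid=grid,
        primary=primary,
        n_iterations=config.n_prune_iterations,
        exclusions=config.exclusions,
    )


def cond_fdr(lookup: FDRLookup, p1: np.ndarray | float, p2: np.ndarray | float) -> np.ndarray | float:
    """Bilinear interpolation of the lookup at (-log10 p1, -log10 p2).

    Queries outside the grid are clamped to the nearest edge.
    """
    scalar = np.isscalar(p1) and np.isscalar(p2)
    x = np.clip(_neglog10(np.atleast_1d(p1)), lookup.q1[0], lookup.q1[-1])
    y = np.clip(_neglog10(np.atleast_1d(p2)), lookup.q2[0], lookup.q2[-1])
    ix = np.clip(np.searchsorted(lookup.q1, x) - 1, 0, len(lookup.q1) - 2)
    iy = np.clip(np.searchsorted(lookup.q2, y) - 1, 0, len(lookup.q2) - 2)
    wx = (x - lookup.q1[ix]) / (lookup.q1[ix + 1] - lookup.q1[ix])
    wy = (y - lookup.q2[iy]) / (lookup.q2[iy + 1] - lookup.q2[iy])
    g = lookup.grid
    val = (
        g[ix, iy] * (1 - wx) * (1 - wy)
        + g[ix + 1, iy] * wx * (1 - wy)
        + g[ix, iy + 1] * (1 - wx) * wy
        + g[ix + 1, iy + 1] * wx * wy
    )
    val = np.clip(val, np.finfo(float).tiny, 1.0)
    return float(val[0]) if scalar else val


def conj_fdr(
    lookup12: FDRLookup,
    lookup21: FDRLookup,
    p1: np.ndarray | float,
    p2: np.ndarray | float,
) -> np.ndarray | float:
    """Conjunctional FDR: max of the two mutual conditional FDR values."""
    return np.maximum(cond_fdr(lookup12, p1, p2), cond_fdr(lookup21, p2, p1))


def conjfdr_table(
    pair: MergedPair, ld: LDStructure, config: FDRConfig | None = None
) -> pd.DataFrame:
    """Per-variant condFDR/conjFDR table for a harmonized pair.

    Output columns: SNP, CHR, BP, A1, A2, Z1, Z2, P1, P2, condFDR12,
    condFDR21, conjFDR.
    """
    config = config or FDRConfig()
    lookup12 = build_fdr_lookup(pair, ld, primary=1, config=config)
    lookup21 = build_fdr_lookup(pair, ld, primary=2, config=config)
    d = pair.df
    c12 = cond_fdr(lookup12, d["P1"].to_numpy(), d["P2"].to_numpy())
    c21 = cond_fdr(lookup21, d["P2"].to_numpy(), d["P1"].to_numpy())
    out = d[["SNP", "CHR", "BP", "A1", "A2", "Z1", "Z2", "P1", "P2"]].copy()
    out["condFDR12"] = c12
    out["condFDR21"] = c21
    out["conjFDR"] = np.maximum(c12, c21)
    return out
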