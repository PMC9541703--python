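"""Reading, validation and harmonization of GWAS summary statistics and related tables.

The pipeline works with tab-delimited summary statistics (one trait per file),
sparse pairwise LD tables, genomic interval lists (BED) and gene-set
collections (GMT).  All coordinates are handled 1-based inclusive internally;
BED input is converted on read.  p-values are clamped to ``[1e-300, 1]``
before any log transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SumstatsFormatError",
    "LoadReport",
    "VariantTable",
    "MergedPair",
    "LDStructure",
    "SparseLD",
    "BlockLD",
    "read_sumstats",
    "write_sumstats",
    "harmonize_pair",
    "read_ld_table",
    "read_bed",
    "read_gmt",
]

P_FLOOR = 1e-300
VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: strand-ambiguous allele pairs (palindromic): complementing does not disambiguate
AMBIGUOUS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "Z", "P", "N")

#: case-insensitive column aliases tried when no explicit dialect is given
DEFAULT_ALIASES: Mapping[str, tuple[str, ...]] = {
    "SNP": ("snp", "rsid", "rs_id", "variant_id", "markername", "id"),
    "CHR": ("chr", "chrom", "chromosome"),
    "BP": ("bp", "pos", "position", "base_pair_location"),
    "A1": ("a1", "allele1", "effect_allele", "ea"),
    "A2": ("a2", "allele2", "other_allele", "oa", "nea"),
    "Z": ("z", "zscore", "z_score", "stat"),
    "P": ("p", "pval", "p_value", "pvalue"),
    "N": ("n", "neff", "n_total", "sample_size"),
    "BETA": ("beta", "b", "effect", "log_odds"),
    "SE": ("se", "stderr", "standard_error"),
}


class SumstatsFormatError(ValueError):
    """Raised when an input table cannot be interpreted."""


def clamp_p(p: np.ndarray | float) -> np.ndarray | float:
    return np.clip(p, P_FLOOR, 1.0)


def p_from_z(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided p-value from a z-score, p = 2*Phi(-|z|)."""
    return clamp_p(2.0 * stats.norm.sf(np.abs(z)))


@dataclass
class LoadReport:
    """Bookkeeping from :func:`read_sumstats`."""

    n_rows_in: int = 0
    n_dropped_numeric: int = 0
    n_dropped_alleles: int = 0
    n_z_from_beta: int = 0
    n_p_recomputed: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_numeric + self.n_dropped_alleles


@dataclass
class VariantTable:
    """Per-variant summary statistics for one trait.

    Wraps a DataFrame with canonical columns SNP, CHR, BP, A1, A2, Z, P, N.
    Construction validates uniqueness of variant ids, positive positions,
    allele alphabet, the p/z consistency contract and the p range.
    """

    df: pd.DataFrame
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SumstatsFormatError(f"missing required column(s): {missing}")
        if df["SNP"].duplicated().any():
            dups = df.loc[df["SNP"].duplicated(), "SNP"].head(5).tolist()
            raise SumstatsFormatError(f"duplicate variant ids, first: {dups}")
        if len(df) and (df["BP"].to_numpy() <= 0).any():
            raise SumstatsFormatError("non-positive base-pair positions")
        if len(df):
            alleles = set(df["A1"]).union(df["A2"])
            bad = alleles - VALID_ALLELES
            if bad:
                raise SumstatsFormatError(f"invalid alleles: {sorted(bad)}")
            p, z = df["P"].to_numpy(float), df["Z"].to_numpy(float)
            if (p <= 0).any() or (p > 1).any():
                raise SumstatsFormatError("p-values outside (0, 1]")
            expect = p_from_z(z)
            rel = np.abs(p - expect) / np.maximum(expect, P_FLOOR)
            # clamped underflow region is exempt from the consistency contract
            chk = expect > 10 * P_FLOOR
            if (rel[chk] > 1e-6).any():
                raise SumstatsFormatError("p and z mutually inconsistent")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["SNP"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.df["Z"].to_numpy(float)

    @property
    def p(self) -> np.ndarray:
        return self.df["P"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.df["N"].to_numpy(float)

    def write(self, path: str | Path) -> None:
        write_sumstats(self, path)


def _resolve_columns(header: Sequence[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical names to actual column names, case-insensitively."""
    lower = {c.lower(): c for c in header}
    out: dict[str, str] = {}
    if dialect:
        for canon, name in dialect.items():
            if name.lower() in lower:
                out[canon.upper()] = lower[name.lower()]
        return out
    for canon, aliases in DEFAULT_ALIASES.items():
        for cand in (canon.lower(), *aliases):
            if cand in lower:
                out[canon] = lower[cand]
                break
    return out


def read_sumstats(path: str | Path, dialect: Mapping[str, str] | None = None) -> VariantTable:
    """Read a tab-delimited summary-statistics file into a :class:`VariantTable`.

    ``dialect`` optionally maps canonical names (SNP, CHR, BP, A1, A2, Z, P, N,
    BETA, SE) to the file's column names.  Column matching is case-insensitive.
    If only BETA/SE are present, ``z = beta/se``; if P is absent (or
    inconsistent with z) it is recomputed as ``2*Phi(-|z|)``.  Rows with
    unparsable numeric fields are dropped and counted in the load report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    report = LoadReport(n_rows_in=len(raw))
    cols = _resolve_columns(raw.columns, dialect)

    required = ["SNP", "CHR", "BP", "A1", "A2", "N"]
    for canon in required:
        if canon not in cols:
            raise SumstatsFormatError(f"missing required column: {canon}")
    if "Z" not in cols and not ("BETA" in cols and "SE" in cols):
        raise SumstatsFormatError("missing required column: Z (or BETA and SE)")

    df = pd.DataFrame({"SNP": raw[cols["SNP"]].astype(str)})
    for canon in ("A1", "A2"):
        df[canon] = raw[cols[canon]].astype(str).str.upper().str.strip()
    numeric = {"CHR": cols["CHR"], "BP": cols["BP"], "N": cols["N"]}
    for canon in ("Z", "P", "BETA", "SE"):
        if canon in cols:
            numeric[canon] = cols[canon]
    for canon, col in numeric.items():
        df[canon] = pd.to_numeric(raw[col], errors="coerce")

    needed = [c for c in ("CHR", "BP", "N", "Z", "BETA", "SE") if c in df.columns]
    bad = df[needed].isna().any(axis=1)
    report.n_dropped_numeric = int(bad.sum())
    df = df.loc[~bad].copy()

    ok_alleles = df["A1"].isin(VALID_ALLELES) & df["A2"].isin(VALID_ALLELES)
    report.n_dropped_alleles = int((~ok_alleles).sum())
    df = df.loc[ok_alleles].copy()

    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
        report.n_z_from_beta = len(df)
    if "P" in df.columns:
        p = clamp_p(df["P"].to_numpy(float))
        expect = p_from_z(df["Z"].to_numpy(float))
        rel = np.abs(p - expect) / np.maximum(expect, P_FLOOR)
        fix = (rel > 1e-6) & (expect > 10 * P_FLOOR) | ~np.isfinite(p)
        p = np.where(fix, expect, p)
        report.n_p_recomputed = int(fix.sum())
        df["P"] = p
    else:
        df["P"] = p_from_z(df["Z"].to_numpy(float))
        report.n_p_recomputed = len(df)

    df["CHR"] = df["CHR"].astype(int)
    df["BP"] = df["BP"].astype(int)
    for col in ("Z", "P", "N"):
        df[col] = df[col].astype(float)
    out = df[list(CANONICAL_COLUMNS)].reset_index(drop=True)
    return VariantTable(out, load_report=report)


def write_sumstats(table: VariantTable, path: str | Path) -> None:
    """Write canonical tab-delimited summary statistics (round-trip safe)."""
    df = table.df[list(CANONICAL_COLUMNS)].copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class MergedPair:
    """Variants present in both traits, harmonized to a common effect allele.

    Columns: SNP, CHR, BP, A1, A2, Z1, P1, N1, Z2, P2, N2,
    allele_flipped, strand_complemented.
    """

    df: pd.DataFrame
    n_ambiguous_dropped: int = 0
    n_irreconcilable_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["SNP"].to_numpy()

    def trait(self, which: int) -> pd.DataFrame:
        """Per-trait view with canonical Z/P/N names (1 or 2)."""
        d = self.df
        return pd.DataFrame(
            {
                "SNP": d["SNP"],
                "CHR": d["CHR"],
                "BP": d["BP"],
                "A1": d["A1"],
                "A2": d["A2"],
                "Z": d[f"Z{which}"],
                "P": d[f"P{which}"],
                "N": d[f"N{which}"],
            }
        )


def harmonize_pair(
    t1: VariantTable, t2: VariantTable, ambiguous_policy: str = "drop"
) -> MergedPair:
    """Intersect two variant tables and align trait-2 effects to trait-1 alleles.

    Allele reconciliation, in order: identical; swapped (z2 sign flipped);
    strand complement; complement of the swap (flipped).  Irreconcilable
    records are dropped and counted.  Strand-ambiguous variants (A/T, C/G)
    are dropped by default (``ambiguous_policy="drop"``) because allele
    frequencies are not available to resolve them.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError("ambiguous_policy must be 'drop' or 'keep'")
    m = t1.df.merge(t2.df, on="SNP", suffixes=("_1", "_2"), how="inner")

    a1, a2 = m["A1_1"], m["A2_1"]
    b1, b2 = m["A1_2"], m["A2_2"]
    ambiguous = pd.Series(list(zip(a1, a2)), index=m.index).isin(AMBIGUOUS)
    same = (a1 == b1) & (a2 == b2)
    swap = (a1 == b2) & (a2 == b1)
    c1 = b1.map(COMPLEMENT)
    c2 = b2.map(COMPLEMENT)
    comp = (a1 == c1) & (a2 == c2) & ~same
    comp_swap = (a1 == c2) & (a2 == c1) & ~swap

    n_ambiguous = 0
    if ambiguous_policy == "drop":
        n_ambiguous = int(ambiguous.sum())
        keepable = ~ambiguous
    else:
        keepable = pd.Series(True, index=m.index)
    resolvable = same | swap | comp | comp_swap
    n_irreconcilable = int((keepable & ~resolvable).sum())
    sel = keepable & resolvable
    m = m.loc[sel]
    flip = (swap | comp_swap).loc[sel]
    complemented = (comp | comp_swap).loc[sel]

    out = pd.DataFrame(
        {
            "SNP": m["SNP"],
            "CHR": m["CHR_1"],
            "BP": m["BP_1"],
            "A1": m["A1_1"],
            "A2": m["A2_1"],
            "Z1": m["Z_1"],
            "P1": m["P_1"],
            "N1": m["N_1"],
            "Z2": np.where(flip, -m["Z_2"], m["Z_2"]),
            "P2": m["P_2"],
            "N2": m["N_2"],
            "allele_flipped": flip.to_numpy(),
            "strand_complemented": complemented.to_numpy(),
        }
    ).reset_index(drop=True)
    return MergedPair(out, n_ambiguous_dropped=n_ambiguous, n_irreconcilable_dropped=n_irreconcilable)


class LDStructure:
    """Symmetric pairwise LD correlation provider.

    ``r(i, i) = 1`` always; pairs not represented return 0 (the synthetic LD
    is block-diagonal, so zero-fill is exact there).
    """

    def r(self, i: str, j: str) -> float:
        raise NotImplementedError

    def neighbors(self, i: str, min_r2: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """(ids, r) of variants with r^2 >= min_r2 to ``i``, excluding ``i``."""
        raise NotImplementedError

    def adjacency(self, ids: Sequence[str], min_r2: float) -> tuple[np.ndarray, np.ndarray]:
        """CSR (indptr, indices) adjacency restricted to ``ids`` at r^2 >= min_r2."""
        idx_of = {v: k for k, v in enumerate(ids)}
        indptr = np.zeros(len(ids) + 1, dtype=np.int64)
        cols: list[int] = []
        for k, v in enumerate(ids):
            nb_ids, _ = self.neighbors(v, min_r2=min_r2)
            row = sorted(idx_of[u] for u in nb_ids if u in idx_of)
            cols.extend(row)
            indptr[k + 1] = len(cols)
        return indptr, np.asarray(cols, dtype=np.int64)

    def r2_profile(self, i: str, min_r2: float) -> np.ndarray:
        """Sorted r^2 values of i's neighborhood *including itself* (r=1)."""
        _, rv = self.neighbors(i, min_r2=min_r2)
        return np.sort(np.concatenate([[1.0], rv**2]))


class SparseLD(LDStructure):
    """Dict-backed sparse LD from an explicit pair list."""

    def __init__(self, pairs: Iterable[tuple[str, str, float]], sign_unknown: bool = False):
        self._r: dict[tuple[str, str], float] = {}
        self._nbr: dict[str, list[tuple[str, float]]] = {}
        self.sign_unknown = sign_unknown
        for a, b, r in pairs:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in self._r:
                continue
            self._r[key] = float(r)
            self._nbr.setdefault(a, []).append((b, float(r)))
            self._nbr.setdefault(b, []).append((a, float(r)))

    def r(self, i: str, j: str) -> float:
        if i == j:
            return 1.0
        key = (i, j) if i <= j else (j, i)
        return self._r.get(key, 0.0)

    def neighbors(self, i: str, min_r2: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        entries = [(u, r) for u, r in self._nbr.get(i, []) if r * r >= min_r2]
        if not entries:
            return np.empty(0, dtype=object), np.empty(0)
        ids, rs = zip(*entries)
        return np.asarray(ids, dtype=object), np.asarray(rs, dtype=float)


class BlockLD(LDStructure):
    """Block-diagonal AR(1) LD: within a block ``r(i, j) = rho**|i-j|``.

    Indexed by the genome template's variant order; cross-block r is 0.
    Neighborhoods are truncated at ``|r| < min_r`` (default 0.05), the same
    truncation the simulator uses when propagating effects.
    """

    def __init__(self, ids: Sequence[str], block: np.ndarray, rho: float, min_r: float = 0.05):
        self.ids = np.asarray(ids)
        self.block = np.asarray(block, dtype=np.int64)
        self.rho = float(rho)
        self.min_r = float(min_r)
        self._idx = {v: k for k, v in enumerate(self.ids)}
        # block start/end (half-open) per variant, from contiguous runs
        starts = np.flatnonzero(np.r_[True, np.diff(self.block) != 0])
        ends = np.r_[starts[1:], len(self.block)]
        self._bstart = np.repeat(starts, ends - starts)
        self._bend = np.repeat(ends, ends - starts)
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        self.max_lag = 0
        if self.rho != 0:
            self.max_lag = int(np.floor(np.log(self.min_r) / np.log(abs(self.rho))))

    def index_of(self, i: str) -> int:
        return self._idx[i]

    def r(self, i: str, j: str) -> float:
        a, b = self._idx[i], self._idx[j]
        if a == b:
            return 1.0
        if self.block[a] != self.block[b]:
            return 0.0
        return self.rho ** abs(a - b)

    def _lag_for(self, min_r2: float) -> int:
        if self.rho == 0:
            return 0
        if min_r2 <= 0:
            return self.max_lag
        lag = int(np.floor(np.log(min_r2) / (2 * np.log(abs(self.rho)))))
        return min(lag, self.max_lag)

    def neighbors(self, i: str, min_r2: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        a = self._idx[i]
        lag = self._lag_for(min_r2)
        lo = max(self._bstart[a], a - lag)
        hi = min(self._bend[a], a + lag + 1)
        idx = np.r_[np.arange(lo, a), np.arange(a + 1, hi)]
        return self.ids[idx], self.rho ** np.abs(idx - a).astype(float)

    def adjacency(self, ids: Sequence[str], min_r2: float) -> tuple[np.ndarray, np.ndarray]:
        # vectorized banded adjacency restricted to the given id subset
        pos = np.asarray([self._idx[v] for v in ids], dtype=np.int64)
        order = np.argsort(pos)
        spos = pos[order]
        lag = self._lag_for(min_r2)
        indptr = np.zeros(len(ids) + 1, dtype=np.int64)
        cols: list[np.ndarray] = []
        n = 0
        for k in range(len(ids)):
            a = pos[k]
            lo = max(self._bstart[a], a - lag)
            hi = min(self._bend[a], a + lag + 1)
            i0, i1 = np.searchsorted(spos, lo), np.searchsorted(spos, hi)
            row = order[i0:i1]
            row = row[row != k]
            cols.append(row)
            n += len(row)
            indptr[k + 1] = n
        return indptr, (np.concatenate(cols) if cols else np.empty(0, dtype=np.int64))

    def signal(self, beta: np.ndarray) -> np.ndarray:
        """LD-propagated signal ``sum_i r(i, j) * beta_i``, truncated at |r| < min_r."""
        from scipy.signal import fftconvolve

        lag = self.max_lag
        kernel = self.rho ** np.abs(np.arange(-lag, lag + 1)).astype(float)
        out = np.empty_like(beta, dtype=float)
        starts = np.unique(self._bstart)
        ends = self._bend[starts]
        sizes = ends - starts
        for size in np.unique(sizes):
            sel = starts[sizes == size]
            block = beta[sel[:, None] + np.arange(size)[None, :]]
            conv = fftconvolve(block, kernel[None, :], mode="same", axes=1)
            out[sel[:, None] + np.arange(size)[None, :]] = conv
        return out


def read_ld_table(path: str | Path) -> SparseLD:
    """Read a pairwise LD table.

    Accepts a 3-column TSV ``id_i, id_j, r`` (with or without header) or a
    PLINK-style ``.ld`` table with columns SNP_A, SNP_B and R or R2
    (whitespace-delimited).  R2 input yields ``|r| = sqrt(R2)`` with the sign
    flagged unknown on the returned structure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.upper(): c for c in df.columns}
    sign_unknown = False
    if "SNP_A" in cols and "SNP_B" in cols:
        a, b = df[cols["SNP_A"]].astype(str), df[cols["SNP_B"]].astype(str)
        if "R" in cols:
            r = pd.to_numeric(df[cols["R"]])
        elif "R2" in cols:
            r = np.sqrt(pd.to_numeric(df[cols["R2"]]))
            sign_unknown = True
        else:
            raise SumstatsFormatError("PLINK .ld table lacks R or R2 column")
    else:
        # headerless or generic 3-column dialect
        first = pd.read_csv(path, sep=r"\s+", header=None, nrows=1)
        try:
            float(first.iloc[0, 2])
            df = pd.read_csv(path, sep=r"\s+", header=None)
        except (TypeError, ValueError):
            pass  # header row present, keep df as read
        if df.shape[1] < 3:
            raise SumstatsFormatError("LD table needs 3 columns (id_i, id_j, r)")
        a = df.iloc[:, 0].astype(str)
        b = df.iloc[:, 1].astype(str)
        r = pd.to_numeric(df.iloc[:, 2])
    r = r.to_numpy(float)
    bad = np.flatnonzero(np.abs(r) > 1)
    if bad.size:
        raise SumstatsFormatError(f"|r| > 1 at line {bad[0] + 2}")
    return SparseLD(zip(a, b, r), sign_unknown=sign_unknown)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED interval list -> DataFrame(CHR, START, END), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    chrom = df[0].astype(str).str.replace("chr", "", regex=False).astype(int)
    return pd.DataFrame(
        {"CHR": chrom, "START": df[1].astype(int) + 1, "END": df[2].astype(int)}
    )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write CHR/START/END (1-based inclusive) intervals as BED."""
    out = intervals.copy()
    out["START"] = out["START"] - 1
    out[["CHR", "START", "END"]].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection -> {set name: [gene symbols]}."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    return sets


def intervals_overlap(s1: int, e1: int, s2: int, e2: int) -> bool:
    """1-based inclusive interval overlap: max(start) <= min(end)."""
    return max(s1, s2) <= min(e1, e2)
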