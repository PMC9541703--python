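"""Replication sign-concordance, positional gene mapping and gene-set enrichment.

Replication support for discovered loci is tested en masse: the number of
lead SNPs whose z-score sign agrees between discovery and replication
follows Binomial(n, 1/2) under the null of no consistent effects, and the
reported p-value is the one-sided exact binomial tail P(X >= k).  Lead SNPs
missing from the replication table are dropped and counted.

Genes are mapped to loci positionally: a gene is mapped iff its span,
extended by a window (default 10 kb), overlaps any candidate-SNP position.
Gene-set enrichment of a mapped (or externally supplied credible) gene list
is a hypergeometric tail test per set with Benjamini-Hochberg adjustment
across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .locus_definition import Locus
from .sumstats_io import VariantTable

__all__ = [
    "ConcordanceResult",
    "EnrichmentRow",
    "sign_concordance_test",
    "map_genes_positional",
    "hypergeometric_enrichment",
]


@dataclass
class ConcordanceResult:
    """En-masse sign-concordance test outcome."""

    n: int  # leads tested (resolvable in replication, nonzero signs)
    k: int  # concordant
    n_missing: int  # leads absent from the replication table
    p: float | None  # one-sided exact binomial tail vs 1/2; None if n == 0

    @property
    def fraction(self) -> float:
        return self.k / self.n if self.n else float("nan")


def sign_concordance_test(
    leads: pd.DataFrame, replication: VariantTable
) -> ConcordanceResult:
    """One-sided exact binomial test of discovery/replication sign agreement.

    ``leads`` needs columns SNP and Z (discovery z at each lead SNP).
    k counts leads with sign(z_discovery) == sign(z_replication);
    p = P(X >= k | n, 1/2).
    """
    rep = replication.df.set_index("SNP")["Z"]
    present = leads["SNP"].isin(rep.index)
    n_missing = int((~present).sum())
    sub = leads.loc[present]
    z_disc = sub["Z"].to_numpy(float)
    z_rep = rep.loc[sub["SNP"]].to_numpy(float)
    usable = (z_disc != 0) & (z_rep != 0)
    z_disc, z_rep = z_disc[usable], z_rep[usable]
    n = len(z_disc)
    if n == 0:
        return ConcordanceResult(n=0, k=0, n_missing=n_missing, p=None)
    k = int((np.sign(z_disc) == np.sign(z_rep)).sum())
    p = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    return ConcordanceResult(n=n, k=k, n_missing=n_missing, p=p)


def map_genes_positional(
    loci: list[Locus],
    positions: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 10_000,
) -> dict[str, list[str]]:
    """Positional gene mapping: gene span +/- window must cover a candidate SNP.

    ``positions`` maps SNP -> CHR, BP (any table with those columns);
    ``genes`` has columns GENE, CHR, START, END.  Returns
    {lead SNP id: sorted gene symbols} per locus.
    """
    pos = positions.set_index("SNP")
    out: dict[str, list[str]] = {}
    for locus in loci:
        cand = pos.loc[[c for c in locus.candidates if c in pos.index]]
        mapped = []
        for _, g in genes.iterrows():
            if int(g["CHR"]) != locus.chrom:
                continue
            lo, hi = int(g["START"]) - window, int(g["END"]) + window
            bp = cand["BP"].to_numpy()
            if ((bp >= lo) & (bp <= hi)).any():
                mapped.append(str(g["GENE"]))
        out[locus.lead] = sorted(mapped)
    return out


@dataclass
class EnrichmentRow:
    """Hypergeometric enrichment of one gene set."""

    set_name: str
    overlap: int
    set_size: int
    list_size: int
    background_size: int
    p: float
    p_adjusted: float


def hypergeometric_enrichment(
    gene_list: list[str],
    gene_sets: dict[str, list[str]],
    background: list[str],
) -> list[EnrichmentRow]:
    """Hypergeometric tail test per gene set with BH adjustment across sets.

    Sets are intersected with the background universe before testing;
    p = P(overlap >= observed) under Hypergeom(N=|background|, K=|set|,
    n=|list|).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background gene universe")
    lst = set(gene_list) & bg
    names = sorted(gene_sets)
    rows = []
    pvals = []
    for name in names:
        members = set(gene_sets[name]) & bg
        k = len(lst & members)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(members), len(lst)))
        pvals.append(min(p, 1.0))
        rows.append((name, k, len(members)))
    if not rows:
        return []
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentRow(
            set_name=name,
            overlap=k,
            set_size=size,
            list_size=len(lst),
            background_size=len(bg),
            p=p,
            p_adjusted=float(max(pa, p)),
        )
        for (name, k, size), p, pa in zip(rows, pvals, adj)
    ]
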