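"""FUMA-protocol locus definition on conjFDR results and transdiagnostic merging.

Significant variants (conjFDR < 0.05) are clumped greedily by ascending
conjFDR: a significant variant becomes an *independent significant SNP*
unless it is in r^2 >= 0.6 with one already chosen; among independent
significant SNPs, *lead SNPs* are chosen greedily at mutual r^2 < 0.1.
*Candidate SNPs* are all variants with conjFDR < 0.10 in r^2 >= 0.6 with an
independent significant SNP (each independent significant SNP tags itself).
Independent significant SNPs within 250 kb of each other or in r^2 >= 0.1
fall into one locus; locus bounds are the min-max positions of its candidate
SNPs.  Ties are broken by position then variant id, so the procedure is
deterministic.

Transdiagnostic loci group loci from different trait-pair analyses that
physically overlap and share at least one candidate SNP with conjFDR <= 0.05
in both paired analyses; groups are closed transitively.  The transdiagnostic
lead SNP minimizes the maximum conjFDR across the contributing analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross_trait_fdr import CONJ_FDR_SIGNIFICANCE
from .sumstats_io import LDStructure, intervals_overlap

__all__ = [
    "LocusConfig",
    "Locus",
    "TransdiagnosticLocus",
    "find_candidate_snps",
    "define_loci",
    "directional_concordance",
    "annotate_novelty",
    "merge_transdiagnostic",
    "loci_frame",
]


@dataclass
class LocusConfig:
    sig_threshold: float = CONJ_FDR_SIGNIFICANCE
    candidate_threshold: float = 0.10
    r2_independent: float = 0.6
    r2_lead: float = 0.1
    merge_kb: float = 250.0


@dataclass
class Locus:
    """A clumped genomic interval jointly associated with both traits."""

    analysis: str
    chrom: int
    start: int
    end: int
    lead: str
    independent: list[str]
    candidates: list[str]
    lead_z1: float
    lead_z2: float
    concordant: bool | None = None
    novel: dict[str, bool] = field(default_factory=dict)


@dataclass
class TransdiagnosticLocus:
    """Overlapping loci from two or more analyses sharing a significant candidate."""

    analyses: list[str]
    chrom: int
    start: int
    end: int
    lead: str
    conjfdr_by_analysis: dict[str, float]
    concordant_by_analysis: dict[str, bool]
    loci: list[Locus] = field(default_factory=list)


def _sort_key(table: pd.DataFrame) -> np.ndarray:
    """Deterministic clumping order: ascending conjFDR, then BP, then SNP."""
    return np.lexsort(
        (table["SNP"].to_numpy(), table["BP"].to_numpy(), table["conjFDR"].to_numpy())
    )


def find_candidate_snps(
    pervariant: pd.DataFrame,
    ld: LDStructure,
    independent_ids: list[str],
    candidate_threshold: float = 0.10,
    r2_independent: float = 0.6,
) -> dict[str, list[str]]:
    """Candidate SNPs tagged by each independent significant SNP.

    A variant is a candidate iff its conjFDR < ``candidate_threshold`` and it
    is in r^2 >= ``r2_independent`` with at least one independent significant
    SNP; each independent significant SNP tags itself (self-LD r^2 = 1).
    """
    fdr_of = dict(zip(pervariant["SNP"], pervariant["conjFDR"]))
    present = set(pervariant["SNP"])
    out: dict[str, list[str]] = {}
    for ind in independent_ids:
        nb_ids, _ = ld.neighbors(ind, min_r2=r2_independent)
        cands = {ind}
        for v in nb_ids:
            if v in present and fdr_of[v] < candidate_threshold:
                cands.add(v)
        out[ind] = sorted(cands)
    return out


def define_loci(
    pervariant: pd.DataFrame,
    ld: LDStructure,
    config: LocusConfig | None = None,
    analysis: str = "pair",
) -> list[Locus]:
    """Greedy FUMA-style clumping of a per-variant conjFDR table into loci.

    ``pervariant`` needs columns SNP, CHR, BP, conjFDR and (optionally)
    Z1/Z2 for lead effect directions.  Returns loci sorted by (CHR, start).
    """
    config = config or LocusConfig()
    t = pervariant.reset_index(drop=True)
    order = _sort_key(t)
    sig_mask = t["conjFDR"].to_numpy() < config.sig_threshold
    if not sig_mask.any():
        return []

    info = t.set_index("SNP")
    chrom_of = info["CHR"].to_dict()
    bp_of = info["BP"].to_dict()
    fdr_of = info["conjFDR"].to_dict()

    # 1. independent significant SNPs (greedy at r^2 >= 0.6)
    independent: list[str] = []
    chosen: set[str] = set()
    for i in order:
        if not sig_mask[i]:
            continue
        snp = t.at[i, "SNP"]
        nb_ids, nb_r = ld.neighbors(snp, min_r2=config.r2_independent)
        if any(v in chosen for v in nb_ids):
            continue
        independent.append(snp)
        chosen.add(snp)

    # 2. lead SNPs among independent ones (greedy at mutual r^2 < 0.1)
    leads: list[str] = []
    for snp in independent:  # already in clumping order
        nb_ids, _ = ld.neighbors(snp, min_r2=config.r2_lead)
        if any(v in leads for v in nb_ids):
            continue
        leads.append(snp)

    # 3. candidates per independent significant SNP
    cand_of = find_candidate_snps(
        t, ld, independent, config.candidate_threshold, config.r2_independent
    )

    # 4. group independent SNPs into loci (union-find over distance / r^2 links)
    parent = {s: s for s in independent}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    max_dist = config.merge_kb * 1_000
    for i, a in enumerate(independent):
        for b in independent[i + 1 :]:
            if chrom_of[a] != chrom_of[b]:
                continue
            if abs(bp_of[a] - bp_of[b]) <= max_dist or ld.r(a, b) ** 2 >= config.r2_lead:
                union(a, b)

    groups: dict[str, list[str]] = {}
    for s in independent:
        groups.setdefault(find(s), []).append(s)

    # 5. assign each candidate to exactly one locus: the one whose linked
    #    independent SNP has the lowest conjFDR (ties: position, id)
    best_locus_of: dict[str, tuple] = {}
    root_of = {s: find(s) for s in independent}
    for ind in independent:
        for c in cand_of[ind]:
            key = (fdr_of[ind], bp_of[ind], ind)
            if c not in best_locus_of or key < best_locus_of[c][0]:
                best_locus_of[c] = (key, root_of[ind])

    loci: list[Locus] = []
    has_z = "Z1" in t.columns and "Z2" in t.columns
    z1_of = info["Z1"].to_dict() if has_z else {}
    z2_of = info["Z2"].to_dict() if has_z else {}
    for root, members in groups.items():
        cands = sorted({c for c, (_, r) in best_locus_of.items() if r == root})
        lead = min(members, key=lambda s: (fdr_of[s], bp_of[s], s))
        positions = [bp_of[c] for c in cands]
        z1 = float(z1_of.get(lead, np.nan)) if has_z else np.nan
        z2 = float(z2_of.get(lead, np.nan)) if has_z else np.nan
        loci.append(
            Locus(
                analysis=analysis,
                chrom=int(chrom_of[lead]),
                start=int(min(positions)),
                end=int(max(positions)),
                lead=lead,
                independent=sorted(members, key=lambda s: (fdr_of[s], bp_of[s], s)),
                candidates=cands,
                lead_z1=z1,
                lead_z2=z2,
                concordant=(np.sign(z1) * np.sign(z2) > 0) if has_z else None,
            )
        )
    loci.sort(key=lambda L: (L.chrom, L.start, L.lead))
    return loci


def directional_concordance(loci: list[Locus]) -> tuple[list[bool | None], int, int, float]:
    """Per-locus lead-SNP effect-direction flags plus the (k, n, percent) summary.

    A locus is concordant iff sign(z1) * sign(z2) > 0 at the lead SNP; leads
    with a zero z in either trait are excluded from n and flagged None.
    """
    flags: list[bool | None] = []
    k = n = 0
    for locus in loci:
        if locus.lead_z1 == 0 or locus.lead_z2 == 0 or np.isnan(locus.lead_z1) or np.isnan(locus.lead_z2):
            flags.append(None)
            locus.concordant = None
            continue
        conc = bool(np.sign(locus.lead_z1) * np.sign(locus.lead_z2) > 0)
        flags.append(conc)
        locus.concordant = conc
        n += 1
        k += conc
    pct = round(100.0 * k / n, 1) if n else float("nan")
    return flags, k, n, pct


def annotate_novelty(loci: list[Locus], known: dict[str, pd.DataFrame]) -> list[Locus]:
    """Flag loci novel per trait: no 1-based inclusive overlap with any known interval.

    ``known`` maps trait label -> DataFrame(CHR, START, END).
    """
    for locus in loci:
        for trait, intervals in known.items():
            hit = False
            for _, row in intervals.iterrows():
                if int(row["CHR"]) == locus.chrom and intervals_overlap(
                    locus.start, locus.end, int(row["START"]), int(row["END"])
                ):
                    hit = True
                    break
            locus.novel[trait] = not hit
    return loci


def merge_transdiagnostic(
    analyses: list[tuple[str, list[Locus], pd.DataFrame]],
    sig_threshold: float = CONJ_FDR_SIGNIFICANCE,
) -> list[TransdiagnosticLocus]:
    """Group loci across analyses into transdiagnostic loci.

    ``analyses`` holds (label, loci, pervariant-conjFDR table) triples sharing
    one variant universe.  Two loci from different analyses pair up when
    their intervals physically overlap (1-based inclusive) and at least one
    SNP that is a candidate in both has conjFDR <= ``sig_threshold`` in both
    analyses; groups are closed transitively.  The result is order-invariant
    in the analyses' input order.
    """
    if len(analyses) < 2:
        raise ValueError("need at least two analyses")
    analyses = sorted(analyses, key=lambda a: a[0])
    fdr_maps = {label: dict(zip(pv["SNP"], pv["conjFDR"])) for label, _, pv in analyses}
    bp_map: dict[str, int] = {}
    for _, _, pv in analyses:
        bp_map.update(zip(pv["SNP"], pv["BP"]))

    nodes: list[tuple[str, Locus]] = [
        (label, locus) for label, loci, _ in analyses for locus in loci
    ]
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(nodes)):
        li, ci = nodes[i]
        for j in range(i + 1, len(nodes)):
            lj, cj = nodes[j]
            if li == lj or ci.chrom != cj.chrom:
                continue
            if not intervals_overlap(ci.start, ci.end, cj.start, cj.end):
                continue
            shared = set(ci.candidates) & set(cj.candidates)
            ok = any(
                fdr_maps[li].get(s, 1.0) <= sig_threshold
                and fdr_maps[lj].get(s, 1.0) <= sig_threshold
                for s in shared
            )
            if ok:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        groups.setdefault(find(i), []).append(i)

    out: list[TransdiagnosticLocus] = []
    for members in groups.values():
        labels = sorted({nodes[i][0] for i in members})
        if len(labels) < 2:
            continue
        loci = [nodes[i][1] for i in members]
        # shared candidates: SNPs that are candidates of >= 2 member loci
        counts: dict[str, int] = {}
        for locus in loci:
            for c in set(locus.candidates):
                counts[c] = counts.get(c, 0) + 1
        shared = [c for c, n in counts.items() if n >= 2]
        if not shared:
            shared = sorted({c for locus in loci for c in locus.candidates})

        def max_fdr(snp: str) -> float:
            return max(fdr_maps[lab].get(snp, 1.0) for lab in labels)

        lead = min(shared, key=lambda s: (max_fdr(s), bp_map.get(s, 0), s))
        conjfdr_by = {lab: float(fdr_maps[lab].get(lead, np.nan)) for lab in labels}
        conc_by: dict[str, bool] = {}
        for label, loci_l, pv in analyses:
            if label not in labels or "Z1" not in pv.columns:
                continue
            row = pv.loc[pv["SNP"] == lead]
            if len(row):
                z1 = float(row["Z1"].iloc[0])
                z2 = float(row["Z2"].iloc[0])
                conc_by[label] = bool(np.sign(z1) * np.sign(z2) > 0)
        out.append(
            TransdiagnosticLocus(
                analyses=labels,
                chrom=loci[0].chrom,
                start=min(l.start for l in loci),
                end=max(l.end for l in loci),
                lead=lead,
                conjfdr_by_analysis=conjfdr_by,
                concordant_by_analysis=conc_by,
                loci=sorted(loci, key=lambda L: (L.analysis, L.start)),
            )
        )
    out.sort(key=lambda T: (T.chrom, T.start, T.lead))
    return out


def loci_frame(loci: list[Locus]) -> pd.DataFrame:
    """One row per locus, ready for TSV export."""
    rows = []
    for L in loci:
        row = {
            "analysis": L.analysis,
            "CHR": L.chrom,
            "start": L.start,
            "end": L.end,
            "lead_snp": L.lead,
            "n_independent": len(L.independent),
            "n_candidates": len(L.candidates),
            "lead_z1": L.lead_z1,
            "lead_z2": L.lead_z2,
            "concordant": L.concordant,
        }
        for trait, flag in L.novel.items():
            row[f"novel_in_{trait}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
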