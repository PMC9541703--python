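"""Clumping, candidate selection, concordance, novelty and transdiagnostic merging.

The clumping and merging tests check the implementation against brute-force
oracles that evaluate the stated rules directly on tiny fixtures.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from crosstrait.locus_definition import (
    Locus,
    LocusConfig,
    annotate_novelty,
    define_loci,
    directional_concordance,
    find_candidate_snps,
    merge_transdiagnostic,
)
from crosstrait.sumstats_io import SparseLD


def table(rows):
    df = pd.DataFrame(rows)
    if "CHR" not in df.columns:
        df["CHR"] = 1
    if "Z1" not in df.columns:
        df["Z1"] = 1.0
    if "Z2" not in df.columns:
        df["Z2"] = 1.0
    return df


class TestCandidates:
    def fixture(self):
        rows = [
            {"SNP": "a", "BP": 1000, "conjFDR": 0.01},
            {"SNP": "b", "BP": 2000, "conjFDR": 0.08},
            {"SNP": "c", "BP": 3000, "conjFDR": 0.2},   # fails threshold
            {"SNP": "d", "BP": 4000, "conjFDR": 0.04},
            {"SNP": "e", "BP": 5000, "conjFDR": 0.09},
            {"SNP": "f", "BP": 6000, "conjFDR": 0.001},
        ]
        ld = SparseLD(
            [
                ("a", "b", 0.9),   # r2 0.81 >= 0.6
                ("a", "c", 0.95),  # high LD but conjFDR too large
                ("d", "e", 0.7),   # r2 0.49 < 0.6
                ("f", "e", 0.8),   # r2 0.64 >= 0.6
            ]
        )
        return table(rows), ld

    def test_candidates_match_exhaustive_rule(self):
        t, ld = self.fixture()
        independent = ["a", "d", "f"]
        got = find_candidate_snps(t, ld, independent)
        # oracle: every variant, every independent SNP, direct rule check
        fdr = dict(zip(t["SNP"], t["conjFDR"]))
        oracle = {}
        for ind in independent:
            cands = set()
            for v in t["SNP"]:
                r2 = ld.r(ind, v) ** 2
                if fdr[v] < 0.10 and r2 >= 0.6:
                    cands.add(v)
            oracle[ind] = sorted(cands)
        assert got == oracle
        assert "c" not in set(sum(got.values(), []))  # threshold rule
        assert "a" in got["a"]  # self-LD inclusion


class TestDefineLoci:
    def test_no_significant_variants_gives_empty_list(self):
        t = table([{"SNP": "a", "BP": 1000, "conjFDR": 0.5}])
        assert define_loci(t, SparseLD([])) == []

    def test_singleton_locus(self):
        t = table([{"SNP": "a", "BP": 1000, "conjFDR": 0.01}])
        loci = define_loci(t, SparseLD([]))
        assert len(loci) == 1
        locus = loci[0]
        assert locus.lead == "a"
        assert locus.independent == ["a"] and locus.candidates == ["a"]
        assert locus.start == locus.end == 1000

    def test_two_distant_uncorrelated_significants_make_two_loci(self):
        t = table(
            [
                {"SNP": "a", "BP": 1_000_000, "conjFDR": 0.01},
                {"SNP": "b", "BP": 2_000_000, "conjFDR": 0.02},
            ]
        )
        loci = define_loci(t, SparseLD([("a", "b", 0.22)]))  # r2 = 0.05
        assert len(loci) == 2

    def oracle_clump(self, t: pd.DataFrame, ld, config: LocusConfig):
        """Direct rule-by-rule evaluation of the clumping protocol."""
        fdr = dict(zip(t["SNP"], t["conjFDR"]))
        bp = dict(zip(t["SNP"], t["BP"]))
        order = sorted(t["SNP"], key=lambda s: (fdr[s], bp[s], s))
        sig = [s for s in order if fdr[s] < config.sig_threshold]
        independent = []
        for s in sig:
            if all(ld.r(s, u) ** 2 < config.r2_independent for u in independent):
                independent.append(s)
        leads = []
        for s in independent:
            if all(ld.r(s, u) ** 2 < config.r2_lead for u in leads):
                leads.append(s)
        cand = {
            i: sorted(
                v
                for v in t["SNP"]
                if fdr[v] < config.candidate_threshold and ld.r(i, v) ** 2 >= config.r2_independent
            )
            for i in independent
        }
        # group independents: transitive closure over the merge relation
        groups = [{i} for i in independent]
        merged = True
        while merged:
            merged = False
            for gi, gj in itertools.combinations(range(len(groups)), 2):
                if any(
                    abs(bp[a] - bp[b]) <= config.merge_kb * 1000
                    or ld.r(a, b) ** 2 >= config.r2_lead
                    for a in groups[gi]
                    for b in groups[gj]
                ):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    merged = True
                    break
        out = []
        for g in groups:
            members = sorted(g, key=lambda s: (fdr[s], bp[s], s))
            lead = members[0]
            cands = sorted(set().union(*(cand[i] for i in g)))
            out.append((lead, tuple(members), tuple(cands)))
        return sorted(out)

    def test_two_block_fixture_matches_oracle(self):
        # two LD blocks 100 kb apart; conjFDR values chosen so each block has
        # one independent significant SNP plus tagged candidates
        rows = [
            {"SNP": "a1", "BP": 500_000, "conjFDR": 0.001},
            {"SNP": "a2", "BP": 501_000, "conjFDR": 0.03},
            {"SNP": "a3", "BP": 502_000, "conjFDR": 0.09},
            {"SNP": "a4", "BP": 503_000, "conjFDR": 0.5},
            {"SNP": "b1", "BP": 600_000, "conjFDR": 0.002},
            {"SNP": "b2", "BP": 601_000, "conjFDR": 0.04},
            {"SNP": "b3", "BP": 602_000, "conjFDR": 0.07},
            {"SNP": "b4", "BP": 603_000, "conjFDR": 0.3},
        ]
        ld = SparseLD(
            [
                ("a1", "a2", 0.9),
                ("a1", "a3", 0.85),
                ("a2", "a3", 0.8),
                ("a1", "a4", 0.9),
                ("b1", "b2", 0.95),
                ("b1", "b3", 0.9),
                ("b2", "b3", 0.88),
                ("a1", "b1", 0.05),
            ]
        )
        t = table(rows)
        config = LocusConfig()
        loci = define_loci(t, ld, config)
        got = sorted(
            (L.lead, tuple(L.independent), tuple(L.candidates)) for L in loci
        )
        assert got == self.oracle_clump(t, ld, config)
        # 100 kb apart -> merged into one locus by the 250 kb rule
        assert len(loci) == 1

    def test_distant_blocks_stay_separate_and_match_oracle(self):
        rows = [
            {"SNP": "a1", "BP": 500_000, "conjFDR": 0.001},
            {"SNP": "a2", "BP": 501_000, "conjFDR": 0.03},
            {"SNP": "b1", "BP": 900_000, "conjFDR": 0.002},
            {"SNP": "b2", "BP": 901_000, "conjFDR": 0.06},
        ]
        ld = SparseLD([("a1", "a2", 0.9), ("b1", "b2", 0.9)])
        t = table(rows)
        config = LocusConfig()
        loci = define_loci(t, ld, config)
        got = sorted((L.lead, tuple(L.independent), tuple(L.candidates)) for L in loci)
        assert got == self.oracle_clump(t, ld, config)
        assert len(loci) == 2

    def test_every_significant_variant_in_exactly_one_locus(self, demo_sim):
        from crosstrait.cross_trait_fdr import FDRConfig, conjfdr_table

        t = conjfdr_table(demo_sim["pair"], demo_sim["ld"], FDRConfig(seed=4))
        loci = define_loci(t, demo_sim["ld"])
        sig = set(t.loc[t["conjFDR"] < 0.05, "SNP"])
        assigned = [s for L in loci for s in L.candidates if s in sig]
        assert len(assigned) == len(set(assigned))  # no double assignment
        assert set(assigned) == sig

    def test_leads_pairwise_unlinked(self, demo_sim):
        from crosstrait.cross_trait_fdr import FDRConfig, conjfdr_table

        t = conjfdr_table(demo_sim["pair"], demo_sim["ld"], FDRConfig(seed=4))
        loci = define_loci(t, demo_sim["ld"])
        ld = demo_sim["ld"]
        leads = [L.lead for L in loci]
        for a, b in itertools.combinations(leads, 2):
            assert ld.r(a, b) ** 2 < 0.1


class TestConcordance:
    def make_loci(self, signs):
        return [
            Locus(
                analysis="x", chrom=1, start=i, end=i, lead=f"l{i}",
                independent=[f"l{i}"], candidates=[f"l{i}"],
                lead_z1=1.0, lead_z2=s,
            )
            for i, s in enumerate(signs)
        ]

    def test_printed_percentages(self):
        # 157 of 163 concordant -> 96.3%; 39 of 60 -> 65.0%
        flags, k, n, pct = directional_concordance(
            self.make_loci([1.0] * 157 + [-1.0] * 6)
        )
        assert (k, n, pct) == (157, 163, 96.3)
        _, k, n, pct = directional_concordance(self.make_loci([1.0] * 39 + [-1.0] * 21))
        assert (k, n, pct) == (39, 60, 65.0)

    def test_zero_z_excluded(self):
        flags, k, n, _ = directional_concordance(self.make_loci([1.0, 0.0, -1.0]))
        assert flags[1] is None and n == 2 and k == 1


class TestNovelty:
    def locus(self, start, end):
        return Locus(
            analysis="x", chrom=1, start=start, end=end, lead="l",
            independent=["l"], candidates=["l"], lead_z1=1.0, lead_z2=1.0,
        )

    def test_empty_known_list_all_novel(self):
        loci = annotate_novelty([self.locus(100, 200)], {"t": pd.DataFrame(columns=["CHR", "START", "END"])})
        assert loci[0].novel["t"]

    def test_boundary_overlap_not_novel(self):
        known = {"t": pd.DataFrame({"CHR": [1], "START": [200], "END": [300]})}
        assert not annotate_novelty([self.locus(100, 200)], known)[0].novel["t"]

    def test_adjacent_interval_is_novel(self):
        known = {"t": pd.DataFrame({"CHR": [1], "START": [201], "END": [300]})}
        assert annotate_novelty([self.locus(100, 200)], known)[0].novel["t"]


class TestTransdiagnostic:
    def analysis(self, label, loci_spec, fdr_map):
        """loci_spec: list of (chrom, start, end, lead, candidates)."""
        loci = [
            Locus(
                analysis=label, chrom=c, start=s, end=e, lead=lead,
                independent=[lead], candidates=list(cands),
                lead_z1=1.0, lead_z2=1.0,
            )
            for c, s, e, lead, cands in loci_spec
        ]
        snps = sorted(fdr_map)
        pv = pd.DataFrame(
            {
                "SNP": snps,
                "CHR": [1] * len(snps),
                "BP": [1000 * (i + 1) for i in range(len(snps))],
                "conjFDR": [fdr_map[s] for s in snps],
                "Z1": 1.0,
                "Z2": 1.0,
            }
        )
        return (label, loci, pv)

    def test_different_chromosomes_never_merge(self):
        fdr = {"a": 0.01, "b": 0.01}
        a = self.analysis("A", [(1, 100, 200, "a", ["a"])], fdr)
        b = self.analysis("B", [(2, 100, 200, "b", ["b"])], fdr)
        assert merge_transdiagnostic([a, b]) == []

    def test_overlap_without_shared_significant_candidate_not_merged(self):
        fdr_a = {"x": 0.04, "y": 0.2}
        fdr_b = {"x": 0.2, "y": 0.04}  # x significant only in A, y only in B
        a = self.analysis("A", [(1, 100, 300, "x", ["x", "y"])], fdr_a)
        b = self.analysis("B", [(1, 200, 400, "y", ["x", "y"])], fdr_b)
        assert merge_transdiagnostic([a, b]) == []

    def three_analysis_fixture(self):
        fdr_a = {"s1": 0.01, "s2": 0.03, "s3": 0.5}
        fdr_b = {"s1": 0.02, "s2": 0.04, "s3": 0.03}
        fdr_c = {"s1": 0.5, "s2": 0.01, "s3": 0.02}
        a = self.analysis("A", [(1, 1000, 2500, "s1", ["s1", "s2"])], fdr_a)
        b = self.analysis("B", [(1, 2000, 3500, "s2", ["s1", "s2", "s3"])], fdr_b)
        c = self.analysis("C", [(1, 3000, 4000, "s3", ["s2", "s3"])], fdr_c)
        return a, b, c

    def oracle_merge(self, analyses, sig=0.05):
        """Brute force: all overlap pairs, transitive closure, exhaustive lead scan."""
        fdr = {lab: dict(zip(pv["SNP"], pv["conjFDR"])) for lab, _, pv in analyses}
        bp = {}
        for _, _, pv in analyses:
            bp.update(zip(pv["SNP"], pv["BP"]))
        nodes = [(lab, L) for lab, loci, _ in analyses for L in loci]
        adj = {i: {i} for i in range(len(nodes))}
        for i, j in itertools.combinations(range(len(nodes)), 2):
            (la, a), (lb, b) = nodes[i], nodes[j]
            if la == lb or a.chrom != b.chrom:
                continue
            if max(a.start, b.start) > min(a.end, b.end):
                continue
            if any(
                fdr[la].get(s, 1) <= sig and fdr[lb].get(s, 1) <= sig
                for s in set(a.candidates) & set(b.candidates)
            ):
                adj[i].add(j)
                adj[j].add(i)
        # transitive closure by repeated expansion
        changed = True
        while changed:
            changed = False
            for i in adj:
                new = set().union(*(adj[j] for j in adj[i]))
                if new != adj[i]:
                    adj[i] = new
                    changed = True
        seen, groups = set(), []
        for i in sorted(adj):
            if i in seen:
                continue
            seen |= adj[i]
            labels = sorted({nodes[j][0] for j in adj[i]})
            if len(labels) < 2:
                continue
            cands = [c for j in adj[i] for c in nodes[j][1].candidates]
            shared = sorted({c for c in cands if cands.count(c) >= 2})
            lead = min(
                shared,
                key=lambda s: (max(fdr[lab].get(s, 1) for lab in labels), bp.get(s, 0), s),
            )
            groups.append((tuple(labels), lead))
        return sorted(groups)

    def test_three_analysis_fixture_matches_oracle(self):
        analyses = list(self.three_analysis_fixture())
        got = merge_transdiagnostic(analyses)
        oracle = self.oracle_merge(analyses)
        assert sorted((tuple(T.analyses), T.lead) for T in got) == oracle
        # the chain A-B-C closes transitively into one 3-analysis group
        assert len(got) == 1 and got[0].analyses == ["A", "B", "C"]

    def test_order_invariant(self):
        analyses = list(self.three_analysis_fixture())
        base = merge_transdiagnostic(analyses)
        for perm in itertools.permutations(analyses):
            again = merge_transdiagnostic(list(perm))
            assert [(T.analyses, T.lead, T.start, T.end) for T in again] == [
                (T.analyses, T.lead, T.start, T.end) for T in base
            ]
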