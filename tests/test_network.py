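"""Haplotype collapsing, connection limit, and minimum-spanning-network build."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gametolog_div.network import (
    Carrier,
    Haplotype,
    build_network,
    collapse_haplotypes,
    connection_limit,
    export_network,
    parsimony_probability,
    read_edge_list,
)
from gametolog_div.recode import RecodedVector, recode

from .conftest import make_marker, rng_for


def hap(idx: str, snp: str, schema="s") -> Haplotype:
    return Haplotype(
        id=idx,
        vector=RecodedVector(snp, (), (), schema),
        multiplicity=1,
        carriers=(Carrier((1, "F", 1), "F", None, "a"),),
    )


class TestCollapse:
    def test_identical_alleles_collapse(self, regions):
        m = make_marker([(f"{i}_F_1_ab", "ACGT") for i in (1, 2)])
        haps = collapse_haplotypes(recode(m), regions)
        assert len(haps) == 1
        assert haps[0].multiplicity == 4  # two ab homozygotes = 4 copies

    def test_multiplicities_and_deterministic_ids(self, regions):
        m = make_marker(
            [("1_F_1_a", "ACGT"), ("1_F_1_b", "ACGT"), ("2_M_1_a", "ACGA"),
             ("2_M_1_b", "ACGT")]
        )
        haps = collapse_haplotypes(recode(m), regions)
        assert [h.multiplicity for h in haps] == [3, 1]
        assert [h.id for h in haps] == ["H_1", "H_2"]
        # carriers preserve sex/region metadata
        assert {c.sex for c in haps[0].carriers} == {"F", "M"}

    def test_copy_count_equals_twice_individuals(self, regions):
        m = make_marker(
            [("1_F_1_a", "ACGT"), ("1_F_1_b", "AAGT"), ("3_M_2_ab", "ACGT"),
             ("4_M_1_a", "TCGT"), ("4_M_1_b", "ACGT")]
        )
        haps = collapse_haplotypes(recode(m), regions)
        assert sum(h.multiplicity for h in haps) == 2 * len(m.individuals())


class TestConnectionLimit:
    def test_very_high_confidence_trusts_single_steps_only(self):
        assert connection_limit(411, confidence=1 - 1e-9) == 1

    def test_limit_nondecreasing_in_sequence_length(self):
        limits = [connection_limit(m) for m in (50, 100, 200, 400, 800, 1600)]
        assert limits == sorted(limits)

    def test_probability_decreases_in_steps(self):
        ps = [parsimony_probability(j, 411) for j in range(1, 20)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)

    def test_override(self):
        assert connection_limit(411, override=14) == 14

    def test_matches_monte_carlo_oracle(self):
        """Cross-check the integral against direct simulation of the model:
        t ~ Exp(1), per-site changes Poisson(theta*t), a site differs when its
        change count is odd; parsimony = every site carries at most one."""
        m, j = 40, 2
        q = j / m
        theta = q / (1 - 2 * q)
        rng = rng_for("tcs-mc-oracle")
        n_trials = 600_000
        t = rng.exponential(1.0, n_trials)
        counts = rng.poisson(theta * t[:, None], (n_trials, m))
        observed_j = (counts % 2 == 1).sum(axis=1) == j
        parsimonious = counts.max(axis=1) <= 1
        hits = observed_j & parsimonious
        n_cond = int(observed_j.sum())
        assert n_cond > 2_000
        p_mc = hits.sum() / n_cond
        se = np.sqrt(p_mc * (1 - p_mc) / n_cond)
        p_exact = parsimony_probability(j, m)
        assert abs(p_exact - p_mc) < 4 * se + 1e-3


def bruteforce_msn(haps, limit, dist):
    """Oracle: an edge (a,b) exists iff d(a,b) <= limit and no path joins a,b
    using only pairs at strictly smaller distances (path search by BFS over
    the full smaller-distance pair graph)."""
    d = {}
    for a, b in itertools.combinations(range(len(haps)), 2):
        d[(a, b)] = dist(haps[a].vector, haps[b].vector)
    edges = set()
    for (a, b), dab in d.items():
        if dab == 0 or dab > limit:
            continue
        smaller = {
            frozenset(p) for p, dp in d.items() if 0 < dp < dab and dp <= limit
        }
        # BFS from a to b through 'smaller' pairs
        seen = {a}
        frontier = [a]
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(len(haps)):
                    if v not in seen and frozenset((u, v)) in smaller:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        if b not in seen:
            edges.add((haps[a].id, haps[b].id, dab))
    return edges


class TestBuildNetwork:
    def test_single_edge(self):
        haps = [hap("H_1", "AAAA"), hap("H_2", "AAAT")]
        net = build_network(haps, limit=5)
        assert net.edges == (("H_1", "H_2", 1),)
        assert len(net.components) == 1

    def test_redundant_longer_connection_excluded(self):
        a, b, c = hap("A", "AAAA"), hap("B", "AAAT"), hap("C", "AATT")
        net = build_network([a, b, c], limit=5)
        got = {frozenset((x, y)) for x, y, _ in net.edges}
        assert got == {frozenset(("A", "B")), frozenset(("B", "C"))}

    def test_equally_parsimonious_ties_all_kept(self):
        # A-B at 1; C at distance 2 from both: both 2-step edges retained
        a, b, c = hap("A", "AAAA"), hap("B", "AAAT"), hap("C", "AAGC")
        net = build_network([a, b, c], limit=5)
        got = {frozenset((x, y)) for x, y, _ in net.edges}
        assert frozenset(("A", "C")) in got and frozenset(("B", "C")) in got

    def test_beyond_limit_disconnects(self):
        haps = [hap("H_1", "AAAA"), hap("H_2", "TTTA")]
        net = build_network(haps, limit=2)
        assert net.edges == ()
        assert len(net.components) == 2

    def test_matches_bruteforce_on_random_instances(self):
        from gametolog_div.recode import step_distance

        rng = rng_for("msn-suite")
        for trial in range(150):
            n = int(rng.integers(2, 7))
            snps = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(n)]
            # de-duplicate: distinct haplotypes differ by >= 1 step
            snps = list(dict.fromkeys(snps))
            haps = [hap(f"H_{i + 1}", s) for i, s in enumerate(snps)]
            limit = int(rng.integers(1, 6))
            net = build_network(haps, limit)
            want = bruteforce_msn(haps, limit, step_distance)
            got = {(a, b, s) for a, b, s in net.edges}
            norm = lambda E: {(min(a, b), max(a, b), s) for a, b, s in E}
            assert norm(got) == norm(want), f"trial {trial}"
            assert all(s <= limit for _, _, s in net.edges)

    def test_within_component_pairs_connected_under_limit(self):
        rng = rng_for("msn-components")
        snps = list(dict.fromkeys("".join(rng.choice(list("ACGT"), 6)) for _ in range(6)))
        haps = [hap(f"H_{i + 1}", s) for i, s in enumerate(snps)]
        net = build_network(haps, limit=3)
        g = net.graph()
        import networkx as nx

        for comp in net.components:
            for u, v in itertools.combinations(sorted(comp), 2):
                assert nx.has_path(g, u, v)


class TestExport:
    def test_tsv_roundtrip(self, tmp_path):
        haps = [hap("H_1", "AAAA"), hap("H_2", "AAAT"), hap("H_3", "GGGG")]
        net = build_network(haps, limit=2)
        out = tmp_path / "net.tsv"
        export_network(net, out, "tsv")
        assert read_edge_list(out) == {
            (min(a, b), max(a, b), s) for a, b, s in net.edges
        }

    def test_gml_has_node_attributes(self, tmp_path, regions):
        m = make_marker([("1_F_1_ab", "ACGT"), ("4_M_1_ab", "ACGA")])
        haps = collapse_haplotypes(recode(m), regions)
        net = build_network(haps, limit=3)
        out = tmp_path / "net.gml"
        export_network(net, out, "gml")
        import networkx as nx

        g = nx.read_gml(out)
        assert set(g.nodes) == {"H_1", "H_2"}
        regions_seen = {g.nodes[n]["region"] for n in g.nodes}
        assert regions_seen <= {"SE_refugia", "Pannonian", "NW_Europe"}

    def test_unknown_format_rejected(self, tmp_path):
        net = build_network([hap("H_1", "AAAA")], limit=1)
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", "dot")
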