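import numpy as np
import pandas as pd
import pytest

from lncfruit import network
from lncfruit.identify import reverse_complement
from lncfruit.model import TargetPair, Transcript
from lncfruit.network import (
    assemble_network,
    edges_to_frame,
    extract_subnetwork,
    filter_ppi,
    mirna_scan,
    site_penalty,
)


def brute_force_sites(mirna, transcript, cutoff=3.0):
    """Naive per-offset penalty recomputation."""
    length = len(mirna.sequence)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "T"), ("T", "G")}
    found = []
    for offset in range(len(transcript.sequence) - length + 1):
        site = transcript.sequence[offset : offset + length]
        total = 0.0
        for pos in range(1, length + 1):
            pair = (mirna.sequence[pos - 1], site[length - pos])
            penalty = 0.0 if pair in wc else (0.5 if pair in wobble else 1.0)
            if 2 <= pos <= 13:
                penalty *= 2.0
            total += penalty
        if total <= cutoff:
            found.append((offset, total))
    return found


class TestSitePenalty:
    def mirna(self, seq="ACGTACGTACGTACGTACGTA"):
        return Transcript("miR", seq)

    def test_perfect_complement_scores_zero(self):
        m = self.mirna()
        site = reverse_complement(m.sequence)
        total, marks = site_penalty(m.sequence, site)
        assert total == 0.0
        assert marks == "|" * 21

    def test_wobble_in_core_costs_one(self):
        m = self.mirna()
        site = list(reverse_complement(m.sequence))
        # position 5 of the miRNA pairs site index 21-5 = 16
        pos = 5
        m_base = m.sequence[pos - 1]
        site[21 - pos] = {"A": "G", "C": "T", "G": "T", "T": "G"}[m_base]
        wobble_site = "".join(site)
        pair = (m_base, wobble_site[21 - pos])
        if pair in network.WOBBLE_PAIRS:
            total, _ = site_penalty(m.sequence, wobble_site)
            assert total == pytest.approx(1.0)  # 0.5 doubled in core

    def test_wobble_gu_pairs_both_orientations(self):
        # miRNA G : target T and miRNA T : target G are wobbles
        total_g, _ = site_penalty(
            "G" + "A" * 17, "T" * 17 + "T"
        )
        total_t, _ = site_penalty(
            "T" + "A" * 17, "T" * 17 + "G"
        )
        assert total_g == total_t == pytest.approx(0.5)

    def test_mismatch_outside_core_costs_one(self):
        m = self.mirna()
        site = list(reverse_complement(m.sequence))
        pos = 20  # outside positions 2-13
        m_base = m.sequence[pos - 1]
        bad = {"A": "A", "C": "C", "G": "G", "T": "T"}[m_base]
        site[21 - pos] = bad
        total, marks = site_penalty(m.sequence, "".join(site))
        assert total == pytest.approx(1.0)
        assert marks.count("x") == 1

    def test_n_never_matches(self):
        total, _ = site_penalty("A" * 18, "N" + "T" * 17)
        assert total == pytest.approx(1.0)


class TestMirnaScan:
    def test_planted_site_found_at_position(self):
        rng = np.random.default_rng(0)
        mirna = Transcript("miR", "".join("ACGT"[i] for i in rng.integers(0, 4, 21)))
        backbone = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        site = reverse_complement(mirna.sequence)
        target = Transcript("t", backbone[:100] + site + backbone[100:])
        sites = [
            s for s in mirna_scan([mirna], [target]) if s.expectation == 0.0
        ]
        assert [s.target_start for s in sites] == [100]

    def test_mirna_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="length"):
            mirna_scan([Transcript("short", "ACGTACGTACGTACGTA")], [])
        with pytest.raises(ValueError, match="length"):
            mirna_scan([Transcript("long", "A" * 27)], [])

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        pairs = []
        for i in range(100):
            length = int(rng.integers(18, 27))
            mirna = Transcript(
                f"m{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, length))
            )
            t_len = int(rng.integers(30, 200))
            target = Transcript(
                f"t{i}", "".join("ACGTN"[b] for b in
                                 rng.choice(5, t_len, p=[0.24] * 4 + [0.04]))
            )
            pairs.append((mirna, target))
        # a permissive cutoff so brute force has something to compare
        cutoff = 16.0
        for mirna, target in pairs:
            got = [
                (s.target_start, s.expectation)
                for s in mirna_scan([mirna], [target], cutoff=cutoff)
            ]
            assert got == brute_force_sites(mirna, target, cutoff)

    def test_raising_cutoff_never_removes_sites(self):
        rng = np.random.default_rng(7)
        mirna = Transcript("m", "".join("ACGT"[b] for b in rng.integers(0, 4, 21)))
        target = Transcript("t", "".join("ACGT"[b] for b in rng.integers(0, 4, 500)))
        lo = {(s.target_start) for s in mirna_scan([mirna], [target], cutoff=14)}
        hi = {(s.target_start) for s in mirna_scan([mirna], [target], cutoff=18)}
        assert lo <= hi


class TestPpiFilter:
    def make(self, confidences):
        return pd.DataFrame(
            {
                "node_a": [f"a{i}" for i in range(len(confidences))],
                "node_b": [f"b{i}" for i in range(len(confidences))],
                "confidence": confidences,
            }
        )

    def test_cutoff_boundary(self):
        kept = filter_ppi(self.make([0.69, 0.70, 0.71]))
        assert kept["confidence"].tolist() == [0.70, 0.71]

    def test_empty_input(self):
        assert len(filter_ppi(self.make([]))) == 0

    def test_raising_cutoff_never_adds_edges(self):
        table = self.make(list(np.linspace(0, 1, 21)))
        low = set(filter_ppi(table, 0.5)["node_a"])
        high = set(filter_ppi(table, 0.8)["node_a"])
        assert high <= low

    def test_out_of_range_confidence_rejected(self):
        with pytest.raises(ValueError, match="confidences"):
            filter_ppi(self.make([1.2]))

    def test_string_scale(self):
        scaled = network.normalize_string_scores(
            self.make([700.0]).assign(confidence=[700.0])
        )
        assert scaled["confidence"].iloc[0] == pytest.approx(700 / 999)


def toy_network():
    ppi = pd.DataFrame(
        {"node_a": ["g1", "g2"], "node_b": ["g2", "g3"],
         "confidence": [0.9, 0.8]}
    )
    sites = [
        network.MirnaSite("miR1", "g1", 10, 1.0, "|" * 21),
        network.MirnaSite("miR1", "l1", 5, 0.0, "|" * 21),
    ]
    pairs = [TargetPair("l1", "g1", "trans", correlation=0.95)]
    node_types = {
        "g1": "mRNA", "g2": "mRNA", "g3": "mRNA",
        "l1": "lncRNA", "miR1": "miRNA",
    }
    return ppi, sites, pairs, node_types


class TestAssembly:
    def test_typed_node_and_edge_counts(self):
        ppi, sites, pairs, node_types = toy_network()
        graph = assemble_network(ppi, sites, pairs, node_types=node_types)
        counts = network.node_counts(graph).set_index("entity")["count"]
        assert counts["mRNA"] == 3
        assert counts["lncRNA"] == 1
        assert counts["miRNA"] == 1
        assert counts["edges_ppi"] == 2
        assert counts["edges_mirna_target"] == 2
        assert counts["edges_lnc_target"] == 1

    def test_same_pair_two_sources_keeps_both_types(self):
        ppi, sites, pairs, node_types = toy_network()
        extra = [TargetPair("l1", "g1", "cis", distance_bp=500)]
        graph = assemble_network(
            ppi, sites, pairs + extra, node_types=node_types
        )
        # cis and trans collapse into one lnc_target edge (max weight),
        # separate from the mirna_target edge on the same pair
        assert graph.number_of_edges("l1", "g1") == 1
        assert graph.number_of_edges("miR1", "g1") == 1

    def test_duplicate_same_type_keeps_max_weight(self):
        ppi = pd.DataFrame(
            {"node_a": ["g1", "g1"], "node_b": ["g2", "g2"],
             "confidence": [0.8, 0.95]}
        )
        graph = assemble_network(
            ppi, node_types={"g1": "mRNA", "g2": "mRNA"}
        )
        assert graph["g1"]["g2"]["ppi"]["weight"] == pytest.approx(0.95)

    def test_unknown_endpoint_rejected(self):
        ppi, sites, pairs, node_types = toy_network()
        node_types.pop("g3")
        with pytest.raises(ValueError, match="g3"):
            assemble_network(ppi, sites, pairs, node_types=node_types)

    def test_no_self_loops(self):
        ppi = pd.DataFrame(
            {"node_a": ["g1"], "node_b": ["g1"], "confidence": [0.9]}
        )
        graph = assemble_network(ppi, node_types={"g1": "mRNA"})
        assert graph.number_of_edges() == 0


class TestSubnetwork:
    def test_one_hop_neighborhood(self):
        ppi, sites, pairs, node_types = toy_network()
        graph = assemble_network(ppi, sites, pairs, node_types=node_types)
        sub = extract_subnetwork(graph, ["g1"], k_hops=1)
        assert set(sub.nodes) == {"g1", "g2", "miR1", "l1"}

    def test_zero_hops_induced_on_seeds(self):
        ppi, sites, pairs, node_types = toy_network()
        graph = assemble_network(ppi, sites, pairs, node_types=node_types)
        sub = extract_subnetwork(graph, ["g1", "g2"], k_hops=0)
        assert set(sub.nodes) == {"g1", "g2"}
        assert sub.number_of_edges() == 1  # the induced g1-g2 PPI edge

    def test_all_seeds_any_k_is_identity(self):
        ppi, sites, pairs, node_types = toy_network()
        graph = assemble_network(ppi, sites, pairs, node_types=node_types)
        for k in (0, 1, 3):
            sub = extract_subnetwork(graph, list(graph.nodes), k_hops=k)
            assert set(sub.nodes) == set(graph.nodes)
            assert sub.number_of_edges() == graph.number_of_edges()

    def test_missing_seed_rejected(self):
        ppi, sites, pairs, node_types = toy_network()
        graph = assemble_network(ppi, sites, pairs, node_types=node_types)
        with pytest.raises(ValueError, match="zzz"):
            extract_subnetwork(graph, ["zzz"])


class TestFixtureNetwork:
    def test_counts_match_independent_recount(self, fixture):
        sites = mirna_scan(fixture.mirnas, fixture.transcripts)
        kept_ppi = filter_ppi(fixture.ppi)
        node_types = {
            t: ("lncRNA" if b == "lncRNA" else "mRNA")
            for t, b in fixture.gt.biotype.items()
        }
        for s in sites:
            node_types[s.mirna_id] = "miRNA"
        graph = assemble_network(kept_ppi, sites, node_types=node_types)

        expected_nodes = set(kept_ppi["node_a"]) | set(kept_ppi["node_b"])
        expected_nodes |= {s.mirna_id for s in sites}
        expected_nodes |= {s.target_id for s in sites}
        assert set(graph.nodes) == expected_nodes

        expected_ppi = {
            frozenset((a, b))
            for a, b in zip(kept_ppi["node_a"], kept_ppi["node_b"])
        }
        got_ppi = {
            frozenset((a, b))
            for a, b, key in graph.edges(keys=True)
            if key == "ppi"
        }
        assert got_ppi == expected_ppi

    def test_seed_gene_neighborhood_matches_bfs_oracle(self, fixture):
        sites = mirna_scan(fixture.mirnas, fixture.transcripts)
        kept_ppi = filter_ppi(fixture.ppi)
        node_types = {
            t: ("lncRNA" if b == "lncRNA" else "mRNA")
            for t, b in fixture.gt.biotype.items()
        }
        for s in sites:
            node_types[s.mirna_id] = "miRNA"
        graph = assemble_network(kept_ppi, sites, node_types=node_types)
        seed = fixture.gt.seed_gene
        sub = extract_subnetwork(graph, [seed], k_hops=1)
        neighborhood = {seed} | {
            b if a == seed else a
            for a, b in graph.edges(seed)
        }
        assert set(sub.nodes) == neighborhood
        assert set(fixture.gt.seed_gene_partners) <= set(sub.nodes)

    def test_edge_frame_round_trips_counts(self, fixture):
        kept_ppi = filter_ppi(fixture.ppi)
        node_types = {
            t: "mRNA" for t in set(kept_ppi["node_a"]) | set(kept_ppi["node_b"])
        }
        graph = assemble_network(kept_ppi, node_types=node_types)
        frame = edges_to_frame(graph)
        assert len(frame) == graph.number_of_edges()
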