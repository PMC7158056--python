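"""SSN builder: pairwise records, node collapse, edges, cross-phylum flags."""

import itertools

import networkx as nx
import numpy as np
import pytest

from olesuite.simulate import make_family
from olesuite.ssn import (
    PairwiseRecord,
    all_vs_all,
    build_network,
    collapse_nodes,
    cross_taxon_edges,
)


def _pair(a, b, identity, evalue=1.0, score=0):
    return PairwiseRecord(a, b, score, identity, evalue)


class TestAllVsAll:
    def test_pair_count_and_order_invariance(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = {f"s{i}": "".join(aas[rng.integers(0, 20, size=50)]) for i in range(4)}
        recs = all_vs_all(seqs)
        assert len(recs) == 6
        shuffled = dict(reversed(list(seqs.items())))
        assert all_vs_all(shuffled) == recs

    def test_identical_pair_full_identity(self):
        seqs = {"a": "MKTAYIAKQRQISFVK", "b": "MKTAYIAKQRQISFVK"}
        (rec,) = all_vs_all(seqs)
        assert rec.percent_identity == 100.0

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            all_vs_all({"a": "MKT"})


class TestCollapse:
    def test_pairwise_threshold(self):
        pairs = [_pair("A", "B", 80.0), _pair("A", "C", 50.0), _pair("B", "C", 60.0)]
        cmap = collapse_nodes(pairs, 75)
        assert cmap["A"] == cmap["B"] != cmap["C"]
        assert len(set(cmap.values())) == 2

    def test_single_linkage_chains(self):
        pairs = [_pair("A", "B", 80.0), _pair("B", "C", 80.0), _pair("A", "C", 60.0)]
        cmap = collapse_nodes(pairs, 75)
        assert len(set(cmap.values())) == 1

    def test_threshold_is_strict(self):
        pairs = [_pair("A", "B", 75.0)]
        assert len(set(collapse_nodes(pairs, 75).values())) == 2
        assert len(set(collapse_nodes(pairs, 74.9).values())) == 1

    def test_representative_is_longest_then_lexicographic(self):
        pairs = [_pair("A", "B", 90.0), _pair("A", "C", 90.0), _pair("B", "C", 90.0)]
        cmap = collapse_nodes(pairs, 75, seq_lengths={"A": 10, "B": 30, "C": 30})
        assert set(cmap.values()) == {"B"}

    def test_matches_union_find_oracle(self, rng):
        """Random identity graphs: components equal a networkx recomputation,
        and node count is monotone non-increasing as the threshold drops."""
        ids = [f"s{i:02d}" for i in range(12)]
        for trial in range(10):
            pairs = [
                _pair(a, b, float(rng.uniform(40, 100)))
                for a, b in itertools.combinations(ids, 2)
            ]
            counts = []
            for thr in (90, 75, 60):
                cmap = collapse_nodes(pairs, thr)
                g = nx.Graph()
                g.add_nodes_from(ids)
                g.add_edges_from(
                    (p.id1, p.id2) for p in pairs if p.percent_identity > thr
                )
                expected = nx.number_connected_components(g)
                assert len(set(cmap.values())) == expected
                counts.append(expected)
            assert counts == sorted(counts, reverse=True)  # fewer nodes at looser thresholds


class TestNetwork:
    def test_no_edges_below_threshold(self):
        pairs = [_pair("A", "B", 10.0, evalue=1.0)]
        net = build_network(pairs, collapse_nodes(pairs, 75))
        assert len(net.nodes) == 2 and net.edges == []

    def test_two_planted_families_two_components(self):
        fam = make_family(3, block_sizes=(4, 4), within_identity=90, between_identity=0)
        pairs = all_vs_all(fam.seqs)
        cmap = collapse_nodes(pairs, 75)
        net = build_network(pairs, cmap, phyla=fam.phyla)
        assert len(net.nodes) == fam.truth["expected_node_count"] == 2
        g = nx.Graph()
        g.add_nodes_from(n.representative_id for n in net.nodes)
        g.add_edges_from((a, b) for a, b, _ in net.edges)
        assert nx.number_connected_components(g) == 2

    def test_collapse_is_a_partition(self):
        fam = make_family(4, block_sizes=(3, 3, 2), within_identity=92, between_identity=30)
        pairs = all_vs_all(fam.seqs)
        cmap = collapse_nodes(pairs, 75)
        net = build_network(pairs, cmap, phyla=fam.phyla)
        members = [m for n in net.nodes for m in n.member_ids]
        assert sorted(members) == sorted(fam.seqs)

    def test_edge_set_monotone_in_evalue(self):
        fam = make_family(5, block_sizes=(3, 3), within_identity=90, between_identity=40)
        pairs = all_vs_all(fam.seqs)
        cmap = collapse_nodes(pairs, 75)
        n_edges = [
            len(build_network(pairs, cmap, evalue_edge=e).edges)
            for e in (1e-2, 1e-5, 1e-30)
        ]
        assert n_edges == sorted(n_edges, reverse=True)


class TestCrossTaxon:
    def test_planted_transfer_is_flagged(self, rng):
        fam = make_family(6, block_sizes=(4,), within_identity=90, between_identity=0)
        seqs = dict(fam.seqs)
        phyla = dict(fam.phyla)  # block 0 is Proteobacteria
        # lateral-transfer mimic: half-diverged copy of a member, other phylum
        donor = seqs["fam0_m0"]
        chars = list(donor)
        for pos in rng.choice(len(chars), size=len(chars) // 2, replace=False):
            chars[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
        seqs["hgt"] = "".join(chars)
        phyla["hgt"] = "Actinobacteria"
        pairs = all_vs_all(seqs)
        net = build_network(pairs, collapse_nodes(pairs, 75), phyla=phyla)
        flagged = cross_taxon_edges(net)
        assert any("hgt" in (a, b) for a, b, _ in flagged)

    def test_unrelated_phyla_no_flags(self):
        fam = make_family(7, block_sizes=(4, 4), within_identity=90, between_identity=0)
        pairs = all_vs_all(fam.seqs)
        net = build_network(pairs, collapse_nodes(pairs, 75), phyla=fam.phyla)
        assert cross_taxon_edges(net) == []

    def test_flags_invariant_under_renaming(self):
        fam = make_family(8, block_sizes=(3, 3), within_identity=90, between_identity=40)
        pairs = all_vs_all(fam.seqs)
        net = build_network(pairs, collapse_nodes(pairs, 75), phyla=fam.phyla)
        renamed_seqs = {"z_" + k: v for k, v in fam.seqs.items()}
        renamed_phyla = {"z_" + k: v for k, v in fam.phyla.items()}
        pairs2 = all_vs_all(renamed_seqs)
        net2 = build_network(pairs2, collapse_nodes(pairs2, 75), phyla=renamed_phyla)
        strip = lambda edges: sorted(
            (min(a.removeprefix("z_"), b.removeprefix("z_")),
             max(a.removeprefix("z_"), b.removeprefix("z_"))) for a, b, _ in edges
        )
        assert strip(cross_taxon_edges(net2)) == strip(cross_taxon_edges(net))


class TestPrefilter:
    def test_prefilter_lossless_above_70_identity(self, rng):
        """The k-mer pre-filter must never skip a pair the full aligner
        would place at >= 70% identity."""
        from olesuite.ssn import _shared_kmer_fraction
        from olesuite.align import local_align

        fams = [
            make_family(100 + i, block_sizes=(4,), within_identity=w, between_identity=0)
            for i, w in enumerate((72, 80, 90, 98))
        ]
        seqs = {}
        for f in fams:
            seqs.update({f"{id(f)}_{k}": v for k, v in f.seqs.items()})
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for i in range(30):  # unrelated sequences too
            seqs[f"rnd{i}"] = "".join(aas[rng.integers(0, 20, size=150)])
        checked = 0
        for a, b in itertools.combinations(sorted(seqs), 2):
            hit = local_align(seqs[a], seqs[b])
            if hit.percent_identity >= 70 and hit.aligned_length >= 50:
                assert _shared_kmer_fraction(seqs[a], seqs[b]) >= 0.02
                checked += 1
        assert checked >= 24  # the within-family pairs

    def test_prefilter_preserves_collapse(self):
        fam = make_family(9, block_sizes=(4, 4), within_identity=88, between_identity=0)
        plain = all_vs_all(fam.seqs)
        fast = all_vs_all(fam.seqs, prefilter=True)
        assert collapse_nodes(plain, 75) == collapse_nodes(fast, 75)
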