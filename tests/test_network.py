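"""Median-joining networks: MSN oracle equivalence, medians, export."""

import itertools

import networkx as nx
import numpy as np
import pytest

from beehap.network import (
    align_sequences,
    build_mjn,
    export_network,
    hamming,
    minimum_spanning_network,
    quasi_medians,
)


def bruteforce_msn(seqs: dict[str, str], epsilon: int = 0) -> set:
    """Independent oracle: edge (u,v) belongs to the MSN iff u and v are not
    connected by any path using only strictly cheaper edges (minus epsilon)."""
    labels = sorted(seqs)
    edges = set()
    for u, v in itertools.combinations(labels, 2):
        d = hamming(seqs[u], seqs[v])
        g = nx.Graph()
        g.add_nodes_from(labels)
        for x, y in itertools.combinations(labels, 2):
            if hamming(seqs[x], seqs[y]) < d - epsilon:
                g.add_edge(x, y)
        if not nx.has_path(g, u, v):
            edges.add((u, v))
    return edges


def random_mutation_tree(rng, n_nodes=7, length=40):
    """Observed haplotypes forming a perfect mutation tree (every ancestor
    sampled, each child one private mutation from its parent)."""
    root = "".join(rng.choice(list("ACGT"), size=length))
    seqs = {"h0": root}
    free_positions = list(rng.permutation(length))
    parents = ["h0"]
    for i in range(1, n_nodes):
        parent = seqs[parents[int(rng.integers(0, len(parents)))]]
        pos = free_positions.pop()
        base = rng.choice([b for b in "ACGT" if b != parent[pos]])
        seqs[f"h{i}"] = parent[:pos] + str(base) + parent[pos + 1 :]
        parents.append(f"h{i}")
    return seqs


def test_single_haplotype_single_node():
    net = build_mjn({"h1": "ACGTACGT"})
    assert net.graph.number_of_nodes() == 1
    assert net.graph.number_of_edges() == 0


def test_two_haplotypes_one_edge():
    net = build_mjn({"h1": "ACGTACGT", "h2": "ACGTACGA"})
    assert sorted(net.graph.edges(data="weight")) == [("h1", "h2", 1)]


def test_star_with_sampled_center_adds_no_medians():
    center = "AAAAAAAAAA"
    seqs = {
        "anc": center,
        "h1": "CAAAAAAAAA",
        "h2": "ACAAAAAAAA",
        "h3": "AACAAAAAAA",
    }
    net = build_mjn(seqs)
    assert net.median_nodes == []
    assert sorted(net.graph.edges(data="weight")) == [
        ("anc", "h1", 1),
        ("anc", "h2", 1),
        ("anc", "h3", 1),
    ]


def test_absent_center_reconstructed_as_single_median():
    # three haplotypes mutually two steps apart around an unsampled ancestor
    seqs = {
        "h1": "CAAAAAAAAA",
        "h2": "ACAAAAAAAA",
        "h3": "AACAAAAAAA",
    }
    net = build_mjn(seqs)
    assert len(net.median_nodes) == 1
    med = net.median_nodes[0]
    assert net.graph.nodes[med]["seq"] == "AAAAAAAAAA"
    assert all(net.graph[med][h]["weight"] == 1 for h in seqs)


def test_quasi_medians_majority_and_branching():
    assert quasi_medians("AAA", "AAC", "ATA") == ["AAA"]
    meds = quasi_medians("AAA", "CCA", "GTA")
    # two fully polymorphic columns branch over 3x3 alternatives
    assert len(meds) == 9
    assert all(m[2] == "A" for m in meds)


def test_mjn_equals_msn_on_mutation_trees():
    rng = np.random.default_rng(13)
    for _ in range(10):
        seqs = random_mutation_tree(rng, n_nodes=int(rng.integers(3, 9)))
        net = build_mjn(seqs)
        assert net.median_nodes == []
        observed_edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert observed_edges == bruteforce_msn(seqs)


def test_msn_matches_bruteforce_oracle_random_sets():
    rng = np.random.default_rng(21)
    for _ in range(10):
        n = int(rng.integers(3, 8))
        seqs = {
            f"h{i}": "".join(rng.choice(list("ACG"), size=12)) for i in range(n)
        }
        if len(set(seqs.values())) != n:
            continue
        msn = minimum_spanning_network(seqs)
        assert {tuple(sorted(e)) for e in msn.edges} == bruteforce_msn(seqs)


def test_edge_weights_equal_hamming_with_gap_state():
    seqs = {"h1": "AC-TA", "h2": "ACGTA", "h3": "ACGTT"}
    net = build_mjn(seqs)
    for u, v, w in net.graph.edges(data="weight"):
        assert w == hamming(seqs[u], seqs[v])


def test_frequency_conservation():
    seqs = {"h1": "AAAA", "h2": "AAAT", "h3": "AATT"}
    freqs = {"h1": 200, "h2": 50, "h3": 19}
    net = build_mjn(seqs, freqs)
    assert net.n_samples == 269


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError, match="align"):
        build_mjn({"h1": "AAAA", "h2": "AAAAA"})


def test_align_sequences_passthrough_and_mafft():
    same = {"a": "ACGT", "b": "ACGA"}
    assert align_sequences(same) == same
    unequal = {"a": "ACGTACGTACGTACGTACGT", "b": "ACGTACGTCGTACGTACGT"}
    aligned = align_sequences(unequal)
    assert len(set(len(s) for s in aligned.values())) == 1
    assert aligned["a"].replace("-", "") == unequal["a"]


def test_export_gml_and_nexus(tmp_path):
    seqs = {"h1": "AAAA", "h2": "AAAT"}
    net = build_mjn(seqs, {"h1": 3, "h2": 1})
    gml = export_network(net, tmp_path / "net.gml")
    g = nx.read_gml(gml)
    assert set(g.nodes) == {"h1", "h2"}
    assert g.nodes["h1"]["freq"] == 3
    nex = export_network(net, tmp_path / "net.nex", fmt="nexus")
    text = nex.read_text()
    assert text.startswith("#NEXUS")
    assert "BEGIN NETWORK;" in text and "NVERTICES=2" in text


def test_export_unknown_format_lists_supported(tmp_path):
    net = build_mjn({"h1": "AAAA"})
    with pytest.raises(ValueError, match="gml, nexus"):
        export_network(net, tmp_path / "net.xyz", fmt="")
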