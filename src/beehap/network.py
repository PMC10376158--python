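"""Median-joining haplotype networks.

The network combines a minimum-spanning network (MSN: all edges tied at the
level where two components first connect, plus any within ``epsilon`` of it)
with inferred median vectors: for triples of linked nodes, quasi-medians
(column-wise consensus; columns where all three states differ branch over
the three alternatives) are added when they reduce the local Steiner cost,
and the construction is iterated to a fixpoint.  Median nodes that end up
with degree < 3 are pruned.  Gaps are coded as a fifth character state, so
haplotypes differing by a whole tandem-repeat copy belong in separate
networks — the pipeline builds one network per allele class (Q / PQQ /
PQQQ), mirroring how such surveys draw separate C- and M-lineage figures.

All tie-breaking is lexicographic by node label, making output
deterministic under a fixed input order.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

GAP = "-"
_MAX_BRANCH_COLUMNS = 4  # cap on 3-way-polymorphic columns per quasi-median
_MAX_ROUNDS = 50


def hamming(a: str, b: str) -> int:
    """Mutational steps between aligned sequences; gap is a fifth state."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    return sum(x != y for x, y in zip(a, b))


def quasi_medians(s1: str, s2: str, s3: str) -> list[str]:
    """Quasi-median vectors of three aligned sequences.

    Columns with a majority state take it; columns where all three states
    differ branch over the three alternatives (capped, first columns vary).
    """
    branch_cols = []
    consensus = []
    for i, (x, y, z) in enumerate(zip(s1, s2, s3)):
        if x == y or x == z:
            consensus.append(x)
        elif y == z:
            consensus.append(y)
        else:
            consensus.append(None)
            branch_cols.append(i)
    out = []
    active = branch_cols[:_MAX_BRANCH_COLUMNS]
    for combo in itertools.product(*[(s1[i], s2[i], s3[i]) for i in active]):
        med = list(consensus)
        for col, base in zip(active, combo):
            med[col] = base
        for col in branch_cols[_MAX_BRANCH_COLUMNS:]:
            med[col] = s1[col]
        out.append("".join(med))
    return sorted(set(out))


def minimum_spanning_network(
    seqs: dict[str, str], epsilon: int = 0
) -> nx.Graph:
    """MSN over aligned sequences: edge (u,v) is kept iff its distance is
    within ``epsilon`` of the minimax path distance between u and v."""
    labels = sorted(seqs)
    g = nx.Graph()
    g.add_nodes_from(labels)
    if len(labels) == 1:
        return g
    complete = nx.Graph()
    for u, v in itertools.combinations(labels, 2):
        complete.add_edge(u, v, weight=hamming(seqs[u], seqs[v]))
    mst = nx.minimum_spanning_tree(complete, weight="weight")
    # minimax (maximum-edge-on-path) distance through the MST is unique even
    # when the MST itself is not
    minimax: dict[tuple[str, str], int] = {}
    for u in labels:
        depth = {u: 0}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in mst.neighbors(x):
                if y not in depth:
                    depth[y] = max(depth[x], mst[x][y]["weight"])
                    stack.append(y)
        for v in labels:
            if v != u:
                minimax[(u, v)] = depth[v]
    for u, v in itertools.combinations(labels, 2):
        d = complete[u][v]["weight"]
        if d <= minimax[(u, v)] + epsilon:
            g.add_edge(u, v, weight=d)
    return g


@dataclass(frozen=True)
class HaplotypeNetwork:
    graph: nx.Graph  # node attrs: seq, freq, median; edge attr: weight
    epsilon: int

    @property
    def n_samples(self) -> int:
        return sum(d["freq"] for _, d in self.graph.nodes(data=True))

    @property
    def median_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["median"]
        )


def build_mjn(
    seqs: dict[str, str],
    freqs: dict[str, int] | None = None,
    epsilon: int = 0,
) -> HaplotypeNetwork:
    """Median-joining network over aligned haplotype sequences.

    ``seqs`` maps haplotype label to aligned sequence (equal lengths, gaps
    as ``-``); ``freqs`` maps label to observed count (default 1 each).
    """
    if not seqs:
        raise ValueError("need at least one haplotype")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(
            "sequences have unequal lengths; align them first (gaps coded "
            "as '-'), e.g. with align_sequences()"
        )
    if len(set(seqs.values())) != len(seqs):
        raise ValueError("haplotype sequences must be unique")
    freqs = dict(freqs or {label: 1 for label in seqs})

    working = dict(seqs)
    seq_to_label = {s: l for l, s in working.items()}
    n_medians = 0
    for _ in range(_MAX_ROUNDS):
        net = minimum_spanning_network(working, epsilon=epsilon)
        candidates: list[tuple[int, str]] = []
        for u, v, w in sorted(itertools.combinations(sorted(working), 3)):
            linked = (
                net.has_edge(u, v) + net.has_edge(u, w) + net.has_edge(v, w)
            )
            if linked < 2:
                continue
            pairwise = sorted(
                (
                    hamming(working[u], working[v]),
                    hamming(working[u], working[w]),
                    hamming(working[v], working[w]),
                )
            )
            current_cost = pairwise[0] + pairwise[1]
            for med in quasi_medians(working[u], working[v], working[w]):
                if med in seq_to_label:
                    continue
                cost = (
                    hamming(med, working[u])
                    + hamming(med, working[v])
                    + hamming(med, working[w])
                )
                if cost < current_cost:
                    candidates.append((cost, med))
        if not candidates:
            break
        best_cost = min(c for c, _ in candidates)
        added = False
        for cost, med in sorted(candidates):
            if cost > best_cost or med in seq_to_label:
                continue
            n_medians += 1
            label = f"mv{n_medians}"
            working[label] = med
            seq_to_label[med] = label
            added = True
        if not added:  # pragma: no cover - defensive
            break

    # prune median vectors that never reach degree 3
    while True:
        net = minimum_spanning_network(working, epsilon=epsilon)
        obsolete = sorted(
            n
            for n in working
            if n not in seqs and net.degree(n) <= 2
        )
        if not obsolete:
            break
        for n in obsolete:
            seq_to_label.pop(working.pop(n))

    net = minimum_spanning_network(working, epsilon=epsilon)
    for n in net.nodes:
        net.nodes[n]["seq"] = working[n]
        net.nodes[n]["freq"] = int(freqs.get(n, 0)) if n in seqs else 0
        net.nodes[n]["median"] = n not in seqs
    return HaplotypeNetwork(graph=net, epsilon=epsilon)


def align_sequences(seqs: dict[str, str]) -> dict[str, str]:
    """Multiple-align haplotype sequences (mafft) for network construction.

    Returns the input unchanged when all sequences already share one length.
    """
    if len({len(s) for s in seqs.values()}) == 1:
        return dict(seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError(
            "sequences have unequal lengths and mafft is not on PATH; "
            "supply pre-aligned sequences"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        order = list(seqs)
        with open(fasta, "w") as fh:
            for i, label in enumerate(order):
                fh.write(f">s{i}\n{seqs[label]}\n")
        out = subprocess.run(
            ["mafft", "--retree", "2", "--quiet", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    aligned: dict[str, str] = {}
    current = None
    for line in out.splitlines():
        if line.startswith(">"):
            current = order[int(line[2:])]
            aligned[current] = ""
        elif current is not None:
            aligned[current] += line.strip().upper()
    return aligned


SUPPORTED_FORMATS = ("gml", "nexus")


def export_network(
    net: HaplotypeNetwork, path: str | Path, fmt: str | None = None
) -> Path:
    """Write a network as GML or a PopArt-style Nexus Network block."""
    path = Path(path)
    if fmt is None:
        fmt = {".gml": "gml", ".nex": "nexus", ".nexus": "nexus"}.get(
            path.suffix.lower(), ""
        )
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unknown format {fmt!r}; supported formats: "
            + ", ".join(SUPPORTED_FORMATS)
        )
    g = net.graph
    if fmt == "gml":
        out = nx.Graph()
        for n, d in sorted(g.nodes(data=True)):
            out.add_node(
                n, freq=int(d["freq"]), median=int(d["median"]), seq=d["seq"]
            )
        for u, v, d in sorted(g.edges(data=True)):
            out.add_edge(u, v, weight=int(d["weight"]))
        nx.write_gml(out, path)
        return path
    nodes = sorted(g.nodes)
    observed = [n for n in nodes if not g.nodes[n]["median"]]
    index = {n: i + 1 for i, n in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(observed)};\n  TAXLABELS\n")
        for n in observed:
            fh.write(f"    '{n}'\n")
        fh.write("  ;\nEND;\n\nBEGIN NETWORK;\n")
        fh.write(
            f"  DIMENSIONS NVERTICES={g.number_of_nodes()} "
            f"NEDGES={g.number_of_edges()};\n"
        )
        fh.write("  [node size proportional to observed frequency]\n")
        fh.write("  VERTICES\n")
        for n in nodes:
            d = g.nodes[n]
            kind = "median" if d["median"] else "observed"
            fh.write(f"    {index[n]} '{n}' {kind} freq={d['freq']}\n")
        fh.write("  ;\n  EDGES\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"    {index[u]} {index[v]} weight={int(d['weight'])}\n")
        fh.write("  ;\nEND;\n")
    return path
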