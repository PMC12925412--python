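"""mtCOI barcode analysis.

Covers the distance and network side of barcode work on a pre-aligned FASTA:
Kimura 2-parameter (K2P) pairwise distances with pairwise deletion of
ambiguous sites, between-group distance summaries, haplotype collapsing
after network-wide masking of gap/ambiguity columns, and a deterministic
median-joining network with graph statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "BarcodeAlignment",
    "Haplotype",
    "HaploNetwork",
    "read_alignment",
    "k2p_distance",
    "k2p_matrix",
    "group_distance_summary",
    "collapse_haplotypes",
    "median_joining",
    "network_stats",
    "write_nexus_network",
]

_UNAMBIGUOUS = frozenset("ACGT")
_ALLOWED = frozenset("ACGTURYSWKMBDHVN-?")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class BarcodeAlignment:
    """Validated aligned sequences with a group label per record."""

    records: dict[str, str]  # id -> aligned sequence (uppercase)
    groups: dict[str, str]  # id -> group label

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        missing = set(self.records) - set(self.groups)
        if missing:
            raise ValueError(f"records without group label: {sorted(missing)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values()))) if self.records else 0

    def ids(self) -> list[str]:
        return list(self.records)

    def ids_in_groups(self, groups: set[str]) -> list[str]:
        return [i for i, g in self.groups.items() if g in groups]

    def ids_not_in_groups(self, groups: set[str]) -> list[str]:
        return [i for i, g in self.groups.items() if g not in groups]


def read_alignment(path: str | Path, group_map: dict[str, str] | str | Path) -> BarcodeAlignment:
    """Read an aligned FASTA plus an id->group mapping (dict or 2-column CSV).

    Sequences are uppercased; ragged lengths, duplicate or unmapped ids and
    characters outside the IUPAC nucleotide alphabet are errors naming the
    offending record.
    """
    if not isinstance(group_map, dict):
        gm = pd.read_csv(group_map, comment="#")
        group_map = dict(zip(gm.iloc[:, 0].astype(str), gm.iloc[:, 1].astype(str)))
    records: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(f"record {rec.id!r} has illegal characters {sorted(bad)}")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"ragged alignment: record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    unknown = set(records) - set(group_map)
    if unknown:
        raise ValueError(f"ids missing from group map: {sorted(unknown)}")
    return BarcodeAlignment(records=records, groups={i: group_map[i] for i in records})


# ---------------------------------------------------------------------------
# K2P distances


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura 2-parameter distance (substitutions/site), pairwise deletion.

    Only sites where both sequences carry an unambiguous A/C/G/T are
    compared.  With transition proportion P and transversion proportion Q,

        K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

    Raises when no sites are comparable or the distance is undefined
    (saturated: 1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    n = ts = tv = 0
    for a, b in zip(seq1, seq2):
        if a in _UNAMBIGUOUS and b in _UNAMBIGUOUS:
            n += 1
            if a != b:
                if frozenset((a, b)) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        raise ValueError("no comparable sites (pairwise deletion removed everything)")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"K2P distance undefined (P={P:.4f}, Q={Q:.4f})")
    return -0.5 * np.log(w1 * np.sqrt(w2))


def k2p_matrix(aln: BarcodeAlignment) -> pd.DataFrame:
    """Symmetric pairwise K2P matrix over all records (zero diagonal)."""
    ids = aln.ids()
    m = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        d = k2p_distance(aln.records[a], aln.records[b])
        m.loc[a, b] = m.loc[b, a] = d
    return m


def group_distance_summary(
    aln: BarcodeAlignment, outgroup: str = "tellensis"
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Between-group mean K2P matrix plus ingroup/outgroup range summary.

    The matrix holds, for each ordered group pair, the mean of all
    cross-group pairwise distances (diagonal: mean within-group distance,
    0 for singleton groups).  The summary reports the min and max
    between-group mean among non-outgroup annotations, and the min and max
    group mean from any ingroup annotation to the outgroup.  All values are
    substitutions/site; multiply by 100 for percent display.
    """
    groups = sorted(set(aln.groups.values()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    members = {g: aln.ids_in_groups({g}) for g in groups}
    for g, mem in members.items():
        if not mem:
            raise ValueError(f"group {g!r} has no records")
    dm = k2p_matrix(aln)
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for g1, g2 in itertools.combinations_with_replacement(groups, 2):
        if g1 == g2:
            pairs = list(itertools.combinations(members[g1], 2))
        else:
            pairs = [(a, b) for a in members[g1] for b in members[g2]]
        val = float(np.mean([dm.loc[a, b] for a, b in pairs])) if pairs else 0.0
        out.loc[g1, g2] = out.loc[g2, g1] = val
    ingroups = [g for g in groups if g != outgroup]
    between = [out.loc[a, b] for a, b in itertools.combinations(ingroups, 2)]
    summary: dict[str, float] = {}
    if between:
        summary["ingroup_min"] = float(min(between))
        summary["ingroup_max"] = float(max(between))
    if outgroup in groups:
        vs_out = [out.loc[g, outgroup] for g in ingroups]
        summary["outgroup_min"] = float(min(vs_out))
        summary["outgroup_max"] = float(max(vs_out))
    return out, summary


# ---------------------------------------------------------------------------
# haplotypes


@dataclass(frozen=True)
class Haplotype:
    sequence: str  # over the retained (unmasked) columns
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def collapse_haplotypes(
    aln: BarcodeAlignment, ids: list[str] | None = None
) -> list[Haplotype]:
    """Collapse in-scope records into haplotypes.

    Columns containing a gap or ambiguity code in *any* in-scope record are
    masked network-wide; records identical over the remaining columns merge.
    The result is sorted by decreasing count, then sequence, so it is
    invariant to record order.
    """
    ids = list(aln.records) if ids is None else list(ids)
    if not ids:
        raise ValueError("no records in scope")
    seqs = [aln.records[i] for i in ids]
    keep = [
        c for c in range(len(seqs[0])) if all(s[c] in _UNAMBIGUOUS for s in seqs)
    ]
    if not keep:
        raise ValueError("all columns masked (every site ambiguous in some record)")
    buckets: dict[str, list[str]] = {}
    for i, s in zip(ids, seqs):
        key = "".join(s[c] for c in keep)
        buckets.setdefault(key, []).append(i)
    haps = [Haplotype(sequence=k, members=tuple(sorted(v))) for k, v in buckets.items()]
    haps.sort(key=lambda h: (-h.count, h.sequence))
    return haps


# ---------------------------------------------------------------------------
# median-joining network


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _msn_edges(seqs: list[str], epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network on Hamming
    distances.  An edge at distance d is kept when its endpoints are not
    connected by included edges of distance <= d - 1 - epsilon."""
    n = len(seqs)
    pairs = sorted(
        ((_hamming(seqs[i], seqs[j]), i, j) for i in range(n) for j in range(i + 1, n))
    )
    edges: list[tuple[int, int, int]] = []
    # component snapshots keyed by distance level, built incrementally
    snapshots: dict[int, list[int]] = {}
    dsu = _DSU(n)
    levels = sorted({d for d, _, _ in pairs})
    by_level: dict[int, list[tuple[int, int]]] = {}
    for d, i, j in pairs:
        by_level.setdefault(d, []).append((i, j))
    done_levels: list[int] = []
    for d in levels:
        cutoff = d - 1 - epsilon
        usable = [lv for lv in done_levels if lv <= cutoff]
        if usable:
            comp = snapshots[max(usable)]
        else:
            comp = list(range(n))
        for i, j in by_level[d]:
            if comp[i] != comp[j]:
                edges.append((i, j, d))
                dsu.union(i, j)
        done_levels.append(d)
        snapshots[d] = [dsu.find(k) for k in range(n)]
    return edges


def _mst_length(seqs: list[str]) -> int:
    """Total Hamming length of a minimum spanning tree over the sequences."""
    n = len(seqs)
    if n <= 1:
        return 0
    pairs = sorted(
        ((_hamming(seqs[i], seqs[j]), i, j) for i in range(n) for j in range(i + 1, n))
    )
    dsu = _DSU(n)
    total = used = 0
    for d, i, j in pairs:
        if dsu.find(i) != dsu.find(j):
            dsu.union(i, j)
            total += d
            used += 1
            if used == n - 1:
                break
    return total


def _median_seq(a: str, b: str, c: str) -> str:
    """Columnwise majority consensus; three-way ties resolve to the
    lexicographically smallest state (deterministic)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(min(x, y, z))
    return "".join(out)


@dataclass
class HaploNetwork:
    """Median-joining network: sampled haplotypes plus inferred medians."""

    graph: nx.Graph  # nodes: sequences; attrs count, members, is_median
    haplotypes: list[Haplotype] = field(default_factory=list)

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def total_length(self) -> int:
        """Minimum-spanning-tree length over all network nodes (the
        objective the median-joining search minimizes)."""
        return _mst_length(list(self.graph.nodes))


def median_joining(haps: list[Haplotype], epsilon: int = 0) -> HaploNetwork:
    """Median-joining network over collapsed haplotypes.

    Iteratively: build the epsilon-relaxed minimum spanning network; among
    triplets sharing a network neighbour, propose the columnwise median
    (quasi-median with deterministic tie-break) and add the candidate that
    most reduces the minimum-spanning-tree length of the node set; drop
    median vectors whose network degree falls below 3; repeat to fixpoint.
    Ties break lexicographically by sequence, so the result is independent
    of input order.
    """
    if not haps:
        raise ValueError("need at least one haplotype")
    sampled = sorted({h.sequence for h in haps})
    if len(sampled) != len(haps):
        raise ValueError("duplicate haplotype sequences")
    medians: set[str] = set()

    def node_list() -> list[str]:
        return sampled + sorted(medians - set(sampled))

    while True:
        nodes = node_list()
        edges = _msn_edges(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        base = _mst_length(nodes)
        best: tuple[int, str] | None = None
        seen: set[str] = set()
        for u in range(len(nodes)):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                m = _median_seq(nodes[u], nodes[v], nodes[w])
                if m in nodes or m in seen:
                    continue
                seen.add(m)
                score = _mst_length(nodes + [m])
                if score < base and (best is None or (score, m) < best):
                    best = (score, m)
        if best is None:
            break
        medians.add(best[1])
        # prune medians that are no longer junctions
        while True:
            nodes = node_list()
            edges = _msn_edges(nodes, epsilon)
            deg = {i: 0 for i in range(len(nodes))}
            for i, j, _ in edges:
                deg[i] += 1
                deg[j] += 1
            drop = {
                nodes[i]
                for i in range(len(nodes))
                if nodes[i] in medians and nodes[i] not in sampled and deg[i] < 3
            }
            if not drop:
                break
            medians -= drop

    nodes = node_list()
    edges = _msn_edges(nodes, epsilon)
    g = nx.Graph()
    by_seq = {h.sequence: h for h in haps}
    for s in nodes:
        h = by_seq.get(s)
        g.add_node(
            s,
            count=h.count if h else 0,
            members=list(h.members) if h else [],
            is_median=h is None,
        )
    for i, j, d in edges:
        g.add_edge(nodes[i], nodes[j], mutations=d)
    return HaploNetwork(graph=g, haplotypes=list(haps))


def network_stats(net: HaploNetwork) -> dict:
    """Counts, the modal haplotype and mutation distances from it.

    Disconnected networks are reported per connected component (a list of
    per-component stat dicts under ``"components"``).
    """
    g = net.graph

    def stats_for(nodes: set[str]) -> dict:
        sub = g.subgraph(nodes)
        sampled = [(d["count"], n) for n, d in sub.nodes(data=True) if not d["is_median"]]
        counts = [c for c, _ in sampled]
        modal = min((n for c, n in sampled if c == max(counts)))
        dist = nx.single_source_dijkstra_path_length(sub, modal, weight="mutations")
        return {
            "n_haplotypes": len(sampled),
            "n_singletons": sum(1 for c in counts if c == 1),
            "modal_haplotype": modal,
            "modal_count": max(counts),
            "distance_from_modal": {
                n: int(dist[n]) for n in sub.nodes if not sub.nodes[n]["is_median"]
            },
        }

    comps = list(nx.connected_components(g))
    if len(comps) == 1:
        return stats_for(comps[0])
    return {"components": [stats_for(c) for c in comps]}


def write_nexus_network(net: HaploNetwork, path: str | Path) -> None:
    """Write a minimal NEXUS file (taxa + haplotype data + network block)."""
    g = net.graph
    names = {}
    h = m = 0
    for n, d in g.nodes(data=True):
        if d["is_median"]:
            m += 1
            names[n] = f"median_{m}"
        else:
            h += 1
            names[n] = f"hap_{h}"
    lines = ["#NEXUS", "", "BEGIN TAXA;"]
    sampled = [n for n, d in g.nodes(data=True) if not d["is_median"]]
    lines.append(f"    DIMENSIONS NTAX={len(sampled)};")
    lines.append("    TAXLABELS " + " ".join(names[n] for n in sampled) + ";")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN CHARACTERS;")
    nchar = len(sampled[0]) if sampled else 0
    lines.append(f"    DIMENSIONS NCHAR={nchar};")
    lines.append("    FORMAT DATATYPE=DNA MISSING=? GAP=-;")
    lines.append("    MATRIX")
    for n in sampled:
        lines.append(f"        {names[n]} {n}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN NETWORK;")
    lines.append(f"    DIMENSIONS NVERTICES={g.number_of_nodes()} NEDGES={g.number_of_edges()};")
    lines.append("    VERTICES")
    for n in g.nodes:
        lines.append(f"        {names[n]} count={g.nodes[n]['count']}")
    lines.append("    ;")
    lines.append("    EDGES")
    for a, b, d in g.edges(data=True):
        lines.append(f"        {names[a]} {names[b]} mutations={d['mutations']}")
    lines.append("    ;")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")
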