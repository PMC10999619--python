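"""Weighted niche-overlap networks, modularity-based module detection,
and cross-stage stable module groups.

Nodes are plant species; an edge joins two species whose (symmetrized)
niche overlap exceeds a threshold, weighted by the overlap value.
Modules are found by maximizing weighted Newman-Girvan modularity

    Q = (1/2m) * sum_ik [A_ik - k_i k_k / 2m] * delta(c_i, c_k)

with a deterministic greedy agglomeration plus single-node refinement;
an exhaustive search over all set partitions serves as an exact oracle
on small graphs.  A stable group is a set of species assigned to the
same module in every degradation stage in which its members co-occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .niche_metrics import OverlapMatrix

SymMode = Literal["mean", "max", "min"]
ModuleMethod = Literal["greedy", "multilevel", "exhaustive"]

_EXHAUSTIVE_MAX_NODES = 12


def build_network(
    matrix: OverlapMatrix,
    threshold: float = 0.0,
    symmetrize: SymMode = "mean",
    species_numbers: Mapping[str, int] | None = None,
) -> nx.Graph:
    """Build the weighted overlap network of one stage.

    An edge (i, k) is present iff the symmetrized overlap exceeds
    ``threshold`` (strictly).  For the asymmetric Levins index the two
    directed values are combined by ``symmetrize``; Pianka values are
    symmetric already.  Species with no retained edge stay as isolated
    nodes.  Optional ``species_numbers`` are attached as a node
    attribute for cross-referencing published node labels.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    g = nx.Graph(stage=matrix.stage, method=matrix.method, threshold=float(threshold))
    for sp in matrix.species:
        attrs = {}
        if species_numbers and sp in species_numbers:
            attrs["species_no"] = int(species_numbers[sp])
        g.add_node(sp, **attrs)
    vals = matrix.values
    for i, k in combinations(range(matrix.n), 2):
        if matrix.method == "pianka":
            w = vals[i, k]
        else:
            pair = (vals[i, k], vals[k, i])
            w = {"mean": np.mean, "max": np.max, "min": np.min}[symmetrize](pair)
        if w > threshold:
            g.add_edge(matrix.species[i], matrix.species[k], weight=float(w))
    return g


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------


def modularity(network: nx.Graph, partition: Mapping) -> float:
    """Weighted Newman-Girvan modularity of a node -> module mapping."""
    if network.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless network")
    missing = [n for n in network.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover node(s) {missing[:3]}")
    m = network.size(weight="weight")
    degree = dict(network.degree(weight="weight"))
    q = 0.0
    for u, v, w in network.edges(data="weight", default=1.0):
        if partition[u] == partition[v]:
            q += w / m  # covers both (u,v) and (v,u) in the double sum
    by_mod: dict = {}
    for node, mod in partition.items():
        if node in degree:
            by_mod[mod] = by_mod.get(mod, 0.0) + degree[node]
    q -= sum((s / (2.0 * m)) ** 2 for s in by_mod.values())
    return q


@dataclass
class ModulePartition:
    """A node -> module assignment with its modularity Q.

    ``n_modules`` counts modules containing at least one connected node;
    isolated nodes sit in singleton modules but are not counted, so the
    figure is comparable with published module counts that show isolated
    species outside any module.
    """

    membership: dict
    q: float
    n_modules: int
    method: str

    def modules(self) -> list[set]:
        out: dict = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, set()).add(node)
        return [out[k] for k in sorted(out, key=str)]


def _canonical_membership(groups: Iterable[frozenset]) -> dict:
    """Relabel modules 0..k-1 by their lexicographically smallest member."""
    ordered = sorted((sorted(map(str, g))[0], g) for g in groups)
    membership = {}
    for label, (_, grp) in enumerate(ordered):
        for node in grp:
            membership[node] = label
    return membership


def _greedy_partition(g: nx.Graph) -> list[frozenset]:
    """CNM-style greedy agglomeration with a node-move refinement pass.

    Merges the community pair with the largest positive modularity gain;
    ties break on the lexicographically smallest (community, community)
    node-pair, which makes the result deterministic.  Afterwards single
    nodes are moved between neighboring communities while Q improves.
    """
    m = g.size(weight="weight")
    degree = dict(g.degree(weight="weight"))
    # community id -> member set; keyed by smallest node for tie-breaking
    comms: dict = {n: {n} for n in g.nodes}
    strength = {n: degree[n] for n in g.nodes}  # sum of degrees per community
    between: dict = {}  # frozenset({a, b}) -> total weight between communities
    node_comm = {n: n for n in g.nodes}
    for u, v, w in g.edges(data="weight", default=1.0):
        between[frozenset((u, v))] = between.get(frozenset((u, v)), 0.0) + w

    def merge_gain(a, b) -> float:
        w_ab = between.get(frozenset((a, b)), 0.0)
        return w_ab / m - strength[a] * strength[b] / (2.0 * m * m)

    while len(comms) > 1:
        best = None
        best_gain = 0.0
        for key in between:
            a, b = sorted(key, key=str)
            gain = merge_gain(a, b)
            if gain > best_gain + 1e-12 or (
                best is not None and abs(gain - best_gain) <= 1e-12 and (str(a), str(b)) < best
            ):
                best, best_gain = (str(a), str(b)), gain
                best_pair = (a, b)
        if best is None:
            break
        a, b = best_pair  # absorb b into a
        comms[a] |= comms.pop(b)
        strength[a] += strength.pop(b)
        for node in comms[a]:
            node_comm[node] = a
        stale = [k for k in between if b in k]
        for k in stale:
            w = between.pop(k)
            other = next(iter(k - {b}), None)
            if other is None or other == a:
                continue
            nk = frozenset((a, other))
            between[nk] = between.get(nk, 0.0) + w

    # local refinement: move single nodes while Q improves
    membership = dict(node_comm)
    improved = True
    while improved:
        improved = False
        for node in sorted(g.nodes, key=str):
            here = membership[node]
            # weight from node to each neighboring community
            w_to: dict = {}
            for nbr, data in g[node].items():
                w_to[membership[nbr]] = w_to.get(membership[nbr], 0.0) + data.get("weight", 1.0)
            s_by: dict = {}
            for n2, c2 in membership.items():
                s_by[c2] = s_by.get(c2, 0.0) + degree[n2]
            base = w_to.get(here, 0.0) / m - degree[node] * (s_by[here] - degree[node]) / (
                2.0 * m * m
            )
            best_c, best_delta = here, 0.0
            for cand in sorted(w_to, key=str):
                if cand == here:
                    continue
                delta = (
                    w_to.get(cand, 0.0) / m
                    - degree[node] * s_by.get(cand, 0.0) / (2.0 * m * m)
                    - base
                )
                if delta > best_delta + 1e-12:
                    best_c, best_delta = cand, delta
            if best_c != here:
                membership[node] = best_c
                improved = True
    groups: dict = {}
    for node, c in membership.items():
        groups.setdefault(c, set()).add(node)
    return [frozenset(s) for s in groups.values()]


def _set_partitions(items: Sequence) -> Iterator[list[list]]:
    """All set partitions, in restricted-growth-string order."""
    n = len(items)
    a = [0] * n
    b = [0] * n  # b[i] = max label among a[:i+1]
    while True:
        groups: dict = {}
        for idx, lab in enumerate(a):
            groups.setdefault(lab, []).append(items[idx])
        yield [groups[k] for k in sorted(groups)]
        # next restricted growth string
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i]


def _exhaustive_partition(g: nx.Graph) -> list[frozenset]:
    """Exact maximum-modularity partition by enumerating set partitions.

    Feasible for small graphs only; the first maximizer in
    restricted-growth order wins ties, making the result deterministic.
    """
    nodes = sorted(g.nodes, key=str)
    if len(nodes) > _EXHAUSTIVE_MAX_NODES:
        raise ValueError(
            f"exhaustive search supports <= {_EXHAUSTIVE_MAX_NODES} connected nodes "
            f"(got {len(nodes)}); use method='greedy' or 'multilevel'"
        )
    idx = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for u, v, wt in g.edges(data="weight", default=1.0):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = wt
    k = w.sum(axis=1)
    m = w.sum() / 2.0
    best_q = -np.inf
    best: list[list] | None = None
    for part in _set_partitions(nodes):
        q = 0.0
        for grp in part:
            ii = [idx[n] for n in grp]
            q += w[np.ix_(ii, ii)].sum() / (2.0 * m) - (k[ii].sum() / (2.0 * m)) ** 2
        if q > best_q + 1e-12:
            best_q, best = q, part
    assert best is not None
    return [frozenset(grp) for grp in best]


def detect_modules(
    network: nx.Graph,
    method: ModuleMethod = "greedy",
    seed: int = 0,
) -> ModulePartition:
    """Find the modularity-maximizing partition of an overlap network.

    Isolated nodes are assigned singleton modules and excluded from
    ``n_modules``.  ``greedy`` (default) is the deterministic
    agglomerative heuristic with refinement; ``multilevel`` is Louvain
    (seeded); ``exhaustive`` enumerates all partitions of the connected
    nodes (<= 12) and is exact.
    """
    if network.number_of_nodes() < 2:
        raise ValueError("module detection needs at least 2 nodes")
    isolated = [n for n in network.nodes if network.degree(n) == 0]
    sub = network.subgraph([n for n in network.nodes if network.degree(n) > 0])

    if sub.number_of_nodes() == 0:
        membership = _canonical_membership([frozenset((n,)) for n in isolated])
        return ModulePartition(membership=membership, q=float("nan"), n_modules=0, method=method)

    if method == "greedy":
        groups = _greedy_partition(sub)
    elif method == "multilevel":
        comms = nx.community.louvain_communities(sub, weight="weight", seed=seed)
        groups = [frozenset(c) for c in comms]
    elif method == "exhaustive":
        groups = _exhaustive_partition(sub)
    else:
        raise ValueError(f"unknown method {method!r}")

    n_modules = len(groups)
    all_groups = list(groups) + [frozenset((n,)) for n in isolated]
    membership = _canonical_membership(all_groups)
    q = modularity(network, membership)
    return ModulePartition(membership=membership, q=q, n_modules=n_modules, method=method)


# ---------------------------------------------------------------------------
# Stable groups across stages
# ---------------------------------------------------------------------------


@dataclass
class StableGroupSet:
    """Disjoint species groups with stable module membership across
    stages, largest first."""

    groups: list[frozenset]
    min_shared_stages: int


def stable_groups(
    partitions: Mapping[str, Mapping[str, object]],
    presence: Mapping[str, set] | None = None,
    min_shared_stages: int = 2,
) -> StableGroupSet:
    """Species groups that stay co-moduled across degradation stages.

    Two species are stably co-moduled when they co-occur in at least
    ``min_shared_stages`` stages and share a module in *every* stage
    where both are present.  Groups are maximal cliques of that
    relation; overlapping cliques are resolved greedily largest-first
    (lexicographic tie-break) so the reported groups are disjoint.
    Singletons are not reported.
    """
    if len(partitions) < 2:
        raise ValueError("stable groups need partitions from at least 2 stages")
    if min_shared_stages < 2:
        raise ValueError("min_shared_stages must be >= 2")
    if presence is None:
        presence = {st: set(p) for st, p in partitions.items()}
    species = sorted(set().union(*presence.values()))
    rel = nx.Graph()
    rel.add_nodes_from(species)
    for a, b in combinations(species, 2):
        shared = [st for st in partitions if a in presence[st] and b in presence[st]]
        if len(shared) < min_shared_stages:
            continue
        if all(partitions[st].get(a) == partitions[st].get(b) for st in shared):
            rel.add_edge(a, b)
    cliques = [frozenset(c) for c in nx.find_cliques(rel) if len(c) >= 2]
    cliques.sort(key=lambda c: (-len(c), sorted(c)))
    used: set = set()
    groups: list[frozenset] = []
    for c in cliques:
        if c & used:
            continue
        groups.append(c)
        used |= c
    return StableGroupSet(groups=groups, min_shared_stages=min_shared_stages)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def export_network(
    network: nx.Graph,
    partition: ModulePartition | Mapping | None,
    path: str | Path,
    format: Literal["graphml", "tsv"] = "graphml",
) -> Path:
    """Write the network (with per-node module attribute) to disk.

    ``graphml`` round-trips through :func:`read_network` losslessly;
    ``tsv`` is a plain-text block format (node and edge lines) that
    round-trips as well.
    """
    path = Path(path)
    g = network.copy()
    membership = partition.membership if isinstance(partition, ModulePartition) else partition
    if membership is not None:
        missing = [n for n in g.nodes if n not in membership]
        if missing:
            raise ValueError(f"partition does not cover node(s) {missing[:3]}")
        nx.set_node_attributes(g, {n: str(membership[n]) for n in g.nodes}, "module")
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# nichecomm overlap network\n")
            fh.write("# node\tname\tmodule\tspecies_no\n")
            for n in sorted(g.nodes, key=str):
                mod = g.nodes[n].get("module", "")
                no = g.nodes[n].get("species_no", "")
                fh.write(f"node\t{n}\t{mod}\t{no}\n")
            fh.write("# edge\tsource\ttarget\tweight\n")
            for u, v, w in sorted(g.edges(data="weight", default=1.0), key=lambda e: (str(e[0]), str(e[1]))):
                fh.write(f"edge\t{u}\t{v}\t{w!r}\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_network(path: str | Path, format: Literal["graphml", "tsv"] = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "tsv":
        g = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "node":
                    _, name, mod, no = parts
                    attrs = {}
                    if mod:
                        attrs["module"] = mod
                    if no:
                        attrs["species_no"] = int(no)
                    g.add_node(name, **attrs)
                elif parts[0] == "edge":
                    _, u, v, w = parts
                    g.add_edge(u, v, weight=float(w))
        return g
    raise ValueError(f"unknown format {format!r}")
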