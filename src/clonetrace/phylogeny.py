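"""Pigeonhole-principle clone trees from cluster CCF vectors.

Clusters become nodes of a rooted tree subject to two constraints in
every sample: a child's CCF cannot exceed its parent's, and the summed
CCFs of siblings cannot exceed their parent's.  Crossing CCFs (each
cluster larger in a different sample) force clusters onto separate
branches.  ``build_tree`` enumerates all feasible parent assignments by
depth-first search and returns them ranked by slack, preferring
shallower, lexicographically earlier trees on ties.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .clonal_clustering import Cluster

A_CONTAINS_B = "a_contains_b"
B_CONTAINS_A = "b_contains_a"
DISJOINT = "disjoint"
INCOMPATIBLE = "incompatible"


class NoFeasibleTreeError(ValueError):
    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations or []


@dataclass
class CloneTree:
    """Rooted clone tree: clusters, parent map, branch mutation sets."""

    clusters: list[Cluster]
    parent: dict[int, int | None]  # cluster_id -> parent cluster_id
    sample_ids: list[str]
    branch_mutations: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [k for k, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        self.root = roots[0]

    def children(self, node: int) -> list[int]:
        return sorted(k for k, p in self.parent.items() if p == node)

    def ccf(self, node: int) -> np.ndarray:
        for c in self.clusters:
            if c.cluster_id == node:
                return np.asarray(c.ccf, dtype=float)
        raise KeyError(node)

    def nodes(self) -> list[int]:
        return sorted(self.parent)

    def depth(self, node: int) -> int:
        d = 0
        while self.parent[node] is not None:
            node = self.parent[node]
            d += 1
        return d

    def validate_pigeonhole(self, tol: float = 0.05) -> None:
        """Machine-check the pigeonhole constraint; raises on violation."""
        for node in self.nodes():
            ccf_n = self.ccf(node)
            kids = self.children(node)
            if not kids:
                continue
            total = np.sum([self.ccf(c) for c in kids], axis=0)
            for c in kids:
                if np.any(self.ccf(c) > ccf_n + tol):
                    raise ValueError(
                        f"child {c} CCF exceeds parent {node} beyond tol {tol}"
                    )
            if np.any(total > ccf_n + tol):
                raise ValueError(
                    f"children of {node} sum to {total} > parent CCF {ccf_n} "
                    f"+ tol {tol}"
                )

    def clone_sizes(self) -> dict[int, np.ndarray]:
        """Exclusive clone size per node and sample:
        max(0, CCF_node - sum of children CCFs)."""
        out = {}
        for node in self.nodes():
            kids = self.children(node)
            total = (
                np.sum([self.ccf(c) for c in kids], axis=0)
                if kids else np.zeros(len(self.sample_ids))
            )
            out[node] = np.maximum(0.0, self.ccf(node) - total)
        return out

    def to_newick(self, branch_lengths: dict[int, float] | None = None) -> str:
        """Newick string; branch lengths default to SNV counts per branch."""
        if branch_lengths is None:
            branch_lengths = {
                k: float(len(self.branch_mutations.get(k, [])))
                for k in self.nodes()
            }

        def render(node: int) -> str:
            kids = self.children(node)
            label = f"c{node}:{branch_lengths.get(node, 0)}"
            if not kids:
                return label
            return "(" + ",".join(render(c) for c in kids) + ")" + label

        return render(self.root) + ";"

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_ids": self.sample_ids,
                "root": self.root,
                "parent": {str(k): v for k, v in self.parent.items()},
                "ccf": {
                    str(c.cluster_id): list(map(float, c.ccf))
                    for c in self.clusters
                },
                "branch_mutations": {
                    str(k): v for k, v in self.branch_mutations.items()
                },
            },
            indent=2,
        )


def nesting_relation(a: Cluster, b: Cluster, tol: float = 0.05) -> str:
    """Pairwise pigeonhole relation between two clusters' CCF vectors."""
    pa = np.asarray(a.ccf, dtype=float)
    pb = np.asarray(b.ccf, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("clusters must share a sample set")
    a_geq = np.all(pa >= pb - tol)
    b_geq = np.all(pb >= pa - tol)
    a_excess = np.any(pa > pb + tol)
    b_excess = np.any(pb > pa + tol)
    if a_excess and b_excess:
        return INCOMPATIBLE
    if a_geq and a_excess:
        return A_CONTAINS_B
    if b_geq and b_excess:
        return B_CONTAINS_A
    return DISJOINT


def build_tree(
    clusters: list[Cluster],
    tol: float = 0.05,
    max_trees: int = 10000,
    prune_noise: bool = True,
    return_all: bool = False,
):
    """Search parent assignments consistent with the pigeonhole principle.

    Returns the top-ranked CloneTree (or the full ranked list when
    ``return_all``).  Ranking: least total negative slack, then shallower,
    then lexicographic parent vector.
    """
    clusters = sorted(clusters, key=lambda c: c.cluster_id)
    if prune_noise:
        kept, pruned = [], []
        for c in clusters:
            if np.max(np.asarray(c.ccf, dtype=float)) <= 2 * tol:
                pruned.append(c.cluster_id)
            else:
                kept.append(c)
        if pruned:
            import logging
            logging.getLogger(__name__).warning(
                "unplaceable noise clusters pruned before tree search: %s", pruned
            )
        clusters = kept
    if not clusters:
        raise NoFeasibleTreeError("no clusters to place")
    if len(clusters) == 1:
        tree = CloneTree(
            clusters=clusters, parent={clusters[0].cluster_id: None},
            sample_ids=[f"s{i}" for i in range(len(clusters[0].ccf))],
        )
        return [tree] if return_all else tree

    ids = [c.cluster_id for c in clusters]
    ccf = {c.cluster_id: np.asarray(c.ccf, dtype=float) for c in clusters}
    n_samples = len(next(iter(ccf.values())))

    # truncal cluster: maximal CCF in every sample (within tol)
    root_candidates = [
        i for i in ids
        if all(np.all(ccf[i] >= ccf[j] - tol) for j in ids if j != i)
    ]
    if not root_candidates:
        raise NoFeasibleTreeError(
            "no truncal cluster: no cluster has maximal CCF in all samples "
            f"(tol={tol}); consider raising tol",
            violations=["missing truncal cluster"],
        )
    root = min(root_candidates)

    # feasible parents per node from the pairwise relation
    order = sorted(
        (i for i in ids if i != root),
        key=lambda i: (-float(ccf[i].sum()), i),
    )
    allowed: dict[int, list[int]] = {}
    for i in order:
        opts = [
            j for j in ids
            if j != i and np.all(ccf[j] >= ccf[i] - tol)
        ]
        if not opts:
            raise NoFeasibleTreeError(
                f"cluster {i} has no feasible parent at tol={tol}",
                violations=[f"cluster {i}: no containing cluster"],
            )
        allowed[i] = sorted(opts)

    feasible: list[dict[int, int | None]] = []

    def violates(parent: dict[int, int | None]) -> bool:
        sums: dict[int, np.ndarray] = {}
        for i, p in parent.items():
            if p is not None:
                sums.setdefault(p, np.zeros(n_samples))
                sums[p] = sums[p] + ccf[i]
        return any(np.any(s > ccf[p] + tol) for p, s in sums.items())

    def dfs(k: int, parent: dict[int, int | None]) -> None:
        if len(feasible) >= max_trees:
            return
        if k == len(order):
            feasible.append(dict(parent))
            return
        node = order[k]
        for p in allowed[node]:
            # parents must already be placed (ancestors have >= CCF sum,
            # so appear earlier in `order`) or be the root
            if p != root and p not in parent:
                continue
            parent[node] = p
            if not violates(parent):
                dfs(k + 1, parent)
            del parent[node]

    dfs(0, {root: None})
    if not feasible:
        raise NoFeasibleTreeError(
            f"no feasible tree at tol={tol}; consider raising tol",
            violations=["sibling CCF sums exceed every candidate parent"],
        )

    def score(parent: dict[int, int | None]):
        slack_pen = 0.0
        sums: dict[int, np.ndarray] = {}
        for i, p in parent.items():
            if p is not None:
                sums.setdefault(p, np.zeros(n_samples))
                sums[p] = sums[p] + ccf[i]
        for p, s in sums.items():
            slack_pen += float(np.sum(np.maximum(0.0, s - ccf[p])))
        depth = {root: 0}
        maxd = 0
        for i in order:
            depth[i] = depth[parent[i]] + 1
            maxd = max(maxd, depth[i])
        lex = tuple(parent[i] for i in sorted(parent) if parent[i] is not None)
        return (slack_pen, maxd, lex)

    feasible.sort(key=score)
    trees = [
        CloneTree(clusters=clusters, parent=p,
                  sample_ids=[f"s{i}" for i in range(n_samples)])
        for p in feasible
    ]
    return trees if return_all else trees[0]


def assign_branch_mutations(tree: CloneTree, assignments: np.ndarray,
                            cluster_ids: list[int] | None = None) -> None:
    """Attach mutation indices to branches from a cluster-assignment vector."""
    tree.branch_mutations = {k: [] for k in tree.nodes()}
    for mut_idx, k in enumerate(assignments):
        k = int(k)
        if k in tree.branch_mutations:
            tree.branch_mutations[k].append(mut_idx)


def branch_lengths(tree: CloneTree, var_classes: list[str] | None = None) -> dict:
    """SNV count per branch (indels, when identified, counted separately).

    Returns {cluster_id: {"snv": n, "indel": n}}.
    """
    out = {}
    for k in tree.nodes():
        muts = tree.branch_mutations.get(k, [])
        if var_classes is None:
            out[k] = {"snv": len(muts), "indel": 0}
        else:
            n_snv = sum(1 for m in muts if var_classes[m] == "SNV")
            out[k] = {"snv": n_snv, "indel": len(muts) - n_snv}
    return out


def clone_size_timecourse(tree: CloneTree) -> "pd.DataFrame":
    """Fishplot table: per-sample exclusive clone size of every node."""
    import pandas as pd

    sizes = tree.clone_sizes()
    rows = []
    for node in tree.nodes():
        for s, sid in enumerate(tree.sample_ids):
            rows.append(
                {"node": node, "sample": sid, "clone_size": float(sizes[node][s])}
            )
    return pd.DataFrame(rows)


def enumerate_all_trees(clusters: list[Cluster], tol: float = 0.0) -> list[dict]:
    """Exhaustive parent-assignment enumeration (oracle-grade, n <= ~8).

    Checks every rooted parent vector directly against the pigeonhole
    constraints, with no search-order pruning.  Returns parent maps.
    """
    ids = sorted(c.cluster_id for c in clusters)
    ccf = {c.cluster_id: np.asarray(c.ccf, dtype=float) for c in clusters}
    n_samples = len(next(iter(ccf.values())))
    out = []
    for root in ids:
        others = [i for i in ids if i != root]
        # necessary condition child <= parent prunes the product space;
        # every remaining combination is still checked in full below
        allowed = [
            [j for j in ids if j != i and np.all(ccf[i] <= ccf[j] + tol)]
            for i in others
        ]
        if any(not a for a in allowed):
            continue
        for combo in itertools.product(*allowed):
            parent = {root: None}
            parent.update(dict(zip(others, combo)))
            # acyclic rooted check
            ok = True
            for i in others:
                seen = {i}
                j = parent[i]
                while j is not None:
                    if j in seen:
                        ok = False
                        break
                    seen.add(j)
                    j = parent[j]
                if not ok:
                    break
            if not ok:
                continue
            # pigeonhole: child <= parent, sibling sums <= parent
            sums: dict[int, np.ndarray] = {}
            for i in others:
                p = parent[i]
                if np.any(ccf[i] > ccf[p] + tol):
                    ok = False
                    break
                sums.setdefault(p, np.zeros(n_samples))
                sums[p] = sums[p] + ccf[i]
            if not ok:
                continue
            if any(np.any(s > ccf[p] + tol) for p, s in sums.items()):
                continue
            out.append(parent)
    return out
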