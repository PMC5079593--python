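"""Nei DA genetic distances, UPGMA clustering with locus-bootstrap node
support, and Newick import/export.

The DA distance between frequency units x and y is

    DA = (1/r) * sum_j (1 - sum_i sqrt(x_ij * y_ij))

over the r loci defined in both units (missing loci are dropped pairwise).
Units may be groups (allele frequencies over members) or single individuals,
where a heterozygote contributes (0.5, 0.5) at that locus.  UPGMA is
classical average linkage with node height = half the merge distance and a
deterministic lexicographic tie-break; node support is the percentage of
locus-resampled replicate trees containing the same leaf cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, GroupAssignment


@dataclass
class TreeNode:
    """Node of a rooted ultrametric cluster tree."""

    height: float
    label: str | None = None  # leaf label
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None  # percent, internal nodes after bootstrap

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def clusters(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        out = []
        if not self.is_leaf:
            out.append(frozenset(self.leaves()))
            for c in self.children:
                out.extend(c.clusters())
        return out

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite distances")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# frequency units


def unit_frequencies(
    matrix: GenotypeMatrix,
    units: Literal["individuals", "groups"] = "individuals",
    groups: GroupAssignment | None = None,
) -> tuple[list[str], np.ndarray]:
    """allele_a frequency per unit per marker (NaN where the unit has no calls).

    Individuals are one-member frequency units: dosage d at a locus gives
    allele_a frequency 1 - d/2, so a heterozygote contributes 0.5.
    """
    if units == "individuals":
        calls = matrix.calls.astype(float)
        calls[calls < 0] = np.nan
        return list(matrix.individuals), 1.0 - calls / 2.0
    if units == "groups":
        if groups is None:
            raise ValueError("groups units require a GroupAssignment")
        groups.validate_against(matrix)
        labels = groups.groups()
        freqs = np.vstack(
            [
                matrix.subset(individuals=groups.members(g)).allele_a_freq()
                for g in labels
            ]
        )
        return labels, freqs
    raise ValueError(f"unknown unit kind {units!r}")


def nei_da(
    x: Sequence[float],
    y: Sequence[float],
    literal: bool = False,
) -> float:
    """Nei et al. (1983) DA distance between two biallelic frequency profiles.

    ``x``/``y`` hold the allele_a frequency per locus; NaN marks loci
    undefined in a unit, which are dropped pairwise.  ``literal=True``
    computes the non-square-root variant 1 - mean sum(x*y) for comparison
    (it does not satisfy d(x, x) = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise ValueError("no shared loci between units")
    xa, ya = x[ok], y[ok]
    if literal:
        sim = xa * ya + (1 - xa) * (1 - ya)
    else:
        sim = np.sqrt(xa * ya) + np.sqrt((1 - xa) * (1 - ya))
    return float(np.mean(1.0 - np.clip(sim, 0.0, None)))


def distance_matrix(
    matrix: GenotypeMatrix,
    units: Literal["individuals", "groups"] = "individuals",
    groups: GroupAssignment | None = None,
) -> DistanceMatrix:
    """Pairwise Nei DA over all units of the matrix."""
    labels, freqs = unit_frequencies(matrix, units, groups)
    all_missing = np.isnan(freqs).all(axis=1)
    if all_missing.any():
        bad = [labels[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"units with all-missing data: {bad}")
    d = _da_matrix(freqs)
    return DistanceMatrix(labels=labels, values=d)


def _da_matrix(freqs: np.ndarray, loci: np.ndarray | None = None) -> np.ndarray:
    """Vectorised pairwise DA over (possibly resampled) locus columns."""
    f = freqs[:, loci] if loci is not None else freqs
    valid = ~np.isnan(f)
    f0 = np.where(valid, f, 0.0)
    s1 = np.sqrt(f0)
    s0 = np.sqrt(np.where(valid, 1.0 - f0, 0.0))
    sim = s1 @ s1.T + s0 @ s0.T
    counts = valid.astype(float) @ valid.astype(float).T
    if (counts == 0).any():
        raise ValueError("unit pair with no shared loci")
    d = 1.0 - sim / counts
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(d: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration; node height = half the merge distance.

    Ties are broken on the lexicographically smallest (min label, max label)
    pair, where a cluster is named by its smallest leaf label.
    """
    if len(d.labels) < 2:
        raise ValueError("UPGMA needs at least two labels")
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances")
    # active clusters: key -> (node, size, smallest-leaf name)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(d.labels)
    }
    sizes = {i: 1 for i in nodes}
    names = {i: lab for i, lab in enumerate(d.labels)}
    dist: dict[tuple[int, int], float] = {}
    n = len(d.labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])
    next_id = n
    while len(nodes) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(names[kv[0][0]], names[kv[0][1]]),
                max(names[kv[0][0]], names[kv[0][1]]),
            ),
        )
        (i, j), dij = best
        new = TreeNode(height=dij / 2.0, children=[nodes[i], nodes[j]])
        nodes.pop(i), nodes.pop(j)
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), v in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = v
        for k in nodes:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            v = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            new_dist[(min(k, next_id), max(k, next_id))] = v
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        names[next_id] = min(names.pop(i), names.pop(j))
        nodes[next_id] = new
        dist = new_dist
        next_id += 1
    return next(iter(nodes.values()))


def cophenetic_matrix(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    """Pairwise cophenetic distances (2 x height of the lowest common node)."""
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def recurse(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]  # type: ignore[list-item]
        child_leaves = [recurse(c) for c in node.children]
        for a in range(len(child_leaves)):
            for b in range(a + 1, len(child_leaves)):
                for la in child_leaves[a]:
                    for lb in child_leaves[b]:
                        i, j = idx[la], idx[lb]
                        out[i, j] = out[j, i] = 2.0 * node.height
        return [x for sub in child_leaves for x in sub]

    recurse(tree)
    return out


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    matrix: GenotypeMatrix,
    units: Literal["individuals", "groups"] = "individuals",
    groups: GroupAssignment | None = None,
    n_reps: int = 2000,
    seed: int = 0,
    min_support: float = 50.0,
) -> TreeNode:
    """Full-data UPGMA tree annotated with locus-bootstrap node support.

    Loci are resampled with replacement ``n_reps`` times; each internal node
    of the full-data tree is labelled with the percentage of replicate trees
    containing the same leaf cluster.  Nodes below ``min_support`` percent
    are conventionally treated as unresolved by downstream grouping.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, freqs = unit_frequencies(matrix, units, groups)
    if len(labels) < 3:
        raise ValueError("bootstrap needs at least 3 units")
    if freqs.shape[1] < 2:
        raise ValueError("bootstrap needs at least 2 loci")
    full = upgma(DistanceMatrix(labels=labels, values=_da_matrix(freqs)))
    target = {cl: 0 for cl in full.clusters()}
    rng = np.random.default_rng(seed)
    n_loci = freqs.shape[1]
    for _ in range(n_reps):
        loci = rng.integers(0, n_loci, size=n_loci)
        rep = upgma(DistanceMatrix(labels=labels, values=_da_matrix(freqs, loci)))
        for cl in rep.clusters():
            if cl in target:
                target[cl] += 1
    for node in full.internal_nodes():
        node.support = 100.0 * target[frozenset(node.leaves())] / n_reps
    return full


# ---------------------------------------------------------------------------
# Newick I/O


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths from heights and support as
    internal-node labels."""

    def fmt(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            s = _quote(node.label or "")
        else:
            inner = ",".join(fmt(c, node.height) for c in node.children)
            s = f"({inner})"
            if node.support is not None:
                s += f"{node.support:g}"
        if parent_height is not None:
            s += f":{parent_height - node.height:.10g}"
        return s

    return fmt(tree, None) + ";"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def read_newick(path_or_string: str | Path) -> TreeNode:
    """Parse a Newick ultrametric tree back into a :class:`TreeNode`."""
    s = str(path_or_string)
    if not s.lstrip().startswith("(") and Path(s).exists():
        s = Path(s).read_text()
    dt = dendropy.Tree.get(data=s, schema="newick")

    def convert(nd: dendropy.Node) -> tuple[TreeNode, float]:
        if nd.is_leaf():
            return TreeNode(height=0.0, label=nd.taxon.label if nd.taxon else None), 0.0
        children = []
        height = 0.0
        for ch in nd.child_nodes():
            sub, h = convert(ch)
            bl = ch.edge.length or 0.0
            height = h + bl  # ultrametric: identical over children
            children.append(sub)
        support = float(nd.label) if nd.label not in (None, "") else None
        return TreeNode(height=height, children=children, support=support), height

    root, _ = convert(dt.seed_node)
    return root
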