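"""Contained (censored) coalescent simulation of organellar gene trees.

The species tree supplies, per branch, a duration in coalescent units (CU).
One gene lineage is sampled per species tip; lineages merge backward in
time. Within a species-tree branch of CU length ``L`` carrying ``k``
lineages, successive waiting times are drawn from Exponential with rate
``k(k-1)/2`` (in CU) and each event joins a uniformly chosen pair; events
that do not fit inside ``L`` are censored and the surviving lineages enter
the parent branch. The branch above the root is infinite, so every draw
ends in a single lineage and the resulting gene tree is binary over the
full tip set.

Rescaling all CU branch lengths by an inheritance scalar ``s`` is exactly
equivalent to multiplying the coalescence rate by ``s``; the simulator
therefore never converts to generations or effective population sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .treeio import Bipartition, InheritanceScalar

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "GeneTree",
    "simulate_contained_gene_tree",
    "simulate_gene_trees",
    "write_gene_trees",
]


class SimulationError(ValueError):
    """Raised when the species tree cannot be simulated under the chosen policy."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    ``missing_internal_length`` is either the string ``"error"`` (refuse to
    simulate when an internal branch has no CU length) or a substitute CU
    value; 0 is the conservative, ILS-maximising choice. Terminal branches
    default to 0 CU: with a single sampled lineage per species no
    coalescence can happen inside a terminal branch, so the value is
    immaterial for the gene-tree topology.
    """

    n_trees: int = 1000
    scalar: Union[InheritanceScalar, float] = 1.0
    seed: Optional[int] = None
    missing_internal_length: Union[str, float] = "error"
    terminal_length: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        factor = self.scalar.factor if isinstance(self.scalar, InheritanceScalar) else self.scalar
        if not factor > 0:
            raise ValueError("scalar must be positive")
        if isinstance(self.missing_internal_length, str):
            if self.missing_internal_length != "error":
                raise ValueError("missing_internal_length must be 'error' or a CU value")
        elif self.missing_internal_length < 0:
            raise ValueError("substitute CU value must be >= 0")
        if self.terminal_length < 0:
            raise ValueError("terminal_length must be >= 0")


class GeneTree:
    """A rooted, binary gene tree produced by the contained coalescent.

    Deliberately lightweight (index arrays, not node objects) because runs
    produce thousands of these: tips are nodes ``0..n-1`` in sorted label
    order, internal nodes follow in merge order, the root is last. Edge
    lengths are in rescaled CU and informational only — the topology is the
    contract. Use :meth:`to_dendropy` when a full tree object is needed.
    """

    __slots__ = ("labels", "children", "lengths")

    def __init__(
        self,
        labels: Sequence[str],
        children: Sequence[Tuple[int, int]],
        lengths: Sequence[float],
    ) -> None:
        self.labels = tuple(labels)
        self.children = tuple(children)
        self.lengths = tuple(lengths)
        if len(self.children) != len(self.labels) - 1:
            raise ValueError("a binary gene tree on n tips has n-1 internal nodes")

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def taxon_set(self) -> FrozenSet[str]:
        return frozenset(self.labels)

    def default_index(self) -> Dict[str, int]:
        return {lab: i for i, lab in enumerate(sorted(self.labels))}

    def clade_masks(self, index: Optional[Dict[str, int]] = None) -> List[int]:
        """Bitmask of tip memberships for every internal node (rooted clades)."""
        if index is None:
            index = self.default_index()
        n = self.n_tips
        masks = [0] * (2 * n - 1)
        for i, lab in enumerate(self.labels):
            masks[i] = 1 << index[lab]
        for j, (a, b) in enumerate(self.children):
            masks[n + j] = masks[a] | masks[b]
        return masks[n:]

    def split_masks(self, index: Optional[Dict[str, int]] = None) -> FrozenSet[int]:
        """Canonical nontrivial split bitmasks of the unrooted view.

        Each mask is flipped, if needed, so bit 0 (the reference taxon,
        lexicographically smallest label under the default index) is clear.
        """
        if index is None:
            index = self.default_index()
        n = self.n_tips
        full = (1 << n) - 1
        out = set()
        for mask in self.clade_masks(index):
            if mask & 1:
                mask ^= full
            size = mask.bit_count()
            if 2 <= size <= n - 2:
                out.add(mask)
        return frozenset(out)

    def bipartitions(self, include_trivial: bool = False):
        """Nontrivial splits as :class:`~cytodisc.treeio.Bipartition` values."""
        labels = sorted(self.labels)
        taxa = frozenset(labels)
        out = set()
        n = self.n_tips
        for mask in self.clade_masks():
            side = frozenset(labels[i] for i in range(n) if mask >> i & 1)
            if len(side) == n:
                continue
            bp = Bipartition(side, taxa)
            if bp.is_trivial and not include_trivial:
                continue
            out.add(bp)
        return out

    def has_clade(self, labels) -> bool:
        """True if ``labels`` form a rooted clade of this gene tree."""
        index = self.default_index()
        want = 0
        for lab in labels:
            want |= 1 << index[lab]
        return want in set(self.clade_masks(index)) or want.bit_count() == 1

    def as_newick(self, precision: int = 6) -> str:
        n = self.n_tips

        def fmt(i: int) -> str:
            sub = self.labels[i] if i < n else (
                "(" + fmt(self.children[i - n][0]) + "," + fmt(self.children[i - n][1]) + ")"
            )
            if i == 2 * n - 2:  # root: no parent edge
                return sub
            return f"{sub}:{self.lengths[i]:.{precision}g}"

        return fmt(2 * n - 2) + ";"

    def to_dendropy(self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.as_newick(),
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneTree(n_tips={self.n_tips})"


@dataclass
class _CompiledTree:
    """Species tree flattened to postorder arrays for the hot loop."""

    labels: Tuple[str, ...]                      # sorted tip labels
    order: List[Tuple[Tuple[int, ...], float, int]] = field(default_factory=list)
    # per postorder entry: (child entry ids, CU length of edge above, tip id or -1)


def _describe_node(node: dendropy.Node) -> str:
    tips = [leaf.taxon.label for leaf in node.leaf_iter()]
    tips.sort()
    shown = ",".join(tips[:4]) + (",..." if len(tips) > 4 else "")
    return f"edge above clade {{{shown}}}"


def compile_species_tree(
    species_tree: dendropy.Tree,
    scalar: Union[InheritanceScalar, float] = 1.0,
    missing_internal_length: Union[str, float] = "error",
    terminal_length: float = 0.0,
) -> _CompiledTree:
    """Resolve length policies, apply the scalar, and flatten to arrays.

    Polytomies are kept: all children of a multifurcation pass their
    surviving lineages jointly into the parent edge, the coalescent
    semantics of a hard, unresolved radiation.
    """
    factor = scalar.factor if isinstance(scalar, InheritanceScalar) else float(scalar)
    if not factor > 0:
        raise SimulationError(f"scalar must be positive, got {factor!r}")
    labels = sorted(leaf.taxon.label for leaf in species_tree.leaf_node_iter())
    if len(labels) < 2:
        raise SimulationError("species tree must have at least two tips")
    if len(set(labels)) != len(labels):
        raise SimulationError("species tree tip labels must be unique")
    tip_id = {lab: i for i, lab in enumerate(labels)}
    ct = _CompiledTree(labels=tuple(labels))
    entry_of: Dict[dendropy.Node, int] = {}
    for node in species_tree.postorder_node_iter():
        if node.parent_node is None:
            length = math.inf  # root edge: all survivors must coalesce
        else:
            raw = node.edge.length
            if node.is_leaf():
                length = terminal_length if raw is None else raw
            elif raw is None:
                if missing_internal_length == "error":
                    raise SimulationError(
                        f"missing CU length on internal {_describe_node(node)}; "
                        "set a substitute value to simulate anyway"
                    )
                length = float(missing_internal_length)
            else:
                length = raw
            if length < 0:
                raise SimulationError(f"negative CU length on {_describe_node(node)}")
            length *= factor
        if node.is_leaf():
            entry = (tuple(), length, tip_id[node.taxon.label])
        else:
            entry = (tuple(entry_of[c] for c in node.child_nodes()), length, -1)
        entry_of[node] = len(ct.order)
        ct.order.append(entry)
    return ct


def _simulate(ct: _CompiledTree, rng: np.random.Generator) -> GeneTree:
    n = len(ct.labels)
    children: List[Tuple[int, int]] = []
    lengths = [0.0] * (2 * n - 1)
    ages = [0.0] * (2 * n - 1)
    next_id = n
    pools: List[List[int]] = [[] for _ in ct.order]
    exponential = rng.exponential
    integers = rng.integers
    for eid, (kids, length, tip) in enumerate(ct.order):
        if tip >= 0:
            pool = [tip]
        else:
            pool = []
            for k in kids:
                pool.extend(pools[k])
                pools[k] = []
        k = len(pool)
        if k > 1:
            t = max(ages[g] for g in pool)
            remaining = length
            while k > 1:
                wait = exponential(2.0 / (k * (k - 1)))
                if wait > remaining:
                    break
                remaining -= wait
                t += wait
                i = int(integers(k))
                j = int(integers(k - 1))
                if j >= i:
                    j += 1
                if i < j:
                    i, j = j, i
                a = pool.pop(i)
                b = pool.pop(j)
                children.append((a, b))
                ages[next_id] = t
                lengths[a] = t - ages[a]
                lengths[b] = t - ages[b]
                pool.append(next_id)
                next_id += 1
                k -= 1
        pools[eid] = pool
    (root,) = pools[len(ct.order) - 1]
    assert root == 2 * n - 2
    return GeneTree(ct.labels, children, lengths)


def simulate_contained_gene_tree(
    species_tree: dendropy.Tree,
    rng: np.random.Generator,
    scalar: Union[InheritanceScalar, float] = 1.0,
    missing_internal_length: Union[str, float] = "error",
    terminal_length: float = 0.0,
) -> GeneTree:
    """Draw one gene tree contained in ``species_tree``.

    The species tree's CU lengths are rescaled by ``scalar`` first; length
    policies are as in :class:`SimulationConfig`.
    """
    ct = compile_species_tree(
        species_tree,
        scalar=scalar,
        missing_internal_length=missing_internal_length,
        terminal_length=terminal_length,
    )
    return _simulate(ct, rng)


def simulate_gene_trees(
    species_tree: dendropy.Tree, config: SimulationConfig
) -> List[GeneTree]:
    """Simulate ``config.n_trees`` contained gene trees.

    The run is bit-reproducible given (seed, species tree, config): the
    master seed spawns one independent counter-derived stream per tree, so
    tree ``i`` is the same regardless of execution order.
    """
    ct = compile_species_tree(
        species_tree,
        scalar=config.scalar,
        missing_internal_length=config.missing_internal_length,
        terminal_length=config.terminal_length,
    )
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_trees)
    return [_simulate(ct, np.random.Generator(np.random.PCG64(s))) for s in streams]


def write_gene_trees(trees: Sequence[GeneTree], path) -> None:
    """Write simulated trees as multi-tree Newick, one per line."""
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.as_newick() + "\n")
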