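"""Synthetic guide trees, observed organellar trees and toy alignments.

The real inputs of a cytonuclear-discordance analysis — a nuclear species
tree with coalescent-unit (CU) branch lengths and an observed organellar
tree over the same taxa — are study-specific. This module generates
stand-ins with known truth so every pipeline stage is testable end to end:

* random guide species trees at any tip count (terminal CU lengths absent,
  as in summary-coalescent species trees);
* observed trees under a pure-ILS scenario (one draw from the contained
  coalescent: any discordance is lineage sorting) or under an organellar
  capture scenario (a clade's plastome replaced by a donor's via a
  topological prune-and-regraft: the discordance is introgression);
* small alignments evolved under Jukes-Cantor with gap/N blocks injected
  at recorded coordinates, so masking expectations are exact.

Generated trees use tip labels "T0001", "T0002", ...
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .alnutils import Alignment
from .msc_sim import SimulationConfig, simulate_gene_trees
from .treeio import bipartitions

__all__ = [
    "ScenarioConfig",
    "generate_species_tree",
    "apply_chloroplast_capture",
    "select_capture_pair",
    "make_observed_tree",
    "GapBlock",
    "evolve_jc69_with_gaps",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """A stated synthetic world for one test scenario.

    ``internal_cu``/``internal_cu_dist`` control how much ILS the guide
    tree allows: internal CU lengths are drawn i.i.d. exponential with the
    given mean (default 1.0, a moderate-ILS regime) or fixed at the given
    value. ``observed_scalar`` is the inheritance scalar at which a
    pure-ILS observed tree is drawn (default 2: a plastome in
    hermaphroditic taxa).
    """

    n_tips: int
    seed: int = 0
    scenario: str = "pure_ils"  # or "capture"
    internal_cu: float = 1.0
    internal_cu_dist: str = "exponential"  # or "fixed"
    capture_donor: Optional[FrozenSet[str]] = None
    capture_recipient: Optional[FrozenSet[str]] = None
    observed_scalar: float = 2.0

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if self.scenario not in ("pure_ils", "capture"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.internal_cu_dist not in ("exponential", "fixed"):
            raise ValueError(f"unknown length distribution {self.internal_cu_dist!r}")
        if self.internal_cu < 0:
            raise ValueError("internal_cu must be >= 0")
        if self.scenario == "capture":
            if not self.capture_donor or not self.capture_recipient:
                raise ValueError("capture scenario needs capture_donor and capture_recipient")
            if frozenset(self.capture_donor) & frozenset(self.capture_recipient):
                raise ValueError("capture donor and recipient must be disjoint")


def _tip_labels(n: int) -> List[str]:
    return [f"T{i:04d}" for i in range(1, n + 1)]


def generate_species_tree(cfg: ScenarioConfig) -> dendropy.Tree:
    """A random rooted binary guide tree with CU lengths on internal edges.

    Topology comes from successive uniformly random pairwise joins (the
    labelled-topology distribution of a pure-birth process); internal edge
    lengths are i.i.d. from the configured distribution; terminal edges
    carry no length, as in summary-coalescent species trees. Reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _tip_labels(cfg.n_tips)
    tns = dendropy.TaxonNamespace(labels)
    nodes: List[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        for k in sorted((i, j), reverse=True):
            nodes.pop(k)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            node.edge.length = None
            continue
        if cfg.internal_cu_dist == "fixed":
            node.edge.length = cfg.internal_cu
        else:
            node.edge.length = float(rng.exponential(cfg.internal_cu))
    return tree


def _mrca(tree: dendropy.Tree, labels: FrozenSet[str]) -> dendropy.Node:
    # dendropy's Tree.mrca caches bipartition encodings that go stale after
    # tree surgery, so walk parent pointers directly
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = labels - leaves.keys()
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    want = iter(labels)
    node = leaves[next(want)]
    ancestors = []
    while node is not None:
        ancestors.append(node)
        node = node.parent_node
    ranks = {nd: i for i, nd in enumerate(ancestors)}
    best = 0
    for lab in want:
        node = leaves[lab]
        while node not in ranks:
            node = node.parent_node
        best = max(best, ranks[node])
    return ancestors[best]


def _exact_clade_mrca(tree: dendropy.Tree, labels: FrozenSet[str], what: str) -> dendropy.Node:
    try:
        mrca = _mrca(tree, labels)
    except ValueError as exc:
        raise ValueError(f"{what} {exc}") from exc
    clade = frozenset(leaf.taxon.label for leaf in mrca.leaf_iter())
    if clade != labels:
        raise ValueError(f"{what} {sorted(labels)} is not a clade (its MRCA spans {sorted(clade)})")
    return mrca


def _collapse_root_unifurcation(tree: dendropy.Tree) -> None:
    while len(tree.seed_node.child_nodes()) == 1:
        child = tree.seed_node.child_nodes()[0]
        tree.seed_node.remove_child(child)
        child.parent_node = None
        child.edge.length = None
        tree.seed_node = child


def apply_chloroplast_capture(
    tree: dendropy.Tree,
    donor: Iterable[str],
    recipient: Iterable[str],
) -> dendropy.Tree:
    """Regraft the recipient clade as sister to the donor clade.

    A topology-level subtree-prune-and-regraft that models organellar
    capture: after hybridisation and backcrossing the recipient lineage
    carries the donor lineage's plastome, so in the plastome tree the
    recipient appears next to the donor. All other relationships are
    unchanged. Donor and recipient must be existing, disjoint clades.
    """
    donor_set = frozenset(donor)
    recipient_set = frozenset(recipient)
    if not donor_set or not recipient_set:
        raise ValueError("donor and recipient must be non-empty")
    if donor_set == recipient_set:
        raise ValueError("donor and recipient clades are identical")
    if donor_set & recipient_set:
        raise ValueError(
            f"donor and recipient clades overlap: {sorted(donor_set & recipient_set)}"
        )
    out = tree.clone(depth=1)
    out.is_rooted = True  # a degree-2 root must survive suppress_unifurcations
    all_tips = frozenset(leaf.taxon.label for leaf in out.leaf_node_iter())
    if recipient_set | donor_set == all_tips:
        raise ValueError("donor plus recipient may not span the whole tree")
    r_node = _exact_clade_mrca(out, recipient_set, "recipient")
    d_node = _exact_clade_mrca(out, donor_set, "donor")
    # prune the recipient, collapsing the degree-two node left behind
    r_parent = r_node.parent_node
    if r_parent is None:
        raise ValueError("recipient clade may not be the whole tree")
    r_parent.remove_child(r_node)
    out.suppress_unifurcations()
    _collapse_root_unifurcation(out)
    # regraft as sister to the donor
    d_parent = d_node.parent_node
    joint = dendropy.Node()
    if d_parent is None:
        out.seed_node = joint
    else:
        d_parent.remove_child(d_node)
        d_parent.add_child(joint)
        joint.edge.length = d_node.edge.length
    joint.add_child(d_node)
    joint.add_child(r_node)
    d_node.edge.length = None
    r_node.edge.length = None
    return out


def select_capture_pair(
    tree: dendropy.Tree,
    rng: np.random.Generator,
    min_separation: int = 3,
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Pick (donor, recipient) tips whose capture moves the recipient far.

    Returns single-tip donor and recipient clades such that regrafting the
    recipient next to the donor moves it across at least ``min_separation``
    species-tree edges (the unrooted tip-to-tip path has at least
    ``min_separation + 2`` edges). Raises if the tree is too small to
    satisfy the separation.
    """
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    # hop counts on the unrooted tree; a root of degree 2 inflates paths
    # through it by one edge, correct for that
    degree2_root = len(tree.seed_node.child_nodes()) == 2
    chain = {}
    for leaf in leaves:
        node, anc = leaf, {}
        depth = 0
        while node is not None:
            anc[node] = depth
            node = node.parent_node
            depth += 1
        chain[leaf] = anc

    def hops(a, b):
        node = b
        while node not in chain[a]:
            node = node.parent_node
        h = chain[a][node] + chain[b][node]
        if degree2_root and node is tree.seed_node:
            h -= 1
        return h

    candidates = [
        (a, b)
        for i, a in enumerate(leaves)
        for b in leaves[i + 1 :]
        if hops(a, b) >= min_separation + 2
    ]
    if not candidates:
        raise ValueError(
            f"no tip pair is separated by >= {min_separation + 2} unrooted edges"
        )
    a, b = candidates[int(rng.integers(len(candidates)))]
    if rng.integers(2):
        a, b = b, a
    return frozenset((a.taxon.label,)), frozenset((b.taxon.label,))


def make_observed_tree(species_tree: dendropy.Tree, cfg: ScenarioConfig) -> dendropy.Tree:
    """An observed organellar tree whose truth is known.

    ``pure_ils``: one contained-coalescent draw at ``cfg.observed_scalar``
    (every discordant branch is lineage sorting). ``capture``: the species
    tree topology with the configured capture applied (the moved branch is
    introgression). Deterministic given ``cfg.seed``.
    """
    if cfg.scenario == "pure_ils":
        sim_cfg = SimulationConfig(n_trees=1, scalar=cfg.observed_scalar, seed=cfg.seed)
        gene = simulate_gene_trees(species_tree, sim_cfg)[0]
        return gene.to_dendropy()
    return apply_chloroplast_capture(species_tree, cfg.capture_donor, cfg.capture_recipient)


@dataclass(frozen=True)
class GapBlock:
    """A rectangular block of gap or missing characters to inject.

    ``taxa`` is a collection of row labels, or ``None`` for every row.
    """

    start: int
    length: int
    char: str = "-"
    taxa: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.length <= 0:
            raise ValueError("block start must be >= 0 and length > 0")
        if self.char not in ("-", "N"):
            raise ValueError("block character must be '-' or 'N'")


def evolve_jc69_with_gaps(
    tree: dendropy.Tree,
    n_sites: int,
    rate: float = 1.0,
    gap_blocks: Sequence[GapBlock] = (),
    seed: Optional[int] = None,
) -> Tuple[Alignment, Dict[str, object]]:
    """Evolve sequences along ``tree`` under Jukes-Cantor, then punch holes.

    ``tree`` must carry substitution-scale branch lengths (missing lengths
    are treated as zero); ``rate`` multiplies them. Along an edge of
    expected ``b`` substitutions per site each site changes with
    probability ``(3/4)(1 - exp(-4b/3))``, to a uniformly random different
    base. Gap/N blocks are applied afterwards at the stated coordinates;
    the returned manifest records them so tests can compute exact masking
    expectations.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    states: Dict[dendropy.Node, np.ndarray] = {}
    rows: Dict[str, np.ndarray] = {}
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = rng.integers(4, size=n_sites)
        else:
            b = (node.edge.length or 0.0) * rate
            p_change = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
            seq = states[node.parent_node].copy()
            hit = np.flatnonzero(rng.random(n_sites) < p_change)
            if hit.size:
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=hit.size)) % 4
        states[node] = seq
        if node.is_leaf():
            rows[node.taxon.label] = seq
    labels = sorted(rows)
    matrix = np.stack([bases[rows[lab]] for lab in labels])
    for blk in gap_blocks:
        if blk.start + blk.length > n_sites:
            raise ValueError(f"gap block {blk} exceeds alignment length {n_sites}")
        if blk.taxa is None:
            ridx = slice(None)
        else:
            missing = set(blk.taxa) - set(labels)
            if missing:
                raise ValueError(f"gap block names unknown taxa: {sorted(missing)}")
            ridx = [labels.index(t) for t in blk.taxa]
        matrix[ridx, blk.start : blk.start + blk.length] = blk.char
    aln = Alignment(labels, ["".join(row) for row in matrix])
    manifest: Dict[str, object] = {
        "seed": seed,
        "n_sites": n_sites,
        "rate": rate,
        "n_sequences": len(labels),
        "gap_blocks": [
            {
                "start": blk.start,
                "length": blk.length,
                "char": blk.char,
                "taxa": "all" if blk.taxa is None else ",".join(blk.taxa),
            }
            for blk in gap_blocks
        ],
    }
    return aln, manifest
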