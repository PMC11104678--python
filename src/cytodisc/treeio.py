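"""Phylogenetic tree I/O and split utilities.

Trees are :class:`dendropy.Tree` objects throughout the package; this
module owns the conventions the rest of the code relies on:

* internal-node labels in Newick input are support values or annotations,
  never taxon names;
* an absent branch length stays absent (``None``) — it is never silently
  coerced to zero, downstream code decides policy;
* splits are canonical :class:`Bipartition` values whose identity does not
  depend on rooting or input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set, Union

import dendropy

__all__ = [
    "NewickParseError",
    "InheritanceScalar",
    "HERMAPHRODITIC",
    "DIOECIOUS",
    "Bipartition",
    "parse_newick",
    "read_newick",
    "write_newick",
    "rescale_branch_lengths",
    "bipartitions",
]


class NewickParseError(ValueError):
    """Raised when Newick input is malformed or violates tree invariants."""


@dataclass(frozen=True)
class InheritanceScalar:
    """Multiplier on coalescent-unit branch lengths for organellar inheritance.

    A haploid, uniparentally inherited genome has a smaller effective
    population size than the diploid nuclear genome, so its lineages
    coalesce faster: two times faster in hermaphroditic taxa (``factor=2``)
    and four times faster in dioecious taxa (``factor=4``). Multiplying the
    coalescent-unit branch lengths of the nuclear guide tree by this factor
    is exactly equivalent to multiplying the coalescence rate.
    """

    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"inheritance scalar must be positive, got {self.factor!r}")


#: Plastome scalar for hermaphroditic taxa (Ne halved relative to nuclear).
HERMAPHRODITIC = InheritanceScalar(2.0)
#: Plastome scalar for dioecious taxa (Ne quartered relative to nuclear).
DIOECIOUS = InheritanceScalar(4.0)


@dataclass(frozen=True, init=False)
class Bipartition:
    """A taxon split induced by one internal edge of an unrooted tree.

    Stored canonically as the side *not* containing the lexicographically
    smallest taxon label, so equality and hashing depend only on the split
    itself, never on rooting or the order a tree was written in.
    """

    side: frozenset
    taxa: frozenset

    def __init__(self, side: Iterable[str], taxa: Iterable[str]) -> None:
        taxa_f = frozenset(taxa)
        side_f = frozenset(side)
        if not side_f <= taxa_f:
            raise ValueError(f"side contains labels outside the taxon set: {sorted(side_f - taxa_f)}")
        other = taxa_f - side_f
        if not side_f or not other:
            raise ValueError("neither side of a bipartition may be empty")
        if min(taxa_f) in side_f:
            side_f = other
        object.__setattr__(self, "side", side_f)
        object.__setattr__(self, "taxa", taxa_f)

    @property
    def is_trivial(self) -> bool:
        """True for a single-tip-versus-rest split."""
        return len(self.side) == 1 or len(self.side) == len(self.taxa) - 1

    @property
    def smaller_side(self) -> frozenset:
        other = self.taxa - self.side
        if len(other) < len(self.side):
            return other
        if len(self.side) < len(other):
            return self.side
        return min(self.side, other, key=lambda s: tuple(sorted(s)))

    def __str__(self) -> str:
        return ",".join(sorted(self.smaller_side))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Bipartition({sorted(self.smaller_side)} | n={len(self.taxa)})"


def _validate_tip_labels(tree: dendropy.Tree) -> None:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not (leaf.taxon.label or "").strip():
            raise NewickParseError("tree contains an empty tip label")
        labels.append(leaf.taxon.label)
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted tree from a Newick string.

    Internal node labels are kept as ``node.label`` (annotation, not taxa);
    missing branch lengths are ``None``. Raises :class:`NewickParseError`
    on malformed input, duplicate tip labels or empty tip labels.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except NewickParseError:
        raise
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    _validate_tip_labels(tree)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise NewickParseError(f"negative branch length {edge.length!r}")
    return tree


def read_newick(path) -> dendropy.Tree:
    """Read the first Newick tree from a file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, label_mode: str = "support", precision: int = 6) -> str:
    """Serialize a tree to a one-line Newick string.

    ``label_mode`` selects the source of internal-node labels: ``"support"``
    (the parsed/stored ``node.label``, the default), ``"name"`` (no internal
    labels at all), or ``"custom"`` (the ``annotation_label`` attribute set
    by callers such as :func:`cytodisc.concordance.annotate_observed_tree`).
    Branch lengths are written to ``precision`` significant digits.
    """
    if label_mode not in ("support", "name", "custom"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    work = tree
    if label_mode == "custom":
        work = tree.clone(depth=1)
        for node in work.preorder_node_iter():
            if not node.is_leaf():
                node.label = getattr(node, "annotation_label", None)
    text = work.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=(label_mode == "name"),
        real_value_format_specifier=f".{precision}g",
    )
    return text.strip()


def write_newick_file(tree: dendropy.Tree, path, label_mode: str = "support") -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree, label_mode=label_mode) + "\n")


def rescale_branch_lengths(
    tree: dendropy.Tree, scalar: Union[InheritanceScalar, float]
) -> dendropy.Tree:
    """Return a copy of ``tree`` with every present edge length multiplied.

    Missing lengths stay missing; topology and labels are untouched.
    """
    factor = scalar.factor if isinstance(scalar, InheritanceScalar) else float(scalar)
    if not factor > 0:
        raise ValueError(f"scaling factor must be positive, got {factor!r}")
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return out


def bipartitions(tree: dendropy.Tree, include_trivial: bool = False) -> Set[Bipartition]:
    """The set of splits induced by the edges of ``tree`` viewed unrooted.

    Trivial (single tip versus rest) splits are excluded unless
    ``include_trivial`` is set. Rerooting leaves the result unchanged.
    """
    taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n = len(taxa)
    clades: dict = {}
    out: Set[Bipartition] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clades[node] = frozenset((node.taxon.label,))
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = clades[node]
        if len(side) == 0 or len(side) == n:
            continue
        bp = Bipartition(side, taxa)
        if bp.is_trivial and not include_trivial:
            continue
        out.add(bp)
    return out
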