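"""Per-branch concordance of simulated gene trees with an observed tree.

For every nontrivial split of the observed organellar tree, the fraction
of simulated gene trees (drawn under each inheritance scalar) whose
unrooted split set contains it is tabulated. A branch whose observed
relationship is rare in the simulations cannot be explained by incomplete
lineage sorting alone and is flagged as an introgression candidate; the
decision rule is ``frequency <= threshold`` with a default threshold of 1%.
When several scalars are evaluated the combined verdict requires the
frequency to be at or below the threshold under every scalar, the
conservative convention; per-scalar verdicts are always derivable from the
reported frequencies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .msc_sim import GeneTree
from .treeio import Bipartition

__all__ = [
    "ILS_PLAUSIBLE",
    "INTROGRESSION_CANDIDATE",
    "DecisionThreshold",
    "BranchReport",
    "ConcordanceReport",
    "clade_frequencies",
    "classify_branch",
    "per_scalar_verdicts",
    "build_report",
    "annotate_observed_tree",
]

ILS_PLAUSIBLE = "ILS-plausible"
INTROGRESSION_CANDIDATE = "introgression-candidate"


@dataclass(frozen=True)
class DecisionThreshold:
    """Frequency at or below which ILS is considered an unlikely explanation."""

    threshold: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be strictly between 0 and 1")


def _tree_labels(tree) -> List[str]:
    if isinstance(tree, GeneTree):
        return sorted(tree.labels)
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _dendropy_split_masks(tree: dendropy.Tree, index: Dict[str, int]) -> frozenset:
    n = len(index)
    full = (1 << n) - 1
    masks: Dict[dendropy.Node, int] = {}
    out = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << index[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= masks[c]
            masks[node] = m
        if node.parent_node is None:
            continue
        m = masks[node]
        if m & 1:
            m ^= full
        if 2 <= m.bit_count() <= n - 2:
            out.add(m)
    return frozenset(out)


def _split_masks(tree, index: Dict[str, int]) -> frozenset:
    if isinstance(tree, GeneTree):
        return tree.split_masks(index)
    return _dendropy_split_masks(tree, index)


def _check_same_taxa(observed_labels: Sequence[str], other, what: str) -> None:
    obs = set(observed_labels)
    oth = set(_tree_labels(other))
    if obs != oth:
        missing = sorted(obs - oth)
        extra = sorted(oth - obs)
        raise ValueError(
            f"taxon sets differ between observed tree and {what}: "
            f"missing from {what}: {missing}; extra in {what}: {extra}"
        )


def _mask_to_bipartition(mask: int, labels: Sequence[str]) -> Bipartition:
    side = frozenset(labels[i] for i in range(len(labels)) if mask >> i & 1)
    return Bipartition(side, frozenset(labels))


def _bipartition_to_mask(bp: Bipartition, index: Dict[str, int]) -> int:
    mask = 0
    for lab in bp.side:
        mask |= 1 << index[lab]
    return mask


def clade_frequencies(observed, sims: Sequence) -> Dict[Bipartition, float]:
    """Fraction of ``sims`` containing each nontrivial split of ``observed``.

    Splits are compared on the unrooted view over the full shared taxon
    set; the rooting of either side is irrelevant. All trees must share the
    observed tree's tip set exactly.
    """
    if not sims:
        raise ValueError("no simulated trees supplied")
    labels = _tree_labels(observed)
    index = {lab: i for i, lab in enumerate(labels)}
    obs_masks = sorted(_split_masks(observed, index))
    counts = {m: 0 for m in obs_masks}
    for i, sim in enumerate(sims):
        if isinstance(sim, GeneTree):
            if frozenset(sim.labels) != frozenset(labels):
                _check_same_taxa(labels, sim, f"simulated tree {i}")
            sim_masks = sim.split_masks(index)
        else:
            _check_same_taxa(labels, sim, f"simulated tree {i}")
            sim_masks = _dendropy_split_masks(sim, index)
        for m in obs_masks:
            if m in sim_masks:
                counts[m] += 1
    n = len(sims)
    return {_mask_to_bipartition(m, labels): counts[m] / n for m in obs_masks}


def classify_branch(
    freq_by_scalar: Mapping[float, float],
    rule: DecisionThreshold = DecisionThreshold(),
) -> str:
    """Combined verdict over all evaluated scalars.

    ``introgression-candidate`` only when the simulated frequency of the
    observed relationship is at or below the threshold under *every*
    scalar (ties at the boundary are candidates: the rule is "less than or
    equal to").
    """
    if not freq_by_scalar:
        raise ValueError("at least one scalar frequency is required")
    if all(f <= rule.threshold for f in freq_by_scalar.values()):
        return INTROGRESSION_CANDIDATE
    return ILS_PLAUSIBLE


def per_scalar_verdicts(
    freq_by_scalar: Mapping[float, float],
    rule: DecisionThreshold = DecisionThreshold(),
) -> Dict[float, str]:
    """Verdict under each scalar separately."""
    if not freq_by_scalar:
        raise ValueError("at least one scalar frequency is required")
    return {
        s: (INTROGRESSION_CANDIDATE if f <= rule.threshold else ILS_PLAUSIBLE)
        for s, f in freq_by_scalar.items()
    }


@dataclass(frozen=True)
class BranchReport:
    """Concordance summary for one internal branch of the observed tree."""

    bipartition: Bipartition
    freq_by_scalar: Mapping[float, float]
    n_trees: int
    classification: str
    conflicts_nuclear: Optional[bool] = None


@dataclass
class ConcordanceReport:
    """One row per nontrivial split of the observed tree."""

    branches: List[BranchReport]
    n_trees: int
    threshold: DecisionThreshold = field(default_factory=DecisionThreshold)

    @property
    def scalars(self) -> List[float]:
        return sorted({s for b in self.branches for s in b.freq_by_scalar})

    def candidates(self) -> List[BranchReport]:
        return [b for b in self.branches if b.classification == INTROGRESSION_CANDIDATE]

    def row_for(self, bipartition: Bipartition) -> Optional[BranchReport]:
        for b in self.branches:
            if b.bipartition == bipartition:
                return b
        return None

    def to_frame(self) -> pd.DataFrame:
        scalars = self.scalars
        rows = []
        for b in sorted(
            self.branches,
            key=lambda b: (len(b.bipartition.smaller_side), str(b.bipartition)),
        ):
            row = {"bipartition": str(b.bipartition), "n_trees": b.n_trees}
            for s in scalars:
                row[f"freq_x{s:g}"] = b.freq_by_scalar.get(s)
            row["conflicts_nuclear"] = (
                "" if b.conflicts_nuclear is None else str(b.conflicts_nuclear).lower()
            )
            row["classification"] = b.classification
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        frame = self.to_frame()
        buf = io.StringIO()
        frame.to_csv(buf, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
        return buf.getvalue()

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())


def build_report(
    observed,
    sims_by_scalar: Mapping[float, Sequence],
    guide: Optional[dendropy.Tree] = None,
    rule: DecisionThreshold = DecisionThreshold(),
) -> ConcordanceReport:
    """Tabulate per-branch frequencies under each scalar and classify.

    ``guide`` (the nuclear species tree) is optional; when given, each row
    records whether the observed branch conflicts with it, which reproduces
    the red-branch flagging of cytonuclear-discordance figures mechanically.
    """
    if not sims_by_scalar:
        raise ValueError("at least one scalar's simulations are required")
    n_trees = {s: len(sims) for s, sims in sims_by_scalar.items()}
    if len(set(n_trees.values())) != 1:
        raise ValueError(f"unequal simulation counts across scalars: {n_trees}")
    freqs = {s: clade_frequencies(observed, sims) for s, sims in sims_by_scalar.items()}
    labels = _tree_labels(observed)
    index = {lab: i for i, lab in enumerate(labels)}
    guide_masks = None
    if guide is not None:
        _check_same_taxa(labels, guide, "guide tree")
        guide_masks = _dendropy_split_masks(guide, index)
    some_scalar = next(iter(freqs))
    branches = []
    for bp in freqs[some_scalar]:
        fb = {s: freqs[s][bp] for s in freqs}
        conflicts = None
        if guide_masks is not None:
            conflicts = _bipartition_to_mask(bp, index) not in guide_masks
        branches.append(
            BranchReport(
                bipartition=bp,
                freq_by_scalar=fb,
                n_trees=len(sims_by_scalar[some_scalar]),
                classification=classify_branch(fb, rule),
                conflicts_nuclear=conflicts,
            )
        )
    branches.sort(key=lambda b: (len(b.bipartition.smaller_side), str(b.bipartition)))
    return ConcordanceReport(branches=branches, n_trees=len(sims_by_scalar[some_scalar]), threshold=rule)


def annotate_observed_tree(observed: dendropy.Tree, report: ConcordanceReport) -> dendropy.Tree:
    """Label internal nodes of a copy of ``observed`` with "p2/p4"-style strings.

    Each internal node gets the simulated frequencies of its split, one per
    scalar in ascending order, as percentages with one decimal (e.g.
    ``"7.4/2.6"``), mirroring the annotation convention of published
    cytonuclear-discordance figures.
    """
    labels = _tree_labels(observed)
    index = {lab: i for i, lab in enumerate(labels)}
    scalars = report.scalars
    by_mask = {
        _bipartition_to_mask(b.bipartition, index): b for b in report.branches
    }
    out = observed.clone(depth=1)
    n = len(labels)
    full = (1 << n) - 1
    masks: Dict[dendropy.Node, int] = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << index[node.taxon.label]
            continue
        m = 0
        for c in node.child_nodes():
            m |= masks[c]
        masks[node] = m
        if node.parent_node is None:
            continue
        canon = m ^ full if m & 1 else m
        row = by_mask.get(canon)
        if row is None:
            continue
        label = "/".join(f"{100 * row.freq_by_scalar[s]:.1f}" for s in scalars)
        node.label = label
        node.annotation_label = label
    return out
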