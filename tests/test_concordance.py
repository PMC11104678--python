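"""Concordance frequencies, the 1% decision rule and tree annotation."""

import pytest

from cytodisc import (
    Bipartition,
    DecisionThreshold,
    ILS_PLAUSIBLE,
    INTROGRESSION_CANDIDATE,
    ScenarioConfig,
    SimulationConfig,
    annotate_observed_tree,
    bipartitions,
    build_report,
    clade_frequencies,
    classify_branch,
    generate_species_tree,
    parse_newick,
    per_scalar_verdicts,
    simulate_gene_trees,
    write_newick,
)
from cytodisc.concordance import BranchReport, ConcordanceReport

from conftest import make_quartet

TAXA4 = frozenset("ABCD")
AB = Bipartition({"A", "B"}, TAXA4)


def quartet(split):
    a, b = sorted(split)
    c, d = sorted(TAXA4 - split)
    return parse_newick(f"(({a},{b}),({c},{d}));")


class TestCladeFrequencies:
    def test_self_concordance(self):
        observed = parse_newick("((A,B),(C,D));")
        freqs = clade_frequencies(observed, [quartet({"A", "B"}) for _ in range(100)])
        assert freqs == {AB: 1.0}

    def test_absent_split_has_zero_frequency(self):
        observed = parse_newick("((A,B),(C,D));")
        freqs = clade_frequencies(observed, [quartet({"A", "C"}) for _ in range(10)])
        assert freqs == {AB: 0.0}

    def test_enumerated_mixture(self):
        # brute-force count over an enumerated list: 3 AB|CD, 5 AC|BD, 2 AD|BC
        sims = (
            [quartet({"A", "B"})] * 3 + [quartet({"A", "C"})] * 5 + [quartet({"A", "D"})] * 2
        )
        freqs = clade_frequencies(parse_newick("((A,B),(C,D));"), sims)
        assert freqs[AB] == pytest.approx(0.3)

    def test_taxon_mismatch_lists_symmetric_difference(self):
        observed = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError) as err:
            clade_frequencies(observed, [parse_newick("((A,B),(C,E));")])
        assert "D" in str(err.value) and "E" in str(err.value)

    def test_rerooting_either_side_leaves_frequencies_unchanged(self):
        guide = generate_species_tree(ScenarioConfig(n_tips=8, seed=6))
        sims = simulate_gene_trees(guide, SimulationConfig(n_trees=200, seed=6))
        observed = sims[0].to_dendropy()
        base = clade_frequencies(observed, sims)
        observed.reroot_at_node(
            [n for n in observed.preorder_node_iter() if not n.is_leaf()][2]
        )
        rerooted_sims = []
        for gt in sims:
            d = gt.to_dendropy()
            d.reroot_at_node([n for n in d.preorder_node_iter() if not n.is_leaf()][1])
            rerooted_sims.append(d)
        assert clade_frequencies(observed, rerooted_sims) == base

    def test_quartet_frequencies_sum_to_one(self):
        # every binary simulated tree resolves the quartet one of three ways
        sims = simulate_gene_trees(make_quartet(0.8), SimulationConfig(n_trees=500, seed=9))
        total = sum(
            clade_frequencies(quartet(s), sims)[Bipartition(s, TAXA4)]
            for s in ({"A", "B"}, {"A", "C"}, {"A", "D"})
        )
        assert total == pytest.approx(1.0)


class TestDecisionRule:
    def test_paper_style_frequencies(self):
        # ~29% under both scalars: comfortably ILS-plausible
        assert classify_branch({2.0: 0.29, 4.0: 0.29}) == ILS_PLAUSIBLE
        # 0.9% / 0.1%: introgression candidate under both scalars
        assert classify_branch({2.0: 0.009, 4.0: 0.001}) == INTROGRESSION_CANDIDATE

    def test_boundary_tie_is_candidate(self):
        # the rule is "less than or equal to 1%"
        assert classify_branch({2.0: 0.01}) == INTROGRESSION_CANDIDATE
        assert classify_branch({2.0: 0.0101}) == ILS_PLAUSIBLE

    def test_combined_verdict_requires_both_scalars(self):
        freqs = {2.0: 0.074, 4.0: 0.009}
        assert classify_branch(freqs) == ILS_PLAUSIBLE
        assert per_scalar_verdicts(freqs) == {
            2.0: ILS_PLAUSIBLE,
            4.0: INTROGRESSION_CANDIDATE,
        }

    def test_empty_frequency_map_rejected(self):
        with pytest.raises(ValueError):
            classify_branch({})

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            DecisionThreshold(0.0)
        with pytest.raises(ValueError):
            DecisionThreshold(1.0)


def report_with(freqs_by_scalar, n_trees=1000):
    branch = BranchReport(
        bipartition=AB,
        freq_by_scalar=freqs_by_scalar,
        n_trees=n_trees,
        classification=classify_branch(freqs_by_scalar),
    )
    return ConcordanceReport(branches=[branch], n_trees=n_trees)


class TestAnnotation:
    @pytest.mark.parametrize(
        "freqs,label",
        [
            ({2.0: 0.074, 4.0: 0.026}, "7.4/2.6"),
            ({2.0: 1.0, 4.0: 1.0}, "100.0/100.0"),
            ({2.0: 0.0, 4.0: 0.0}, "0.0/0.0"),
        ],
    )
    def test_percent_labels(self, freqs, label):
        observed = parse_newick("((A,B),(C,D));")
        annotated = annotate_observed_tree(observed, report_with(freqs))
        assert label in write_newick(annotated)


class TestReport:
    def test_row_count_and_columns(self):
        guide = generate_species_tree(ScenarioConfig(n_tips=10, seed=10))
        sims = {
            s: simulate_gene_trees(guide, SimulationConfig(n_trees=100, seed=int(s), scalar=s))
            for s in (2.0, 4.0)
        }
        report = build_report(guide, sims, guide=guide)
        assert len(report.branches) == 10 - 3
        frame = report.to_frame()
        assert list(frame.columns) == [
            "bipartition",
            "n_trees",
            "freq_x2",
            "freq_x4",
            "conflicts_nuclear",
            "classification",
        ]
        # the observed tree IS the guide here: nothing conflicts
        assert set(frame["conflicts_nuclear"]) == {"false"}
        assert set(frame["n_trees"]) == {100}

    def test_long_branches_of_guide_reach_full_concordance(self):
        guide = generate_species_tree(
            ScenarioConfig(n_tips=8, seed=1, internal_cu_dist="fixed", internal_cu=50.0)
        )
        sims = {2.0: simulate_gene_trees(guide, SimulationConfig(n_trees=200, seed=3, scalar=2.0))}
        report = build_report(guide, sims, guide=guide)
        assert all(b.freq_by_scalar[2.0] == 1.0 for b in report.branches)
        assert not report.candidates()

    def test_unequal_sim_counts_rejected(self):
        guide = generate_species_tree(ScenarioConfig(n_tips=6, seed=2))
        sims2 = simulate_gene_trees(guide, SimulationConfig(n_trees=10, seed=1))
        with pytest.raises(ValueError, match="unequal"):
            build_report(guide, {2.0: sims2, 4.0: sims2[:5]})

    def test_conflict_flag_against_guide(self):
        guide = parse_newick("(((A,B),(C,D)),(E,F));")
        observed = parse_newick("(((A,C),(B,D)),(E,F));")
        sims = {2.0: simulate_gene_trees(
            parse_newick("(((A:1,B:1):5,(C:1,D:1):5):5,(E:1,F:1):5);"),
            SimulationConfig(n_trees=50, seed=2),
        )}
        report = build_report(observed, sims, guide=guide)
        by_bp = {b.bipartition: b for b in report.branches}
        taxa = frozenset("ABCDEF")
        assert by_bp[Bipartition({"E", "F"}, taxa)].conflicts_nuclear is False
        assert by_bp[Bipartition({"A", "C"}, taxa)].conflicts_nuclear is True
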