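"""Support trees: monophyly, Bayes factors, posterior consolidation."""

import itertools
import math

import numpy as np
import pytest

from barcodegap.gaps import SpeciesPartition
from barcodegap.trees import (
    BayesFactorInput,
    TreeParseError,
    bayes_factor,
    consolidate_partition,
    monophyly_test,
    parse_tree,
)


def random_newick(rng, tips):
    """Random binary topology over the given tip labels."""
    nodes = [str(t) for t in tips]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}){int(rng.integers(50, 101))}")
    return nodes[0] + ";"


def brute_force_monophyletic(newick_tips_sets, query):
    """Oracle: a tip set is a clade iff it or its complement appears as
    the leaf set of some internal node under any rooting — equivalently,
    iff the query matches one side of an internal-edge bipartition."""
    return any(
        side == query or comp == query for side, comp in newick_tips_sets
    )


def all_bipartitions(newick):
    """Independently parse a newick string into internal-edge bipartitions
    (naive bracket matching, no tree library)."""
    newick = newick.rstrip(";")

    def tips_of(expr):
        return frozenset(
            t.split(")")[0]
            for t in expr.replace("(", ",").split(",")
            if t and not t[0].isdigit() and t.split(")")[0]
        )

    all_tips = tips_of(newick)
    sides = []
    # every balanced-parenthesis substring is a clade of the rooted reading
    for start, c in enumerate(newick):
        if c != "(":
            continue
        depth = 0
        for end in range(start, len(newick)):
            if newick[end] == "(":
                depth += 1
            elif newick[end] == ")":
                depth -= 1
                if depth == 0:
                    clade = tips_of(newick[start : end + 1])
                    if 1 < len(clade) < len(all_tips):
                        sides.append((clade, all_tips - clade))
                    break
    return sides


class TestParseTree:
    def test_parses_tips_and_supports(self):
        t = parse_tree("((a,b)95,(c,d)88);")
        assert t.tips == {"a", "b", "c", "d"}
        assert sorted(t.support_values) == [88.0, 95.0]

    def test_probability_scale_rescaled(self):
        t = parse_tree("((a,b)0.95,(c,d)0.88);")
        assert monophyly_test(t, {"a", "b"}).support == pytest.approx(95.0)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeParseError):
            parse_tree("((a,a),(b,c));")

    def test_malformed_newick_rejected(self):
        with pytest.raises(TreeParseError):
            parse_tree("((a,b),(c,d;")


class TestMonophyly:
    def test_clade_found_with_support(self):
        t = parse_tree("((a1,a2)97,(b1,b2)88);")
        res = monophyly_test(t, {"a1", "a2"})
        assert res.monophyletic and res.support == 97.0

    def test_non_clade_rejected(self):
        t = parse_tree("((a1,a2)97,(b1,b2)88);")
        res = monophyly_test(t, {"a1", "b1"})
        assert not res.monophyletic and res.support is None

    def test_singleton_trivially_monophyletic(self):
        t = parse_tree("((a1,a2),(b1,b2));")
        res = monophyly_test(t, {"a1"})
        assert res.monophyletic and res.support is None

    def test_unknown_tip_rejected(self):
        t = parse_tree("((a,b),(c,d));")
        with pytest.raises(ValueError):
            monophyly_test(t, {"a", "zzz"})

    def test_invariant_under_rerooting(self):
        # same unrooted tree written with two different rootings
        t1 = parse_tree("(((a,b)90,c)80,(d,e)70);")
        t2 = parse_tree("((d,e)70,(c,(a,b)90)80);")
        for tips in ({"a", "b"}, {"d", "e"}, {"a", "b", "c"}, {"a", "c"}):
            assert (
                monophyly_test(t1, tips).monophyletic
                == monophyly_test(t2, tips).monophyletic
            )

    def test_complement_side_counts_as_clade(self):
        # {c,d,e} is the complement of the (a,b) edge: a clade unrooted
        t = parse_tree("((a,b)90,(c,(d,e)80)70);")
        assert monophyly_test(t, {"c", "d", "e"}).monophyletic

    def test_agrees_with_bracket_matching_oracle(self, rng):
        tips = [f"t{i}" for i in range(12)]
        for _ in range(60):
            newick = random_newick(rng, tips)
            tree = parse_tree(newick)
            sides = all_bipartitions(newick)
            for size in (2, 3, 6):
                query = frozenset(
                    str(x) for x in rng.choice(tips, size=size, replace=False)
                )
                expected = brute_force_monophyletic(sides, query)
                assert monophyly_test(tree, query).monophyletic == expected


class TestBayesFactor:
    def test_equal_models_give_zero(self):
        bf, verdict = bayes_factor(BayesFactorInput(-100.0, -100.0, 5, 5))
        assert bf == 0.0 and verdict == "not favored"

    def test_printed_formula(self):
        bf, verdict = bayes_factor(BayesFactorInput(50.0, 0.0, 2, 1))
        assert bf == pytest.approx(100.0 + math.log(0.01))
        assert verdict == "partitioned favored"

    def test_threshold_inclusive_at_ten(self):
        # arrange BF == 10 exactly: 2*dlnl + dp*ln(0.01) = 10
        dlnl = (10.0 - math.log(0.01)) / 2.0
        bf, verdict = bayes_factor(BayesFactorInput(dlnl, 0.0, 2, 1))
        assert bf == pytest.approx(10.0, abs=1e-12)
        assert verdict == "partitioned favored"

    def test_antisymmetric_up_to_penalty(self):
        x = BayesFactorInput(-50.0, -60.0, 7, 3)
        swapped = BayesFactorInput(-60.0, -50.0, 3, 7)
        bf1, _ = bayes_factor(x)
        bf2, _ = bayes_factor(swapped)
        assert bf1 == pytest.approx(-bf2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            BayesFactorInput(math.nan, 0.0, 1, 1)
        with pytest.raises(ValueError):
            BayesFactorInput(0.0, 0.0, 0, 1)


class TestConsolidation:
    def base_partition(self):
        return SpeciesPartition(
            {"h1": "A", "h2": "A", "h3": "B", "h4": "C"}, threshold=0.027
        )

    def test_high_posterior_split_retained(self):
        p = consolidate_partition(self.base_partition(), {("A", "B"): 1.0})
        assert p.n_species() == 3

    def test_low_posterior_split_merged(self):
        p = consolidate_partition(self.base_partition(), {("B", "C"): 0.25})
        assert p.n_species() == 2
        assert p.assignment["h3"] == p.assignment["h4"] == "B"

    def test_empty_posteriors_unchanged(self):
        p = consolidate_partition(self.base_partition(), {})
        assert p.assignment == self.base_partition().assignment

    def test_never_increases_species_count(self, rng):
        base = self.base_partition()
        for _ in range(10):
            posteriors = {
                pair: float(rng.uniform())
                for pair in itertools.combinations("ABC", 2)
            }
            merged = consolidate_partition(base, posteriors)
            assert merged.n_species() <= base.n_species()

    def test_merge_commutative_across_independent_splits(self):
        base = SpeciesPartition(
            {"h1": "A", "h2": "B", "h3": "C", "h4": "D"}, threshold=0.027
        )
        p1 = consolidate_partition(base, {("A", "B"): 0.1, ("C", "D"): 0.2})
        p2 = consolidate_partition(base, {("C", "D"): 0.2, ("A", "B"): 0.1})
        assert p1.assignment == p2.assignment

    def test_posterior_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            consolidate_partition(self.base_partition(), {("A", "B"): 1.5})
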