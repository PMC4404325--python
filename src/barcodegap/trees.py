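"""Species evaluation on support-annotated gene trees.

Putative species from threshold clustering are checked against a
posterior consensus tree: a species is corroborated when its haplotypes
are monophyletic (some internal-edge bipartition isolates exactly that
tip set, in the unrooted sense) with high posterior clade probability.
Also here: the stepping-stone Bayes-factor comparison with a
parameter-count penalty, and the decision rule that consolidates
putative species using externally computed multispecies-coalescent
speciation posteriors (the rjMCMC sampling itself is out of scope; its
posteriors are inputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from .gaps import SpeciesPartition


class TreeParseError(ValueError):
    pass


@dataclass
class SupportTree:
    """Unrooted topology with internal-edge supports on the [0, 100] scale."""

    tree: dendropy.Tree
    #: frozenset(tip labels) of one side of each internal edge -> support or None
    bipartitions: dict[frozenset, float | None]
    tips: frozenset
    #: every internal-node support label as read (rescaled), rooted reading
    support_values: tuple = ()

    def n_tips(self) -> int:
        return len(self.tips)


@dataclass
class MonophylyResult:
    species: str
    monophyletic: bool
    support: float | None = None  # present iff monophyletic and edge internal


@dataclass
class BayesFactorInput:
    lnl1: float  # marginal log-likelihood, partitioned (alternative) model
    lnl0: float  # marginal log-likelihood, unpartitioned (null) model
    p1: int
    p0: int

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p0 <= 0:
            raise ValueError("parameter counts must be positive integers")
        for v in (self.lnl1, self.lnl0):
            if not math.isfinite(v):
                raise ValueError("marginal log-likelihoods must be finite")


def _collect_supports_and_bipartitions(tree: dendropy.Tree):
    tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    raw: list[tuple[frozenset, float | None]] = []

    def leafset(node) -> frozenset:
        return frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )

    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        side = leafset(node)
        # skip the trivial bipartition produced by a rooted reading
        if len(side) in (0, len(tips)) or len(tips - side) == 0:
            continue
        support = None
        if node.label is not None and node.label != "":
            try:
                support = float(node.label)
            except ValueError:
                support = None
        raw.append((side, support))
    return tips, raw


def parse_tree(source) -> SupportTree:
    """Read a newick tree with supports as internal node labels.

    Accepts a path or a newick string.  Support values on a [0, 1] scale
    (all values <= 1) are auto-rescaled to [0, 100].  Duplicate tip
    labels are an error.
    """
    text = None
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        raise TreeParseError(f"cannot read tree from {source!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeParseError(f"duplicate tip labels: {dups}")
    tips, raw = _collect_supports_and_bipartitions(tree)
    supports = [s for _, s in raw if s is not None]
    scale = 100.0 if supports and max(supports) <= 1.0 else 1.0
    bipartitions: dict[frozenset, float | None] = {}
    for side, s in raw:
        key = min(side, tips - side, key=lambda x: (len(x), sorted(x)))
        val = s * scale if s is not None else None
        # keep the better-annotated copy if an edge appears twice
        if key not in bipartitions or bipartitions[key] is None:
            bipartitions[key] = val
    support_values = tuple(
        s * scale for _, s in raw if s is not None
    )
    return SupportTree(tree, bipartitions, tips, support_values)


def monophyly_test(tree: SupportTree, tips) -> MonophylyResult:
    """Is the tip set a clade of the unrooted tree, and how supported?

    ``tips`` may be any iterable of tip labels; a label absent from the
    tree is an error.  Singletons are trivially monophyletic with no
    defining internal edge, hence no support value.
    """
    tipset = frozenset(tips)
    unknown = tipset - tree.tips
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")
    if not tipset or len(tipset) >= len(tree.tips):
        raise ValueError("tip set must be a proper non-empty subset")
    name = ",".join(sorted(tipset))
    if len(tipset) == 1:
        return MonophylyResult(name, True, None)
    key = min(
        tipset, tree.tips - tipset, key=lambda x: (len(x), sorted(x))
    )
    if key in tree.bipartitions:
        return MonophylyResult(name, True, tree.bipartitions[key])
    return MonophylyResult(name, False, None)


def bayes_factor(x: BayesFactorInput, threshold: float = 10.0):
    """BF = 2*(lnL1 - lnL0) + (P1 - P0)*ln(0.01); favored iff BF >= 10.

    The ln(0.01) term penalizes each extra parameter of the partitioned
    model; the threshold of 10 ("at least 10") is inclusive.
    """
    bf = 2.0 * (x.lnl1 - x.lnl0) + (x.p1 - x.p0) * math.log(0.01)
    verdict = "partitioned favored" if bf >= threshold else "not favored"
    return bf, verdict


def consolidate_partition(
    p: SpeciesPartition,
    posteriors: dict,
    keep_threshold: float = 0.95,
) -> SpeciesPartition:
    """Merge putative species whose speciation posterior is unconvincing.

    ``posteriors`` maps (label_a, label_b) -> posterior probability that
    the split is a true speciation event (e.g. from a multispecies-
    coalescent analysis).  Splits below ``keep_threshold`` are merged;
    the lexicographically smaller label wins.  Merging is applied with
    union–find so it is commutative across independent splits and never
    increases the species count.
    """
    labels = set(p.assignment.values())
    parent = {l: l for l in labels}

    def find(l: str) -> str:
        while parent[l] != l:
            parent[l] = parent[parent[l]]
            l = parent[l]
        return l

    merged: list[str] = []
    for (a, b), post in posteriors.items():
        if not (0.0 <= post <= 1.0):
            raise ValueError(f"posterior outside [0, 1] for ({a}, {b}): {post}")
        if a not in labels or b not in labels:
            raise ValueError(f"unknown species label in split ({a}, {b})")
        if post < keep_threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                lo, hi = min(ra, rb), max(ra, rb)
                parent[hi] = lo
                merged.append(f"merged {a}+{b} (posterior {post:.2f})")
    assignment = {h: find(l) for h, l in p.assignment.items()}
    prov = list(p.provenance) + [
        f"posterior consolidation at keep_threshold={keep_threshold}"
    ] + merged
    return SpeciesPartition(assignment, p.threshold, prov)


def monophyly_report(
    tree: SupportTree,
    partition: SpeciesPartition,
    membership: dict | None = None,
) -> list[MonophylyResult]:
    """Monophyly of every species with >= 1 tip present in the tree.

    ``membership`` optionally maps tree tip label -> haplotype id (for
    trees whose tips are sample ids rather than haplotype ids).
    """
    results = []
    for label in partition.labels():
        haps = set(partition.members(label))
        if membership:
            tipset = {t for t, h in membership.items() if h in haps}
        else:
            tipset = haps & set(tree.tips)
        if not tipset or len(tipset) >= len(tree.tips):
            continue
        res = monophyly_test(tree, tipset)
        res.species = label
        results.append(res)
    return results


def write_monophyly_report(results, path, analysis_id: str = "COI") -> None:
    with open(path, "w") as fh:
        fh.write("species\tanalysis\tmonophyletic\tposterior_clade_probability\n")
        for r in results:
            sup = "" if r.support is None else f"{r.support:.1f}"
            fh.write(
                f"{r.species}\t{analysis_id}\t"
                f"{'yes' if r.monophyletic else 'no'}\t{sup}\n"
            )
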