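"""Neutral coalescent machinery used throughout the package.

Time is measured in *mutational units* x = 2ut (t in generations, u the
per-sequence per-generation mutation rate): a pair of lineages in a
population with scaled diversity theta coalesces at rate 1/theta per
unit x, and mutations fall on each lineage at rate 1/2 per unit x, so
the expected pairwise difference count in a stationary population is
exactly theta.  This is the same parameterization as the classical
"theta = mean pairwise differences" convention and makes the sudden-
expansion parameters (tau, theta0, theta1) directly comparable between
the simulator and the mismatch-model expectations.

Demographies: constant size, and a sudden (stepwise) expansion in which
the population had scaled size theta0 until tau mutational-time units
ago and theta1 since.  A structured (infinite-island) variant supports
the spatial-expansion bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConstantSize:
    theta: float

    def size_at(self, x: float) -> float:
        return self.theta


@dataclass(frozen=True)
class SuddenExpansion:
    """theta0 before the expansion (x >= tau, backwards), theta1 after."""

    theta0: float
    theta1: float
    tau: float

    def size_at(self, x: float) -> float:
        return self.theta1 if x < self.tau else self.theta0


@dataclass
class Genealogy:
    """Binary coalescent tree over n leaves (nodes 0..n-1).

    Internal nodes are n..2n-2 in coalescence order; the root is 2n-2.
    ``parent[i]`` and ``lengths[i]`` give each non-root node's parent
    and branch duration (mutational units); ``masks[i]`` is the leaf
    bitmask below node i.
    """

    n: int
    parent: np.ndarray
    lengths: np.ndarray
    masks: list  # python ints
    children: list  # (left, right) per internal node, index n..2n-2

    @property
    def total_length(self) -> float:
        return float(self.lengths[: 2 * self.n - 2].sum())

    def n_coalescent_events(self) -> int:
        return self.n - 1


def simulate_genealogy(n: int, demography, rng: np.random.Generator) -> Genealogy:
    """Hudson coalescent with exponential waiting times.

    Under a sudden expansion the waiting time is drawn piecewise: the
    exponential clock runs at rate C(k,2)/theta1 until it would cross
    tau, then restarts (memorylessly) at rate C(k,2)/theta0.
    """
    if n < 2:
        raise ValueError("need n >= 2 lineages")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    lengths = np.zeros(n_nodes)
    masks: list[int] = [1 << i for i in range(n)] + [0] * (n - 1)
    children: list[tuple[int, int]] = []

    active = list(range(n))
    x = 0.0
    next_node = n
    tau = getattr(demography, "tau", math.inf)
    while len(active) > 1:
        k = len(active)
        pair_rate = k * (k - 1) / 2.0
        while True:
            theta = demography.size_at(x)
            w = rng.exponential(theta / pair_rate)
            if x < tau <= x + w and demography.size_at(tau) != theta:
                x = tau  # epoch boundary: restart the memoryless clock
                continue
            x += w
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node = next_node
        next_node += 1
        node_time[node] = x
        masks[node] = masks[a] | masks[b]
        for child in (a, b):
            parent[child] = node
            lengths[child] = x - node_time[child]
        children.append((a, b))
        active = [v for v in active if v not in (a, b)] + [node]
    return Genealogy(n, parent, lengths, masks, children)


def simulate_structured_genealogy(
    n: int,
    theta: float,
    migration: float,
    tau: float,
    rng: np.random.Generator,
    theta_ancestral: float | None = None,
) -> Genealogy:
    """Infinite-island coalescent for the spatial-expansion model.

    All n lineages start in one deme of scaled size ``theta``.  Within a
    deme, each pair coalesces at rate 1/theta; each lineage emigrates to
    a fresh (empty) deme at rate M/(2*theta), after which it can only
    coalesce in the ancestral population.  At time tau (backwards) the
    expansion ends: all remaining lineages enter a panmictic ancestral
    population of size ``theta_ancestral`` (default: theta).
    """
    if theta_ancestral is None:
        theta_ancestral = theta
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    lengths = np.zeros(n_nodes)
    masks: list[int] = [1 << i for i in range(n)] + [0] * (n - 1)
    children: list[tuple[int, int]] = []

    deme: dict[int, int] = {i: 0 for i in range(n)}
    next_deme = 1
    active = list(range(n))
    x = 0.0
    next_node = n
    mig_rate_per_lineage = migration / (2.0 * theta)

    def merge(a: int, b: int, when: float) -> int:
        nonlocal next_node
        node = next_node
        next_node += 1
        node_time[node] = when
        masks[node] = masks[a] | masks[b]
        for child in (a, b):
            parent[child] = node
            lengths[child] = when - node_time[child]
        children.append((a, b))
        return node

    while len(active) > 1 and x < tau:
        by_deme: dict[int, list[int]] = {}
        for v in active:
            by_deme.setdefault(deme[v], []).append(v)
        copairs = sum(
            len(vs) * (len(vs) - 1) // 2 for vs in by_deme.values()
        )
        coal_rate = copairs / theta
        mig_rate = len(active) * mig_rate_per_lineage
        total = coal_rate + mig_rate
        if total == 0:
            break
        w = rng.exponential(1.0 / total)
        if x + w >= tau:
            x = tau
            break
        x += w
        if rng.random() < coal_rate / total:
            pairs = [
                (a, b)
                for vs in by_deme.values()
                for idx, a in enumerate(vs)
                for b in vs[idx + 1 :]
            ]
            a, b = pairs[rng.integers(len(pairs))]
            node = merge(a, b, x)
            deme[node] = deme[a]
            active = [v for v in active if v not in (a, b)] + [node]
        else:
            v = active[rng.integers(len(active))]
            deme[v] = next_deme
            next_deme += 1

    # ancestral panmictic phase
    while len(active) > 1:
        k = len(active)
        w = rng.exponential(theta_ancestral / (k * (k - 1) / 2.0))
        x = max(x, tau) + w
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node = merge(a, b, x)
        active = [v for v in active if v not in (a, b)] + [node]
    return Genealogy(n, parent, lengths, masks, children)


# ---------------------------------------------------------------------------
# infinite-sites mutations and summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SampleStats:
    """Infinite-sites summaries of one simulated sample."""

    n: int
    S: int
    eta_s: int          # singleton mutations (minor count 1)
    k: float            # mean pairwise differences
    K: int              # distinct haplotypes
    U: np.ndarray       # per-sequence singleton counts
    field_order = ("S", "eta_s", "k", "K")


def drop_mutations(
    g: Genealogy,
    rng: np.random.Generator,
    fixed_S: int | None = None,
    theta: float | None = None,
) -> list[int]:
    """Place mutations on branches; return one carrier bitmask per mutation.

    ``fixed_S`` conditions on exactly S mutations (multinomial on branch
    lengths); otherwise the count is Poisson(total_length / 2), the
    theta-conditioned mode (the genealogy's time scale already carries
    theta, so no extra rate factor is needed; ``theta`` is accepted only
    for signature clarity and must match the genealogy's demography).
    """
    n_branches = 2 * g.n - 2
    lens = g.lengths[:n_branches]
    total = lens.sum()
    if fixed_S is not None:
        s = int(fixed_S)
    else:
        s = int(rng.poisson(total / 2.0))
    if s == 0:
        return []
    alloc = rng.multinomial(s, lens / total)
    masks: list[int] = []
    for branch, count in enumerate(alloc):
        masks.extend([g.masks[branch]] * int(count))
    return masks


def stats_from_mutations(n: int, mutation_masks: list[int]) -> SampleStats:
    S = len(mutation_masks)
    k = 0.0
    eta_s = 0
    U = np.zeros(n)
    full = (1 << n) - 1
    pairs = n * (n - 1) / 2.0
    leaf_signature: list[list[int]] = [[] for _ in range(n)]
    for m_idx, mask in enumerate(mutation_masks):
        c = bin(mask).count("1")
        k += c * (n - c) / pairs
        if c == 1 or c == n - 1:
            eta_s += 1
            carrier = (mask if c == 1 else (~mask) & full).bit_length() - 1
            U[carrier] += 1
        for i in range(n):
            if mask >> i & 1:
                leaf_signature[i].append(m_idx)
    K = len({tuple(sig) for sig in leaf_signature})
    return SampleStats(n=n, S=S, eta_s=eta_s, k=k, K=K, U=U)


def simulate_sample_stats(
    n: int,
    demography,
    rng: np.random.Generator,
    fixed_S: int | None = None,
) -> SampleStats:
    g = simulate_genealogy(n, demography, rng)
    masks = drop_mutations(g, rng, fixed_S=fixed_S)
    return stats_from_mutations(n, masks)


def mismatch_counts_from_mutations(
    n: int, mutation_masks: list[int]
) -> np.ndarray:
    """Pairwise-difference histogram of a simulated infinite-sites sample."""
    diffs = np.zeros((n, n), dtype=np.int64)
    for mask in mutation_masks:
        carriers = [i for i in range(n) if mask >> i & 1]
        others = [i for i in range(n) if not mask >> i & 1]
        for i in carriers:
            for j in others:
                diffs[i, j] += 1
    iu = np.triu_indices(n, k=1)
    vals = (diffs + diffs.T)[iu]
    return np.bincount(vals)
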