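"""Coalescent synthetic-data generator with truth records.

Emits barcode datasets with the statistical structure the analysis
pipeline assumes: several species clusters separated by target
model-corrected divergences, within-species coalescent variation under
constant-size or sudden-expansion demographies, and optional NUMT
contaminants (stop-codon or transversion-biased).  Every dataset comes
with a truth record (species partition, per-species theta and tau, numt
ids) so each pipeline stage can be tested against known ground truth.

Sequences evolve under a finite-site K2P kernel (transition:transversion
exchangeability kappa, default 8 — COI-like transition bias) so the
distance corrections and saturation behavior are genuinely exercised.
Root sequences are COI-like: reading frame 0 of the window is kept free
of stop codons (and accidental frame-0 stops arising during descent are
rejected, mimicking purifying selection on the real mitochondrial locus),
while the two off-frames carry stop codons as any real COI fragment
does — this is what makes the stop-codon NUMT screen informative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .alignment_io import Alignment, PopulationMap, SequenceRecord
from .coalescent import ConstantSize, SuddenExpansion, simulate_genealogy
from .distances import jc69_distance
from .numt import find_stop_codons, stop_codons

BASES = "ACGT"


@dataclass
class SpeciesSpec:
    name: str
    n: int = 10
    theta: float = 3.0
    demography: str = "constant"    # "constant" | "expansion"
    tau: float = 6.0                # used by the expansion demography
    growth_factor: float = 100.0    # theta1 = growth_factor * theta0
    populations: list[int] | None = None  # sample counts per population


@dataclass
class SimConfig:
    """Study conditions for a simulated species complex.

    Defaults emulate a barcode study of a cryptic complex: 640-nt COI
    haplotypes, three species whose corrected divergences (5% and 12%)
    straddle the empirical barcode gap, within-species diversity
    theta = 3 (pi ~ 0.005 on 640 nt, inside the observed 0-0.011 range),
    and a COI-like transition bias.
    """

    seed: int = 1
    L: int = 640
    species: list[SpeciesSpec] = field(default_factory=lambda: [
        SpeciesSpec("speciesA"),
        SpeciesSpec("speciesB"),
        SpeciesSpec("speciesC"),
    ])
    #: condensed upper-triangle pairwise corrected-divergence targets
    #: (substitutions/site) in scipy squareform order; default realizes
    #: d(A,B)=0.05, d(A,C)=d(B,C)=0.12
    divergence_targets: list[float] = field(
        default_factory=lambda: [0.05, 0.12, 0.12]
    )
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 8.0
    n_numts: int = 0
    numt_mode: str = "stop"         # "stop" | "tv_bias"
    target_tolerance: float = 0.05  # +-5% on realized divergences


@dataclass
class TruthRecord:
    species_of_sample: dict
    species_of_population: dict
    theta: dict
    tau: dict
    numt_samples: list
    realized_divergences: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# K2P finite-site mutation kernel
# ---------------------------------------------------------------------------

TRANSITION_OF = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T


def _mutate_base(base_idx: int, kappa: float, rng) -> int:
    """K2P substitution: transition with probability kappa/(kappa+2)."""
    if rng.random() < kappa / (kappa + 2.0):
        return TRANSITION_OF[base_idx]
    # one of the two transversion targets
    choices = [b for b in range(4) if b != base_idx and b != TRANSITION_OF[base_idx]]
    return choices[rng.integers(2)]


def _has_frame0_stop(seq: list[int], pos: int, stops: set[str]) -> bool:
    codon_start = (pos // 3) * 3
    if codon_start + 3 > len(seq):
        return False
    codon = "".join(BASES[b] for b in seq[codon_start : codon_start + 3])
    return codon in stops


def _apply_mutations(
    seq: list[int],
    n_mut: int,
    kappa: float,
    rng,
    stops: set[str],
    coding_guard: bool = True,
    max_tries: int = 50,
) -> list[int]:
    out = list(seq)
    for _ in range(n_mut):
        for _try in range(max_tries):
            pos = int(rng.integers(len(out)))
            old = out[pos]
            out[pos] = _mutate_base(old, kappa, rng)
            if coding_guard and _has_frame0_stop(out, pos, stops):
                out[pos] = old  # rejected: would break the reading frame
                continue
            break
    return out


def _random_coding_root(L: int, base_freqs, rng, stops: set[str]) -> list[int]:
    """Random sequence with an open frame 0 and >= 1 stop in frames 1 and 2."""
    freqs = np.asarray(base_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    while True:
        seq = list(rng.choice(4, size=L, p=freqs))
        text = "".join(BASES[b] for b in seq)
        ok = True
        for offset in range(3):
            n_stop = sum(
                1
                for i in range(offset, L - 2, 3)
                if text[i : i + 3] in stops
            )
            if offset == 0 and n_stop > 0:
                ok = False
            if offset > 0 and n_stop == 0:
                ok = False
        if ok:
            return seq


def _seq_str(seq: list[int]) -> str:
    return "".join(BASES[b] for b in seq)


def _evolve_to_target(
    parent: list[int],
    target: float,
    kappa: float,
    rng,
    stops: set[str],
    tolerance: float,
) -> list[int]:
    """Mutate until the JC-corrected distance from the parent hits target."""
    if target <= 0:
        return list(parent)
    child = list(parent)
    parent_str = _seq_str(parent)
    d = 0.0
    max_total = 20 * len(parent)
    for _ in range(max_total):
        if d >= target:
            break
        child = _apply_mutations(child, 1, kappa, rng, stops)
        d = jc69_distance(parent_str, _seq_str(child))
    if not (target <= d <= target * (1.0 + 2 * tolerance) + 2.0 / len(parent)):
        raise RuntimeError(
            f"could not realize divergence target {target}: reached {d}"
        )
    return child


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate_coalescent_sample(
    n: int,
    theta: float,
    demography=None,
    L: int = 640,
    seed=None,
    root_seq: list[int] | None = None,
    kappa: float = 8.0,
    base_freqs=(0.25, 0.25, 0.25, 0.25),
    coding_guard: bool = True,
    code: int = 5,
):
    """Hudson coalescent sample of n sequences of length L.

    ``demography`` defaults to constant size theta.  Mutations are
    Poisson on branches (1/2 per lineage per mutational-time unit, so
    the expected pairwise difference count equals theta) and hit random
    sites under the K2P kernel.  Returns (list of sequence strings,
    genealogy).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if demography is None:
        demography = ConstantSize(theta)
    stops = stop_codons(code)
    if root_seq is None:
        root_seq = _random_coding_root(L, base_freqs, rng, stops)
    g = simulate_genealogy(n, demography, rng)
    n_nodes = 2 * n - 1
    seqs: list[list[int] | None] = [None] * n_nodes
    seqs[n_nodes - 1] = list(root_seq)
    # internal nodes were created in coalescence order; walk root-to-leaves
    for node in range(n_nodes - 1, n - 1, -1):
        left, right = g.children[node - n]
        for child in (left, right):
            n_mut = int(rng.poisson(g.lengths[child] / 2.0))
            seqs[child] = _apply_mutations(
                seqs[node], n_mut, kappa, rng, stops, coding_guard
            )
    return [_seq_str(seqs[i]) for i in range(n)], g


def simulate_numt(
    source: str,
    mode: str = "stop",
    seed=None,
    n_background: int = 5,
    n_tv: int = 24,
    kappa: float = 8.0,
    code: int = 5,
) -> str:
    """Derive a NUMT contaminant from a source haplotype.

    ``stop`` mode guarantees the result has >= 1 stop codon in its best
    reading frame; ``tv_bias`` mode guarantees a transition:transversion
    ratio <= 1/6 against the source over >= ``n_tv`` differences
    (nuclear pseudogenes lose the transition bias of the mitochondrial
    locus, and the ones worth screening for sit several percent away
    from the true barcode cluster).
    """
    if len(source.replace("-", "")) < 30:
        raise ValueError("source too short for a numt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stops = stop_codons(code)
    seq = [BASES.index(c) for c in source]
    if mode == "stop":
        seq = _apply_mutations(seq, n_background, kappa, rng, stops,
                               coding_guard=False)
        while find_stop_codons(_seq_str(seq), code)[1] < 1:
            codon = int(rng.integers(1, len(seq) // 3 - 1))
            stop = list(stops)[int(rng.integers(len(stops)))]
            seq[3 * codon : 3 * codon + 3] = [BASES.index(c) for c in stop]
        return _seq_str(seq)
    if mode == "tv_bias":
        from .distances import count_substitution_types

        while True:
            out = _seq_str(seq)
            ts, tv = count_substitution_types(source, out)
            if ts + tv >= n_tv and tv >= 6 * max(ts, 1):
                return out
            pos = int(rng.integers(len(seq)))
            old = seq[pos]
            # transversion-biased: 95% transversions
            if rng.random() < 0.95:
                choices = [
                    b for b in range(4)
                    if b != old and b != TRANSITION_OF[old]
                ]
                seq[pos] = choices[rng.integers(2)]
            else:
                seq[pos] = TRANSITION_OF[old]
    raise ValueError(f"unknown numt mode: {mode}")


def _species_ancestors(cfg: SimConfig, root: list[int], rng, stops):
    """Realize pairwise divergence targets by evolving along a UPGMA tree."""
    k = len(cfg.species)
    if k == 1:
        return [list(root)], {}
    targets = np.asarray(cfg.divergence_targets, dtype=float)
    expected = k * (k - 1) // 2
    if targets.size != expected:
        raise ValueError(
            f"need {expected} pairwise divergence targets, got {targets.size}"
        )
    square = squareform(targets)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                if square[a, b] > square[a, c] + square[c, b] + 1e-12:
                    raise ValueError(
                        "divergence targets violate the triangle inequality"
                    )
    link = average(targets)
    # build sequences down the UPGMA tree: node -> (height, sequence)
    heights = {i: 0.0 for i in range(k)}
    seqs: dict[int, list[int]] = {}
    node_children = {}
    for idx, (a, b, h, _cnt) in enumerate(link):
        node = k + idx
        heights[node] = h / 2.0  # cophenetic distance -> per-lineage height
        node_children[node] = (int(a), int(b))
    root_node = k + len(link) - 1
    seqs[root_node] = list(root)

    def descend(node: int) -> None:
        if node < k:
            return
        a, b = node_children[node]
        for child in (a, b):
            branch = heights[node] - heights[child]
            seqs[child] = _evolve_to_target(
                seqs[node], branch, cfg.kappa, rng, stops, cfg.target_tolerance
            )
            descend(child)

    descend(root_node)
    realized = {}
    for a in range(k):
        for b in range(a + 1, k):
            realized[f"{cfg.species[a].name}|{cfg.species[b].name}"] = (
                jc69_distance(_seq_str(seqs[a]), _seq_str(seqs[b]))
            )
    return [seqs[i] for i in range(k)], realized


def simulate_species_complex(cfg: SimConfig):
    """Simulate a full species complex.

    Returns (Alignment, PopulationMap, TruthRecord); deterministic for a
    fixed config (single global seed, all sub-streams derived from it).
    """
    rng = np.random.default_rng(cfg.seed)
    stops = stop_codons(5)
    root = _random_coding_root(cfg.L, cfg.base_freqs, rng, stops)
    ancestors, realized = _species_ancestors(cfg, root, rng, stops)

    from collections import OrderedDict

    records: list[SequenceRecord] = []
    species_of_sample: dict[str, str] = {}
    species_of_population: dict[str, str] = {}
    theta_truth: dict[str, float] = {}
    tau_truth: dict[str, float | None] = {}
    popmap: "OrderedDict[str, tuple[str, str, str]]" = OrderedDict()
    numt_samples: list[str] = []

    for s_idx, spec in enumerate(cfg.species):
        if spec.demography == "expansion":
            theta1 = spec.theta
            theta0 = theta1 / spec.growth_factor
            demog = SuddenExpansion(theta0, theta1, spec.tau)
            tau_truth[spec.name] = spec.tau
        else:
            demog = ConstantSize(spec.theta)
            tau_truth[spec.name] = None
        theta_truth[spec.name] = spec.theta
        seqs, _g = simulate_coalescent_sample(
            spec.n, spec.theta, demography=demog, L=cfg.L, seed=rng,
            root_seq=ancestors[s_idx], kappa=cfg.kappa,
            base_freqs=cfg.base_freqs,
        )
        pops = spec.populations or [spec.n]
        if sum(pops) != spec.n:
            raise ValueError(
                f"population sizes {pops} do not sum to n={spec.n} "
                f"for {spec.name}"
            )
        cursor = 0
        for p_idx, p_n in enumerate(pops):
            pop_code = f"{spec.name}_P{p_idx + 1}"
            species_of_population[pop_code] = spec.name
            for i in range(p_n):
                sample = f"{spec.name}_{cursor + i + 1:03d}"
                records.append(SequenceRecord(sample, seqs[cursor + i]))
                species_of_sample[sample] = spec.name
                popmap[sample] = (pop_code, "host", "country")
            cursor += p_n

    for j in range(cfg.n_numts):
        source = records[0].seq  # contaminate the first species' samples
        contaminant = simulate_numt(source, mode=cfg.numt_mode, seed=rng)
        sample = f"NUMT_{j + 1:02d}"
        records.append(SequenceRecord(sample, contaminant))
        species_of_sample[sample] = "numt"
        pop_code = popmap[records[0].id][0]
        popmap[sample] = (pop_code, "host", "country")
        numt_samples.append(sample)

    truth = TruthRecord(
        species_of_sample=species_of_sample,
        species_of_population=species_of_population,
        theta=theta_truth,
        tau=tau_truth,
        numt_samples=numt_samples,
        realized_divergences=realized,
    )
    return Alignment(tuple(records)), PopulationMap(popmap), truth


def realized_divergence_ratio(aln: Alignment, truth: TruthRecord) -> float:
    """Min between-species / max within-species corrected distance.

    Numt contaminants are ignored.  Used to check whether a simulated
    complex actually satisfies a stated between/within separation
    condition (the coalescent tail occasionally realizes a within-species
    lineage deep enough to blur the barcode gap).
    """
    seqs_by_species: dict[str, list[str]] = {}
    for rec in aln.records:
        sp = truth.species_of_sample[rec.id]
        if sp == "numt":
            continue
        seqs_by_species.setdefault(sp, []).append(rec.seq)
    within_max = 0.0
    for seqs in seqs_by_species.values():
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = jc69_distance(seqs[i], seqs[j])
                if not math.isnan(d):
                    within_max = max(within_max, d)
    between_min = math.inf
    names = sorted(seqs_by_species)
    for a_idx in range(len(names)):
        for b_idx in range(a_idx + 1, len(names)):
            for sa in seqs_by_species[names[a_idx]]:
                for sb in seqs_by_species[names[b_idx]]:
                    d = jc69_distance(sa, sb)
                    if not math.isnan(d):
                        between_min = min(between_min, d)
    if within_max == 0.0:
        return math.inf
    return between_min / within_max


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


PRESETS = {
    "complex": lambda seed: SimConfig(seed=seed),
    "expansion": lambda seed: SimConfig(
        seed=seed,
        species=[
            SpeciesSpec(
                "speciesA", n=30, theta=50.0, demography="expansion",
                tau=5.0, growth_factor=100.0,
            )
        ],
        divergence_targets=[],
    ),
    "numt": lambda seed: SimConfig(seed=seed, n_numts=2, numt_mode="stop"),
}
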