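"""Screening for nuclear mitochondrial pseudogenes (NUMTs).

A NUMT — a nuclear copy of a mitochondrial gene — evolves free of the
coding constraint on the real COI locus, so it betrays itself in two
ways: in-frame stop codons (no open reading frame in any of the three
frames), and an excess of transversion substitutions relative to the
consensus of the most similar haplotype cluster (true mitochondrial COI
evolution is strongly transition-biased).  Both signals are screened
here; flagged haplotypes are reported and optionally excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .alignment_io import HaplotypeTable
from .distances import BASE_INDEX, count_substitution_types, distance_matrix
from .gaps import cluster_at_threshold

#: NCBI translation table 5 — invertebrate mitochondrial (insect COI)
INVERT_MITO = 5


@dataclass
class NumtScreenParams:
    """Screen thresholds.

    ``max_tstv``/``min_diffs`` define "transversion excess": a haplotype
    is flagged when it differs from its nearest-cluster consensus at
    >= min_diffs resolved sites with ts/tv below max_tstv.  The defaults
    (0.5 with 10 differences) demand a clear transversion *majority*
    over a substantial number of substitutions: with COI's strong
    transition bias a clean haplotype essentially never shows that
    pattern, while pseudogenes — which evolve free of the mitochondrial
    mutation bias and typically sit several percent away from the true
    barcode cluster — do.
    """

    code: int = INVERT_MITO
    max_tstv: float = 0.5      # flag transversion excess when ts/tv below this
    min_diffs: int = 10        # ... and at least this many differences
    cluster_threshold: float = 0.027  # nearest-cluster scope for the consensus
    min_stops: int = 1         # stop-codon flag when best frame has >= this


@dataclass
class NumtReport:
    haplotype: str
    frame: int
    stop_count: int
    transitions: int = 0
    transversions: int = 0
    tstv: float = math.inf
    flags: set = field(default_factory=set)

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


def stop_codons(code: int = INVERT_MITO) -> set[str]:
    return set(CodonTable.unambiguous_dna_by_id[code].stop_codons)


def find_stop_codons(seq: str, code: int = INVERT_MITO) -> tuple[int, int]:
    """Scan all three frame offsets; return (best offset, min stop count).

    Gaps are removed before translation.  The best frame is the one with
    the fewest stop codons (ties go to the smallest offset) — a clean
    protein-coding sequence has an open frame, a pseudogene typically
    has stops in every frame.
    """
    ungapped = seq.replace("-", "")
    if len(ungapped) < 3:
        raise ValueError("sequence shorter than one codon")
    stops = stop_codons(code)
    best = (0, math.inf)
    for offset in range(3):
        count = 0
        for i in range(offset, len(ungapped) - 2, 3):
            if ungapped[i : i + 3] in stops:
                count += 1
        if count < best[1]:
            best = (offset, count)
    return best[0], int(best[1])


def majority_consensus(seqs: list[str]) -> str:
    """Majority-rule consensus; ties broken alphabetically, no resolved
    base at a column gives N."""
    length = len(seqs[0])
    out = []
    for col in range(length):
        counts: dict[str, int] = {}
        for s in seqs:
            c = s[col]
            if c in BASE_INDEX:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("N")
        else:
            out.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(out)


def transversion_excess(
    h: str,
    consensus: str,
    max_tstv: float = 0.5,
    min_diffs: int = 10,
) -> tuple[int, int, float, bool]:
    """(ts, tv, ts/tv ratio, flag) for a haplotype against a consensus.

    Only resolved differing sites are counted; zero transversions give an
    infinite ratio (never flagged), zero differences leave the ratio
    undefined (reported as inf, no flag).
    """
    ts, tv = count_substitution_types(h, consensus)
    ratio = ts / tv if tv > 0 else math.inf
    flag = (ts + tv) >= min_diffs and ratio < max_tstv
    return ts, tv, ratio, flag


def screen_numts(
    table: HaplotypeTable,
    params: NumtScreenParams | None = None,
) -> list[NumtReport]:
    """One NumtReport per haplotype; flags: stop_codon, transversion_excess.

    The transversion comparison is against the majority-rule consensus of
    the most similar haplotype cluster (single-linkage clusters on
    p-distance at ``cluster_threshold``, excluding the query itself).
    A haplotype whose cluster has no other member is compared to the
    nearest cluster carrying *at least as many samples* as itself (a
    pseudogene is
    rare relative to the true barcode cluster it derives from, so the
    consensus must represent an established cluster, not another
    contaminant); with no such cluster, simply the nearest.  Haplotypes
    with nothing to compare against skip the transversion test.
    """
    if params is None:
        params = NumtScreenParams()
    if len(table) == 0:
        raise ValueError("empty haplotype table")
    reports: list[NumtReport] = []
    cluster_members: dict[str, list[str]] = {}
    if len(table) >= 2:
        counts = table.counts
        dm = distance_matrix(table, model="p")
        part = cluster_at_threshold(dm, params.cluster_threshold)
        cluster_samples = {
            label: sum(counts[m] for m in part.members(label))
            for label in part.labels()
        }
        for hap in table.ids:
            own = part.assignment[hap]
            mates = [h for h in part.members(own) if h != hap]
            if mates:
                cluster_members[hap] = mates
                continue
            # singleton cluster: rank other clusters by distance
            i = dm.ids.index(hap)
            d = dm.values[i].copy()
            d[i] = np.inf
            d[~np.isfinite(d)] = np.inf
            dist_to = {}
            for j, other in enumerate(dm.ids):
                if other == hap or not math.isfinite(d[j]):
                    continue
                label = part.assignment[other]
                dist_to[label] = min(dist_to.get(label, np.inf), d[j])
            if not dist_to:
                continue
            bigger = [
                l for l in dist_to if cluster_samples[l] >= counts[hap]
            ]
            pool = bigger or list(dist_to)
            near = min(pool, key=lambda l: dist_to[l])
            cluster_members[hap] = part.members(near)
    seqs = dict(zip(table.ids, table.sequences))
    for hap in table.ids:
        frame, nstop = find_stop_codons(seqs[hap], params.code)
        rep = NumtReport(hap, frame, nstop)
        if nstop >= params.min_stops:
            rep.flags.add("stop_codon")
        mates = cluster_members.get(hap)
        if mates:
            cons = majority_consensus([seqs[m] for m in mates])
            ts, tv, ratio, flag = transversion_excess(
                seqs[hap], cons, params.max_tstv, params.min_diffs
            )
            rep.transitions, rep.transversions, rep.tstv = ts, tv, ratio
            if flag:
                rep.flags.add("transversion_excess")
        reports.append(rep)
    return reports


def flagged_haplotypes(reports: list[NumtReport]) -> list[str]:
    return [r.haplotype for r in reports if r.flagged]


def write_report(reports: list[NumtReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\tframe\tstops\tts\ttv\ttstv\tflags\n")
        for r in reports:
            ratio = "inf" if math.isinf(r.tstv) else f"{r.tstv:.3f}"
            fh.write(
                f"{r.haplotype}\t{r.frame}\t{r.stop_count}\t{r.transitions}"
                f"\t{r.transversions}\t{ratio}\t{','.join(sorted(r.flags))}\n"
            )
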