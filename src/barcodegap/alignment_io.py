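"""Aligned-barcode input, haplotype collapsing, and population metadata.

The entry point of the whole workflow is an aligned set of COI barcode
sequences.  Samples are retained only if a fixed window of the alignment
(by default the first 640 aligned sites, the minimum-length rule used for
delimitation) is fully resolved — no fully ambiguous base (N) and no
partial-ambiguity code inside the window.  Retained sequences are truncated
to the window and collapsed to unique haplotypes; downstream modules
operate on the unique haplotypes while sample multiplicities are preserved
for the population-genetic statistics.
"""

from __future__ import annotations

import io as _stdio
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

IUPAC_NT = set("ACGTURYSWKMBDHVN-")
#: codes that do not resolve to a single base at a site
AMBIGUOUS = set("RYSWKMBDHVN")


class AlignmentError(ValueError):
    """Records of unequal length, or an otherwise unusable alignment."""


class InputError(ValueError):
    """Malformed or empty input file."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - IUPAC_NT
        if bad:
            raise InputError(
                f"record {self.id!r} has non-IUPAC characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class Alignment:
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment has no records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"records have unequal lengths: {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HaplotypeTable:
    """Unique haplotypes with sample multiplicities.

    ``haplotypes`` maps haplotype id -> sequence (ids assigned in
    first-seen sample order, so the table is deterministic for a given
    input order).  ``membership`` maps every retained sample id to its
    haplotype id; ``exclusions`` lists (sample id, reason) for samples
    that failed the window filter.
    """

    haplotypes: "OrderedDict[str, str]"
    membership: "OrderedDict[str, str]"
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {h: 0 for h in self.haplotypes}
        for hap in self.membership.values():
            c[hap] += 1
        return c

    @property
    def ids(self) -> list[str]:
        return list(self.haplotypes)

    @property
    def sequences(self) -> list[str]:
        return list(self.haplotypes.values())

    def n_samples(self) -> int:
        return len(self.membership)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def drop(self, hap_ids) -> "HaplotypeTable":
        """Return a copy without the given haplotypes (and their samples)."""
        drop = set(hap_ids)
        haps = OrderedDict(
            (h, s) for h, s in self.haplotypes.items() if h not in drop
        )
        memb = OrderedDict(
            (s, h) for s, h in self.membership.items() if h not in drop
        )
        return HaplotypeTable(haps, memb, list(self.exclusions))

    # ---- round-trippable exports -------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype\tcount\tmembers\tsequence\n")
            counts = self.counts
            members: dict[str, list[str]] = {h: [] for h in self.haplotypes}
            for s, h in self.membership.items():
                members[h].append(s)
            for h, seq in self.haplotypes.items():
                fh.write(
                    f"{h}\t{counts[h]}\t{','.join(members[h])}\t{seq}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        haps: OrderedDict[str, str] = OrderedDict()
        memb: OrderedDict[str, str] = OrderedDict()
        for _, row in df.iterrows():
            haps[row["haplotype"]] = row["sequence"]
            if isinstance(row["members"], str) and row["members"]:
                for s in row["members"].split(","):
                    memb[s] = row["haplotype"]
        return cls(haps, memb)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for h, seq in self.haplotypes.items():
                fh.write(f">{h}\n{seq}\n")


@dataclass
class PopulationMap:
    """sample id -> (population code, host, country)."""

    mapping: "OrderedDict[str, tuple[str, str, str]]"

    def population(self, sample: str) -> str:
        return self.mapping[sample][0]

    def __contains__(self, sample: str) -> bool:
        return sample in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def unmapped(self, samples) -> list[str]:
        """Samples present in the data but absent from the map."""
        return [s for s in samples if s not in self.mapping]

    def populations(self) -> list[str]:
        seen: OrderedDict[str, None] = OrderedDict()
        for pop, _, _ in self.mapping.values():
            seen.setdefault(pop, None)
        return list(seen)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; sequences are upper-cased.

    Raises ``InputError`` for an empty/unparseable file and
    ``AlignmentError`` when records differ in length.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment(tuple(records))


def read_alignment_string(text: str) -> Alignment:
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(_stdio.StringIO(text), "fasta")
    ]
    if not records:
        raise InputError("no FASTA records in string")
    return Alignment(tuple(records))


def collapse_haplotypes(
    aln: Alignment, min_len: int = 640, window_start: int = 0
) -> HaplotypeTable:
    """Filter samples on a resolved window and collapse to unique haplotypes.

    A sample is retained iff sites [window_start, window_start+min_len) of
    its aligned sequence contain no fully ambiguous call (N) and at least
    ``min_len`` resolved sites (gap characters count as resolved alignment
    columns; partial ambiguity codes do not).  Retained sequences are
    truncated to the window.  Identical windows share one haplotype id;
    ids are H001, H002, ... in first-seen order.
    """
    stop = window_start + min_len
    if window_start < 0 or stop > aln.length:
        raise InputError(
            f"window [{window_start}, {stop}) outside alignment of "
            f"length {aln.length}"
        )
    haps: OrderedDict[str, str] = OrderedDict()
    seq_to_id: dict[str, str] = {}
    memb: OrderedDict[str, str] = OrderedDict()
    exclusions: list[tuple[str, str]] = []
    for rec in aln.records:
        window = rec.seq[window_start:stop]
        if "N" in window:
            exclusions.append((rec.id, "fully ambiguous base (N) in window"))
            continue
        resolved = sum(1 for c in window if c not in AMBIGUOUS)
        if resolved < min_len:
            exclusions.append(
                (rec.id, f"only {resolved}/{min_len} resolved sites in window")
            )
            continue
        hap_id = seq_to_id.get(window)
        if hap_id is None:
            hap_id = f"H{len(haps) + 1:03d}"
            seq_to_id[window] = hap_id
            haps[hap_id] = window
        memb[rec.id] = hap_id
    return HaplotypeTable(haps, memb, exclusions)


def load_population_map(path) -> PopulationMap:
    """Read a tab-separated sample->population map.

    Requires columns ``sample``, ``population``, ``host``, ``country``;
    duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample", "population", "host", "country"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"population map missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise InputError(f"duplicate sample ids in population map: {dups}")
    mapping: OrderedDict[str, tuple[str, str, str]] = OrderedDict()
    for _, row in df.iterrows():
        mapping[row["sample"]] = (row["population"], row["host"], row["country"])
    return PopulationMap(mapping)


def write_population_map(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\thost\tcountry\n")
        for s, (pop, host, country) in pm.mapping.items():
            fh.write(f"{s}\t{pop}\t{host}\t{country}\n")
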