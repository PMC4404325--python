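#!/usr/bin/env python
"""Per-population diversity, neutrality tests, differentiation, AMOVA.

Computes the standard population-genetic summary table (n, S, k, pi, HD,
Watterson's theta, Tajima's D, Fu & Li's D*/F*, Fu's Fs, R2) with
coalescent-simulation p-values for the expansion population and for the
three species of the clean complex, then runs the exact test of
differentiation and AMOVA on a two-population split of one species.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from barcodegap.alignment_io import (
    collapse_haplotypes,
    load_population_map,
    read_alignment,
)
from barcodegap.popgen import (
    NeutralNull,
    amova,
    basic_diversity,
    exact_differentiation,
    statistics_from_seqs,
)
from barcodegap.simulate import SimConfig, SpeciesSpec, simulate_species_complex

ROOT = Path(__file__).resolve().parents[1] / "results"
NULL_REPS = 2000
SEED = 20240917


def population_rows(datasets) -> pd.DataFrame:
    rng = np.random.default_rng(SEED)
    rows = []
    for pop, seqs in datasets:
        div = basic_diversity(seqs)
        stats = statistics_from_seqs(seqs)
        row = dict(population=pop, n=div.n, S=div.S, k=round(div.k, 2),
                   pi=round(div.pi, 4), HD=round(div.hd, 2),
                   theta_w=round(div.theta_w, 2))
        row.update({k: round(v, 2) for k, v in stats.items()})
        if div.S >= 1:
            null = NeutralNull(
                div.n, reps=NULL_REPS,
                seed=int(rng.integers(2**31 - 1)), fixed_S=div.S,
            )
            row.update({
                f"p_{k}": round(v, 4)
                for k, v in null.p_values(stats).items()
            })
        rows.append(row)
    return pd.DataFrame(rows)


def main() -> None:
    datasets = []
    for name in ("expansion", "complex"):
        aln = read_alignment(ROOT / "data" / f"{name}.fasta")
        popmap = load_population_map(ROOT / "data" / f"{name}.popmap.tsv")
        table = collapse_haplotypes(aln)
        pops: dict[str, list[str]] = {}
        for sample, hap in table.membership.items():
            pops.setdefault(popmap.population(sample), []).append(
                table.haplotypes[hap]
            )
        datasets.extend(
            (f"{name}:{pop}", seqs) for pop, seqs in sorted(pops.items())
        )
    df = population_rows(datasets)
    df.to_csv(ROOT / "population_stats.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    # differentiation between two subpopulations of one panmictic species
    cfg = SimConfig(
        seed=SEED + 1,
        species=[SpeciesSpec("split", n=30, theta=3.0, populations=[15, 15])],
        divergence_targets=[],
    )
    aln, popmap, _truth = simulate_species_complex(cfg)
    table = collapse_haplotypes(aln)
    pops: dict[str, list[str]] = {}
    for sample, hap in table.membership.items():
        pops.setdefault(popmap.population(sample), []).append(
            table.haplotypes[hap]
        )
    names = sorted(pops)
    seqs = pops[names[0]] + pops[names[1]]
    uniq = {s: i for i, s in enumerate(dict.fromkeys(seqs))}
    counts = np.zeros((len(uniq), 2), dtype=np.int64)
    for s in pops[names[0]]:
        counts[uniq[s], 0] += 1
    for s in pops[names[1]]:
        counts[uniq[s], 1] += 1
    exact = exact_differentiation(counts, reps=20000, seed=SEED)
    print(
        f"\nexact differentiation {names[0]} vs {names[1]}: "
        f"p = {exact.p_value:.3f} ({exact.method}, same panmictic pool)"
    )
    res = amova(pops, permutations=2000, seed=SEED)
    print(
        f"AMOVA: Phi_ST = {res.phi['Phi_ST']:.3f}, "
        f"p = {res.p_values['Phi_ST']:.3f} "
        f"(components: {', '.join(f'{k}={v:.4g}' for k, v in res.components.items())})"
    )


if __name__ == "__main__":
    main()
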