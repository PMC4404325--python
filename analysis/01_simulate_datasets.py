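#!/usr/bin/env python
"""Generate the synthetic datasets the downstream analyses run on.

Three datasets, all with truth records, under results/data/:
  complex       three species at 5%/12% corrected divergence, theta=3
  contaminated  the same complex plus two stop-codon NUMTs
  expansion     one population of 30 sampled after a 100-fold sudden
                expansion (tau=5, theta0=0.5, theta1=50)
"""

from pathlib import Path

from barcodegap.alignment_io import write_population_map
from barcodegap.simulate import (
    PRESETS,
    SimConfig,
    simulate_species_complex,
    write_fasta,
)

SEED = 20240917
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def emit(name: str, cfg: SimConfig) -> None:
    aln, popmap, truth = simulate_species_complex(cfg)
    write_fasta(aln, OUT / f"{name}.fasta")
    write_population_map(popmap, OUT / f"{name}.popmap.tsv")
    truth.to_json(OUT / f"{name}.truth.json")
    species = sorted(set(truth.species_of_sample.values()) - {"numt"})
    print(
        f"{name}: {len(aln)} sequences, {len(species)} species, "
        f"{len(truth.numt_samples)} planted numts"
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    emit("complex", SimConfig(seed=SEED))
    emit("contaminated", SimConfig(seed=SEED, n_numts=2, numt_mode="stop"))
    emit("expansion", PRESETS["expansion"](SEED))
    print(f"wrote datasets to {OUT}")


if __name__ == "__main__":
    main()
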