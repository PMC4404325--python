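#!/usr/bin/env python
"""Mismatch-distribution expansion fit, goodness of fit, and dating.

Fits the sudden-expansion model to the expansion population's mismatch
distribution, bootstraps SSD and raggedness p-values, converts tau to
calendar time with the thrips clock (13.5 generations/year, 6.5%/My
pairwise), and reproduces the pooled-sample dating from a published
tau = 6.74 on the 640-nt window (~160,000 years before present).
"""

import json
from pathlib import Path

import numpy as np

from barcodegap.alignment_io import collapse_haplotypes, read_alignment
from barcodegap.mismatch import date_expansion, fit_expansion, mismatch_distribution

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240917
BOOTSTRAP_REPS = 500


def main() -> None:
    aln = read_alignment(ROOT / "data" / "expansion.fasta")
    seqs = [r.seq for r in aln.records]
    counts = mismatch_distribution(seqs)
    np.savetxt(
        ROOT / "mismatch_counts.tsv",
        np.column_stack([np.arange(counts.size), counts]),
        fmt="%d", delimiter="\t", header="differences\tpairs", comments="",
    )
    fit = fit_expansion(
        counts, model="demographic", bootstrap_reps=BOOTSTRAP_REPS,
        seed=SEED, sample_size=len(seqs),
    )
    date = date_expansion(fit.params["tau"], L=aln.length)
    report = {
        "tau": fit.params["tau"],
        "theta0": fit.params["theta0"],
        "theta1": fit.params["theta1"],
        "SSD": fit.ssd,
        "raggedness": fit.raggedness,
        "p_SSD": fit.p_ssd,
        "p_raggedness": fit.p_rg,
        "bootstrap_reps": fit.bootstrap_reps,
        "t_generations": date.t_generations,
        "t_years": date.t_years,
    }
    (ROOT / "mismatch_fit.json").write_text(
        json.dumps(report, indent=2, default=str)
    )
    print(f"n = {len(seqs)}, true expansion: tau=5, theta0=0.5, theta1=50")
    print(
        f"fitted: tau={fit.params['tau']:.2f}, theta0={fit.params['theta0']:.3g}, "
        f"theta1={fit.params['theta1']:.3g}"
    )
    print(
        f"SSD={fit.ssd:.4f} (p={fit.p_ssd:.3f}), "
        f"raggedness={fit.raggedness:.4f} (p={fit.p_rg:.3f}) "
        f"[large p = expansion model not rejected]"
    )
    print(f"dated expansion: {date.t_years:,.0f} years before present")

    published = date_expansion(6.74, L=640)
    print(
        f"\npublished-tau check: tau=6.74 on 640 nt -> "
        f"{published.t_years:,.0f} years BP (~160,000 expected)"
    )


if __name__ == "__main__":
    main()
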