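"""Distance models: closed forms, the constrained-GTR ML distance, matrices."""

import math
import subprocess
import textwrap

import numpy as np
import pytest

from barcodegap.alignment_io import collapse_haplotypes
from barcodegap.distances import (
    DistanceError,
    JC_CLASSES,
    TIM3_CLASSES,
    apply_rate_classes,
    distance_matrix,
    estimate_exchangeabilities,
    gtr_i_distance,
    jc69_distance,
    k2p_distance,
    p_distance,
    pairwise_distance,
    proportion_invariant,
    tn93_distance,
)
from barcodegap.simulate import SimConfig, simulate_species_complex
from tests.conftest import make_alignment


class TestClosedForms:
    @pytest.mark.parametrize("model", ["p", "jc69", "k2p", "tn93"])
    def test_identical_sequences_distance_zero(self, model):
        assert pairwise_distance("ACGTACGT", "ACGTACGT", model) == 0.0

    def test_p_distance_example(self):
        assert p_distance("ACGT", "ACGA") == pytest.approx(0.25)

    def test_jc69_at_quarter_divergence(self):
        a = "A" * 75 + "C" * 25
        b = "A" * 75 + "G" * 25
        assert jc69_distance(a, b) == pytest.approx(-0.75 * math.log(2 / 3), abs=1e-10)

    def test_jc69_small_p_limit(self):
        # JC correction vanishes as p -> 0
        a = "A" * 10000
        b = "G" + "A" * 9999  # p = 1e-4
        assert jc69_distance(a, b) == pytest.approx(1e-4, abs=1e-6)

    def test_saturation_reported_missing(self):
        a = "A" * 100
        b = "C" * 80 + "A" * 20  # p = 0.8 > 3/4
        assert math.isnan(jc69_distance(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DistanceError):
            p_distance("ACGT", "ACG")

    def test_corrected_distances_exceed_p(self, rng, random_pair):
        for _ in range(20):
            a, b = random_pair(rng, n_sub=int(rng.integers(5, 100)))
            p = p_distance(a, b)
            for model in ("jc69", "k2p", "tn93"):
                d = pairwise_distance(a, b, model)
                if not math.isnan(d):
                    assert d >= p - 1e-12

    def test_ambiguity_sites_excluded(self):
        # N and R sites drop out pairwise; only the final site differs
        a = "NACGTA"
        b = "AACGRT"
        assert p_distance(a, b) == pytest.approx(1 / 4)


class TestAgainstIndependentOracles:
    def test_k2p_hand_formula(self, rng, random_pair):
        """K2P from an independently coded textbook evaluation."""
        for _ in range(25):
            a, b = random_pair(rng, n_sub=int(rng.integers(2, 120)))
            transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
            n = len(a)
            P = sum(1 for x, y in zip(a, b) if x != y and transition[x] == y) / n
            Q = sum(
                1 for x, y in zip(a, b) if x != y and transition[x] != y
            ) / n
            expected = -0.5 * math.log(
                (1 - 2 * P - Q) * math.sqrt(1 - 2 * Q)
            )
            assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-9)

    def test_jc_k2p_match_r_ape(self, rng, random_pair, tmp_path):
        """ape::dist.dna as an external oracle for JC69 and K2P."""
        pairs = [random_pair(rng, length=400, n_sub=int(rng.integers(5, 60)))
                 for _ in range(3)]
        fasta = tmp_path / "pairs.fasta"
        with open(fasta, "w") as fh:
            for i, (a, b) in enumerate(pairs):
                fh.write(f">a{i}\n{a}\n>b{i}\n{b}\n")
        script = tmp_path / "dist.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(ape))
            aln <- read.dna("{fasta}", format="fasta")
            for (i in 0:2) {{
                sub <- aln[c(sprintf("a%d", i), sprintf("b%d", i)), ]
                cat(sprintf("%.10f %.10f\\n",
                    dist.dna(sub, model="JC69")[1],
                    dist.dna(sub, model="K80")[1]))
            }}
        """))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        ).stdout.split()
        for i, (a, b) in enumerate(pairs):
            r_jc, r_k2p = float(out[2 * i]), float(out[2 * i + 1])
            assert jc69_distance(a, b) == pytest.approx(r_jc, abs=1e-6)
            assert k2p_distance(a, b) == pytest.approx(r_k2p, abs=1e-6)

    def test_tn93_high_precision_recomputation(self, rng, random_pair):
        """TN93 against a from-scratch mpmath-style recount in the test."""
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for _ in range(15):
            a, b = random_pair(rng, n_sub=int(rng.integers(4, 80)))
            n = len(a)
            counts = {c: 0.0 for c in "ACGT"}
            for s in (a, b):
                for c in s:
                    counts[c] += 1
            freq = {c: counts[c] / (2 * n) for c in "ACGT"}
            gr, gy = freq["A"] + freq["G"], freq["C"] + freq["T"]
            p1 = sum(1 for x, y in zip(a, b) if {x, y} == {"A", "G"}) / n
            p2 = sum(1 for x, y in zip(a, b) if {x, y} == {"C", "T"}) / n
            q = sum(
                1 for x, y in zip(a, b) if x != y and transition[x] != y
            ) / n
            k1 = 2 * freq["A"] * freq["G"] / gr
            k2 = 2 * freq["C"] * freq["T"] / gy
            k3 = 2 * (
                gr * gy
                - freq["A"] * freq["G"] * gy / gr
                - freq["C"] * freq["T"] * gr / gy
            )
            w1 = 1 - p1 / k1 - q / (2 * gr)
            w2 = 1 - p2 / k2 - q / (2 * gy)
            w3 = 1 - q / (2 * gr * gy)
            expected = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
            assert tn93_distance(a, b) == pytest.approx(expected, abs=1e-9)

    def test_gtr_with_jc_constraints_recovers_jc69(self, rng, random_pair):
        for _ in range(15):
            a, b = random_pair(rng, n_sub=int(rng.integers(2, 120)))
            d_jc = jc69_distance(a, b)
            d_gtr = gtr_i_distance(
                a, b, freqs=[0.25] * 4,
                rates=apply_rate_classes([1.0], JC_CLASSES), pinv=0.0,
            )
            assert d_gtr == pytest.approx(d_jc, abs=1e-4)


class TestDistanceMatrix:
    def test_zero_matrix_for_identical_haplotypes(self):
        aln = make_alignment(["ACGTACGT"] * 3)
        table = collapse_haplotypes(aln, min_len=8)
        with pytest.raises(DistanceError):
            distance_matrix(table)  # only one haplotype survives collapsing

    def test_symmetry_and_zero_diagonal(self):
        aln, _pm, _truth = simulate_species_complex(SimConfig(seed=21))
        table = collapse_haplotypes(aln)
        dm = distance_matrix(table, model="jc69")
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_between_cluster_exceeds_within(self):
        aln, _pm, truth = simulate_species_complex(SimConfig(seed=22))
        table = collapse_haplotypes(aln)
        dm = distance_matrix(table, model="jc69")
        species = {
            h: truth.species_of_sample[s]
            for s, h in table.membership.items()
        }
        within, between = [], []
        for i, hi in enumerate(dm.ids):
            for j in range(i + 1, len(dm.ids)):
                d = dm.values[i, j]
                (within if species[hi] == species[dm.ids[j]] else between).append(d)
        assert max(within) < min(between)

    def test_order_invariance(self):
        aln, _pm, _truth = simulate_species_complex(SimConfig(seed=23))
        table = collapse_haplotypes(aln)
        dm = distance_matrix(table, model="tn93")
        reversed_table = collapse_haplotypes(
            make_alignment(list(reversed(table.sequences)), prefix="r")
        )
        dm_rev = distance_matrix(reversed_table, model="tn93")
        for i, hi in enumerate(table.ids):
            for j, hj in enumerate(table.ids):
                si, sj = table.haplotypes[hi], table.haplotypes[hj]
                ri = reversed_table.ids[
                    reversed_table.sequences.index(si)
                ]
                rj = reversed_table.ids[
                    reversed_table.sequences.index(sj)
                ]
                assert dm.values[i, j] == pytest.approx(
                    dm_rev.get(ri, rj), abs=1e-12
                )

    def test_tim3i_matrix_runs_with_estimated_nuisances(self):
        aln, _pm, _truth = simulate_species_complex(SimConfig(seed=24))
        table = collapse_haplotypes(aln)
        dm = distance_matrix(table, model="tim3i")
        assert 0.0 <= dm.pinv < 1.0
        off = dm.upper_triangle()
        assert np.isfinite(off).all()
        assert (off > 0).all()

    def test_exchangeability_estimate_transition_biased(self):
        aln, _pm, _truth = simulate_species_complex(SimConfig(seed=25))
        table = collapse_haplotypes(aln)
        rates = estimate_exchangeabilities(table.sequences, TIM3_CLASSES)
        # AG and CT exchangeabilities should dominate under kappa = 8
        assert rates[1] > rates[0] and rates[4] > rates[0]

    def test_proportion_invariant_counts_constant_columns(self):
        seqs = ["AAGT", "AAGA", "AACT"]
        assert proportion_invariant(seqs) == pytest.approx(0.5)
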