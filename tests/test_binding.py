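"""TF-binding specificity, annotation, PWM scanning and enrichment tests."""

import math

import numpy as np
import pandas as pd
import pytest

from chromdyn.binding import (
    AnnotationSet,
    assign_peaks_to_genes,
    condition_specific_peaks,
    genomic_distribution,
    hypergeom_upper_tail,
    motif_enrichment,
    motif_enrichment_table,
    overlap_enrichment_test,
    promoter_windows,
    reverse_complement,
    scan_pwm,
)
from chromdyn.intervals import GenomicInterval, PeakSet, intervals_from_coords
from chromdyn.io import PWM
from chromdyn.simulate import SimConfig, default_pwm, simulate_annotation_and_binding


def hypergeom_tail_by_summation(k, n_draws, k_total, population):
    """Explicit mass-function summation (independent oracle)."""
    total = 0.0
    for x in range(k, min(n_draws, k_total) + 1):
        total += (
            math.comb(k_total, x)
            * math.comb(population - k_total, n_draws - x)
        )
    return total / math.comb(population, n_draws)


class TestConditionSpecific:
    def test_empty_b_makes_everything_a_specific(self):
        a = intervals_from_coords([("chr1", 0, 10), ("chr1", 50, 60)])
        split = condition_specific_peaks(a, PeakSet("b"))
        assert len(split["a_specific"]) == 2
        assert len(split["shared"]) == 0

    def test_identical_sets_have_no_specific_peaks(self):
        a = intervals_from_coords([("chr1", 0, 10), ("chr1", 50, 60)])
        split = condition_specific_peaks(a, a)
        assert len(split["a_specific"]) == 0
        assert len(split["b_specific"]) == 0
        assert len(split["shared"]) == 2

    def test_partition_is_exact_from_a_side(self, small_sim):
        sim = simulate_annotation_and_binding(small_sim)
        split = condition_specific_peaks(sim.tf_a, sim.tf_b)
        assert len(split["a_specific"]) + len(split["shared"]) == len(sim.tf_a)

    def test_nested_fixture_recovers_planted_counts(self, small_sim):
        sim = simulate_annotation_and_binding(small_sim)
        split = condition_specific_peaks(sim.tf_a, sim.tf_b)
        assert len(split["b_specific"]) == 0  # B is a subset of A
        planted = (~sim.truth.shared_with_b).sum()
        assert len(split["a_specific"]) == planted


class TestGenomicDistribution:
    def test_all_peaks_in_promoters(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "tss": [5_000], "strand": ["+"]}
        )
        ann = AnnotationSet.from_genes(genes, PeakSet("enh"), window=2_000)
        peaks = intervals_from_coords([("chr1", 4_900, 5_100)] * 3)
        dist = genomic_distribution(peaks, ann)
        assert dist["frac_promoter"] == 1.0
        assert dist["percent_promoter_or_enhancer"] == 100.0

    def test_planted_category_split_recovered_exactly(self, small_sim):
        sim = simulate_annotation_and_binding(small_sim)
        split = condition_specific_peaks(sim.tf_a, sim.tf_b)
        ann = AnnotationSet.from_genes(sim.genes, sim.enhancers,
                                       small_sim.promoter_window)
        dist = genomic_distribution(split["a_specific"], ann)
        planted = sim.truth.loc[~sim.truth.shared_with_b, "category"]
        assert dist["n_promoter"] == (planted == "promoter").sum()
        assert dist["n_enhancer"] == (planted == "enhancer").sum()
        assert dist["n_intergenic"] == (planted == "intergenic").sum()


class TestAssignPeaksToGenes:
    GENES = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["chr1", "chr1"],
            "tss": [10_000, 30_000],
            "strand": ["+", "-"],
        }
    )

    def _ann(self, window=2_000):
        return AnnotationSet.from_genes(self.GENES, PeakSet("enh"), window)

    def test_promoter_overlap_maps_to_that_gene(self):
        peaks = intervals_from_coords([("chr1", 9_500, 9_700)])
        mapping, targets = assign_peaks_to_genes(peaks, self.GENES, self._ann())
        assert mapping == {0: "gA"}
        assert targets == {"gA"}

    def test_equidistant_tie_breaks_lexicographically(self):
        peaks = intervals_from_coords([("chr1", 19_950, 20_050)])  # midway
        mapping, _ = assign_peaks_to_genes(peaks, self.GENES, self._ann())
        assert mapping == {0: "gA"}

    def test_peak_beyond_max_dist_unassigned(self):
        peaks = intervals_from_coords([("chr1", 500_000, 500_100)])
        mapping, _ = assign_peaks_to_genes(peaks, self.GENES, self._ann(),
                                           max_dist=100_000)
        assert mapping == {}

    def test_agrees_with_brute_force_nearest_tss(self, rng):
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in range(40)],
                "chrom": ["chr1"] * 40,
                "tss": sorted(int(x) for x in rng.integers(0, 400_000, 40)),
                "strand": ["+"] * 40,
            }
        ).drop_duplicates("tss")
        window, max_dist = 1_000, 50_000
        ann = AnnotationSet.from_genes(genes, PeakSet("enh"), window)
        starts = rng.integers(0, 400_000, 200)
        peaks = intervals_from_coords([("chr1", int(s), int(s) + 150) for s in starts])

        def dist(iv, tss):
            return max(iv.start - tss, tss - (iv.end - 1), 0)

        expected = {}
        for i, iv in enumerate(peaks):
            prom = [
                (dist(iv, int(g.tss)), g.gene_id)
                for g in genes.itertuples()
                if iv.overlap_length(
                    GenomicInterval(g.chrom, max(0, g.tss - window), g.tss + window + 1)
                ) >= 1
            ]
            if prom:
                expected[i] = min(prom)[1]
                continue
            near = min(
                ((dist(iv, int(g.tss)), g.gene_id) for g in genes.itertuples()),
            )
            if near[0] <= max_dist:
                expected[i] = near[1]
        mapping, _ = assign_peaks_to_genes(peaks, genes, ann, max_dist)
        assert mapping == expected


class TestScanPwm:
    def test_consensus_scores_exactly_max(self):
        pwm = default_pwm()
        hits = scan_pwm(pwm.consensus, pwm, frac_of_max=1.0)
        assert (0, "+") in hits
        assert all(strand == "+" for _, strand in hits) or len(hits) == 1

    def test_all_n_sequence_has_no_hits(self):
        pwm = default_pwm()
        assert scan_pwm("N" * 50, pwm) == []

    def test_strand_symmetry(self):
        pwm = default_pwm()
        seq = "TTTT" + pwm.consensus + "AAAACCGG"
        fwd = scan_pwm(seq, pwm, 0.9)
        rev = scan_pwm(reverse_complement(seq), pwm, 0.9)
        flipped = sorted(
            (len(seq) - len(pwm) - pos, {"+": "-", "-": "+"}[st]) for pos, st in rev
        )
        assert flipped == fwd

    def test_agrees_with_per_offset_rescoring(self, rng):
        pwm = default_pwm(strength=0.7)
        lom = np.log2(pwm.probs / pwm.background)
        threshold = 0.8 * pwm.max_score()
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

        def brute(seq):
            out = []
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                for off in range(len(s) - len(pwm) + 1):
                    window = s[off : off + len(pwm)]
                    if "N" in window:
                        continue
                    score = sum(lom[j, base_idx[b]] for j, b in enumerate(window))
                    if score >= threshold - 1e-9:
                        pos = off if strand == "+" else len(s) - len(pwm) - off
                        out.append((pos, strand))
            return sorted(out)

        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            assert scan_pwm(seq, pwm, 0.8) == brute(seq)


class TestEnrichment:
    def test_hand_checkable_extreme_case(self):
        pwm = default_pwm()
        target = ["TT" + pwm.consensus + "GG"] * 10
        background = ["A" * 20] * 10
        res = motif_enrichment(target, background, pwm)
        assert (res["k_t"], res["k_b"]) == (10, 0)
        assert res["p"] == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_equal_rates_are_not_enriched(self):
        pwm = default_pwm()
        hit, miss = "AA" + pwm.consensus, "A" * 10
        res = motif_enrichment([hit, miss] * 5, [hit, miss] * 5, pwm)
        assert res["p"] >= 0.5

    def test_tail_matches_explicit_summation(self, rng):
        for _ in range(200):
            population = int(rng.integers(2, 500))
            k_total = int(rng.integers(0, population + 1))
            n_draws = int(rng.integers(1, population + 1))
            lo = max(0, n_draws + k_total - population)
            k = int(rng.integers(lo, min(n_draws, k_total) + 1))
            assert hypergeom_upper_tail(k, n_draws, k_total, population) == (
                pytest.approx(
                    hypergeom_tail_by_summation(k, n_draws, k_total, population),
                    rel=1e-9, abs=1e-300,
                )
            )

    def test_planted_motif_simulation_is_strongly_enriched(self, small_sim):
        from chromdyn.io import extract_sequences

        sim = simulate_annotation_and_binding(small_sim)
        targets = extract_sequences(sim.fasta, sim.tf_a)
        background = extract_sequences(sim.fasta, sim.background)
        res = motif_enrichment(targets, background, sim.pwm)
        assert res["p"] < 1e-10

    def test_bh_correction_bounded_and_ordered(self):
        pwm_hit = default_pwm()
        pwm_other = PWM("other", np.array([[0.05, 0.85, 0.05, 0.05]] * 8))
        target = ["TT" + pwm_hit.consensus + "GG"] * 20
        background = ["A" * 20] * 20
        table = motif_enrichment_table(target, background, [pwm_hit, pwm_other])
        assert ((table["q"] >= table["p"] - 1e-12) & (table["q"] <= 1)).all()


class TestOverlapEnrichment:
    def test_disjoint_cover_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        res = overlap_enrichment_test(a, universe - a, universe)
        assert res["n_overlap"] == 0
        assert res["p"] == pytest.approx(1.0)

    def test_subset_validation(self):
        with pytest.raises(ValueError):
            overlap_enrichment_test({"x"}, {"y"}, {"y"})

    def test_matches_summation_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(30)}
        b = {f"g{i}" for i in range(20, 60)}
        res = overlap_enrichment_test(a, b, universe)
        assert res["p"] == pytest.approx(
            hypergeom_tail_by_summation(res["n_overlap"], 30, 40, 100), rel=1e-9
        )
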