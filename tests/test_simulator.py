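"""RAD read simulator: sites, tags, diploidization, reads, synthetic genomes."""

import numpy as np
import pytest

from radml.depth_model import DepthModelSpec, DepthObservations, ks_fitness
from radml.simulate import (MotifError, SimConfig, SyntheticGenomeConfig,
                            diploidize, extract_tags, find_restriction_sites,
                            make_synthetic_genome, parse_read_locus,
                            sample_reads, simulate_reads)


class TestRestrictionSites:
    def test_by_inspection(self):
        assert find_restriction_sites({"s": "GAATTCAAGAATTC"}, "GAATTC") == {"s": [0, 8]}

    def test_absent_motif(self):
        assert find_restriction_sites({"s": "AAAA"}, "GAATTC") == {"s": []}

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(MotifError):
            find_restriction_sites({"s": "ACGT"}, "GANTC")

    def test_matches_naive_scan_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        motif = "GAATTC"
        expected = [i for i in range(len(seq) - len(motif) + 1)
                    if seq[i: i + len(motif)] == motif]
        assert find_restriction_sites({"s": seq}, motif)["s"] == expected


class TestExtractTags:
    def test_centered_site_yields_both_flanks(self):
        seq = "A" * 50 + "GAATTC" + "T" * 50
        tags = extract_tags({"s": seq}, {"s": [50]}, read_length=35)
        assert len(tags) == 2
        strands = {t.strand for t in tags}
        assert strands == {"+", "-"}
        fwd = next(t for t in tags if t.strand == "+")
        assert fwd.sequence.startswith("GAATTC") and len(fwd.sequence) == 35
        rev = next(t for t in tags if t.strand == "-")
        assert rev.sequence.startswith("GAATTC")  # palindromic motif

    def test_truncated_flank_dropped(self):
        seq = "A" * 4 + "GAATTC" + "T" * 50   # site 4 bp from the start
        tags = extract_tags({"s": seq}, {"s": [4]}, read_length=35)
        assert len(tags) == 1 and tags[0].strand == "+"

    def test_tag_count_arithmetic_on_random_genome(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        motif = "GAATTC"
        sites = find_restriction_sites({"s": seq}, motif)
        L = 35
        expected = sum((s + L <= len(seq)) + (s + len(motif) - L >= 0)
                       for s in sites["s"])
        tags = extract_tags({"s": seq}, sites, read_length=L)
        assert len(tags) == expected
        # coordinates round-trip: every tag window has the stated length
        assert all(t.end - t.start == L for t in tags)


class TestDiploidize:
    def _tags(self, rng, n, L=35):
        seq = "".join(rng.choice(list("ACGT"), size=n * L))
        return extract_tags({"s": seq}, {"s": list(range(0, n * L - L, L))},
                            read_length=L, both_flanks=False)

    def test_zero_rate_all_homozygous(self, rng):
        loci, truth = diploidize(self._tags(rng, 50), 0.0, rng)
        assert all(d.allele1 == d.allele2 for d in loci)
        assert truth.snp_set() == set()

    def test_rate_one_every_position_heterozygous(self, rng):
        loci, _ = diploidize(self._tags(rng, 10), 1.0, rng)
        assert all(a != b for d in loci
                   for a, b in zip(d.allele1, d.allele2))

    def test_het_fraction_within_three_binomial_sd(self, rng):
        tags = self._tags(rng, 10_000)
        loci, truth = diploidize(tags, 0.005, rng)
        n_pos = sum(len(t.sequence) for t in tags)
        frac = len(truth.snp_set()) / n_pos
        sd = np.sqrt(0.005 * 0.995 / n_pos)
        assert abs(frac - 0.005) < 3 * sd


class TestSampleReads:
    def _diploid(self, rng, n_loci=200, L=35, snp_rate=0.005):
        seq = "".join(rng.choice(list("ACGT"), size=n_loci * L))
        tags = extract_tags({"s": seq}, {"s": list(range(0, n_loci * L - L, L))},
                            read_length=L, both_flanks=False)
        return diploidize(tags, snp_rate, rng)

    def test_error_free_reads_equal_alleles(self, rng):
        loci, _ = self._diploid(rng, 50)
        cfg = SimConfig(mean_error_rate=0.0, mean_depth=20)
        reads = sample_reads(loci, cfg, rng)
        alleles = {(d.locus.locus_id, k): s for d in loci
                   for k, s in ((1, d.allele1), (2, d.allele2))}
        for r in reads:
            locus, rest = r.id[1:].split("|", 1)
            k = int(rest.split("|")[0][1:])
            assert r.sequence == alleles[(int(locus), k)]

    def test_mean_depth_within_three_sd(self, rng):
        loci, _ = self._diploid(rng, 5000, snp_rate=0.0)
        cfg = SimConfig(mean_error_rate=0.0, mean_depth=30)
        reads = sample_reads(loci, cfg, rng)
        mean = len(reads) / len(loci)
        sd = np.sqrt(30 / len(loci))
        assert abs(mean - 30) < 3 * sd

    def test_error_rate_mean_and_linear_ramp(self, rng):
        loci, _ = self._diploid(rng, 500, L=100, snp_rate=0.0)
        cfg = SimConfig(read_length=100, mean_error_rate=0.01, mean_depth=30)
        reads = sample_reads(loci, cfg, rng)
        alleles = {d.locus.locus_id: d.allele1 for d in loci}
        mis = np.zeros(100)
        n_reads = len(reads)
        for r in reads:
            truth_seq = alleles[parse_read_locus(r.id)]
            mis += np.frombuffer(r.sequence.encode(), np.uint8) != \
                   np.frombuffer(truth_seq.encode(), np.uint8)
        rate = mis.sum() / (n_reads * 100)
        sd = np.sqrt(0.01 * 0.99 / (n_reads * 100))
        assert abs(rate - 0.01) < 3 * sd
        # linear ramp: second half of the read carries ~3x the first half's errors
        first, second = mis[:50].sum(), mis[50:].sum()
        assert second > 2 * first
        assert mis[:5].sum() < 0.02 * second  # near-zero at the read start


class TestSyntheticGenome:
    def test_zero_repeat_fraction_empty_annotation(self):
        cfg = SyntheticGenomeConfig(genome_length=10_000, repeat_fraction=0.0, seed=1)
        genome, ann = make_synthetic_genome(cfg)
        assert ann == [] and len(genome["synthetic_1"]) == 10_000

    def test_realized_repeat_fraction_close_to_target(self):
        cfg = SyntheticGenomeConfig(genome_length=2_000_000, repeat_fraction=0.35,
                                    seed=2)
        genome, ann = make_synthetic_genome(cfg)
        realized = sum(c.end - c.start for c in ann) / len(genome["synthetic_1"])
        assert abs(realized - 0.35) < 0.02

    def test_zero_divergence_copies_identical(self):
        cfg = SyntheticGenomeConfig(genome_length=100_000, repeat_fraction=0.2,
                                    repeat_divergence=0.0, seed=3)
        genome, ann = make_synthetic_genome(cfg)
        seq = genome["synthetic_1"]
        by_family = {}
        for c in ann:
            by_family.setdefault(c.family_id, []).append(seq[c.start:c.end])
        for copies in by_family.values():
            assert len(set(copies)) == 1

    def test_annotation_coordinates_match_planted_motif(self):
        cfg = SyntheticGenomeConfig(genome_length=200_000, repeat_fraction=0.2, seed=4)
        genome, ann = make_synthetic_genome(cfg)
        seq = genome["synthetic_1"]
        for c in ann:
            centre = c.start + cfg.template_length // 2 - len(cfg.motif) // 2
            assert seq[centre: centre + len(cfg.motif)] == cfg.motif


class TestReproducibilityAndTruth:
    def test_same_seed_identical_output(self):
        cfg = SyntheticGenomeConfig(genome_length=100_000, repeat_fraction=0.2, seed=7)
        genome, ann = make_synthetic_genome(cfg)
        sim = SimConfig(seed=9, mean_depth=15)
        r1, t1 = simulate_reads(genome, sim, ann)
        r2, t2 = simulate_reads(genome, sim, ann)
        assert [(a.id, a.sequence) for a in r1] == [(b.id, b.sequence) for b in r2]
        assert t1.snp_set() == t2.snp_set()

    def test_every_read_resolves_to_one_truth_locus(self):
        cfg = SyntheticGenomeConfig(genome_length=50_000, repeat_fraction=0.1, seed=5)
        genome, ann = make_synthetic_genome(cfg)
        reads, truth = simulate_reads(genome, SimConfig(seed=5, mean_depth=10), ann)
        ids = {d.locus.locus_id for d in truth.loci}
        assert all(parse_read_locus(r.id) in ids for r in reads)

    def test_truth_table_tsv_roundtrip(self, tmp_path):
        cfg = SyntheticGenomeConfig(genome_length=50_000, repeat_fraction=0.1, seed=5)
        genome, ann = make_synthetic_genome(cfg)
        _, truth = simulate_reads(genome, SimConfig(seed=5, mean_depth=10), ann)
        path = tmp_path / "truth.tsv"
        truth.to_tsv(path)
        back = truth.from_tsv(path)
        assert back.snp_set() == truth.snp_set()
        assert {d.locus.copy_number for d in back.loci} == \
               {d.locus.copy_number for d in truth.loci}

    def test_locus_depths_fit_poisson_without_repeats(self, rng):
        """Read counts per truth locus follow Poisson(C) when repeats are absent."""
        seq = "".join(rng.choice(list("ACGT"), size=500_000))
        genome = {"s": seq}
        reads, truth = simulate_reads(genome, SimConfig(seed=11, mean_depth=30,
                                                        snp_rate=0.0))
        counts = {}
        for r in reads:
            counts[parse_read_locus(r.id)] = counts.get(parse_read_locus(r.id), 0) + 1
        depths = np.array([c for c in counts.values()])
        model = DepthModelSpec("poisson", 30.0, np.array([1.0]))
        assert ks_fitness(DepthObservations(depths), model).p_value > 0.01
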