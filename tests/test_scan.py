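import numpy as np
import pytest

from editscan import (
    DistanceParams,
    KernelParams,
    MotifModel,
    enumerate_candidates,
    extract_context,
    seed_match,
    train_binary,
    train_one_class,
    two_stage_scan,
    write_hits,
)
from editscan.exceptions import ParameterError
from editscan.io import revcomp
from editscan.scan import read_hits_tsv
from editscan.synthetic import generate_genome, plant_sites

from conftest import random_context, random_dna

DP = DistanceParams(w=0.5, l1=21, l2=11)
KP = KernelParams(gamma=0.1)


class TestEnumerateCandidates:
    def test_single_plus_candidate(self):
        out = list(enumerate_candidates({"c": "CCACC"}, 5))
        assert len(out) == 1
        site, ctx = out[0]
        assert (site.chrom, site.pos, site.strand) == ("c", 3, "+")
        assert ctx.seq == "CCACC"

    def test_single_minus_candidate(self):
        out = list(enumerate_candidates({"c": "CCTCC"}, 5))
        assert len(out) == 1
        site, ctx = out[0]
        assert site.strand == "-"
        assert ctx.seq == revcomp("CCTCC") == "GGAGG"

    def test_count_matches_composition(self, rng):
        contig = random_dna(rng, 20_000)
        out = list(enumerate_candidates({"c": contig}, 21))
        usable = contig[10:-10]
        expect = usable.count("A") + usable.count("T")
        assert len(out) == expect

    def test_every_candidate_reextracts(self, rng):
        contig = random_dna(rng, 2_000)
        genome = {"c": contig}
        for site, ctx in list(enumerate_candidates(genome, 21))[:200]:
            assert extract_context(genome, site, 10).seq == ctx.seq

    def test_even_length_errors(self):
        with pytest.raises(ParameterError):
            list(enumerate_candidates({"c": "ACGT"}, 4))


class TestSeedMatch:
    def _genome_with_seed(self, rng, seed_seq, strand="+"):
        contig = list(random_dna(rng, 3_000))
        placed = seed_seq if strand == "+" else revcomp(seed_seq)
        start = 1_500
        contig[start : start + len(seed_seq)] = placed
        return {"c": "".join(contig)}, start

    def test_exact_recovery(self, rng):
        seed = random_context(rng, 21)
        genome, start = self._genome_with_seed(rng, seed)
        hits = seed_match([seed], genome, max_mismatch=0)
        centers = {(h.chrom, h.pos, h.strand) for h in hits}
        assert ("c", start + 11, "+") in centers
        assert all(h.mismatches == 0 for h in hits)

    def test_exact_recovery_minus_strand(self, rng):
        seed = random_context(rng, 21)
        genome, start = self._genome_with_seed(rng, seed, strand="-")
        hits = seed_match([seed], genome, max_mismatch=0)
        match = [h for h in hits if h.pos == start + 11]
        assert match and match[0].strand == "-"
        assert match[0].context.seq == seed

    def test_three_substitutions_found_at_3_not_2(self, rng):
        seed = random_context(rng, 21)
        mutated = list(seed)
        for i in (1, 5, 17):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        genome, start = self._genome_with_seed(rng, "".join(mutated))
        hits3 = seed_match([seed], genome, max_mismatch=3)
        hits2 = seed_match([seed], genome, max_mismatch=2)
        assert any(h.pos == start + 11 and h.mismatches == 3 for h in hits3)
        assert not any(h.pos == start + 11 for h in hits2)

    def test_mismatch_budget_monotonic(self, rng):
        seeds = [random_context(rng, 21) for _ in range(3)]
        genome = {"c": random_dna(rng, 5_000)}
        prev: set = set()
        for k in range(4):
            hits = {(h.chrom, h.pos, h.strand) for h in
                    seed_match(seeds, genome, max_mismatch=k)}
            assert prev <= hits
            prev = hits

    def test_best_seed_wins_merge(self, rng):
        target = random_context(rng, 21)
        near = list(target)
        near[0] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[0]]
        genome, start = self._genome_with_seed(rng, target)
        # seed 0 is one mismatch away, seed 1 is exact: exact must win
        hits = seed_match(["".join(near), target], genome, max_mismatch=3)
        hit = [h for h in hits if h.pos == start + 11 and h.strand == "+"][0]
        assert hit.seed_id == 1 and hit.mismatches == 0

    def test_coordinate_correctness_reextraction(self, rng):
        seeds = [random_context(rng, 21) for _ in range(2)]
        genome = {"c": random_dna(rng, 4_000)}
        for h in seed_match(seeds, genome, max_mismatch=3):
            assert extract_context(genome, h.site, 10).seq == h.context.seq \
                or h.context.center != "A"  # non-adenine centers cannot re-extract

    def test_max_mismatch_validation(self, rng):
        with pytest.raises(ParameterError):
            seed_match([random_context(rng, 21)], {"c": "ACGT" * 10},
                       max_mismatch=4)


@pytest.fixture(scope="module")
def trained_models():
    rng = np.random.default_rng(0)
    motif = MotifModel(random_context(rng, 21), 0.05)
    pos = [motif.sample(rng) for _ in range(60)]
    neg = [random_dna(rng, 21) for _ in range(60)]
    oneclass = train_one_class(pos, DP, KP, nu=0.1)
    binary = train_binary(pos, neg, DP, KP)
    return motif, pos, oneclass, binary


class TestTwoStageScan:
    def test_training_sequence_passes_stage_one(self, trained_models):
        from editscan.contexts import ContextSequence, GenomicSite

        motif, pos, oneclass, binary = trained_models
        cands = [(GenomicSite("c", i + 11, "+"), ContextSequence(s))
                 for i, s in enumerate(pos)]
        hits = two_stage_scan(cands, oneclass, binary)
        assert len(hits) >= 0.8 * len(pos)
        assert all(h.oneclass_pass for h in hits)

    def test_random_contexts_mostly_rejected(self, trained_models):
        from editscan.contexts import ContextSequence, GenomicSite

        rng = np.random.default_rng(5)
        motif, pos, oneclass, binary = trained_models
        cands = [(GenomicSite("c", i + 11, "+"), ContextSequence(random_dna(rng, 21)))
                 for i in range(200)]
        hits = two_stage_scan(cands, oneclass, binary)
        n_positive = sum(h.binary_label == 1 for h in hits)
        assert n_positive < 0.5 * len(cands)

    def test_empty_candidates(self, trained_models):
        _, _, oneclass, binary = trained_models
        assert two_stage_scan([], oneclass, binary) == []

    def test_parameter_mismatch_errors(self, trained_models):
        motif, pos, oneclass, _ = trained_models
        rng = np.random.default_rng(1)
        other_dp = DistanceParams(w=0.2, l1=21, l2=11)
        binary_other = train_binary(pos[:20], [random_dna(rng, 21) for _ in range(20)],
                                    other_dp, KP)
        with pytest.raises(ParameterError):
            two_stage_scan([], oneclass, binary_other)

    def test_model_order_enforced(self, trained_models):
        _, _, oneclass, binary = trained_models
        with pytest.raises(ParameterError):
            two_stage_scan([], binary, oneclass)

    def test_output_subset_of_candidates(self, trained_models, rng):
        motif, pos, oneclass, binary = trained_models
        genome = generate_genome(3_000, seed=8)
        genome, _ = plant_sites(genome, motif, 10, seed=9)
        cands = list(enumerate_candidates(genome, 21))
        keys = {(s.chrom, s.pos, s.strand) for s, _ in cands}
        hits = two_stage_scan(cands, oneclass, binary)
        assert {(h.chrom, h.pos, h.strand) for h in hits} <= keys

    def test_planted_recall_beats_background(self, trained_models):
        motif, pos, oneclass, binary = trained_models
        genome = generate_genome(20_000, seed=12)
        genome, truth = plant_sites(genome, motif, 30, seed=13)
        cands = list(enumerate_candidates(genome, 21))
        hits = two_stage_scan(cands, oneclass, binary)
        called = {(h.chrom, h.pos, h.strand) for h in hits if h.binary_label == 1}
        truth_keys = {(s.chrom, s.pos, s.strand) for s in truth}
        recall = len(called & truth_keys) / len(truth_keys)
        background_rate = len(called - truth_keys) / (len(cands) - len(truth_keys))
        # the one-class pre-filter (nu=0.1) alone drops ~10% of motif-like
        # candidates, so recall is bounded near 0.9 by construction
        assert recall > 0.6
        assert recall > 10 * background_rate


class TestWriteHits:
    def test_tsv_roundtrip_and_ordering(self, trained_models, tmp_path, rng):
        motif, pos, oneclass, binary = trained_models
        genome = generate_genome(4_000, seed=20)
        genome, _ = plant_sites(genome, motif, 10, seed=21)
        hits = two_stage_scan(list(enumerate_candidates(genome, 21)),
                              oneclass, binary)
        assert hits
        path = tmp_path / "hits.tsv"
        write_hits(hits, path, format="tsv")
        back = read_hits_tsv(path)
        keys = [(h.chrom, h.pos, h.strand) for h in back]
        assert keys == sorted(keys)
        assert {(h.chrom, h.pos, h.strand, h.context.seq, h.binary_label)
                for h in back} == \
            {(h.chrom, h.pos, h.strand, h.context.seq, h.binary_label)
             for h in hits}

    def test_bed_zero_based_and_scores_in_range(self, trained_models, tmp_path):
        motif, pos, oneclass, binary = trained_models
        genome = generate_genome(4_000, seed=22)
        genome, _ = plant_sites(genome, motif, 10, seed=23)
        hits = two_stage_scan(list(enumerate_candidates(genome, 21)),
                              oneclass, binary)
        path = tmp_path / "hits.bed"
        write_hits(hits, path, format="bed")
        for line in path.read_text().splitlines():
            chrom, start, end, name, score, strand = line.split("\t")
            assert int(end) - int(start) == 1
            assert 0 <= int(score) <= 1000
            assert strand in "+-"

    def test_bad_format_errors(self, tmp_path):
        with pytest.raises(ParameterError):
            write_hits([], tmp_path / "x", format="gff")
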