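"""Discovery: seed counting, extension, filtering, redundancy, classing."""

import dataclasses

import numpy as np
import pytest

from tedyn import (
    DiscoveryConfig,
    SimConfig,
    TEFamily,
    build_family_set,
    classify_family,
    count_seeds,
    discover_families,
    extend_seed,
    filter_candidates,
    merge_redundant,
    simulate_two_lineages,
)
from tedyn._seq import random_seq, revcomp
from tedyn.discovery import Candidate, alignment_identity
from tedyn.errors import ConfigError

CFG = DiscoveryConfig()


def plant(rng, background_len, element, n_copies, mutate=0.0):
    """Random genome with n copies of an element planted non-overlapping."""
    gaps = background_len // (n_copies + 1)
    pieces = []
    for i in range(n_copies):
        pieces.append(random_seq(rng, gaps))
        copy = list(element)
        if mutate:
            for j in range(len(copy)):
                if rng.random() < mutate:
                    copy[j] = "ACGT"[(("ACGT".index(copy[j])) + rng.integers(1, 4)) % 4]
        pieces.append("".join(copy))
    pieces.append(random_seq(rng, gaps))
    return "".join(pieces)


class TestCountSeeds:
    def test_homopolymer_sliding_window(self):
        cfg = dataclasses.replace(CFG, lmer_size=8, min_seed_count=2)
        out = count_seeds("A" * 13, cfg)
        assert out == [("A" * 8, 6)]

    def test_canonical_symmetry_doubles_counts(self, rng):
        g = random_seq(rng, 5_000)
        cfg = dataclasses.replace(CFG, min_seed_count=1)
        single = dict(count_seeds({"c1": g}, cfg))
        doubled = dict(count_seeds({"c1": g, "c2": revcomp(g)}, cfg))
        assert {k: 2 * v for k, v in single.items()} == doubled

    def test_planted_repeat_dominates(self, rng):
        element = random_seq(rng, 500)
        g = plant(rng, 100_000, element, 20)
        top, count = count_seeds(g, CFG)[0]
        assert count >= 20
        assert top in element or revcomp(top) in element

    def test_short_contig_warns_empty(self):
        with pytest.warns(UserWarning):
            assert count_seeds("ACGT", CFG) == []


class TestExtendSeed:
    def test_exact_copies_recovered(self, rng):
        element = random_seq(rng, 300)
        g = plant(rng, 30_000, element, 10)
        seed = element[100 : 100 + CFG.lmer_size]
        cand = extend_seed(seed, g, CFG)
        assert element in cand.consensus
        assert cand.support == 10

    def test_mutated_copies_majority_vote(self, rng):
        element = random_seq(rng, 300)
        g = plant(rng, 60_000, element, 20, mutate=0.05)
        seeds = count_seeds(g, CFG)
        # pick the best-counted seed that lies in the element
        seed = next(s for s, _ in seeds if s in element or revcomp(s) in element)
        cand = extend_seed(seed, g, CFG)
        assert alignment_identity(cand.consensus, element) >= 0.98

    def test_stop_rule_bounds_extension(self, rng):
        # a bare seed with random flanks: with enough occurrences the random
        # flank columns cannot reach majority support, so extension stops
        # within the patience budget on each side
        cfg = dataclasses.replace(CFG, min_seed_count=30)
        seed = random_seq(rng, cfg.lmer_size)
        g = plant(rng, 120_000, seed, 30)
        cand = extend_seed(seed, g, cfg)
        assert len(cand.consensus) < cfg.lmer_size + 2 * cfg.extension_stop_patience

    def test_too_few_occurrences_raises(self, rng):
        with pytest.raises(ConfigError):
            extend_seed("ACGTACGTACGTAC", random_seq(rng, 1000), CFG)


class TestFilters:
    def mk(self, seq, support=10):
        return Candidate(consensus=seq, seed=seq[:14], support=support)

    def test_tandem_removed(self):
        kept, log = filter_candidates([self.mk("AT" * 100)], CFG)
        assert kept == []
        assert log[0][1] in ("tandem", "low_complexity")

    def test_short_removed(self, rng):
        kept, log = filter_candidates([self.mk(random_seq(rng, 90))], CFG)
        assert kept == [] and log[0][1] == "length"

    def test_low_support_removed(self, rng):
        kept, log = filter_candidates([self.mk(random_seq(rng, 500), support=1)], CFG)
        assert kept == [] and log[0][1] == "support"

    def test_good_candidate_retained(self, rng):
        kept, log = filter_candidates([self.mk(random_seq(rng, 1000))], CFG)
        assert len(kept) == 1 and log == []

    def test_period_three_tandem_removed(self):
        kept, log = filter_candidates([self.mk("ACG" * 80)], CFG)
        assert kept == [] and log[0][1] == "tandem"


class TestMergeRedundant:
    def test_identical_dropped(self, rng):
        seq = random_seq(rng, 800)
        known = [TEFamily("RU0001", seq, "unknown", "known")]
        out = merge_redundant([TEFamily("CAND0000", seq)], known, CFG)
        assert [f.family_id for f in out] == ["RU0001"]

    def test_distant_retained(self, rng):
        known = [TEFamily("RU0001", random_seq(rng, 800), "unknown", "known")]
        out = merge_redundant([TEFamily("CAND0000", random_seq(rng, 800))], known, CFG)
        assert [f.family_id for f in out] == ["RU0001", "RS0001"]

    def test_exact_boundary_identity_retained(self, rng):
        # the redundancy rule is strictly "more than": a candidate whose best
        # identity to the known set EQUALS the threshold survives, and is
        # dropped as soon as the threshold moves below it
        base = random_seq(rng, 1000)
        cand = list(base[:100])
        for j in rng.choice(100, size=20, replace=False):
            cand[j] = "ACGT"[("ACGT".index(cand[j]) + 2) % 4]
        cand = "".join(cand)
        ident = alignment_identity(cand, base)
        assert 0.75 < ident < 0.85
        known = [TEFamily("RU0001", base, "unknown", "known")]
        at_threshold = dataclasses.replace(CFG, redundancy_identity=ident)
        assert len(merge_redundant([TEFamily("CAND0000", cand)], known, at_threshold)) == 2
        below = dataclasses.replace(CFG, redundancy_identity=ident - 1e-9)
        assert len(merge_redundant([TEFamily("CAND0000", cand)], known, below)) == 1

    def test_idempotent(self, rng):
        known = [TEFamily("RU0001", random_seq(rng, 800), "unknown", "known")]
        de_novo = [TEFamily(f"CAND{i:04d}", random_seq(rng, 600)) for i in range(3)]
        once = merge_redundant(de_novo, known, CFG)
        twice = merge_redundant([f for f in once if f.source == "de_novo"], known, CFG)
        assert [f.family_id for f in once] == [f.family_id for f in twice]
        assert [f.consensus for f in once] == [f.consensus for f in twice]


class TestClassify:
    def test_direct_terminal_repeats_ltr(self, rng):
        tr = random_seq(rng, 200)
        fam = TEFamily("X", tr + random_seq(rng, 600) + tr)
        assert classify_family(fam) == "LTR"

    def test_short_perfect_tir_dna(self, rng):
        tir = random_seq(rng, 30)
        fam = TEFamily("X", tir + random_seq(rng, 500) + revcomp(tir))
        assert classify_family(fam) == "DNA"

    def test_polya_non_ltr(self, rng):
        assert classify_family(TEFamily("X", random_seq(rng, 500) + "A" * 12)) == "non-LTR"

    def test_random_is_unknown(self, rng):
        calls = [classify_family(TEFamily("X", random_seq(rng, 1000))) for _ in range(100)]
        assert calls.count("unknown") >= 99


@pytest.fixture(scope="module")
def low_divergence_sim():
    cfg = SimConfig(
        seed=3,
        genome_length=800_000,
        n_families=8,
        insertion_rate_per_family=3.0,
        split_time=2.0,
        ancestral_depth=1.5,
        fragmentation_prob=0.15,
    )
    fams = build_family_set(cfg)
    return fams, simulate_two_lineages(fams, cfg)


class TestDiscoverFamilies:
    def test_recovery_on_simulated_genomes(self, low_divergence_sim):
        # >= 90% of true families represented at >= 90% identity
        fams, sim = low_divergence_sim
        lib, _ = discover_families([sim.genome_a, sim.genome_b], CFG, known=[])
        recovered = sum(
            max(alignment_identity(f.consensus, d.consensus) for d in lib) >= 0.9
            for f in fams
        )
        assert recovered >= 0.9 * len(fams)

    def test_deterministic(self, low_divergence_sim):
        _, sim = low_divergence_sim
        small = {"a": sim.genome_a["chrA"][:200_000]}
        l1, _ = discover_families(small, CFG, known=[])
        l2, _ = discover_families(small, CFG, known=[])
        assert [(f.family_id, f.consensus) for f in l1] == [
            (f.family_id, f.consensus) for f in l2
        ]

    def test_conservative_mode_is_subset(self, low_divergence_sim):
        # every conservative-library de novo consensus matches a
        # default-library consensus at high identity
        _, sim = low_divergence_sim
        genomes = [sim.genome_a, sim.genome_b]
        default, _ = discover_families(genomes, CFG, known=[])
        conservative, _ = discover_families(
            genomes, dataclasses.replace(CFG, min_consensus_len=2000), known=[]
        )
        assert len(conservative) <= len(default)
        for f in conservative:
            assert max(alignment_identity(f.consensus, d.consensus) for d in default) >= 0.9
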