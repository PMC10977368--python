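"""Candidate enumeration, filtering, ranking and display chemistry."""

import numpy as np
import pytest

from skipdesign.aon_design import (
    DesignConfig,
    DesignError,
    antisense_of,
    enumerate_candidates,
    run_design,
    score_and_rank,
    to_2omeps,
)
from skipdesign.folding import SSCountProfile
from skipdesign.gene_model import TargetRegion, reverse_complement
from skipdesign.synthetic_data import (
    CONTROL_AON,
    IGFBP1_AON,
    IGFBP3_AON,
    FixtureSpec,
    make_toy_gene,
)


def _region(seq: str) -> TargetRegion:
    return TargetRegion(
        sequence=seq,
        flank=0,
        exon_span=(0, len(seq)),
        flank_lengths=(0, 0),
        truncated=(False, False),
    )


def _flat_profile(n: int) -> SSCountProfile:
    return SSCountProfile(openness=np.ones(n), n_structures=1)


LENIENT = dict(
    gc_min=0.0, gc_max=1.0, tm_min=-50.0, tm_max=200.0,
    max_self_dimer_dg=100.0, max_cross_dimer_dg=100.0,
    min_mean_openness=0.0, min_ese_density=0.0,
)


class TestEnumerateCandidates:
    def test_window_count_is_n_minus_l_plus_one(self):
        cfg = DesignConfig(length_min=20, length_max=20)
        cands = enumerate_candidates(_region("ACGTACGTACGTACGTACGTACGTACGTAC"), cfg)
        assert len(cands) == 30 - 20 + 1

    def test_length_below_eighteen_requires_override(self):
        with pytest.raises(DesignError, match="18"):
            DesignConfig(length_min=17, length_max=20)
        cfg = DesignConfig(length_min=17, length_max=17, allow_length_override=True)
        assert cfg.length_min == 17

    def test_antisense_is_reverse_complement_in_rna_alphabet(self):
        cfg = DesignConfig(length_min=18, length_max=20)
        region = _region("ACGTTGCAACGTTGCAACGTTGCAACGTAC")
        for c in enumerate_candidates(region, cfg):
            expected = reverse_complement(c.target_window).replace("T", "U")
            assert c.antisense == expected
            assert set(c.antisense) <= set("ACGU")

    def test_deterministic_order_by_start_then_length(self):
        cfg = DesignConfig(length_min=18, length_max=19)
        region = _region("ACGTTGCAACGTTGCAACGTTGCAACGTAC")
        keys = [(c.start, c.length) for c in enumerate_candidates(region, cfg)]
        assert keys == sorted(keys)

    def test_too_short_region_rejected(self):
        with pytest.raises(DesignError, match="region"):
            enumerate_candidates(_region("ACGTACGT"), DesignConfig())


class TestScoreAndRank:
    def test_tie_broken_by_five_prime_most_start(self):
        # periodic sequence: windows at start 0 and 3 are identical
        seq = "GAT" * 16
        cfg = DesignConfig(length_min=18, length_max=18, **LENIENT)
        cands = enumerate_candidates(_region(seq), cfg)
        report = score_and_rank(cands, _flat_profile(len(seq)), [], cfg)
        top = report.ranked[0]
        same = [
            c for c in report.ranked
            if c.composite_score == pytest.approx(top.composite_score)
        ]
        assert top.start == min(c.start for c in same)

    def test_ranking_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        cfg = DesignConfig(length_min=18, length_max=20, **LENIENT)
        cands = enumerate_candidates(_region(seq), cfg)
        profile = SSCountProfile(
            openness=rng.random(len(seq)), n_structures=10
        )
        ranked_a = score_and_rank(cands, profile, [], cfg).ranked
        shuffled = list(cands)
        rng.shuffle(shuffled)
        ranked_b = score_and_rank(shuffled, profile, [], cfg).ranked
        assert [(c.start, c.length) for c in ranked_a] == [
            (c.start, c.length) for c in ranked_b
        ]

    def test_gc_out_of_bounds_excluded_but_reported(self):
        seq = "A" * 20 + "GCGCGCGCGCGCGCGCGCGC" + "A" * 20
        cfg = DesignConfig(length_min=20, length_max=20, **{**LENIENT, "gc_min": 0.3, "gc_max": 0.7})
        cands = enumerate_candidates(_region(seq), cfg)
        report = score_and_rank(cands, _flat_profile(len(seq)), [], cfg)
        gc_fails = [c for c in report.failed if not c.passes["gc"]]
        assert gc_fails  # pure-A and pure-GC windows are out of bounds
        assert report.failure_counts["gc"] == len(gc_fails)
        assert all(c.passed_all for c in report.ranked)
        assert len(report.ranked) + len(report.failed) == len(cands)

    def test_empty_report_when_all_fail(self):
        seq = "A" * 40
        cfg = DesignConfig(length_min=20, length_max=20, **{**LENIENT, "gc_min": 0.4})
        cands = enumerate_candidates(_region(seq), cfg)
        report = score_and_rank(cands, _flat_profile(len(seq)), [], cfg)
        assert report.ranked == []
        assert report.failure_counts["gc"] == len(cands)


class TestChemistryDisplay:
    def test_dna_renders_as_rna(self):
        assert to_2omeps("ACGT") == "ACGU"

    def test_idempotent(self):
        assert to_2omeps(to_2omeps("acgtu")) == to_2omeps("acgtu")

    def test_non_nucleotide_rejected(self):
        with pytest.raises(DesignError):
            to_2omeps("ACGX")

    def test_published_aons_within_standard_length_band(self):
        for aon in (IGFBP1_AON, IGFBP3_AON, CONTROL_AON):
            assert 18 <= len(aon) <= 30
            assert to_2omeps(aon) == aon

    def test_planted_target_window_renders_published_aon(self, igfbp1_fixture):
        from skipdesign.gene_model import spliced_sequence

        t = igfbp1_fixture.transcript()
        mrna = spliced_sequence(t, igfbp1_fixture.genome())
        lo, hi = igfbp1_fixture.truth.aon["spliced_span"]
        assert antisense_of(mrna[lo:hi]) == IGFBP1_AON


class TestPlantedWindowRecovery:
    def test_top_candidate_overlaps_planted_open_ese_window(self):
        recovered = 0
        for seed in range(3):
            gene = make_toy_gene(FixtureSpec(seed=100 + seed))
            cfg = DesignConfig(length_min=20, length_max=20)
            report, region = run_design(
                gene.transcript(), gene.genome(), gene.truth.target_exon, cfg=cfg
            )
            plant_lo = region.exon_span[0] + gene.truth.ese["exon_offset"]
            plant_hi = plant_lo + gene.truth.ese["length"]
            top = report.top
            overlap = max(0, min(top.end, plant_hi) - max(top.start, plant_lo))
            if overlap >= (plant_hi - plant_lo) // 2:
                recovered += 1
        assert recovered >= 2
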