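import logging
import random

import numpy as np
import pytest

from ighdkit.cluster_architecture import DHGene
from ighdkit.fusion_inference import (
    FusionParams,
    conserved_codon_check,
    locate_breakpoint,
    score_fusion,
)
from ighdkit.locus_io import Interval
from ighdkit.rss_model import site_from_elements

from conftest import random_dna


def _mk_gene(name, coding_seq, rng, rss5_spacer=None, rss3_spacer=None):
    rss5 = site_from_elements(
        "CACGGTG",
        rss5_spacer or random_dna(rng, 12),
        "GGTTTCTGA",
        "five_prime",
    )
    rss3 = site_from_elements(
        "CACAGTG",
        rss3_spacer or random_dna(rng, 12),
        "ACAAAAACC",
        "three_prime",
    )
    return DHGene(name, 1, rss5, rss3, Interval(0, len(coding_seq)), coding_seq)


@pytest.fixture
def constructed_fusion():
    """Target built by concatenating d5's prefix with d3's suffix."""
    rng = np.random.default_rng(21)
    d5 = _mk_gene("d5", random_dna(rng, 80), rng)
    d3 = _mk_gene("d3", random_dna(rng, 90), rng)
    decoys = [_mk_gene(f"decoy{i}", random_dna(rng, 85), rng) for i in range(3)]
    cut5, cut3 = 45, 30
    target = DHGene(
        "target",
        2,
        d5.rss5,
        d3.rss3,
        Interval(0, cut5 + 90 - cut3),
        d5.coding_seq[:cut5] + d3.coding_seq[cut3:],
    )
    return target, d5, d3, decoys, cut5


class TestScoreFusion:
    def test_constructed_target_top_ranked(self, constructed_fusion):
        target, d5, d3, decoys, _ = constructed_fusion
        hyps = score_fusion(target, [d5, d3] + decoys)
        top = hyps[0]
        assert (top.donor5, top.donor3) == ("d5", "d3")
        assert top.prefix.identity_pct == 100.0
        assert top.suffix.identity_pct == 100.0
        assert top.rss5_diffs == 0 and top.rss3_diffs == 0

    def test_true_pair_strictly_maximal(self, constructed_fusion):
        target, d5, d3, decoys, _ = constructed_fusion
        hyps = score_fusion(target, [d5, d3] + decoys)
        assert hyps[0].composite > hyps[1].composite

    def test_ranking_invariant_to_input_order(self, constructed_fusion):
        target, d5, d3, decoys, _ = constructed_fusion
        pool = [d5, d3] + decoys
        ranking1 = [(h.donor5, h.donor3) for h in score_fusion(target, pool)]
        shuffled = pool[:]
        random.Random(5).shuffle(shuffled)
        ranking2 = [(h.donor5, h.donor3) for h in score_fusion(target, shuffled)]
        assert ranking1 == ranking2

    def test_composite_monotone_in_rss_agreement(self, constructed_fusion):
        target, d5, d3, decoys, _ = constructed_fusion
        rng = np.random.default_rng(3)
        # same donor coding, RSS spacer fully matching target vs fully different
        good = _mk_gene("good", d5.coding_seq, rng, rss5_spacer=target.rss5.spacer)
        bad = _mk_gene("bad", d5.coding_seq, rng, rss5_spacer="T" * 12)
        if target.rss5.spacer == "T" * 12:  # pragma: no cover
            pytest.skip("degenerate spacer draw")
        hyps = score_fusion(target, [good, bad, d3])
        by_pair = {(h.donor5, h.donor3): h.composite for h in hyps}
        assert by_pair[("good", "d3")] > by_pair[("bad", "d3")]

    def test_target_excluded_from_donors(self, constructed_fusion):
        target, d5, d3, decoys, _ = constructed_fusion
        hyps = score_fusion(target, [target, d5, d3])
        assert all("target" not in (h.donor5, h.donor3) for h in hyps)

    def test_candidate_without_rss_excluded(self, constructed_fusion, caplog):
        target, d5, d3, _, _ = constructed_fusion
        broken = DHGene("broken", 1, None, None, Interval(0, 50), "ACGT" * 13)
        with caplog.at_level(logging.WARNING):
            hyps = score_fusion(target, [d5, d3, broken])
        assert all("broken" not in (h.donor5, h.donor3) for h in hyps)
        assert any("lacks an RSS" in r.message for r in caplog.records)

    def test_too_few_candidates(self, constructed_fusion):
        target, d5, *_ = constructed_fusion
        with pytest.raises(ValueError):
            score_fusion(target, [d5])


class TestLocateBreakpoint:
    def test_clean_fusion_contains_junction(self, constructed_fusion):
        target, d5, d3, _, cut5 = constructed_fusion
        bp = locate_breakpoint(target, d5, d3)
        assert bp.contains(cut5)
        # random flanks: interval is tight up to the configured pad
        pad = FusionParams().breakpoint_pad
        assert bp.end - bp.start <= 2 * pad + 2

    def test_zero_pad_zero_width(self, constructed_fusion):
        target, d5, d3, _, cut5 = constructed_fusion
        bp = locate_breakpoint(
            target, d5, d3, FusionParams(breakpoint_pad=0)
        )
        assert bp.start <= cut5 <= bp.end

    def test_repeat_junction_widened_and_contained(self):
        # junction inside a shared repeat array: interval must widen but
        # still contain an equivalent cut position
        from ighdkit.synthetic_locus import SimParams, simulate
        from ighdkit.cluster_architecture import call_genes, segment_clusters

        found = False
        for seed in range(30):
            params = SimParams(seed=seed, mu=0.0)
            locus, truth = simulate(params)
            if not truth.meta["junction_in_repeat"]:
                continue
            genes = call_genes(locus, max_heptamer_mm=0, max_nonamer_mm=0)
            clusters = segment_clusters(locus, genes)
            i0, j0 = params.fuse_ordinals
            fused = clusters[0].genes[i0 + 1]
            bp = locate_breakpoint(
                fused, clusters[1].genes[i0], clusters[1].genes[j0]
            )
            lo, hi = truth.meta["junction_interval"]
            assert bp.start <= hi and lo <= bp.end, (seed, (bp.start, bp.end), (lo, hi))
            found = True
        assert found

    def test_no_alignment_raises(self):
        rng = np.random.default_rng(31)
        target = _mk_gene("t", "A" * 60, rng)
        d5 = _mk_gene("d5", "C" * 40, rng)
        d3 = _mk_gene("d3", "C" * 40, rng)
        with pytest.raises(ValueError):
            locate_breakpoint(target, d5, d3)


class TestConservedCodon:
    def test_self_comparison_all_agree(self):
        rng = np.random.default_rng(41)
        coding = "TGT" + random_dna(rng, 57)  # Cys codon at position 0
        g = _mk_gene("g", coding, rng)
        res = conserved_codon_check(g, g, "C")
        assert res.matches and all(m.agrees for m in res.matches)
        assert res.any_shared

    def test_mutated_codon_disagrees(self):
        rng = np.random.default_rng(42)
        tail = "GGA" * 19  # Gly only: no stray cysteines
        target = _mk_gene("t", "AGT" + tail, rng)  # Cys -> Ser in the target
        donor = _mk_gene("d", "TGT" + tail, rng)
        res = conserved_codon_check(target, donor, "C")
        assert res.matches and not res.any_shared

    def test_shared_cysteine_after_fusion(self, constructed_fusion):
        target, d5, d3, _, _ = constructed_fusion
        # engineer a Cys into the shared prefix of d5 and target
        seq = list(d5.coding_seq)
        seq[9:12] = "TGC"
        d5b = _mk_gene("d5b", "".join(seq), np.random.default_rng(43))
        tgt = DHGene(
            "t2", 2, target.rss5, target.rss3, Interval(0, 60),
            d5b.coding_seq[:45] + d3.coding_seq[30:45],
        )
        res = conserved_codon_check(tgt, d5b, "C")
        assert res.any_shared
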