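import numpy as np
import pytest
from hypothesis import given, strategies as st

from ighdkit.locus_io import NucSequence
from ighdkit.rss_model import (
    DEFAULT_MAX_HEPTAMER_MM,
    DEFAULT_MAX_NONAMER_MM,
    FIVE_PRIME_MOTIF,
    RSS_FOOTPRINT,
    THREE_PRIME_MOTIF,
    RSSMotif,
    compare_rss,
    hamming,
    load_reference_rss,
    reference_site,
    rss_table,
    scan_rss,
    site_from_elements,
)

from conftest import random_dna
from oracles import (
    oracle_exact_rss_positions,
    oracle_hamming,
    oracle_mismatch_rss_positions,
)

el = st.text(alphabet="ACGT", min_size=7, max_size=7)
non = st.text(alphabet="ACGT", min_size=9, max_size=9)
spc = st.text(alphabet="ACGT", min_size=12, max_size=12)


class TestSite:
    def test_footprint_decomposition(self):
        s = site_from_elements("CACAGTG", "A" * 12, "ACAAAAACC", "three_prime")
        assert len(s.interval) == RSS_FOOTPRINT == 28
        assert len(s.heptamer) + len(s.spacer) + len(s.nonamer) == 28

    def test_bad_lengths(self):
        with pytest.raises(ValueError):
            site_from_elements("CACAGT", "A" * 12, "ACAAAAACC", "three_prime")


class TestScan:
    def test_planted_three_prime(self):
        rng = np.random.default_rng(5)
        s = list(random_dna(rng, 100))
        planted = "CACAGTG" + random_dna(rng, 12) + "ACAAAAACC"
        s[30:58] = planted
        seq = NucSequence("t", "".join(s))
        hits = scan_rss(seq, THREE_PRIME_MOTIF, 0, 0)
        assert [h.interval.start for h in hits] == [30]
        assert hits[0].interval.end == 58
        assert hits[0].heptamer == "CACAGTG"

    def test_all_a_no_hits(self):
        assert scan_rss(NucSequence("a", "A" * 100), THREE_PRIME_MOTIF, 0, 0) == []

    def test_short_sequence_empty(self):
        assert scan_rss(NucSequence("a", "ACGT"), THREE_PRIME_MOTIF) == []

    def test_five_prime_element_order(self):
        core = (
            FIVE_PRIME_MOTIF.nonamer_consensus
            + "T" * 12
            + FIVE_PRIME_MOTIF.heptamer_consensus
        )
        hits = scan_rss(NucSequence("x", "GG" + core + "GG"), FIVE_PRIME_MOTIF, 0, 0)
        assert len(hits) == 1
        assert hits[0].interval.start == 2
        assert hits[0].nonamer == FIVE_PRIME_MOTIF.nonamer_consensus
        assert hits[0].heptamer == FIVE_PRIME_MOTIF.heptamer_consensus

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_scan_equals_regex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = list(random_dna(rng, 2000))
        for off in rng.integers(0, 1970, 3):  # plant a few signals
            s[off : off + 28] = (
                "CACAGTG" + random_dna(rng, 12) + "ACAAAAACC"
            )
        seq = NucSequence("r", "".join(s))
        got = [h.interval.start for h in scan_rss(seq, THREE_PRIME_MOTIF, 0, 0)]
        want = oracle_exact_rss_positions(
            seq.residues, "CACAGTG", "ACAAAAACC", 12, "three_prime"
        )
        assert got == want

    @pytest.mark.parametrize("seed", range(3))
    def test_mismatch_scan_equals_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = NucSequence("r", random_dna(rng, 2000))
        got = [
            h.interval.start
            for h in scan_rss(
                seq, THREE_PRIME_MOTIF, DEFAULT_MAX_HEPTAMER_MM, DEFAULT_MAX_NONAMER_MM
            )
        ]
        want = oracle_mismatch_rss_positions(
            seq.residues,
            "CACAGTG",
            "ACAAAAACC",
            12,
            "three_prime",
            DEFAULT_MAX_HEPTAMER_MM,
            DEFAULT_MAX_NONAMER_MM,
        )
        assert got == want


class TestCompare:
    def test_identity(self):
        a = site_from_elements("CACAGTG", "A" * 12, "ACAAAAACC", "three_prime")
        cmp = compare_rss(a, a)
        assert (cmp.heptamer_diffs, cmp.spacer_diffs, cmp.nonamer_diffs, cmp.total_diffs) == (0, 0, 0, 0)

    def test_side_mismatch(self):
        a = site_from_elements("CACAGTG", "A" * 12, "ACAAAAACC", "three_prime")
        b = site_from_elements("CACGGTG", "A" * 12, "GGTTTCTGA", "five_prime")
        with pytest.raises(ValueError):
            compare_rss(a, b)

    @given(el, spc, non, el, spc, non)
    def test_hamming_matches_bruteforce_and_symmetry(self, h1, s1, n1, h2, s2, n2):
        a = site_from_elements(h1, s1, n1, "three_prime")
        b = site_from_elements(h2, s2, n2, "three_prime")
        cmp = compare_rss(a, b)
        assert cmp.heptamer_diffs == oracle_hamming(h1, h2)
        assert cmp.spacer_diffs == oracle_hamming(s1, s2)
        assert cmp.nonamer_diffs == oracle_hamming(n1, n2)
        rev = compare_rss(b, a)
        assert rev.total_diffs == cmp.total_diffs

    @given(el, el, el)
    def test_triangle_inequality(self, x, y, z):
        assert hamming(x, z) <= hamming(x, y) + hamming(y, z)


class TestReferenceTable:
    def test_row_count_and_cluster_split(self):
        df = load_reference_rss()
        assert len(df) == 17
        assert df.groupby("cluster").size().to_dict() == {2: 5, 3: 6, 4: 6}

    def test_spacers_are_12(self):
        df = load_reference_rss()
        assert (df["five_spacer"].str.len() == 12).all()
        assert (df["three_spacer"].str.len() == 12).all()

    def test_three_prime_heptamers(self):
        df = load_reference_rss()
        assert (df["three_heptamer"] == "cacagtg").all()

    def test_ultralong_three_rss_matches_family7(self):
        a = reference_site("IGHD8-2", "three_prime")
        for other in ("IGHD7-3", "IGHD7-4"):
            assert compare_rss(a, reference_site(other, "three_prime")).total_diffs == 0

    def test_family1_cluster2_five_prime_row(self):
        df = load_reference_rss()
        row = df[df["gene"] == "IGHD1-2"].iloc[0]
        assert row["five_nonamer"] == "ggattttga"
        assert row["five_spacer"] == "gggtgtgcgtgt"
        assert row["five_heptamer"] == "caccctg"

    def test_default_maxima_recover_every_row(self):
        # the loosest maxima that admit all printed sites on both sides
        df = load_reference_rss()
        for _, r in df.iterrows():
            s5 = site_from_elements(
                r["five_heptamer"], r["five_spacer"], r["five_nonamer"], "five_prime"
            )
            s3 = site_from_elements(
                r["three_heptamer"], r["three_spacer"], r["three_nonamer"], "three_prime"
            )
            assert s5.heptamer_mismatches <= DEFAULT_MAX_HEPTAMER_MM
            assert s5.nonamer_mismatches <= DEFAULT_MAX_NONAMER_MM
            assert s3.heptamer_mismatches <= DEFAULT_MAX_HEPTAMER_MM
            assert s3.nonamer_mismatches <= DEFAULT_MAX_NONAMER_MM


class TestTable:
    def test_empty_gene_list(self):
        df = rss_table([])
        assert len(df) == 0
        assert "five_heptamer" in df.columns

    def test_synthetic_genes_roundtrip(self, sim_ancestor):
        from ighdkit.cluster_architecture import call_genes

        params, seq, truth = sim_ancestor
        genes = call_genes(seq, max_heptamer_mm=0, max_nonamer_mm=0)
        df = rss_table(genes)
        assert len(df) == params.n_genes
        assert (df["three_heptamer"] == "cacagtg").all()
        assert (df["five_heptamer"] == FIVE_PRIME_MOTIF.heptamer_consensus.lower()).all()

    def test_missing_rss_marker(self, caplog):
        import logging
        from ighdkit.cluster_architecture import DHGene
        from ighdkit.locus_io import Interval

        g = DHGene("g", 1, None, None, Interval(0, 30), "A" * 30)
        with caplog.at_level(logging.WARNING):
            df = rss_table([g])
        assert (df.iloc[0][["five_heptamer", "three_heptamer"]] == ".").all()
        assert any("missing an RSS" in r.message for r in caplog.records)


def test_motif_validation():
    with pytest.raises(ValueError):
        RSSMotif("CACAGT", "ACAAAAACC")
    with pytest.raises(ValueError):
        RSSMotif("CACAGTG", "ACAAAAAC")


class TestAssignReferenceNames:
    def test_reconstructed_cluster3_named_correctly(self):
        # build a locus whose RSS elements are the printed cluster-3 strings
        from ighdkit.cluster_architecture import call_genes, segment_clusters
        from ighdkit.rss_model import assign_reference_names, load_reference_rss

        order = ["IGHD1-3", "IGHD2-3", "IGHD3-3", "IGHD7-3", "IGHD5-3", "IGHD6-3"]
        df = load_reference_rss().set_index("gene")
        rng = np.random.default_rng(17)
        parts = []
        for name in order:
            r = df.loc[name]
            parts.append(
                (r["five_nonamer"] + r["five_spacer"] + r["five_heptamer"]).upper()
                + random_dna(rng, 40)
                + (r["three_heptamer"] + r["three_spacer"] + r["three_nonamer"]).upper()
            )
            parts.append(random_dna(rng, 400))
        locus = NucSequence("mini", "".join(parts[:-1]))
        genes = call_genes(locus)  # default mismatch maxima must find all sites
        clusters = segment_clusters(locus, genes, first_cluster_id=1)
        assert len(clusters) == 1 and len(clusters[0].genes) == 6
        mapping = assign_reference_names(clusters)
        assert mapping == {1: 3}
        assert [g.name for g in clusters[0].genes] == order
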