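"""Recombination signal sequence (RSS) detection and comparison.

A D-gene RSS is a 28-nt footprint: heptamer + 12-nt spacer + nonamer. On the
top strand the 5'-side RSS reads nonamer-spacer-heptamer (heptamer adjacent
to the coding segment) and the 3'-side RSS reads heptamer-spacer-nonamer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING

import pandas as pd

from .locus_io import Interval, NucSequence, normalize_gene_name

if TYPE_CHECKING:  # pragma: no cover
    from .cluster_architecture import DHGene

logger = logging.getLogger(__name__)

HEPTAMER_LEN = 7
SPACER_LEN = 12
NONAMER_LEN = 9
RSS_FOOTPRINT = HEPTAMER_LEN + SPACER_LEN + NONAMER_LEN  # 28

#: Loosest mismatch maxima that recover every printed reference site.
DEFAULT_MAX_HEPTAMER_MM = 3
DEFAULT_MAX_NONAMER_MM = 4


@dataclass(frozen=True)
class RSSMotif:
    heptamer_consensus: str
    nonamer_consensus: str
    spacer_len: int = SPACER_LEN
    side: str = "three_prime"

    def __post_init__(self) -> None:
        if len(self.heptamer_consensus) != HEPTAMER_LEN:
            raise ValueError("heptamer consensus must be 7 nt")
        if len(self.nonamer_consensus) != NONAMER_LEN:
            raise ValueError("nonamer consensus must be 9 nt")
        if self.side not in ("five_prime", "three_prime"):
            raise ValueError(f"invalid side {self.side!r}")


# Column-wise majority of the packaged reference table.
THREE_PRIME_MOTIF = RSSMotif("CACAGTG", "ACAAAAACC", side="three_prime")
FIVE_PRIME_MOTIF = RSSMotif("CACGGTG", "GGTTTCTGA", side="five_prime")


@dataclass(frozen=True)
class RSSite:
    """A located RSS hit; elements stored as found on the top strand."""

    interval: Interval
    heptamer: str
    spacer: str
    nonamer: str
    heptamer_mismatches: int
    nonamer_mismatches: int
    side: str

    def __post_init__(self) -> None:
        if len(self.heptamer) != HEPTAMER_LEN:
            raise ValueError("heptamer must be 7 nt")
        if len(self.spacer) != SPACER_LEN:
            raise ValueError("spacer must be 12 nt")
        if len(self.nonamer) != NONAMER_LEN:
            raise ValueError("nonamer must be 9 nt")
        if len(self.interval) != RSS_FOOTPRINT:
            raise ValueError("RSS footprint must be 28 nt")


@dataclass(frozen=True)
class RSSComparison:
    site_a: RSSite
    site_b: RSSite
    heptamer_diffs: int
    spacer_diffs: int
    nonamer_diffs: int

    @property
    def total_diffs(self) -> int:
        return self.heptamer_diffs + self.spacer_diffs + self.nonamer_diffs


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def site_from_elements(
    heptamer: str,
    spacer: str,
    nonamer: str,
    side: str,
    start: int = 0,
    motif: RSSMotif | None = None,
) -> RSSite:
    """Build an RSSite from its three elements (e.g. a printed table row)."""
    if motif is None:
        motif = FIVE_PRIME_MOTIF if side == "five_prime" else THREE_PRIME_MOTIF
    heptamer, spacer, nonamer = heptamer.upper(), spacer.upper(), nonamer.upper()
    return RSSite(
        interval=Interval(start, start + RSS_FOOTPRINT),
        heptamer=heptamer,
        spacer=spacer,
        nonamer=nonamer,
        heptamer_mismatches=hamming(heptamer, motif.heptamer_consensus),
        nonamer_mismatches=hamming(nonamer, motif.nonamer_consensus),
        side=side,
    )


def scan_rss(
    seq: NucSequence,
    motif: RSSMotif,
    max_heptamer_mm: int = DEFAULT_MAX_HEPTAMER_MM,
    max_nonamer_mm: int = DEFAULT_MAX_NONAMER_MM,
) -> list[RSSite]:
    """Top-strand scan for RSS footprints within the mismatch maxima.

    Returns all qualifying sites in coordinate order; overlaps are not
    suppressed. A sequence shorter than the footprint yields an empty list.
    """
    s = seq.residues
    n = len(s)
    sites: list[RSSite] = []
    if n < RSS_FOOTPRINT:
        return sites
    hep = motif.heptamer_consensus
    non = motif.nonamer_consensus
    if motif.side == "three_prime":
        hep_off, non_off = 0, HEPTAMER_LEN + motif.spacer_len
    else:
        non_off, hep_off = 0, NONAMER_LEN + motif.spacer_len
    for i in range(n - RSS_FOOTPRINT + 1):
        h = s[i + hep_off : i + hep_off + HEPTAMER_LEN]
        hm = hamming(h, hep)
        if hm > max_heptamer_mm:
            continue
        m = s[i + non_off : i + non_off + NONAMER_LEN]
        nm = hamming(m, non)
        if nm > max_nonamer_mm:
            continue
        if motif.side == "three_prime":
            spacer = s[i + HEPTAMER_LEN : i + HEPTAMER_LEN + motif.spacer_len]
        else:
            spacer = s[i + NONAMER_LEN : i + NONAMER_LEN + motif.spacer_len]
        sites.append(
            RSSite(
                interval=Interval(i, i + RSS_FOOTPRINT),
                heptamer=h,
                spacer=spacer,
                nonamer=m,
                heptamer_mismatches=hm,
                nonamer_mismatches=nm,
                side=motif.side,
            )
        )
    return sites


def compare_rss(a: RSSite, b: RSSite) -> RSSComparison:
    """Element-wise Hamming comparison of two same-side sites."""
    if a.side != b.side:
        raise ValueError(f"cannot compare {a.side} site with {b.side} site")
    return RSSComparison(
        site_a=a,
        site_b=b,
        heptamer_diffs=hamming(a.heptamer, b.heptamer),
        spacer_diffs=hamming(a.spacer, b.spacer),
        nonamer_diffs=hamming(a.nonamer, b.nonamer),
    )


_MISSING = "."


def rss_table(genes: list["DHGene"]) -> pd.DataFrame:
    """One row per gene mirroring the printed reference layout.

    Elements are lowercase; missing RSSs are emitted as '.' with a warning.
    Rows are ordered by (cluster, coding start).
    """
    rows = []
    for g in sorted(genes, key=lambda g: (g.cluster_id, g.coding.start)):
        if g.rss5 is None or g.rss3 is None:
            logger.warning("gene %s is missing an RSS", g.name)
        rows.append(
            {
                "gene": g.name,
                "cluster": g.cluster_id,
                "five_nonamer": g.rss5.nonamer.lower() if g.rss5 else _MISSING,
                "five_spacer": g.rss5.spacer.lower() if g.rss5 else _MISSING,
                "five_heptamer": g.rss5.heptamer.lower() if g.rss5 else _MISSING,
                "three_heptamer": g.rss3.heptamer.lower() if g.rss3 else _MISSING,
                "three_spacer": g.rss3.spacer.lower() if g.rss3 else _MISSING,
                "three_nonamer": g.rss3.nonamer.lower() if g.rss3 else _MISSING,
            }
        )
    columns = [
        "gene",
        "cluster",
        "five_nonamer",
        "five_spacer",
        "five_heptamer",
        "three_heptamer",
        "three_spacer",
        "three_nonamer",
    ]
    return pd.DataFrame(rows, columns=columns)


def load_reference_rss() -> pd.DataFrame:
    """The packaged reference RSS table (clusters 2-4 of the bovine locus)."""
    with resources.files("ighdkit.data").joinpath("dh_rss_reference.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"cluster": int})
    df["gene"] = df["gene"].map(normalize_gene_name)
    return df


def assign_reference_names(clusters, table: pd.DataFrame | None = None, max_distance: int = 8) -> dict[int, int]:
    """Name called genes after the packaged reference rows they best match.

    Distance between a called gene and a reference row is the summed element
    Hamming distance over both RSSs. Each segmentation cluster is mapped to
    the reference cluster its genes vote for; names are then assigned within
    that reference cluster, best match first, one row per gene. Returns the
    {segmentation cluster id: reference cluster id} mapping.
    """
    if table is None:
        table = load_reference_rss()
    ref_sites = {
        r["gene"]: (
            site_from_elements(r["five_heptamer"], r["five_spacer"], r["five_nonamer"], "five_prime"),
            site_from_elements(r["three_heptamer"], r["three_spacer"], r["three_nonamer"], "three_prime"),
            int(r["cluster"]),
        )
        for _, r in table.iterrows()
    }

    def _distance(gene, ref5, ref3) -> int:
        return (
            compare_rss(gene.rss5, ref5).total_diffs
            + compare_rss(gene.rss3, ref3).total_diffs
        )

    mapping: dict[int, int] = {}
    taken_refs: set[int] = set()
    per_cluster: list[tuple] = []
    for cluster in clusters:
        scored = []  # (distance, gene, row_name, row_cluster)
        for g in cluster.genes:
            if g.rss5 is None or g.rss3 is None:
                continue
            for name, (ref5, ref3, ref_cluster) in ref_sites.items():
                d = _distance(g, ref5, ref3)
                if d <= max_distance:
                    scored.append((d, g, name, ref_cluster))
        if not scored:
            continue
        # each gene votes for every reference cluster tied at its minimal
        # distance (sibling clusters print identical RSS strings)
        best: dict[int, int] = {}
        for d, g, name, rc in scored:
            best[id(g)] = min(best.get(id(g), d), d)
        votes: dict[int, set[int]] = {}
        for d, g, name, rc in scored:
            if d == best[id(g)]:
                votes.setdefault(rc, set()).add(id(g))
        per_cluster.append((cluster, scored, {rc: len(v) for rc, v in votes.items()}))
    # clusters appear in coordinate order; ties between reference clusters
    # with identical RSS content resolve by that order (ids ascend along
    # the locus)
    for cluster, scored, votes in per_cluster:
        choices = sorted(votes, key=lambda rc: (-votes[rc], rc))
        ref_cluster = next((rc for rc in choices if rc not in taken_refs), None)
        if ref_cluster is None:
            continue
        taken_refs.add(ref_cluster)
        mapping[cluster.cluster_id] = ref_cluster
        taken: set[str] = set()
        named: set[int] = set()
        for d, g, name, rc in sorted(scored, key=lambda t: t[0]):
            if rc != ref_cluster or name in taken or id(g) in named:
                continue
            g.name = name
            taken.add(name)
            named.add(id(g))
    return mapping


def reference_site(gene: str, side: str, table: pd.DataFrame | None = None) -> RSSite:
    """RSSite for one gene/side of the packaged reference table."""
    if table is None:
        table = load_reference_rss()
    gene = normalize_gene_name(gene)
    row = table[table["gene"] == gene]
    if row.empty:
        raise KeyError(f"gene {gene!r} not in reference RSS table")
    r = row.iloc[0]
    if side == "five_prime":
        return site_from_elements(
            r["five_heptamer"], r["five_spacer"], r["five_nonamer"], side
        )
    return site_from_elements(
        r["three_heptamer"], r["three_spacer"], r["three_nonamer"], side
    )
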