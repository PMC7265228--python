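"""Gene calling, cluster segmentation, paralog mapping and event detection.

A D gene is modeled as 5'RSS + coding + 3'RSS on the top strand. The coding
segment runs from the 3' edge of the 5' heptamer to the 5' edge of the 3'
heptamer. A cluster spans from its first gene's 5'RSS start to its last
gene's 3'RSS end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .locus_io import AnnotationRecord, Interval, NucSequence, extract
from .pairwise_align import AlignParams, align
from .rss_model import (
    DEFAULT_MAX_HEPTAMER_MM,
    DEFAULT_MAX_NONAMER_MM,
    FIVE_PRIME_MOTIF,
    THREE_PRIME_MOTIF,
    RSSMotif,
    RSSite,
    scan_rss,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_CODING = 9
DEFAULT_MAX_CODING = 200
DEFAULT_MAX_INTERGENE_GAP = 2000
DEFAULT_PAIR_FLOOR = 70.0


@dataclass
class DHGene:
    name: str
    cluster_id: int
    rss5: RSSite | None
    rss3: RSSite | None
    coding: Interval
    coding_seq: str
    ordinal: int = 0

    @property
    def footprint(self) -> Interval:
        start = self.rss5.interval.start if self.rss5 else self.coding.start
        end = self.rss3.interval.end if self.rss3 else self.coding.end
        return Interval(start, end)


@dataclass
class Cluster:
    cluster_id: int
    span: Interval
    genes: list[DHGene]
    intergenic: list[Interval | None]
    parent: NucSequence

    def gene(self, name: str) -> DHGene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"no gene {name!r} in cluster {self.cluster_id}")


@dataclass
class OrderEvent:
    type: str  # missing_family | transposition | length_delta
    gene_a: str | None = None
    gene_b: str | None = None
    value: float | None = None


@dataclass
class ParalogMap:
    cluster_a: int
    cluster_b: int
    pairs: list[tuple[DHGene, DHGene, float]]
    unmatched_a: list[DHGene]
    unmatched_b: list[DHGene]
    order_events: list[OrderEvent] = field(default_factory=list)


@dataclass
class IntergenicComparison:
    flank5: str
    flank3: str
    interval_b: Interval
    identity_pct: float
    coverage: float
    deleted_in_a: bool


def call_genes(
    cluster_seq: NucSequence,
    five_motif: RSSMotif = FIVE_PRIME_MOTIF,
    three_motif: RSSMotif = THREE_PRIME_MOTIF,
    max_heptamer_mm: int = DEFAULT_MAX_HEPTAMER_MM,
    max_nonamer_mm: int = DEFAULT_MAX_NONAMER_MM,
    min_coding: int = DEFAULT_MIN_CODING,
    max_coding: int = DEFAULT_MAX_CODING,
    max_total_mm: int = 9,
    names: list[AnnotationRecord] | None = None,
    cluster_id: int = 0,
) -> list[DHGene]:
    """Pair 5'-side RSS hits with compatible downstream 3'-side hits.

    All (5', 3') site pairs whose enclosed coding segment is
    min_coding..max_coding nt are candidates; non-overlapping genes are
    selected best-quality first (fewest summed element mismatches over both
    sites, then leftmost), with a per-gene cap of *max_total_mm* summed
    mismatches — at the loose per-side maxima spurious sites otherwise pair
    into false genes. Unpairable sites are skipped.
    Names come from an optional annotation table (gene records matched by
    footprint overlap), else placeholders "D1", "D2", ...
    """
    sites5 = scan_rss(cluster_seq, five_motif, max_heptamer_mm, max_nonamer_mm)
    sites3 = scan_rss(cluster_seq, three_motif, max_heptamer_mm, max_nonamer_mm)
    candidates: list[tuple[int, int, int, RSSite, RSSite]] = []
    for s5 in sites5:
        coding_start = s5.interval.end
        for s3 in sites3:
            if s3.interval.start < coding_start + min_coding:
                continue
            if s3.interval.start > coding_start + max_coding:
                break
            mm = (
                s5.heptamer_mismatches
                + s5.nonamer_mismatches
                + s3.heptamer_mismatches
                + s3.nonamer_mismatches
            )
            if mm <= max_total_mm:
                candidates.append(
                    (mm, s5.interval.start, s3.interval.start, s5, s3)
                )
    candidates.sort(key=lambda c: c[:3])
    chosen: list[tuple[RSSite, RSSite]] = []
    for mm, _, _, s5, s3 in candidates:
        fp = Interval(s5.interval.start, s3.interval.end)
        if all(
            not fp.overlaps(Interval(c5.interval.start, c3.interval.end))
            for c5, c3 in chosen
        ):
            chosen.append((s5, s3))
    chosen.sort(key=lambda c: c[0].interval.start)
    genes: list[DHGene] = []
    for s5, s3 in chosen:
        coding = Interval(s5.interval.end, s3.interval.start)
        genes.append(
            DHGene(
                name="",
                cluster_id=cluster_id,
                rss5=s5,
                rss3=s3,
                coding=coding,
                coding_seq=cluster_seq.residues[coding.start : coding.end],
                ordinal=len(genes),
            )
        )
    for idx, g in enumerate(genes):
        g.name = f"D{idx + 1}"
        if names:
            best_overlap = 0
            for rec in names:
                if rec.feature_type != "gene" or not rec.interval.overlaps(g.footprint):
                    continue
                overlap = min(rec.interval.end, g.footprint.end) - max(
                    rec.interval.start, g.footprint.start
                )
                if overlap > best_overlap:
                    best_overlap = overlap
                    g.name = rec.name
    return genes


def segment_clusters(
    locus: NucSequence,
    genes: list[DHGene],
    max_intergene_gap: int = DEFAULT_MAX_INTERGENE_GAP,
    first_cluster_id: int = 1,
) -> list[Cluster]:
    """Group coordinate-sorted genes into clusters by intergene distance."""
    genes = sorted(genes, key=lambda g: g.footprint.start)
    clusters: list[Cluster] = []
    group: list[DHGene] = []

    def _close(group: list[DHGene]) -> None:
        cid = first_cluster_id + len(clusters)
        intergenic: list[Interval | None] = []
        for prev, nxt in zip(group, group[1:]):
            s, e = prev.footprint.end, nxt.footprint.start
            intergenic.append(Interval(s, e) if e > s else None)
        for ordinal, g in enumerate(group):
            g.cluster_id = cid
            g.ordinal = ordinal
        clusters.append(
            Cluster(
                cluster_id=cid,
                span=Interval(group[0].footprint.start, group[-1].footprint.end),
                genes=list(group),
                intergenic=intergenic,
                parent=locus,
            )
        )

    for g in genes:
        if group and g.footprint.start - group[-1].footprint.end > max_intergene_gap:
            _close(group)
            group = []
        group.append(g)
    if group:
        _close(group)
    return clusters


def _lis_indices(seq: list[int], disp: list[int]) -> set[int]:
    """Indices of a longest strictly increasing subsequence (O(n^2)).

    Ties between equal-length subsequences are broken by keeping the pairs
    with the smallest total |ordinal displacement|, so the genes flagged as
    moved are the ones that actually moved farthest.
    """
    n = len(seq)
    if n == 0:
        return set()
    # value = (length, -sum of displacements kept); maximize lexicographically
    best: list[tuple[int, int]] = [(1, -disp[i]) for i in range(n)]
    prev = [-1] * n
    for i in range(1, n):
        for j in range(i):
            if seq[j] < seq[i]:
                cand = (best[j][0] + 1, best[j][1] - disp[i])
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    out = set()
    while end != -1:
        out.add(end)
        end = prev[end]
    return out


def map_paralogs(
    a: Cluster,
    b: Cluster,
    params: AlignParams | None = None,
    pair_floor: float = DEFAULT_PAIR_FLOOR,
) -> ParalogMap:
    """Optimal-assignment paralog matching on coding-region global identity.

    Pairs below *pair_floor* percent identity are dropped to unmatched.
    Order events: a gene of b left unmatched is a missing_family in a;
    matched pairs outside the longest increasing subsequence of partner
    ordinals are transpositions; nonzero coding-length differences are
    length_delta events.
    """
    if params is None:
        params = AlignParams(mode="global")
    na, nb = len(a.genes), len(b.genes)
    ident = np.zeros((na, nb))
    for i, ga in enumerate(a.genes):
        for j, gb in enumerate(b.genes):
            ident[i, j] = align(ga.coding_seq, gb.coding_seq, params).identity_pct
    rows, cols = linear_sum_assignment(-ident)
    pairs: list[tuple[DHGene, DHGene, float]] = []
    matched_a, matched_b = set(), set()
    for i, j in zip(rows, cols):
        if ident[i, j] >= pair_floor:
            pairs.append((a.genes[i], b.genes[j], float(ident[i, j])))
            matched_a.add(i)
            matched_b.add(j)
    pairs.sort(key=lambda p: p[0].ordinal)
    unmatched_a = [g for i, g in enumerate(a.genes) if i not in matched_a]
    unmatched_b = [g for j, g in enumerate(b.genes) if j not in matched_b]
    events: list[OrderEvent] = []
    for g in unmatched_b:
        j = b.genes.index(g)
        best = float(ident[:, j].max()) if na else 0.0
        events.append(OrderEvent("missing_family", gene_b=g.name, value=best))
    b_ordinals = [gb.ordinal for _, gb, _ in pairs]
    displacements = [abs(ga.ordinal - gb.ordinal) for ga, gb, _ in pairs]
    keep = _lis_indices(b_ordinals, displacements)
    for idx, (ga, gb, _) in enumerate(pairs):
        if idx not in keep:
            events.append(OrderEvent("transposition", gene_a=ga.name, gene_b=gb.name))
    for ga, gb, _ in pairs:
        delta = len(ga.coding_seq) - len(gb.coding_seq)
        if delta != 0:
            events.append(
                OrderEvent(
                    "length_delta", gene_a=ga.name, gene_b=gb.name, value=float(delta)
                )
            )
    return ParalogMap(
        cluster_a=a.cluster_id,
        cluster_b=b.cluster_id,
        pairs=pairs,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        order_events=events,
    )


_SEPARATOR = "N" * 30  # N never matches, so alignments cannot bridge regions

# Stiffer gaps than the package-wide default: with lenient extension the
# local-alignment statistics enter the linear phase on unrelated DNA and
# spurious coverage swamps the deletion signal.
INTERGENIC_PARAMS = AlignParams(5, -4, -16, -4, "local")


def compare_intergenic(
    a: Cluster,
    b: Cluster,
    pmap: ParalogMap | None = None,
    params: AlignParams | None = None,
    coverage_threshold: float = 0.30,
) -> list[IntergenicComparison]:
    """Locate each intergenic interval of *b* inside *a*'s intergenic space.

    Each interval of b is locally aligned into the concatenation of a's
    intergenic sequences; coverage below *coverage_threshold* flags the
    interval as deleted in a.
    """
    if params is None:
        params = INTERGENIC_PARAMS
    a_parts = [
        extract(a.parent, iv).residues for iv in a.intergenic if iv is not None
    ]
    a_concat = _SEPARATOR.join(a_parts) if a_parts else ""
    out: list[IntergenicComparison] = []
    for idx, iv in enumerate(b.intergenic):
        if iv is None:
            continue
        seq_b = extract(b.parent, iv).residues
        if a_concat:
            aln = align(a_concat, seq_b, params)
        else:
            aln = align("N", seq_b, params)
        if aln.span_b is None:
            identity, coverage = 0.0, 0.0
        else:
            identity = aln.identity_pct
            coverage = len(aln.span_b) / len(seq_b)
        out.append(
            IntergenicComparison(
                flank5=b.genes[idx].name,
                flank3=b.genes[idx + 1].name,
                interval_b=iv,
                identity_pct=identity,
                coverage=coverage,
                deleted_in_a=coverage < coverage_threshold,
            )
        )
    return out
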