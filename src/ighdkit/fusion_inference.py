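"""Scoring of candidate donor pairs for the fusion origin of a target gene.

Scores sequence compatibility only. Alternative mechanisms that the same
evidence supports (gene conversion into a family-3 paralog followed by
fusion; deletion plus repeat insertion into the 3' donor family) are listed
as caveats in reports and are deliberately not distinguished here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .cluster_architecture import DHGene
from .pairwise_align import AlignParams, EndIdentity, LOCAL, end_identity
from .rss_model import RSS_FOOTPRINT, compare_rss

logger = logging.getLogger(__name__)

MECHANISM_CAVEATS = (
    "fusion of a 5' donor onto a 3' donor",
    "gene conversion into another family followed by fusion",
    "deletion followed by repeat insertion into the 3' donor",
)


@dataclass(frozen=True)
class FusionParams:
    weights: tuple[float, float, float, float] = (0.35, 0.35, 0.15, 0.15)
    align: AlignParams = LOCAL
    terminus_slack: int = 5
    breakpoint_pad: int = 2
    min_window: int = 12  # end windows shorter than this are no evidence

    def __post_init__(self) -> None:
        if len(self.weights) != 4 or any(w < 0 for w in self.weights):
            raise ValueError("weights must be 4 non-negative numbers")


@dataclass
class Breakpoint:
    """Closed positional range on the target coding segment.

    May be zero-width (start == end); ``ambiguous`` marks overlapping end
    alignments whose intersection is reported instead.
    """

    start: int
    end: int
    ambiguous: bool = False

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class FusionHypothesis:
    target: str
    donor5: str
    donor3: str
    prefix: EndIdentity
    suffix: EndIdentity
    rss5_diffs: int
    rss3_diffs: int
    breakpoint: Breakpoint | None
    composite: float
    caveats: tuple[str, ...] = MECHANISM_CAVEATS


def locate_breakpoint(
    target: DHGene,
    d5: DHGene,
    d3: DHGene,
    params: FusionParams | None = None,
    prefix: EndIdentity | None = None,
    suffix: EndIdentity | None = None,
) -> Breakpoint:
    """Interval on the target coding between the two end-alignment spans.

    If the prefix and suffix spans overlap, their intersection is returned
    flagged ambiguous. The interval is widened by ``breakpoint_pad`` on each
    side (clipped to the coding segment) to absorb single-base end trimming
    of the local alignments.
    """
    if params is None:
        params = FusionParams()
    if prefix is None:
        prefix = end_identity(d5, target, "five_prime", params.align, params.terminus_slack)
    if suffix is None:
        suffix = end_identity(d3, target, "three_prime", params.align, params.terminus_slack)
    if prefix.alignment.span_b is None or suffix.alignment.span_b is None:
        raise ValueError(
            f"no local alignment for donor pair ({d5.name}, {d3.name}) "
            f"against {target.name}"
        )
    pe = prefix.alignment.span_b.end
    ss = suffix.alignment.span_b.start
    if pe <= ss:
        start, end, ambiguous = pe, ss, False
    else:
        start, end, ambiguous = ss, pe, True
    n = len(target.coding_seq)
    pad = params.breakpoint_pad
    return Breakpoint(max(0, start - pad), min(n, end + pad), ambiguous)


def score_fusion(
    target: DHGene,
    candidates: list[DHGene],
    params: FusionParams | None = None,
) -> list[FusionHypothesis]:
    """Rank every ordered donor pair by the composite compatibility score.

    composite = w1*prefix_id + w2*suffix_id + w3*(1 - rss5_diffs/28)
              + w4*(1 - rss3_diffs/28), identities as fractions.
    Candidates missing an RSS are excluded with a warning; the target itself
    is never a donor. Ties break on (donor5 name, donor3 name).
    """
    if params is None:
        params = FusionParams()
    pool = []
    for c in candidates:
        if c.name == target.name:
            continue
        if c.rss5 is None or c.rss3 is None:
            logger.warning("candidate %s lacks an RSS; excluded", c.name)
            continue
        pool.append(c)
    if len(pool) < 2:
        raise ValueError("need at least two usable donor candidates")
    end5 = {
        c.name: end_identity(c, target, "five_prime", params.align, params.terminus_slack)
        for c in pool
    }
    end3 = {
        c.name: end_identity(c, target, "three_prime", params.align, params.terminus_slack)
        for c in pool
    }
    rss5 = {
        c.name: compare_rss(target.rss5, c.rss5).total_diffs
        for c in pool
        if target.rss5 is not None
    }
    rss3 = {
        c.name: compare_rss(target.rss3, c.rss3).total_diffs
        for c in pool
        if target.rss3 is not None
    }
    w1, w2, w3, w4 = params.weights
    hypotheses: list[FusionHypothesis] = []
    for d5 in pool:
        for d3 in pool:
            if d5.name == d3.name:
                continue
            prefix, suffix = end5[d5.name], end3[d3.name]
            r5 = rss5.get(d5.name, RSS_FOOTPRINT)
            r3 = rss3.get(d3.name, RSS_FOOTPRINT)
            # an alignment that misses the terminus or covers only a trivial
            # window is no evidence for that end, however identical it is
            pre_id = (
                prefix.identity_pct
                if prefix.at_terminus and prefix.window_nt >= params.min_window
                else 0.0
            )
            suf_id = (
                suffix.identity_pct
                if suffix.at_terminus and suffix.window_nt >= params.min_window
                else 0.0
            )
            composite = (
                w1 * pre_id / 100.0
                + w2 * suf_id / 100.0
                + w3 * (1.0 - r5 / RSS_FOOTPRINT)
                + w4 * (1.0 - r3 / RSS_FOOTPRINT)
            )
            try:
                bp = locate_breakpoint(
                    target, d5, d3, params, prefix=prefix, suffix=suffix
                )
            except ValueError:
                bp = None
            hypotheses.append(
                FusionHypothesis(
                    target=target.name,
                    donor5=d5.name,
                    donor3=d3.name,
                    prefix=prefix,
                    suffix=suffix,
                    rss5_diffs=r5,
                    rss3_diffs=r3,
                    breakpoint=bp,
                    composite=composite,
                )
            )
    hypotheses.sort(key=lambda h: (-h.composite, h.donor5, h.donor3))
    return hypotheses


@dataclass
class CodonMatch:
    donor_codon: int
    target_codon: int
    donor_aa: str
    target_aa: str
    agrees: bool


@dataclass
class CodonCheckResult:
    residue: str
    matches: list[CodonMatch]
    any_shared: bool
    stop_in_window: bool


def conserved_codon_check(
    target: DHGene,
    donor: DHGene,
    codon: str = "C",
    frame: int = 0,
    params: FusionParams | None = None,
) -> CodonCheckResult:
    """Check whether donor and target encode *codon* at aligned positions.

    Alignment is the 5' end-identity local alignment; codon coordinates use
    *frame* (offset into the coding segment). Internal stops inside the
    aligned window are flagged.
    """
    if params is None:
        params = FusionParams()
    ei = end_identity(donor, target, "five_prime", params.align, params.terminus_slack)
    aln = ei.alignment
    if aln.span_a is None or aln.span_b is None:
        return CodonCheckResult(codon, [], False, False)
    def _translate(seq: str) -> str:
        usable = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
        return str(Seq(usable).translate())

    donor_aa = _translate(donor.coding_seq)
    target_aa = _translate(target.coding_seq)
    # positional map over non-gap alignment columns
    pmap: dict[int, int] = {}
    p, q = aln.span_a.start, aln.span_b.start
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            pmap[p] = q
        if x != "-":
            p += 1
        if y != "-":
            q += 1
    matches: list[CodonMatch] = []
    stop = False
    for cd, aa in enumerate(donor_aa):
        mid = frame + 3 * cd + 1
        if mid not in pmap:
            continue
        cq = (pmap[mid] - frame) // 3
        if cq < 0 or cq >= len(target_aa):
            continue
        if aa == "*" or target_aa[cq] == "*":
            stop = True
        if aa != codon:
            continue
        matches.append(
            CodonMatch(
                donor_codon=cd,
                target_codon=cq,
                donor_aa=aa,
                target_aa=target_aa[cq],
                agrees=target_aa[cq] == codon,
            )
        )
    return CodonCheckResult(
        residue=codon,
        matches=matches,
        any_shared=any(m.agrees for m in matches),
        stop_in_window=stop,
    )
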