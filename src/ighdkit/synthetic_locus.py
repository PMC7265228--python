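"""Simulation of a duplicated D-gene cluster locus with ground truth.

An ancestral cluster of RSS-flanked genes is duplicated into several
clusters with point substitutions; one designated cluster then receives a
scripted segmental deletion that fuses two adjacent genes (preserving the
outer RSSs), a gene transposition, and a repeat expansion of the fused
gene. Every edit is logged with coordinates valid at the moment it was
applied, so replaying the event list on the ancestor reproduces the
emitted locus byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .locus_io import AnnotationRecord, Interval, NucSequence, write_annotations, write_fasta
from .rss_model import FIVE_PRIME_MOTIF, THREE_PRIME_MOTIF

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# primitive hexamers from distinct rotation classes; the two fused genes
# share a unit so the junction can fall inside homologous repeats
DEFAULT_REPEAT_UNITS = ("TGGTTA", "GGTAGC", "TACGAC", "AGGTCC", "TTGCAC", "CAGGAT")


@dataclass(frozen=True)
class SimParams:
    n_genes: int = 6
    n_clusters: int = 3
    mu: float = 0.02
    repeat_units: tuple[str, ...] = DEFAULT_REPEAT_UNITS
    expansion_geom_p: float = 0.5
    intergenic_len_range: tuple[int, int] = (300, 700)
    intercluster_gap_range: tuple[int, int] = (2500, 3500)
    flank_len_range: tuple[int, int] = (12, 28)
    copies_range: tuple[int, int] = (3, 6)
    fuse_ordinals: tuple[int, int] = (2, 3)
    transpose_ordinal: int = 4
    target_cluster: int = 0
    junction_in_repeat_p: float = 0.5
    protect_rss: bool = True
    max_fused_coding: int = 190
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 0.2):
            raise ValueError("mu must be in [0, 0.2]")
        if self.n_genes < 2:
            raise ValueError("need at least two genes per cluster")
        if self.fuse_ordinals[1] != self.fuse_ordinals[0] + 1:
            raise ValueError("fused genes must be adjacent")
        if not (0 <= self.fuse_ordinals[0] < self.fuse_ordinals[1] < self.n_genes):
            raise ValueError("fuse_ordinals out of range")


@dataclass
class TruthLog:
    events: list[dict] = field(default_factory=list)
    final_annotations: list[AnnotationRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@dataclass
class _GeneTemplate:
    """Ancestral gene geometry, coordinates in the ancestor frame."""

    ordinal: int
    rss5: tuple[int, int]
    coding: tuple[int, int]
    rss3: tuple[int, int]
    unit: str
    array: tuple[int, int]  # repeat array span, ancestor frame


def simulate_ancestor(params: SimParams) -> tuple[NucSequence, TruthLog]:
    """One cluster of RSS-flanked genes with planted consensus RSS elements.

    Each coding region is unique flank + tandem repeat array + unique
    flank. Deterministic for a given seed.
    """
    rng = np.random.default_rng(params.seed)
    parts: list[str] = []
    pos = 0
    genes: list[_GeneTemplate] = []
    i0, j0 = params.fuse_ordinals
    for i in range(params.n_genes):
        unit = params.repeat_units[i % len(params.repeat_units)]
        if i == j0:
            unit = params.repeat_units[i0 % len(params.repeat_units)]
        rss5 = (
            FIVE_PRIME_MOTIF.nonamer_consensus
            + _random_dna(rng, 12)
            + FIVE_PRIME_MOTIF.heptamer_consensus
        )
        left = _random_dna(rng, int(rng.integers(*params.flank_len_range)))
        copies = int(rng.integers(params.copies_range[0], params.copies_range[1] + 1))
        right = _random_dna(rng, int(rng.integers(*params.flank_len_range)))
        rss3 = (
            THREE_PRIME_MOTIF.heptamer_consensus
            + _random_dna(rng, 12)
            + THREE_PRIME_MOTIF.nonamer_consensus
        )
        coding = left + unit * copies + right
        genes.append(
            _GeneTemplate(
                ordinal=i,
                rss5=(pos, pos + 28),
                coding=(pos + 28, pos + 28 + len(coding)),
                rss3=(pos + 28 + len(coding), pos + 56 + len(coding)),
                unit=unit,
                array=(
                    pos + 28 + len(left),
                    pos + 28 + len(left) + len(unit) * copies,
                ),
            )
        )
        parts.append(rss5 + coding + rss3)
        pos += 56 + len(coding)
        if i < params.n_genes - 1:
            gap = _random_dna(rng, int(rng.integers(*params.intergenic_len_range)))
            parts.append(gap)
            pos += len(gap)
    residues = "".join(parts)
    seq = NucSequence(id=f"ancestor_seed{params.seed}", residues=residues, source="simulated")
    annotations = [
        AnnotationRecord(
            name=f"D{g.ordinal + 1}",
            interval=Interval(g.rss5[0], g.rss3[1]),
            feature_type="gene",
            seq_id=seq.id,
        )
        for g in genes
    ]
    truth = TruthLog(
        events=[],
        final_annotations=annotations,
        meta={
            "kind": "ancestor",
            "seed": params.seed,
            "genes": [asdict(g) for g in genes],
            "ancestor_residues": residues,
        },
    )
    return seq, truth


def _protected_mask(length: int, offsets: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in offsets:
        mask[s:e] = True
    return mask


def evolve(
    ancestor: tuple[NucSequence, TruthLog], params: SimParams
) -> tuple[NucSequence, TruthLog]:
    """Duplicate, mutate and structurally rearrange the ancestral cluster."""
    anc_seq, anc_truth = ancestor
    anc = anc_seq.residues
    templates = [_GeneTemplate(**d) if not isinstance(d, _GeneTemplate) else d
                 for d in anc_truth.meta["genes"]]
    templates = [
        _GeneTemplate(
            ordinal=t.ordinal,
            rss5=tuple(t.rss5),
            coding=tuple(t.coding),
            rss3=tuple(t.rss3),
            unit=t.unit,
            array=tuple(t.array),
        )
        for t in templates
    ]
    rng = np.random.default_rng([params.seed, 0xE0])
    events: list[dict] = []
    L = len(anc)

    # --- assembly: cluster 0 is the ancestor; further copies appended ------
    locus = anc
    offsets = [0]
    for k in range(1, params.n_clusters):
        gap = _random_dna(rng, int(rng.integers(*params.intercluster_gap_range)))
        events.append({"type": "duplication", "gap_seq": gap, "source_len": L})
        offsets.append(len(locus) + len(gap))
        locus = locus + gap + anc

    # per-cluster gene bookkeeping: dicts with absolute element coordinates
    clusters: list[list[dict]] = []
    for k, off in enumerate(offsets):
        clusters.append(
            [
                {
                    "name": f"D{t.ordinal + 1}-{k + 1}",
                    "family": t.ordinal + 1,
                    "rss5": [t.rss5[0] + off, t.rss5[1] + off],
                    "coding": [t.coding[0] + off, t.coding[1] + off],
                    "rss3": [t.rss3[0] + off, t.rss3[1] + off],
                    "unit": t.unit,
                    "array": [t.array[0] + off, t.array[1] + off],
                }
                for t in templates
            ]
        )

    # --- substitutions -----------------------------------------------------
    chars = list(locus)
    for k, off in enumerate(offsets):
        protected: list[tuple[int, int]] = []
        if params.protect_rss:
            for g in clusters[k]:
                protected.append((g["rss5"][0], g["rss5"][1]))
                protected.append((g["rss3"][0], g["rss3"][1]))
        mask = _protected_mask(len(chars), [(off, off + L)])
        pmask = _protected_mask(len(chars), protected)
        eligible = np.flatnonzero(mask & ~pmask)
        hits = eligible[rng.random(eligible.size) < params.mu]
        subs = []
        for p in hits:
            old = chars[p]
            alternatives = [b for b in "ACGT" if b != old]
            new = alternatives[int(rng.integers(0, 3))]
            chars[p] = new
            subs.append([int(p), old, new])
        events.append({"type": "substitution_batch", "cluster": k, "subs": subs})
    locus = "".join(chars)

    # --- deletion fusing two adjacent genes of the target cluster ----------
    t = params.target_cluster
    i0, j0 = params.fuse_ordinals
    gi, gj = clusters[t][i0], clusters[t][j0]
    len_i = gi["coding"][1] - gi["coding"][0]
    len_j = gj["coding"][1] - gj["coding"][0]
    ai = (gi["array"][0] - gi["coding"][0], gi["array"][1] - gi["coding"][0])
    aj = (gj["array"][0] - gj["coding"][0], gj["array"][1] - gj["coding"][0])
    in_repeat = bool(rng.random() < params.junction_in_repeat_p)
    if in_repeat:
        cut_i = int(rng.integers(max(ai[0], 15), max(ai[1] - 1, 16)))
        cut_j = int(rng.integers(max(aj[0], 3), max(min(aj[1], len_j - 15), aj[0] + 4)))
    else:
        cut_i = int(rng.integers(15, len_i - 2))
        cut_j = int(rng.integers(3, len_j - 14))
    del_start = gi["coding"][0] + cut_i
    del_end = gj["coding"][0] + cut_j
    del_len = del_end - del_start
    # equivalence interval of the junction: cut pairs (cut_i+d, cut_j+d)
    # produce an identical fused sequence while the donors agree around the
    # cuts, so the true junction is only defined up to this window
    ci = locus[gi["coding"][0] : gi["coding"][1]]
    cj = locus[gj["coding"][0] : gj["coding"][1]]
    left_run = 0
    while (
        cut_i - 1 - left_run >= 0
        and cut_j - 1 - left_run >= 0
        and ci[cut_i - 1 - left_run] == cj[cut_j - 1 - left_run]
    ):
        left_run += 1
    right_run = 0
    while (
        cut_i + right_run < len_i
        and cut_j + right_run < len_j
        and ci[cut_i + right_run] == cj[cut_j + right_run]
    ):
        right_run += 1
    junction_lo = cut_i - left_run
    junction_hi = cut_i + right_run
    locus = locus[:del_start] + locus[del_end:]
    events.append({"type": "deletion_fusion", "start": del_start, "end": del_end})

    fused = {
        "name": f"D{params.n_genes + 2}-{t + 1}",
        "family": params.n_genes + 2,
        "rss5": list(gi["rss5"]),
        "coding": [gi["coding"][0], gj["coding"][1] - del_len],
        "rss3": [gj["rss3"][0] - del_len, gj["rss3"][1] - del_len],
        "unit": gj["unit"],
        "array": None,
    }
    junction = cut_i  # offset of the fusion point in the fused coding

    def _shift_all(threshold: int, delta: int) -> None:
        for k in range(params.n_clusters):
            for g in clusters[k]:
                for key in ("rss5", "coding", "rss3", "array"):
                    if g.get(key):
                        g[key] = [
                            c + delta if c >= threshold else c for c in g[key]
                        ]

    _shift_all(del_end, -del_len)
    order = [g for idx, g in enumerate(clusters[t]) if idx not in (i0, j0)]
    order.insert(i0, fused)
    clusters[t] = order

    # --- transposition: move one gene in front of the fused gene -----------
    moved_name = f"D{params.transpose_ordinal + 1}-{t + 1}"
    midx = next(i for i, g in enumerate(clusters[t]) if g["name"] == moved_name)
    gm = clusters[t][midx]
    seg_start, seg_end = gm["rss5"][0], gm["rss3"][1]
    seg_len = seg_end - seg_start
    dest = fused["rss5"][0]
    assert dest < seg_start, "transposed gene must start downstream of the fused gene"
    seg = locus[seg_start:seg_end]
    locus = locus[:dest] + seg + locus[dest:seg_start] + locus[seg_end:]
    events.append(
        {
            "type": "transposition",
            "seg_start": seg_start,
            "seg_end": seg_end,
            "insert_at": dest,
        }
    )
    move_delta = dest - seg_start
    for key in ("rss5", "coding", "rss3", "array"):
        if gm.get(key):
            gm[key] = [c + move_delta for c in gm[key]]
    # genes between dest and seg_start shift right by the segment length
    for k in range(params.n_clusters):
        for g in clusters[k]:
            if g is gm:
                continue
            for key in ("rss5", "coding", "rss3", "array"):
                if g.get(key):
                    g[key] = [
                        c + seg_len if dest <= c < seg_start else c for c in g[key]
                    ]
    clusters[t].remove(gm)
    fidx = clusters[t].index(fused)
    clusters[t].insert(fidx, gm)

    # --- repeat expansion of the fused gene --------------------------------
    n_extra = int(rng.geometric(params.expansion_geom_p))
    fused_len = fused["coding"][1] - fused["coding"][0]
    unit_len = len(fused["unit"])
    cap = max(0, (params.max_fused_coding - fused_len) // unit_len)
    n_extra = min(n_extra, cap)
    if cut_j < aj[1]:  # gene j's array survives in part: insert at its start
        insert_off = junction + max(aj[0] - cut_j, 0)
        shifts_junction = False
    elif cut_i > ai[0]:  # fall back to the prefix-side array of gene i
        insert_off = min(cut_i, ai[1])
        shifts_junction = True
    else:
        insert_off = junction
        shifts_junction = False
    insert_at = fused["coding"][0] + insert_off
    insertion = fused["unit"] * n_extra
    locus = locus[:insert_at] + insertion + locus[insert_at:]
    events.append(
        {"type": "repeat_expansion", "insert_at": insert_at, "seq": insertion}
    )
    ins_len = len(insertion)
    fused["coding"][1] += ins_len
    fused["rss3"] = [c + ins_len for c in fused["rss3"]]
    for k in range(params.n_clusters):
        for g in clusters[k]:
            if g is fused:
                continue
            for key in ("rss5", "coding", "rss3", "array"):
                if g.get(key):
                    g[key] = [c + ins_len if c >= insert_at else c for c in g[key]]
    if ins_len:
        # a cut at a position strictly before the insertion point keeps its
        # coordinate; later equivalent cuts shift with the inserted bases
        if insert_off < junction_lo:
            junction_lo += ins_len
            junction_hi += ins_len
        elif insert_off <= junction_hi:
            junction_hi += ins_len
        if shifts_junction:
            junction += ins_len

    # --- final annotations and meta ----------------------------------------
    seq_id = f"locus_seed{params.seed}"
    annotations: list[AnnotationRecord] = []
    for k in range(params.n_clusters):
        span = Interval(clusters[k][0]["rss5"][0], clusters[k][-1]["rss3"][1])
        annotations.append(
            AnnotationRecord(
                name=f"cluster{k + 1}", interval=span, feature_type="cluster", seq_id=seq_id
            )
        )
        for g in clusters[k]:
            annotations.append(
                AnnotationRecord(
                    name=g["name"],
                    interval=Interval(g["rss5"][0], g["rss3"][1]),
                    feature_type="gene",
                    seq_id=seq_id,
                )
            )
    meta = {
        "kind": "locus",
        "seed": params.seed,
        "n_clusters": params.n_clusters,
        "n_genes": params.n_genes,
        "mu": params.mu,
        "target_cluster": t + 1,
        "fused_gene": fused["name"],
        "fused_from_families": [i0 + 1, j0 + 1],
        "donor5_family": i0 + 1,
        "donor3_family": j0 + 1,
        "transposed_gene": moved_name,
        "deletion_len": del_len,
        "junction": junction,
        "junction_interval": [junction_lo, junction_hi],
        "junction_in_repeat": in_repeat,
        "expansion_copies": n_extra,
        "expansion_unit": fused["unit"],
        "clusters": [
            {
                "cluster": k + 1,
                "genes": [
                    {
                        "name": g["name"],
                        "family": g["family"],
                        "rss5": g["rss5"],
                        "coding": g["coding"],
                        "rss3": g["rss3"],
                    }
                    for g in clusters[k]
                ],
            }
            for k in range(params.n_clusters)
        ],
        "ancestor_residues": anc,
    }
    truth = TruthLog(events=events, final_annotations=annotations, meta=meta)
    return NucSequence(id=seq_id, residues=locus, source="simulated"), truth


def simulate(params: SimParams) -> tuple[NucSequence, TruthLog]:
    """Convenience: simulate_ancestor followed by evolve."""
    return evolve(simulate_ancestor(params), params)


def replay(ancestor_residues: str, events: list[dict]) -> str:
    """Re-apply a logged event list to the ancestral sequence."""
    anc = ancestor_residues
    locus = anc
    for ev in events:
        kind = ev["type"]
        if kind == "duplication":
            locus = locus + ev["gap_seq"] + anc
        elif kind == "substitution_batch":
            chars = list(locus)
            for pos, old, new in ev["subs"]:
                if chars[pos] != old:
                    raise ValueError(f"replay mismatch at {pos}: {chars[pos]} != {old}")
                chars[pos] = new
            locus = "".join(chars)
        elif kind == "deletion_fusion":
            locus = locus[: ev["start"]] + locus[ev["end"] :]
        elif kind == "transposition":
            s, e, d = ev["seg_start"], ev["seg_end"], ev["insert_at"]
            seg = locus[s:e]
            without = locus[:s] + locus[e:]
            locus = without[:d] + seg + without[d:]
        elif kind == "repeat_expansion":
            p = ev["insert_at"]
            locus = locus[:p] + ev["seq"] + locus[p:]
        else:
            raise ValueError(f"unknown event type {kind!r}")
    return locus


def emit(locus: NucSequence, truth: TruthLog, out_dir: str | Path) -> dict[str, Path]:
    """Write locus FASTA, annotation BED and the truth log JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "locus.fasta"
    bed = out_dir / "annotations.bed"
    truth_json = out_dir / "truth.json"
    write_fasta([locus], fasta)
    write_annotations(truth.final_annotations, bed, format="bed")
    payload = {
        "events": truth.events,
        "final_annotations": [
            {
                "name": r.name,
                "start": r.interval.start,
                "end": r.interval.end,
                "strand": r.interval.strand,
                "feature_type": r.feature_type,
                "seq_id": r.seq_id,
            }
            for r in truth.final_annotations
        ],
        "meta": truth.meta,
    }
    with open(truth_json, "w") as fh:
        json.dump(payload, fh, indent=1)
    return {"fasta": fasta, "bed": bed, "truth": truth_json}


def load_truth(path: str | Path) -> TruthLog:
    with open(path) as fh:
        payload = json.load(fh)
    annotations = [
        AnnotationRecord(
            name=r["name"],
            interval=Interval(r["start"], r["end"], r["strand"]),
            feature_type=r["feature_type"],
            seq_id=r["seq_id"],
        )
        for r in payload["final_annotations"]
    ]
    return TruthLog(
        events=payload["events"],
        final_annotations=annotations,
        meta=payload["meta"],
    )
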