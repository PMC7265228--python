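"""Tandem-repeat decomposition of D-gene coding regions.

Arrays are found by an exhaustive period scan over unit lengths and starts,
then selected greedily (longest span first, then smaller unit, then
leftmost). Units are compared by canonical cyclic rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .locus_io import Interval, NucSequence


def canonical_unit(u: str) -> str:
    """Lexicographically smallest cyclic rotation; idempotent."""
    if not u:
        raise ValueError("unit must be nonempty")
    u = u.upper()
    return min(u[i:] + u[:i] for i in range(len(u)))


@dataclass
class RepeatArray:
    unit: str  # canonical rotation
    unit_len: int
    copies: float  # fractional copies at half-unit resolution
    span: Interval
    mismatches: int
    seed_unit: str = ""  # unit as it occurs at span start (pre-canonicalization)


@dataclass
class RepeatProfile:
    gene: str
    arrays: list[RepeatArray] = field(default_factory=list)
    unexplained: float = 1.0
    coding_len: int = 0


@dataclass
class UnitDelta:
    unit: str
    copies_a: float
    copies_b: float

    @property
    def delta(self) -> float:
        return self.copies_a - self.copies_b


@dataclass
class ProfileComparison:
    gene_a: str
    gene_b: str
    shared: list[UnitDelta]
    private_a: list[RepeatArray]
    private_b: list[RepeatArray]
    length_delta: int


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _extend_array(
    s: str, start: int, unit_len: int, max_mm_per_copy: int
) -> tuple[int, float, int]:
    """Maximal tandem run of period *unit_len* starting at *start*.

    The first window is the reference unit; each further full copy may carry
    up to *max_mm_per_copy* mismatches against it. A trailing partial copy
    counts 0.5 when at least half the unit matches within the tolerance.
    Returns (end, copies, mismatches).
    """
    unit = s[start : start + unit_len]
    pos = start + unit_len
    copies = 1.0
    mm_total = 0
    while pos + unit_len <= len(s):
        mm = _mismatches(s[pos : pos + unit_len], unit)
        if mm > max_mm_per_copy:
            break
        copies += 1.0
        mm_total += mm
        pos += unit_len
    # trailing partial copy: count the matched prefix, at half-unit grain
    tail = s[pos : pos + unit_len]
    if tail:
        prefix = 0
        mm = 0
        for x, y in zip(tail, unit):
            if x != y:
                mm += 1
                if mm > max_mm_per_copy:
                    break
            prefix += 1
        if prefix >= (unit_len + 1) // 2 and prefix >= 2:
            copies += 0.5
            mm_total += mm if mm <= max_mm_per_copy else 0
            pos += prefix
    return pos, copies, mm_total


def decompose(
    coding: NucSequence | str,
    min_unit: int = 3,
    max_unit: int = 12,
    max_mm_per_copy: int = 1,
    gene: str = "",
) -> RepeatProfile:
    """Greedy non-overlapping decomposition into tandem repeat arrays."""
    if isinstance(coding, NucSequence):
        s = coding.residues
        gene = gene or coding.id
    else:
        s = coding.upper()
    n = len(s)
    if n < 2 * min_unit:
        return RepeatProfile(gene=gene, arrays=[], unexplained=1.0, coding_len=n)
    def _allowed(unit_len: int) -> int:
        # tolerance scales with unit length: one mismatch per 3-nt copy is a
        # 33% error rate and lets short pseudo-periods absorb real arrays
        return min(max_mm_per_copy, unit_len // 4)

    def _primitive(unit: str) -> bool:
        # a unit that is itself a tolerant repetition of a shorter unit
        # belongs to that shorter period's candidate, not its own
        for d in range(min_unit, len(unit) // 2 + 1):
            if len(unit) % d:
                continue
            head = unit[:d]
            if all(
                _mismatches(unit[i : i + d], head) <= _allowed(d)
                for i in range(d, len(unit), d)
            ):
                return False
        return True

    candidates: list[RepeatArray] = []
    for unit_len in range(min_unit, max_unit + 1):
        allowed_mm = _allowed(unit_len)
        for start in range(0, n - 2 * unit_len + 1):
            end, copies, mm = _extend_array(s, start, unit_len, allowed_mm)
            if copies >= 2.0:
                seed = s[start : start + unit_len]
                if not _primitive(seed):
                    continue
                candidates.append(
                    RepeatArray(
                        unit=canonical_unit(seed),
                        unit_len=unit_len,
                        copies=copies,
                        span=Interval(start, end),
                        mismatches=mm,
                        seed_unit=seed,
                    )
                )
    candidates.sort(
        key=lambda r: (-len(r.span), r.unit_len, r.mismatches, r.span.start)
    )
    chosen: list[RepeatArray] = []
    for cand in candidates:
        if all(not cand.span.overlaps(c.span) for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.span.start)
    covered = sum(len(r.span) for r in chosen)
    return RepeatProfile(
        gene=gene, arrays=chosen, unexplained=1.0 - covered / n, coding_len=n
    )


def compare_profiles(a: RepeatProfile, b: RepeatProfile) -> ProfileComparison:
    """Pair arrays of identical canonical unit; report copy-number deltas.

    Arrays sharing a unit are aggregated by summed copies; units present in
    only one profile are reported as private. length_delta is the coding
    length difference (a minus b).
    """

    def _by_unit(p: RepeatProfile) -> dict[str, float]:
        out: dict[str, float] = {}
        for arr in p.arrays:
            out[arr.unit] = out.get(arr.unit, 0.0) + arr.copies
        return out

    units_a, units_b = _by_unit(a), _by_unit(b)
    shared = [
        UnitDelta(unit=u, copies_a=units_a[u], copies_b=units_b[u])
        for u in sorted(set(units_a) & set(units_b))
    ]
    private_a = [arr for arr in a.arrays if arr.unit not in units_b]
    private_b = [arr for arr in b.arrays if arr.unit not in units_a]
    length_delta = a.coding_len - b.coding_len
    return ProfileComparison(
        gene_a=a.gene,
        gene_b=b.gene,
        shared=shared,
        private_a=private_a,
        private_b=private_b,
        length_delta=length_delta,
    )


def render_profile(profile: RepeatProfile, seq: str) -> str:
    """Plain-text rendering with bracketed array boundaries."""
    marks: list[tuple[int, str]] = []
    for arr in profile.arrays:
        marks.append((arr.span.start, f"[{arr.unit}x{arr.copies:g} "))
        marks.append((arr.span.end, "]"))
    marks.sort(key=lambda t: t[0])
    out = []
    pos = 0
    for at, text in marks:
        out.append(seq[pos:at])
        out.append(text)
        pos = at
    out.append(seq[pos:])
    return "".join(out)
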