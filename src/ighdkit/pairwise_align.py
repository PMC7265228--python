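"""Native pairwise global/local/semiglobal alignment with affine gaps.

Every percent-identity figure produced by this package flows through this
module. Correctness is defined by the quadratic Gotoh DP below; the fill
kernels are numba-jitted when numba is importable and run as plain Python
otherwise (identical code path).

Conventions
-----------
* A gap run of length k costs ``gap_open + (k-1) * gap_extend``.
* Tie-breaking prefers diagonal, then up (gap in b), then left.
* A column is a match iff both characters are equal and neither is a gap
  or N. Internal gap columns count in the identity denominator; in
  semiglobal mode terminal overhangs are trimmed from the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .locus_io import Interval, NucSequence, normalize_residues

try:  # numba is optional at runtime
    from numba import njit as _njit

    def njit(func):
        return _njit(cache=True)(func)

except ImportError:  # pragma: no cover

    def njit(func):
        return func


_NEG = -(1 << 30)
_N_CODE = 4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_MODE_CODES = {"global": 0, "local": 1, "semiglobal": 2, "local_prefix": 3}
_START = 3  # pointer sentinel: path starts at this cell


@dataclass(frozen=True)
class AlignParams:
    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -2
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap scores must be <= 0")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend")
        if self.mode not in _MODE_CODES:
            raise ValueError(f"unknown mode {self.mode!r}")


GLOBAL = AlignParams(mode="global")
LOCAL = AlignParams(mode="local")
SEMIGLOBAL = AlignParams(mode="semiglobal")


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: int
    span_a: Interval | None
    span_b: Interval | None
    params: AlignParams = field(default=GLOBAL)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            x == y and x != "-" and x != "N"
            for x, y in zip(self.aligned_a, self.aligned_b)
        )

    @property
    def identity_pct(self) -> float:
        if self.columns == 0:
            raise ZeroDivisionError("identity undefined for a zero-column alignment")
        return 100.0 * self.matches / self.columns


@dataclass
class EndIdentity:
    donor: str
    target: str
    end: str
    window_nt: int
    identity_pct: float
    alignment: PairwiseAlignment
    at_terminus: bool


@njit
def _fill(a, b, match, mismatch, gap_open, gap_extend, mode):
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, np.int32)
    X = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in b (consume a, "up")
    Y = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in a (consume b, "left")
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    M[0, 0] = 0
    pM[0, 0] = _START
    for i in range(1, n + 1):
        if mode == 0:  # global: leading gap in b is penalized
            X[i, 0] = gap_open + (i - 1) * gap_extend
            pX[i, 0] = 0 if i == 1 else 1
        elif mode == 2:  # semiglobal: free leading overhang
            X[i, 0] = 0
            pX[i, 0] = _START
    for j in range(1, m + 1):
        if mode == 0:
            Y[0, j] = gap_open + (j - 1) * gap_extend
            pY[0, j] = 0 if j == 1 else 2
        elif mode == 2:
            Y[0, j] = 0
            pY[0, j] = _START
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            if ai == bj and ai != _N_CODE:
                s = match
            else:
                s = mismatch
            # match/mismatch state; tie-break prefers M, then X, then Y
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            if (mode == 1 or (mode == 3 and j == 1)) and best <= 0:
                # fresh local start; local_prefix may only start on b's
                # first character (terminus-anchored local alignment)
                best = 0
                p = _START
            M[i, j] = best + s
            pM[i, j] = p
            # gap in b (up)
            best = M[i - 1, j] + gap_open
            p = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                p = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                p = 2
            X[i, j] = best
            pX[i, j] = p
            # gap in a (left)
            best = M[i, j - 1] + gap_open
            p = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                p = 1
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                p = 2
            Y[i, j] = best
            pY[i, j] = p
    return M, X, Y, pM, pX, pY


def _find_end(M, X, Y, n, m, mode):
    """Terminal cell/state under the deterministic preference order."""
    if mode == 0:
        state = 0
        best = M[n, m]
        if X[n, m] > best:
            best, state = X[n, m], 1
        if Y[n, m] > best:
            best, state = Y[n, m], 2
        return int(best), n, m, state
    if mode in (1, 3):
        idx = int(np.argmax(M))
        i, j = divmod(idx, M.shape[1])
        return int(M[i, j]), i, j, 0
    # semiglobal: best over last row and last column, prefer M over X over Y
    best, bi, bj, bstate = _NEG, n, m, 0
    for i in range(n + 1):
        for arr, state in ((M, 0), (X, 1), (Y, 2)):
            if arr[i, m] > best:
                best, bi, bj, bstate = int(arr[i, m]), i, m, state
    for j in range(m + 1):
        for arr, state in ((M, 0), (X, 1), (Y, 2)):
            if arr[n, j] > best:
                best, bi, bj, bstate = int(arr[n, j]), n, j, state
    return best, bi, bj, bstate


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))), dtype=np.uint8)


def align(a, b, params: AlignParams = GLOBAL) -> PairwiseAlignment:
    """Optimal pairwise alignment of two sequences under *params*.

    Accepts NucSequence or plain strings. In local mode with no
    positive-scoring cell an empty alignment (score 0) is returned.
    """
    sa = a.residues if isinstance(a, NucSequence) else normalize_residues(str(a))
    sb = b.residues if isinstance(b, NucSequence) else normalize_residues(str(b))
    mode = _MODE_CODES[params.mode]
    if not sa or not sb:
        if mode == 0:
            raise ValueError("global alignment requires nonempty sequences")
        return PairwiseAlignment("", "", 0, None, None, params)
    M, X, Y, pM, pX, pY = _fill(
        _encode(sa),
        _encode(sb),
        params.match,
        params.mismatch,
        params.gap_open,
        params.gap_extend,
        mode,
    )
    n, m = len(sa), len(sb)
    score, i, j, state = _find_end(M, X, Y, n, m, mode)
    if mode in (1, 3) and score <= 0:
        return PairwiseAlignment("", "", 0, None, None, params)
    end_i, end_j = i, j
    out_a: list[str] = []
    out_b: list[str] = []
    ptrs = (pM, pX, pY)
    while True:
        if mode == 0 and i == 0 and j == 0:
            break
        if mode == 2 and (i == 0 or j == 0):
            break
        p = ptrs[state][i, j]
        if state == 0:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
        if p == _START:
            break
        state = p
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    span_a = Interval(i, end_i) if end_i > i else None
    span_b = Interval(j, end_j) if end_j > j else None
    return PairwiseAlignment(aligned_a, aligned_b, score, span_a, span_b, params)


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 * matches / columns under the package-wide match definition."""
    return aln.identity_pct


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Reporting-layer rounding (round-half-up, as printed figures use)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _coding_of(gene) -> str:
    if isinstance(gene, NucSequence):
        return gene.residues
    if isinstance(gene, str):
        return gene.upper()
    return gene.coding_seq


def _name_of(gene) -> str:
    if isinstance(gene, NucSequence):
        return gene.id
    if isinstance(gene, str):
        return "<anonymous>"
    return gene.name


def anchored_end_align(
    donor_seq: str, target_seq: str, end: str, params: AlignParams
) -> PairwiseAlignment:
    """Best local alignment whose target span is pinned to one target end.

    five_prime pins the alignment start to target position 0; three_prime
    is realized by aligning both sequences reversed and mapping back.
    """
    p = AlignParams(
        params.match, params.mismatch, params.gap_open, params.gap_extend, "local_prefix"
    )
    if end == "five_prime":
        return align(donor_seq, target_seq, p)
    aln = align(donor_seq[::-1], target_seq[::-1], p)
    if aln.span_a is None or aln.span_b is None:
        return PairwiseAlignment("", "", 0, None, None, p)
    la, lb = len(donor_seq), len(target_seq)
    return PairwiseAlignment(
        aligned_a=aln.aligned_a[::-1],
        aligned_b=aln.aligned_b[::-1],
        score=aln.score,
        span_a=Interval(la - aln.span_a.end, la - aln.span_a.start),
        span_b=Interval(lb - aln.span_b.end, lb - aln.span_b.start),
        params=p,
    )


def end_identity(
    donor,
    target,
    end: str,
    params: AlignParams | None = None,
    terminus_slack: int = 5,
) -> EndIdentity:
    """Best terminus-anchored local alignment of donor vs target coding.

    ``window_nt`` is the aligned span length on the target; ``at_terminus``
    records whether that span abuts the requested target end within
    *terminus_slack* nt (true by construction unless no alignment exists).
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError(f"invalid end {end!r}")
    if params is None:
        params = LOCAL
    donor_seq = _coding_of(donor)
    target_seq = _coding_of(target)
    aln = anchored_end_align(donor_seq, target_seq, end, params)
    if aln.span_b is None:
        return EndIdentity(
            _name_of(donor), _name_of(target), end, 0, 0.0, aln, False
        )
    window_nt = len(aln.span_b)
    if end == "five_prime":
        at_term = aln.span_b.start <= terminus_slack
    else:
        at_term = len(target_seq) - aln.span_b.end <= terminus_slack
    return EndIdentity(
        donor=_name_of(donor),
        target=_name_of(target),
        end=end,
        window_nt=window_nt,
        identity_pct=aln.identity_pct,
        alignment=aln,
        at_terminus=at_term,
    )
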