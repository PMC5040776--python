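"""Word-seeded local nucleotide homology search.

The search mirrors the classic word-seeded BLASTn strategy used to trace
short RNA queries (19-250 nt) across whole fungal genome assemblies: exact
word matches of length ``word_size`` (default 19) seed an ungapped X-drop
extension, which is then refined by an affine-gap local alignment restricted
to a window around the seeded region.  Hits are scored with simple
nucleotide weights (match +2, mismatch -3, gap open -5, gap extend -2) and
filtered by an expectation value ``E = K * m * n * exp(-lambda * S)`` whose
Gumbel parameters are fitted by seeded simulation on random sequences
(:func:`calibrate_evalue_params`); the fitted constants are stored as
defaults and are documented as approximate.

An exact Smith-Waterman implementation (:func:`smith_waterman`, affine gaps,
deterministic traceback) is included as the full-sensitivity oracle for the
heuristic; it is intended for short sequences only.

``N`` never matches anything, including another ``N``: words containing N
are never seeded and N-containing columns score as mismatches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ScoringScheme",
    "DEFAULT_SCHEME",
    "MIRNA_PRESET",
    "HomologyHit",
    "LocalAlignment",
    "reverse_complement",
    "find_seeds",
    "extend_seed",
    "smith_waterman",
    "search",
    "best_identity",
    "evalue",
    "calibrate_evalue_params",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("N")] = 4

# Gumbel parameters for the default scheme, fitted once by
# calibrate_evalue_params(seed=20160915); see docs/methods.md.
_DEFAULT_LAMBDA = 0.6495
_DEFAULT_K = 0.3327


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores, seeding word size and e-value acceptance cutoff.

    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    xdrop: float = 20.0
    word_size: int = 19
    evalue_cutoff: float = 1e-3
    lam: float = _DEFAULT_LAMBDA
    k: float = _DEFAULT_K

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.xdrop <= 0:
            raise ValueError("xdrop must be positive")
        if self.match < 0 or self.mismatch >= 0:
            raise ValueError("need match >= 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


DEFAULT_SCHEME = ScoringScheme()
#: Relaxed cutoff for very short queries (mature miRNAs, ~19-23 nt), whose
#: perfect hits cannot reach strong expectation values.
MIRNA_PRESET = replace(DEFAULT_SCHEME, evalue_cutoff=1e-1)


@dataclass(frozen=True)
class HomologyHit:
    """One local alignment of a query against a subject contig.

    Coordinates are 0-based half-open with ``s_start < s_end`` on the
    forward subject strand; ``strand == '-'`` means the reverse complement
    of the query matches the forward subject.  ``identity`` is percent
    matching columns, rounded to two decimals.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    evalue: float
    score: float
    subject_genome: str | None = None
    matches: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.matches is not None and self.matches > self.aln_len:
            raise ValueError("matches exceed alignment length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.evalue < 0:
            raise ValueError("negative evalue")


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal (or refined) local alignment between two sequences."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str

    @property
    def aln_len(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-" and x != "N"
        )

    @property
    def mismatches(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-" and (x != y or x == "N")
        )

    @property
    def gap_opens(self) -> int:
        opens = 0
        for s in (self.aligned_a, self.aligned_b):
            in_gap = False
            for ch in s:
                if ch == "-":
                    if not in_gap:
                        opens += 1
                    in_gap = True
                else:
                    in_gap = False
        return opens

    @property
    def identity(self) -> float:
        if self.aln_len == 0:
            return 0.0
        return 100.0 * self.matches / self.aln_len


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A, C, G, T, N}."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid letters for reverse_complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains letters outside {A,C,G,T,N}")
    return arr


def _wmer_codes(arr: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all w-mers plus a validity mask (no N inside)."""
    n = len(arr) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.minimum(arr, 3).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    p = np.int64(1)
    for j in range(w):
        codes += vals[j : j + n] * p
        p *= 4
    is_n = np.concatenate(([0], np.cumsum(arr == 4)))
    valid = (is_n[w:] - is_n[:-w]) == 0
    return codes, valid


def find_seeds(
    query: str, subject: str, word_size: int
) -> list[tuple[int, int, str]]:
    """Exhaustively enumerate exact word matches on both strands.

    Returns ``(q_pos, s_pos, strand)`` triples where ``q_pos`` indexes the
    *oriented* query: the query itself for plus-strand seeds and its reverse
    complement for minus-strand seeds.  Words containing N never match.
    """
    if word_size > len(query):
        warnings.warn(
            f"word_size {word_size} exceeds query length {len(query)}; no seeds",
            stacklevel=2,
        )
        return []
    s_arr = _encode(subject)
    s_codes, s_valid = _wmer_codes(s_arr, word_size)
    seeds: list[tuple[int, int, str]] = []
    for strand, oriented in (("+", query), ("-", reverse_complement(query))):
        q_codes, q_valid = _wmer_codes(_encode(oriented), word_size)
        lookup: dict[int, list[int]] = {}
        for q_pos in np.nonzero(q_valid)[0]:
            lookup.setdefault(int(q_codes[q_pos]), []).append(int(q_pos))
        if not lookup:
            continue
        wanted = np.fromiter(lookup.keys(), dtype=np.int64)
        hit_mask = np.isin(s_codes, wanted) & s_valid
        for s_pos in np.nonzero(hit_mask)[0]:
            for q_pos in lookup[int(s_codes[s_pos])]:
                seeds.append((q_pos, int(s_pos), strand))
    seeds.sort(key=lambda t: (t[2], t[0], t[1]))
    return seeds


def _score_pair(a: str, b: str, scheme: ScoringScheme) -> float:
    if a == b and a != "N":
        return scheme.match
    return scheme.mismatch


def _affine_local_dp(a: str, b: str, scheme: ScoringScheme) -> LocalAlignment:
    """Exact affine-gap local alignment, anti-diagonal vectorised.

    Deterministic traceback: at every cell the diagonal move is preferred,
    then the vertical (gap in ``b``), then the horizontal (gap in ``a``); on
    a tie for the global maximum the smallest (i, j) in row-major order wins.
    """
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, "", "")
    av = np.minimum(_encode(a), 4)
    bv = np.minimum(_encode(b), 4)
    sub = np.where(
        (av[:, None] == bv[None, :]) & (av[:, None] != 4),
        scheme.match,
        scheme.mismatch,
    )
    neg = -np.inf
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), neg)  # gap in a (consume b; "left")
    F = np.full((m + 1, n + 1), neg)  # gap in b (consume a; "up")
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    ext_e = np.zeros((m + 1, n + 1), dtype=bool)
    ext_f = np.zeros((m + 1, n + 1), dtype=bool)
    go_ge = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    for k in range(2, m + n + 1):
        i_lo, i_hi = max(1, k - n), min(m, k - 1)
        if i_lo > i_hi:
            continue
        i = np.arange(i_lo, i_hi + 1)
        j = k - i
        e_open = H[i, j - 1] + go_ge
        e_ext = E[i, j - 1] + ge
        E[i, j] = np.maximum(e_open, e_ext)
        ext_e[i, j] = e_ext > e_open
        f_open = H[i - 1, j] + go_ge
        f_ext = F[i - 1, j] + ge
        F[i, j] = np.maximum(f_open, f_ext)
        ext_f[i, j] = f_ext > f_open
        diag = H[i - 1, j - 1] + sub[i - 1, j - 1]
        best = diag
        choice = np.ones(len(i), dtype=np.int8)
        up = F[i, j]
        take = up > best
        best = np.where(take, up, best)
        choice = np.where(take, 2, choice)
        left = E[i, j]
        take = left > best
        best = np.where(take, left, best)
        choice = np.where(take, 3, choice)
        stop = best <= 0
        H[i, j] = np.where(stop, 0.0, best)
        ptr_h[i, j] = np.where(stop, 0, choice)
    flat = int(np.argmax(H))
    bi, bj = divmod(flat, n + 1)
    score = float(H[bi, bj])
    if score <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, "", "")
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i_, j_ = bi, bj
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i_, j_]
            if p == 0:
                break
            if p == 1:
                out_a.append(a[i_ - 1])
                out_b.append(b[j_ - 1])
                i_ -= 1
                j_ -= 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            extended = ext_f[i_, j_]
            out_a.append(a[i_ - 1])
            out_b.append("-")
            i_ -= 1
            if not extended:
                state = "H"
        else:  # E
            extended = ext_e[i_, j_]
            out_a.append("-")
            out_b.append(b[j_ - 1])
            j_ -= 1
            if not extended:
                state = "H"
    return LocalAlignment(
        score=score,
        a_start=i_,
        a_end=bi,
        b_start=j_,
        b_end=bj,
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
    )


_SW_MAX = 5000


def smith_waterman(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> LocalAlignment:
    """Optimal local alignment (oracle; sequences capped at 5 kb each)."""
    if len(a) > _SW_MAX or len(b) > _SW_MAX:
        raise ValueError(f"smith_waterman is limited to {_SW_MAX} bp sequences")
    return _affine_local_dp(a, b, scheme)


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Expected chance hits of at least ``score`` in an m x n search space."""
    return scheme.k * m * n * math.exp(-scheme.lam * score)


def _extend_exact_run(
    oq: str, subject: str, q_pos: int, s_pos: int, w: int
) -> tuple[int, int, int]:
    """Grow a word seed to the maximal exact run containing it."""
    qs, ss = q_pos, s_pos
    while qs > 0 and ss > 0 and oq[qs - 1] == subject[ss - 1] != "N":
        qs -= 1
        ss -= 1
    qe, se = q_pos + w, s_pos + w
    while qe < len(oq) and se < len(subject) and oq[qe] == subject[se] != "N":
        qe += 1
        se += 1
    return qs, ss, qe - qs


def _ungapped_xdrop(
    oq: str, subject: str, qs: int, ss: int, run: int, scheme: ScoringScheme
) -> tuple[int, int, int, float]:
    """Ungapped X-drop extension of an exact run in both directions."""
    score = run * scheme.match
    best = score
    # rightward
    qe, se = qs + run, ss + run
    best_qe = qe
    cur = best
    while qe < len(oq) and se < len(subject):
        cur += _score_pair(oq[qe], subject[se], scheme)
        qe += 1
        se += 1
        if cur > best:
            best, best_qe = cur, qe
        elif cur < best - scheme.xdrop:
            break
    # leftward
    cur = best
    q0, s0 = qs, ss
    best_q0 = q0
    while q0 > 0 and s0 > 0:
        cur += _score_pair(oq[q0 - 1], subject[s0 - 1], scheme)
        q0 -= 1
        s0 -= 1
        if cur > best:
            best, best_q0 = cur, q0
        elif cur < best - scheme.xdrop:
            break
    length = best_qe - best_q0
    return best_q0, ss - (qs - best_q0), length, best


_WINDOW_PAD = 16


def extend_seed(
    seed: tuple[int, int, str],
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
) -> HomologyHit:
    """Extend one word seed into a scored local alignment.

    The seed is first grown to its maximal exact run, extended ungapped with
    the X-drop rule, and finally refined by an affine-gap local alignment of
    the whole oriented query against a subject window spanning the ungapped
    segment plus the remaining query length and a fixed pad.
    """
    q_pos, s_pos, strand = seed
    oq = query if strand == "+" else reverse_complement(query)
    qs, ss, run = _extend_exact_run(oq, subject, q_pos, s_pos, scheme.word_size)
    uq0, us0, ulen, _ = _ungapped_xdrop(oq, subject, qs, ss, run, scheme)
    win_lo = max(0, us0 - uq0 - _WINDOW_PAD)
    win_hi = min(len(subject), us0 + ulen + (len(oq) - (uq0 + ulen)) + _WINDOW_PAD)
    aln = _affine_local_dp(oq, subject[win_lo:win_hi], scheme)
    s_start = win_lo + aln.b_start
    s_end = win_lo + aln.b_end
    if strand == "+":
        q_start, q_end = aln.a_start, aln.a_end
    else:
        q_start, q_end = len(query) - aln.a_end, len(query) - aln.a_start
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=round(aln.identity, 2),
        aln_len=aln.aln_len,
        mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        strand=strand,
        evalue=evalue(aln.score, len(query), 2 * len(subject), scheme),
        score=aln.score,
        matches=aln.matches,
    )


def search(
    query: str,
    genome: Sequence,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    genome_name: str | None = None,
) -> list[HomologyHit]:
    """Word-seeded search of one query against a genome (list of contigs).

    Hits are deduplicated (identical subject span and strand keep the best
    score), filtered to ``evalue <= scheme.evalue_cutoff`` and sorted by
    ascending e-value then descending score; fully deterministic.
    E-values use the total genome length on both strands as the subject
    search-space size.
    """
    total_len = sum(len(getattr(c, "sequence", c)) for c in genome)
    if total_len == 0:
        return []
    n_space = 2 * total_len
    raw: list[HomologyHit] = []
    for contig in genome:
        subject = getattr(contig, "sequence", contig)
        subject_id = getattr(contig, "id", "subject")
        seeds = find_seeds(query, subject, scheme.word_size)
        covered: dict[str, list[tuple[int, int, int, int]]] = {"+": [], "-": []}
        w = scheme.word_size
        for q_pos, s_pos, strand in seeds:
            if any(
                qs <= q_pos and q_pos + w <= qe and ss <= s_pos and s_pos + w <= se
                for qs, qe, ss, se in covered[strand]
            ):
                continue
            hit = extend_seed(
                (q_pos, s_pos, strand),
                query,
                subject,
                scheme,
                query_id=query_id,
                subject_id=subject_id,
            )
            if hit.strand == "+":
                oq_span = (hit.q_start, hit.q_end)
            else:
                oq_span = (len(query) - hit.q_end, len(query) - hit.q_start)
            covered[strand].append((*oq_span, hit.s_start, hit.s_end))
            hit = replace(
                hit,
                evalue=evalue(hit.score, len(query), n_space, scheme),
                subject_genome=genome_name,
            )
            raw.append(hit)
    best: dict[tuple, HomologyHit] = {}
    for hit in raw:
        key = (hit.subject_id, hit.s_start, hit.s_end, hit.strand)
        prev = best.get(key)
        if prev is None or hit.score > prev.score:
            best[key] = hit
    kept = [h for h in best.values() if h.evalue <= scheme.evalue_cutoff]
    kept.sort(
        key=lambda h: (h.evalue, -h.score, h.subject_id, h.s_start, h.strand)
    )
    return kept


def best_identity(
    query: str,
    genome: Sequence,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    genome_name: str | None = None,
) -> float:
    """Identity of the best-scoring accepted hit, or 0.0 when none passes."""
    hits = search(query, genome, scheme, query_id=query_id, genome_name=genome_name)
    return hits[0].identity if hits else 0.0


def calibrate_evalue_params(
    scheme: ScoringScheme = DEFAULT_SCHEME,
    seed: int = 20160915,
    n_samples: int = 400,
    m: int = 50,
    n: int = 1000,
) -> tuple[float, float]:
    """Fit (lambda, K) of the e-value model by Gumbel regression.

    Draws random uniform nucleotide pairs of sizes m x n, records the optimal
    local-alignment score of each, and fits a Gumbel law to the score sample;
    ``lambda = 1/scale`` and ``K = exp(loc/scale) / (m*n)``.  The fit is
    approximate (lattice scores, finite sizes) and is used only to place
    accepted hits on a common expectation scale, never to reproduce any
    external tool's e-values.
    """
    from scipy.stats import gumbel_r

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    scores = []
    for _ in range(n_samples):
        a = "".join(rng.choice(bases, size=m))
        b = "".join(rng.choice(bases, size=n))
        scores.append(_affine_local_dp(a, b, scheme).score)
    loc, scale = gumbel_r.fit(scores)
    lam = 1.0 / scale
    k = math.exp(loc / scale) / (m * n)
    return lam, k
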