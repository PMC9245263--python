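"""Seed-and-extend local nucleotide alignment.

The aligner mirrors the classic BLASTN strategy: exact ``word_size``-mer
seeds on both strands anchor banded affine-gap Smith-Waterman extension, and
hits are filtered by Karlin-Altschul E-value.  Scoring follows the BLAST
convention: a gap of length g costs ``gap_open + g * gap_extend``, i.e. the
open penalty is charged on opening and the extend penalty on every gap
column including the first.

Default scoring is reward +2 / penalty -3 with gap open 5 / extend 2; the
gapped Karlin-Altschul constants for that scheme (lambda = 0.625,
K = 0.410) are the published values for this parameter set and are
configurable.

Seeds are clustered by diagonal and query position; each cluster is solved
by banded dynamic programming over the cluster's diagonal range plus a pad.
When the clustered band covers most of the DP matrix (dense seeds, small
inputs) the extension degenerates to full Smith-Waterman, so the optimal
local alignment is exact in that regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .core import revcomp

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignmentParams:
    word_size: int = 9
    match: int = 2
    mismatch: int = 3  # penalty, positive
    gap_open: int = 5  # penalty, positive
    gap_extend: int = 2  # penalty, positive
    evalue_max: Optional[float] = 1e-5
    lambda_gapped: float = 0.625
    k_gapped: float = 0.410
    band_pad: int = 48
    diag_join: int = 12  # max diagonal drift when chaining seeds
    seed_gap: int = 500
    ext_pad: int = 250
    min_seeds: int = 2  # two-hit seeding
    min_score: int = 20
    dust: bool = False  # low-complexity masking off, as in the study setup

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if min(self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("penalties must be positive")

    def evalue(self, score: int, m: int, n: int) -> float:
        return self.k_gapped * m * n * math.exp(-self.lambda_gapped * score)


@dataclass
class LocalAlignment:
    """One local alignment; intervals are 0-based half-open on the forward
    strands of the inputs.  ``strand`` is '-' when the subject was reverse
    complemented."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    n_match: int
    n_mismatch: int
    n_gap: int  # gap columns
    length: int  # alignment columns
    evalue: float = field(default=float("nan"))

    @property
    def identity(self) -> float:
        return self.n_match / self.length if self.length else 0.0


_NEG = -(10**8)


@njit(cache=True)
def _fill_banded(q, s, dlo, dhi, match, mismatch, go, ge):
    """Banded affine local DP.  Returns (H, E, F, best, bi, bc); cell (i, c)
    corresponds to query prefix i, subject prefix j = i + dlo + c."""
    m = q.shape[0]
    n = s.shape[0]
    W = dhi - dlo + 1
    H = np.full((m + 1, W), _NEG, dtype=np.int64)
    E = np.full((m + 1, W), _NEG, dtype=np.int64)
    F = np.full((m + 1, W), _NEG, dtype=np.int64)
    for c in range(W):
        j = 0 + dlo + c
        if 0 <= j <= n:
            H[0, c] = 0
    best = 0
    bi = 0
    bc = 0
    for i in range(1, m + 1):
        qc = q[i - 1]
        for c in range(W):
            j = i + dlo + c
            if j < 0 or j > n:
                continue
            if j == 0:
                H[i, c] = 0
                continue
            # E: gap consuming subject (j-1 -> j at same i) = band col c-1
            e = _NEG
            if c - 1 >= 0:
                hl = H[i, c - 1]
                el = E[i, c - 1]
                if hl > _NEG // 2:
                    e = hl - go - ge
                if el > _NEG // 2 and el - ge > e:
                    e = el - ge
            # F: gap consuming query (i-1 -> i at same j) = band col c+1, row i-1
            f = _NEG
            if c + 1 < W:
                hu = H[i - 1, c + 1]
                fu = F[i - 1, c + 1]
                if hu > _NEG // 2:
                    f = hu - go - ge
                if fu > _NEG // 2 and fu - ge > f:
                    f = fu - ge
            # diagonal
            h = _NEG
            hd = H[i - 1, c]
            if hd > _NEG // 2:
                sc = match if (qc == s[j - 1] and qc < 4) else -mismatch
                h = hd + sc
            v = 0
            if h > v:
                v = h
            if e > v:
                v = e
            if f > v:
                v = f
            H[i, c] = v
            E[i, c] = e
            F[i, c] = f
            if v > best:
                best = v
                bi = i
                bc = c
    return H, E, F, best, bi, bc


def _traceback(q, s, H, E, F, bi, bc, dlo, params):
    """Walk back from the best cell; returns (qa, sa, n_match, n_mismatch,
    n_gap, columns) with [qa, bi) x [sa, bj) the aligned region."""
    go, ge = params.gap_open, params.gap_extend
    match, mismatch = params.match, params.mismatch
    i, c = bi, bc
    n_match = n_mismatch = n_gap = cols = 0
    while H[i, c] > 0:
        j = i + dlo + c
        v = H[i, c]
        hd = H[i - 1, c] if i >= 1 else _NEG
        diag_ok = hd > _NEG // 2
        if diag_ok:
            sc = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else -mismatch
        if diag_ok and v == hd + sc:
            if sc > 0:
                n_match += 1
            else:
                n_mismatch += 1
            cols += 1
            i -= 1
            continue
        if v == E[i, c]:
            # gap in query (consumes subject): follow the E chain
            while True:
                n_gap += 1
                cols += 1
                e_here = E[i, c]
                hl = H[i, c - 1]
                opened = hl > _NEG // 2 and e_here == hl - go - ge
                c -= 1
                if opened:
                    break
            continue
        if v == F[i, c]:
            while True:
                n_gap += 1
                cols += 1
                f_here = F[i, c]
                hu = H[i - 1, c + 1]
                opened = hu > _NEG // 2 and f_here == hu - go - ge
                i -= 1
                c += 1
                if opened:
                    break
            continue
        break  # v == 0
    qa = i
    sa = i + dlo + c
    return qa, sa, n_match, n_mismatch, n_gap, cols


def _align_window(q, s, qlo, qhi, dlo, dhi, params) -> Optional[LocalAlignment]:
    """Run banded DP on query rows [qlo, qhi) over diagonals [dlo, dhi]."""
    slo = max(0, qlo + dlo)
    shi = min(s.shape[0], qhi + dhi)
    if shi <= slo:
        return None
    qv = q[qlo:qhi]
    sv = s[slo:shi]
    off = slo - qlo
    H, E, F, best, bi, bc = _fill_banded(
        qv, sv, dlo - off, dhi - off,
        params.match, params.mismatch, params.gap_open, params.gap_extend,
    )
    if best < params.min_score:
        return None
    qa, sa, n_match, n_mismatch, n_gap, cols = _traceback(
        qv, sv, H, E, F, bi, bc, dlo - off, params
    )
    bj = bi + (dlo - off) + bc
    return LocalAlignment(
        q_start=qlo + qa,
        q_end=qlo + bi,
        s_start=slo + sa,
        s_end=slo + bj,
        strand="+",
        score=int(best),
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_gap=n_gap,
        length=cols,
    )


def _seed_clusters(q: np.ndarray, s: np.ndarray, params: AlignmentParams):
    """Exact word seeds grouped into (qlo, qhi, dlo, dhi) windows."""
    w = params.word_size
    m, n = q.shape[0], s.shape[0]
    if m < w or n < w:
        return []
    # rolling word codes; words containing N (code 4) are excluded
    def codes(arr):
        mult = np.int64(4) ** (w - 1)
        vals = arr.astype(np.int64)
        cur = np.int64(0)
        for k in range(w):
            cur = cur * 4 + vals[k]
        out = np.empty(arr.shape[0] - w + 1, dtype=np.int64)
        out[0] = cur
        for p in range(1, out.shape[0]):
            cur = (cur - vals[p - 1] * mult) * 4 + vals[p + w - 1]
            out[p] = cur
        ok = np.ones(out.shape[0], dtype=bool)
        bad = arr >= 4
        if bad.any():
            cum = np.cumsum(bad.astype(np.int64))
            winbad = cum[w - 1 :].copy()
            winbad[1:] -= cum[: out.shape[0] - 1]
            ok = winbad == 0
        return out, ok

    qcodes, qok = codes(q)
    scodes, sok = codes(s)
    index: dict[int, list[int]] = {}
    for p in np.nonzero(sok)[0]:
        index.setdefault(int(scodes[p]), []).append(int(p))
    seeds = []  # (diag, qpos)
    for p in np.nonzero(qok)[0]:
        hits = index.get(int(qcodes[p]))
        if hits:
            for sp in hits:
                seeds.append((sp - int(p), int(p)))
    if not seeds:
        return []
    # chain seeds on nearby diagonals (indel drift), then split chains at
    # large query gaps; windows backed by a single seed are discarded
    # (two-hit seeding), which keeps random word matches from spawning DP
    seeds.sort()
    clusters = []
    cur: list[tuple[int, int]] = [seeds[0]]
    for d, p in seeds[1:]:
        if d - cur[-1][0] <= params.diag_join:
            cur.append((d, p))
        else:
            clusters.append(cur)
            cur = [(d, p)]
    clusters.append(cur)
    windows = []
    for cl in clusters:
        cl.sort(key=lambda t: t[1])
        sub: list[tuple[int, int]] = [cl[0]]
        for d, p in cl[1:]:
            if p - sub[-1][1] <= params.seed_gap:
                sub.append((d, p))
            else:
                windows.append(sub)
                sub = [(d, p)]
        windows.append(sub)
    out = []
    for wl in windows:
        if len(wl) < params.min_seeds:
            continue
        ds = [d for d, _ in wl]
        ps = [p for _, p in wl]
        qlo = max(0, min(ps) - params.ext_pad)
        qhi = min(m, max(ps) + w + params.ext_pad)
        dlo = min(ds) - params.band_pad
        dhi = max(ds) + params.band_pad
        out.append((qlo, qhi, dlo, dhi))
    return out


def local_align(query: str, subject: str, params: Optional[AlignmentParams] = None,
                strands: str = "both") -> list[LocalAlignment]:
    """All significant local alignments between query and subject.

    Subject coordinates of '-'-strand hits are reported on the forward
    strand.  Hits whose E-value exceeds ``params.evalue_max`` are dropped
    (set it to None to keep everything above ``min_score``); lower-scoring
    hits subsumed by a higher-scoring overlap are removed.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    params = params or AlignmentParams()
    q = encode(query)
    m, n = len(query), len(subject)
    results: list[LocalAlignment] = []
    strand_list = {"both": "+-", "plus": "+", "minus": "-"}[strands]
    for strand in strand_list:
        subj = subject if strand == "+" else revcomp(subject)
        s = encode(subj)
        windows = _seed_clusters(q, s, params)
        if not windows:
            continue
        area = sum((qhi - qlo) * (dhi - dlo + 1) for qlo, qhi, dlo, dhi in windows)
        if area > 0.5 * m * n:
            windows = [(0, m, -(m - 1), n - 1)]
        for qlo, qhi, dlo, dhi in windows:
            aln = _align_window(q, s, qlo, qhi, dlo, dhi, params)
            if aln is None:
                continue
            aln.evalue = params.evalue(aln.score, m, n)
            if params.evalue_max is not None and aln.evalue > params.evalue_max:
                continue
            if strand == "-":
                aln.s_start, aln.s_end = n - aln.s_end, n - aln.s_start
                aln.strand = "-"
            results.append(aln)
    return _drop_subsumed(results)


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _drop_subsumed(alns: list[LocalAlignment], frac: float = 0.9) -> list[LocalAlignment]:
    alns = sorted(alns, key=lambda a: (-a.score, a.q_start, a.s_start))
    kept: list[LocalAlignment] = []
    for a in alns:
        qlen = a.q_end - a.q_start
        slen = a.s_end - a.s_start
        redundant = False
        for b in kept:
            qo = _overlap(a.q_start, a.q_end, b.q_start, b.q_end)
            so = _overlap(a.s_start, a.s_end, b.s_start, b.s_end)
            if qlen and slen and qo / qlen >= frac and so / slen >= frac:
                redundant = True
                break
        if not redundant:
            kept.append(a)
    return kept
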