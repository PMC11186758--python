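"""Banded global alignment of two near-identical mitochondrial genomes.

Mammalian mitochondrial genomes of two inbred strains are ~16.3 kb and
>99% identical, so a full O(n*m) dynamic program is wasteful: the optimal
path never strays far from the main diagonal. We therefore run a banded
Needleman-Wunsch with affine gap costs (Gotoh three-state recursion)
restricted to diagonals ``j - i`` within ``band`` of zero. If the optimal
path touches the band boundary the band may have clipped a better path,
and :class:`BandTooNarrowError` is raised so the caller can widen it.

Scoring: match +1, mismatch -1, and a gap of length k costs
``gap_open + k * gap_extend`` (so the first gapped base costs
``gap_open + gap_extend``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["BandTooNarrowError", "banded_global_align", "aligned_columns"]

# traceback codes for the match state: which state the path came from
_FROM_M, _FROM_X, _FROM_Y = 0, 1, 2
_NEG = -1.0e18

# column operation codes
OP_MATCH = 0  # one base from each sequence
OP_GAP_B = 1  # base from a, gap in b
OP_GAP_A = 2  # base from b, gap in a


class BandTooNarrowError(ValueError):
    """The optimal alignment path touched the band edge ("band too narrow")."""


@njit(cache=True)
def _gotoh_banded(a, b, band, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    w = 2 * band + 1
    gap_first = gap_open + gap_extend

    # rolling score rows; full (row x diagonal) traceback packed into one byte:
    # bits 0-1 M-state origin, bit 2 X gap-extension, bit 3 Y gap-extension
    Mprev = np.full(w, _NEG)
    Xprev = np.full(w, _NEG)
    Yprev = np.full(w, _NEG)
    Mcur = np.full(w, _NEG)
    Xcur = np.full(w, _NEG)
    Ycur = np.full(w, _NEG)
    tb = np.zeros((n + 1, w), dtype=np.uint8)

    Mprev[band] = 0.0
    for k in range(band + 1, w):
        j = k - band
        if j > m:
            break
        Yprev[k] = gap_first + gap_extend * (j - 1)
        if j > 1:
            tb[0, k] |= 8

    for i in range(1, n + 1):
        Mcur[:] = _NEG
        Xcur[:] = _NEG
        Ycur[:] = _NEG
        k_lo = max(0, band - i)
        k_hi = min(w - 1, band + m - i)
        for k in range(k_lo, k_hi + 1):
            j = i + k - band
            if j < 0 or j > m:
                continue
            code = np.uint8(0)
            if j >= 1:
                s = match if a[i - 1] == b[j - 1] else mismatch
                best = Mprev[k]
                frm = 0
                if Xprev[k] > best:
                    best = Xprev[k]
                    frm = 1
                if Yprev[k] > best:
                    best = Yprev[k]
                    frm = 2
                if best > _NEG / 2:
                    Mcur[k] = best + s
                    code |= frm
            # X: gap in b, from (i-1, j) i.e. diagonal k+1
            if k + 1 < w:
                open_sc = Mprev[k + 1] + gap_first
                ext_sc = Xprev[k + 1] + gap_extend
                if ext_sc > open_sc:
                    Xcur[k] = ext_sc
                    code |= 4
                else:
                    Xcur[k] = open_sc
            # Y: gap in a, from (i, j-1) i.e. diagonal k-1
            if k - 1 >= 0:
                open_sc = Mcur[k - 1] + gap_first
                ext_sc = Ycur[k - 1] + gap_extend
                if ext_sc > open_sc:
                    Ycur[k] = ext_sc
                    code |= 8
                else:
                    Ycur[k] = open_sc
            tb[i, k] = code
        Mprev, Mcur = Mcur, Mprev
        Xprev, Xcur = Xcur, Xprev
        Yprev, Ycur = Ycur, Yprev

    empty = np.zeros(0, dtype=np.uint8)
    k_end = m - n + band
    if k_end < 0 or k_end >= w:
        return empty, -2, _NEG  # length difference exceeds band

    end_state = 0
    score = Mprev[k_end]
    if Xprev[k_end] > score:
        score = Xprev[k_end]
        end_state = 1
    if Yprev[k_end] > score:
        score = Yprev[k_end]
        end_state = 2
    if score <= _NEG / 2:
        return empty, -2, _NEG

    # traceback, emitting ops in reverse; also detect band-edge contact
    ops = np.empty(n + m, dtype=np.uint8)
    nops = 0
    i = n
    k = k_end
    state = end_state
    touched = False
    while i > 0 or k != band:
        if k == 0 or k == w - 1:
            touched = True
        if state == 0:
            frm = tb[i, k] & 3
            ops[nops] = OP_MATCH
            nops += 1
            i -= 1
            state = frm
        elif state == 1:
            ext = tb[i, k] & 4
            ops[nops] = OP_GAP_B
            nops += 1
            i -= 1
            k += 1
            state = 1 if ext else 0
        else:
            ext = tb[i, k] & 8
            ops[nops] = OP_GAP_A
            nops += 1
            k -= 1
            state = 2 if ext else 0
    return ops[:nops][::-1].copy(), (1 if touched else 0), score


_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
_ENC[ord("N")] = 5


def _encode(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 4).any():
        bad = seq[int(np.argmax(arr == 4))]
        raise ValueError(f"non-DNA character {bad!r} in sequence")
    return arr


def banded_global_align(
    a: str,
    b: str,
    band: int = 256,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    full_dp: bool = False,
) -> tuple[np.ndarray, float]:
    """Globally align two DNA strings, returning (ops, score).

    ``ops`` is a vector of per-column codes: 0 = aligned pair,
    1 = gap in ``b``, 2 = gap in ``a``. With ``full_dp`` the band spans
    the whole matrix (exact but memory-hungry for long inputs).

    Raises
    ------
    BandTooNarrowError
        If the optimal path touches the band edge, or the sequence length
        difference exceeds the band.
    ValueError
        On empty input or characters outside {A, C, G, T, N}.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ea, eb = _encode(a.upper()), _encode(b.upper())
    if full_dp:
        band = max(len(a), len(b))
    if abs(len(a) - len(b)) > band:
        raise BandTooNarrowError(
            f"band too narrow: length difference {abs(len(a) - len(b))} exceeds band {band}"
        )
    ops, status, score = _gotoh_banded(
        ea, eb, int(band), float(match), float(mismatch), float(gap_open), float(gap_extend)
    )
    if status == -2:
        raise BandTooNarrowError("band too narrow: no path within band")
    if status == 1 and not full_dp:
        raise BandTooNarrowError("band too narrow: optimal path touches the band edge")
    return np.asarray(ops, dtype=np.uint8), float(score)


def aligned_columns(ops: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map alignment columns to 1-based coordinates (0 where gapped).

    Returns (pos_a, pos_b) arrays of the same length as ``ops``.
    """
    ops = np.asarray(ops)
    pos_a = np.cumsum(ops != OP_GAP_A)
    pos_b = np.cumsum(ops != OP_GAP_B)
    pos_a = np.where(ops == OP_GAP_A, 0, pos_a)
    pos_b = np.where(ops == OP_GAP_B, 0, pos_b)
    return pos_a.astype(np.int64), pos_b.astype(np.int64)
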