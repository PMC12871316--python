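"""Local alignment scoring for paralog discrimination.

Near-identical paralogs are told apart by the margin between a read's best
and second-best alignment score, so the scorer here is the primitive the
whole assignment stage rests on. Two numba kernels implement the same
Smith-Waterman scheme with affine gaps:

* an exact full dynamic program (:func:`score_read`), used as the contract
  scorer and for arbitrary sequence pairs;
* a banded variant restricted to a diagonal corridor located by shared
  k-mer seeds (:func:`seeded_score`), which is what bulk assignment uses.
  Whenever the optimal path stays inside the corridor the two kernels
  return identical scores; for reads that differ from their reference by
  substitutions only (the default simulation), the optimal path is the
  main diagonal and the banded score is exact by construction.

Scoring scheme (defaults): match +1, mismatch -2, and a gap of length k
costs 4 + 2k (open -4 charged once, extend -2 per gap base). Scores are
integers; the empty alignment scores 0, so all scores are >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InputError

__all__ = [
    "ScoringParams",
    "encode_sequence",
    "reverse_complement",
    "score_read",
    "seeded_score",
]

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring scheme. ``gap_open`` is charged once per gap and
    ``gap_extend`` once per gap base, so a length-k gap costs
    ``gap_open + k * gap_extend``."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -2


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3).

    IUPAC ambiguity codes are accepted but score as mismatches against
    every base, including themselves.
    """
    if not seq:
        raise InputError("empty sequence")
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@njit(cache=True)
def _affine_local_score(q, t, match, mismatch, open_cost, ext_cost):
    # open_cost already includes the first gap base: length-k gap costs
    # open_cost + (k-1)*ext_cost.
    n = q.shape[0]
    m = t.shape[0]
    NEG = -(1 << 40)
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        diag = 0
        F = NEG
        prev = 0
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[j] - ext_cost
            eo = H[j] - open_cost
            if eo > e:
                e = eo
            E[j] = e
            f = F - ext_cost
            fo = prev - open_cost
            if fo > f:
                f = fo
            F = f
            if qi == t[j - 1] and qi < 4:
                h = diag + match
            else:
                h = diag + mismatch
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            prev = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _affine_banded_score(q, t, offset, band, match, mismatch, open_cost, ext_cost):
    # Restrict DP to cells with (j - i) in [offset-band, offset+band],
    # stored band-relative. Column k holds j = i + offset - band + k.
    n = q.shape[0]
    m = t.shape[0]
    w = 2 * band + 1
    NEG = -(1 << 40)
    H = np.full(w, NEG, dtype=np.int64)
    E = np.full(w, NEG, dtype=np.int64)
    Hprev = np.full(w, NEG, dtype=np.int64)
    best = 0
    for k in range(w):
        j = offset - band + k
        if 0 <= j <= m:
            Hprev[k] = 0
    for i in range(1, n + 1):
        for k in range(w):
            H[k] = NEG
        F = NEG
        qi = q[i - 1]
        for k in range(w):
            j = i + offset - band + k
            if j < 1 or j > m:
                if j == 0:
                    H[k] = 0
                    F = NEG
                continue
            # vertical (gap in target): from Hprev same diagonal shift
            # cell (i-1, j) sits at band index k+1 in the previous row
            e = NEG
            if k + 1 < w:
                ev = E[k + 1] - ext_cost
                eo = Hprev[k + 1] - open_cost
                e = ev if ev > eo else eo
            En = e
            # horizontal (gap in query): from H[k-1] current row
            f = F - ext_cost
            if k >= 1:
                fo = H[k - 1] - open_cost
                if fo > f:
                    f = fo
            F = f
            d = Hprev[k]  # cell (i-1, j-1) is same band index, previous row
            if qi == t[j - 1] and qi < 4:
                h = d + match
            else:
                h = d + mismatch
            if En > h:
                h = En
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[k] = h
            E[k] = En
            if h > best:
                best = h
        for k in range(w):
            Hprev[k] = H[k]
    return best


def score_read(
    read_sequence: str,
    reference_sequence: str,
    params: ScoringParams = ScoringParams(),
    *,
    both_strands: bool = False,
) -> int:
    """Exact local alignment score of a read against one reference.

    With ``both_strands=True`` the read is also scored as its reverse
    complement and the larger score returned, so orientation-unknown reads
    are handled without caller bookkeeping.
    """
    q = encode_sequence(read_sequence)
    t = encode_sequence(reference_sequence)
    open_cost = -(params.gap_open + params.gap_extend)
    ext_cost = -params.gap_extend
    s = _affine_local_score(q, t, params.match, params.mismatch, open_cost, ext_cost)
    if both_strands:
        q_rc = encode_sequence(reverse_complement(read_sequence))
        s_rc = _affine_local_score(
            q_rc, t, params.match, params.mismatch, open_cost, ext_cost
        )
        s = max(s, s_rc)
    return int(s)


def _kmer_index(seq: str, k: int) -> dict:
    index: dict = {}
    for i in range(0, len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def find_diagonal(read: str, ref_index: dict, k: int, stride: int) -> int | None:
    """Modal diagonal offset (ref_pos - read_pos) from shared k-mer seeds.

    Returns None when read and reference share no sampled k-mer, e.g. for
    a read from an unrelated locus.
    """
    votes: dict = {}
    for i in range(0, max(1, len(read) - k + 1), stride):
        hits = ref_index.get(read[i : i + k])
        if hits:
            for j in hits:
                d = j - i
                votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    return max(votes.items(), key=lambda kv: (kv[1], -abs(kv[0])))[0]


def seeded_score(
    read_sequence: str,
    reference_sequence: str,
    params: ScoringParams = ScoringParams(),
    *,
    band: int = 64,
    seed_k: int = 21,
    seed_stride: int = 7,
    ref_index: dict | None = None,
) -> int:
    """Banded local alignment score around a seeded diagonal.

    Falls back to the exact full DP when no seed is found. ``ref_index``
    may be precomputed with :func:`_kmer_index` to amortise indexing over
    many reads.
    """
    if ref_index is None:
        ref_index = _kmer_index(reference_sequence, seed_k)
    offset = find_diagonal(read_sequence, ref_index, seed_k, seed_stride)
    if offset is None:
        return score_read(read_sequence, reference_sequence, params)
    q = encode_sequence(read_sequence)
    t = encode_sequence(reference_sequence)
    open_cost = -(params.gap_open + params.gap_extend)
    ext_cost = -params.gap_extend
    return int(
        _affine_banded_score(
            q, t, offset, band, params.match, params.mismatch, open_cost, ext_cost
        )
    )
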