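"""Low-level pairwise alignment kernels.

Smith-Waterman local alignment with affine (Gotoh) gap costs over
byte-encoded sequences, numba-compiled. A gap of length ``k`` costs
``gap_open + k * gap_extend`` (BLAST convention, so 11/1 charges 12 for a
single-residue gap). Used both for peptide comparisons (BLOSUM62 by
default) and for nucleotide fragment mapping in the ANI calculator.

Two execution paths share the same recurrences:

* a full-matrix kernel with traceback pointers, used directly when the
  problem is small;
* a linear-memory score/endpoint kernel plus a reverse pass to locate the
  alignment start, after which the full kernel runs on the bounded
  subwindow only. This keeps memory flat for long nucleotide subjects.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# Alphabets and encodings

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
AA_X = AA_ALPHABET.index("X")
AA_STOP = AA_ALPHABET.index("*")
AA_BREAK = len(AA_ALPHABET)  # sentinel: never aligned, breaks k-mer windows

_AA_CODE = np.full(128, AA_BREAK, dtype=np.uint8)
for _i, _ch in enumerate(AA_ALPHABET):
    _AA_CODE[ord(_ch)] = _i
    if _ch.isalpha():
        _AA_CODE[ord(_ch.lower())] = _i
for _ch in "BZJUO":  # ambiguous / rare residues collapse to X
    _AA_CODE[ord(_ch)] = AA_X
    _AA_CODE[ord(_ch.lower())] = AA_X

NT_ALPHABET = "ACGTN"
_NT_CODE = np.full(128, 4, dtype=np.uint8)  # unknown -> N
for _i, _ch in enumerate("ACGT"):
    _NT_CODE[ord(_ch)] = _i
    _NT_CODE[ord(_ch.lower())] = _i


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string into BLOSUM row indices (uint8)."""
    return _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_protein(codes: np.ndarray) -> str:
    lut = np.frombuffer((AA_ALPHABET + "!").encode("ascii"), dtype=np.uint8)
    return lut[np.minimum(codes, AA_BREAK)].tobytes().decode("ascii")


def encode_dna(seq: str) -> np.ndarray:
    """Encode a nucleotide string as A=0 C=1 G=2 T=3, everything else N=4."""
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def blosum62() -> np.ndarray:
    """BLOSUM62 as an int64 matrix over the package's residue codes."""
    bl = substitution_matrices.load("BLOSUM62")
    n = AA_BREAK + 1
    mat = np.full((n, n), -1000, dtype=np.int64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            mat[i, j] = int(bl[a, b])
    return mat


def dna_matrix(match: int = 1, mismatch: int = -2) -> np.ndarray:
    """Simple nucleotide scoring; N never matches anything (incl. itself)."""
    mat = np.full((5, 5), mismatch, dtype=np.int64)
    for i in range(4):
        mat[i, i] = match
    return mat


_BLOSUM62 = None


def blosum62_cached() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = blosum62()
    return _BLOSUM62


# ---------------------------------------------------------------------------
# Kernels

NEG = -(10**12)


@njit(cache=True)
def _sw_score_end(a, b, mat, go, ge):
    """Best local score and its (exclusive) end coordinates; O(m) memory."""
    n = a.shape[0]
    m = b.shape[0]
    h_prev = np.zeros(m + 1, dtype=np.int64)
    h_cur = np.zeros(m + 1, dtype=np.int64)
    f_col = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - go - ge, e - ge)
            f_col[j] = max(h_prev[j] - go - ge, f_col[j] - ge)
            h = h_prev[j - 1] + mat[ai, b[j - 1]]
            if e > h:
                h = e
            if f_col[j] > h:
                h = f_col[j]
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj


@njit(cache=True)
def _sw_full(a, b, mat, go, ge):
    """Full-matrix local alignment with traceback.

    Returns (score, matches, aln_len, a_start, a_end, b_start, b_end) with
    end coordinates exclusive; a zero score yields an empty alignment.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 opened from H
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            open_e = H[i, j - 1] - go - ge
            ext_e = E[i, j - 1] - ge
            if open_e >= ext_e:
                E[i, j] = open_e
                ptr_e[i, j] = 1
            else:
                E[i, j] = ext_e
            open_f = H[i - 1, j] - go - ge
            ext_f = F[i - 1, j] - ge
            if open_f >= ext_f:
                F[i, j] = open_f
                ptr_f[i, j] = 1
            else:
                F[i, j] = ext_f
            diag = H[i - 1, j - 1] + mat[ai, b[j - 1]]
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    matches = 0
    aln_len = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = ptr_e[i, j]
            aln_len += 1
            j -= 1
            if opened == 1:
                state = 0
        else:
            opened = ptr_f[i, j]
            aln_len += 1
            i -= 1
            if opened == 1:
                state = 0
    return best, matches, aln_len, i, bi, j, bj


_FULL_CELL_LIMIT = 4_000_000


def sw_local(a: np.ndarray, b: np.ndarray, mat: np.ndarray,
             gap_open: int, gap_extend: int):
    """Optimal local alignment of two encoded sequences.

    Returns ``(score, matches, aln_len, a_start, a_end, b_start, b_end)``.
    For large problems the alignment window is located with linear-memory
    passes before the traceback kernel runs on the subwindow.
    """
    a = np.ascontiguousarray(a)
    b = np.ascontiguousarray(b)
    if a.size == 0 or b.size == 0:
        return 0, 0, 0, 0, 0, 0, 0
    if a.size * b.size <= _FULL_CELL_LIMIT:
        return _sw_full(a, b, mat, gap_open, gap_extend)
    score, ae, be = _sw_score_end(a, b, mat, gap_open, gap_extend)
    if score == 0:
        return 0, 0, 0, 0, 0, 0, 0
    # reverse pass over the prefixes locates the start of the same alignment
    r_score, rae, rbe = _sw_score_end(a[:ae][::-1], b[:be][::-1], mat,
                                      gap_open, gap_extend)
    a0 = ae - rae
    b0 = be - rbe
    s, matches, aln_len, wa0, wa1, wb0, wb1 = _sw_full(
        a[a0:ae], b[b0:be], mat, gap_open, gap_extend)
    return s, matches, aln_len, a0 + wa0, a0 + wa1, b0 + wb0, b0 + wb1
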