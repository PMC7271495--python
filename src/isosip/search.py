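"""Six-frame translated homology search of protein queries against reads.

This is a tBLASTn-style engine: nucleotide reads are translated in all six
frames, frame segments (between stop codons) that share a 5-residue word
with any query are locally aligned (Smith-Waterman, BLOSUM62, affine gaps)
and scored with Karlin-Altschul expectation values

    E = K * m * n * exp(-lambda * S)

where ``m`` is the total number of query residues and ``n`` the total
number of translated residues searched. Hits are reported once per
(query, read) pair, best frame first. A BLASTx-style verification step
re-aligns each hit's translated segment against a trusted protein set and
discards hits below an identity floor; surviving hits are deduplicated to
one per read ("unique hits").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._align import (
    AA_BREAK,
    AA_STOP,
    AA_X,
    blosum62_cached,
    decode_protein,
    encode_protein,
    sw_local,
)
from Bio.Align import substitution_matrices
from ._align import AA_ALPHABET

# ---------------------------------------------------------------------------
# Parameters and record types

ROLE_TARGET = "target_marker"
ROLE_VERIFY = "verification_set"
ROLE_NORM = "normalization_marker"


@dataclass(frozen=True)
class ProteinReference:
    """One protein query/reference sequence."""

    ref_id: str
    sequence: str
    role: str = ROLE_TARGET

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for reference {self.ref_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SearchParams:
    """Scoring and filtering parameters of the translated search.

    Defaults follow standard gapped BLASTP statistics for BLOSUM62 with
    gap open 11 / extend 1 (lambda = 0.267 nats, K = 0.041); the e-value
    cutoffs are the screen's operating points (1e-4 for the target marker,
    1e-6 for the normalization marker) and ``min_verify_identity`` the
    percent-identity floor of the verification step.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    K: float = 0.041
    evalue_cutoff_target: float = 1e-4
    evalue_cutoff_norm: float = 1e-6
    min_verify_identity: float = 50.0
    min_verify_coverage: float = 0.5

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.evalue_cutoff_target <= 0 or self.evalue_cutoff_norm <= 0:
            raise ValueError("e-value cutoffs must be positive")


FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class AlignmentHit:
    """One translated-search match (best alignment of a query to a read)."""

    query_id: str
    read_id: str
    frame: int
    raw_score: int
    evalue: float
    pct_identity: float
    aln_len: int
    peptide: str = ""  # translated read segment carrying the hit

    def __post_init__(self):
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")


# ---------------------------------------------------------------------------
# Translation

_T11 = CodonTable.unambiguous_dna_by_id[11]


def _codon_lut() -> np.ndarray:
    """Codon index (base-5 over ACGTN) -> amino-acid code, table 11."""
    lut = np.full(125, AA_X, dtype=np.uint8)
    letters = "ACGT"
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            for k, c in enumerate(letters):
                codon = a + b + c
                idx = i * 25 + j * 5 + k
                if codon in _T11.stop_codons:
                    lut[idx] = AA_STOP
                else:
                    aa = _T11.forward_table[codon]
                    lut[idx] = AA_ALPHABET.index(aa)
    return lut


_CODON_AA = _codon_lut()
_RC = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N

_NT_CODE5 = np.full(128, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _NT_CODE5[ord(_ch)] = _i
    _NT_CODE5[ord(_ch.lower())] = _i


def _encode_reads(seqs: Sequence[str]) -> np.ndarray:
    """Equal-length nucleotide strings -> (n, L) uint8 code matrix."""
    joined = "".join(seqs).encode("ascii")
    arr = _NT_CODE5[np.frombuffer(joined, dtype=np.uint8)]
    return arr.reshape(len(seqs), -1)


def _translate_matrix(nt: np.ndarray, offset: int) -> np.ndarray:
    """Translate every row of a nucleotide code matrix at a frame offset."""
    length = nt.shape[1]
    n_codons = (length - offset) // 3
    if n_codons <= 0:
        return np.zeros((nt.shape[0], 0), dtype=np.uint8)
    end = offset + 3 * n_codons
    a = nt[:, offset:end:3].astype(np.int32)
    b = nt[:, offset + 1:end:3].astype(np.int32)
    c = nt[:, offset + 2:end:3].astype(np.int32)
    return _CODON_AA[a * 25 + b * 5 + c]


def _six_frame_matrices(nt: np.ndarray):
    """Yield (frame_label, peptide code matrix) for all six frames."""
    rc = _RC[nt][:, ::-1]
    for off in range(3):
        yield off + 1, _translate_matrix(nt, off)
    for off in range(3):
        yield -(off + 1), _translate_matrix(rc, off)


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading frame of a read, with a peptide -> read coordinate map."""

    frame: int
    peptide: str
    read_length: int

    def read_coords(self, pep_index: int) -> tuple[int, int]:
        """0-based read coordinates (start, end exclusive) of codon ``i``."""
        off = abs(self.frame) - 1
        if self.frame > 0:
            start = off + 3 * pep_index
            return start, start + 3
        # codon sits at rc positions [off+3i, off+3i+3); map back through rc
        rc_start = off + 3 * pep_index
        return self.read_length - rc_start - 3, self.read_length - rc_start


def six_frame_translate(read: str) -> list[TranslatedFrame]:
    """Translate a read in all six frames (bacterial table 11).

    Codons containing N translate to X; stop codons appear as '*'. Frames
    +1..+3 come from the read itself, -1..-3 from its reverse complement.
    Reads shorter than 3 nt yield six empty frames.
    """
    frames = []
    if len(read) < 3:
        return [TranslatedFrame(f, "", len(read)) for f in FRAMES]
    nt = _encode_reads([read])
    for label, mat in _six_frame_matrices(nt):
        frames.append(TranslatedFrame(label, decode_protein(mat[0]), len(read)))
    return frames


def translated_residue_count(read_lengths: Iterable[int]) -> int:
    """Total residues produced by six-frame translation of the read set."""
    total = 0
    for length in read_lengths:
        for off in range(3):
            total += 2 * max((length - off) // 3, 0)
    return total


# ---------------------------------------------------------------------------
# Alignment and statistics

_MATRICES: dict[str, np.ndarray] = {}


def _score_matrix(name: str) -> np.ndarray:
    if name == "BLOSUM62":
        return blosum62_cached()
    if name not in _MATRICES:
        src = substitution_matrices.load(name)
        n = AA_BREAK + 1
        mat = np.full((n, n), -1000, dtype=np.int64)
        for i, a in enumerate(AA_ALPHABET):
            for j, b in enumerate(AA_ALPHABET):
                if a in src.alphabet and b in src.alphabet:
                    mat[i, j] = int(src[a, b])
        _MATRICES[name] = mat
    return _MATRICES[name]


def local_align(query: str, subject: str,
                params: SearchParams | None = None) -> tuple[int, float, int]:
    """Optimal local alignment score, percent identity and length.

    Identity is computed over aligned columns only (gaps count as columns
    but never as matches). An all-negative comparison yields (0, 0.0, 0).
    """
    params = params or SearchParams()
    if not query or not subject:
        raise ValueError("local_align requires two non-empty sequences")
    score, matches, aln_len, *_ = sw_local(
        encode_protein(query), encode_protein(subject),
        _score_matrix(params.matrix), params.gap_open, params.gap_extend)
    pct = 100.0 * matches / aln_len if aln_len else 0.0
    return int(score), pct, int(aln_len)


def estimate_evalue(raw_score: float, m: int, n: int,
                    params: SearchParams | None = None) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    params = params or SearchParams()
    if m <= 0 or n <= 0:
        raise ValueError("search-space sizes m and n must be positive")
    return params.K * m * n * math.exp(-params.lambda_ * raw_score)


# ---------------------------------------------------------------------------
# The search proper

_KMER = 5
_KBASE = AA_BREAK + 1
_MIN_SEGMENT = 5  # residues; shorter segments cannot seed or score


def _query_kmer_hashes(queries: Sequence[ProteinReference]) -> np.ndarray:
    hashes = set()
    for q in queries:
        codes = encode_protein(q.sequence)
        for i in range(len(codes) - _KMER + 1):
            window = codes[i:i + _KMER]
            if window.max() < AA_X:
                h = 0
                for c in window:
                    h = h * _KBASE + int(c)
                hashes.add(h)
    return np.fromiter(sorted(hashes), dtype=np.int64, count=len(hashes))


def _candidate_rows(pep: np.ndarray, qhashes: np.ndarray) -> np.ndarray:
    """Row indices of peptide matrix sharing a k-mer with the query set."""
    n, w = pep.shape
    if w < _KMER or qhashes.size == 0:
        return np.empty(0, dtype=np.int64)
    nw = w - _KMER + 1
    h = np.zeros((n, nw), dtype=np.int64)
    bad = np.zeros((n, nw), dtype=bool)
    for j in range(_KMER):
        col = pep[:, j:j + nw]
        h = h * _KBASE + col
        bad |= col >= AA_X
    h[bad] = -1
    hit = np.isin(h, qhashes)
    return np.nonzero(hit.any(axis=1))[0]


def _segments(codes: np.ndarray):
    """Split a frame's peptide codes at stop codons ('*' and sentinels)."""
    breaks = np.nonzero(codes >= AA_STOP)[0]
    start = 0
    for b in breaks:
        if b - start >= _MIN_SEGMENT:
            yield codes[start:b]
        start = b + 1
    if len(codes) - start >= _MIN_SEGMENT:
        yield codes[start:]


def _as_id_seq(reads) -> list[tuple[str, str]]:
    out = []
    for i, r in enumerate(reads):
        if isinstance(r, tuple):
            out.append((str(r[0]), str(r[1])))
        elif hasattr(r, "sequence"):
            out.append((r.id, r.sequence))
        elif hasattr(r, "seq"):
            out.append((r.id, str(r.seq)))
        else:
            out.append((f"read_{i}", str(r)))
    return out


def search_translated(queries: Sequence[ProteinReference], reads,
                      params: SearchParams | None = None,
                      cutoff: float | None = None,
                      batch_size: int = 50_000) -> list[AlignmentHit]:
    """Search protein queries against nucleotide reads in six frames.

    Returns at most one hit per (query, read) pair - the best-scoring
    frame, ties resolved in favour of the lowest frame index - filtered at
    ``cutoff`` on the expectation value. The search space ``n`` is the
    total number of translated residues of the read set, recomputed per
    call; ``m`` is the total query residue count.
    """
    params = params or SearchParams()
    queries = list(queries)
    if not queries:
        raise ValueError("query set is empty")
    if cutoff is None:
        cutoff = params.evalue_cutoff_target
    id_seq = _as_id_seq(reads)
    if not id_seq:
        return []

    m_total = sum(q.length for q in queries)
    n_total = translated_residue_count(len(s) for _, s in id_seq)
    mat = _score_matrix(params.matrix)
    qhashes = _query_kmer_hashes(queries)
    qcodes = [encode_protein(q.sequence) for q in queries]
    # minimum raw score that can still reach the cutoff: prune early
    min_score = math.ceil(
        math.log(max(params.K * m_total * n_total / cutoff, 1.0))
        / params.lambda_)

    # best[(qi, read_id)] = (score, frame_order, identity, aln_len, segment)
    best: dict[tuple[int, str], tuple] = {}

    # group reads by length so frames translate as dense matrices
    by_len: dict[int, list[int]] = {}
    for idx, (_, seq) in enumerate(id_seq):
        by_len.setdefault(len(seq), []).append(idx)

    for length, indices in by_len.items():
        if length < 3 * _MIN_SEGMENT:
            continue
        for start in range(0, len(indices), batch_size):
            chunk = indices[start:start + batch_size]
            nt = _encode_reads([id_seq[i][1] for i in chunk])
            for order, (label, pep) in enumerate(_six_frame_matrices(nt)):
                for row in _candidate_rows(pep, qhashes):
                    read_id = id_seq[chunk[row]][0]
                    for seg in _segments(pep[row]):
                        for qi, qc in enumerate(qcodes):
                            score, matches, aln, *_ = sw_local(
                                seg, qc, mat, params.gap_open,
                                params.gap_extend)
                            if score < min_score or aln == 0:
                                continue
                            key = (qi, read_id)
                            prev = best.get(key)
                            if prev is None or score > prev[0]:
                                best[key] = (score, order,
                                             100.0 * matches / aln, aln,
                                             decode_protein(seg), label)

    hits = []
    for (qi, read_id), (score, _order, ident, aln, seg, label) in best.items():
        ev = estimate_evalue(score, m_total, n_total, params)
        if ev <= cutoff:
            hits.append(AlignmentHit(
                query_id=queries[qi].ref_id, read_id=read_id, frame=label,
                raw_score=int(score), evalue=ev, pct_identity=ident,
                aln_len=aln, peptide=seg))
    hits.sort(key=lambda h: (h.read_id, h.evalue, h.query_id))
    return hits


# ---------------------------------------------------------------------------
# Verification ("manual BLASTx check")


def verify_hits(hits: Sequence[AlignmentHit],
                verification_set: Sequence[ProteinReference],
                params: SearchParams | None = None
                ) -> tuple[int, pd.DataFrame]:
    """Screen hits against a trusted protein set and count unique reads.

    Each hit's translated segment is locally aligned to every verification
    protein; the best identity among alignments covering at least
    ``min_verify_coverage`` of the segment is recorded. Hits strictly below
    ``min_verify_identity`` percent (or without any qualifying alignment)
    are discarded. Survivors are deduplicated to one hit per read - best
    e-value, ties to the lexicographically smallest query id - and the
    unique-read count is returned with the per-hit table.
    """
    params = params or SearchParams()
    refs = list(verification_set)
    if not refs:
        raise ValueError("verification set is empty - verification impossible")
    mat = _score_matrix(params.matrix)
    ref_codes = [encode_protein(r.sequence) for r in refs]

    rows = []
    for h in hits:
        seg = encode_protein(h.peptide)
        best_ident = 0.0
        best_ref = ""
        for ref, rc in zip(refs, ref_codes):
            score, matches, aln, *_ = sw_local(
                seg, rc, mat, params.gap_open, params.gap_extend)
            if aln < params.min_verify_coverage * len(seg) or aln == 0:
                continue
            ident = 100.0 * matches / aln
            if ident > best_ident:
                best_ident = ident
                best_ref = ref.ref_id
        keep = best_ident >= params.min_verify_identity
        rows.append((h.query_id, h.read_id, h.frame, h.raw_score, h.evalue,
                     h.pct_identity, h.aln_len, best_ref, best_ident, keep))
    table = pd.DataFrame(rows, columns=[
        "query_id", "read_id", "frame", "raw_score", "evalue",
        "pct_identity", "aln_len", "verify_ref", "verify_identity", "kept"])
    if table.empty:
        table["unique"] = pd.Series(dtype=bool)
        return 0, table
    kept = table[table["kept"]].sort_values(["evalue", "query_id"])
    unique = kept.drop_duplicates(subset="read_id", keep="first")
    table["unique"] = table.index.isin(unique.index)
    return len(unique), table
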