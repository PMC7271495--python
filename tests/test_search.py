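"""Translated search: frames, statistics, hit filtering, verification."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from isosip import (AlignmentHit, ProteinReference, SearchParams,
                    estimate_evalue, search_translated, six_frame_translate,
                    verify_hits)
from isosip.search import translated_residue_count
from isosip.synthetic import generate_community, simulate_reads, ReadSimConfig
from conftest import encode_peptide, random_protein
from oracles import oracle_evalue


# ---------------------------------------------------------------------------
# six-frame translation


@pytest.mark.parametrize("read,frame,expected", [
    ("ATGAAA", 1, "MK"),
    ("TTTCAT", -1, "MK"),          # reverse complement of the above
    ("ATGNAA", 1, "MX"),           # N-containing codon
])
def test_translation_examples(read, frame, expected):
    frames = {f.frame: f.peptide for f in six_frame_translate(read)}
    assert frames[frame] == expected


def test_short_read_gives_empty_frames():
    assert all(f.peptide == "" for f in six_frame_translate("AT"))


def test_frames_agree_with_biopython(rng):
    read = "".join(rng.choice(list("ACGT"), size=100))
    rc = str(Seq(read).reverse_complement())
    for f in six_frame_translate(read):
        src = read if f.frame > 0 else rc
        off = abs(f.frame) - 1
        n = (len(read) - off) // 3
        expected = str(Seq(src[off:off + 3 * n]).translate(table=11))
        assert f.peptide == expected


def test_frame_completeness_and_coordinates(rng):
    """Six frames cover every codon of read and reverse complement once."""
    read = "".join(rng.choice(list("ACGT"), size=97))
    frames = six_frame_translate(read)
    total = sum(len(f.peptide) for f in frames)
    assert total == translated_residue_count([len(read)])
    fwd_covered = []
    rev_covered = []
    for f in frames:
        for i in range(len(f.peptide)):
            start, end = f.read_coords(i)
            assert 0 <= start < end <= len(read)
            assert end - start == 3
            (fwd_covered if f.frame > 0 else rev_covered).append((start, end))
            if f.frame > 0:
                assert str(Seq(read[start:end]).translate(table=11)) \
                    == f.peptide[i]
            else:
                codon = str(Seq(read[start:end]).reverse_complement()
                            .translate(table=11))
                assert codon == f.peptide[i]
    assert len(set(fwd_covered)) == len(fwd_covered)
    assert len(set(rev_covered)) == len(rev_covered)


# ---------------------------------------------------------------------------
# e-values


def test_evalue_closed_form():
    p = SearchParams()
    assert estimate_evalue(0, 10, 20, p) == pytest.approx(p.K * 10 * 20)
    assert estimate_evalue(50, 10, 40, p) == pytest.approx(
        2 * estimate_evalue(50, 10, 20, p))
    assert estimate_evalue(100, 1000, 1000, p) == pytest.approx(
        oracle_evalue(100, 1000, 1000))
    assert estimate_evalue(100, 1000, 1000, p) == pytest.approx(
        0.041 * 1e6 * math.exp(-26.7))


def test_evalue_monotone_in_score():
    p = SearchParams()
    evs = [estimate_evalue(s, 500, 10_000, p) for s in range(0, 200, 10)]
    assert all(a > b for a, b in zip(evs, evs[1:]))


# ---------------------------------------------------------------------------
# search


def _pad(seq, length, rng):
    extra = length - len(seq)
    left = extra // 2
    bases = list("ACGT")
    return ("".join(rng.choice(bases, size=left)) + seq
            + "".join(rng.choice(bases, size=extra - left)))


def test_planted_exact_substring_hit(rng, marker_refs):
    query = marker_refs["isoA_queries"][0]
    sub = query.sequence[100:147]  # 47 residues
    read = _pad(encode_peptide(sub), 150, rng)
    hits = search_translated([query], [("r1", read)], cutoff=1e-4)
    assert len(hits) == 1
    h = hits[0]
    assert h.pct_identity == 100.0
    assert h.aln_len >= 47
    assert h.evalue <= 1e-4


def test_duplicate_read_ids_get_identical_scores(rng, marker_refs):
    query = marker_refs["isoA_queries"][0]
    read = _pad(encode_peptide(query.sequence[10:57]), 150, rng)
    hits = search_translated([query], [("a", read), ("b", read)],
                             cutoff=1e-4)
    assert len(hits) == 2
    assert hits[0].raw_score == hits[1].raw_score
    assert hits[0].evalue == hits[1].evalue


def test_empty_read_set_gives_no_hits(marker_refs):
    assert search_translated(marker_refs["isoA_queries"], []) == []


def test_empty_query_set_rejected():
    with pytest.raises(ValueError):
        search_translated([], [("r", "ACGT" * 40)])


def test_search_is_specific_on_marker_free_reads(marker_refs):
    """No isoA hit, raw or verified, in 1e5 reads without the marker."""
    genomes, community = generate_community(
        20, carrier_fraction=0.0, seed=77, abundance="uniform")
    reads, _ = simulate_reads(genomes, community,
                              ReadSimConfig(n_reads=100_000, read_length=143,
                                            sub_error_rate=0.0, seed=78))
    hits = search_translated(marker_refs["isoA_queries"], reads,
                             cutoff=1e-4)
    assert hits == []
    n_unique, _ = verify_hits(hits, marker_refs["isoA_verification"])
    assert n_unique == 0


def test_sensitivity_on_planted_marker_reads(marker_refs):
    """Reads overlapping >= 45 codons of the marker are recovered."""
    genomes, community = generate_community(
        4, carrier_fraction=1.0, seed=5, abundance="uniform")
    reads, truth = simulate_reads(
        genomes, community, ReadSimConfig(n_reads=6000, read_length=150,
                                          sub_error_rate=0.0, seed=6))
    loci = {g.taxon_id: next((s, e) for name, s, e, _ in g.marker_loci
                             if name == "isoA") for g in genomes}
    overlapping = set()
    for row in truth.itertuples(index=False):
        s, e = loci[row.taxon_id]
        if min(row.end, e) - max(row.start, s) >= 135:  # 45 codons
            overlapping.add(row.read_id)
    assert len(overlapping) > 100
    hits = search_translated(marker_refs["isoA_queries"], reads,
                             cutoff=1e-4)
    hit_reads = {h.read_id for h in hits}
    recall = len(overlapping & hit_reads) / len(overlapping)
    assert recall >= 0.99


# ---------------------------------------------------------------------------
# verification


def _forced_identity_pair(rng, n_match, n_mismatch_extra):
    """A (segment, reference) pair whose best local alignment is the full
    gap-free diagonal with a known match count.

    The segment alternates match columns with single mismatches; ends are
    matches, every mismatch scores >= -2, so no trimming or gap variant
    scores higher and identity = matches / columns exactly.
    """
    from Bio.Align import substitution_matrices
    bl = substitution_matrices.load("BLOSUM62")
    aa20 = "ACDEFGHIKLMNPQRSTVWY"

    def mild_mismatch(x):
        for y in aa20:
            if y != x and -2 <= bl[x, y] <= -1:
                return y
        raise AssertionError("no mild mismatch partner")

    seg = []
    ref = []
    matches = 0
    cols = 0
    # alternate M X M X ...; the extra mismatches sit mid-sequence so both
    # ends stay net-positive and no trimming can raise the score
    while matches < n_match:
        x = str(rng.choice(list(aa20)))
        seg.append(x)
        ref.append(x)
        matches += 1
        cols += 1
        budget = 1 + (n_mismatch_extra if matches == n_match // 2 else 0)
        if matches < n_match:
            for _ in range(budget):
                x = str(rng.choice(list(aa20)))
                seg.append(x)
                ref.append(mild_mismatch(x))
                cols += 1
    return "".join(seg), "".join(ref), matches, cols


def _hit_with_peptide(peptide):
    return AlignmentHit("q0", "r0", 1, 500, 1e-20, 100.0, len(peptide),
                        peptide=peptide)


def test_verification_boundary_just_below_50_discarded(rng):
    seg, ref, matches, cols = _forced_identity_pair(rng, 60, 2)
    identity = 100.0 * matches / cols
    assert 49.0 < identity < 50.0
    n, table = verify_hits([_hit_with_peptide(seg)],
                           [ProteinReference("v", ref)])
    assert n == 0
    assert table["verify_identity"].iloc[0] == pytest.approx(identity)


def test_verification_at_exactly_50_retained(rng):
    seg, ref, matches, cols = _forced_identity_pair(rng, 60, 1)
    # 60 matches over 120 columns = exactly 50%: not "< 50", so retained
    assert matches / cols == 0.5
    n, _ = verify_hits([_hit_with_peptide(seg)],
                       [ProteinReference("v", ref)])
    assert n == 1


def test_unique_hits_counted_once_per_read(marker_refs, rng):
    """One read hitting two queries contributes a single unique hit."""
    q1, q2 = marker_refs["isoA_queries"][:2]
    read = _pad(encode_peptide(q1.sequence[50:97]), 150, rng)
    hits = search_translated([q1, q2], [("r1", read)], cutoff=1e-4)
    assert {h.query_id for h in hits} == {q1.ref_id, q2.ref_id}
    n, table = verify_hits(hits, marker_refs["isoA_verification"])
    assert n == 1
    assert table["unique"].sum() == 1


def test_cross_marker_hits_fail_verification(marker_refs, rng):
    """A recA read passing the recA search is rejected by the IsoA check."""
    reca = marker_refs["recA_queries"][0]
    read = _pad(encode_peptide(reca.sequence[100:147]), 150, rng)
    hits = search_translated([reca], [("r1", read)], cutoff=1e-6)
    assert len(hits) == 1
    n, table = verify_hits(hits, marker_refs["isoA_verification"])
    assert n == 0
    assert (table["verify_identity"] < 50).all()


def test_empty_verification_set_rejected(marker_refs):
    with pytest.raises(ValueError):
        verify_hits([], [])
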