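"""Homolog tiers, cluster classification, MAG gates and fragment ANI."""

import math

import numpy as np
import pytest

from isosip.cluster import (ANIResult, GeneAnnotation, MAGQuality,
                            PERMISSIVE_E, RESTRICTIVE_E, assign_homologs,
                            compute_ani, detect_clusters, mag_gate,
                            read_annotations)
from isosip.synthetic import (_mutate, iso_cluster_references,
                              generate_community)
from oracles import oracle_evalue, oracle_local_score

REFS = iso_cluster_references()


def _ann(contig, gene_id, start, protein, strand="+"):
    return GeneAnnotation(contig, gene_id, start,
                          start + 3 * len(protein) + 2, strand, protein)


# ---------------------------------------------------------------------------
# homolog assignment


def test_identical_protein_assigned_restrictive():
    ann = _ann("c1", "g1", 1, REFS["isoA"].sequence)
    out = assign_homologs([ann], REFS)
    assert len(out) == 1
    assert out[0].iso_gene == "isoA"
    assert out[0].tier == "restrictive"
    assert out[0].pct_identity == 100.0


def test_partial_homolog_lands_between_tiers(rng):
    """A short diverged match whose oracle E-value sits in (1e-40, 1e-10)."""
    fragment = _mutate(REFS["isoA"].sequence[:90], 0.45, rng)
    padding = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
    protein = fragment + padding
    n_total = len(protein)
    score = oracle_local_score(protein, REFS["isoA"].sequence)
    ev = oracle_evalue(score, len(REFS["isoA"].sequence), n_total)
    assert RESTRICTIVE_E <= ev < PERMISSIVE_E
    out = assign_homologs([_ann("c1", "g1", 1, protein)], REFS)
    assert len(out) == 1
    assert out[0].tier == "permissive"
    assert out[0].evalue == pytest.approx(ev, rel=1e-6)


def test_unrelated_protein_not_assigned(rng):
    protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=400))
    assert assign_homologs([_ann("c1", "g1", 1, protein)], REFS) == []


def test_restrictive_assignments_nest_within_permissive(rng):
    """Every restrictive assignment also satisfies the permissive cutoff."""
    anns = [_ann("c1", f"g{i}", 1 + 2000 * i,
                 _mutate(REFS[g].sequence, d, rng))
            for i, (g, d) in enumerate(
                [("isoA", 0.0), ("isoB", 0.1), ("isoE", 0.3), ("garB", 0.5)])]
    for a in assign_homologs(anns, REFS):
        assert a.evalue < PERMISSIVE_E
        if a.tier == "restrictive":
            assert a.evalue < RESTRICTIVE_E


def test_empty_reference_set_rejected():
    with pytest.raises(ValueError):
        assign_homologs([_ann("c", "g", 1, "MKL" * 20)], {})


# ---------------------------------------------------------------------------
# cluster detection


def _cluster_annotations(contig, genes, rng, start=101, gap=100,
                         divergence=0.05):
    anns = []
    pos = start
    for i, g in enumerate(genes):
        prot = _mutate(REFS[g].sequence, divergence, rng)
        ann = _ann(contig, f"{contig}_g{i}", pos, prot)
        anns.append(ann)
        pos = ann.end + 1 + gap
    return anns


def test_full_cluster_with_aldh1_is_complete(rng):
    genes = ["isoA", "isoB", "isoC", "isoD", "isoE", "isoF",
             "isoG", "isoH", "isoI", "isoJ", "aldH1"]
    anns = _cluster_annotations("c1", genes, rng)
    reports = detect_clusters(assign_homologs(anns, REFS), anns)
    r = reports[0]
    assert r.classification == "complete"
    assert r.core_count == 6 and r.extended_count == 4
    assert "aldH1" in r.accessory


def test_core_only_cluster_is_putative_novel(rng):
    anns = _cluster_annotations("c1", ["isoA", "isoB", "isoC", "isoD",
                                       "isoE", "isoF"], rng, divergence=0.3)
    reports = detect_clusters(assign_homologs(anns, REFS), anns)
    assert reports[0].classification == "putative_novel"


def test_no_assignments_classified_none(rng):
    protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
    anns = [_ann("c1", "g1", 1, protein)]
    reports = detect_clusters(assign_homologs(anns, REFS), anns)
    assert reports[0].classification == "none"


def test_clusters_never_bridge_contigs(rng):
    half1 = _cluster_annotations("c1", ["isoA", "isoB", "isoC"], rng)
    half2 = _cluster_annotations("c2", ["isoD", "isoE", "isoF"], rng)
    anns = half1 + half2
    reports = {r.contig_id: r for r in
               detect_clusters(assign_homologs(anns, REFS), anns)}
    assert reports["c1"].classification == "partial"
    assert reports["c2"].classification == "partial"


def test_large_gap_splits_cluster(rng):
    near = _cluster_annotations("c1", ["isoA", "isoB", "isoC", "isoD",
                                       "isoE"], rng)
    far = _cluster_annotations("c1", ["isoF"], rng,
                               start=near[-1].end + 20_000)
    anns = near + far
    r = detect_clusters(assign_homologs(anns, REFS), anns, max_gap=5000)[0]
    assert r.classification == "partial"  # isoF is beyond the gap
    assert r.core_count == 5


def test_genes_reported_in_coordinate_order_regardless_of_strand(rng):
    anns = []
    pos = 101
    for i, g in enumerate(["isoC", "isoA", "isoB"]):
        prot = _mutate(REFS[g].sequence, 0.05, rng)
        ann = _ann("c1", f"g{i}", pos, prot,
                   strand="-" if i % 2 else "+")
        anns.append(ann)
        pos = ann.end + 50
    r = detect_clusters(assign_homologs(anns, REFS), anns)[0]
    assert r.genes == ["isoC", "isoA", "isoB"]


# ---------------------------------------------------------------------------
# MAG gate


@pytest.mark.parametrize("completeness,contamination,expected", [
    (97.6, 2.5, True),    # high completeness, low contamination
    (75.0, 2.0, False),   # boundary completeness fails (strict >)
    (80.0, 10.0, False),  # boundary contamination fails (strict <)
    (75.01, 9.99, True),
    (60.0, 1.0, False),
])
def test_mag_gate_strict_inequalities(completeness, contamination, expected):
    q = MAGQuality("m", completeness, contamination)
    assert mag_gate(q) is expected


def test_mag_gate_reassembly_variant():
    q = MAGQuality("m", 80.0, 7.0)
    assert mag_gate(q) is True
    assert mag_gate(q, contamination_max=5.0) is False


def test_mag_quality_validation():
    with pytest.raises(ValueError):
        MAGQuality("m", 101.0, 0.0)


# ---------------------------------------------------------------------------
# ANI


def _random_genome(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_self_ani_is_exactly_100(rng):
    genome = _random_genome(rng, 5100)
    res = compute_ani(genome, genome)
    assert res.ani == 100.0
    assert res.n_fragments_used == res.n_fragments_total == 5


def test_single_substitution_fragment_identity(rng):
    genome = _random_genome(rng, 1020)
    mutated = list(genome)
    orig = mutated[510]
    mutated[510] = {"A": "C", "C": "G", "G": "T", "T": "A"}[orig]
    res = compute_ani("".join(mutated), genome)
    assert res.n_fragments_used == 1
    assert res.ani == pytest.approx(100.0 * 1019 / 1020, abs=1e-9)


def test_unrelated_genomes_have_undefined_ani(rng):
    a = _random_genome(rng, 3060)
    b = _random_genome(rng, 3060)
    with pytest.warns(UserWarning, match="undefined"):
        res = compute_ani(a, b)
    assert math.isnan(res.ani)
    assert res.n_fragments_used == 0
    assert not res.defined


def test_ani_nearly_symmetric_at_low_divergence(rng):
    a = _random_genome(rng, 6120)
    b = list(a)
    sub = rng.random(len(b)) < 0.03
    for i in np.nonzero(sub)[0]:
        b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
    b = "".join(b)
    ab = compute_ani(a, b).ani
    ba = compute_ani(b, a).ani
    assert abs(ab - ba) <= 1.0
    assert ab == pytest.approx(97.0, abs=1.0)


def test_partial_final_fragment_discarded(rng):
    genome = _random_genome(rng, 2500)
    res = compute_ani(genome, genome)
    assert res.n_fragments_total == 2


# ---------------------------------------------------------------------------
# annotation I/O


def test_annotation_roundtrip_tsv_and_gff(tmp_path, rng):
    anns = _cluster_annotations("c1", ["isoA", "isoB"], rng)
    tsv = tmp_path / "ann.tsv"
    with open(tsv, "w") as fh:
        fh.write("contig\tgene\tstart\tend\tstrand\tprotein\n")
        for a in anns:
            fh.write(f"{a.contig_id}\t{a.gene_id}\t{a.start}\t{a.end}"
                     f"\t{a.strand}\t{a.protein}\n")
    gff = tmp_path / "ann.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in anns:
            fh.write(f"{a.contig_id}\tisosip\tCDS\t{a.start}\t{a.end}\t."
                     f"\t{a.strand}\t0\tID={a.gene_id};"
                     f"translation={a.protein}\n")
    assert read_annotations(tsv) == anns
    assert read_annotations(gff) == anns


def test_gff_without_translation_rejected(tmp_path):
    gff = tmp_path / "bad.gff3"
    gff.write_text("c1\tx\tCDS\t1\t30\t.\t+\t0\tID=g1\n")
    with pytest.raises(ValueError, match="translation"):
        read_annotations(gff)
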