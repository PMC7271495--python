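"""Isoprene gene-cluster screening, MAG quality gating and fragment ANI.

Annotated proteins are assigned to isoprene-pathway genes by local
alignment against labelled references under two expectation-value tiers
(permissive E < 1e-10, restrictive E < 1e-40); assigned genes are chained
into clusters per contig when consecutive genes lie within a maximum gap,
and each contig is classified by its core (isoABCDEF) and extended
(isoGHIJ) gene content. MAG quality is gated on strict completeness /
contamination inequalities. Average nucleotide identity follows the
classical fragment recipe: the query genome is cut into fixed-length
pieces, each locally aligned to the subject, and retained fragments
(>= 30% identity over >= 70% of their length) contribute their identity
to the mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import dna_matrix, encode_dna, sw_local
from .search import ProteinReference, SearchParams, estimate_evalue, local_align

ISO_CORE = ("isoA", "isoB", "isoC", "isoD", "isoE", "isoF")
ISO_EXTENDED = ("isoG", "isoH", "isoI", "isoJ")
ISO_ACCESSORY = ("aldH1", "aldH2", "gshB", "garB", "CoA-DSR")
ISO_GENES = ISO_CORE + ISO_EXTENDED + ISO_ACCESSORY

PERMISSIVE_E = 1e-10
RESTRICTIVE_E = 1e-40


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated CDS (1-based inclusive nucleotide coordinates)."""

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class HomologAssignment:
    gene_id: str
    iso_gene: str
    ref_id: str
    evalue: float
    pct_identity: float
    tier: str  # "permissive" or "restrictive"


@dataclass
class ClusterReport:
    contig_id: str
    genes: list[str] = field(default_factory=list)  # iso genes, contig order
    core_count: int = 0
    extended_count: int = 0
    accessory: list[str] = field(default_factory=list)
    max_gap: int = 0
    classification: str = "none"


@dataclass(frozen=True)
class MAGQuality:
    mag_id: str
    completeness: float
    contamination: float
    strain_heterogeneity: float | None = None

    def __post_init__(self):
        for v in (self.completeness, self.contamination):
            if not 0.0 <= v <= 100.0:
                raise ValueError("quality percentages must be in [0, 100]")


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    ani: float  # percent; NaN when undefined
    n_fragments_used: int
    n_fragments_total: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ani)


# ---------------------------------------------------------------------------


def assign_homologs(annotations: Sequence[GeneAnnotation],
                    references: Mapping[str, ProteinReference] |
                    Sequence[ProteinReference],
                    params: SearchParams | None = None,
                    permissive_e: float = PERMISSIVE_E,
                    restrictive_e: float = RESTRICTIVE_E,
                    ) -> list[HomologAssignment]:
    """Assign annotated proteins to iso pathway genes by protein alignment.

    ``references`` maps iso gene name -> reference protein (or is a
    sequence whose ``ref_id`` carries the gene name before a ``|``). Each
    protein is aligned to every reference; the best (lowest-E) reference
    wins and the assignment carries the strictest tier its E-value passes.
    The search space ``n`` is the total annotated residue count.
    """
    params = params or SearchParams()
    if not references:
        raise ValueError("empty reference set")
    if isinstance(references, Mapping):
        ref_items = [(g, r) for g, r in references.items()]
    else:
        ref_items = [(r.ref_id.split("|")[0], r) for r in references]
    n_total = sum(len(a.protein) for a in annotations)
    out = []
    for ann in annotations:
        best = None
        for gene, ref in ref_items:
            score, ident, _aln = local_align(ann.protein, ref.sequence, params)
            ev = estimate_evalue(score, ref.length, max(n_total, 1), params)
            if best is None or ev < best[1]:
                best = (gene, ev, ident, ref.ref_id)
        gene, ev, ident, ref_id = best
        if ev < restrictive_e:
            tier = "restrictive"
        elif ev < permissive_e:
            tier = "permissive"
        else:
            continue
        out.append(HomologAssignment(ann.gene_id, gene, ref_id, ev, ident,
                                     tier))
    return out


def detect_clusters(assignments: Sequence[HomologAssignment],
                    annotations: Sequence[GeneAnnotation],
                    max_gap: int = 5000) -> list[ClusterReport]:
    """Group assigned genes into per-contig clusters and classify them.

    Consecutive assigned genes on the same contig belong to one cluster
    when the gap between them is at most ``max_gap`` bp; clusters never
    bridge contigs. The report for a contig describes its best cluster
    (most distinct iso genes). Classification: complete (all isoABCDEF +
    all isoGHIJ), putative_novel (full core, no extended genes anywhere on
    the contig), core_only (full core, partial extended set), partial
    (incomplete core), none.
    """
    by_gene = {a.gene_id: a for a in assignments}
    contigs: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        contigs.setdefault(ann.contig_id, []).append(ann)

    reports = []
    for contig_id, anns in contigs.items():
        assigned = sorted((a for a in anns if a.gene_id in by_gene),
                          key=lambda a: a.start)
        if not assigned:
            reports.append(ClusterReport(contig_id=contig_id))
            continue
        chains: list[list[GeneAnnotation]] = [[assigned[0]]]
        for prev, cur in zip(assigned, assigned[1:]):
            gap = cur.start - prev.end - 1
            if gap <= max_gap:
                chains[-1].append(cur)
            else:
                chains.append([cur])
        best = max(chains,
                   key=lambda ch: len({by_gene[a.gene_id].iso_gene
                                       for a in ch}))
        iso_names = [by_gene[a.gene_id].iso_gene for a in best]
        present = set(iso_names)
        core = sum(g in present for g in ISO_CORE)
        ext = sum(g in present for g in ISO_EXTENDED)
        acc = [g for g in ISO_ACCESSORY if g in present]
        gaps = [cur.start - prev.end - 1
                for prev, cur in zip(best, best[1:])]
        if core == 6 and ext == 4:
            cls = "complete"
        elif core == 6 and ext == 0:
            cls = "putative_novel"
        elif core == 6:
            cls = "core_only"
        elif core > 0:
            cls = "partial"
        else:
            cls = "none"
        reports.append(ClusterReport(
            contig_id=contig_id, genes=iso_names, core_count=core,
            extended_count=ext, accessory=acc,
            max_gap=max(gaps) if gaps else 0, classification=cls))
    return reports


def mag_gate(quality: MAGQuality, completeness_min: float = 75.0,
             contamination_max: float = 10.0) -> bool:
    """Strict MAG quality gate: completeness > min AND contamination < max.

    Both inequalities are strict, so the boundary values themselves fail.
    """
    return (quality.completeness > completeness_min
            and quality.contamination < contamination_max)


# ---------------------------------------------------------------------------
# Fragment-based ANI

_DNA_MAT = dna_matrix()
_DNA_GAP_OPEN = 3
_DNA_GAP_EXTEND = 1


def compute_ani(genome_a: Sequence[str] | str, genome_b: Sequence[str] | str,
                fragment_len: int = 1020,
                min_identity: float = 30.0,
                min_coverage: float = 0.70,
                name_a: str = "genome_a", name_b: str = "genome_b"
                ) -> ANIResult:
    """Fragment-based average nucleotide identity of genome A against B.

    Each sequence of A is cut into consecutive ``fragment_len`` pieces
    (final partial fragments discarded); each fragment is locally aligned
    to every sequence of B and its best alignment kept. Fragments aligned
    at >= ``min_identity`` percent over >= ``min_coverage`` of their
    length are retained; ANI is the mean identity of retained fragments.
    With no retained fragment the ANI is undefined (NaN) and a warning is
    emitted.
    """
    seqs_a = [genome_a] if isinstance(genome_a, str) else list(genome_a)
    seqs_b = [genome_b] if isinstance(genome_b, str) else list(genome_b)
    if not any(seqs_a) or not any(seqs_b):
        raise ValueError("both genomes must be non-empty")
    subjects = [encode_dna(s) for s in seqs_b if s]

    fragments = []
    for s in seqs_a:
        enc = encode_dna(s)
        for off in range(0, len(enc) - fragment_len + 1, fragment_len):
            fragments.append(enc[off:off + fragment_len])

    identities = []
    for frag in fragments:
        best_ident = None
        for subj in subjects:
            score, matches, aln, *_ = sw_local(
                frag, subj, _DNA_MAT, _DNA_GAP_OPEN, _DNA_GAP_EXTEND)
            if aln < min_coverage * fragment_len or aln == 0:
                continue
            ident = 100.0 * matches / aln
            if best_ident is None or ident > best_ident:
                best_ident = ident
        if best_ident is not None and best_ident >= min_identity:
            identities.append(best_ident)

    if not identities:
        warnings.warn(f"ANI({name_a}, {name_b}) undefined: "
                      "no fragment met the retention criteria")
        ani = float("nan")
    else:
        ani = float(np.mean(identities))
    return ANIResult(name_a, name_b, ani, len(identities), len(fragments))


def read_annotations(path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (CDS with translation=) or TSV.

    The TSV fallback needs columns contig, gene, start, end, strand,
    protein (1-based inclusive coordinates, as in GFF3).
    """
    path = str(path)
    out = []
    if path.endswith((".gff", ".gff3")):
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{line_no}: not a GFF3 record")
                if parts[2] != "CDS":
                    continue
                attrs = dict(kv.split("=", 1)
                             for kv in parts[8].split(";") if "=" in kv)
                if "translation" not in attrs:
                    raise ValueError(
                        f"{path}:{line_no}: CDS lacks translation attribute")
                out.append(GeneAnnotation(
                    parts[0], attrs.get("ID", f"cds_{line_no}"),
                    int(parts[3]), int(parts[4]), parts[6],
                    attrs["translation"]))
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        for row in df.itertuples(index=False):
            out.append(GeneAnnotation(str(row.contig), str(row.gene),
                                      int(row.start), int(row.end),
                                      str(row.strand), str(row.protein)))
    return out


def assignments_to_frame(assignments: Sequence[HomologAssignment]
                         ) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.gene_id, a.iso_gene, a.ref_id, a.evalue, a.pct_identity, a.tier)
         for a in assignments],
        columns=["gene_id", "iso_gene", "ref_id", "evalue", "pct_identity",
                 "tier"])


def reports_to_frame(reports: Sequence[ClusterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.contig_id, ";".join(r.genes), r.core_count, r.extended_count,
          ";".join(r.accessory), r.max_gap, r.classification)
         for r in reports],
        columns=["contig_id", "iso_genes", "core_count", "extended_count",
                 "accessory", "max_gap", "classification"])
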