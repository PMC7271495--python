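"""Synthetic communities, genomes, shotgun reads and SIP gradients.

The generator emulates the statistical structure the downstream analysis
assumes: bacterial communities in which a known fraction of genomes carry
a single-copy isoprene-monooxygenase marker gene (isoA) while every genome
carries exactly one copy of the single-copy normalization marker (recA);
shotgun reads drawn proportionally to abundance x genome length with
substitution errors; and an isopycnic (CsCl) gradient in which each
taxon's DNA bands as a Gaussian centred at

    rho = intercept + slope * GC + shift * label_atom_fraction

so that fully 13C-labelled DNA is resolved from unlabelled DNA in the
heavy fractions. Per-read provenance is always retained for truth-based
testing; it is never part of the emitted FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from Bio.Data import CodonTable

from .search import ProteinReference, ROLE_NORM, ROLE_TARGET, ROLE_VERIFY

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_T11 = CodonTable.unambiguous_dna_by_id[11]

# codons per amino acid (translation table 11, stops excluded)
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _T11.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class GenomeModel:
    """A synthetic genome: background sequence plus planted marker genes."""

    taxon_id: str
    length: int
    gc: float
    markers: list[tuple[str, str, int]] = field(default_factory=list)
    label_atom_fraction: float = 0.0
    sequence: str = ""
    marker_loci: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.length < 10_000:
            raise ValueError("genome length must be >= 10,000 bp")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if not 0.0 <= self.label_atom_fraction <= 1.0:
            raise ValueError("label_atom_fraction must be in [0, 1]")


@dataclass
class CommunityProfile:
    """Relative abundances per taxon (sum to one)."""

    abundances: dict[str, float]

    def __post_init__(self):
        vals = np.fromiter(self.abundances.values(), dtype=float)
        if vals.size and (vals < 0).any():
            raise ValueError("abundances must be non-negative")
        total = vals.sum() if vals.size else 0.0
        # an all-zero profile is allowed as the composition of an empty
        # gradient fraction; any other total must be 1
        if vals.size and total != 0.0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.abundances, dtype=float)


@dataclass
class ReadSimConfig:
    """Shotgun read simulation settings (default length mirrors short
    quality-trimmed Illumina metagenome reads, ~143 bp)."""

    n_reads: int = 100_000
    read_length: int = 143
    sub_error_rate: float = 0.005
    quality_model: str = "constant:30"
    seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.sub_error_rate < 0.25:
            raise ValueError("sub_error_rate must be in [0, 0.25)")


@dataclass
class SIPGradientModel:
    """Linear buoyant-density model of an isopycnic CsCl gradient."""

    base_density_intercept: float = 1.660
    gc_density_slope: float = 0.098
    full_label_shift: float = 0.036
    fraction_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(1.690, 1.760, 13))
    density_noise_sd: float = 0.004
    center_jitter_sd: float = 0.0

    def __post_init__(self):
        self.fraction_edges = np.asarray(self.fraction_edges, dtype=float)
        if self.fraction_edges.size < 2 or \
                not (np.diff(self.fraction_edges) > 0).all():
            raise ValueError("fraction_edges must be strictly increasing")
        if self.full_label_shift <= 0:
            raise ValueError("full_label_shift must be positive")
        if self.density_noise_sd <= 0:
            raise ValueError("density_noise_sd must be positive")


@dataclass
class FractionSample:
    """One gradient fraction: density, DNA yield and its composition."""

    fraction_index: int
    mean_density: float
    dna_amount: float
    composition: CommunityProfile


def buoyant_density(model: SIPGradientModel, gc: float,
                    label_atom_fraction: float = 0.0) -> float:
    """Centre density of a genome's DNA band in the gradient."""
    return (model.base_density_intercept + model.gc_density_slope * gc
            + model.full_label_shift * label_atom_fraction)


# ---------------------------------------------------------------------------
# Reference protein sets (synthetic marker families)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    n_mut = int(round(divergence * len(chars)))
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        alternatives = [a for a in _AA20 if a != chars[pos]]
        chars[pos] = str(rng.choice(alternatives))
    return "".join(chars)


def make_protein_family(prefix: str, length: int, n_members: int, seed: int,
                        divergence: float = 0.05,
                        role: str = ROLE_TARGET) -> list[ProteinReference]:
    """A family of related synthetic proteins around a common ancestor."""
    rng = np.random.default_rng(seed)
    base = _random_protein(length, rng)
    return [ProteinReference(f"{prefix}_{i:02d}",
                             _mutate(base, divergence, rng), role)
            for i in range(n_members)]


_ISOA_LEN = 500
_RECA_LEN = 355
_FAMILY_SEED_ISOA = 120_301
_FAMILY_SEED_RECA = 120_302


def default_marker_references() -> dict:
    """The fixed synthetic marker database used across the package.

    Returns a dict with isoA query and verification sets, recA queries,
    and the planted protein sequences carried by synthetic genomes (family
    members distinct from, but recognisably homologous to, the queries).
    """
    isoa = make_protein_family("IsoA", _ISOA_LEN, 7, _FAMILY_SEED_ISOA,
                               divergence=0.05)
    reca = make_protein_family("RecA", _RECA_LEN, 3, _FAMILY_SEED_RECA,
                               divergence=0.03)
    return {
        "isoA_queries": [ProteinReference(p.ref_id, p.sequence, ROLE_TARGET)
                         for p in isoa[:3]],
        "isoA_verification": [ProteinReference(p.ref_id, p.sequence,
                                               ROLE_VERIFY)
                              for p in isoa[3:6]],
        "recA_queries": [ProteinReference(p.ref_id, p.sequence, ROLE_NORM)
                         for p in reca[:2]],
        "planted": {"isoA": isoa[6].sequence, "recA": reca[2].sequence},
    }


_ISO_GENE_LENGTHS = {
    "isoA": 500, "isoB": 340, "isoC": 110, "isoD": 170, "isoE": 350,
    "isoF": 100, "isoG": 280, "isoH": 320, "isoI": 250, "isoJ": 150,
    "aldH1": 480, "aldH2": 470, "gshB": 310, "garB": 440, "CoA-DSR": 530,
}


def iso_cluster_references(seed: int = 777_001) -> dict[str, ProteinReference]:
    """One synthetic reference protein per isoprene-pathway gene."""
    rng = np.random.default_rng(seed)
    return {gene: ProteinReference(f"{gene}|ref",
                                   _random_protein(length, rng))
            for gene, length in _ISO_GENE_LENGTHS.items()}


# ---------------------------------------------------------------------------
# Genome construction


def reverse_translate(protein: str, gc: float,
                      rng: np.random.Generator) -> str:
    """Back-translate a protein with codons sampled to match a target GC.

    Synonymous codons are weighted by the product of per-base probabilities
    implied by the target GC (table 11); a TAA stop codon is appended.
    """
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    out = []
    for aa in protein:
        codons = _CODONS[aa]
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        out.append(codons[rng.choice(len(codons), p=w / w.sum())])
    out.append("TAA")
    return "".join(out)


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


_NT_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def build_genome(model: GenomeModel, rng: np.random.Generator) -> GenomeModel:
    """Emit the genome sequence: GC-matched background + planted genes."""
    codes = _background(model.length, model.gc, rng)
    seq = _NT_LUT[codes].tobytes().decode("ascii")
    occupied: list[tuple[int, int]] = []
    loci = []
    for gene_name, protein, copies in model.markers:
        for _ in range(copies):
            gene = reverse_translate(protein, model.gc, rng)
            if rng.random() < 0.5:
                gene = revcomp(gene)
                strand = "-"
            else:
                strand = "+"
            glen = len(gene)
            if glen > model.length:
                raise ValueError(
                    f"gene {gene_name} ({glen} bp) exceeds genome length")
            for _attempt in range(1000):
                start = int(rng.integers(0, model.length - glen + 1))
                if all(start + glen <= s or start >= e
                       for s, e in occupied):
                    break
            else:
                raise ValueError("could not place markers without overlap")
            occupied.append((start, start + glen))
            seq = seq[:start] + gene + seq[start + glen:]
            loci.append((gene_name, start, start + glen, strand))
    model.sequence = seq
    model.marker_loci = sorted(loci, key=lambda t: t[1])
    return model


# ---------------------------------------------------------------------------
# Community generation


def generate_community(n_taxa: int, carrier_fraction: float,
                       labeled_taxa: Iterable[str] = (),
                       seed: int = 0, *,
                       genome_length: int = 10_000,
                       gc_range: tuple[float, float] = (0.40, 0.60),
                       abundance: str = "dirichlet",
                       dirichlet_alpha: float = 1.0,
                       marker_set: Mapping[str, str] | None = None,
                       ) -> tuple[list[GenomeModel], CommunityProfile]:
    """Generate a community with a fixed fraction of isoA carriers.

    Exactly ``round(n_taxa * carrier_fraction)`` genomes carry a single
    isoA copy; every genome carries exactly one recA copy (the single-copy
    normalization assumption). Abundances are drawn from a symmetric
    Dirichlet (default concentration 1) or set uniform
    (``abundance="uniform"``). Taxa named in ``labeled_taxa`` are fully
    13C-labelled; ids follow ``taxon_NNNN``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    planted = dict(marker_set) if marker_set is not None \
        else default_marker_references()["planted"]
    rng = np.random.default_rng(seed)
    ids = [f"taxon_{i:04d}" for i in range(n_taxa)]
    labeled = set(labeled_taxa)
    unknown = labeled - set(ids)
    if unknown:
        raise ValueError(f"labeled taxa not in community: {sorted(unknown)}")

    n_carriers = int(round(n_taxa * carrier_fraction))
    carriers = set(rng.choice(n_taxa, size=n_carriers, replace=False).tolist())

    genomes = []
    for i, taxon in enumerate(ids):
        gc = float(rng.uniform(*gc_range))
        markers = [("recA", planted["recA"], 1)]
        if i in carriers:
            markers.append(("isoA", planted["isoA"], 1))
        genome = GenomeModel(
            taxon_id=taxon, length=genome_length, gc=gc, markers=markers,
            label_atom_fraction=1.0 if taxon in labeled else 0.0)
        genomes.append(build_genome(genome, rng))

    if abundance == "uniform":
        ab = np.full(n_taxa, 1.0 / n_taxa)
    elif abundance == "dirichlet":
        ab = rng.dirichlet(np.full(n_taxa, dirichlet_alpha))
    else:
        raise ValueError(f"unknown abundance distribution {abundance!r}")
    ab = ab / ab.sum()
    return genomes, CommunityProfile(dict(zip(ids, ab.tolist())))


# ---------------------------------------------------------------------------
# Read simulation


def _qualities(cfg: ReadSimConfig, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Per-read Phred qualities, (n, L) int array."""
    spec = cfg.quality_model
    if spec.startswith("constant:"):
        q = int(spec.split(":")[1])
        return np.full((n, cfg.read_length), q, dtype=np.int16)
    if spec.startswith("two-state:"):
        hi, lo, p_lo = spec.split(":")[1].split(",")
        state = rng.random((n, cfg.read_length)) < float(p_lo)
        return np.where(state, int(lo), int(hi)).astype(np.int16)
    raise ValueError(f"unknown quality model {spec!r}")


def simulate_reads(genomes: Sequence[GenomeModel], community: CommunityProfile,
                   cfg: ReadSimConfig):
    """Simulate shotgun reads with per-read provenance.

    Reads are sampled from genomes proportionally to abundance x genome
    length, from either strand, with i.i.d. substitution errors. Returns
    ``(reads, truth)`` where reads is a list of
    :class:`isosip.io.SequenceRecord` and truth a DataFrame with columns
    read_id, taxon_id, start, end, strand (test scaffolding only).
    """
    from .io import SequenceRecord  # avoid import cycle at module load

    by_id = {g.taxon_id: g for g in genomes}
    taxa = [t for t, a in community.abundances.items() if a > 0]
    if not taxa:
        raise ValueError("community is empty")
    missing = [t for t in taxa if t not in by_id]
    if missing:
        raise ValueError(f"community taxa without genomes: {missing[:5]}")
    L = cfg.read_length
    for t in taxa:
        if by_id[t].length < L:
            raise ValueError(f"genome {t} shorter than read length")

    rng = np.random.default_rng(cfg.seed)
    w = np.array([community.abundances[t] * by_id[t].length for t in taxa])
    w = w / w.sum()
    choice = rng.choice(len(taxa), size=cfg.n_reads, p=w)
    starts = np.empty(cfg.n_reads, dtype=np.int64)
    strands = rng.random(cfg.n_reads) < 0.5  # True = minus

    code_of = {c: i for i, c in enumerate("ACGT")}
    genome_codes = {}
    for t in taxa:
        seq = by_id[t].sequence
        genome_codes[t] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)

    nt_code = np.full(128, 0, dtype=np.uint8)
    for c, i in code_of.items():
        nt_code[ord(c)] = i

    reads_codes = np.empty((cfg.n_reads, L), dtype=np.uint8)
    offs = np.arange(L)
    for ti, t in enumerate(taxa):
        rows = np.nonzero(choice == ti)[0]
        if rows.size == 0:
            continue
        g = nt_code[genome_codes[t]]
        pos = rng.integers(0, by_id[t].length - L + 1, size=rows.size)
        starts[rows] = pos
        reads_codes[rows] = g[pos[:, None] + offs]

    minus = np.nonzero(strands)[0]
    if minus.size:
        comp = np.array([3, 2, 1, 0], dtype=np.uint8)
        reads_codes[minus] = comp[reads_codes[minus]][:, ::-1]

    if cfg.sub_error_rate > 0:
        err = rng.random((cfg.n_reads, L)) < cfg.sub_error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        flat = reads_codes[err]
        reads_codes[err] = (flat + shift) % 4

    quals = _qualities(cfg, cfg.n_reads, rng)
    ascii_all = _NT_LUT[reads_codes].tobytes().decode("ascii")
    reads = []
    truth_rows = []
    for i in range(cfg.n_reads):
        rid = f"read_{i:07d}"
        seq = ascii_all[i * L:(i + 1) * L]
        reads.append(SequenceRecord(rid, seq, quals[i].tolist()))
        truth_rows.append((rid, taxa[choice[i]], int(starts[i]),
                           int(starts[i]) + L, "-" if strands[i] else "+"))
    truth = pd.DataFrame(truth_rows, columns=[
        "read_id", "taxon_id", "start", "end", "strand"])
    return reads, truth


# ---------------------------------------------------------------------------
# Gradient simulation


def simulate_gradient(genomes: Sequence[GenomeModel],
                      community: CommunityProfile,
                      model: SIPGradientModel | None = None,
                      seed: int = 0,
                      total_dna: float = 1.0) -> list[FractionSample]:
    """Distribute each taxon's DNA over gradient fractions.

    Each taxon bands as a Gaussian centred at the linear buoyant-density
    model (plus an optional seeded per-taxon centre jitter) with sd
    ``density_noise_sd``. The outermost fractions absorb the tails so DNA
    mass is conserved exactly. Fractions are returned densest first
    (fraction 1 = heaviest).
    """
    model = model or SIPGradientModel()
    by_id = {g.taxon_id: g for g in genomes}
    taxa = list(community.abundances)
    masses = np.array([community.abundances[t] for t in taxa]) * total_dna
    if masses.sum() <= 0:
        raise ValueError("community has no DNA mass")
    missing = [t for t in taxa if t not in by_id]
    if missing:
        raise ValueError(f"community taxa without genomes: {missing[:5]}")

    rng = np.random.default_rng(seed)
    edges = model.fraction_edges
    n_frac = edges.size - 1
    # open-ended outer bins conserve total mass
    lo = np.concatenate(([-np.inf], edges[1:-1]))
    hi = np.concatenate((edges[1:-1], [np.inf]))

    frac_mass = np.zeros(n_frac)
    frac_comp = np.zeros((n_frac, len(taxa)))
    for k, t in enumerate(taxa):
        g = by_id[t]
        centre = buoyant_density(model, g.gc, g.label_atom_fraction)
        if model.center_jitter_sd > 0:
            centre += rng.normal(0.0, model.center_jitter_sd)
        share = (norm.cdf(hi, loc=centre, scale=model.density_noise_sd)
                 - norm.cdf(lo, loc=centre, scale=model.density_noise_sd))
        frac_comp[:, k] = masses[k] * share
    frac_mass = frac_comp.sum(axis=1)

    mids = 0.5 * (edges[:-1] + edges[1:])
    samples = []
    order = np.argsort(mids)[::-1]  # densest first
    for rank, b in enumerate(order, start=1):
        amount = float(frac_mass[b])
        if amount > 0:
            comp = dict(zip(taxa, (frac_comp[b] / amount).tolist()))
        else:
            comp = {t: 0.0 for t in taxa}
        samples.append(FractionSample(
            fraction_index=rank, mean_density=float(mids[b]),
            dna_amount=amount, composition=CommunityProfile(comp)))
    return samples
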