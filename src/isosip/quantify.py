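"""Normalized marker-carrier statistics across metagenomes.

Unique verified hit counts for a target marker (isoA) and a single-copy
normalization marker (recA) are made commensurable across metagenomes by
two multiplicative factors: a depth factor ``N_min / N_i`` (read count of
the smallest metagenome over this metagenome's) and a per-gene length
factor ``L_min / L_gene`` (shortest reference protein in the gene's own
set over this gene's length). Because recA is single copy, the ratio of
the scaled totals estimates the fraction of genomes carrying the target:

    pct_carriers = 100 * scaled_target / scaled_recA
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MetagenomeStats:
    metagenome_id: str
    n_reads: int
    mean_read_length: float = 143.0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")


@dataclass
class MarkerAbundanceResult:
    """Per-metagenome carrier statistic ("% of bacteria containing isoA")."""

    metagenome_id: str
    raw_target_hits: int
    raw_norm_hits: int
    scaled_target_hits: float
    scaled_norm_hits: float
    pct_carriers: float


class DegenerateNormalizationError(ValueError):
    """Raised when the normalization-marker total is zero but target > 0."""


def normalize_hits(per_gene_hits: Mapping[str, Mapping[str, float]],
                   stats: Sequence[MetagenomeStats],
                   gene_lengths: Mapping[str, int],
                   l_min: int | None = None) -> pd.DataFrame:
    """Depth- and length-scale unique hit counts per metagenome.

    ``per_gene_hits`` maps metagenome_id -> {ref_id: unique verified
    count}. Depth scaling multiplies every count by N_min/N_i (N_min over
    the metagenomes supplied); length scaling multiplies each gene's count
    by L_min/L_gene. By default L_min is the shortest reference length in
    ``gene_lengths``; pass ``l_min`` to anchor the scaling to a minimum
    taken over several gene sets (required when two marker totals are to
    be divided - only a common anchor makes each total proportional to
    count/length and hence a genome-count proxy). Returns a frame with raw
    and scaled totals.
    """
    by_id = {s.metagenome_id: s for s in stats}
    n_min = min(s.n_reads for s in stats)
    if l_min is None:
        if not gene_lengths:
            raise KeyError("gene_lengths is empty")
        l_min = min(gene_lengths.values())
    rows = []
    for mg_id, hits in per_gene_hits.items():
        if mg_id not in by_id:
            raise ValueError(f"no MetagenomeStats for {mg_id!r}")
        depth = n_min / by_id[mg_id].n_reads
        raw = 0.0
        scaled = 0.0
        for gene, count in hits.items():
            if gene not in gene_lengths:
                raise KeyError(f"missing length for gene {gene!r}")
            raw += count
            scaled += count * depth * (l_min / gene_lengths[gene])
        rows.append((mg_id, raw, scaled))
    return pd.DataFrame(rows, columns=["metagenome_id", "raw_hits",
                                       "scaled_hits"]).set_index(
                                           "metagenome_id")


def percent_marker_carriers(target_scaled: float, norm_scaled: float) -> float:
    """100 x target / normalization marker, guarded against a zero norm."""
    if target_scaled < 0 or norm_scaled < 0:
        raise ValueError("scaled hit totals must be non-negative")
    if norm_scaled == 0:
        if target_scaled == 0:
            return 0.0
        raise DegenerateNormalizationError(
            "normalization-marker total is zero but target hits exist")
    return 100.0 * target_scaled / norm_scaled


def marker_abundance(target_hits: Mapping[str, Mapping[str, float]],
                     norm_hits: Mapping[str, Mapping[str, float]],
                     stats: Sequence[MetagenomeStats],
                     target_lengths: Mapping[str, int],
                     norm_lengths: Mapping[str, int],
                     length_norm: str = "global",
                     ) -> list[MarkerAbundanceResult]:
    """Full carrier statistic for a set of metagenomes.

    ``length_norm="global"`` (default) anchors the length scaling to the
    shortest gene across both marker sets, making the target/norm ratio a
    genome-count proxy; ``"per_set"`` anchors each set to its own minimum.
    """
    if length_norm == "global":
        l_min = min(min(target_lengths.values()), min(norm_lengths.values()))
    elif length_norm == "per_set":
        l_min = None
    else:
        raise ValueError("length_norm must be 'global' or 'per_set'")
    t = normalize_hits(target_hits, stats, target_lengths, l_min=l_min)
    n = normalize_hits(norm_hits, stats, norm_lengths, l_min=l_min)
    out = []
    for s in stats:
        ts = t.loc[s.metagenome_id] if s.metagenome_id in t.index else None
        ns = n.loc[s.metagenome_id] if s.metagenome_id in n.index else None
        t_raw = int(ts["raw_hits"]) if ts is not None else 0
        n_raw = int(ns["raw_hits"]) if ns is not None else 0
        t_sc = float(ts["scaled_hits"]) if ts is not None else 0.0
        n_sc = float(ns["scaled_hits"]) if ns is not None else 0.0
        out.append(MarkerAbundanceResult(
            metagenome_id=s.metagenome_id, raw_target_hits=t_raw,
            raw_norm_hits=n_raw, scaled_target_hits=t_sc,
            scaled_norm_hits=n_sc,
            pct_carriers=percent_marker_carriers(t_sc, n_sc)))
    return out


def compare_habitats(results: Sequence[MarkerAbundanceResult]) -> pd.DataFrame:
    """Pairwise fold-ratios of carrier percentages (larger/smaller)."""
    if len(results) < 2:
        raise ValueError("need at least two results to compare")
    rows = []
    for i, a in enumerate(results):
        for b in results[i + 1:]:
            pa, pb = a.pct_carriers, b.pct_carriers
            if pa >= pb:
                hi, lo, hi_id, lo_id = pa, pb, a.metagenome_id, b.metagenome_id
            else:
                hi, lo, hi_id, lo_id = pb, pa, b.metagenome_id, a.metagenome_id
            if lo == 0:
                warnings.warn(
                    f"fold ratio {hi_id}/{lo_id} is infinite (zero percent)")
                ratio = np.inf
            else:
                ratio = hi / lo
            rows.append((hi_id, lo_id, hi, lo, ratio))
    return pd.DataFrame(rows, columns=[
        "higher", "lower", "pct_higher", "pct_lower", "fold_ratio"])
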