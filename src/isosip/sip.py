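"""Heavy/light fraction identification and labeled-taxon calling.

A DNA-SIP experiment compares a 13C-substrate incubation against a 12C
control. The light window is centred on the control's DNA peak in the
density profile; the heavy window on the labelled profile's excess-DNA
peak at higher density. Taxa whose relative abundance is strongly
enriched in the heavy versus light window of the 13C incubation - and
whose enrichment is not mirrored in the 12C control - are called labelled
(active substrate consumers). The decision rule:

    labeled        <=> fc_13C >= min_fold_13C and
                       (no 12C data or fc_13C / fc_12C >= min_control_ratio)
    not_confirmed  <=> fc_13C >= min_fold_13C but the control criterion fails
    unlabeled      otherwise

with fc = (RA_heavy + pseudocount) / (RA_light + pseudocount).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import CommunityProfile, FractionSample

SAMPLE_LABELS = ("T0", "13C_H", "13C_L", "13C_UF", "12C_H", "12C_L")


@dataclass
class FractionProfile:
    """DNA yield as a function of buoyant density for one gradient."""

    sample_id: str
    points: list[tuple[float, float]]  # (density g/ml, dna amount)

    def __post_init__(self):
        dens = np.array([p[0] for p in self.points])
        if np.any(np.diff(dens) == 0) or not (
                np.all(np.diff(dens) > 0) or np.all(np.diff(dens) < 0)):
            raise ValueError("densities must be strictly monotonic")
        if any(p[1] < 0 for p in self.points):
            raise ValueError("dna_amount must be non-negative")

    @classmethod
    def from_fractions(cls, sample_id: str,
                       fractions: Sequence[FractionSample]):
        pts = sorted(((f.mean_density, f.dna_amount) for f in fractions))
        return cls(sample_id, [(float(d), float(a)) for d, a in pts])


@dataclass
class FractionWindow:
    """Non-overlapping heavy and light density windows."""

    heavy: tuple[float, float]
    light: tuple[float, float]
    heavy_indices: list[int] | None = None
    light_indices: list[int] | None = None
    fallback: bool = False

    def __post_init__(self):
        if self.heavy[0] <= self.light[1]:
            raise ValueError("heavy window must lie above the light window")


@dataclass
class EnrichmentParams:
    """Thresholds of the labeled/not-confirmed/unlabeled decision rule."""

    min_fold_13C: float = 5.0
    min_control_ratio: float = 2.0
    pseudocount: float = 1e-4

    def __post_init__(self):
        if min(self.min_fold_13C, self.min_control_ratio,
               self.pseudocount) <= 0:
            raise ValueError("all enrichment parameters must be positive")


@dataclass
class EnrichmentRecord:
    taxon: str
    fc_13C: float
    fc_12C: float | None = None
    ra_unfractionated: float | None = None
    call: str = ""


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average with edge replication."""
    padded = np.concatenate(([y[0]], y, [y[-1]]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _peak_index(y: np.ndarray) -> int:
    """Index of the global maximum; ties go to the denser (higher) side."""
    best = np.nonzero(y == y.max())[0]
    return int(best[-1])


def identify_fractions(labeled_profile: FractionProfile,
                       control_profile: FractionProfile,
                       window_halfwidth_fracs: int = 1) -> FractionWindow:
    """Locate heavy and light windows from density-vs-DNA profiles.

    The light window is centred on the control (12C) profile's smoothed
    DNA peak; the heavy window on the smoothed excess (labelled minus
    control, after total-DNA normalization) peak at higher density. When
    no excess peak is resolvable the heavy window falls back to a fixed
    +0.03 to +0.04 g/ml offset from the light peak, with a warning.
    """
    for p in (labeled_profile, control_profile):
        if len(p.points) < 6:
            raise ValueError(f"profile {p.sample_id} has fewer than 6 points")
    dens_c = np.array([d for d, _ in control_profile.points])
    dna_c = np.array([a for _, a in control_profile.points])
    dens_l = np.array([d for d, _ in labeled_profile.points])
    dna_l = np.array([a for _, a in labeled_profile.points])
    # ascending density
    oc = np.argsort(dens_c)
    ol = np.argsort(dens_l)
    dens_c, dna_c = dens_c[oc], dna_c[oc]
    dens_l, dna_l = dens_l[ol], dna_l[ol]

    sm_c = _smooth3(dna_c)
    light_peak = _peak_index(sm_c)
    light_density = dens_c[light_peak]

    # excess DNA of the labelled gradient, on a common (labelled) axis
    ctrl_interp = np.interp(dens_l, dens_c, sm_c)
    scale = dna_l.sum() / dna_c.sum() if dna_c.sum() > 0 else 1.0
    excess = _smooth3(dna_l) - ctrl_interp * scale
    heavier = dens_l > light_density
    step = np.median(np.diff(dens_l))
    resolvable = False
    if heavier.any():
        cand = np.where(heavier, excess, -np.inf)
        hi = _peak_index(cand)
        # require a genuinely heavier, positive excess peak
        if excess[hi] > 0.02 * sm_c.max() and \
                dens_l[hi] >= light_density + 2 * step:
            resolvable = True
            heavy_density = dens_l[hi]

    fallback = not resolvable
    if fallback:
        warnings.warn("no resolvable heavy peak; falling back to a fixed "
                      "+0.03 to +0.04 g/ml offset window")
        heavy_lo = light_density + 0.03
        heavy_hi = light_density + 0.04
        heavy_idx = [int(i) for i in np.nonzero(
            (dens_l >= heavy_lo) & (dens_l <= heavy_hi))[0]]
    else:
        k = window_halfwidth_fracs
        lo_i = max(hi - k, 0)
        hi_i = min(hi + k, len(dens_l) - 1)
        half = step / 2
        heavy_lo, heavy_hi = dens_l[lo_i] - half, dens_l[hi_i] + half
        heavy_idx = list(range(lo_i, hi_i + 1))

    k = window_halfwidth_fracs
    lo_i = max(light_peak - k, 0)
    hi_i = min(light_peak + k, len(dens_c) - 1)
    step_c = np.median(np.diff(dens_c))
    light_lo, light_hi = dens_c[lo_i] - step_c / 2, dens_c[hi_i] + step_c / 2
    # trim any overlap in favour of the heavy window
    if light_hi >= heavy_lo:
        light_hi = heavy_lo - 1e-9
    return FractionWindow(heavy=(float(heavy_lo), float(heavy_hi)),
                          light=(float(light_lo), float(light_hi)),
                          heavy_indices=heavy_idx,
                          light_indices=list(range(lo_i, hi_i + 1)),
                          fallback=fallback)


def pool_window(fractions: Sequence[FractionSample],
                window: tuple[float, float]) -> pd.Series:
    """DNA-weighted taxon composition pooled over a density window."""
    total = 0.0
    acc: dict[str, float] = {}
    for f in fractions:
        if window[0] <= f.mean_density <= window[1] and f.dna_amount > 0:
            total += f.dna_amount
            for t, ra in f.composition.abundances.items():
                acc[t] = acc.get(t, 0.0) + ra * f.dna_amount
    if total == 0:
        return pd.Series(dtype=float)
    return pd.Series(acc) / total


def make_abundance_table(columns: Mapping[str, pd.Series | Mapping[str, float]]
                         ) -> pd.DataFrame:
    """Taxon x sample relative-abundance table; columns renormalized."""
    table = pd.DataFrame({k: pd.Series(v) for k, v in columns.items()})
    table = table.fillna(0.0)
    sums = table.sum(axis=0)
    for c in table.columns:
        if sums[c] > 0:
            table[c] = table[c] / sums[c]
    return table


def fold_enrichment(table: pd.DataFrame,
                    params: EnrichmentParams | None = None
                    ) -> list[EnrichmentRecord]:
    """Heavy/light fold-changes per taxon from an abundance table.

    Requires ``13C_H`` and ``13C_L`` columns; ``12C_H``/``12C_L`` are used
    for the control fold-change when both are present. A pseudocount
    floors the relative abundances so ratios stay finite.
    """
    params = params or EnrichmentParams()
    missing = [c for c in ("13C_H", "13C_L") if c not in table.columns]
    if missing:
        raise ValueError(f"abundance table missing required columns {missing}")
    has_ctrl = {"12C_H", "12C_L"} <= set(table.columns)
    pc = params.pseudocount
    records = []
    for taxon, row in table.iterrows():
        fc13 = (row["13C_H"] + pc) / (row["13C_L"] + pc)
        fc12 = (row["12C_H"] + pc) / (row["12C_L"] + pc) if has_ctrl else None
        ra_uf = float(row["13C_UF"]) if "13C_UF" in table.columns else None
        records.append(EnrichmentRecord(str(taxon), float(fc13),
                                        None if fc12 is None else float(fc12),
                                        ra_uf))
    return records


def call_labeled(records: Sequence[EnrichmentRecord],
                 params: EnrichmentParams | None = None
                 ) -> list[EnrichmentRecord]:
    """Apply the labeled / not_confirmed / unlabeled decision rule.

    The unfractionated relative abundance, when present, is reported as
    supporting evidence only - it never changes a call.
    """
    params = params or EnrichmentParams()
    for r in records:
        if r.fc_13C >= params.min_fold_13C:
            if r.fc_12C is None or \
                    r.fc_13C / r.fc_12C >= params.min_control_ratio:
                r.call = "labeled"
            else:
                r.call = "not_confirmed"
        else:
            r.call = "unlabeled"
    return list(records)


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.taxon, r.fc_13C, r.fc_12C, r.ra_unfractionated, r.call)
         for r in records],
        columns=["taxon", "fc_13C", "fc_12C", "ra_unfractionated", "call"])
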