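"""Scoring of the cell-based mitochondrial-clearance screen.

Per-cell reporter intensities (mito-DsRed) arrive as long-format tables with
one row per cell; wells are negative controls (vehicle only, mitochondria
retained, high intensity), positive controls (depolarizer-treated, cleared,
low intensity) or compound wells.  The pipeline:

1. derive an intensity cutoff separating the two control populations;
2. per-well clearance = % of cells below the cutoff;
3. per-plate Z-factor, Z' = 1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg|;
4. normalize compound clearance to percent-of-positive-control per plate;
5. robust MAD z-score per compound, averaged over screen replicates;
6. top-k hit calling and hit rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigError, ScreenError

__all__ = [
    "NEGATIVE_CONTROL",
    "POSITIVE_CONTROL",
    "COMPOUND",
    "PLATE_COLUMNS",
    "IntensityCutoff",
    "PlateQC",
    "CompoundScore",
    "ScreenResult",
    "validate_plate_table",
    "derive_intensity_cutoff",
    "well_clearance",
    "z_factor",
    "mad_z",
    "call_hits",
    "score_screen",
]

NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"
COMPOUND = "compound"
ROLES = (NEGATIVE_CONTROL, POSITIVE_CONTROL, COMPOUND)
PLATE_COLUMNS = ["plate", "well", "role", "compound", "cell_id", "intensity"]

MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma for normal data


@dataclass(frozen=True)
class IntensityCutoff:
    """Threshold separating cleared (below) from retained (at/above) cells."""

    tau: float
    method: str
    neg_misclass: float
    pos_misclass: float


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    z_factor: float


@dataclass
class CompoundScore:
    compound_id: str
    clearance_pct: tuple[float, ...]  # mean clearance per screen replicate
    normalized_value: float  # percent-of-positive-control, mean over replicates
    mad_z: float  # replicate z-scores aggregated by mean
    rank: int = 0
    is_hit: bool = False


@dataclass(frozen=True)
class ScreenResult:
    compound_scores: tuple[CompoundScore, ...]
    plate_qc: tuple[PlateQC, ...]
    cutoffs: tuple[IntensityCutoff, ...]
    hit_rate: float
    hits: tuple[str, ...] = field(default_factory=tuple)


def validate_plate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-cell table schema and control-well invariants."""
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"plate table missing columns: {missing}")
    bad_roles = set(table["role"]) - set(ROLES)
    if bad_roles:
        raise ConfigError(f"unknown roles in plate table: {sorted(bad_roles)}")
    intensity = table["intensity"].to_numpy(dtype=float)
    if not np.all(np.isfinite(intensity)) or np.any(intensity < 0):
        raise ConfigError("intensities must be finite and >= 0")
    roles_per_well = table.groupby(["plate", "well"])["role"].nunique()
    if (roles_per_well > 1).any():
        raise ConfigError("a (plate, well) pair carries more than one role")
    for plate, sub in table.groupby("plate"):
        for role in (NEGATIVE_CONTROL, POSITIVE_CONTROL):
            n = sub[sub["role"] == role]["well"].nunique()
            if n < 2:
                raise ConfigError(
                    f"plate {plate!r} has {n} {role} wells; at least 2 required"
                )
    return table


def derive_intensity_cutoff(
    neg_cells: Sequence[float], pos_cells: Sequence[float]
) -> IntensityCutoff:
    """Control-derived intensity cutoff.

    The objective ``frac(neg < tau) + frac(pos >= tau)`` is piecewise
    constant between consecutive pooled unique intensities, so the scan
    evaluates the midpoint of every such interval and returns the minimizer
    (smallest tau on ties).  For well-separated controls this lands the
    cutoff midway between the two populations.
    """
    neg = np.asarray(neg_cells, dtype=float)
    pos = np.asarray(pos_cells, dtype=float)
    if neg.size < 50 or pos.size < 50:
        # tolerate small fixtures but insist on non-trivial populations
        if neg.size < 2 or pos.size < 2:
            raise ScreenError("need at least 2 cells per control population")
    uniq = np.unique(np.concatenate([neg, pos]))
    if uniq.size < 2:
        raise ScreenError("non-separable controls")
    taus = (uniq[:-1] + uniq[1:]) / 2.0
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    neg_below = np.searchsorted(neg_sorted, taus) / neg.size
    pos_above = (pos.size - np.searchsorted(pos_sorted, taus)) / pos.size
    objective = neg_below + pos_above
    best = int(np.argmin(objective))  # argmin takes the first -> smallest tau
    return IntensityCutoff(
        tau=float(taus[best]),
        method="misclassification-sum",
        neg_misclass=float(neg_below[best]),
        pos_misclass=float(pos_above[best]),
    )


def well_clearance(cells: Sequence[float], cutoff: IntensityCutoff) -> float:
    """Percent of cells with intensity below the cutoff (cleared mitochondria)."""
    arr = np.asarray(cells, dtype=float)
    if arr.size == 0:
        raise ScreenError("empty well")
    return 100.0 * float(np.mean(arr < cutoff.tau))


def z_factor(
    pos_wells: Sequence[float],
    neg_wells: Sequence[float],
    plate_id: str = "",
) -> PlateQC:
    """Z' = 1 - 3(sigma_pos + sigma_neg) / |mu_pos - mu_neg|.

    Standard deviations are sample (n-1) SDs over control-well clearance
    percentages; values near 1 indicate a robust assay window, and negative
    values are valid (overlapping controls).
    """
    pos = np.asarray(pos_wells, dtype=float)
    neg = np.asarray(neg_wells, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ScreenError("need at least 2 wells per control role")
    mu_pos, mu_neg = float(np.mean(pos)), float(np.mean(neg))
    if mu_pos == mu_neg:
        raise ScreenError("zero dynamic range")
    sigma_pos = float(np.std(pos, ddof=1))
    sigma_neg = float(np.std(neg, ddof=1))
    z = 1.0 - 3.0 * (sigma_pos + sigma_neg) / abs(mu_pos - mu_neg)
    return PlateQC(plate_id, mu_pos, sigma_pos, mu_neg, sigma_neg, z)


def mad_z(values: Sequence[float]) -> np.ndarray:
    """Robust z-scores: (x - median) / (1.4826 * MAD)."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ScreenError("need at least 4 values for MAD z-scores")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ScreenError("degenerate spread (MAD = 0)")
    return (x - med) / (MAD_SCALE * mad)


def call_hits(
    scores: Sequence[CompoundScore], k: int
) -> tuple[list[CompoundScore], float]:
    """Top-k hit calling on aggregated MAD z-scores.

    Returns the hit list and the hit rate (100*k/#compounds, one decimal).
    Ties are broken by ascending compound_id; ``scores`` entries get their
    ``rank`` and ``is_hit`` fields filled in place.
    """
    if k > len(scores):
        raise ScreenError(f"k={k} exceeds the number of compounds ({len(scores)})")
    ordered = sorted(scores, key=lambda s: (-s.mad_z, s.compound_id))
    for i, s in enumerate(ordered):
        s.rank = i + 1
        s.is_hit = i < k
    hit_rate = round(100.0 * k / len(scores), 1)
    return ordered[:k], hit_rate


def _replicate_scores(
    table: pd.DataFrame, normalization: str
) -> tuple[dict[str, float], dict[str, float], list[PlateQC], IntensityCutoff]:
    """Per-compound clearance and normalized values for one screen replicate."""
    validate_plate_table(table)
    neg_cells = table.loc[table["role"] == NEGATIVE_CONTROL, "intensity"]
    pos_cells = table.loc[table["role"] == POSITIVE_CONTROL, "intensity"]
    cutoff = derive_intensity_cutoff(neg_cells, pos_cells)

    wells = (
        table.groupby(["plate", "well", "role", "compound"], dropna=False)["intensity"]
        .apply(lambda g: well_clearance(g, cutoff))
        .reset_index(name="clearance")
    )
    qc = []
    pos_mean_by_plate = {}
    for plate, sub in wells.groupby("plate"):
        pos_wells = sub.loc[sub["role"] == POSITIVE_CONTROL, "clearance"].to_list()
        neg_wells = sub.loc[sub["role"] == NEGATIVE_CONTROL, "clearance"].to_list()
        qc.append(z_factor(pos_wells, neg_wells, plate_id=str(plate)))
        pos_mean_by_plate[plate] = float(np.mean(pos_wells))

    comp = wells[wells["role"] == COMPOUND].copy()
    if normalization == "percent-of-control":
        comp["value"] = [
            100.0 * c / pos_mean_by_plate[p]
            for p, c in zip(comp["plate"], comp["clearance"])
        ]
    elif normalization == "raw":
        comp["value"] = comp["clearance"]
    else:
        raise ConfigError(f"unknown normalization {normalization!r}")
    clearance = comp.groupby("compound")["clearance"].mean().to_dict()
    values = comp.groupby("compound")["value"].mean().to_dict()
    return clearance, values, qc, cutoff


def score_screen(
    replicates: Sequence[pd.DataFrame],
    k: int = 3,
    normalization: str = "percent-of-control",
) -> ScreenResult:
    """Score a full screen across independent replicates.

    Each replicate table is scored separately (own cutoff, own plate QC and
    normalization); MAD z-scores are computed within each replicate and
    aggregated per compound by their mean before ranking and hit calling.
    """
    if not replicates:
        raise ScreenError("no replicate tables given")
    per_rep = [_replicate_scores(t, normalization) for t in replicates]
    compounds = sorted(per_rep[0][1])
    for _, values, _, _ in per_rep[1:]:
        if sorted(values) != compounds:
            raise ScreenError("replicates disagree on the compound set")
    z_by_rep = []
    for _, values, _, _ in per_rep:
        z_by_rep.append(mad_z([values[c] for c in compounds]))
    z_mean = np.mean(z_by_rep, axis=0)
    scores = [
        CompoundScore(
            compound_id=c,
            clearance_pct=tuple(rep[0][c] for rep in per_rep),
            normalized_value=float(np.mean([rep[1][c] for rep in per_rep])),
            mad_z=float(z_mean[i]),
        )
        for i, c in enumerate(compounds)
    ]
    hits, hit_rate = call_hits(scores, k)
    return ScreenResult(
        compound_scores=tuple(sorted(scores, key=lambda s: s.rank)),
        plate_qc=tuple(qc for rep in per_rep for qc in rep[2]),
        cutoffs=tuple(rep[3] for rep in per_rep),
        hit_rate=hit_rate,
        hits=tuple(h.compound_id for h in hits),
    )
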