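"""Synthetic corpora, screening plates, and reporter images with ground truth.

Every downstream stage of the pipeline is exercised against data whose true
structure is known:

* ``gen_corpus`` builds a topic-structured abstract corpus in which the
  training ("positive") drugs share elevated-frequency signal terms over a
  Zipf background vocabulary, with a mixing weight beta controlling signal
  strength (beta=0 makes positives and decoys token-exchangeable);
* ``gen_plate`` builds per-cell reporter-intensity tables as a two-component
  log-normal mixture (retained vs. cleared mitochondria) with configurable
  well-level cleared fractions and planted compound effects;
* ``gen_images`` builds two/three-channel rasters containing a shared
  mitochondrial network (both channels), red-only puncta (mCherry only) and
  circular lipid-droplet spots with an exactly controlled mitochondria
  overlap fraction.

All randomness flows from one ``numpy.random.Generator`` seeded per call;
identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .errors import ConfigError, GenerationError
from .image_quant import ImageStack
from .literature_ranking import CANDIDATE, TRAINING, Document, EntityCorpus
from .screen_scoring import COMPOUND, NEGATIVE_CONTROL, POSITIVE_CONTROL, PLATE_COLUMNS

__all__ = [
    "CorpusSimConfig",
    "PlateSimConfig",
    "ImageSimConfig",
    "SyntheticTruth",
    "gen_corpus",
    "gen_plate",
    "gen_images",
]

# image intensity levels (arbitrary fluorescence units)
BACKGROUND_LEVEL = 5.0
CYTO_LEVEL = 20.0  # dim cytoplasmic GFP so whole cells are segmentable
MITO_LEVEL = 100.0
PUNCTUM_LEVEL = 100.0
LD_LEVEL = 80.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator ground truth; fields are populated per generator."""

    # corpus
    planted_enhancers: tuple[str, ...] = ()
    signal_terms: tuple[str, ...] = ()
    # plates
    true_cleared_fraction: Mapping[tuple[str, str], float] = field(default_factory=dict)
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    # images
    cell_labels: np.ndarray | None = None
    mito_mask: np.ndarray | None = None
    ld_labels: np.ndarray | None = None
    true_puncta: Mapping[int, tuple] = field(default_factory=dict)
    true_puncta_count: Mapping[int, int] = field(default_factory=dict)
    true_red_only_area_pct: Mapping[int, float] = field(default_factory=dict)
    true_overlap_intensity_fraction: Mapping[int, float] = field(default_factory=dict)
    true_m1: Mapping[int, float] = field(default_factory=dict)
    true_m2: Mapping[int, float] = field(default_factory=dict)


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ConfigError(message)


# ---------------------------------------------------------------------------
# corpus


@dataclass(frozen=True)
class CorpusSimConfig:
    """Topic-structured abstract corpus.

    Positives draw each token from the shared signal-term set with
    probability ``signal_weight`` and otherwise from a Zipf(1.0) background
    over the whole vocabulary; decoys draw from the background only.  The
    signal terms are the rarest background words, mimicking the specialist
    vocabulary that co-cited drugs share.
    """

    n_positives: int = 7
    n_decoys: int = 100
    vocab_size: int = 500
    n_signal_terms: int = 10
    docs_per_entity_range: tuple[int, int] = (20, 20)
    doc_length_range: tuple[int, int] = (50, 150)
    signal_weight: float = 0.8
    year_range: tuple[int, int] = (2000, 2022)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_positives", "n_decoys", "vocab_size", "n_signal_terms"):
            _require(getattr(self, name) >= 1, f"{name} must be >= 1")
        _require(
            self.n_signal_terms < self.vocab_size,
            "n_signal_terms must be < vocab_size",
        )
        _require(0.0 <= self.signal_weight <= 1.0, "signal_weight must be in [0, 1]")
        for name in ("docs_per_entity_range", "doc_length_range", "year_range"):
            lo, hi = getattr(self, name)
            _require(1 <= lo <= hi or name == "year_range" and lo <= hi,
                     f"{name} must satisfy 1 <= min <= max")


def _zipf_probs(vocab_size: int) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = 1.0 / ranks
    return p / p.sum()


def gen_corpus(config: CorpusSimConfig) -> tuple[EntityCorpus, SyntheticTruth]:
    """Generate an entity corpus with planted positive-set signal."""
    rng = np.random.default_rng(config.seed)
    vocab = np.array([f"tok{i:05d}" for i in range(config.vocab_size)])
    # signal terms = rarest words under the Zipf background
    signal_idx = np.arange(config.vocab_size - config.n_signal_terms, config.vocab_size)
    background = _zipf_probs(config.vocab_size)

    positives = [f"positive_{i:03d}" for i in range(config.n_positives)]
    decoys = [f"decoy_{i:03d}" for i in range(config.n_decoys)]
    entities: dict[str, list[Document]] = {}
    roles: dict[str, str] = {}
    d_lo, d_hi = config.docs_per_entity_range
    l_lo, l_hi = config.doc_length_range
    y_lo, y_hi = config.year_range
    for eid in positives + decoys:
        is_positive = eid in positives
        n_docs = int(rng.integers(d_lo, d_hi + 1))
        docs = []
        for _ in range(n_docs):
            length = int(rng.integers(l_lo, l_hi + 1))
            idx = rng.choice(config.vocab_size, size=length, p=background)
            if is_positive and config.signal_weight > 0:
                use_signal = rng.random(length) < config.signal_weight
                idx[use_signal] = rng.choice(signal_idx, size=int(use_signal.sum()))
            year = int(rng.integers(y_lo, y_hi + 1))
            docs.append(Document(year=year, text=" ".join(vocab[idx])))
        entities[eid] = docs
        roles[eid] = TRAINING if is_positive else CANDIDATE
    truth = SyntheticTruth(
        planted_enhancers=tuple(positives),
        signal_terms=tuple(vocab[signal_idx]),
    )
    return EntityCorpus(entities, roles), truth


# ---------------------------------------------------------------------------
# plates


@dataclass(frozen=True)
class PlateSimConfig:
    """Per-cell reporter-intensity tables for a clearance screen.

    Each well is a two-component mixture: with well-specific probability f a
    cell's intensity comes from the (low) cleared log-normal, otherwise from
    the (high) retained log-normal.  Negative-control wells use a small
    cleared floor, positive controls ``positive_control_cleared_fraction``,
    and compound wells ``baseline_cleared_fraction`` plus any planted effect.
    The positive-control default of 0.78 matches the ~78% clearance typical
    of vehicle + depolarizer control wells in this assay.
    """

    n_plates: int = 1
    wells_per_plate: int = 96
    n_neg_control_wells: int = 4
    n_pos_control_wells: int = 4
    n_compounds: int = 79
    cells_per_well_range: tuple[int, int] = (180, 220)
    retained_intensity: tuple[float, float] = (6.2, 0.4)  # log-scale (mu, sigma)
    cleared_intensity: tuple[float, float] = (3.9, 0.4)
    baseline_cleared_fraction: float = 0.35
    positive_control_cleared_fraction: float = 0.78
    negative_control_floor: float = 0.02
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_plates >= 1, "n_plates must be >= 1")
        _require(self.n_neg_control_wells >= 2, "need >= 2 negative-control wells per plate")
        _require(self.n_pos_control_wells >= 2, "need >= 2 positive-control wells per plate")
        n_controls = self.n_neg_control_wells + self.n_pos_control_wells
        _require(
            self.wells_per_plate > n_controls,
            "wells_per_plate must exceed the number of control wells",
        )
        capacity = self.n_plates * (self.wells_per_plate - n_controls)
        _require(
            self.n_compounds <= capacity,
            f"n_compounds={self.n_compounds} exceeds plate capacity {capacity}",
        )
        lo, hi = self.cells_per_well_range
        _require(1 <= lo <= hi, "cells_per_well_range must satisfy 1 <= min <= max")
        _require(
            self.cleared_intensity[0] < self.retained_intensity[0],
            "cleared location must be below retained location",
        )
        f0 = self.baseline_cleared_fraction
        _require(0.0 <= f0 <= 1.0, "baseline_cleared_fraction must be in [0, 1]")
        _require(
            0.0 <= self.positive_control_cleared_fraction <= 1.0,
            "positive_control_cleared_fraction must be in [0, 1]",
        )
        for comp, df in self.planted_effects.items():
            _require(
                0.0 <= f0 + df <= 1.0,
                f"planted effect for {comp!r} pushes cleared fraction outside [0, 1]",
            )

    @property
    def compound_ids(self) -> list[str]:
        return [f"cmp{i:03d}" for i in range(self.n_compounds)]


def _well_name(index: int) -> str:
    rows = "ABCDEFGHIJKLMNOP"
    return f"{rows[index // 12]}{index % 12 + 1:02d}"


def gen_plate(config: PlateSimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one screen replicate as a long-format per-cell table."""
    rng = np.random.default_rng(config.seed)
    for comp in config.planted_effects:
        _require(comp in config.compound_ids, f"unknown planted compound {comp!r}")
    mu_r, sd_r = config.retained_intensity
    mu_c, sd_c = config.cleared_intensity
    c_lo, c_hi = config.cells_per_well_range

    records = []
    fractions: dict[tuple[str, str], float] = {}
    compounds = list(config.compound_ids)
    next_compound = 0
    cell_counter = 0
    for p in range(config.n_plates):
        plate_id = f"plate{p + 1:02d}"
        layout: list[tuple[str, str | None, float]] = []
        layout += [(NEGATIVE_CONTROL, None, config.negative_control_floor)] * config.n_neg_control_wells
        layout += [(POSITIVE_CONTROL, None, config.positive_control_cleared_fraction)] * config.n_pos_control_wells
        while len(layout) < config.wells_per_plate and next_compound < len(compounds):
            comp = compounds[next_compound]
            f = config.baseline_cleared_fraction + config.planted_effects.get(comp, 0.0)
            layout.append((COMPOUND, comp, f))
            next_compound += 1
        for w, (role, comp, f) in enumerate(layout):
            well_id = _well_name(w)
            n_cells = int(rng.integers(c_lo, c_hi + 1))
            cleared = rng.random(n_cells) < f
            intensity = np.where(
                cleared,
                rng.lognormal(mu_c, sd_c, n_cells),
                rng.lognormal(mu_r, sd_r, n_cells),
            )
            fractions[(plate_id, well_id)] = f
            for i in range(n_cells):
                records.append(
                    (plate_id, well_id, role, comp or "", cell_counter + i, intensity[i])
                )
            cell_counter += n_cells
    table = pd.DataFrame(records, columns=PLATE_COLUMNS)
    truth = SyntheticTruth(
        planted_enhancers=tuple(c for c, d in config.planted_effects.items() if d > 0),
        true_cleared_fraction=fractions,
        planted_effects=dict(config.planted_effects),
    )
    return table, truth


# ---------------------------------------------------------------------------
# images


@dataclass(frozen=True)
class ImageSimConfig:
    """Two/three-channel mitoQC-style reporter image.

    Cells are disjoint disks on a grid, each containing a dilated-chord
    mitochondrial network (signal in GFP and mCherry), red-only puncta
    (mCherry only), and uniform-intensity circular lipid-droplet spots in a
    third channel.  Exactly ``ld_mito_overlap_fraction`` of each cell's LD
    intensity is made to fall on mitochondrial pixels by painting
    mitochondrial signal under the chosen LD pixels.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 4
    cell_radius: int = 60
    puncta_count_range: tuple[int, int] = (2, 10)
    puncta_radius: int = 3
    ld_count_range: tuple[int, int] = (2, 5)
    ld_radius: int = 5
    ld_mito_overlap_fraction: float = 0.3
    noise_sd: float = 0.0
    n_mito_branches: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells must be >= 1")
        _require(self.cell_radius >= 10, "cell_radius must be >= 10")
        _require(self.puncta_radius >= 1 and self.ld_radius >= 1, "spot radii must be >= 1")
        for name in ("puncta_count_range", "ld_count_range"):
            lo, hi = getattr(self, name)
            _require(0 <= lo <= hi, f"{name} must satisfy 0 <= min <= max")
        _require(
            0.0 <= self.ld_mito_overlap_fraction <= 1.0,
            "ld_mito_overlap_fraction must be in [0, 1]",
        )
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")


def _cell_centers(config: ImageSimConfig) -> list[tuple[int, int]]:
    h, w = config.image_size
    step = 2 * config.cell_radius + 6
    n_cols = max(1, (w - 4) // step)
    n_rows = max(1, (h - 4) // step)
    if n_cols * n_rows < config.n_cells:
        raise GenerationError(
            f"cannot place {config.n_cells} cells of radius {config.cell_radius} "
            f"in a {h}x{w} image"
        )
    centers = []
    for i in range(config.n_cells):
        r, c = divmod(i, n_cols)
        centers.append(
            (2 + step // 2 + r * step, 2 + step // 2 + c * step)
        )
    return centers


def _place_spot(
    rng: np.random.Generator,
    center: tuple[int, int],
    cell_radius: int,
    spot_radius: int,
    blocked: np.ndarray,
    shape: tuple[int, int],
    max_attempts: int = 1000,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Random disk inside the cell, 8-disconnected from every blocked pixel."""
    margin = cell_radius - spot_radius - 3
    for _ in range(max_attempts):
        radius = margin * np.sqrt(rng.random())
        angle = rng.random() * 2 * np.pi
        sc = (
            int(round(center[0] + radius * np.sin(angle))),
            int(round(center[1] + radius * np.cos(angle))),
        )
        rr_pad, cc_pad = draw_disk(sc, spot_radius + 2, shape=shape)
        if blocked[rr_pad, cc_pad].any():
            continue
        rr, cc = draw_disk(sc, spot_radius, shape=shape)
        return rr, cc, sc
    raise GenerationError(
        f"could not place a spot of radius {spot_radius} after {max_attempts} attempts"
    )


def gen_images(config: ImageSimConfig) -> tuple[ImageStack, SyntheticTruth]:
    """Generate a reporter image stack plus ground-truth masks and counts."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    gfp = np.full((h, w), BACKGROUND_LEVEL)
    mcherry = np.full((h, w), BACKGROUND_LEVEL)
    ld_chan = np.full((h, w), BACKGROUND_LEVEL)
    cell_labels = np.zeros((h, w), dtype=np.uint16)
    mito_mask = np.zeros((h, w), dtype=bool)
    ld_labels = np.zeros((h, w), dtype=np.uint16)

    true_puncta: dict[int, tuple] = {}
    true_counts: dict[int, int] = {}
    true_red_pct: dict[int, float] = {}
    true_overlap: dict[int, float] = {}
    true_m1: dict[int, float] = {}
    true_m2: dict[int, float] = {}
    ld_id = 0

    for cell_id, center in enumerate(_cell_centers(config), start=1):
        rr, cc = draw_disk(center, config.cell_radius, shape=(h, w))
        cell_labels[rr, cc] = cell_id
        gfp[rr, cc] = CYTO_LEVEL  # cytosolic reporter fills the whole cell
        cell_mask = np.zeros((h, w), dtype=bool)
        cell_mask[rr, cc] = True

        # mitochondrial network: dilated random chords through the interior
        net = np.zeros((h, w), dtype=bool)
        reach = 0.7 * config.cell_radius
        for _ in range(config.n_mito_branches):
            pts = []
            for _ in range(2):
                radius = reach * np.sqrt(rng.random())
                angle = rng.random() * 2 * np.pi
                pts.append(
                    (
                        int(round(center[0] + radius * np.sin(angle))),
                        int(round(center[1] + radius * np.cos(angle))),
                    )
                )
            lr, lc = draw_line(*pts[0], *pts[1])
            net[lr, lc] = True
        net = ndi.binary_dilation(net, ndi.generate_binary_structure(2, 2), iterations=2)
        net &= cell_mask
        gfp[net] = MITO_LEVEL
        mcherry[net] = MITO_LEVEL

        # red-only puncta: mCherry signal, GFP stays at background
        blocked = net.copy()
        n_puncta = int(rng.integers(*config.puncta_count_range, endpoint=True))
        puncta = []
        puncta_mask = np.zeros((h, w), dtype=bool)
        for _ in range(n_puncta):
            prr, pcc, pc = _place_spot(
                rng, center, config.cell_radius, config.puncta_radius, blocked, (h, w)
            )
            mcherry[prr, pcc] = PUNCTUM_LEVEL
            puncta_mask[prr, pcc] = True
            blocked[prr, pcc] = True
            puncta.append((pc, int(prr.size)))

        # lipid droplets, disjoint from mitochondria and puncta
        n_ld = int(rng.integers(*config.ld_count_range, endpoint=True))
        ld_pixels: list[tuple[np.ndarray, np.ndarray]] = []
        for _ in range(n_ld):
            lrr, lcc, _ = _place_spot(
                rng, center, config.cell_radius, config.ld_radius, blocked, (h, w)
            )
            ld_id += 1
            ld_chan[lrr, lcc] = LD_LEVEL
            ld_labels[lrr, lcc] = ld_id
            blocked[lrr, lcc] = True
            ld_pixels.append((lrr, lcc))

        # paint mitochondrial signal under exactly the configured fraction of
        # LD intensity (uniform spots: intensity fraction == pixel fraction)
        painted = np.zeros((h, w), dtype=bool)
        if ld_pixels:
            all_r = np.concatenate([p[0] for p in ld_pixels])
            all_c = np.concatenate([p[1] for p in ld_pixels])
            n_ld_px = all_r.size
            k = int(round(config.ld_mito_overlap_fraction * n_ld_px))
            if k:
                gfp[all_r[:k], all_c[:k]] = MITO_LEVEL
                mcherry[all_r[:k], all_c[:k]] = MITO_LEVEL
                painted[all_r[:k], all_c[:k]] = True
            true_overlap[cell_id] = k / n_ld_px

        cell_mito = net | puncta_mask | painted  # everything bright in mCherry
        mito_mask |= cell_mito
        punct_area = int(puncta_mask.sum())
        true_puncta[cell_id] = tuple(puncta)
        true_counts[cell_id] = n_puncta
        true_red_pct[cell_id] = 100.0 * punct_area / int(cell_mito.sum())
        if ld_pixels:
            ld_cell = ld_labels > 0
            ld_cell &= cell_mask
            true_m1[cell_id] = float(
                ld_chan[ld_cell & cell_mito].sum() / ld_chan[ld_cell].sum()
            )
            true_m2[cell_id] = float(
                mcherry[cell_mito & ld_cell].sum() / mcherry[cell_mito].sum()
            )

    if config.noise_sd > 0:
        gfp = np.clip(gfp + rng.normal(0, config.noise_sd, (h, w)), 0, None)
        mcherry = np.clip(mcherry + rng.normal(0, config.noise_sd, (h, w)), 0, None)
        ld_chan = np.clip(ld_chan + rng.normal(0, config.noise_sd, (h, w)), 0, None)

    stack = ImageStack(
        channels={"GFP": gfp, "mCherry": mcherry, "LD": ld_chan},
        cell_labels=cell_labels,
    )
    truth = SyntheticTruth(
        cell_labels=cell_labels.copy(),
        mito_mask=mito_mask,
        ld_labels=ld_labels,
        true_puncta=true_puncta,
        true_puncta_count=true_counts,
        true_red_only_area_pct=true_red_pct,
        true_overlap_intensity_fraction=true_overlap,
        true_m1=true_m1,
        true_m2=true_m2,
    )
    return stack, truth
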