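"""Readers and writers for the package's on-disk formats.

Corpus: JSONL, one object per document {entity_id, year, text}.
Training / exclusion lists: plain text, one item per line.
Plates: long-format CSV (plate, well, role, compound, cell_id, intensity).
Images: multi-channel TIFF (C, H, W) with channel names in the image
description; label masks as 16-bit TIFF.  Truth: JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError
from .image_quant import ImageStack
from .literature_ranking import (
    CANDIDATE,
    TRAINING,
    Document,
    EntityCorpus,
    SimilarityRanking,
)
from .ranking_validation import ValidationResult
from .screen_scoring import PLATE_COLUMNS, ScreenResult
from .synthetic_data import SyntheticTruth

__all__ = [
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "read_id_list",
    "write_ranking_tsv",
    "write_validation_json",
    "write_roc_csv",
    "read_plate_csv",
    "write_plate_csv",
    "write_image_tiff",
    "read_image_tiff",
    "write_labels_tiff",
    "write_truth_json",
]


def write_corpus_jsonl(corpus: EntityCorpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for eid, docs in corpus.entities.items():
            for d in docs:
                fh.write(json.dumps({"entity_id": eid, "year": d.year, "text": d.text}))
                fh.write("\n")


def read_corpus_jsonl(
    path: str | Path, training_ids: Sequence[str] = ()
) -> EntityCorpus:
    entities: dict[str, list[Document]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            entities.setdefault(rec["entity_id"], []).append(
                Document(year=int(rec["year"]), text=rec["text"])
            )
    training = set(training_ids)
    roles = {eid: TRAINING if eid in training else CANDIDATE for eid in entities}
    return EntityCorpus(entities, roles)


def read_id_list(path: str | Path) -> list[str]:
    """One item per line; blank lines and #-comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            item = line.strip()
            if item and not item.startswith("#"):
                out.append(item)
    return out


def write_ranking_tsv(ranking: SimilarityRanking, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tentity_id\tscore\n")
        for eid, score, rank in ranking.entries:
            fh.write(f"{rank}\t{eid}\t{score:.6f}\n")


def write_validation_json(result: ValidationResult, path: str | Path) -> None:
    payload = {
        "held_out": [
            {"entity_id": h.entity_id, "rank": h.rank, "n_neg": h.n_neg}
            for h in result.held_out
        ],
        "auc": result.auc,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_roc_csv(result: ValidationResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in result.roc_points:
            fh.write(f"{fpr:.10g},{tpr:.10g}\n")


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"plate CSV {path} missing columns: {missing}")
    return table


def write_plate_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_screen_csvs(result: ScreenResult, scores_path: str | Path, qc_path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": s.compound_id,
                "mean_clearance": float(np.mean(s.clearance_pct)),
                "normalized_value": s.normalized_value,
                "mad_z": s.mad_z,
                "rank": s.rank,
                "is_hit": s.is_hit,
            }
            for s in result.compound_scores
        ]
    ).to_csv(scores_path, index=False)
    pd.DataFrame(
        [
            {
                "plate_id": q.plate_id,
                "z_factor": q.z_factor,
                "mu_pos": q.mu_pos,
                "sigma_pos": q.sigma_pos,
                "mu_neg": q.mu_neg,
                "sigma_neg": q.sigma_neg,
            }
            for q in result.plate_qc
        ]
    ).to_csv(qc_path, index=False)


def write_image_tiff(stack: ImageStack, path: str | Path) -> None:
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate",
        description=json.dumps({"channels": names}),
    )


def read_image_tiff(path: str | Path, labels_path: str | Path | None = None) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        names = json.loads(desc).get("channels")
    except json.JSONDecodeError:
        names = None
    if data.ndim == 2:
        data = data[None]
    if not names or len(names) != data.shape[0]:
        names = [f"channel{i}" for i in range(data.shape[0])]
    labels = None
    if labels_path is not None:
        labels = tifffile.imread(labels_path).astype(np.int32)
    return ImageStack(
        channels={n: data[i].astype(float) for i, n in enumerate(names)},
        cell_labels=labels,
    )


def write_labels_tiff(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, labels.astype(np.uint16))


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    """Scalar/tabular ground truth as JSON (array masks go to TIFF instead)."""

    def _mapify(m, fmt_key=str):
        return {fmt_key(k): v for k, v in m.items()}

    payload = {
        "planted_enhancers": list(truth.planted_enhancers),
        "signal_terms": list(truth.signal_terms),
        "planted_effects": dict(truth.planted_effects),
        "true_cleared_fraction": {
            f"{p}/{w}": f for (p, w), f in truth.true_cleared_fraction.items()
        },
        "true_puncta_count": _mapify(truth.true_puncta_count),
        "true_red_only_area_pct": _mapify(truth.true_red_only_area_pct),
        "true_overlap_intensity_fraction": _mapify(truth.true_overlap_intensity_fraction),
        "true_m1": _mapify(truth.true_m1),
        "true_m2": _mapify(truth.true_m2),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
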