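"""Sensitivity-analysis biomarker ranking from the teacher model.

Feature importance combines variable sensitivity — the standard deviation
sigma_i of input feature i over all samples — with weight sensitivity —
that feature's aggregate connection weight into the network's first layer:

    importance_i = sigma_i * sum_j |W_ij|

When the classifier consumes the encoder's latent features rather than raw
inputs, latent importances are propagated back to raw features through the
encoder's first-layer weight magnitudes (a chain rule on absolute weights),
so the report always names raw omics features. Rankings are per omics
block; the top-k lists extracted on a fixed epoch schedule (every 400
epochs by default) are consolidated into one report with occurrence counts
and mean within-checkpoint ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceTable",
    "BiomarkerReport",
    "sensitivity_importance",
    "latent_importance_to_raw",
    "extract_top_k",
    "consolidate",
    "write_report_tsv",
]


@dataclass(frozen=True)
class ImportanceTable:
    """Per-omics importance scores at one training checkpoint."""

    scores: dict[str, pd.Series]  # omics name -> Series(feature_id -> score)
    epoch: int

    def __post_init__(self):
        for name, s in self.scores.items():
            if (s.values < 0).any() or not np.isfinite(s.values).all():
                raise ValueError(f"{name}: importance scores must be finite and >= 0")


@dataclass(frozen=True)
class BiomarkerReport:
    """Consolidated per-omics marker lists across checkpoints."""

    tables: dict[str, pd.DataFrame]  # omics -> (feature_id, occurrences, mean_rank, mean_importance)
    k: int
    checkpoint_epochs: tuple[int, ...]


def sensitivity_importance(
    X: np.ndarray,
    first_layer_weights: np.ndarray,
    feature_ids: list[str],
    block_widths: list[int],
    omics_names: list[str],
    epoch: int = 0,
    aggregation: str = "abs-sum",
) -> ImportanceTable:
    """Rank input features by sigma_i times aggregated first-layer weight.

    ``X`` holds the (preprocessed) input columns the classifier consumes;
    ``first_layer_weights`` is the teacher's first-layer matrix with one row
    per input column. ``block_widths`` maps columns back to omics blocks.
    """
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(first_layer_weights, dtype=np.float64)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns but the weight matrix has {W.shape[0]} rows"
        )
    if sum(block_widths) != X.shape[1]:
        raise ValueError("block widths do not sum to the column count")
    sigma = X.std(axis=0, ddof=0)
    if aggregation == "abs-sum":
        w_sens = np.abs(W).sum(axis=1)
    elif aggregation == "sq-sum":
        w_sens = (W**2).sum(axis=1)
    elif aggregation == "abs-max":
        w_sens = np.abs(W).max(axis=1)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    imp = sigma * w_sens

    scores: dict[str, pd.Series] = {}
    offset = 0
    for name, width in zip(omics_names, block_widths):
        ids = feature_ids[offset : offset + width]
        scores[name] = pd.Series(imp[offset : offset + width], index=ids, name="importance")
        offset += width
    return ImportanceTable(scores=scores, epoch=epoch)


def latent_importance_to_raw(
    latent_weight_rowsums: np.ndarray, encoder_first_layer: np.ndarray, X_raw: np.ndarray
) -> np.ndarray:
    """Chain latent importances back to raw features via |W_enc|.

    ``latent_weight_rowsums[k]`` is the aggregated classifier weight out of
    latent unit k; raw feature i receives
    sigma_i * sum_k |W_enc[i, k]| * latent_weight_rowsums[k].
    """
    sigma = np.asarray(X_raw, dtype=np.float64).std(axis=0, ddof=0)
    chained = np.abs(np.asarray(encoder_first_layer)) @ np.asarray(latent_weight_rowsums)
    return sigma * chained


def extract_top_k(table: ImportanceTable, k: int = 30) -> dict[str, list[str]]:
    """Per-omics top-k feature ids; ties broken by original feature order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[str]] = {}
    for name, s in table.scores.items():
        kk = min(k, len(s))
        # stable sort on descending score keeps original order among ties
        order = np.argsort(-s.values, kind="stable")[:kk]
        out[name] = [s.index[i] for i in order]
    return out


def consolidate(
    checkpoints: list[tuple[int, ImportanceTable, dict[str, list[str]]]],
    k: int = 30,
) -> BiomarkerReport:
    """Union of per-checkpoint top-k lists with occurrence counts.

    ``checkpoints`` holds (epoch, importance table, top-k lists). Features
    are sorted by occurrence count (descending) then mean within-checkpoint
    rank (ascending, 1-based).
    """
    if not checkpoints:
        raise ValueError("need at least one checkpoint")
    omics_names = list(checkpoints[0][1].scores.keys())
    tables: dict[str, pd.DataFrame] = {}
    for name in omics_names:
        rows: dict[str, dict] = {}
        for epoch, table, top in checkpoints:
            for rank, fid in enumerate(top[name], start=1):
                entry = rows.setdefault(fid, {"occurrences": 0, "ranks": [], "importances": []})
                entry["occurrences"] += 1
                entry["ranks"].append(rank)
                entry["importances"].append(float(table.scores[name][fid]))
        df = pd.DataFrame(
            {
                "feature_id": list(rows),
                "occurrences": [r["occurrences"] for r in rows.values()],
                "mean_rank": [float(np.mean(r["ranks"])) for r in rows.values()],
                "mean_importance": [float(np.mean(r["importances"])) for r in rows.values()],
            }
        )
        df = df.sort_values(
            ["occurrences", "mean_rank", "feature_id"],
            ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
        tables[name] = df
    return BiomarkerReport(
        tables=tables, k=k, checkpoint_epochs=tuple(e for e, _, _ in checkpoints)
    )


def write_report_tsv(report: BiomarkerReport, path: str | Path) -> None:
    """Write the consolidated report as one TSV over all omics blocks."""
    frames = []
    for name, df in report.tables.items():
        df = df.copy()
        df.insert(0, "omics", name)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
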