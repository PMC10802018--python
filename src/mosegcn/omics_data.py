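"""Loading, alignment and preprocessing of per-omics matrices.

A multi-omics study ships one numeric matrix per molecular layer (mRNA
expression, DNA methylation, microRNA expression, ...) over a shared set of
patients, plus a label file covering only some of those patients. This
module turns those files into an aligned :class:`MultiOmicsDataset` and
applies the standard preprocessing chain: restrict to common samples, drop
zero-signal (zero-mean and constant) features, keep the top-variance
fraction per omics, and min-max scale each feature to [0, 1].

Scaling statistics are computed over *all* samples once, before any
train/test split: the downstream graph classifier is transductive (every
node participates in training), so this mirrors how the model is actually
deployed, at the cost of a known information-leakage trade-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "LabelSet",
    "MultiOmicsDataset",
    "UNLABELED",
    "read_omics_csv",
    "read_labels_csv",
    "align_samples",
    "drop_zero_signal",
    "variance_filter",
    "minmax_scale",
    "concat_features",
    "preprocess",
    "save_dataset",
    "load_dataset",
]

#: Sentinel class code for samples without a label.
UNLABELED = -1


@dataclass(frozen=True)
class OmicsMatrix:
    """One omics block: samples x features with identifiers."""

    name: str
    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if values.ndim != 2:
            raise ValueError(f"{self.name}: values must be 2-D")
        if values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"{self.name}: shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for kind, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if list(ids).count(i) > 1})
                raise ValueError(f"{self.name}: duplicate {kind} ids {dupes[:5]}")
        if np.isnan(values).any():
            raise ValueError(f"{self.name}: missing values present (NaN)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class LabelSet:
    """Partial labels: class codes in [0, C) or UNLABELED per sample."""

    sample_ids: tuple[str, ...]
    y: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        y = np.asarray(self.y, dtype=np.int64)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "class_names", tuple(self.class_names))
        if y.shape != (len(self.sample_ids),):
            raise ValueError("y must be one code per sample id")
        C = len(self.class_names)
        bad = (y != UNLABELED) & ((y < 0) | (y >= C))
        if bad.any():
            raise ValueError(f"label codes out of range [0, {C}): {np.unique(y[bad])}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.y != UNLABELED

    @property
    def unlabeled_mask(self) -> np.ndarray:
        return self.y == UNLABELED


@dataclass(frozen=True)
class MultiOmicsDataset:
    """Aligned omics blocks plus partial labels over one sample order."""

    omics: tuple[OmicsMatrix, ...]
    labels: LabelSet

    def __post_init__(self):
        object.__setattr__(self, "omics", tuple(self.omics))
        if not self.omics:
            raise ValueError("dataset needs at least one omics block")
        ref = self.omics[0].sample_ids
        for block in self.omics[1:]:
            if block.sample_ids != ref:
                raise ValueError(
                    f"omics block '{block.name}' sample order differs from "
                    f"'{self.omics[0].name}' — call align_samples first"
                )
        if self.labels.sample_ids != ref:
            raise ValueError("labels are not aligned to the omics sample order")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.omics[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def block_widths(self) -> tuple[int, ...]:
        return tuple(b.n_features for b in self.omics)


# --------------------------------------------------------------------- I/O
def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_omics_csv(
    path: str | Path,
    orientation: str = "rows-are-samples",
    name: str | None = None,
    delimiter: str | None = None,
) -> OmicsMatrix:
    """Read one omics matrix from CSV/TSV into samples x features form.

    Parameters
    ----------
    path:
        CSV (comma) or TSV/TXT (tab) file; first column and first row hold
        identifiers.
    orientation:
        ``"rows-are-samples"`` or ``"rows-are-features"``; the returned
        matrix is always samples x features.
    """
    if orientation not in {"rows-are-samples", "rows-are-features"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, delimiter)
    if orientation == "rows-are-features":
        df = df.T
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        bad = df.apply(pd.to_numeric, errors="coerce")
        rows, cols = np.where(bad.isna() & df.notna())
        loc = ""
        if len(rows):
            loc = f" at row {df.index[rows[0]]!r}, column {df.columns[cols[0]]!r}"
        raise ValueError(f"non-numeric cell in {path}{loc}") from exc
    return OmicsMatrix(
        name=name or Path(path).stem,
        values=values,
        sample_ids=tuple(map(str, df.index)),
        feature_ids=tuple(map(str, df.columns)),
    )


def read_labels_csv(path: str | Path, delimiter: str | None = None) -> LabelSet:
    """Read a two-column (sample_id, label) file; class codes follow sorted names."""
    df = _read_table(path, delimiter)
    if df.shape[1] != 1:
        raise ValueError(f"label file must have exactly two columns, got {df.shape[1] + 1}")
    raw = df.iloc[:, 0].astype(str)
    class_names = tuple(sorted(raw.unique()))
    code = {c: i for i, c in enumerate(class_names)}
    return LabelSet(
        sample_ids=tuple(map(str, df.index)),
        y=np.array([code[v] for v in raw], dtype=np.int64),
        class_names=class_names,
    )


# ----------------------------------------------------------------- alignment
def align_samples(omics: list[OmicsMatrix], labels: LabelSet) -> MultiOmicsDataset:
    """Restrict all blocks to their common samples, in sorted id order.

    Samples present in every omics block but absent from the label file are
    retained as unlabeled; this is what makes the semi-supervised setting
    non-trivial.
    """
    if len(omics) < 2:
        raise ValueError("align_samples needs at least two omics blocks")
    return _align(omics, labels)


def _align(omics: list[OmicsMatrix], labels: LabelSet) -> MultiOmicsDataset:
    common: set[str] = set(omics[0].sample_ids)
    for block in omics[1:]:
        common &= set(block.sample_ids)
    if not common:
        raise ValueError("no samples are shared across all omics blocks")
    order = tuple(sorted(common))

    aligned = []
    for block in omics:
        pos = {s: i for i, s in enumerate(block.sample_ids)}
        idx = np.array([pos[s] for s in order])
        aligned.append(replace(block, values=block.values[idx], sample_ids=order))

    label_pos = {s: i for i, s in enumerate(labels.sample_ids)}
    y = np.full(len(order), UNLABELED, dtype=np.int64)
    for i, s in enumerate(order):
        if s in label_pos:
            y[i] = labels.y[label_pos[s]]
    new_labels = LabelSet(sample_ids=order, y=y, class_names=labels.class_names)
    return MultiOmicsDataset(omics=tuple(aligned), labels=new_labels)


# ------------------------------------------------------------- preprocessing
_ZERO_TOL = 1e-12


def drop_zero_signal(m: OmicsMatrix) -> OmicsMatrix:
    """Remove zero-mean (signal-free) and zero-variance (constant) features.

    Constant features are removed alongside so that min-max scaling never
    divides by zero. Idempotent.
    """
    mean = m.values.mean(axis=0)
    var = m.values.var(axis=0)
    keep = (np.abs(mean) > _ZERO_TOL) & (var > _ZERO_TOL)
    if not keep.any():
        raise ValueError(f"{m.name}: every feature is zero-mean or constant")
    return replace(
        m,
        values=m.values[:, keep],
        feature_ids=tuple(f for f, k in zip(m.feature_ids, keep) if k),
    )


def variance_filter(m: OmicsMatrix, keep_fraction: float = 0.25) -> OmicsMatrix:
    """Keep the ceil(keep_fraction * p) highest-variance features.

    Ties at the cut are broken by original column order (earlier wins);
    surviving features keep their original relative order.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if keep_fraction == 1.0:
        return m
    k = int(np.ceil(keep_fraction * m.n_features))
    var = m.values.var(axis=0)
    # stable sort on -var keeps earlier columns first among ties
    order = np.argsort(-var, kind="stable")[:k]
    keep = np.zeros(m.n_features, dtype=bool)
    keep[order] = True
    return replace(
        m,
        values=m.values[:, keep],
        feature_ids=tuple(f for f, kf in zip(m.feature_ids, keep) if kf),
    )


def minmax_scale(m: OmicsMatrix) -> OmicsMatrix:
    """Affinely map each feature to [0, 1] over all samples."""
    lo = m.values.min(axis=0)
    hi = m.values.max(axis=0)
    span = hi - lo
    if (span <= _ZERO_TOL).any():
        bad = [f for f, s in zip(m.feature_ids, span) if s <= _ZERO_TOL]
        raise ValueError(
            f"{m.name}: constant feature(s) {bad[:5]} cannot be min-max scaled; "
            "run drop_zero_signal first"
        )
    return replace(m, values=(m.values - lo) / span)


def concat_features(d: MultiOmicsDataset) -> tuple[np.ndarray, tuple[int, ...]]:
    """Horizontally concatenate blocks; returns (X, block widths)."""
    X = np.concatenate([b.values for b in d.omics], axis=1)
    return X, d.block_widths


def preprocess(
    omics: list[OmicsMatrix],
    labels: LabelSet,
    keep_fraction: float | dict[str, float] = 0.25,
) -> MultiOmicsDataset:
    """Full chain: align -> drop zero signal -> variance filter -> min-max.

    ``keep_fraction`` may be a single fraction or a per-omics-name mapping;
    a value of 1.0 means no variance selection for that block (the usual
    choice for small microRNA panels or inputs already feature-selected
    upstream). Accepts a single block as well (used by single-omics
    ablations), in which case alignment is the trivial intersection with
    the label file.
    """
    d = _align(omics, labels)
    out = []
    for block in d.omics:
        frac = keep_fraction.get(block.name, 1.0) if isinstance(keep_fraction, dict) else keep_fraction
        block = drop_zero_signal(block)
        block = variance_filter(block, frac)
        block = minmax_scale(block)
        out.append(block)
    return MultiOmicsDataset(omics=tuple(out), labels=d.labels)


# ------------------------------------------------------------- serialization
def save_dataset(d: MultiOmicsDataset, directory: str | Path) -> None:
    """Write the dataset as one CSV per block + labels.csv + manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for block in d.omics:
        pd.DataFrame(
            block.values, index=list(block.sample_ids), columns=list(block.feature_ids)
        ).to_csv(directory / f"{block.name}.csv")
    labeled = d.labels.labeled_mask
    pd.DataFrame(
        {"label": [d.labels.class_names[c] for c in d.labels.y[labeled]]},
        index=[s for s, m in zip(d.sample_ids, labeled) if m],
    ).rename_axis("sample_id").to_csv(directory / "labels.csv")
    manifest = {
        "omics": [b.name for b in d.omics],
        "block_widths": list(d.block_widths),
        "class_names": list(d.labels.class_names),
        "n_samples": d.n_samples,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(directory: str | Path) -> MultiOmicsDataset:
    """Inverse of :func:`save_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    omics = [read_omics_csv(directory / f"{name}.csv", name=name) for name in manifest["omics"]]
    labels_df = pd.read_csv(directory / "labels.csv", index_col=0)
    class_names = tuple(manifest["class_names"])
    code = {c: i for i, c in enumerate(class_names)}
    labels = LabelSet(
        sample_ids=tuple(map(str, labels_df.index)),
        y=np.array([code[v] for v in labels_df.iloc[:, 0]], dtype=np.int64),
        class_names=class_names,
    )
    return align_samples(omics, labels)
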