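"""Synthetic data generation: the package's test and demo conditions.

The generator emulates the kind of input a prioritization exercise sees:
entities (chemicals) measured on positive, right-skewed assay metrics
(log-normal draws), with a configurable fraction of missing cells (the
literal ``NA`` token) and of negative cells (which importers must convert
to missing).  One underlying dataset can be written in all four CSV
dialects so that representation equivalence is testable.

Named fixtures:

``uvcb_model``
    A complete-dialect file with the structure of a published petroleum
    UVCB prioritization model: 25 entities and four equally-weighted slices
    of 8 cardiophysiology (yellow), 3 cardiotoxicity (blue), 5
    hepatotoxicity (dark gray), and 2 physico-chemical (red) metrics.
``blobs``
    Well-separated Gaussian clusters in slice-score space for cluster
    recovery tests.

Example dataset sizes of 50, 300, and 1000 entities mirror the small /
medium / large demonstration files distributed with the original tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import DataTable
from .data_io import write_model_file
from .model import SliceDef, ToxPiModel, build_model

__all__ = [
    "SyntheticData",
    "generate_dataset",
    "default_model",
    "uvcb_model_fixture",
    "blobs",
    "generate_fixture",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = (
    "matrix",
    "row_annotated",
    "column_annotated",
    "complete",
    "uvcb_model",
    "blobs",
)

_CLASS_POOL = ("ClassA", "ClassB", "ClassC")

_UVCB_SLICES = (
    ("Cardiophysiology", 8, "#FFD700"),  # yellow
    ("Cardiotox", 3, "#1F77B4"),  # blue
    ("Hepatotox", 5, "#404040"),  # dark gray
    ("PhysChem", 2, "#D62728"),  # red
)


@dataclass
class SyntheticData:
    """One generated dataset plus the token matrix its files are written from."""

    entity_ids: list[str]
    entity_class: list[str]
    metric_ids: list[str]
    values: np.ndarray  # positive log-normal draws
    na_mask: np.ndarray  # cells written as the literal token NA
    neg_mask: np.ndarray  # cells written with a negated (negative) value

    def cell_token(self, i: int, j: int) -> str:
        if self.na_mask[i, j]:
            return "NA"
        v = self.values[i, j]
        if self.neg_mask[i, j]:
            v = -v
        return repr(float(v))

    def to_table(self) -> DataTable:
        """The DataTable a correct importer must produce from these files."""
        mask = self.na_mask | self.neg_mask
        return DataTable(
            entity_ids=list(self.entity_ids),
            metric_ids=list(self.metric_ids),
            values=np.where(mask, np.nan, self.values),
            missing_mask=mask,
            entity_class=list(self.entity_class),
        )


def generate_dataset(
    n_entities: int = 50,
    n_metrics: int = 12,
    missing_frac: float = 0.05,
    negative_frac: float = 0.02,
    seed: int = 0,
    id_prefix: str = "chem",
) -> SyntheticData:
    """Log-normal assay-like matrix with seeded NA and negative cells."""
    for name, frac in (("missing_frac", missing_frac), ("negative_frac", negative_frac)):
        if not (0.0 <= frac < 1.0):
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=0.0, sigma=1.0, size=(n_entities, n_metrics))
    u = rng.random((n_entities, n_metrics))
    na_mask = u < missing_frac
    neg_mask = (u >= missing_frac) & (u < missing_frac + negative_frac)
    width = max(2, len(str(n_entities)))
    ids = [f"{id_prefix}-{i + 1:0{width}d}" for i in range(n_entities)]
    classes = [
        _CLASS_POOL[c] for c in rng.integers(0, len(_CLASS_POOL), size=n_entities)
    ]
    metrics = [f"metric{j + 1:02d}" for j in range(n_metrics)]
    return SyntheticData(ids, classes, metrics, values, na_mask, neg_mask)


def default_model(table: DataTable, n_slices: int = 4) -> ToxPiModel:
    """Equal-weight model partitioning the metrics into contiguous slices."""
    from .hier_cluster import PALETTE

    n_slices = min(n_slices, table.n_metrics)
    bounds = np.linspace(0, table.n_metrics, n_slices + 1).astype(int)
    slices = tuple(
        SliceDef(
            name=f"slice{i + 1}",
            metric_ids=tuple(table.metric_ids[bounds[i] : bounds[i + 1]]),
            weight=1.0,
            color=PALETTE[i % len(PALETTE)],
            transform="linear",
        )
        for i in range(n_slices)
    )
    model = ToxPiModel(slices)
    model.validate_against(table)
    return model


# -- dialect writers -------------------------------------------------------


def _write(path, lines) -> None:
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_matrix_csv(data: SyntheticData, path) -> None:
    lines = ["id," + ",".join(data.metric_ids)]
    for i, e in enumerate(data.entity_ids):
        lines.append(
            e + "," + ",".join(data.cell_token(i, j) for j in range(len(data.metric_ids)))
        )
    _write(path, lines)


def write_row_annotated_csv(data: SyntheticData, path) -> None:
    lines = ["id,class," + ",".join(data.metric_ids)]
    for i, e in enumerate(data.entity_ids):
        lines.append(
            f"{e},{data.entity_class[i]},"
            + ",".join(data.cell_token(i, j) for j in range(len(data.metric_ids)))
        )
    _write(path, lines)


def write_column_annotated_csv(data: SyntheticData, path, model: ToxPiModel) -> None:
    slice_of = {}
    weight_of = {}
    color_of = {}
    transform_of = {}
    for s in model.slices:
        for m in s.metric_ids:
            slice_of[m] = s.name
            weight_of[m] = repr(float(s.weight))
            color_of[m] = s.color
            transform_of[m] = s.transform
    lines = [
        "slice," + ",".join(slice_of.get(m, "") for m in data.metric_ids),
        "weight," + ",".join(weight_of.get(m, "") for m in data.metric_ids),
        "color," + ",".join(color_of.get(m, "") for m in data.metric_ids),
        "transform," + ",".join(transform_of.get(m, "") for m in data.metric_ids),
        "id,class," + ",".join(data.metric_ids),
    ]
    for i, e in enumerate(data.entity_ids):
        lines.append(
            f"{e},{data.entity_class[i]},"
            + ",".join(data.cell_token(i, j) for j in range(len(data.metric_ids)))
        )
    _write(path, lines)


def write_complete_csv(data: SyntheticData, path, model: ToxPiModel) -> None:
    # the complete dialect never carries raw negatives: they were dropped
    # when the table was built, so this file shares only the NA pattern
    write_model_file(data.to_table(), model, path)


def uvcb_model_fixture(path=None, n_entities: int = 25, seed: int = 0):
    """Synthetic stand-in with the published UVCB model's slice structure.

    Four equally-weighted slices of 8/3/5/2 metrics over a generated
    25-entity table; written as a complete-dialect file when ``path`` given.
    """
    n_metrics = sum(k for _, k, _ in _UVCB_SLICES)
    data = generate_dataset(
        n_entities=n_entities,
        n_metrics=n_metrics,
        missing_frac=0.05,
        negative_frac=0.0,
        seed=seed,
        id_prefix="UVCB",
    )
    metrics = []
    specs = []
    j = 0
    for name, count, color in _UVCB_SLICES:
        ms = tuple(f"{name}_{k + 1}" for k in range(count))
        metrics.extend(ms)
        specs.append(SliceDef(name=name, metric_ids=ms, weight=1.0, color=color))
        j += count
    data.metric_ids = metrics
    table = data.to_table()
    model = build_model(specs, table)
    if path is not None:
        write_model_file(table, model, path)
    return table, model


def blobs(
    n_per_cluster: int = 20,
    n_clusters: int = 3,
    n_features: int = 4,
    separation: float = 1.0,
    sigma: float = 0.01,
    seed: int = 0,
):
    """Separable Gaussian clusters in feature space, for recovery tests.

    Cluster centers sit at least ``separation`` apart (axis-aligned simplex
    corners scaled by ``separation``); points get isotropic N(0, sigma²)
    noise.  Returns (X, labels) with labels in 1..n_clusters.
    """
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_clusters, n_features))
    for c in range(n_clusters):
        centers[c, c % n_features] = separation * (1 + c // n_features)
    X = np.vstack(
        [
            centers[c] + rng.normal(0.0, sigma, size=(n_per_cluster, n_features))
            for c in range(n_clusters)
        ]
    )
    labels = np.repeat(np.arange(1, n_clusters + 1), n_per_cluster)
    return X, labels


def generate_fixture(
    kind: str,
    path,
    n_entities: int = 50,
    n_metrics: int = 12,
    missing_frac: float = 0.05,
    negative_frac: float = 0.02,
    seed: int = 0,
) -> None:
    """Write one reproducible fixture file of the requested kind."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if kind == "uvcb_model":
        uvcb_model_fixture(path=path, seed=seed)
        return
    if kind == "blobs":
        X, labels = blobs(n_per_cluster=max(n_entities // 3, 2), seed=seed)
        lines = ["id,label," + ",".join(f"f{j + 1}" for j in range(X.shape[1]))]
        for i in range(X.shape[0]):
            lines.append(
                f"blob-{i + 1:03d},{labels[i]},"
                + ",".join(repr(float(v)) for v in X[i])
            )
        _write(path, lines)
        return
    data = generate_dataset(
        n_entities=n_entities,
        n_metrics=n_metrics,
        missing_frac=missing_frac,
        negative_frac=negative_frac,
        seed=seed,
    )
    if kind == "matrix":
        write_matrix_csv(data, path)
    elif kind == "row_annotated":
        write_row_annotated_csv(data, path)
    else:
        model = default_model(data.to_table())
        if kind == "column_annotated":
            write_column_annotated_csv(data, path, model)
        else:
            write_complete_csv(data, path, model)
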