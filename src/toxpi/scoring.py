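"""Slice scores, missingness, unit-interval overall scores, and ranks.

For entity j and slice i with weight w_i:

* each metric in the slice is transformed by the slice's transform,
* the raw slice value r_ij is the mean of the transformed non-missing
  components (0 with missingness 1 if every component is missing),
* slice scores are rescaled by the column maximum, s_ij = r_ij / max_j r_ij
  (all zero if the column is identically zero), so each slice column attains
  1 somewhere unless empty of signal,
* the overall score is the weight-normalised average
  ``overall_j = sum_i (w_i / sum_k w_k) * s_ij``, which lies in [0, 1] and is
  comparable across models,
* rank 1 is the highest overall score; exact ties break by ascending
  entity id so the ordering is total and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataError, DataTable
from .model import SliceDef, ToxPiModel, apply_transform

__all__ = [
    "ScoreResult",
    "transformed_components",
    "raw_slice_values",
    "scale_slice",
    "overall_scores",
    "rank_entities",
    "score",
    "sort_results",
]


@dataclass
class ScoreResult:
    entity_ids: list[str]
    slice_names: list[str]
    slice_scores: np.ndarray  # (n, S) in [0, 1]
    missingness: np.ndarray  # (n, S) fraction in [0, 1]
    overall: np.ndarray  # (n,) in [0, 1]
    rank: np.ndarray  # (n,) ints, 1 = highest overall
    entity_class: list[str] | None = None
    weights: np.ndarray = field(default=None)

    def row(self, entity_id: str) -> int:
        try:
            return self.entity_ids.index(entity_id)
        except ValueError:
            raise DataError(f"entity not scored: {entity_id!r}") from None


def transformed_components(table: DataTable, slice_def: SliceDef) -> np.ndarray:
    """(n_entities, n_components) transformed values, NaN where missing."""
    cols = [table.metric_index(m) for m in slice_def.metric_ids]
    out = np.empty((table.n_entities, len(cols)))
    for k, j in enumerate(cols):
        x = table.values[:, j]
        present = ~table.missing_mask[:, j]
        max_m = float(x[present].max()) if present.any() else 0.0
        t = np.full_like(x, np.nan)
        t[present] = apply_transform(slice_def.transform, x[present], max_m)
        out[:, k] = t
    return out


def raw_slice_values(
    table: DataTable, slice_def: SliceDef
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of transformed non-missing components, plus missingness fraction.

    An entity with every component missing gets raw value 0 (missingness 1);
    its absence of evidence is carried by the missingness channel, not the
    score.
    """
    comp = transformed_components(table, slice_def)
    miss = np.isnan(comp)
    n_present = (~miss).sum(axis=1)
    total = np.nansum(comp, axis=1)
    raw = np.where(n_present > 0, total / np.maximum(n_present, 1), 0.0)
    missingness = miss.sum(axis=1) / comp.shape[1]
    return raw, missingness


def scale_slice(raw: np.ndarray) -> np.ndarray:
    """Divide by the column maximum; identically-zero columns stay zero."""
    raw = np.asarray(raw, dtype=float)
    m = raw.max() if raw.size else 0.0
    if m <= 0:
        return np.zeros_like(raw)
    return raw / m


def overall_scores(slice_scores: np.ndarray, model: ToxPiModel) -> np.ndarray:
    w = model.weights
    return slice_scores @ (w / w.sum())


def rank_entities(overall: np.ndarray, entity_ids: list[str]) -> np.ndarray:
    """Descending-score ranks, ties broken by ascending entity id."""
    id_order = np.argsort(np.argsort(entity_ids, kind="stable"), kind="stable")
    order = np.lexsort((id_order, -np.asarray(overall)))
    rank = np.empty(len(entity_ids), dtype=int)
    rank[order] = np.arange(1, len(entity_ids) + 1)
    return rank


def score(table: DataTable, model: ToxPiModel) -> ScoreResult:
    """Full scoring pipeline for one table under one model."""
    model.validate_against(table, allow_shared_metrics=True)
    n, S = table.n_entities, len(model.slices)
    slice_scores = np.empty((n, S))
    missingness = np.empty((n, S))
    for i, s in enumerate(model.slices):
        raw, miss = raw_slice_values(table, s)
        slice_scores[:, i] = scale_slice(raw)
        missingness[:, i] = miss
    overall = overall_scores(slice_scores, model)
    rank = rank_entities(overall, table.entity_ids)
    return ScoreResult(
        entity_ids=list(table.entity_ids),
        slice_names=model.slice_names,
        slice_scores=slice_scores,
        missingness=missingness,
        overall=overall,
        rank=rank,
        entity_class=None if table.entity_class is None else list(table.entity_class),
        weights=model.weights,
    )


def sort_results(
    scores: ScoreResult,
    keys,
    directions=None,
    clusters=None,
) -> list[str]:
    """Stable lexicographic multi-key sort; returns the entity-id ordering.

    Keys come from {name, class, overall, cluster, <slice name>}; directions
    is a matching list of 'asc'/'desc' (default ascending, except 'overall'
    which defaults to descending, matching rank order).
    """
    keys = list(keys)
    if not keys:
        return list(scores.entity_ids)
    frame = {"name": scores.entity_ids, "overall": scores.overall}
    frame["class"] = scores.entity_class or [""] * len(scores.entity_ids)
    if clusters is not None:
        frame["cluster"] = np.asarray(clusters.labels)
    for j, s in enumerate(scores.slice_names):
        frame[s] = scores.slice_scores[:, j]
    df = pd.DataFrame(frame, index=scores.entity_ids)
    for k in keys:
        if k not in df.columns:
            raise DataError(f"unknown sort key: {k!r}")
    if directions is None:
        directions = ["desc" if k == "overall" else "asc" for k in keys]
    ascending = [d == "asc" for d in directions]
    df = df.sort_values(list(keys), ascending=ascending, kind="stable")
    return list(df.index)
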