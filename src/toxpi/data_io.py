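"""Flat-CSV import/export in four dialects, plus result tables.

Dialects
--------
``matrix``
    Header row of metric names (first cell is a corner label, typically
    empty or ``id``); each data row is ``<entity>,<v1>,...``.
``row_annotated``
    As ``matrix`` but with a second header cell ``class`` and a per-entity
    class/source column.
``column_annotated``
    Extra header rows *above* the metric header carry per-metric
    annotations; each starts with a reserved tag in
    {``slice``, ``weight``, ``color``, ``transform``}.  Annotations are
    validated and reported, but a full model is only reconstructed from the
    ``complete`` dialect.
``complete``
    The round-trippable file this package writes: ``#``-prefixed metadata
    lines describing every slice, then an ``id,class,<metrics...>`` matrix.

Missing cells are the literal, case-sensitive token ``NA``.  Strictly
negative values are converted to missing on import (zero is retained).
"""

from __future__ import annotations

import csv
import io
import math
import re
from pathlib import Path

import numpy as np

from .data import DataError, DataTable, ImportReport
from .model import SliceDef, ToxPiModel

__all__ = [
    "read_table",
    "merge_tables",
    "write_model_file",
    "write_results_csv",
    "DIALECTS",
]

DIALECTS = ("matrix", "row_annotated", "column_annotated", "complete")

_ANNOTATION_TAGS = ("slice", "weight", "color", "transform")
_SLICE_LINE = re.compile(
    r"^#\s*slice:\s*(?P<name>.*?),\s*weight=(?P<weight>\S+),\s*"
    r"color=(?P<color>#[0-9A-Fa-f]{6}),\s*scale=(?P<scale>\S+)\s*$"
)
_METRICS_LINE = re.compile(r"^#\s*metrics:\s*(?P<metrics>.*)$")

_MISSING_TOKEN = "NA"


def _parse_cell(token: str, row: int, col: str) -> tuple[float, bool, bool]:
    """Return (value, is_missing, was_negative) for one matrix cell."""
    if token == _MISSING_TOKEN:
        return math.nan, True, False
    try:
        v = float(token)
    except ValueError:
        raise DataError(
            f"non-numeric cell {token!r} at row {row}, column {col!r} "
            f"(only the token 'NA' marks missing data)"
        ) from None
    if math.isnan(v):
        raise DataError(f"non-numeric cell {token!r} at row {row}, column {col!r}")
    if v < 0:
        return math.nan, True, True
    return v, False, False


def detect_dialect(lines: list[list[str]], raw_lines: list[str]) -> str:
    if raw_lines and raw_lines[0].startswith("#"):
        return "complete"
    first = lines[0]
    if first and first[0].strip().lower() in _ANNOTATION_TAGS:
        return "column_annotated"
    if len(first) >= 2 and first[1].strip().lower() == "class":
        return "row_annotated"
    return "matrix"


def read_table(path, dialect: str = "auto"):
    """Read one CSV file.

    Returns
    -------
    (DataTable, ToxPiModel or None, ImportReport)
        The model is reconstructed only for the ``complete`` dialect.
    """
    path = Path(path)
    raw_lines = path.read_text(encoding="utf-8").splitlines()
    raw_lines = [ln for ln in raw_lines if ln.strip() != ""]
    if not raw_lines:
        raise DataError(f"{path}: empty file")
    body = [ln for ln in raw_lines if not ln.startswith("#")]
    rows = list(csv.reader(io.StringIO("\n".join(body))))
    if dialect == "auto":
        dialect = detect_dialect(rows, raw_lines)
    if dialect not in DIALECTS:
        raise DataError(f"unknown dialect: {dialect!r}")

    model = None
    annotations: dict[str, list[str]] = {}
    if dialect == "complete":
        model_meta = _parse_model_header(raw_lines, path)
    elif dialect == "column_annotated":
        while rows and rows[0] and rows[0][0].strip().lower() in _ANNOTATION_TAGS:
            tag = rows[0][0].strip().lower()
            annotations[tag] = [c.strip() for c in rows[0][1:]]
            rows = rows[1:]
        if not annotations:
            raise DataError(f"{path}: column_annotated file has no annotation rows")

    if not rows:
        raise DataError(f"{path}: no matrix content")
    header = [c.strip() for c in rows[0]]
    has_class = dialect in ("row_annotated", "complete") or (
        dialect == "column_annotated"
        and len(header) >= 2
        and header[1].lower() == "class"
    )
    n_lead = 2 if has_class else 1
    metric_ids = header[n_lead:]
    if not metric_ids:
        raise DataError(f"{path}: no metric columns")
    _check_unique(metric_ids, "metric", path)

    for tag, ann in annotations.items():
        if len(ann) != len(metric_ids):
            raise DataError(
                f"{path}: annotation row {tag!r} has {len(ann)} entries for "
                f"{len(metric_ids)} metrics"
            )

    entity_ids: list[str] = []
    entity_class: list[str] = []
    values = np.full((len(rows) - 1, len(metric_ids)), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    n_na = n_neg = 0
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n_lead + len(metric_ids):
            raise DataError(
                f"{path}: ragged row {r}: {len(row)} fields, expected "
                f"{n_lead + len(metric_ids)}"
            )
        entity_ids.append(row[0].strip())
        entity_class.append(row[1].strip() if has_class else "")
        for j, tok in enumerate(row[n_lead:]):
            v, miss, neg = _parse_cell(tok.strip(), r, metric_ids[j])
            values[r - 2, j] = v
            mask[r - 2, j] = miss
            n_na += miss and not neg
            n_neg += neg
    _check_unique(entity_ids, "entity", path)

    classes = entity_class if any(entity_class) else None
    table = DataTable(entity_ids, metric_ids, values, mask, classes)
    if dialect == "complete":
        model = _build_model_from_meta(model_meta, table, path)
    report = ImportReport(
        n_entities=table.n_entities,
        n_metrics=table.n_metrics,
        n_missing_na=int(n_na),
        n_negative_dropped=int(n_neg),
        dialect=dialect,
        annotations=annotations,
    )
    report.validate_against(table)
    return table, model, report


def _check_unique(ids: list[str], kind: str, path) -> None:
    seen: set[str] = set()
    dupes = sorted({i for i in ids if i in seen or seen.add(i)})
    if dupes:
        raise DataError(f"{path}: duplicate {kind} names: {dupes}")


def _parse_model_header(raw_lines: list[str], path) -> list[dict]:
    meta: list[dict] = []
    pending: dict | None = None
    for ln in raw_lines:
        if not ln.startswith("#"):
            continue
        m = _SLICE_LINE.match(ln)
        if m:
            if pending is not None:
                raise DataError(f"{path}: slice {pending['name']!r} has no metrics line")
            pending = {
                "name": m["name"],
                "weight": float(m["weight"]),
                "color": m["color"],
                "transform": m["scale"],
            }
            continue
        m = _METRICS_LINE.match(ln)
        if m:
            if pending is None:
                raise DataError(f"{path}: metrics line without preceding slice line")
            pending["metrics"] = m["metrics"].split("|")
            meta.append(pending)
            pending = None
            continue
        raise DataError(f"{path}: unrecognized metadata line: {ln!r}")
    if pending is not None:
        raise DataError(f"{path}: slice {pending['name']!r} has no metrics line")
    if not meta:
        raise DataError(f"{path}: complete dialect requires slice metadata lines")
    return meta


def _build_model_from_meta(meta: list[dict], table: DataTable, path) -> ToxPiModel:
    slices = tuple(
        SliceDef(
            name=s["name"],
            metric_ids=tuple(s["metrics"]),
            weight=s["weight"],
            color=s["color"],
            transform=s["transform"],
        )
        for s in meta
    )
    model = ToxPiModel(slices)
    model.validate_against(table)
    return model


# -- merging ---------------------------------------------------------------


def merge_tables(tables, entity_subset=None) -> DataTable:
    """Union of entities over the metrics common to all tables.

    A metric value present in several tables for the same entity must agree;
    a present value fills a missing one.  ``entity_subset`` restricts and
    orders the output rows.
    """
    tables = list(tables)
    if not tables:
        raise DataError("merge_tables requires at least one table")
    common = [m for m in tables[0].metric_ids if all(m in t.metric_ids for t in tables)]
    if not common:
        raise DataError("no metric is common to all tables")

    entity_order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    for t in tables:
        cols = [t.metric_index(m) for m in common]
        for i, e in enumerate(t.entity_ids):
            vals = t.values[i, cols]
            miss = t.missing_mask[i, cols]
            if e not in rows:
                entity_order.append(e)
                rows[e], masks[e] = vals.copy(), miss.copy()
                if t.entity_class is not None:
                    classes[e] = t.entity_class[i]
                continue
            both = ~miss & ~masks[e]
            if np.any(rows[e][both] != vals[both]):
                bad = [common[j] for j in np.where(both)[0] if rows[e][j] != vals[j]]
                raise DataError(
                    f"entity {e!r}: conflicting values for common metrics {bad}"
                )
            fill = masks[e] & ~miss
            rows[e][fill] = vals[fill]
            masks[e][fill] = False
            if e not in classes and t.entity_class is not None:
                classes[e] = t.entity_class[i]

    if entity_subset is not None:
        missing = [e for e in entity_subset if e not in rows]
        if missing:
            raise DataError(f"subset entities not found: {missing}")
        entity_order = list(entity_subset)
    values = np.vstack([rows[e] for e in entity_order])
    mask = np.vstack([masks[e] for e in entity_order])
    cls = [classes.get(e, "") for e in entity_order] if classes else None
    return DataTable(entity_order, common, values, mask, cls)


# -- writing ---------------------------------------------------------------


def _fmt(v: float) -> str:
    """Shortest decimal that round-trips the double exactly."""
    return repr(float(v))


def _quote(field: str) -> str:
    if any(c in field for c in ',"\n'):
        return '"' + field.replace('"', '""') + '"'
    return field


def write_model_file(table: DataTable, model: ToxPiModel, path, scores=None) -> None:
    """Write the round-trippable complete-dialect file.

    Reading the result back with ``read_table`` reproduces the table and
    every slice field (membership, weight, color, transform, order) exactly.
    """
    model.validate_against(table, allow_shared_metrics=True)
    lines = []
    for s in model.slices:
        lines.append(
            f"# slice: {s.name}, weight={_fmt(s.weight)}, color={s.color}, "
            f"scale={s.transform}"
        )
        lines.append("# metrics: " + "|".join(s.metric_ids))
    lines.append(",".join(["id", "class"] + [_quote(m) for m in table.metric_ids]))
    cls = table.entity_class or [""] * table.n_entities
    for i, e in enumerate(table.entity_ids):
        cells = [
            _MISSING_TOKEN if table.missing_mask[i, j] else _fmt(table.values[i, j])
            for j in range(table.n_metrics)
        ]
        lines.append(",".join([_quote(e), _quote(cls[i])] + cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_results_csv(
    scores,
    path,
    ci=None,
    clusters=None,
    selection=None,
    extra_columns=None,
) -> None:
    """Results table: ``id,class,overall_score,rank,cluster,<slices...>``.

    With a ConfidenceResult, ``overall_lo/overall_hi/rank_lo/rank_hi`` and
    per-slice ``_lo/_hi`` columns are appended; ``extra_columns`` maps names
    to per-entity vectors (e.g. PCA coordinates).
    """
    ids = scores.entity_ids
    if selection is not None:
        missing = [e for e in selection if e not in ids]
        if missing:
            raise DataError(f"selection ids not scored: {missing}")
        order = [ids.index(e) for e in selection]
    else:
        order = list(range(len(ids)))

    header = ["id", "class", "overall_score", "rank", "cluster"] + list(
        scores.slice_names
    )
    if ci is not None:
        header += ["overall_lo", "overall_hi", "rank_lo", "rank_hi"]
        for s in scores.slice_names:
            header += [f"{s}_lo", f"{s}_hi"]
    if extra_columns:
        header += list(extra_columns)

    cls = scores.entity_class or [""] * len(ids)
    label = {}
    if clusters is not None:
        label = dict(zip(ids, np.asarray(clusters.labels).astype(str)))
    lines = [",".join(_quote(h) for h in header)]
    for i in order:
        row = [
            _quote(ids[i]),
            _quote(cls[i]),
            _fmt(scores.overall[i]),
            str(int(scores.rank[i])),
            label.get(ids[i], ""),
        ]
        row += [_fmt(v) for v in scores.slice_scores[i]]
        if ci is not None:
            row += [
                _fmt(ci.overall_lo[i]),
                _fmt(ci.overall_hi[i]),
                str(int(ci.rank_lo[i])),
                str(int(ci.rank_hi[i])),
            ]
            for j in range(len(scores.slice_names)):
                row += [_fmt(ci.slice_lo[i, j]), _fmt(ci.slice_hi[i, j])]
        if extra_columns:
            row += [_fmt(extra_columns[k][i]) for k in extra_columns]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
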