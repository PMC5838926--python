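"""Core data container for entity × metric matrices with explicit missingness.

The unit of analysis is an *entity* (a chemical, a clinical subject, ...)
measured on a set of *metrics* (assay readouts, physico-chemical
descriptors).  Values are nonnegative reals; a cell may instead be missing,
in which case no scoring operation ever reads it.  Negative inputs are
converted to missing at import time, so a validated table contains no
negative retained cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DataTable", "ImportReport"]


class DataError(ValueError):
    """Raised for structurally invalid tables or files."""


@dataclass
class DataTable:
    """Entities × metrics numeric matrix with names and a missingness mask.

    Parameters
    ----------
    entity_ids : list of str
        Unique, non-empty row labels.
    metric_ids : list of str
        Unique, non-empty column labels.
    values : ndarray of float, shape (n_entities, n_metrics)
        Cell values; entries under ``missing_mask`` are undefined (stored
        as NaN) and must never be read by scoring code.
    missing_mask : ndarray of bool, same shape
        True where the cell is missing.
    entity_class : list of str, optional
        Per-entity source/category annotation.
    """

    entity_ids: list[str]
    metric_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    entity_class: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()
        # missing cells are undefined: normalise storage to NaN
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan

    # -- structure ---------------------------------------------------------

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_metrics(self) -> int:
        return len(self.metric_ids)

    def validate(self) -> None:
        for kind, ids in (("entity", self.entity_ids), ("metric", self.metric_ids)):
            if any(not i for i in ids):
                raise DataError(f"empty {kind} id")
            dupes = {i for i in ids if ids.count(i) > 1} if len(ids) < 100 else None
            if dupes is None:
                seen: set[str] = set()
                dupes = {i for i in ids if i in seen or seen.add(i)}
            if dupes:
                raise DataError(f"duplicate {kind} ids: {sorted(dupes)}")
        shape = (len(self.entity_ids), len(self.metric_ids))
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise DataError(
                f"shape mismatch: values {self.values.shape}, mask "
                f"{self.missing_mask.shape}, ids imply {shape}"
            )
        if self.entity_class is not None and len(self.entity_class) != shape[0]:
            raise DataError("entity_class length does not match entity count")
        retained = self.values[~self.missing_mask]
        if retained.size and (np.isnan(retained).any() or (retained < 0).any()):
            raise DataError("retained cells must be defined and nonnegative")

    def metric_index(self, metric_id: str) -> int:
        try:
            return self.metric_ids.index(metric_id)
        except ValueError:
            raise DataError(f"unknown metric: {metric_id!r}") from None

    def entity_index(self, entity_id: str) -> int:
        try:
            return self.entity_ids.index(entity_id)
        except ValueError:
            raise DataError(f"unknown entity: {entity_id!r}") from None

    def subset_entities(self, entity_subset: list[str]) -> "DataTable":
        """Rows restricted to ``entity_subset``, in subset order."""
        idx = [self.entity_index(e) for e in entity_subset]
        return DataTable(
            entity_ids=[self.entity_ids[i] for i in idx],
            metric_ids=list(self.metric_ids),
            values=self.values[idx],
            missing_mask=self.missing_mask[idx],
            entity_class=None
            if self.entity_class is None
            else [self.entity_class[i] for i in idx],
        )

    def equals(self, other: "DataTable") -> bool:
        """Content equality: ids, classes, mask, and non-missing values."""
        if self.entity_ids != other.entity_ids or self.metric_ids != other.metric_ids:
            return False
        if (self.entity_class or None) != (other.entity_class or None):
            return False
        if not np.array_equal(self.missing_mask, other.missing_mask):
            return False
        keep = ~self.missing_mask
        return bool(np.array_equal(self.values[keep], other.values[keep]))


@dataclass
class ImportReport:
    """Bookkeeping for a single file import."""

    n_entities: int
    n_metrics: int
    n_missing_na: int
    n_negative_dropped: int
    dialect: str
    annotations: dict = field(default_factory=dict)

    def validate_against(self, table: DataTable) -> None:
        if self.n_missing_na + self.n_negative_dropped != int(table.missing_mask.sum()):
            raise DataError("import report missing counts do not reconcile with mask")
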