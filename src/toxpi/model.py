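"""Model definition: apportionment of metrics into weighted, colored slices.

A model is an ordered list of slices.  Each slice names the metrics it
combines, a positive weight (its angular share of the radial profile and of
the overall score), a display color, and a scaling transform applied to its
metrics before aggregation.

Transforms map retained (nonnegative) values into [0, inf) and are monotone;
the ``*_inverted`` variants reverse direction so that *small* raw values
score high (e.g. potency expressed as an effective concentration).  Logs are
taken after a fixed +1 offset so zero is representable.  ``max_m`` denotes a
metric's maximum over non-missing entities.

========================  =======================================
name                      t(x)
========================  =======================================
linear                    x
linear_inverted           max_m - x
log10                     log10(x + 1)
log10_inverted            log10(max_m + 1) - log10(x + 1)
sqrt                      sqrt(x)
========================  =======================================
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np

from .data import DataError, DataTable

__all__ = [
    "TRANSFORMS",
    "SliceDef",
    "ToxPiModel",
    "build_model",
    "edit_model",
    "select_metrics",
    "summarize_slice",
]

logger = logging.getLogger(__name__)

TRANSFORMS = ("linear", "linear_inverted", "log10", "log10_inverted", "sqrt")

_HEX_COLOR = re.compile(r"^#[0-9A-Fa-f]{6}$")

#: advisory only; mirrors the visual-effectiveness guidance for radial charts
SOFT_MAX_SLICES = 20


class ModelError(ValueError):
    """Raised for invalid slice or model definitions."""


def apply_transform(name: str, x: np.ndarray, max_m: float) -> np.ndarray:
    """Apply a named transform elementwise; ``x`` holds NaN where missing."""
    if name == "linear":
        return x
    if name == "linear_inverted":
        return max_m - x
    if name == "log10":
        return np.log10(x + 1.0)
    if name == "log10_inverted":
        return np.log10(max_m + 1.0) - np.log10(x + 1.0)
    if name == "sqrt":
        return np.sqrt(x)
    raise ModelError(f"unknown transform: {name!r}")


@dataclass(frozen=True)
class SliceDef:
    name: str
    metric_ids: tuple[str, ...]
    weight: float = 1.0
    color: str = "#808080"
    transform: str = "linear"

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("slice name must be non-empty")
        object.__setattr__(self, "metric_ids", tuple(self.metric_ids))
        if not self.metric_ids:
            raise ModelError(f"slice {self.name!r} has no metrics")
        if not (self.weight > 0):
            raise ModelError(f"slice {self.name!r}: weight must be > 0")
        if not _HEX_COLOR.match(self.color):
            raise ModelError(f"slice {self.name!r}: color must be #RRGGBB")
        if self.transform not in TRANSFORMS:
            raise ModelError(
                f"slice {self.name!r}: unknown transform {self.transform!r}"
            )


@dataclass(frozen=True)
class ToxPiModel:
    slices: tuple[SliceDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "slices", tuple(self.slices))
        if not self.slices:
            raise ModelError("model needs at least one slice")
        names = [s.name for s in self.slices]
        if len(set(names)) != len(names):
            raise ModelError(f"duplicate slice names: {names}")
        if len(self.slices) > SOFT_MAX_SLICES:
            logger.warning(
                "%d slices: an excessive number may reduce the visual "
                "effectiveness of the profiles",
                len(self.slices),
            )

    @property
    def slice_names(self) -> list[str]:
        return [s.name for s in self.slices]

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.slices], dtype=float)

    def get_slice(self, name: str) -> SliceDef:
        for s in self.slices:
            if s.name == name:
                return s
        raise ModelError(f"unknown slice: {name!r}")

    def validate_against(
        self, table: DataTable, allow_shared_metrics: bool = False
    ) -> None:
        seen: dict[str, str] = {}
        for s in self.slices:
            for m in s.metric_ids:
                if m not in table.metric_ids:
                    raise ModelError(f"slice {s.name!r}: unknown metric {m!r}")
                if m in seen and not allow_shared_metrics:
                    raise ModelError(
                        f"metric {m!r} appears in slices {seen[m]!r} and "
                        f"{s.name!r} (pass allow_shared_metrics to permit)"
                    )
                seen[m] = s.name


def build_model(
    slice_specs,
    table: DataTable,
    allow_shared_metrics: bool = False,
) -> ToxPiModel:
    """Build and validate a model from (name, metrics, weight, color, transform).

    Each spec may be a SliceDef or a tuple with trailing elements optional.
    """
    slices = []
    for spec in slice_specs:
        if isinstance(spec, SliceDef):
            slices.append(spec)
        else:
            slices.append(SliceDef(*spec))
    model = ToxPiModel(tuple(slices))
    model.validate_against(table, allow_shared_metrics=allow_shared_metrics)
    return model


def edit_model(model: ToxPiModel, op: str, **args) -> ToxPiModel:
    """Return a new model with one edit applied; untouched slices are identical.

    Supported ops: add_metric(slice, metric), remove_metric(slice, metric),
    reweight(slice, weight), recolor(slice or slices, color),
    rename(slice, new_name), reorder_slices(order).
    """
    slices = list(model.slices)

    def _idx(name: str) -> int:
        for i, s in enumerate(slices):
            if s.name == name:
                return i
        raise ModelError(f"unknown slice: {name!r}")

    if op == "add_metric":
        i = _idx(args["slice"])
        slices[i] = replace(
            slices[i], metric_ids=slices[i].metric_ids + (args["metric"],)
        )
    elif op == "remove_metric":
        i = _idx(args["slice"])
        remaining = tuple(m for m in slices[i].metric_ids if m != args["metric"])
        if args["metric"] not in slices[i].metric_ids:
            raise ModelError(f"metric {args['metric']!r} not in slice")
        if not remaining:
            raise ModelError(
                "cannot remove the last metric of a slice; delete the slice instead"
            )
        slices[i] = replace(slices[i], metric_ids=remaining)
    elif op == "reweight":
        i = _idx(args["slice"])
        slices[i] = replace(slices[i], weight=float(args["weight"]))
    elif op == "recolor":
        targets = args.get("slices") or [args["slice"]]
        for name in targets:
            i = _idx(name)
            slices[i] = replace(slices[i], color=args["color"])
    elif op == "rename":
        i = _idx(args["slice"])
        slices[i] = replace(slices[i], name=args["new_name"])
    elif op == "reorder_slices":
        order = list(args["order"])
        if sorted(order) != sorted(s.name for s in slices):
            raise ModelError("reorder must permute the existing slice names")
        slices = [slices[_idx(n)] for n in order]
    else:
        raise ModelError(f"unknown edit op: {op!r}")
    return ToxPiModel(tuple(slices))


def select_metrics(table: DataTable, query: str = "") -> list[str]:
    """Case-insensitive substring match on metric ids, in table order."""
    q = query.lower()
    return [m for m in table.metric_ids if q in m.lower()]


def summarize_slice(slice_def: SliceDef, table: DataTable) -> dict[str, dict]:
    """Per-metric summary over non-missing cells: n present/missing, min, max, median."""
    out: dict[str, dict] = {}
    for m in slice_def.metric_ids:
        j = table.metric_index(m)
        present = ~table.missing_mask[:, j]
        vals = table.values[present, j]
        stats = {
            "n_present": int(present.sum()),
            "n_missing": int((~present).sum()),
        }
        if vals.size:
            stats.update(
                min=float(vals.min()), max=float(vals.max()), median=float(np.median(vals))
            )
        else:
            stats.update(min=None, max=None, median=None)
        out[m] = stats
    return out
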