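"""Measurement-table I/O and measurement taxonomy.

Per-cell morphology tables come from high-content microscopy pipelines
(CellProfiler-style exports): rows are segmented cells, columns are numeric
measurements whose names encode what was measured
(``AreaShape_Zernike_4_2``, ``Intensity_MeanIntensity_FUS_Nucleus``, ...).
This module parses those names into a small taxonomy (measurement category,
cellular compartment, stain channel), validates a measurement table against
its cell annotations, and provides the canonical in-memory container —
:class:`FeatureTable` — used by the rest of the package.

Convention used everywhere: cells are rows, measurements are columns.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Condition labels understood by the downstream contrasts.
CONDITIONS = ("control", "sod1", "vcp", "sals")


class Category(str, Enum):
    """Measurement category (the three groups reported by the analysis)."""

    AREA_SHAPE = "area_shape"
    TEXTURE = "texture"
    INTENSITY = "intensity"
    OTHER = "other"


class Compartment(str, Enum):
    NUCLEUS = "nucleus"
    CYTOPLASM = "cytoplasm"
    WHOLE_CELL = "whole_cell"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class MeasurementInfo:
    """Taxonomy entry for one measurement column."""

    name: str
    category: Category
    compartment: Compartment = Compartment.UNKNOWN
    channel: str | None = None


@dataclass(frozen=True)
class NamingDialect:
    """Prefix/substring rules mapping measurement names to the taxonomy.

    A dialect is a deterministic function of the measurement name; deposited
    datasets with different naming conventions can register their own dialect
    or supply a per-name JSON override (see :func:`read_feature_table`).
    """

    name: str
    category_prefixes: Mapping[str, Category]
    channels: tuple[str, ...] = ("FUS", "SFPQ", "ChAT", "DAPI")
    nucleus_tokens: tuple[str, ...] = ("Nucleus", "Nuclei", "Nuc")
    cytoplasm_tokens: tuple[str, ...] = ("Cytoplasm", "Cyto")
    whole_cell_tokens: tuple[str, ...] = ("Cell", "Cells", "MN", "WholeCell")


CELLPROFILER = NamingDialect(
    name="cellprofiler",
    category_prefixes={
        "AreaShape": Category.AREA_SHAPE,
        "Texture": Category.TEXTURE,
        "Granularity": Category.TEXTURE,
        "RadialDistribution": Category.TEXTURE,
        "Intensity": Category.INTENSITY,
    },
)

DIALECTS: dict[str, NamingDialect] = {"cellprofiler": CELLPROFILER}

_NC_RATIO_RE = re.compile(r"NC_?Ratio", re.IGNORECASE)


def is_nc_ratio(name: str) -> bool:
    """True if *name* denotes a nuclear/cytoplasmic intensity ratio."""
    return bool(_NC_RATIO_RE.search(name))


def _resolve_dialect(dialect: str | NamingDialect) -> NamingDialect:
    if isinstance(dialect, NamingDialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown naming dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        ) from None


def classify_measurement(
    name: str,
    dialect: str | NamingDialect = "cellprofiler",
    overrides: Mapping[str, Mapping[str, str | None]] | None = None,
) -> MeasurementInfo:
    """Map a measurement name to its :class:`MeasurementInfo`.

    Deterministic given the dialect. Names matching no rule fall back to
    ``category=other`` with a logged warning. ``overrides`` (typically loaded
    from a user JSON mapping file) take precedence over the dialect rules.
    """
    if not name:
        raise ValueError("empty measurement name")
    d = _resolve_dialect(dialect)
    if overrides and name in overrides:
        o = overrides[name]
        return MeasurementInfo(
            name=name,
            category=Category(o.get("category", "other")),
            compartment=Compartment(o.get("compartment", "unknown")),
            channel=o.get("channel"),
        )
    tokens = name.split("_")
    category = d.category_prefixes.get(tokens[0])
    if category is None:
        if is_nc_ratio(name):
            # e.g. CellProfiler "Math_NCRatio_SFPQ": a derived intensity ratio
            category = Category.INTENSITY
        else:
            category = Category.OTHER
            logger.warning(
                "measurement %r matched no rule of dialect %r; category=other",
                name,
                d.name,
            )
    channel = None
    lowered = [t.lower() for t in tokens[1:]]
    for ch in d.channels:
        if ch.lower() in lowered:
            channel = ch
            break
    compartment = Compartment.UNKNOWN
    for t in tokens[1:]:
        if t in d.nucleus_tokens:
            compartment = Compartment.NUCLEUS
            break
        if t in d.cytoplasm_tokens:
            compartment = Compartment.CYTOPLASM
            break
        if t in d.whole_cell_tokens:
            compartment = Compartment.WHOLE_CELL
            break
    return MeasurementInfo(name, category, compartment, channel)


@dataclass
class FeatureTable:
    """Cells x measurements matrix with taxonomy and cell annotations.

    ``values`` is a float DataFrame indexed by cell id; ``cells`` is the
    annotation frame (same index, columns ``sample_id``, ``condition``,
    ``stain_panel``); ``measurements`` holds one :class:`MeasurementInfo`
    per column, in column order.
    """

    values: pd.DataFrame
    measurements: list[MeasurementInfo]
    cells: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("empty feature table")
        if self.values.shape[1] != len(self.measurements):
            raise ValueError(
                f"{self.values.shape[1]} value columns but "
                f"{len(self.measurements)} measurement records"
            )
        names = [m.name for m in self.measurements]
        if names != list(self.values.columns):
            raise ValueError("measurement records not aligned with value columns")
        if len(set(names)) != len(names):
            raise ValueError("duplicate measurement names")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate cell ids: {dup}")
        if not self.values.index.equals(self.cells.index):
            raise ValueError("annotation index not aligned with value rows")
        for col in ("sample_id", "condition"):
            if col not in self.cells.columns:
                raise ValueError(f"annotations lack required column {col!r}")
        bad = set(self.cells["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        nmap = self.cells.groupby("sample_id")["condition"].nunique()
        if (nmap > 1).any():
            raise ValueError(
                "sample(s) mapped to multiple conditions: "
                f"{nmap.index[nmap > 1].tolist()}"
            )
        if self.values.isna().any().any():
            raise ValueError("missing values present after validation")

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.values.shape[1]

    @property
    def measurement_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> pd.Series:
        return self.cells["condition"]

    @property
    def sample_ids(self) -> pd.Series:
        return self.cells["sample_id"]

    def categories(self) -> np.ndarray:
        """Per-measurement category values, aligned with columns."""
        return np.array([m.category.value for m in self.measurements])

    def column_index(self, name: str) -> int:
        try:
            return int(self.values.columns.get_loc(name))
        except KeyError:
            raise KeyError(f"no measurement named {name!r}") from None

    def taxonomy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [m.name for m in self.measurements],
                "category": [m.category.value for m in self.measurements],
                "compartment": [m.compartment.value for m in self.measurements],
                "channel": [m.channel for m in self.measurements],
            }
        )

    def subset_cells(self, mask: Sequence[bool] | pd.Series) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            self.values.loc[mask].copy(),
            list(self.measurements),
            self.cells.loc[mask].copy(),
            scaled=self.scaled,
        )


def read_feature_table(
    values_path: str | Path,
    annotations_path: str | Path,
    dialect: str | NamingDialect = "cellprofiler",
    mapping_path: str | Path | None = None,
) -> FeatureTable:
    """Read and validate a measurement table plus its cell annotations.

    Delimiter (comma or tab) is auto-detected. The cell id is taken from a
    ``cell_id`` column if present, else from the first column. Rows with any
    missing measurement are rejected (dropped with a warning) rather than
    imputed; cells present in the values but absent from the annotations are
    an error naming the orphan ids.
    """
    values_path, annotations_path = Path(values_path), Path(annotations_path)
    for p in (values_path, annotations_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    values = pd.read_csv(values_path, sep=None, engine="python")
    if values.shape[0] == 0 or values.shape[1] < 2:
        raise ValueError(f"empty measurement table: {values_path}")
    id_col = "cell_id" if "cell_id" in values.columns else values.columns[0]
    values = values.set_index(id_col)
    values.index = values.index.astype(str)
    if values.index.has_duplicates:
        dup = sorted(set(values.index[values.index.duplicated()]))
        raise ValueError(f"duplicate cell ids in {values_path}: {dup}")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-numeric measurement cell in {values_path}: {e}") from e
    n_bad = int(values.isna().any(axis=1).sum())
    if n_bad:
        bad_ids = values.index[values.isna().any(axis=1)].tolist()
        logger.warning(
            "rejecting %d cell(s) with missing measurements: %s", n_bad, bad_ids
        )
        values = values.dropna(axis=0)
    if values.shape[0] == 0:
        raise ValueError("no complete cells left after rejecting missing values")

    ann = pd.read_csv(annotations_path, sep=None, engine="python")
    if "cell_id" not in ann.columns:
        ann = ann.rename(columns={ann.columns[0]: "cell_id"})
    ann["cell_id"] = ann["cell_id"].astype(str)
    if ann["cell_id"].duplicated().any():
        dup = sorted(set(ann.loc[ann["cell_id"].duplicated(), "cell_id"]))
        raise ValueError(f"duplicate cell ids in {annotations_path}: {dup}")
    ann = ann.set_index("cell_id")
    if "stain_panel" not in ann.columns:
        ann["stain_panel"] = None
    orphans = values.index.difference(ann.index).tolist()
    if orphans:
        raise ValueError(f"cells without annotation: {orphans}")
    ann = ann.loc[values.index, ["sample_id", "condition", "stain_panel"]]

    overrides = None
    if mapping_path is not None:
        with open(mapping_path) as fh:
            overrides = json.load(fh)
    measurements = [
        classify_measurement(c, dialect, overrides) for c in values.columns
    ]
    return FeatureTable(values, measurements, ann, scaled=False)


def write_feature_table(
    table: FeatureTable,
    values_path: str | Path,
    annotations_path: str | Path,
    schema_path: str | Path | None = None,
) -> None:
    """Write canonical CSVs plus an optional sidecar taxonomy/provenance JSON."""
    table.values.to_csv(values_path, index_label="cell_id")
    table.cells.to_csv(annotations_path, index_label="cell_id")
    if schema_path is not None:
        schema = {
            "n_cells": table.n_cells,
            "n_measurements": table.n_measurements,
            "scaled": table.scaled,
            "measurements": [
                {
                    "name": m.name,
                    "category": m.category.value,
                    "compartment": m.compartment.value,
                    "channel": m.channel,
                }
                for m in table.measurements
            ],
        }
        with open(schema_path, "w") as fh:
            json.dump(schema, fh, indent=1)


def select_nc_ratio(table: FeatureTable, channel: str) -> int:
    """Column index of the N/C intensity-ratio measurement for *channel*.

    Raises if no column or more than one column matches: the N/C ratio is a
    single derived measurement per stain, so ambiguity indicates a naming
    problem upstream.
    """
    matches = [
        j
        for j, m in enumerate(table.measurements)
        if is_nc_ratio(m.name) and m.channel == channel
    ]
    if not matches:
        raise ValueError(f"no N/C-ratio measurement for channel {channel!r}")
    if len(matches) > 1:
        names = [table.measurements[j].name for j in matches]
        raise ValueError(f"ambiguous N/C-ratio for channel {channel!r}: {names}")
    return matches[0]
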