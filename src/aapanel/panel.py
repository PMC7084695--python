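"""Labeled sample-by-analyte concentration tables and CSV I/O.

The central container is :class:`AnalytePanel`: one row per serum (or brain
tissue) sample, one column per quantified analyte (concentrations in nmol/mL),
plus the metadata needed by the downstream pipeline — a binary injury label,
the sampling timepoint, the animal id (pre/post samples share animals), the
injury model and the compartment the sample was drawn from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, SchemaError, ValidationError

#: Metadata columns every panel carries alongside the analyte columns.
META_COLUMNS = ("sample_id", "animal_id", "label", "timepoint", "injury_model", "compartment")

TIMEPOINTS = ("pre", "24h", "4d", "8d", "sham")
INJURY_MODELS = ("RNR", "CCI", "sham", "none")
COMPARTMENTS = ("serum", "tissue")


@dataclass
class AnalytePanel:
    """A validated sample-by-analyte concentration matrix with metadata.

    Parameters
    ----------
    data
        One row per sample.  Must contain every column in ``META_COLUMNS``
        and one numeric column per entry of ``analyte_names``.  Missing
        concentrations are ``NaN``; present values must be non-negative.
    analyte_names
        Ordered analyte identifiers; duplicates are rejected.
    """

    data: pd.DataFrame
    analyte_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.analyte_names = list(self.analyte_names)
        if len(set(self.analyte_names)) != len(self.analyte_names):
            raise ValidationError("duplicate analyte names in panel")
        for col in META_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"panel is missing mandatory column {col!r}")
        for name in self.analyte_names:
            if name not in self.data.columns:
                raise SchemaError(f"panel is missing analyte column {name!r}")
        if self.data["label"].isna().any():
            bad = self.data.index[self.data["label"].isna()][0]
            raise ValidationError(f"label undefined for sample at row {bad}")
        labels = set(self.data["label"].astype(int).unique())
        if not labels <= {0, 1}:
            raise ValidationError(f"labels must be 0/1, found {sorted(labels)}")
        for name in self.analyte_names:
            col = pd.to_numeric(self.data[name], errors="coerce")
            neg = col < 0
            if neg.any():
                row = self.data.index[neg][0]
                raise ValidationError(
                    f"negative concentration for analyte {name!r} at row {row}"
                )
        self.data = self.data.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def pp(self) -> int:
        """Total number of analyte variables available for selection."""
        return len(self.analyte_names)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    def values(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Concentration matrix (n_samples × p) for ``subset`` (default: all)."""
        names = list(subset) if subset is not None else self.analyte_names
        for name in names:
            if name not in self.analyte_names:
                raise KeyError(f"unknown analyte {name!r}")
        return self.data[names].to_numpy(dtype=float)

    def take(self, indices: Sequence[int]) -> "AnalytePanel":
        """Row subset by positional indices, order preserved."""
        return AnalytePanel(self.data.iloc[list(indices)].copy(), self.analyte_names)

    def filter(self, **conditions) -> "AnalytePanel":
        """Row subset by metadata equality, e.g. ``filter(timepoint="24h")``."""
        mask = pd.Series(True, index=self.data.index)
        for col, value in conditions.items():
            mask &= self.data[col] == value
        return AnalytePanel(self.data[mask].copy(), self.analyte_names)

    def with_analytes(self, names: Sequence[str]) -> "AnalytePanel":
        return AnalytePanel(self.data.copy(), list(names))

    def to_csv(self, path) -> None:
        cols = list(META_COLUMNS) + self.analyte_names
        self.data[cols].to_csv(path, index=False)


@dataclass
class DatasetSplit:
    """One of the three evaluation cohorts: development, validation, exploration.

    The development split is used for model building and cross-validation; the
    validation split evaluates the frozen model on unseen animals; the
    exploration split probes a later post-injury timepoint and may contain no
    uninjured samples at all (then only sensitivity is defined).
    """

    name: str
    panel: AnalytePanel

    def __post_init__(self) -> None:
        if self.name not in ("development", "validation", "exploration"):
            raise ValidationError(f"unknown split name {self.name!r}")

    @property
    def n_positive(self) -> int:
        return int((self.panel.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.panel.labels == 0).sum())


DEFAULT_SCHEMA = {col: col for col in META_COLUMNS}


def read_panel(path, schema: Mapping[str, str] | None = None) -> AnalytePanel:
    """Read a sample-by-analyte CSV into a validated :class:`AnalytePanel`.

    Parameters
    ----------
    path
        CSV file with one row per sample.  Empty cells and ``NA`` are both
        accepted as missing-value markers.
    schema
        Maps the canonical metadata names (``sample_id``, ``animal_id``,
        ``label``, ``timepoint``, ``injury_model``, ``compartment``) to the
        column names used in the file.  Unmapped columns are analytes.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    frame = pd.read_csv(
        path, na_values=["NA"], keep_default_na=True, float_precision="round_trip"
    )
    rename = {}
    for canonical in META_COLUMNS:
        source = schema.get(canonical, canonical)
        if source not in frame.columns:
            raise SchemaError(f"CSV is missing mandatory column {source!r} ({canonical})")
        rename[source] = canonical
    frame = frame.rename(columns=rename)
    analytes = [c for c in frame.columns if c not in META_COLUMNS]
    for name in analytes:
        frame[name] = pd.to_numeric(frame[name], errors="coerce")
    return AnalytePanel(frame, analytes)


def drop_incomplete_analytes(panel: AnalytePanel) -> AnalytePanel:
    """Drop every analyte that could not be measured in all samples.

    Mirrors the screening step in which analytes with any missing measurement
    are excluded before model building; the sample set is unchanged.  Raises
    :class:`EmptyPanelError` when nothing survives.
    """
    complete = [
        name for name in panel.analyte_names if not panel.data[name].isna().any()
    ]
    if not complete:
        raise EmptyPanelError("every analyte has at least one missing measurement")
    return panel.with_analytes(complete)
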