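"""Core in-memory containers shared across the pipeline.

The canonical container for a proteomic panel is a pandas DataFrame of
shape (samples x analytes) wrapped with two pieces of provenance that the
preprocessing rules depend on: the tissue compartment of every analyte
(``blood`` or ``bal``) and whether values are raw concentrations or
log2-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

BLOOD = "blood"
BAL = "bal"
RAW = "raw"
LOG = "log"

GREATER = "greater"
LESSER = "lesser"


class ConfigurationError(ValueError):
    """Raised when inputs or configuration violate a documented precondition."""


@dataclass
class ProteomicMatrix:
    """A samples x analytes concentration table.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are analyte ids.
    compartment
        Either a single tag (``"blood"``/``"bal"``) applied to every
        analyte, or a per-analyte Series aligned with ``values.columns``.
    scale
        ``"raw"`` for concentrations, ``"log"`` after log2 transform.
    """

    values: pd.DataFrame
    compartment: pd.Series | str = BLOOD
    scale: str = RAW

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if isinstance(self.compartment, str):
            if self.compartment not in (BLOOD, BAL):
                raise ConfigurationError(
                    f"unknown compartment {self.compartment!r}"
                )
            self.compartment = pd.Series(
                self.compartment, index=self.values.columns, dtype=object
            )
        else:
            self.compartment = pd.Series(self.compartment)
            if not self.compartment.index.equals(self.values.columns):
                self.compartment = self.compartment.reindex(self.values.columns)
            if self.compartment.isna().any():
                missing = list(
                    self.compartment.index[self.compartment.isna()][:5]
                )
                raise ConfigurationError(
                    f"analytes without a compartment tag: {missing}"
                )
        if self.scale not in (RAW, LOG):
            raise ConfigurationError(f"unknown scale {self.scale!r}")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def analytes(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ProteomicMatrix":
        return ProteomicMatrix(
            self.values.copy(), self.compartment.copy(), self.scale
        )

    def select_analytes(self, analytes: Iterable[str]) -> "ProteomicMatrix":
        cols = list(analytes)
        return ProteomicMatrix(
            self.values[cols], self.compartment[cols], self.scale
        )

    def with_scale(self, scale: str) -> "ProteomicMatrix":
        return replace(self, scale=scale)


# Columns of the participant table, in canonical order.  ``delta_fev1``,
# ``decline_class`` and ``anderson_class`` are derived downstream.
PARTICIPANT_COLUMNS = [
    "id",
    "group",
    "sex",
    "age",
    "race",
    "height_cm",
    "smoking_status",
    "pack_years",
    "ics_use",
    "v1_fev1",
    "v5_fev1",
    "v1_fev1_pct_pred",
    "v5_fev1_pct_pred",
    "v1_date",
    "v5_date",
]


@dataclass
class ParticipantRecord:
    """One participant's spirometry and covariates.

    FEV1 volumes are in litres, dates are ISO-8601 calendar dates, the
    derived decline ``delta_fev1`` is in mL/year (negative = decline).
    """

    id: str
    group: str  # COPD | TEPPS
    sex: str  # M | F
    age: float
    race: str
    height_cm: float
    smoking_status: str  # current | former
    pack_years: float
    ics_use: bool
    v1_fev1: float
    v5_fev1: float
    v1_fev1_pct_pred: float
    v5_fev1_pct_pred: float
    v1_date: str
    v5_date: str
    delta_fev1: float | None = None
    decline_class: str | None = None
    anderson_class: str | None = None


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])
    return frame.set_index("id", drop=False)


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    known = {f for f in ParticipantRecord.__dataclass_fields__}
    out = []
    for _, row in frame.iterrows():
        kwargs = {k: v for k, v in row.items() if k in known}
        out.append(ParticipantRecord(**kwargs))
    return out


def as_binary_classes(classes, positive: str = GREATER) -> np.ndarray:
    """Encode a two-level label vector as 0/1 with ``positive`` -> 1."""
    arr = np.asarray(classes)
    levels = pd.unique(arr)
    if len(levels) != 2:
        raise ConfigurationError(
            f"expected exactly two classes, got {list(levels)}"
        )
    if positive not in levels:
        raise ConfigurationError(f"positive class {positive!r} not present")
    return (arr == positive).astype(float)
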