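"""Annualized FEV1 decline and progression-class assignment.

Decline is the two-point slope (V5 FEV1 - V1 FEV1) / time with time
measured in fixed-length years of 365.2425 days, expressed in mL/year
(negative = decline).  The primary phenotype dichotomizes the cohort at
the 30th percentile of decline; an alternative threshold-based scheme
(rapid / decliner / stable-improver) is also provided.
"""

from __future__ import annotations

import logging
from datetime import date

import numpy as np
import pandas as pd

from .datatypes import GREATER, LESSER, ConfigurationError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.2425

RAPID = "rapid"
DECLINER = "decliner"
STABLE = "stable_improver"


def _as_date(d) -> date:
    if isinstance(d, date):
        return d
    return date.fromisoformat(str(d))


def annualized_decline(v1_fev1: float, v5_fev1: float, v1_date, v5_date) -> float:
    """Two-point annualized FEV1 slope in mL/year (negative = decline)."""
    d1, d5 = _as_date(v1_date), _as_date(v5_date)
    days = (d5 - d1).days
    if days <= 0:
        raise ConfigurationError(
            f"visit interval must be positive (got {days} days)"
        )
    if v1_fev1 <= 0 or v5_fev1 <= 0:
        raise ConfigurationError("FEV1 volumes must be positive")
    years = days / DAYS_PER_YEAR
    return 1000.0 * (v5_fev1 - v1_fev1) / years


def compute_declines(
    participants: pd.DataFrame, use_pct_pred: bool = False
) -> pd.Series:
    """Annualized decline for every participant in a cohort table.

    With ``use_pct_pred=True`` the %-predicted FEV1 columns are substituted
    into the same slope formula (units then %pred/year), the alternative
    labeling the supplementary analyses use.
    """
    v1c, v5c = ("v1_fev1_pct_pred", "v5_fev1_pct_pred") if use_pct_pred else (
        "v1_fev1",
        "v5_fev1",
    )
    scale = 1.0 if use_pct_pred else 1000.0
    out = {}
    for pid, row in participants.iterrows():
        d1, d5 = _as_date(row["v1_date"]), _as_date(row["v5_date"])
        days = (d5 - d1).days
        if days <= 0:
            raise ConfigurationError(f"participant {pid}: non-positive interval")
        out[pid] = scale * (row[v5c] - row[v1c]) / (days / DAYS_PER_YEAR)
    return pd.Series(out, name="delta_fev1")


def percentile_dichotomize(
    declines: pd.Series, pct: float = 30.0
) -> tuple[pd.Series, float]:
    """Label the ceil(pct% * n) most negative declines as greater decliners.

    Returns the label Series ({greater, lesser}) and the realized
    threshold — the largest (least negative) decline labeled greater.
    With n = 45 and pct = 30 this yields the 14 / 31 split
    (ceil(13.5) = 14).  Ties spanning the boundary are resolved by stable
    rank order (value, then position) with a warning.
    """
    declines = pd.Series(declines)
    n = len(declines)
    if n < 2:
        raise ConfigurationError("need at least two participants")
    if not 0 < pct <= 100:
        raise ConfigurationError("percentile must be in (0, 100]")
    n_greater = int(np.ceil(pct / 100.0 * n))
    vals = declines.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        logger.warning("all declines identical; labeling everyone lesser")
        return pd.Series(LESSER, index=declines.index), float(vals[0])
    order = np.argsort(vals, kind="stable")  # most negative first
    greater_pos = order[:n_greater]
    threshold = float(vals[greater_pos].max())
    boundary_val = vals[order[n_greater - 1]]
    if n_greater < n and vals[order[n_greater]] == boundary_val:
        logger.warning(
            "ties span the %g-percentile boundary (value %g); "
            "resolved by stable rank order",
            pct,
            boundary_val,
        )
    labels = np.full(n, LESSER, dtype=object)
    labels[greater_pos] = GREATER
    return pd.Series(labels, index=declines.index, name="decline_class"), threshold


def threshold_classes(declines: pd.Series) -> pd.Series:
    """Three-level threshold classification of annualized decline.

    Based on the magnitude of the (negative) slope: rapid decliners lose
    more than 100 mL/year, decliners 20-100 mL/year (boundaries assigned
    to this middle class), stable/improvers less than 20 mL/year — any
    positive slope is stable.
    """
    declines = pd.Series(declines)
    magnitude = -declines.to_numpy(dtype=float)  # positive = loss
    labels = np.where(
        magnitude > 100.0,
        RAPID,
        np.where(magnitude >= 20.0, DECLINER, STABLE),
    )
    return pd.Series(labels, index=declines.index, name="anderson_class")


def label_participants(
    participants: pd.DataFrame,
    pct: float = 30.0,
    use_pct_pred: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Attach ``delta_fev1``, ``decline_class`` and ``anderson_class``.

    Only COPD participants enter the percentile dichotomization; a TEPPS
    reference group (if present in ``group``) keeps its declines but gets
    no decline class.
    """
    out = participants.copy()
    out["delta_fev1"] = compute_declines(out, use_pct_pred=use_pct_pred)
    is_copd = (
        out["group"].eq("COPD") if "group" in out.columns
        else pd.Series(True, index=out.index)
    )
    classes, threshold = percentile_dichotomize(
        out.loc[is_copd, "delta_fev1"], pct=pct
    )
    out["decline_class"] = classes.reindex(out.index)
    out["anderson_class"] = threshold_classes(out["delta_fev1"])
    logger.info(
        "labeled %d COPD participants: %d greater / %d lesser "
        "(threshold %.1f mL/yr)",
        int(is_copd.sum()),
        int((classes == GREATER).sum()),
        int((classes == LESSER).sum()),
        threshold,
    )
    return out, threshold
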