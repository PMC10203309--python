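"""Dataset-construction rules for the multi-compartment panel.

Order of operations mirrors the assay workflow: detection-limit censoring
of the BAL multiplex panel, removal of analytes dominated by below-LLOD
measurements, normalization of BAL concentrations to per-sample total
protein, log2 transform of everything, removal of sex-associated analytes,
and finally the column-wise merge of blood and BAL into one feature table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BAL, BLOOD, LOG, RAW, ConfigurationError, ProteomicMatrix
from .univariate import bh_adjust, two_sample_ttest

logger = logging.getLogger(__name__)

# censoring-flag codes
BELOW_LLOD = -1
UNCENSORED = 0
ABOVE_ULOD = 1


@dataclass
class LODSpec:
    """Per-analyte detection limits of an immunoassay panel.

    ``limits`` is a DataFrame indexed by analyte id with columns ``llod``
    and ``ulod`` (concentration units).  The below-LLOD substitution uses a
    single global constant: half the lowest minimum detectable
    concentration across all analytes' standard curves.
    """

    limits: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"llod", "ulod"}
        if not required.issubset(self.limits.columns):
            raise ConfigurationError("LODSpec needs 'llod' and 'ulod' columns")
        lim = self.limits
        if (lim["llod"] <= 0).any():
            raise ConfigurationError("LLOD values must be positive")
        if (lim["llod"] >= lim["ulod"]).any():
            bad = list(lim.index[lim["llod"] >= lim["ulod"]][:5])
            raise ConfigurationError(f"LLOD >= ULOD for analytes {bad}")

    @property
    def imputation_constant(self) -> float:
        return 0.5 * float(self.limits["llod"].min())

    def to_frame(self) -> pd.DataFrame:
        return self.limits.copy()


def censor_bal_lod(
    raw: ProteomicMatrix, lod: LODSpec
) -> tuple[ProteomicMatrix, pd.DataFrame]:
    """Apply detection-limit censoring to a raw BAL matrix.

    Values above an analyte's ULOD are set to that analyte's maximum
    detectable concentration (the ULOD itself); values below the LLOD are
    set to the global imputation constant (half the lowest minimum
    detectable concentration across the whole panel).  Returns the
    censored matrix together with a per-cell flag matrix
    (-1 below LLOD, 0 untouched, +1 above ULOD).
    """
    if raw.scale != RAW:
        raise ConfigurationError("censoring applies to raw-scale data")
    limits = lod.limits
    missing = raw.analytes.difference(limits.index)
    if len(missing):
        # a matrix read back from disk carries compartment-prefixed ids;
        # match the spec on the bare analyte name
        bare = {a: str(a).split(":", 1)[-1] for a in raw.analytes}
        if all(bare[a] in limits.index for a in raw.analytes):
            limits = limits.loc[[bare[a] for a in raw.analytes]]
            limits.index = raw.analytes
        else:
            still = [a for a in raw.analytes if bare[a] not in limits.index]
            raise ConfigurationError(
                f"analytes missing from LOD spec: {still[:5]}"
            )
    llod = limits["llod"].reindex(raw.analytes)
    ulod = limits["ulod"].reindex(raw.analytes)

    vals = raw.values
    below = vals.lt(llod, axis=1)
    above = vals.gt(ulod, axis=1)
    out = vals.mask(above, ulod, axis=1)
    out = out.mask(below, lod.imputation_constant)
    flags = pd.DataFrame(
        np.where(below, BELOW_LLOD, np.where(above, ABOVE_ULOD, UNCENSORED)),
        index=vals.index,
        columns=vals.columns,
        dtype=np.int8,
    )
    return ProteomicMatrix(out, raw.compartment.copy(), RAW), flags


def filter_bal_analytes(
    censored: ProteomicMatrix, flags: pd.DataFrame, max_below_fraction: float = 0.5
) -> ProteomicMatrix:
    """Drop analytes in which >= 50% of measurements fell below the LLOD.

    Column order of the surviving analytes is preserved.
    """
    if censored.n_analytes == 0:
        raise ConfigurationError("empty matrix")
    if not flags.columns.equals(censored.analytes):
        flags = flags[censored.analytes]
    below_frac = (flags == BELOW_LLOD).mean(axis=0)
    keep = below_frac < max_below_fraction
    n_removed = int((~keep).sum())
    logger.info(
        "BAL LLOD filter: %d -> %d analytes (%d removed)",
        censored.n_analytes,
        int(keep.sum()),
        n_removed,
    )
    if not keep.any():
        logger.warning("all BAL analytes removed by the LLOD filter")
    survivors = list(censored.analytes[keep])
    return censored.select_analytes(survivors)


def normalize_and_log(
    bal: ProteomicMatrix,
    totals: pd.Series,
    blood: ProteomicMatrix,
) -> tuple[ProteomicMatrix, ProteomicMatrix]:
    """Total-protein-normalize BAL, then log2-transform both compartments.

    Every BAL value is divided by its sample's total BAL protein
    concentration; afterwards all analytes (blood and BAL) are
    log2-transformed.  Returns ``(blood_log, bal_log)`` ready for the merge.
    """
    for m, name in ((bal, "bal"), (blood, "blood")):
        if m.scale != RAW:
            raise ConfigurationError(f"{name} matrix must be raw scale")
    totals = totals.reindex(bal.samples)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()][:5])
        raise ConfigurationError(f"missing total protein for samples {missing}")
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0][:5])
        raise ConfigurationError(f"nonpositive total protein for samples {bad}")

    bal_norm = bal.values.div(totals, axis=0)
    for vals, name in ((bal_norm, "bal"), (blood.values, "blood")):
        if (vals <= 0).any().any():
            raise ConfigurationError(
                f"nonpositive concentration in {name} matrix at log step"
            )
    bal_log = ProteomicMatrix(np.log2(bal_norm), bal.compartment.copy(), LOG)
    blood_log = ProteomicMatrix(
        np.log2(blood.values), blood.compartment.copy(), LOG
    )
    return blood_log, bal_log


def sex_association_filter(
    matrix: ProteomicMatrix,
    sex: pd.Series,
    alpha: float = 0.05,
) -> tuple[ProteomicMatrix, list[str]]:
    """Remove analytes associated with sex after BH correction.

    Per analyte a two-tailed two-sample pooled t-test compares the sexes on
    the log scale; Benjamini-Hochberg adjustment is applied across all
    tested analytes and analytes with adjusted p < ``alpha`` are removed.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if matrix.scale != LOG:
        raise ConfigurationError("sex filter expects log-scale data")
    sex = pd.Series(sex).reindex(matrix.samples)
    levels = sex.dropna().unique()
    if len(levels) != 2:
        raise ConfigurationError(
            f"both sexes must be present, found {list(levels)}"
        )
    mask_a = (sex == levels[0]).to_numpy()
    vals = matrix.values.to_numpy()
    pvals = np.empty(matrix.n_analytes)
    for j in range(matrix.n_analytes):
        _, pvals[j] = two_sample_ttest(vals[mask_a, j], vals[~mask_a, j])
    padj = bh_adjust(pvals)
    removed = list(matrix.analytes[padj < alpha])
    kept = [a for a in matrix.analytes if a not in set(removed)]
    logger.info(
        "sex filter: %d -> %d analytes (%d removed)",
        matrix.n_analytes,
        len(kept),
        len(removed),
    )
    return matrix.select_analytes(kept), removed


def merge_compartments(
    blood: ProteomicMatrix, bal: ProteomicMatrix
) -> ProteomicMatrix:
    """Column-concatenate the two compartments into one feature table.

    Analyte ids are prefixed ``blood:`` / ``bal:`` so an analyte measured
    in both compartments remains two distinct features.
    """
    if blood.scale != bal.scale:
        raise ConfigurationError("cannot merge matrices on different scales")
    if not blood.samples.equals(bal.samples):
        reordered = bal.values.reindex(blood.samples)
        if reordered.isna().any().any():
            only_blood = blood.samples.difference(bal.samples)
            only_bal = bal.samples.difference(blood.samples)
            raise ConfigurationError(
                "sample mismatch between compartments: "
                f"blood-only {list(only_blood[:5])}, bal-only {list(only_bal[:5])}"
            )
        bal = ProteomicMatrix(reordered, bal.compartment, bal.scale)

    def prefixed(m: ProteomicMatrix, tag: str) -> pd.DataFrame:
        out = m.values.copy()
        out.columns = [
            c if str(c).startswith(f"{tag}:") else f"{tag}:{c}"
            for c in out.columns
        ]
        return out

    bvals = prefixed(blood, BLOOD)
    lvals = prefixed(bal, BAL)
    merged = pd.concat([bvals, lvals], axis=1)
    compartment = pd.Series(
        [BLOOD] * bvals.shape[1] + [BAL] * lvals.shape[1],
        index=merged.columns,
        dtype=object,
    )
    return ProteomicMatrix(merged, compartment, blood.scale)
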