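"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-compartment proteomic study of COPD
progression: a plasma panel of ~1305 analytes and a small BAL multiplex
panel of ~48 analytes measured once, with lung function followed for
~6 years.  Concentrations are log-normal (Gaussian on the log2 scale)
with analyte-specific baselines and spreads.  A planted co-varying
signature — members share a latent module factor and each differs
between progression classes by a configurable standardized effect on the
log scale — separates the two classes; the progression classes
themselves are definitional (the configured number of most negative
realized declines), as in a percentile-dichotomized phenotype.  A
configurable set of blood analytes carries a sex effect; a
configurable number of BAL analytes is constructed to fail the >= 50%
below-LLOD rule.  FEV1 decline is drawn first and the V5 volume is
back-computed from the drawn slope and an integer-day follow-up, so that
re-deriving the slope from volumes and dates round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .datatypes import (
    BAL,
    BLOOD,
    GREATER,
    LESSER,
    RAW,
    ConfigurationError,
    ProteomicMatrix,
)
from .preprocess import LODSpec
from .progression import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

ROLE_PLANTED = "planted"
ROLE_SEX = "sex"
ROLE_NOISE = "noise"


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions the pipeline targets: a 14/31
    greater/lesser decliner split plus a 40-person reference group of
    tobacco-exposed people with preserved spirometry (TEPPS), 1305 blood
    and 48 BAL analytes, group decline means of -104.6 +/- 32.0 and
    -28.8 +/- 21.5 mL/year, ~6.31 +/- 0.86 years of follow-up, 8
    sex-associated blood analytes, and 23 BAL analytes failing the
    below-LLOD prevalence rule.  ``effect_size`` and ``sex_effect`` are
    standardized mean differences in log2-scale SD units.
    """

    n_greater: int = 14
    n_lesser: int = 31
    n_tepps: int = 40
    n_blood: int = 1305
    n_bal: int = 48
    n_planted: int = 20
    n_planted_bal: int = 1
    effect_size: float = 1.5
    planted_correlation: float = 0.3
    n_sex_assoc: int = 8
    sex_effect: float = 2.0
    decline_mean_greater: float = -104.6
    decline_sd_greater: float = 32.0
    decline_mean_lesser: float = -28.8
    decline_sd_lesser: float = 21.5
    male_prop_greater: float = 0.857
    male_prop_lesser: float = 0.548
    male_prop_tepps: float = 0.55
    bal_llod_quantile: float = 0.6
    n_bal_fail_lod: int = 23
    followup_years_mean: float = 6.31
    followup_years_sd: float = 0.86
    v1_fev1_mean_greater: float = 2.63
    v1_fev1_sd_greater: float = 0.60
    v1_fev1_mean_lesser: float = 2.11
    v1_fev1_sd_lesser: float = 0.66
    v1_pct_pred_mean_greater: float = 84.2
    v1_pct_pred_sd_greater: float = 13.1
    v1_pct_pred_mean_lesser: float = 71.1
    v1_pct_pred_sd_lesser: float = 17.7
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_greater": self.n_greater,
            "n_lesser": self.n_lesser,
            "n_tepps": self.n_tepps,
            "n_blood": self.n_blood,
            "n_bal": self.n_bal,
            "n_planted": self.n_planted,
            "n_planted_bal": self.n_planted_bal,
            "n_sex_assoc": self.n_sex_assoc,
            "n_bal_fail_lod": self.n_bal_fail_lod,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0 (got {v})")
        if self.n_greater == 0 or self.n_lesser == 0:
            raise ConfigurationError("both decline classes need participants")
        if self.n_planted > self.n_blood + self.n_bal:
            raise ConfigurationError("n_planted exceeds panel size")
        if self.n_planted_bal > self.n_bal:
            raise ConfigurationError("n_planted_bal exceeds n_bal")
        if self.n_sex_assoc > self.n_blood:
            raise ConfigurationError("n_sex_assoc exceeds n_blood")
        if self.n_bal_fail_lod > self.n_bal:
            raise ConfigurationError("n_bal_fail_lod exceeds n_bal")
        if not 0 <= self.planted_correlation < 1:
            raise ConfigurationError("planted_correlation must be in [0, 1)")
        if not 0.5 <= self.bal_llod_quantile < 1:
            raise ConfigurationError(
                "bal_llod_quantile must be in [0.5, 1) so constructed "
                "analytes actually fail the >= 50% rule"
            )


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort: analyte roles and class labels."""

    roles: pd.DataFrame  # analyte, compartment, role
    planted: list[str] = field(default_factory=list)
    sex_associated: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.roles.copy()


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    blood: ProteomicMatrix
    bal: ProteomicMatrix
    bal_totals: pd.Series
    lod: LODSpec
    truth: CohortTruth


def _midpoint_llod(sorted_vals: np.ndarray, k_below: int) -> float:
    """An LLOD placed so that exactly ``k_below`` realized values fall below."""
    n = len(sorted_vals)
    if k_below <= 0:
        return 0.5 * sorted_vals[0]
    if k_below >= n:
        return 2.0 * sorted_vals[-1]
    return 0.5 * (sorted_vals[k_below - 1] + sorted_vals[k_below])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort: participants, panels, LODs, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_copd = config.n_greater + config.n_lesser
    n_total = n_copd + config.n_tepps
    ids = [f"S{i:04d}" for i in range(1, n_total + 1)]
    group = np.array(["COPD"] * n_copd + ["TEPPS"] * config.n_tepps)

    # ---- decline and definitional classes ------------------------------
    # Declines are drawn from the two configured component distributions,
    # but the truth class is *definitional*: the n_greater most negative
    # realized declines among the COPD cases are the greater decliners —
    # exactly how a percentile-dichotomized progression phenotype is
    # defined — so downstream labeling round-trips the truth exactly.
    # TEPPS spirometry and analytes follow the lesser-decliner parameters
    # (the reference group resembles lesser decliners).
    draw_greater = np.zeros(n_total, dtype=bool)
    draw_greater[: config.n_greater] = True
    decl_mean = np.where(
        draw_greater, config.decline_mean_greater, config.decline_mean_lesser
    )
    decl_sd = np.where(
        draw_greater, config.decline_sd_greater, config.decline_sd_lesser
    )
    delta = rng.normal(decl_mean, decl_sd)

    copd_order = np.argsort(delta[:n_copd], kind="stable")
    is_greater = np.zeros(n_total, dtype=bool)
    is_greater[copd_order[: config.n_greater]] = True
    true_class = np.where(
        group == "TEPPS", "TEPPS", np.where(is_greater, GREATER, LESSER)
    )

    # ---- spirometry and demographics -----------------------------------
    male_p = np.where(
        is_greater,
        config.male_prop_greater,
        np.where(group == "COPD", config.male_prop_lesser, config.male_prop_tepps),
    )
    sex = np.where(rng.random(n_total) < male_p, "M", "F")

    v1_mean = np.where(
        is_greater, config.v1_fev1_mean_greater, config.v1_fev1_mean_lesser
    )
    v1_sd = np.where(
        is_greater, config.v1_fev1_sd_greater, config.v1_fev1_sd_lesser
    )
    v1 = np.clip(rng.normal(v1_mean, v1_sd), 0.8, None)
    # TEPPS have preserved spirometry at baseline
    v1[group == "TEPPS"] = np.clip(
        rng.normal(2.9, 0.55, (group == "TEPPS").sum()), 1.2, None
    )

    days = np.round(
        np.clip(
            rng.normal(config.followup_years_mean, config.followup_years_sd, n_total),
            1.0,
            None,
        )
        * DAYS_PER_YEAR
    ).astype(int)
    years = days / DAYS_PER_YEAR
    v5 = v1 + delta * years / 1000.0
    clipped = v5 < 0.3
    if clipped.any():
        v5 = np.where(clipped, 0.3, v5)
        delta = 1000.0 * (v5 - v1) / years  # keep slope consistent

    pct_mean = np.where(
        is_greater,
        config.v1_pct_pred_mean_greater,
        np.where(group == "COPD", config.v1_pct_pred_mean_lesser, 95.0),
    )
    pct_sd = np.where(
        is_greater,
        config.v1_pct_pred_sd_greater,
        np.where(group == "COPD", config.v1_pct_pred_sd_lesser, 10.0),
    )
    v1_pct = np.clip(rng.normal(pct_mean, pct_sd), 25.0, 130.0)
    v5_pct = v1_pct * v5 / v1

    base = date(2010, 11, 10)
    v1_offsets = rng.integers(0, 731, n_total)
    v1_dates = [base + timedelta(days=int(o)) for o in v1_offsets]
    v5_dates = [d1 + timedelta(days=int(d)) for d1, d in zip(v1_dates, days)]

    ics_p = np.where(
        is_greater, 0.214, np.where(group == "COPD", 0.452, 0.35)
    )
    participants = pd.DataFrame(
        {
            "id": ids,
            "group": group,
            "true_class": true_class,
            "sex": sex,
            "age": np.round(np.clip(rng.normal(63.4, 7.75, n_total), 40, 80), 1),
            "race": np.where(rng.random(n_total) < 0.82, "white", "other"),
            "height_cm": np.round(
                np.where(sex == "M", rng.normal(176, 7, n_total),
                         rng.normal(163, 6, n_total)), 1
            ),
            "smoking_status": np.where(
                rng.random(n_total) < 0.333, "current", "former"
            ),
            "pack_years": np.round(
                np.clip(rng.normal(50, 25, n_total), 20, None), 1
            ),
            "ics_use": rng.random(n_total) < ics_p,
            "v1_fev1": np.round(v1, 4),
            "v5_fev1": np.round(v5, 4),
            "v1_fev1_pct_pred": np.round(v1_pct, 2),
            "v5_fev1_pct_pred": np.round(v5_pct, 2),
            "v1_date": [d.isoformat() for d in v1_dates],
            "v5_date": [d.isoformat() for d in v5_dates],
        }
    ).set_index("id", drop=False)

    # ---- analyte panels ------------------------------------------------
    blood_ids = [f"BP{i:04d}" for i in range(1, config.n_blood + 1)]
    bal_ids = [f"BL{i:03d}" for i in range(1, config.n_bal + 1)]

    # analyte-specific baselines and spreads on the log2 scale
    blood_mu = rng.uniform(6.0, 12.0, config.n_blood)
    blood_sd = rng.uniform(0.4, 1.2, config.n_blood)
    bal_mu = rng.uniform(2.0, 8.0, config.n_bal)
    bal_sd = rng.uniform(0.5, 1.5, config.n_bal)

    # role assignment; BAL planted analytes are drawn from the analytes
    # that will pass the LOD prevalence filter
    fail_bal_idx = rng.choice(config.n_bal, config.n_bal_fail_lod, replace=False)
    fail_mask = np.zeros(config.n_bal, dtype=bool)
    fail_mask[fail_bal_idx] = True
    pass_bal_idx = np.flatnonzero(~fail_mask)
    n_planted_bal = min(config.n_planted_bal, config.n_planted, len(pass_bal_idx))
    planted_bal_idx = (
        rng.choice(pass_bal_idx, n_planted_bal, replace=False)
        if n_planted_bal
        else np.array([], dtype=int)
    )
    n_planted_blood = config.n_planted - n_planted_bal
    if n_planted_blood > config.n_blood:
        raise ConfigurationError("not enough blood analytes for planted set")
    blood_perm = rng.permutation(config.n_blood)
    planted_blood_idx = blood_perm[:n_planted_blood]
    sex_blood_idx = blood_perm[
        n_planted_blood : n_planted_blood + config.n_sex_assoc
    ]

    male = (sex == "M").astype(float)

    # one latent module factor shared by every planted analyte: the
    # planted signature is a co-varying network, not a set of independent
    # markers, so its members are pairwise correlated (|r| =
    # planted_correlation) while each keeps a marginal standardized class
    # difference of exactly effect_size
    module_factor = rng.standard_normal(n_total)
    rho = config.planted_correlation

    def panel(mu, sd, n_analytes, planted_idx, sex_idx, sign_offset) -> np.ndarray:
        z = rng.standard_normal((n_total, n_analytes))
        logv = mu + z * sd
        if len(planted_idx):
            # alternating signs: the signature has both up- and
            # down-regulated members in greater decliners
            signs = np.where(
                (np.arange(len(planted_idx)) + sign_offset) % 2 == 0, 1.0, -1.0
            )
            noise = (
                np.sqrt(rho) * np.outer(module_factor, signs)
                + np.sqrt(1 - rho) * z[:, planted_idx]
            )
            shift = config.effect_size * signs
            logv[:, planted_idx] = mu[planted_idx] + sd[planted_idx] * (
                noise + np.outer(is_greater.astype(float), shift)
            )
        if len(sex_idx):
            logv[:, sex_idx] += np.outer(male, config.sex_effect * sd[sex_idx])
        return logv

    blood_log = panel(
        blood_mu, blood_sd, config.n_blood, planted_blood_idx, sex_blood_idx, 0
    )
    bal_log = panel(
        bal_mu,
        bal_sd,
        config.n_bal,
        planted_bal_idx,
        np.array([], dtype=int),
        len(planted_blood_idx),
    )

    blood_raw = np.exp2(blood_log)
    bal_raw = np.exp2(bal_log)

    blood = ProteomicMatrix(
        pd.DataFrame(blood_raw, index=ids, columns=blood_ids), BLOOD, RAW
    )
    bal = ProteomicMatrix(
        pd.DataFrame(bal_raw, index=ids, columns=bal_ids), BAL, RAW
    )

    # per-sample total BAL protein (arbitrary units, median ~1)
    bal_totals = pd.Series(
        np.exp2(rng.normal(0.0, 0.3, n_total)), index=ids, name="total_protein"
    )

    # ---- detection limits ----------------------------------------------
    # LLODs are placed against the realized concentration distribution so
    # that exactly the configured number of analytes fails the >= 50% rule:
    # censor-prone analytes get an LLOD at the configured quantile
    # (>= 0.5), the rest at the 5th percentile.  The ULOD leaves the top
    # measurement above it so the upper-censoring rule is exercised.
    llod = np.empty(config.n_bal)
    ulod = np.empty(config.n_bal)
    k_fail = int(np.ceil(config.bal_llod_quantile * n_total))
    k_pass = int(np.floor(0.05 * n_total))
    for j in range(config.n_bal):
        sv = np.sort(bal_raw[:, j])
        k = k_fail if fail_mask[j] else k_pass
        llod[j] = _midpoint_llod(sv, k)
        ulod[j] = 0.5 * (sv[-2] + sv[-1])
        if ulod[j] <= llod[j]:
            ulod[j] = 2.0 * llod[j]
    lod = LODSpec(
        pd.DataFrame({"llod": llod, "ulod": ulod}, index=pd.Index(bal_ids))
    )

    # ---- truth ----------------------------------------------------------
    planted_names = [blood_ids[i] for i in sorted(planted_blood_idx)] + [
        bal_ids[i] for i in sorted(planted_bal_idx)
    ]
    sex_names = [blood_ids[i] for i in sorted(sex_blood_idx)]
    roles = pd.DataFrame(
        {
            "analyte": blood_ids + bal_ids,
            "compartment": [BLOOD] * config.n_blood + [BAL] * config.n_bal,
        }
    )
    roles["role"] = ROLE_NOISE
    roles.loc[roles["analyte"].isin(planted_names), "role"] = ROLE_PLANTED
    roles.loc[roles["analyte"].isin(sex_names), "role"] = ROLE_SEX
    roles = roles.set_index("analyte", drop=False)
    truth = CohortTruth(
        roles=roles, planted=planted_names, sex_associated=sex_names
    )

    logger.info(
        "generated cohort: %d greater / %d lesser / %d TEPPS; "
        "%d blood + %d BAL analytes (%d planted, %d sex-associated)",
        config.n_greater,
        config.n_lesser,
        config.n_tepps,
        config.n_blood,
        config.n_bal,
        len(planted_names),
        len(sex_names),
    )
    return SyntheticCohort(
        participants=participants,
        blood=blood,
        bal=bal,
        bal_totals=bal_totals,
        lod=lod,
        truth=truth,
    )
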