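import numpy as np
import pandas as pd
import pytest

from declinesig import preprocess as pp
from declinesig.progression import label_participants
from declinesig.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort: full participant structure, 150 blood analytes."""
    cfg = CohortConfig(n_blood=150, n_bal=48, n_planted=10, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Fully preprocessed COPD analysis frame from the small cohort."""
    c = small_cohort
    censored, flags = pp.censor_bal_lod(c.bal, c.lod)
    filtered = pp.filter_bal_analytes(censored, flags)
    blood_log, bal_log = pp.normalize_and_log(filtered, c.bal_totals, c.blood)
    merged = pp.merge_compartments(blood_log, bal_log)
    copd_ids = c.participants.index[c.participants.group == "COPD"]
    copd = type(merged)(
        merged.values.loc[copd_ids], merged.compartment, merged.scale
    )
    fm, removed = pp.sex_association_filter(
        copd, c.participants.loc[copd_ids, "sex"]
    )
    labeled, threshold = label_participants(c.participants)
    classes = labeled.loc[copd_ids, "decline_class"].to_numpy()
    planted = {
        ("blood:" if a.startswith("BP") else "bal:") + a for a in c.truth.planted
    } & set(fm.analytes)
    return {
        "X": fm.values,
        "classes": classes,
        "matrix": fm,
        "planted": planted,
        "sex_removed": removed,
        "participants": labeled,
        "threshold": threshold,
        "copd_ids": copd_ids,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20230522)


def make_separated_panel(
    n_pos=14, n_neg=31, n_noise=200, n_planted=5, effect=2.0, seed=0
):
    """A direct construction: independent noise plus shifted planted columns."""
    r = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = r.standard_normal((n, n_noise + n_planted))
    X[:n_pos, :n_planted] += effect
    cols = [f"sig{j}" for j in range(n_planted)] + [
        f"noise{j}" for j in range(n_noise)
    ]
    classes = np.array(["greater"] * n_pos + ["lesser"] * n_neg)
    return pd.DataFrame(X, columns=cols), classes, cols[:n_planted]
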