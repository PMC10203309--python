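"""End-to-end orchestration of the discovery pipeline.

Stages run in the analysis order: simulate (or load) -> preprocess ->
label -> univariate screen -> elastic-net ranking -> step-forward
selection -> random-signature null -> evaluation report -> profiles.
Every stage writes delimited-text artifacts into the output directory and
the run finishes with a manifest recording configuration, seeds, package
versions and stage timings.  A master seed spawns an independent
substream per stage, so toggling one stage does not perturb another's
randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, discovery, evaluation, io, plsda, profiles
from .datatypes import GREATER, LESSER, ConfigurationError
from .preprocess import (
    censor_bal_lod,
    filter_bal_analytes,
    merge_compartments,
    normalize_and_log,
    sex_association_filter,
)
from .progression import label_participants
from .synthdata import CohortConfig, generate_cohort
from .univariate import univariate_screen

logger = logging.getLogger(__name__)

# fixed substream index per stage (stable across stage toggling)
STAGE_STREAMS = {
    "simulate": 0,
    "rank": 1,
    "select": 2,
    "null": 3,
    "profile": 4,
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``synthetic`` holds a cohort configuration, or the four path
    fields point at existing delimited-text inputs.
    """

    outdir: str = "declinesig_run"
    seed: int = 0
    synthetic: CohortConfig | None = None
    blood_path: str | None = None
    bal_path: str | None = None
    participants_path: str | None = None
    lod_path: str | None = None
    bal_totals_path: str | None = None
    # analysis knobs
    decline_percentile: float = 30.0
    use_pct_pred: bool = False
    fdr_alpha: float = 0.05
    n_en_iterations: int = 2000
    alpha_mix: float = 0.5
    k_folds: int = 6
    max_signature_size: int = 100
    n_lv: int = 2
    n_random_signatures: int = 2000
    n_permutations: int = 10000
    n_jobs: int = 1
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate",
            "preprocess",
            "label",
            "screen",
            "rank",
            "select",
            "null",
            "evaluate",
            "profile",
        ]
    )

    def validate(self) -> None:
        if self.synthetic is None:
            needed = [self.blood_path, self.bal_path, self.participants_path]
            if any(p is None for p in needed):
                raise ConfigurationError(
                    "provide either a synthetic cohort config or paths to "
                    "blood/bal/participants tables"
                )
            bal_stages = {"preprocess"} & set(self.stages)
            if bal_stages and (self.lod_path is None or self.bal_totals_path is None):
                raise ConfigurationError(
                    "stage 'preprocess' needs lod_path and bal_totals_path"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = CohortConfig(**synth)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _stage_seed(master: int, stage: str) -> int:
    child = np.random.SeedSequence(master).spawn(len(STAGE_STREAMS))
    return int(child[STAGE_STREAMS[stage]].generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and return the output directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }
    state: dict = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise ConfigurationError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": state.get(f"{stage}_outputs", []),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


# ---------------------------------------------------------------------
# stage implementations; each reads missing inputs from disk so the CLI
# subcommands can run stages independently on a shared output directory


def _load_inputs(config: RunConfig, out: Path, state: dict) -> None:
    if "blood_raw" in state:
        return
    if (out / "blood_raw.tsv").exists():
        state["blood_raw"] = io.read_matrix(out / "blood_raw.tsv")
        state["bal_raw"] = io.read_matrix(out / "bal_raw.tsv")
        state["participants"] = io.read_participants(out / "participants.tsv")
        state["bal_totals"] = io.read_series(out / "bal_totals.tsv")
        state["lod"] = io.read_lodspec(out / "lod.tsv")
    elif config.blood_path is not None:
        state["blood_raw"] = io.read_matrix(config.blood_path)
        state["bal_raw"] = io.read_matrix(config.bal_path)
        state["participants"] = io.read_participants(config.participants_path)
        if config.bal_totals_path:
            state["bal_totals"] = io.read_series(config.bal_totals_path)
        if config.lod_path:
            state["lod"] = io.read_lodspec(config.lod_path)
    else:
        raise ConfigurationError(
            "no inputs on disk; run the simulate stage or provide paths"
        )


def stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    if config.synthetic is None:
        logger.info("no synthetic block; simulate stage loads real inputs")
        _load_inputs(config, out, state)
        return
    cc = config.synthetic
    cc.seed = _stage_seed(config.seed, "simulate")
    cohort = generate_cohort(cc)
    state.update(
        blood_raw=cohort.blood,
        bal_raw=cohort.bal,
        participants=cohort.participants,
        bal_totals=cohort.bal_totals,
        lod=cohort.lod,
        truth=cohort.truth,
    )
    io.write_matrix(cohort.blood, out / "blood_raw.tsv")
    io.write_matrix(cohort.bal, out / "bal_raw.tsv")
    io.write_participants(cohort.participants, out / "participants.tsv")
    io.write_series(cohort.bal_totals, out / "bal_totals.tsv")
    io.write_lodspec(cohort.lod, out / "lod.tsv")
    io.write_table(cohort.truth.to_frame(), out / "truth.tsv")
    state["simulate_outputs"] = [
        "blood_raw.tsv",
        "bal_raw.tsv",
        "participants.tsv",
        "bal_totals.tsv",
        "lod.tsv",
        "truth.tsv",
    ]


def stage_label(config: RunConfig, out: Path, state: dict) -> None:
    _load_inputs(config, out, state)
    labeled, threshold = label_participants(
        state["participants"],
        pct=config.decline_percentile,
        use_pct_pred=config.use_pct_pred,
    )
    state["participants"] = labeled
    state["threshold"] = threshold
    io.write_participants(labeled, out / "participants_labeled.tsv")
    state["label_outputs"] = ["participants_labeled.tsv"]


def _copd_mask(state: dict) -> pd.Series:
    p = state["participants"]
    return p["group"].eq("COPD") if "group" in p.columns else pd.Series(
        True, index=p.index
    )


def stage_preprocess(config: RunConfig, out: Path, state: dict) -> None:
    _load_inputs(config, out, state)
    if "decline_class" not in state["participants"].columns:
        stage_label(config, out, state)
    censored, flags = censor_bal_lod(state["bal_raw"], state["lod"])
    filtered = filter_bal_analytes(censored, flags)
    blood_log, bal_log = normalize_and_log(
        filtered, state["bal_totals"], state["blood_raw"]
    )
    # the sex filter is computed on the COPD analysis cohort only
    copd = _copd_mask(state)
    copd_ids = state["participants"].index[copd]
    merged_all = merge_compartments(blood_log, bal_log)
    copd_matrix = type(merged_all)(
        merged_all.values.loc[copd_ids],
        merged_all.compartment,
        merged_all.scale,
    )
    sex = state["participants"].loc[copd_ids, "sex"]
    _, removed = sex_association_filter(copd_matrix, sex, alpha=config.fdr_alpha)
    kept = [a for a in merged_all.analytes if a not in set(removed)]
    merged = merged_all.select_analytes(kept)
    state["merged"] = merged
    state["sex_removed"] = removed
    io.write_matrix(merged, out / "merged_log.tsv")
    pd.Series(removed, name="analyte").to_csv(
        out / "sex_removed.tsv", sep="\t", index=False
    )
    logger.info(
        "preprocess: %d blood + %d BAL -> %d merged features "
        "(%d sex-associated removed)",
        state["blood_raw"].n_analytes,
        state["bal_raw"].n_analytes,
        merged.n_analytes,
        len(removed),
    )
    state["preprocess_outputs"] = ["merged_log.tsv", "sex_removed.tsv"]


def _analysis_frame(config, out, state) -> tuple[pd.DataFrame, np.ndarray]:
    if "participants" not in state:
        if (out / "participants_labeled.tsv").exists():
            state["participants"] = io.read_participants(
                out / "participants_labeled.tsv"
            )
        else:
            _load_inputs(config, out, state)
    if "merged" not in state:
        if (out / "merged_log.tsv").exists():
            state["merged"] = io.read_matrix(out / "merged_log.tsv")
        else:
            stage_preprocess(config, out, state)
    if "decline_class" not in state["participants"].columns:
        if (out / "participants_labeled.tsv").exists():
            state["participants"] = io.read_participants(
                out / "participants_labeled.tsv"
            )
        else:
            stage_label(config, out, state)
    copd = _copd_mask(state)
    ids = state["participants"].index[copd]
    X = state["merged"].values.loc[ids]
    classes = state["participants"].loc[ids, "decline_class"].to_numpy()
    return X, classes


def stage_screen(config: RunConfig, out: Path, state: dict) -> None:
    X, classes = _analysis_frame(config, out, state)
    matrix = state["merged"]
    copd_matrix = type(matrix)(X, matrix.compartment, matrix.scale)
    table = univariate_screen(copd_matrix, classes)
    state["screen"] = table
    io.write_table(table, out / "univariate.tsv")
    state["screen_outputs"] = ["univariate.tsv"]


def stage_rank(config: RunConfig, out: Path, state: dict) -> None:
    X, classes = _analysis_frame(config, out, state)
    ranking = discovery.enet_selection_frequencies(
        X,
        classes,
        n_iterations=config.n_en_iterations,
        alpha_mix=config.alpha_mix,
        seed=_stage_seed(config.seed, "rank"),
        n_jobs=config.n_jobs,
    )
    state["ranking"] = ranking
    io.write_table(ranking.table.reset_index(), out / "ranking.tsv")
    state["rank_outputs"] = ["ranking.tsv"]


def _load_ranking(out: Path, state: dict) -> discovery.SelectionRanking:
    if "ranking" not in state:
        t = io.read_table(out / "ranking.tsv", index_col="analyte")
        state["ranking"] = discovery.SelectionRanking(
            table=t, n_iterations=0
        )
    return state["ranking"]


def stage_select(config: RunConfig, out: Path, state: dict) -> None:
    X, classes = _analysis_frame(config, out, state)
    ranking = _load_ranking(out, state)
    curve, optimal = discovery.step_forward_search(
        ranking,
        X,
        classes,
        k=config.k_folds,
        max_size=config.max_signature_size,
        seed=_stage_seed(config.seed, "select"),
        n_lv=config.n_lv,
    )
    minimal = discovery.minimal_signatures(curve)
    state["curve"] = curve
    state["optimal"] = optimal
    io.write_table(curve.table, out / "step_forward_curve.tsv")
    io.write_table(minimal, out / "minimal_signatures.tsv")
    pd.Series(optimal.features, name="analyte").to_csv(
        out / "optimal_signature.tsv", sep="\t", index=False
    )
    state["select_outputs"] = [
        "step_forward_curve.tsv",
        "minimal_signatures.tsv",
        "optimal_signature.tsv",
    ]


def _load_optimal(config, out, state) -> discovery.SignatureEvaluation:
    if "optimal" not in state:
        feats = pd.read_csv(out / "optimal_signature.tsv", sep="\t")[
            "analyte"
        ].tolist()
        X, classes = _analysis_frame(config, out, state)
        state["optimal"] = discovery.kfold_cv_evaluate(
            feats,
            X,
            classes,
            k=config.k_folds,
            seed=_stage_seed(config.seed, "select"),
            n_lv=config.n_lv,
        )
    return state["optimal"]


def stage_null(config: RunConfig, out: Path, state: dict) -> None:
    X, classes = _analysis_frame(config, out, state)
    optimal = _load_optimal(config, out, state)
    null = discovery.random_signature_null(
        X,
        classes,
        signature_size=len(optimal.features),
        n_random=config.n_random_signatures,
        k=config.k_folds,
        seed=_stage_seed(config.seed, "null"),
        observed_accuracy=optimal.cv["balanced_accuracy"],
        n_lv=config.n_lv,
        n_jobs=config.n_jobs,
    )
    state["null"] = null
    pd.DataFrame({"cv_balanced_accuracy": null.accuracies}).to_csv(
        out / "null_accuracies.tsv", sep="\t", index=False
    )
    (out / "null_summary.json").write_text(
        json.dumps(
            {
                "observed": null.observed,
                "empirical_p": null.empirical_p,
                "ttest_p": null.ttest_p,
                "signature_size": null.signature_size,
                "n_random": len(null.accuracies),
            },
            indent=1,
        )
    )
    state["null_outputs"] = ["null_accuracies.tsv", "null_summary.json"]


def stage_evaluate(config: RunConfig, out: Path, state: dict) -> None:
    X, classes = _analysis_frame(config, out, state)
    optimal = _load_optimal(config, out, state)
    model = plsda.fit_plsda(
        X[optimal.features], classes, n_lv=min(config.n_lv, len(optimal.features))
    )
    model = plsda.orthogonalize(model)
    (out / "plsda_model.json").write_text(model.to_json())
    lv1 = model.x_scores[:, 0]
    participants = state["participants"]
    copd = _copd_mask(state)
    ids = participants.index[copd]
    decline = participants.loc[ids, "delta_fev1"].to_numpy()
    covars = participants.loc[ids, [
        "age", "race", "height_cm", "sex", "v1_fev1_pct_pred",
        "smoking_status", "pack_years", "ics_use",
    ]]
    assoc = evaluation.adjusted_linear_association(lv1, decline, covars)
    report = {
        "signature_size": len(optimal.features),
        "cv": optimal.cv,
        "calibration": optimal.calibration,
        "cv_auc": optimal.cv_auc,
        "calibration_auc": optimal.calibration_auc,
        "lv1_variance_explained": float(model.x_variance_explained[0]),
        "lv1_decline_association": assoc,
    }
    (out / "evaluation.json").write_text(json.dumps(report, indent=1))
    io.write_table(optimal.cv_roc, out / "roc_cv.tsv")
    io.write_table(optimal.calibration_roc, out / "roc_calibration.tsv")
    state["evaluation_report"] = report
    state["model"] = model
    state["evaluate_outputs"] = [
        "plsda_model.json",
        "evaluation.json",
        "roc_cv.tsv",
        "roc_calibration.tsv",
    ]


def stage_profile(config: RunConfig, out: Path, state: dict) -> None:
    X, classes = _analysis_frame(config, out, state)
    optimal = _load_optimal(config, out, state)
    feats = optimal.features
    seed = _stage_seed(config.seed, "profile")
    # clustering of the signature
    cluster = profiles.hierarchical_cluster_eval(X[feats], classes)
    (out / "dendrogram.nwk").write_text(cluster.newick + "\n")
    # PCA of the signature over COPD + reference group
    participants = state["participants"]
    merged = state["merged"]
    all_ids = participants.index
    prof = profiles.pca_fit(merged.values.loc[all_ids, feats], n_components=2)
    outliers = profiles.hotelling_outliers(prof)
    if outliers.any():  # single removal pass, then refit
        keep = outliers.index[~outliers]
        prof = profiles.pca_fit(merged.values.loc[keep, feats], n_components=2)
    groups = participants.loc[prof.scores.index]
    group_label = np.where(
        groups["group"].eq("TEPPS"), "TEPPS", groups["decline_class"]
    )
    anova = profiles.group_score_anova(
        prof.scores.iloc[:, 0].to_numpy(), group_label, posthoc="tukey"
    )
    copd_scores = prof.scores.loc[prof.scores.index.isin(
        participants.index[_copd_mask(state)])]
    copd_groups = participants.loc[copd_scores.index, "decline_class"].to_numpy()
    perm_p = profiles.permutation_group_test(
        copd_scores, copd_groups, n_perm=config.n_permutations, seed=seed
    )
    io.write_table(prof.scores, out / "pca_scores.tsv", index=True)
    io.write_table(prof.loadings, out / "pca_loadings.tsv", index=True)
    summary = {
        "pc_variance_explained": prof.variance_explained.tolist(),
        "pc12_variance_pct": float(100 * prof.variance_explained[:2].sum()),
        "n_outliers_removed": int(outliers.sum()),
        "cluster_sensitivity": cluster.sensitivity,
        "cluster_specificity": cluster.specificity,
        "cluster_misclassified": cluster.misclassified,
        "anova_f": anova["f"],
        "anova_p": anova["p"],
        "tukey": anova["comparisons"].to_dict(orient="records"),
        "permutation_p_class_separation": perm_p,
    }
    (out / "profiles.json").write_text(json.dumps(summary, indent=1))
    state["profiles_summary"] = summary
    state["profile_outputs"] = [
        "dendrogram.nwk",
        "pca_scores.tsv",
        "pca_loadings.tsv",
        "profiles.json",
    ]


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "label": stage_label,
    "preprocess": stage_preprocess,
    "screen": stage_screen,
    "rank": stage_rank,
    "select": stage_select,
    "null": stage_null,
    "evaluate": stage_evaluate,
    "profile": stage_profile,
}
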