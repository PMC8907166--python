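"""End-to-end experiment orchestration and command-line entry point.

Trains the clinical, cognitive and image-component predictors in repeated
nested cross-validation on a discovery cohort, stacks them, applies every
predictor to a validation cohort, and emits a metric table (one row per
predictor per cohort), permutation p-values, predictor comparisons and
feature-importance reports.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import time
from dataclasses import dataclass, field

import click
import numpy as np
import pandas as pd
import yaml

from . import cvlearn, evalstats, imgprep, importance, synthcohort
from .cvlearn import C_GRID, CVScheme, build_cv_scheme, oof_bac, predict_external, train_stacked, train_unimodal
from .evalstats import confusion_from_predictions, metric_panel
from .tabprep import FeatureMatrix


@dataclass
class ExperimentConfig:
    synth: synthcohort.SynthConfig = field(default_factory=synthcohort.SynthConfig)
    n_validation: int = 73
    validation_effect_multiplier: float = 0.5
    n_controls: int = 60
    outer_folds: int = 10
    outer_perms: int = 5
    inner_folds: int = 10
    inner_perms: int = 5
    c_grid: tuple = C_GRID
    n_perm: int = 1000
    fdr: float = 0.05
    gtheory_threshold: float = 0.8
    similarity_weight: float = 0.5
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = synthcohort.SynthConfig(**raw.pop("synth", {}))
        return cls(synth=synth, **raw)


def _prepare_imaging(cfg: ExperimentConfig, cohorts: dict) -> dict:
    """Control-fitted imaging pipeline: TIV -> mask -> harmonization -> residualize -> ICA."""
    ctrl_vox, ctrl_sites, ctrl_cov = synthcohort.generate_reference_controls(
        cfg.synth, cfg.n_controls, seed=cfg.seed + 11
    )
    ctrl_vox = imgprep.scale_tiv(ctrl_vox, ctrl_cov["tiv"].to_numpy())
    mask = imgprep.fit_gtheory_mask(ctrl_vox, ctrl_sites, threshold=cfg.gtheory_threshold)
    ctrl_masked = mask.apply(ctrl_vox)
    combat = imgprep.fit_combat(ctrl_masked, ctrl_sites, ctrl_cov)
    ctrl_harm = imgprep.apply_combat(combat, ctrl_masked, ctrl_sites, ctrl_cov)
    resid = imgprep.fit_covariate_betas(ctrl_harm, ctrl_cov)

    out = {"mask": mask, "combat": combat, "resid": resid}
    for name, (vox, sites, cov, refs) in cohorts.items():
        v = imgprep.scale_tiv(vox, cov["tiv"].to_numpy())
        v = mask.apply(v)
        v = imgprep.apply_combat(combat, v, sites, cov)
        v = imgprep.residualize_age_sex(resid, v, cov)
        refs_masked = imgprep.ReferenceComponents(maps=refs[mask.keep, :])
        _, loadings = imgprep.gig_ica(v, refs_masked, similarity_weight=cfg.similarity_weight)
        out[name] = imgprep.loadings_to_features(loadings)
    return out


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Full synthetic experiment; returns the report bundle and writes CSV/JSON."""
    t0 = time.time()
    outdir = pathlib.Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    synth_cfg = dataclasses.replace(cfg.synth, seed=cfg.seed)
    clin, cog, vox, y, sites, cov, truth = synthcohort.generate_cohort(synth_cfg)
    v_clin, v_cog, v_vox, v_y, v_sites, v_cov, _ = synthcohort.generate_validation_cohort(
        synth_cfg, cfg.n_validation, cfg.validation_effect_multiplier
    )

    imaging = _prepare_imaging(
        cfg,
        {
            "discovery": (vox, sites, cov, truth.component_maps),
            "validation": (v_vox, v_sites, v_cov, truth.component_maps),
        },
    )

    scheme = build_cv_scheme(
        y, cfg.outer_folds, cfg.outer_perms, cfg.inner_folds, cfg.inner_perms, seed=cfg.seed
    )

    modalities = {
        "clinical": (clin, v_clin),
        "cognitive": (cog, v_cog),
        "smri": (imaging["discovery"], imaging["validation"]),
    }
    ensembles, oofs, external = {}, {}, {}
    for name, (X, Xv) in modalities.items():
        ens, oof = train_unimodal(X, y, scheme, C_grid=cfg.c_grid)
        ensembles[name] = ens
        oofs[name] = oof
        external[name] = predict_external(ens, Xv)

    stacks = {
        "stacked_clinical_smri": ["clinical", "smri"],
        "stacked_clinical_cognitive": ["clinical", "cognitive"],
        "stacked_clinical_smri_cognitive": ["clinical", "smri", "cognitive"],
    }
    for sname, parts in stacks.items():
        ens, oof = train_stacked([oofs[p] for p in parts], y, scheme, modality_names=parts, C_grid=cfg.c_grid)
        ensembles[sname] = ens
        oofs[sname] = oof
        ext_tables = [external[p] for p in parts]
        Xv_stack = cvlearn.stack_scores(ext_tables, parts)
        external[sname] = predict_external(ens, Xv_stack)

    rows = []
    for name in list(modalities) + list(stacks):
        for cohort, (tab, labels) in {
            "discovery": (oofs[name], y),
            "validation": (external[name], v_y),
        }.items():
            c = confusion_from_predictions(labels, tab.predicted)
            panel = metric_panel(c, scores=tab.scores, labels=labels)
            row = {"predictor": name, "cohort": cohort, "n": c.n,
                   "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN}
            row.update(panel.rounded())
            rows.append(row)
    report = pd.DataFrame(rows)

    perm_results = {}
    for name in list(modalities):
        X = modalities[name][0]

        def pipeline(labels, X=X):
            sch = build_cv_scheme(
                labels, cfg.outer_folds, cfg.outer_perms, cfg.inner_folds, cfg.inner_perms, seed=cfg.seed
            )
            _, oof = train_unimodal(X, labels, sch, C_grid=cfg.c_grid)
            return oof_bac(oof, labels)

        perm_results[name] = evalstats.permutation_test(
            pipeline, y, n_perm=cfg.n_perm, seed=cfg.seed + 1
        )

    # predictor comparison over outer-fold BAC blocks
    names = list(modalities) + list(stacks)
    fold_mat = np.column_stack([oofs[n].fold_bacs(y) for n in names])
    quade_stat, quade_p, quade_pairwise = evalstats.quade_test(fold_mat)
    rs_stat, rs_p = evalstats.ranksum_test(
        oofs["clinical"].fold_bacs(y),
        _external_fold_bacs(external["clinical"], v_y, cfg, seed=cfg.seed + 3),
    )

    imp = {
        "cv_ratio": importance.cv_ratio(ensembles["clinical"]),
        "sign_consistency": importance.sign_consistency(ensembles["clinical"], fdr=cfg.fdr)
        if len(ensembles["clinical"].base) >= 10
        else None,
    }

    report.to_csv(outdir / "metrics.csv", index=False)
    imp["cv_ratio"].to_csv(outdir / "cv_ratio.csv", index=False)
    if imp["sign_consistency"] is not None:
        imp["sign_consistency"].to_csv(outdir / "sign_consistency.csv")
    log = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "elapsed_s": time.time() - t0,
        "scheme": {
            "outer_folds": cfg.outer_folds,
            "outer_perms": cfg.outer_perms,
            "inner_folds": cfg.inner_folds,
            "inner_perms": cfg.inner_perms,
        },
        "permutation_p": {k: v.p_value for k, v in perm_results.items()},
        "quade": {"statistic": quade_stat, "p": quade_p},
        "ranksum_discovery_vs_validation": {"statistic": rs_stat, "p": rs_p},
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)

    return {
        "report": report,
        "ensembles": ensembles,
        "oofs": oofs,
        "external": external,
        "permutation": perm_results,
        "quade": (quade_stat, quade_p, quade_pairwise),
        "ranksum": (rs_stat, rs_p),
        "importance": imp,
        "truth": truth,
        "log": log,
    }


def _external_fold_bacs(table, y, cfg, seed=0, n_folds=10) -> np.ndarray:
    """Bootstrap-free fold-wise BACs of external predictions (for rank-sum)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, n_folds)
    out = []
    for f in folds:
        if np.unique(y[f]).size < 2:
            continue
        out.append(cvlearn.balanced_accuracy(y[f], table.predicted[f]))
    return np.array(out)


def subgroup_metrics(scores_table, labels: np.ndarray, groups: np.ndarray) -> dict:
    """Metric panel per stratum; strata missing a class report available metrics only."""
    out = {}
    groups = np.asarray(groups)
    for g in np.unique(groups):
        rows = groups == g
        if not rows.any():
            continue
        y_g = labels[rows]
        if np.unique(y_g).size < 2:
            out[g] = None
            continue
        c = confusion_from_predictions(y_g, scores_table.predicted[rows])
        out[g] = metric_panel(c, scores=scores_table.scores[rows], labels=y_g)
    return out


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli():
    """Multimodal nested-CV prediction toolkit."""


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--n-subjects", default=109, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "outdir", default="cohort", show_default=True)
def simulate(config_path, n_subjects, seed, outdir):
    """Generate a synthetic multimodal cohort and write it to disk."""
    if config_path:
        cfg = ExperimentConfig.from_yaml(config_path).synth
    else:
        cfg = synthcohort.SynthConfig(n_subjects=n_subjects, seed=seed)
    clin, cog, vox, y, sites, cov, truth = synthcohort.generate_cohort(cfg)
    synthcohort.write_cohort(outdir, clin, cog, vox, cov, truth)
    click.echo(f"cohort written to {outdir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "outdir", default="results", show_default=True)
@click.option("--n-perm", default=99, show_default=True)
@click.option("--quick/--full", default=True, help="quick uses a reduced CV scheme")
def train(config_path, seed, outdir, n_perm, quick):
    """Run the full experiment (train, apply, test, report)."""
    if config_path:
        cfg = ExperimentConfig.from_yaml(config_path)
        cfg = dataclasses.replace(cfg, seed=seed, outdir=outdir, n_perm=n_perm)
    else:
        synth = synthcohort.SynthConfig(
            n_subjects=120, n_clinical=20, n_informative=3,
            effect_vector=np.array([1.0, 0.8, 0.8]), n_voxels=300, seed=seed,
        )
        cfg = ExperimentConfig(synth=synth, seed=seed, outdir=outdir, n_perm=n_perm, n_validation=80)
    if quick:
        cfg = dataclasses.replace(cfg, outer_folds=5, outer_perms=2, inner_folds=3, inner_perms=1)
    res = run_experiment(cfg)
    click.echo(res["report"].to_string(index=False))


@cli.command("apply")
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--data", "data_path", type=click.Path(exists=True), required=True)
@click.option("--modality", default="clinical", show_default=True)
@click.option("--out", "out_path", default="scores.csv", show_default=True)
def apply_cmd(model_path, data_path, modality, out_path):
    """Apply a serialized ensemble to a feature CSV."""
    ens = cvlearn.ensemble_from_json(model_path)
    X = FeatureMatrix.from_csv(data_path, modality=modality)
    table = predict_external(ens, X)
    table.frame().to_csv(out_path, index=False)
    click.echo(f"scores written to {out_path}")


@cli.command()
@click.option("--scores", "scores_path", type=click.Path(exists=True), required=True)
@click.option("--labels", "labels_path", type=click.Path(exists=True), required=True)
def report(scores_path, labels_path):
    """Metric panel from a scores CSV (score, predicted) and a labels CSV (label)."""
    sc = pd.read_csv(scores_path)
    y = pd.read_csv(labels_path)["label"].to_numpy()
    c = confusion_from_predictions(y, sc["predicted"].to_numpy())
    panel = metric_panel(c, scores=sc["score"].to_numpy(), labels=y)
    click.echo(json.dumps(panel.rounded(), indent=2))


@cli.command("importance")
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--fdr", default=0.05, show_default=True)
@click.option("--out", "out_path", default="importance.csv", show_default=True)
def importance_cmd(model_path, fdr, out_path):
    """Reliability report (cv-ratio + sign consistency) for a serialized ensemble."""
    ens = cvlearn.ensemble_from_json(model_path)
    df = importance.cv_ratio(ens)
    if len(ens.base) >= 10:
        rep = importance.sign_consistency(ens, fdr=fdr)
        df = df.merge(rep.table, on="feature", how="left")
    df.to_csv(out_path, index=False)
    click.echo(f"importance written to {out_path}")
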