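"""End-to-end orchestration and command-line interface.

The full analysis runs, in order: cohort generation (or ingestion) ->
feature extraction -> NMF clustering of the full cohort -> chronological
train/validation split -> primary feature selection on the training cohort
-> LASSO-Cox prognostic models per endpoint -> validation scoring ->
median-threshold risk stratification with subgroup Kaplan-Meier analyses.
Every stage writes its artifacts (CSV/JSON, plus convenience plots) under
the configured output directory, so stages can also be run one at a time
from the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as clu
from . import features as feat
from . import selection as sel
from . import survival as surv
from . import synthetic_data as synth
from .imaging_io import (ENDPOINTS, read_clinical_table, read_survival_table,
                         read_volume_pair, split_cohort, survival_frame)

log = logging.getLogger("npcradiomics")


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    lesion_kind: str = "primary"
    endpoints: list = field(default_factory=lambda: list(ENDPOINTS))
    icc_threshold: float = 0.8
    corr_cutoff: float = 0.5
    nmf_rank: int = 2
    nmf_restarts: int = 20
    nmf_max_iter: int = 500
    lambda_folds: "str | int" = "loocv"
    n_bootstrap: int = 500
    stratify_endpoint: str = "DFS"
    split_fraction: float = 200 / 303
    input_dir: "str | None" = None      # pre-existing cohort; else synthetic
    synthetic: dict = field(default_factory=dict)  # SyntheticCohortSpec kwargs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return Path(path)

    @property
    def cohort_dir(self) -> Path:
        return Path(self.input_dir) if self.input_dir else \
            Path(self.out_dir) / "cohort"


class StageError(RuntimeError):
    """An analysis stage failed; partial artifacts are preserved."""


def _timed(stage):
    def wrapper(config, *args, **kwargs):
        t0 = _time.perf_counter()
        log.info("stage %s: start", stage.__name__)
        try:
            out = stage(config, *args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {stage.__name__!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", stage.__name__,
                 _time.perf_counter() - t0)
        return out
    wrapper.__name__ = stage.__name__
    return wrapper


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@_timed
def stage_generate(config: PipelineConfig) -> Path:
    spec = synth.SyntheticCohortSpec(
        seed=config.seed, split_fraction=config.split_fraction,
        **config.synthetic)
    synth.generate_cohort(spec, config.cohort_dir)
    return config.cohort_dir


def _mask_suffix(lesion_kind: str, rater2: bool) -> str:
    base = "_mask" if lesion_kind == "primary" else "_mask_lymph_node"
    return base + ("_rater2" if rater2 else "") + ".nii.gz"


@_timed
def stage_extract(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract the 208-feature vector per patient (and per rater-2 mask)."""
    images = config.cohort_dir / "images"
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, rows_r2 = {}, {}
    for image_path in sorted(images.glob("*_image.nii.gz")):
        pid = image_path.name.replace("_image.nii.gz", "")
        mask_path = images / (pid + _mask_suffix(config.lesion_kind, False))
        volume, mask = read_volume_pair(image_path, mask_path,
                                        lesion_kind=config.lesion_kind,
                                        patient_id=pid)
        rows[pid] = feat.extract_all(volume, mask)
        r2_path = images / (pid + _mask_suffix(config.lesion_kind, True))
        if r2_path.exists():
            _, r2 = read_volume_pair(image_path, r2_path,
                                     lesion_kind=config.lesion_kind,
                                     patient_id=pid)
            rows_r2[pid] = feat.extract_all(volume, r2)
    if not rows:
        raise ValueError(f"no image/mask pairs found under {images}")
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.index.name = "patient_id"
    matrix.to_csv(out / f"features_{config.lesion_kind}.csv")
    rater2 = pd.DataFrame.from_dict(rows_r2, orient="index")
    rater2.index.name = "patient_id"
    rater2.to_csv(out / f"features_{config.lesion_kind}_rater2.csv")
    return matrix, rater2


def _load_features(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(config.out_dir)
    matrix = pd.read_csv(out / f"features_{config.lesion_kind}.csv",
                         index_col="patient_id")
    rater2 = pd.read_csv(out / f"features_{config.lesion_kind}_rater2.csv",
                         index_col="patient_id")
    return matrix, rater2


@_timed
def stage_cluster(config: PipelineConfig, matrix: pd.DataFrame | None = None,
                  ) -> dict:
    """NMF clustering of the full cohort + stage association + KM/log-rank."""
    if matrix is None:
        matrix, _ = _load_features(config)
    out = Path(config.out_dir)
    scaled = clu.minmax_scale_features(matrix)
    scaled = scaled.loc[:, scaled.sum(axis=0) > 0]
    result = clu.nmf_cluster(scaled, rank=config.nmf_rank, seed=config.seed,
                             n_restarts=config.nmf_restarts,
                             max_iter=config.nmf_max_iter)
    result.assignments.to_csv(out / "cluster_assignments.csv")

    clinical = pd.DataFrame(
        [dataclasses.asdict(r) for r in
         read_clinical_table(config.cohort_dir / "clinical.csv")]
    ).set_index("patient_id")
    clinical = clinical.loc[result.assignments.index]
    tests = {}
    for label in ("t_stage", "n_stage", "overall_stage"):
        stat, dof, p = clu.chi_squared_association(result.assignments,
                                                   clinical[label])
        tests[label] = {"statistic": stat, "df": dof, "p": p}

    records = read_survival_table(config.cohort_dir / "survival.csv")
    km_rows = []
    for endpoint in config.endpoints:
        frame = survival_frame(records, endpoint).loc[result.assignments.index]
        g1 = frame[result.assignments == 1]
        g2 = frame[result.assignments == 2]
        stat, p = clu.log_rank(g1["time"], g1["event"],
                               g2["time"], g2["event"])
        tests[f"logrank_{endpoint}"] = {"statistic": stat, "p": p}
        for gname, g in (("1", g1), ("2", g2)):
            curve = clu.kaplan_meier(g["time"], g["event"])
            for t, s in zip(curve.times, curve.survival):
                km_rows.append({"endpoint": endpoint, "cluster": gname,
                                "time": t, "survival": s})
    pd.DataFrame(km_rows).to_csv(out / "cluster_km_curves.csv", index=False)
    sizes = result.assignments.value_counts().to_dict()
    report = {"group_sizes": {str(k): int(v) for k, v in sizes.items()},
              "reconstruction_error": result.reconstruction_error,
              "tests": tests}
    (out / "cluster_report.json").write_text(json.dumps(report, indent=2))
    _plot_heatmap(scaled, result.assignments, out / "cluster_heatmap.png")
    return report


@_timed
def stage_select(config: PipelineConfig,
                 matrix: pd.DataFrame | None = None,
                 rater2: pd.DataFrame | None = None) -> sel.SelectionReport:
    """Chronological split + ICC and correlation screening on training."""
    if matrix is None:
        matrix, rater2 = _load_features(config)
    out = Path(config.out_dir)
    clinical = read_clinical_table(config.cohort_dir / "clinical.csv")
    training_ids, validation_ids = split_cohort(clinical,
                                                config.split_fraction)
    (out / "split.json").write_text(json.dumps(
        {"training": training_ids, "validation": validation_ids}, indent=2))
    dual = rater2.index.intersection(training_ids)
    report = sel.primary_selection(matrix.loc[training_ids],
                                   rater2.loc[dual],
                                   icc_threshold=config.icc_threshold,
                                   corr_cutoff=config.corr_cutoff)
    report.to_json(out / "selection_report.json")
    return report


@_timed
def stage_model(config: PipelineConfig,
                matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Radiomics / clinical / combined LASSO-Cox models per endpoint."""
    if matrix is None:
        matrix, _ = _load_features(config)
    out = Path(config.out_dir)
    split = json.loads((out / "split.json").read_text())
    report = json.loads((out / "selection_report.json").read_text())
    kept = report["kept_features"]
    clinical = pd.DataFrame(
        [dataclasses.asdict(r) for r in
         read_clinical_table(config.cohort_dir / "clinical.csv")]
    ).set_index("patient_id")
    records = read_survival_table(config.cohort_dir / "survival.csv")
    frames = {e: survival_frame(records, e) for e in config.endpoints}
    tr, va = split["training"], split["validation"]
    table, signatures = surv.run_prognostic_models(
        matrix.loc[tr], matrix.loc[va], clinical.loc[tr], clinical.loc[va],
        frames, kept, endpoints=config.endpoints,
        folds=config.lambda_folds, seed=config.seed,
        n_bootstrap=config.n_bootstrap)
    table.to_csv(out / "model_table.csv", index=False)
    (out / "signatures.json").write_text(json.dumps(
        {f"{e}_{f}": s.to_dict() for (e, f), s in signatures.items()},
        indent=2))
    comparison = surv.compare_cohorts(clinical.loc[tr], clinical.loc[va])
    comparison.to_csv(out / "cohort_comparison.csv", index=False)
    return table


@_timed
def stage_stratify(config: PipelineConfig,
                   matrix: pd.DataFrame | None = None) -> dict:
    """Median-threshold risk groups of the stratification endpoint, with
    subgroup Kaplan-Meier / log-rank analyses and a nomogram points table."""
    if matrix is None:
        matrix, _ = _load_features(config)
    out = Path(config.out_dir)
    split = json.loads((out / "split.json").read_text())
    sigs = json.loads((out / "signatures.json").read_text())
    endpoint = config.stratify_endpoint
    key = next((f"{endpoint}_{fam}"
                for fam in ("combined", "radiomics", "clinical")
                if sigs.get(f"{endpoint}_{fam}", {}).get("coefficients")),
               None)
    if key is None:
        # every penalized model for this endpoint shrank to the null model:
        # no risk score exists, so stratification is reported unavailable
        results = {"available": False, "endpoint": endpoint,
                   "reason": "no nonempty signature"}
        (out / "stratification.json").write_text(json.dumps(results,
                                                            indent=2))
        return results
    raw = sigs[key]
    signature = surv.CoxSignature(
        endpoint=raw["endpoint"], coefficients=raw["coefficients"],
        chosen_lambda=raw["chosen_lambda"],
        lambda_path=np.asarray(raw["lambda_path"]),
        means=raw["means"], sds=raw["sds"],
        entered_covariates=raw["entered_covariates"])

    clinical = pd.DataFrame(
        [dataclasses.asdict(r) for r in
         read_clinical_table(config.cohort_dir / "clinical.csv")]
    ).set_index("patient_id")
    design = pd.concat([matrix, surv.encode_clinical(clinical)], axis=1)
    tr, va = split["training"], split["validation"]
    train_scores = surv.risk_score(signature, design.loc[tr])
    valid_scores = surv.risk_score(signature, design.loc[va])
    strat = surv.stratify(train_scores, valid_scores)
    pd.DataFrame({"risk_score": valid_scores,
                  "risk_group": strat.group}).to_csv(out / "risk_groups.csv")

    records = read_survival_table(config.cohort_dir / "survival.csv")
    frame = survival_frame(records, endpoint).loc[va]
    clin_va = clinical.loc[va]
    subgroups = {
        "all": pd.Series(True, index=frame.index),
        "stage_I_II": clin_va["overall_stage"].isin(["I", "II"]),
        "stage_III_IV": clin_va["overall_stage"].isin(["III", "IV"]),
        "male": clin_va["sex"] == "male",
        "female": clin_va["sex"] == "female",
        "age_le_median": clin_va["age"] <= clin_va["age"].median(),
        "age_gt_median": clin_va["age"] > clin_va["age"].median(),
    }
    results = {"available": True, "threshold": strat.threshold,
               "endpoint": endpoint, "signature": key, "subgroups": {}}
    for name, member in subgroups.items():
        sub = frame[member.reindex(frame.index, fill_value=False)]
        groups = strat.group.loc[sub.index]
        hi, lo = sub[groups == "high"], sub[groups == "low"]
        entry = {"n_high": len(hi), "n_low": len(lo)}
        try:
            stat, p = clu.log_rank(hi["time"], hi["event"],
                                   lo["time"], lo["event"])
            entry.update({"logrank_statistic": stat, "p": p})
        except ValueError as exc:
            entry["note"] = str(exc)
        results["subgroups"][name] = entry
    (out / "stratification.json").write_text(json.dumps(results, indent=2))

    ranges = {name: (float(design.loc[tr, name].min()),
                     float(design.loc[tr, name].max()))
              for name in signature.coefficients}
    nomogram = surv.nomogram_points(signature, ranges)
    nomogram.rows.to_csv(out / "nomogram_points.csv", index=False)
    _plot_km_by_group(frame, strat.group, out / "stratified_km.png")
    return results


def run_full_analysis(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the summary report."""
    logging.basicConfig(level=logging.INFO)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    if config.input_dir is None:
        stage_generate(config)
    matrix, rater2 = stage_extract(config)
    cluster_report = stage_cluster(config, matrix)
    selection_report = stage_select(config, matrix, rater2)
    model_table = stage_model(config, matrix)
    strat_report = stage_stratify(config, matrix)
    report = {
        "n_patients": int(len(matrix)),
        "n_features": int(matrix.shape[1]),
        "cluster": cluster_report,
        "n_selected_features": len(selection_report.kept_features),
        "selected_features": selection_report.kept_features,
        "models": model_table.to_dict(orient="records"),
        "stratification": strat_report,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# Plots (conveniences; the numeric CSVs are the tested surface)
# ---------------------------------------------------------------------------

def _plot_heatmap(scaled: pd.DataFrame, assignments: pd.Series,
                  path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    order = assignments.sort_values().index
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(scaled.loc[order].T, aspect="auto", cmap="viridis")
    ax.set_xlabel("patients (sorted by cluster)")
    ax.set_ylabel("features")
    fig.savefig(path, dpi=90)
    plt.close(fig)


def _plot_km_by_group(frame: pd.DataFrame, groups: pd.Series,
                      path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in ("high", "low"):
        sub = frame[groups.loc[frame.index] == name]
        if len(sub) == 0:
            continue
        curve = clu.kaplan_meier(sub["time"], sub["event"])
        ax.step(curve.times, curve.survival, where="post",
                label=f"{name} risk (n={len(sub)})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.savefig(path, dpi=90)
    plt.close(fig)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def main() -> None:
    import click

    @click.group()
    @click.option("--log-level", default="INFO")
    def cli(log_level):
        logging.basicConfig(level=getattr(logging, log_level.upper()))

    def _config(path, seed):
        cfg = PipelineConfig.from_yaml(path)
        if seed is not None:
            cfg.seed = seed
        return cfg

    def _stage_command(name, fn):
        @cli.command(name=name)
        @click.option("--config", "config_path", required=True,
                      type=click.Path(exists=True, dir_okay=False))
        @click.option("--seed", type=int, default=None)
        def _cmd(config_path, seed):
            fn(_config(config_path, seed))

    _stage_command("generate", stage_generate)
    _stage_command("extract", stage_extract)
    _stage_command("cluster", stage_cluster)
    _stage_command("select", stage_select)
    _stage_command("model", stage_model)
    _stage_command("stratify", stage_stratify)
    _stage_command("all", run_full_analysis)
    cli()


if __name__ == "__main__":
    main()
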