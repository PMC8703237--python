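"""End-to-end pipeline: simulate -> QC -> derive -> train/evaluate ->
project -> MetaboWAS -> survival, with per-stage seeds, artifact manifest,
and deterministic re-runs.

Every stochastic stage derives its seed from the global seed plus the stage
name, so toggling stages does not reshuffle the randomness of the others, and
an identical config + seed reproduces identical artifacts (verified through
the manifest hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, metabowas as mw, qc, simulate as sim, survival as surv
from .dataset import CohortDataset
from .panel import default_panel
from .surrogate import (TrainConfig, evaluate_cv, evaluate_lobov,
                        predict_surrogate, train_surrogate)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "qc", "derive", "evaluate", "train", "project",
          "metabowas", "survival")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulate
    n_cohorts: int = 10
    cohort_size: int = 500
    cohort_shift_sd: float = 0.15
    missing_rate: float = 0.001
    zero_rate: float = 0.0005
    outlier_rate: float = 0.0005
    # input instead of simulation
    in_tsv: str | None = None
    thresholds_file: str | None = None
    # qc
    sd_limit: float = 5.0
    max_missing: int = 0
    # training / evaluation
    phenotypes: list[str] | None = None   # default: planted demo phenotypes
    n_lambda: int = 30
    inner_folds: int = 5
    inner_repeats: int = 1
    outer_folds: int = 5
    outer_repeats: int = 1
    # metabowas
    metabowas_phenotype: str | None = None
    metabowas_covariates: list[str] = field(
        default_factory=lambda: ["age", "sex"])
    # survival
    survival_log_hr: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.2
    n_families: int = 150
    cluster_col: str | None = "family_id"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def train_config(self) -> TrainConfig:
        return TrainConfig(n_lambda=self.n_lambda,
                           inner_folds=self.inner_folds,
                           inner_repeats=self.inner_repeats,
                           outer_folds=self.outer_folds,
                           outer_repeats=self.outer_repeats,
                           seed=stage_seed(self.seed, "train"))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the toggled stages; returns the run directory.

    Writes every artifact plus ``manifest.json`` mapping each output file to
    its SHA-256 hash, producing stage, and the config snapshot.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    panel = default_panel()
    artifacts: dict[str, str] = {}   # filename -> stage

    if config.thresholds_file is not None \
            and not Path(config.thresholds_file).exists():
        raise FileNotFoundError(
            f"thresholds file not found: {config.thresholds_file}")

    truth = None
    if "simulate" in enabled:
        gen = sim.demo_config(seed=stage_seed(config.seed, "simulate"),
                              n_cohorts=config.n_cohorts,
                              cohort_size=config.cohort_size,
                              cohort_shift_sd=config.cohort_shift_sd,
                              missing_rate=config.missing_rate,
                              zero_rate=config.zero_rate,
                              outlier_rate=config.outlier_rate)
        ds, truth = sim.generate_dataset(gen)
        ds = sim.plant_survival(
            ds,
            config.survival_log_hr or
            {spec.name: np.log(1.5) for spec in gen.phenotype_specs[:2]},
            censor_rate=config.censor_rate, n_families=config.n_families,
            seed=stage_seed(config.seed, "survival_gen"), truth=truth)
        ds.to_tsv(out / "dataset.tsv")
        truth.to_json(out / "truth.json")
        artifacts["dataset.tsv"] = artifacts["truth.json"] = "simulate"
    elif config.in_tsv is not None:
        ds = CohortDataset.from_tsv(config.in_tsv, panel)
    else:
        raise ValueError("either enable the simulate stage or set in_tsv")

    report = None
    if "qc" in enabled:
        ds, report = qc.run_qc(ds, panel, max_missing=config.max_missing,
                               sd_limit=config.sd_limit)
        report.to_json(out / "qc_report.json")
        ds.to_tsv(out / "qc_data.tsv")
        artifacts["qc_report.json"] = artifacts["qc_data.tsv"] = "qc"

    if "derive" in enabled:
        specs = clinical.load_threshold_specs(config.thresholds_file)
        derived = clinical.derive_all(ds.df, specs)
        derived.insert(0, "sample_id", ds.df["sample_id"].to_numpy())
        derived.to_csv(out / "clinical_derived.tsv", sep="\t", index=False,
                       na_rep="NA")
        artifacts["clinical_derived.tsv"] = "derive"

    pheno_names = config.phenotypes
    if pheno_names is None:
        pheno_names = [c for c in ds.clinical_cols
                       if c.startswith("planted_")] or []

    X = ds.metabolite_matrix()
    tc = config.train_config()
    models = {}
    if "train" in enabled or "project" in enabled:
        if not pheno_names:
            raise ValueError("train stage enabled but no phenotypes resolved")
        mdir = out / "models"
        mdir.mkdir(exist_ok=True)
        scaling = None
        if report is not None and report.scaling_mean:
            scaling = (np.array([report.scaling_mean[m]
                                 for m in ds.metabolite_cols]),
                       np.array([report.scaling_sd[m]
                                 for m in ds.metabolite_cols]))
        for name in pheno_names:
            y = ds.df[name].to_numpy(dtype=float).astype(int)
            models[name] = train_surrogate(X, y, tc,
                                           marker_names=ds.metabolite_cols,
                                           name=name, scaling=None)
            if scaling is not None:
                models[name].metadata["raw_scale_mean"] = scaling[0].tolist()
                models[name].metadata["raw_scale_sd"] = scaling[1].tolist()
            models[name].to_json(mdir / f"{name}.json")
            artifacts[f"models/{name}.json"] = "train"

    if "evaluate" in enabled:
        rows = []
        for name in pheno_names:
            y = ds.df[name].to_numpy(dtype=float).astype(int)
            cv = evaluate_cv(X, y, tc, phenotype=name)
            lob = evaluate_lobov(X, y, ds.df["cohort"].to_numpy(), tc,
                                 phenotype=name)
            rows.append({"phenotype": name, "cv_auc": cv.mean_auc,
                         "lobov_auc": lob.weighted_mean_auc,
                         "pass_cv": cv.passes, "pass_lobov": lob.passes})
            cv.to_json(out / f"eval_cv_{name}.json")
            lob.to_json(out / f"eval_lobov_{name}.json")
            artifacts[f"eval_cv_{name}.json"] = "evaluate"
            artifacts[f"eval_lobov_{name}.json"] = "evaluate"
        pd.DataFrame(rows).to_csv(out / "evaluation.tsv", sep="\t",
                                  index=False)
        artifacts["evaluation.tsv"] = "evaluate"

    surro = None
    if "project" in enabled:
        if not models:
            raise ValueError("project stage requires trained models")
        surro = pd.DataFrame({n: predict_surrogate(m, ds.metabolites())
                              for n, m in models.items()})
        surro.insert(0, "sample_id", ds.df["sample_id"].to_numpy())
        surro.to_csv(out / "surrogates.tsv", sep="\t", index=False)
        artifacts["surrogates.tsv"] = "project"

    if "metabowas" in enabled:
        target = config.metabowas_phenotype or (pheno_names[0]
                                                if pheno_names else None)
        if target is None:
            raise ValueError("metabowas stage enabled but no phenotype given")
        covs = ds.df[config.metabowas_covariates] \
            if config.metabowas_covariates else None
        res = mw.run_metabowas(ds.metabolites(), ds.df[target], covs,
                               phenotype_name=target)
        res.to_tsv(out / "metabowas.tsv")
        (out / "metabowas_summary.json").write_text(
            json.dumps(res.summary(), indent=2), encoding="utf-8")
        artifacts["metabowas.tsv"] = "metabowas"
        artifacts["metabowas_summary.json"] = "metabowas"

    if "survival" in enabled:
        if not ds.has_survival():
            raise ValueError("survival stage enabled but dataset has no "
                             "time/event columns")
        terms = list(surro.columns[1:]) if surro is not None else pheno_names
        frame = ds.df.copy()
        if surro is not None:
            for c in surro.columns[1:]:
                frame[c] = surro[c].to_numpy()
        constant = [t for t in terms if frame[t].std(ddof=1) < 1e-12]
        if constant:
            logger.warning("survival stage: dropping constant terms %s "
                           "(e.g. an all-zero surrogate model)", constant)
            terms = [t for t in terms if t not in constant]
        if not terms:
            raise ValueError("survival stage has no non-constant terms")
        assocs = []
        strata = {"all": np.ones(len(frame), dtype=bool)}
        if "sex" in frame.columns:
            strata["male"] = frame["sex"].to_numpy() == 1
            strata["female"] = frame["sex"].to_numpy() == 0
        for stratum, mask in strata.items():
            covs = ["age"] if stratum != "all" else ["age", "sex"]
            covs = [c for c in covs if c in frame.columns]
            for term in terms:
                assocs.append(surv.cox_association(
                    frame.loc[mask], term, covariates=covs,
                    cluster_col=config.cluster_col, stratum=stratum))
        surv.stratified_fdr(assocs)
        pd.DataFrame([a.to_dict() for a in assocs]).to_csv(
            out / "survival_associations.tsv", sep="\t", index=False,
            na_rep="NA")
        artifacts["survival_associations.tsv"] = "survival"
        trace = surv.stepwise_cox(frame, candidates=list(terms),
                                  fixed_covariates=[c for c in ("age", "sex")
                                                    if c in frame.columns],
                                  cluster_col=config.cluster_col)
        trace.to_json(out / "stepwise_trace.json")
        artifacts["stepwise_trace.json"] = "survival"

    manifest = {
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "artifacts": {f: {"stage": s, "sha256": _sha256(out / f)}
                      for f, s in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    logger.info("pipeline run complete: %d artifacts in %s",
                len(artifacts), out)
    return out
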