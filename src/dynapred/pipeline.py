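"""End-to-end orchestration: preprocessing -> screening -> single-source
models -> CVPIs -> stacked model -> evaluation -> landmark prediction.

Every stage writes its artifacts as tab-separated or JSON text under the
output directory and logs one structured line (inputs, outputs, timing).
All randomness flows from a single top-level seed expanded per stage.  A
run manifest records parameters, seeds, library versions and SHA-256
hashes of every artifact, so identical config + seed implies identical
manifest hashes.  With ``resume=True`` stages whose artifacts already
exist reload them instead of refitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._utils import spawn_seeds
from .coxph import fit_cox, model_chi_square
from .datasets import SurvivalDataset
from .evaluation import compare_models, kl_prediction_error
from .exceptions import ConfigurationError, DynapredError, EstimationError
from .landmark import (
    LandmarkConfig,
    SupermodelFit,
    build_landmark_stack,
    fit_supermodel_ipl_star,
    mortality_curves,
)
from ._stepfun import StepFunction
from .lasso import select_lambda_cv
from .preprocessing import (
    match_samples,
    normalize_expression,
    read_clinical_table,
    read_expression_matrix,
    univariate_gene_screen,
)
from .screening import backward_stepwise_cox, build_design, km_screen, screen_reports_frame
from .stacking import fit_super_learner, loocv_prognostic_index, representative_profiles

__all__ = ["PipelineConfig", "run_full_pipeline", "save_supermodel", "load_supermodel"]

logger = logging.getLogger(__name__)

STAGES = ["preprocess", "screen", "fit_clinical", "fit_genetic", "cvpi", "combine",
          "evaluate", "landmark"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML document."""

    clinical_path: str
    expression_path: Optional[str] = None
    out_dir: str = "dynapred_run"
    expression_normalized: bool = False
    screen_alpha: float = 0.05
    gene_alpha: float = 0.05
    stepwise_criterion: str = "aic"
    clinical_covariates: Optional[list[str]] = None  # override stepwise selection
    covariate_schema: Optional[dict] = None
    lasso_k_folds: int = 10
    lasso_repeats: int = 5
    lasso_n_lambdas: int = 30
    lasso_eps: float = 0.05
    lasso_max_nonzero: Optional[int] = None
    landmark_s_max: float = 7.0
    landmark_s_step: float = 0.1
    landmark_w: float = 5.0
    landmark_tau: Optional[float] = None
    eval_grid_start: float = 0.5
    eval_grid_stop: float = 7.0
    eval_grid_step: float = 0.5
    split_variable: Optional[str] = None
    seed: int = 0
    resume: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self):
        if not Path(self.clinical_path).exists():
            raise ConfigurationError(f"clinical_path does not exist: {self.clinical_path}")
        if self.expression_path is not None and not Path(self.expression_path).exists():
            raise ConfigurationError(f"expression_path does not exist: {self.expression_path}")

    def landmark_config(self) -> LandmarkConfig:
        grid = np.round(np.arange(0.0, self.landmark_s_max + 1e-9, self.landmark_s_step), 10)
        tau = self.landmark_tau if self.landmark_tau is not None else self.landmark_s_max
        return LandmarkConfig(s_grid=grid, w=self.landmark_w, tau=tau)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_supermodel(fit: SupermodelFit, path) -> None:
    """Serialize a landmark supermodel to self-describing JSON text."""
    doc = {
        "model": "landmark_ipl_star_supermodel",
        "coefficients": {"gamma1": fit.gamma1, "gamma2": fit.gamma2,
                         "beta0": fit.beta0, "beta1": fit.beta1},
        "config": {"s_grid": list(map(float, fit.config.s_grid)),
                   "w": fit.config.w, "tau": fit.config.tau},
        "baseline_cumhaz": {"knots": fit.baseline_cumhaz.knots.tolist(),
                            "values": fit.baseline_cumhaz.values.tolist()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_supermodel(path) -> SupermodelFit:
    doc = json.loads(Path(path).read_text())
    cfg = LandmarkConfig(s_grid=np.asarray(doc["config"]["s_grid"], dtype=float),
                         w=doc["config"]["w"], tau=doc["config"]["tau"])
    c = doc["coefficients"]
    H0 = StepFunction(np.asarray(doc["baseline_cumhaz"]["knots"], dtype=float),
                      np.asarray(doc["baseline_cumhaz"]["values"], dtype=float))
    return SupermodelFit(gamma1=c["gamma1"], gamma2=c["gamma2"], beta0=c["beta0"],
                         beta1=c["beta1"], baseline_cumhaz=H0, config=cfg, cox_fit=None)


class _Runner:
    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seeds = dict(zip(STAGES, spawn_seeds(config.seed, len(STAGES))))
        self.manifest: dict = {"config": asdict(config), "seed": config.seed,
                               "stage_seeds": self.seeds, "stages": {}, "artifacts": {}}
        self.state: dict = {}

    def _log_stage(self, name, t0, **info):
        dt = _time.time() - t0
        self.manifest["stages"][name] = {"seconds": round(dt, 3), **info}
        logger.info("stage=%s seconds=%.2f %s", name, dt,
                    " ".join(f"{k}={v}" for k, v in info.items()))

    def _write(self, name: str, df: pd.DataFrame, index=True):
        path = self.out / name
        df.to_csv(path, sep="\t", index=index)
        self.manifest["artifacts"][name] = _sha256(path)
        return path

    def _have(self, *names) -> bool:
        return self.cfg.resume and all((self.out / n).exists() for n in names)

    # ----- stages ---------------------------------------------------------

    def preprocess(self):
        t0 = _time.time()
        cfg = self.cfg
        ds = read_clinical_table(cfg.clinical_path, schema=cfg.covariate_schema)
        if cfg.expression_path is not None:
            expr = read_expression_matrix(cfg.expression_path, normalized=cfg.expression_normalized)
            if not expr.normalized:
                expr = normalize_expression(expr)
            ds = match_samples(ds, expr)
        self.state["dataset"] = ds
        self._write("matched_clinical.tsv", ds.data)
        self._log_stage("preprocess", t0, n_subjects=ds.n_subjects,
                        n_events=int(ds.status.sum()),
                        n_genes=0 if ds.expression is None else ds.expression.shape[0])

    def screen(self):
        t0 = _time.time()
        ds = self.state["dataset"]
        variables = ds.covariate_names
        reports = km_screen(ds, variables, alpha=self.cfg.screen_alpha, schema=self.cfg.covariate_schema)
        frame = screen_reports_frame(reports)
        self._write("clinical_screen.tsv", frame, index=False)
        kept = [r.variable for r in reports if r.decision == "keep"]
        self.state["km_kept"] = kept if kept else [r.variable for r in reports if not r.degenerate]

        if ds.expression is not None:
            if self._have("screened_genes.txt"):
                genes = (self.out / "screened_genes.txt").read_text().split()
            else:
                genes = univariate_gene_screen(ds.expression, ds, alpha=self.cfg.gene_alpha)
                (self.out / "screened_genes.txt").write_text("\n".join(genes) + "\n")
            self.manifest["artifacts"]["screened_genes.txt"] = _sha256(self.out / "screened_genes.txt")
            self.state["screened_genes"] = genes
        self._log_stage("screen", t0, km_kept=len(kept),
                        genes_kept=len(self.state.get("screened_genes", [])))

    def fit_clinical(self):
        t0 = _time.time()
        ds = self.state["dataset"]
        cfg = self.cfg
        if cfg.clinical_covariates:
            selected = list(cfg.clinical_covariates)
            design, groups = build_design(ds.clinical, selected, cfg.covariate_schema)
            cols = [c for v in selected for c in groups[v]]
            fit = fit_cox(design[cols], ds.time, ds.status)
        else:
            fit, selected = backward_stepwise_cox(
                ds, self.state["km_kept"], criterion=cfg.stepwise_criterion,
                schema=cfg.covariate_schema)
            if not selected:
                logger.warning("stepwise selection empty; keeping all first-screen variables")
                selected = self.state["km_kept"]
                design, groups = build_design(ds.clinical, selected, cfg.covariate_schema)
                cols = [c for v in selected for c in groups[v]]
                fit = fit_cox(design[cols], ds.time, ds.status)
        self.state["clinical_variables"] = selected
        self.state["clinical_fit"] = fit
        self._write("clinical_model.tsv", fit.summary())
        self._log_stage("fit_clinical", t0, selected=",".join(selected))

    def fit_genetic(self):
        t0 = _time.time()
        ds = self.state["dataset"]
        if ds.expression is None:
            self._log_stage("fit_genetic", t0, skipped=True)
            return
        genes = self.state["screened_genes"]
        if not genes:
            raise EstimationError("no genes passed the univariate screen")
        X = ds.expression_aligned().loc[genes].T
        cfg = self.cfg
        if self._have("selected_genes.txt", "lasso_cv.tsv"):
            selected = (self.out / "selected_genes.txt").read_text().split()
            self.manifest["artifacts"]["lasso_cv.tsv"] = _sha256(self.out / "lasso_cv.tsv")
        else:
            path = select_lambda_cv(
                X, ds.time, ds.status, k_folds=cfg.lasso_k_folds, repeats=cfg.lasso_repeats,
                seed=self.seeds["fit_genetic"], n_lambdas=cfg.lasso_n_lambdas,
                eps=cfg.lasso_eps, max_nonzero=cfg.lasso_max_nonzero)
            cv = pd.DataFrame({"lambda": path.lambda_grid, "cv_deviance": path.cv_deviance,
                               "n_nonzero": path.n_nonzero})
            self._write("lasso_cv.tsv", cv, index=False)
            selected = path.selected_genes
            if not selected:
                # fall back to the smallest penalty that admits at least one gene
                nz = np.flatnonzero(path.n_nonzero > 0)
                if nz.size == 0:
                    raise EstimationError("LASSO selected zero genes at every penalty")
                selected = list(path.coefficients.index[path.coefficients.iloc[:, nz[0]] != 0])
                logger.warning("CV minimizer selected zero genes; falling back to %d genes", len(selected))
            (self.out / "selected_genes.txt").write_text("\n".join(selected) + "\n")
        self.manifest["artifacts"]["selected_genes.txt"] = _sha256(self.out / "selected_genes.txt")
        self.state["selected_genes"] = selected
        refit = fit_cox(X[selected], ds.time, ds.status)
        self.state["genetic_fit"] = refit
        self._write("genetic_model.tsv", refit.summary())
        self._log_stage("fit_genetic", t0, n_selected=len(selected))

    def cvpi(self):
        t0 = _time.time()
        ds = self.state["dataset"]
        cfg = self.cfg
        if self._have("cvpi.tsv"):
            df = pd.read_csv(self.out / "cvpi.tsv", sep="\t", index_col=0,
                             float_precision="round_trip")
            from .stacking import CVPIVector
            self.state["cvpi_clin"] = CVPIVector(df["cvpi_clin"], source="clinical")
            if "cvpi_gene" in df:
                self.state["cvpi_gene"] = CVPIVector(df["cvpi_gene"], source="genetic")
            self.manifest["artifacts"]["cvpi.tsv"] = _sha256(self.out / "cvpi.tsv")
        else:
            design, groups = build_design(ds.clinical, self.state["clinical_variables"],
                                          cfg.covariate_schema)
            cols = [c for v in self.state["clinical_variables"] for c in groups[v]]
            self.state["cvpi_clin"] = loocv_prognostic_index(
                design[cols], ds.time, ds.status, source="clinical", subject_id=ds.subject_id)
            if "selected_genes" in self.state:
                Xg = ds.expression_aligned().loc[self.state["selected_genes"]].T
                self.state["cvpi_gene"] = loocv_prognostic_index(
                    Xg, ds.time, ds.status, source="genetic", subject_id=ds.subject_id)
            out = pd.DataFrame({"cvpi_clin": self.state["cvpi_clin"].values})
            if "cvpi_gene" in self.state:
                out["cvpi_gene"] = self.state["cvpi_gene"].values
            self._write("cvpi.tsv", out)
        self._log_stage("cvpi", t0)

    def combine(self):
        t0 = _time.time()
        ds = self.state["dataset"]
        if "cvpi_gene" not in self.state:
            self._log_stage("combine", t0, skipped=True)
            return
        sl = fit_super_learner(self.state["cvpi_clin"], self.state["cvpi_gene"],
                               ds.time, ds.status)
        self.state["super_learner"] = sl
        profiles = representative_profiles(self.state["cvpi_clin"], self.state["cvpi_gene"], sl)
        self.state["profiles"] = profiles
        self._write("profiles.tsv", profiles)
        doc = {"alpha_clin": sl.alpha_clin, "alpha_gene": sl.alpha_gene,
               "chi_square": model_chi_square(sl.cox_fit)[0]}
        (self.out / "superlearner.json").write_text(json.dumps(doc, indent=1))
        self.manifest["artifacts"]["superlearner.json"] = _sha256(self.out / "superlearner.json")
        self._log_stage("combine", t0, alpha_clin=round(sl.alpha_clin, 4),
                        alpha_gene=round(sl.alpha_gene, 4))

    def evaluate(self):
        t0 = _time.time()
        ds = self.state["dataset"]
        if "super_learner" not in self.state:
            self._log_stage("evaluate", t0, skipped=True)
            return
        sl = self.state["super_learner"]
        clin = self.state["cvpi_clin"].values
        gene = self.state["cvpi_gene"].values
        models = {
            "clinical": pd.DataFrame({"cvpi_clin": clin}),
            "genetic": pd.DataFrame({"cvpi_gene": gene}),
            "super_learner": pd.DataFrame({"cvpi_clin": clin, "cvpi_gene": gene}),
        }
        comparison = compare_models(ds, models, split_variable=self.cfg.split_variable)
        self._write("model_comparison.tsv", comparison.table, index=False)

        grid = np.arange(self.cfg.eval_grid_start,
                         min(self.cfg.eval_grid_stop, ds.time.max()) + 1e-9,
                         self.cfg.eval_grid_step)
        curves = {}
        for name, X in models.items():
            fit = fit_cox(X, ds.time, ds.status)
            S = fit.predict_survival(X, grid)
            curves[name] = kl_prediction_error(S, ds.time, ds.status, grid)
        frames = []
        for name, c in curves.items():
            f = c.to_frame()
            f.insert(0, "model", name)
            frames.append(f)
        self._write("prediction_error.tsv", pd.concat(frames, ignore_index=True), index=False)
        self.state["comparison"] = comparison
        self.state["pe_curves"] = curves
        self._log_stage("evaluate", t0, n_models=len(models))

    def landmark(self):
        t0 = _time.time()
        ds = self.state["dataset"]
        if "super_learner" not in self.state:
            self._log_stage("landmark", t0, skipped=True)
            return
        sl = self.state["super_learner"]
        config = self.cfg.landmark_config()
        stack = build_landmark_stack(ds, sl.cvpi_comb.values, config)
        self._write("landmark_stack.tsv", stack, index=False)
        fit = fit_supermodel_ipl_star(stack, config, robust_se=True)
        self.state["supermodel"] = fit
        save_supermodel(fit, self.out / "supermodel.json")
        self.manifest["artifacts"]["supermodel.json"] = _sha256(self.out / "supermodel.json")
        curves = mortality_curves(fit, self.state["profiles"])
        self._write("mortality_curves.tsv", curves, index=False)
        self._log_stage("landmark", t0, n_records=len(stack),
                        beta0=round(fit.beta0, 4), beta1=round(fit.beta1, 4))

    def run(self, until: Optional[str] = None):
        for stage in STAGES:
            getattr(self, stage)()
            if stage == until:
                break
        manifest_path = self.out / "manifest.json"
        self.manifest["versions"] = _versions()
        manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return self


def _versions() -> dict:
    import sklearn

    from . import __version__

    return {"dynapred": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__}


def run_full_pipeline(config: PipelineConfig, until: Optional[str] = None) -> dict:
    """Execute the pipeline end to end (or up to stage ``until``).

    Returns the runner state dict with every fitted object, and leaves all
    artifacts plus ``manifest.json`` in ``config.out_dir``.  Any stage
    failure propagates with the stage name in the log and all artifacts of
    completed stages preserved on disk.
    """
    runner = _Runner(config)
    try:
        runner.run(until=until)
    except DynapredError:
        logger.exception("pipeline halted; artifacts of completed stages kept in %s", runner.out)
        raise
    return runner.state
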