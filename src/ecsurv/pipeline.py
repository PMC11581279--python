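"""End-to-end orchestration: cohort -> Cox and TAN models -> report tables.

One run executes the full comparison: train/test split, univariate Cox
screen, multivariate Cox fit, network importance ranking, rank-based
variable selection, TAN fit, operating-threshold derivation on the training
set, and test-set (plus optional external-cohort) evaluation of both
models. Every stage is seeded from the single run seed, so a config
reproduces its tables byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cox as cx
from . import importance as imp
from . import metrics as mt
from . import tan
from .codebook import VariableCodebook, load_codebook
from .cohort import HORIZON_MONTHS, Cohort, read_cohort, split_cohort
from .simulate import GeneratorParams, default_generator_params, generate_cohort

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration. Exactly one input mode: simulate or read."""

    simulate_n: int | None = 618
    cohort_path: str | None = None
    codebook: VariableCodebook | str | None = None
    generator_params: GeneratorParams | None = None
    seed: int = 0
    train_fraction: float = 0.75
    tan_alpha: float = 1.0
    k_grid: tuple[int, ...] | None = None
    forced_k: int | None = None
    cv_folds: int = 5
    ties: str = "efron"
    threshold_rule: str = "youden"  # "youden" (on train) or "fixed"
    fixed_threshold: float = 0.5
    external_n: int | None = None
    external_path: str | None = None
    external_early_censoring: float = 0.1

    def __post_init__(self) -> None:
        if (self.simulate_n is None) == (self.cohort_path is None):
            raise ValueError("exactly one of simulate_n / cohort_path required")
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must lie in (0, 1]")
        if self.threshold_rule not in ("youden", "fixed"):
            raise ValueError("threshold_rule must be 'youden' or 'fixed'")
        if self.external_n is not None and self.external_path is not None:
            raise ValueError("external cohort: give either n or path, not both")


@dataclass
class ModelEvaluation:
    name: str
    confusion: mt.ConfusionMatrix
    accuracy: float
    auc: float
    threshold: float
    c_index: float
    roc: mt.RocCurve | None = None


@dataclass
class ReportBundle:
    config: PipelineConfig
    n_total: int
    n_train: int
    n_test: int
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    importance: imp.ImportanceTable
    importance_frame: pd.DataFrame
    ranked_variables: list[str]
    selected_variables: list[str]
    cox_fit: cx.CoxFit
    tan_model: tan.TanModel
    cox_eval: ModelEvaluation
    tan_eval: ModelEvaluation
    external_tan_eval: ModelEvaluation | None = None
    external_cox_eval: ModelEvaluation | None = None
    log: list[str] = field(default_factory=list)


def _survival_scores_cox(fit, baseline, cohort: Cohort) -> np.ndarray:
    lp = cx.linear_predictors(fit, cohort)
    s0 = baseline.survival_at(HORIZON_MONTHS)
    return s0 ** np.exp(lp)


def _evaluate(
    name: str,
    survival_scores: np.ndarray,
    risk_scores: np.ndarray,
    cohort: Cohort,
    threshold: float,
) -> ModelEvaluation:
    """Classification metrics on determinate records; C-index on all."""
    det_mask = cohort.label_array() >= 0
    y = cohort.label_array()[det_mask]
    s = survival_scores[det_mask]
    pred = (s >= threshold).astype(np.int64)
    cm = mt.confusion_matrix(pred, y)
    curve = mt.roc_curve(s, y)
    return ModelEvaluation(
        name=name,
        confusion=cm,
        accuracy=mt.accuracy(cm),
        auc=mt.auc(curve),
        threshold=threshold,
        c_index=mt.harrell_c_index(risk_scores, cohort.months, cohort.events),
        roc=curve,
    )


def _confusion_frame(ev: ModelEvaluation) -> pd.DataFrame:
    cm = ev.confusion
    return pd.DataFrame(
        {
            "true_alive": [cm.tp, cm.fn],
            "true_dead": [cm.fp, cm.tn],
        },
        index=pd.Index(["predicted_alive", "predicted_dead"], name=""),
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    log: list[str] = []
    seed = int(config.seed)

    # --- stage: cohort -----------------------------------------------------
    if config.simulate_n is not None:
        params = config.generator_params or default_generator_params()
        cohort, _ = generate_cohort(params, config.simulate_n, seed)
        log.append(
            f"simulate: n={config.simulate_n} seed={seed} "
            f"events={int(cohort.events.sum())}"
        )
    else:
        cb = (
            config.codebook
            if isinstance(config.codebook, VariableCodebook)
            else load_codebook(config.codebook)
        )
        cohort = read_cohort(config.cohort_path, cb)
        log.append(f"read: {config.cohort_path} n={len(cohort)}")

    # --- stage: split ------------------------------------------------------
    train, test = split_cohort(cohort, config.train_fraction, seed + 1)
    log.append(
        f"split: fraction={config.train_fraction} seed={seed + 1} "
        f"train={len(train)} test={len(test)}"
    )

    # --- stage: univariate Cox screen -------------------------------------
    uni_rows = []
    for var in cohort.codebook.names:
        try:
            res = cx.univariate_lr_test(train, var, ties=config.ties)
            uni_rows.append(
                {"variable": var, "LR": res.lr, "df": res.df, "p": res.p_value}
            )
        except ValueError as exc:
            log.append(f"univariate: {var} skipped ({exc})")
    univariate = pd.DataFrame(uni_rows)
    log.append(f"univariate screen: {len(uni_rows)} variables, ties={config.ties}")

    # --- stage: multivariate Cox ------------------------------------------
    design = cx.dummy_encode(train)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cox_fit = cx.fit_cox(design, ties=config.ties)
    for w in caught:
        log.append(f"cox warning: {w.message}")
    multivariate = cox_fit.summary_frame().reset_index(names="term")
    baseline = cx.breslow_baseline(cox_fit, design)
    log.append(
        f"multivariate cox: {len(cox_fit.column_names)} columns, "
        f"iterations={cox_fit.n_iter}, converged={cox_fit.converged}"
    )

    # --- stage: importance ranking ----------------------------------------
    full_tan = tan.fit_tan(train, alpha=config.tan_alpha)
    table = imp.build_importance_table(train, full_tan)
    ranked = table.ranked_names()
    log.append("importance ranking: " + " > ".join(ranked))

    # --- stage: variable selection ----------------------------------------
    if config.forced_k is not None:
        selected = ranked[: config.forced_k]
        log.append(f"selection: k forced to {config.forced_k}")
    else:
        grid = list(config.k_grid or range(1, len(ranked) + 1))
        selected = imp.select_top_k(
            train, ranked, grid, folds=config.cv_folds, seed=seed + 2,
            alpha=config.tan_alpha,
        )
        log.append(
            f"selection: cv folds={config.cv_folds} seed={seed + 2} "
            f"k={len(selected)}"
        )

    # --- stage: TAN fit ----------------------------------------------------
    tan_model = tan.fit_tan(
        train, selected, alpha=config.tan_alpha, root=selected[0]
    )
    log.append(
        f"tan: alpha={config.tan_alpha} root={selected[0]} "
        f"edges={list(tan_model.structure.edges)}"
    )

    # --- stage: thresholds (derived on TRAIN, frozen) ----------------------
    def thresholds_for(cohort_: Cohort) -> tuple[float, float]:
        det = cohort_.determinate()
        y = det.label_array()
        tan_scores = tan.posterior_alive_many(tan_model, det.levels)
        cox_scores = _survival_scores_cox(cox_fit, baseline, det)
        if config.threshold_rule == "fixed":
            return config.fixed_threshold, config.fixed_threshold
        return (
            mt.youden_threshold(tan_scores, y),
            mt.youden_threshold(cox_scores, y),
        )

    thr_tan, thr_cox = thresholds_for(train)
    log.append(
        f"thresholds ({config.threshold_rule}, on train): "
        f"tan={thr_tan:.6f} cox={thr_cox:.6f}"
    )

    # --- stage: test evaluation --------------------------------------------
    def eval_on(name: str, cohort_: Cohort) -> tuple[ModelEvaluation, ModelEvaluation]:
        tan_surv = tan.posterior_alive_many(tan_model, cohort_.levels)
        cox_surv = _survival_scores_cox(cox_fit, baseline, cohort_)
        cox_risk = cx.linear_predictors(cox_fit, cohort_)
        tan_ev = _evaluate(
            f"tan_{name}", tan_surv, 1.0 - tan_surv, cohort_, thr_tan
        )
        cox_ev = _evaluate(f"cox_{name}", cox_surv, cox_risk, cohort_, thr_cox)
        return tan_ev, cox_ev

    tan_eval, cox_eval = eval_on("test", test)
    log.append(
        f"test: tan acc={tan_eval.accuracy:.4f} auc={tan_eval.auc:.4f} "
        f"c={tan_eval.c_index:.4f} | cox acc={cox_eval.accuracy:.4f} "
        f"auc={cox_eval.auc:.4f} c={cox_eval.c_index:.4f}"
    )

    # --- stage: optional external cohort ------------------------------------
    external_tan_eval = external_cox_eval = None
    if config.external_n is not None or config.external_path is not None:
        if config.external_n is not None:
            params_ext = default_generator_params(
                early_censoring_rate=config.external_early_censoring
            )
            external, _ = generate_cohort(params_ext, config.external_n, seed + 3)
            log.append(
                f"external: simulated n={config.external_n} seed={seed + 3} "
                f"early_censoring={config.external_early_censoring}"
            )
        else:
            external = read_cohort(config.external_path, cohort.codebook)
            log.append(f"external: read {config.external_path} n={len(external)}")
        external_tan_eval, external_cox_eval = eval_on("external", external)
        log.append(
            f"external: tan acc={external_tan_eval.accuracy:.4f} "
            f"cox acc={external_cox_eval.accuracy:.4f}"
        )
    else:
        log.append("external: none")

    return ReportBundle(
        config=config,
        n_total=len(cohort),
        n_train=len(train),
        n_test=len(test),
        univariate=univariate,
        multivariate=multivariate,
        importance=table,
        importance_frame=table.to_frame(cohort.codebook),
        ranked_variables=ranked,
        selected_variables=list(selected),
        cox_fit=cox_fit,
        tan_model=tan_model,
        cox_eval=cox_eval,
        tan_eval=tan_eval,
        external_tan_eval=external_tan_eval,
        external_cox_eval=external_cox_eval,
        log=log,
    )


def _metrics_frame(evals: list[ModelEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [e.name for e in evals],
            "c_index": [e.c_index for e in evals],
            "accuracy_pct": [100.0 * e.accuracy for e in evals],
            "auc": [e.auc for e in evals],
            "threshold": [e.threshold for e in evals],
        }
    )


def _roc_frame(ev: ModelEvaluation) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": ev.roc.thresholds,
            "fpr": ev.roc.fpr,
            "tpr": ev.roc.tpr,
        }
    )


def render_report(bundle: ReportBundle, out_dir) -> list[Path]:
    """Write the bundle as stable-named CSV tables plus a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index, float_format="%.10g")
        written.append(path)

    save(bundle.univariate, "univariate_cox.csv")
    save(bundle.multivariate, "multivariate_cox.csv")
    save(bundle.importance_frame, "importance.csv")
    save(_confusion_frame(bundle.cox_eval), "confusion_cox_test.csv", index=True)
    save(_confusion_frame(bundle.tan_eval), "confusion_tan_test.csv", index=True)
    save(_metrics_frame([bundle.cox_eval, bundle.tan_eval]), "metrics_test.csv")
    log = list(bundle.log)
    if bundle.external_tan_eval is not None:
        save(
            _confusion_frame(bundle.external_tan_eval),
            "confusion_tan_external.csv",
            index=True,
        )
        save(
            _metrics_frame([bundle.external_cox_eval, bundle.external_tan_eval]),
            "metrics_external.csv",
        )
    else:
        log.append("render: external tables omitted (no external cohort)")
    save(_roc_frame(bundle.cox_eval), "roc_cox_test.csv")
    save(_roc_frame(bundle.tan_eval), "roc_tan_test.csv")
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n", encoding="utf-8")
    written.append(log_path)
    return written
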