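"""Canonical benchmark runs on the default synthetic cohort.

Two reference computations, shared by the test suite and the acceptance
script:

* :func:`calibration_sensitivities` — fit every OOD detector family on one
  training split of the benchmark cohort, calibrate its threshold with the
  sensitivity-constrained rule, and report the sensitivity each family
  actually achieves on its calibration exercise windows;
* :func:`detection_and_classification` — five-fold subject-wise evaluation
  of the proxy-trained random forest detector (engineered features) and of
  pooled random-forest classification at exercise and simple-motion
  grouping.

FCN-dependent families run at test-scale settings (few epochs, higher
learning rate, capped training subsample); the calibration guarantee is a
property of the threshold rule, not of model quality, so it must hold at
any training budget.
"""

from __future__ import annotations

import logging

import numpy as np

from .evaluation import make_cv_plan
from .pipeline import (
    DETECTOR_KINDS,
    CohortData,
    ExperimentConfig,
    FoldRunner,
    build_cohort_data,
    stage_seed,
)
from .synthetic import default_benchmark_config, generate_cohort

logger = logging.getLogger(__name__)

#: test-scale FCN settings used by every benchmark entry point
BENCH_FCN = dict(
    fcn_epochs=4,
    fcn_learning_rate=0.001,
    fcn_batch_size=64,
    fcn_max_train_windows=256,
    max_embedding_fit_windows=400,
    max_calibration_windows=400,
)


def benchmark_data(seed: int = 7) -> CohortData:
    """Generate and preprocess the default benchmark cohort."""
    cohort = generate_cohort(default_benchmark_config(seed=seed))
    return build_cohort_data(cohort)


def calibration_sensitivities(
    data: CohortData,
    seed: int = 0,
    detectors: tuple = DETECTOR_KINDS,
    grouping: str = "exercise",
    fold: int = 0,
) -> dict[str, float]:
    """Achieved calibration sensitivity per detector family (one fold).

    For patient-specific families the reported value is the minimum over
    the fold's per-subject detectors.
    """
    cfg = ExperimentConfig(
        groupings=(grouping,),
        detectors=tuple(detectors),
        classifiers=(),
        seed=seed,
        **BENCH_FCN,
    )
    plan = make_cv_plan(data.manifest, n_folds=cfg.n_folds, seed=stage_seed(seed, "cv"))
    runner = FoldRunner(data, plan, fold, cfg)
    out: dict[str, float] = {}
    for kind in detectors:
        fitted = runner.fit_detector(kind, grouping)
        if isinstance(fitted, dict):
            vals = [d.calibration_info["achieved_sensitivity"] for d in fitted.values()]
            out[kind] = float(min(vals))
        else:
            out[kind] = float(fitted.calibration_info["achieved_sensitivity"])
        logger.info("calibration sensitivity %-24s %.4f", kind, out[kind])
    return out


def detection_and_classification(data: CohortData, seed: int = 0) -> dict[str, float]:
    """Proxy-RF OOD AUROC and pooled-RF accuracy on held-out subjects.

    Returns cross-validation means: ``ood_auroc`` (clinic-style, proxy
    random forest on engineered features), ``accuracy_exercise`` and
    ``accuracy_simple_motion`` (pooled random forest), over five
    subject-wise folds.
    """
    cfg = ExperimentConfig(
        groupings=("exercise", "simple_motion"),
        detectors=("proxy_rf_engineered",),
        classifiers=("rf_engineered",),
        seed=seed,
        **BENCH_FCN,
    )
    plan = make_cv_plan(data.manifest, n_folds=cfg.n_folds, seed=stage_seed(seed, "cv"))
    aurocs, acc_ex, acc_sm = [], [], []
    for fold in range(cfg.n_folds):
        runner = FoldRunner(data, plan, fold, cfg)
        det = runner.fit_detector("proxy_rf_engineered", "exercise")
        rows = runner.evaluate_detector_clinic("proxy_rf_engineered", "exercise", det)
        aurocs += [r["value"] for r in rows if r["metric"] == "auroc"]
        for grouping, sink in (("exercise", acc_ex), ("simple_motion", acc_sm)):
            clf = runner.fit_classifier("rf_engineered", grouping)
            rows = runner.evaluate_classifier("rf_engineered", grouping, clf)
            sink += [r["value"] for r in rows if r["metric"] == "accuracy"]
        logger.info("fold %d: auroc=%.4f", fold, aurocs[-1])
    return {
        "ood_auroc": float(np.mean(aurocs)),
        "accuracy_exercise": float(np.mean(acc_ex)),
        "accuracy_simple_motion": float(np.mean(acc_sm)),
    }
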