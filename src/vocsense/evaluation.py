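"""Cross-method evaluation: confusion matrices, replicate simulation
studies, and robustness of the classifiers to retention-time jitter.

The replicate study is the package's acceptance surface: because the
original patient chromatograms are not deposited, headline sensitivity and
specificity are assessed as medians over independently seeded synthetic
cohorts run end-to-end through both classification methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .simulate import simulate_cohort

METHOD1 = "method1"  # stepwise LDA
METHOD2 = "method2"  # PLS-DA factor sweep


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 classification counts with cancer as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        """Percent of cancer cases correctly predicted, one decimal."""
        return round(100.0 * self.tp / (self.tp + self.fn), 1)

    @property
    def specificity(self) -> float:
        """Percent of controls correctly predicted, one decimal."""
        return round(100.0 * self.tn / (self.fp + self.tn), 1)

    @property
    def accuracy(self) -> float:
        return round(100.0 * (self.tp + self.tn) / self.n, 1)

    def to_table(self) -> pd.DataFrame:
        """Two-row predicted-group-membership table (counts and percent)."""
        pos, neg = self.tp + self.fn, self.fp + self.tn
        return pd.DataFrame({
            "true_group": ["cancer", "control"],
            "predicted_cancer": [self.tp, self.fp],
            "predicted_cancer_pct": [round(100.0 * self.tp / pos, 1),
                                     round(100.0 * self.fp / neg, 1)],
            "predicted_control": [self.fn, self.tn],
            "predicted_control_pct": [round(100.0 * self.fn / pos, 1),
                                      round(100.0 * self.tn / neg, 1)],
            "total": [pos, neg],
        })


def confusion(labels, predictions, positive=1) -> ConfusionMatrix:
    """Exact 2x2 counts from paired label/prediction sequences."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs "
                         f"{predictions.shape} predictions")
    is_pos = labels == positive
    if not (is_pos.any() and (~is_pos).any()):
        raise ValueError("labels must contain both classes")
    pred_pos = predictions == positive
    return ConfusionMatrix(tp=int(np.sum(is_pos & pred_pos)),
                           fn=int(np.sum(is_pos & ~pred_pos)),
                           fp=int(np.sum(~is_pos & pred_pos)),
                           tn=int(np.sum(~is_pos & ~pred_pos)))


@dataclass
class ReplicateSummary:
    """Per-seed metrics plus medians/extremes and provenance."""

    table: pd.DataFrame
    config_fingerprint: str
    seeds: list[int] = field(default_factory=list)

    def median(self, column: str) -> float:
        return float(self.table[column].median())

    def summary(self) -> pd.DataFrame:
        metrics = [c for c in self.table.columns if c != "seed"]
        return self.table[metrics].agg(["median", "min", "max"])


def _run_method1(cohort, loocv_kwargs) -> dict[str, float]:
    from .lda import loocv

    cm = loocv(cohort, **loocv_kwargs)
    return {"method1_loo_sensitivity": cm.sensitivity,
            "method1_loo_specificity": cm.specificity,
            "method1_loo_accuracy": cm.accuracy}


def _run_method2(cohort, max_factors, best_factor_range) -> dict[str, float]:
    from .pls import loocv_sweep

    sweep = loocv_sweep(cohort, max_factors=max_factors)
    sel = sweep[sweep["n_factors"].isin(best_factor_range)]
    # best factor count in the range by overall LOO correct count
    total = sel["loo_cancer_correct"] + sel["loo_control_correct"]
    best = sel.loc[total.idxmax()]
    return {"method2_best_factors": float(best["n_factors"]),
            "method2_loo_sensitivity": float(best["loo_cancer_pct"]),
            "method2_loo_specificity": float(best["loo_control_pct"])}


def replicate_study(config: SimulationConfig,
                    methods=(METHOD1, METHOD2),
                    n_reps: int = 20,
                    seed_list=None,
                    loocv_kwargs: dict | None = None,
                    max_factors: int = 10,
                    best_factor_range=(8, 9, 10)) -> ReplicateSummary:
    """Run both classification methods end-to-end over seeded cohorts.

    For each seed: simulate a cohort from ``config`` (with that seed),
    standardize, and record leave-one-out sensitivity/specificity for each
    requested method.  Deterministic given (config, seed_list).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for m in methods:
        if m not in (METHOD1, METHOD2):
            raise ValueError(f"unknown method name {m!r}")
    if seed_list is None:
        seed_list = [config.seed + i for i in range(n_reps)]
    seed_list = [int(s) for s in seed_list][:n_reps]
    loocv_kwargs = loocv_kwargs or {}

    rows = []
    for seed in seed_list:
        cohort = simulate_cohort(config.replace(seed=seed))
        row: dict[str, float] = {"seed": seed}
        if METHOD1 in methods:
            row.update(_run_method1(cohort, loocv_kwargs))
        if METHOD2 in methods:
            row.update(_run_method2(cohort, max_factors, best_factor_range))
        rows.append(row)
    return ReplicateSummary(table=pd.DataFrame(rows),
                            config_fingerprint=config.fingerprint(),
                            seeds=list(seed_list))


def jitter_robustness(config: SimulationConfig, jitter_levels,
                      n_reps: int = 5,
                      methods=(METHOD1,),
                      loocv_kwargs: dict | None = None) -> pd.DataFrame:
    """Median LOO accuracy as a function of retention-time jitter.

    Re-runs the replicate study at each jitter level with every other
    parameter fixed; one row per level.
    """
    rows = []
    for level in jitter_levels:
        if level < 0:
            raise ValueError("jitter level must be >= 0")
        rep = replicate_study(config.replace(rt_jitter_frac=float(level)),
                              methods=methods, n_reps=n_reps,
                              loocv_kwargs=loocv_kwargs)
        row = {"rt_jitter_frac": float(level)}
        for col in rep.table.columns:
            if col.endswith(("accuracy", "sensitivity", "specificity")):
                row[f"median_{col}"] = rep.median(col)
        rows.append(row)
    return pd.DataFrame(rows)
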