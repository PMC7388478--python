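"""Preset variable-subset classification experiments.

Each experiment assembles a design matrix from named variable groups —
imaging PC scores, clinical (Age, BBC), family history (FDR/SDR/TDR counts
plus MBC) and TNBC — optionally dropping columns, then routes to the
estimator: an unpenalized maximum-likelihood logistic fit when the design has
two or fewer predictors, otherwise the penalized path with the full
lambda-grid repeated-CV protocol.  All experiments run on one cohort share
the same fold seeds so AUC differences are paired rather than confounded by
fold noise.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import COVARIATE_COLUMNS
from .errors import SchemaError
from .lpcr import (
    CVCurve,
    PenalizedLogisticFit,
    ROCResult,
    ConfusionDiagnostics,
    cross_validate,
    confusion_diagnostics,
    fit_penalized_logistic,
    fit_unpenalized_logistic,
    roc_with_ci,
    variable_importance,
)

__all__ = [
    "VARIABLE_GROUPS",
    "PRESETS",
    "ExperimentSpec",
    "ExperimentResult",
    "assemble_design",
    "run_experiment",
    "compare_experiments",
]

#: Non-imaging variable groups; the "imaging" group is whatever PC columns
#: the score table provides.
VARIABLE_GROUPS: dict[str, list[str]] = {
    "clinical": ["Age", "BBC"],
    "family": ["FDR.BC", "FDR.OC", "SDR.BC", "SDR.OC", "TDR.BC", "TDR.OC", "MBC"],
    "tnbc": ["TNBC"],
}

_DISTANT_RELATIVES = ["SDR.BC", "SDR.OC", "TDR.BC", "TDR.OC"]


@dataclass(frozen=True)
class ExperimentSpec:
    """Named variable-subset specification."""

    name: str
    groups: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.groups) - (set(VARIABLE_GROUPS) | {"imaging"})
        if unknown:
            raise ValueError(f"unknown variable groups {sorted(unknown)}")
        if not self.groups:
            raise ValueError("experiment needs >= 1 variable group")


#: The comparisons drawn in the study's figures, as shippable presets.
PRESETS: dict[str, ExperimentSpec] = {
    spec.name: spec
    for spec in [
        ExperimentSpec("imaging", ("imaging",)),
        ExperimentSpec("family", ("family",)),
        ExperimentSpec("clinical", ("clinical",)),
        ExperimentSpec("tnbc", ("tnbc",)),
        ExperimentSpec("imaging+tnbc", ("imaging", "tnbc")),
        ExperimentSpec("imaging+clinical", ("imaging", "clinical")),
        ExperimentSpec("imaging+family", ("imaging", "family")),
        ExperimentSpec("all-imaging", ("clinical", "family", "tnbc")),
        ExperimentSpec(
            "all-distant-relatives",
            ("imaging", "clinical", "family", "tnbc"),
            exclude=tuple(_DISTANT_RELATIVES),
        ),
        ExperimentSpec("all-family", ("imaging", "clinical", "tnbc")),
        ExperimentSpec("all", ("imaging", "clinical", "family", "tnbc")),
    ]
}


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    estimator: str  # "penalized" | "unpenalized"
    cv: CVCurve
    fit: PenalizedLogisticFit
    roc: ROCResult
    importance: list[tuple[str, float]]
    confusion: ConfusionDiagnostics
    selected: list[str]
    rng_seed: int

    @property
    def cv_auc(self) -> float:
        return self.cv.optimal_auc

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name,
            "groups": list(self.spec.groups),
            "exclude": list(self.spec.exclude),
            "estimator": self.estimator,
            "cv": self.cv.to_dict(),
            "coefficients": {
                n: c for n, c in zip(self.fit.feature_names, self.fit.coefficients.tolist())
            },
            "intercept": self.fit.intercept,
            "roc": self.roc.to_dict(),
            "importance": [[n, s] for n, s in self.importance],
            "confusion": self.confusion.to_dict(),
            "selected": self.selected,
            "rng_seed": self.rng_seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def assemble_design(
    subjects: pd.DataFrame,
    pc_scores: pd.DataFrame | None,
    spec: ExperimentSpec,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-wise concatenation of the requested groups, schema-checked.

    ``subjects`` must be indexed by subject_id (or carry a subject_id column)
    with the covariate columns plus a binary ``label``; ``pc_scores`` is the
    PC-score table indexed by subject_id (required iff "imaging" requested).
    """
    table = subjects
    if "subject_id" in table.columns:
        table = table.set_index("subject_id")
    missing_cols = [c for c in COVARIATE_COLUMNS + ["label"] if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"covariate table missing columns {missing_cols}")

    blocks: list[pd.DataFrame] = []
    for group in spec.groups:
        if group == "imaging":
            if pc_scores is None:
                raise SchemaError("spec requests imaging PCs but no score table given")
            orphans = sorted(set(table.index).symmetric_difference(pc_scores.index))
            if orphans:
                raise SchemaError(f"subject ids do not align; orphans: {orphans}")
            blocks.append(pc_scores.loc[table.index])
        else:
            blocks.append(table[VARIABLE_GROUPS[group]])
    X = pd.concat(blocks, axis=1)
    X = X.drop(columns=[c for c in spec.exclude if c in X.columns])
    if X.shape[1] < 1:
        raise SchemaError("no predictors left after exclusions")
    if X.columns.duplicated().any():
        raise SchemaError("duplicate predictor columns after assembly")
    y = table["label"].to_numpy(dtype=int)
    return X, y


def run_experiment(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ExperimentSpec,
    grid: np.ndarray | None = None,
    k: int = 5,
    L: int = 20,
    alpha: float = 1.0,
    rng_seed: int = 0,
    threshold: float = 0.5,
) -> ExperimentResult:
    """Run one experiment end to end, applying the <=2-predictor routing rule."""
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if X.shape[1] <= 2:
        estimator = "unpenalized"
        cv = cross_validate(
            Xv, y, grid=np.array([0.0]), k=k, L=L, alpha=alpha, rng_seed=rng_seed
        )
        fit = fit_unpenalized_logistic(Xv, y, feature_names=names)
    else:
        estimator = "penalized"
        cv = cross_validate(Xv, y, grid=grid, k=k, L=L, alpha=alpha, rng_seed=rng_seed)
        fit = fit_penalized_logistic(
            Xv, y, lam=cv.optimal_lambda, alpha=alpha, feature_names=names
        )
    scores = fit.predict_proba(Xv)
    roc = roc_with_ci(scores, y, rng_seed=rng_seed)
    return ExperimentResult(
        spec=spec,
        estimator=estimator,
        cv=cv,
        fit=fit,
        roc=roc,
        importance=variable_importance(fit),
        confusion=confusion_diagnostics(scores, y, threshold=threshold),
        selected=fit.selected,
        rng_seed=rng_seed,
    )


def compare_experiments(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Ranked summary table, AUC descending (stable for ties)."""
    if len(results) < 2:
        raise ValueError("need >= 2 results to compare")
    seeds = {r.rng_seed for r in results}
    if len(seeds) > 1:
        raise ValueError("results stem from different fold seeds; not comparable")
    rows = [
        {
            "name": r.spec.name,
            "estimator": r.estimator,
            "cv_auc": r.cv_auc,
            "optimal_lambda": r.cv.optimal_lambda,
            "n_selected": len(r.selected),
            "selected": ",".join(r.selected),
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    return frame.sort_values("cv_auc", ascending=False, kind="stable").reset_index(
        drop=True
    )
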