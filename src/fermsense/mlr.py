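"""Multiple-linear-regression baseline with ANOVA-based term pruning.

Ordinary least squares on the named features; terms whose coefficient
p-value exceeds alpha are removed in a single pruning pass and the reduced
model is refitted.  The overall model significance is the F-test p-value
of the refitted model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MlrModel", "fit_mlr", "predict_mlr"]


@dataclass
class MlrModel:
    intercept: float
    coefficients: dict            # feature name -> coefficient (reduced model)
    p_values: dict                # feature name -> p-value (reduced model)
    overall_p: float
    dropped: list                 # terms pruned at fit time, with their p-values
    alpha: float
    rmse: float
    r2: float

    @property
    def features(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MlrModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _design(frame: pd.DataFrame, names) -> np.ndarray:
    missing = [n for n in names if n not in frame]
    if missing:
        raise KeyError(f"missing features: {missing}")
    return frame.loc[:, list(names)].to_numpy(dtype=float)


def _check_rank(x: np.ndarray, names) -> None:
    xc = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        # point at the most collinear direction by the smallest singular vector
        _, _, vt = np.linalg.svd(xc - xc.mean(axis=0))
        weights = np.abs(vt[-1][1:])
        worst = [names[i] for i in np.argsort(weights)[::-1][:2]]
        raise ValueError(
            f"design matrix is rank-deficient; near-collinear terms include {worst}"
        )


def fit_mlr(
    features: pd.DataFrame, target, alpha: float = 0.05, feature_names=None
) -> MlrModel:
    """OLS fit with one-pass pruning of terms whose p-value exceeds alpha."""
    if feature_names is None:
        feature_names = list(features.columns)
    y = np.asarray(target, dtype=float).ravel()
    x = _design(features, feature_names)
    if x.shape[0] <= x.shape[1] + 1:
        raise ValueError("need more rows than terms plus intercept")
    _check_rank(x, feature_names)
    fit = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    pvals = dict(zip(feature_names, fit.pvalues[1:]))
    kept = [n for n in feature_names if pvals[n] <= alpha]
    dropped = [[n, float(pvals[n])] for n in feature_names if pvals[n] > alpha]
    if not kept:
        kept = feature_names  # never prune everything; keep the full model
        dropped = []
    x2 = _design(features, kept)
    fit2 = sm.OLS(y, sm.add_constant(x2, has_constant="add")).fit()
    resid = y - fit2.fittedvalues
    rmse = float(np.sqrt(np.mean(resid**2)))
    return MlrModel(
        intercept=float(fit2.params[0]),
        coefficients={n: float(c) for n, c in zip(kept, fit2.params[1:])},
        p_values={n: float(p) for n, p in zip(kept, fit2.pvalues[1:])},
        overall_p=float(fit2.f_pvalue),
        dropped=dropped,
        alpha=alpha,
        rmse=rmse,
        r2=float(fit2.rsquared),
    )


def predict_mlr(model: MlrModel, features: pd.DataFrame) -> np.ndarray:
    """Linear combination of the reduced model's terms; no clipping."""
    x = _design(features, model.features)
    coef = np.array([model.coefficients[n] for n in model.features])
    return model.intercept + x @ coef
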