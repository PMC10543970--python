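"""Connection-weight (Garson) sensitivity analysis of the soft sensors.

For hidden node j the share of input i is |w1[j,i]| / Σ_k |w1[j,k]|,
weighted by the absolute hidden-to-output weight |w2[j]|; summing over
hidden nodes and normalizing across inputs gives each input's relative
effect.  Absolute values are used throughout so effects are non-negative
and sum to one.  Because effects vary with the random initialization of
each training, the reported analysis averages several retrainings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ann import AnnModel, AnnSpec

__all__ = ["SensitivityReport", "relative_effects", "mean_effects"]


@dataclass
class SensitivityReport:
    inputs: tuple
    effects: np.ndarray            # relative effects, sum to 1
    se: np.ndarray | None = None   # standard error over retrainings
    n_retrainings: int = 1

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        d = {"input": list(self.inputs), "effect": self.effects}
        d["se"] = self.se if self.se is not None else np.zeros_like(self.effects)
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def relative_effects(model: AnnModel) -> SensitivityReport:
    """Relative effect of each input from one trained network's weights."""
    w1, _, w2, _ = model.weights
    a = np.abs(w1)                      # H × I
    rowsum = a.sum(axis=1, keepdims=True)
    if np.all(rowsum == 0):
        raise ValueError("all-zero input weights: effects are undefined")
    share = np.divide(a, rowsum, out=np.zeros_like(a), where=rowsum > 0)
    contrib = (np.abs(w2)[:, None] * share).sum(axis=0)
    total = contrib.sum()
    if total == 0:
        raise ValueError("all-zero output weights: effects are undefined")
    effects = contrib / total
    names = model.feature_names or tuple(f"x{i}" for i in range(model.n_inputs))
    return SensitivityReport(tuple(names), effects)


def mean_effects(
    spec: AnnSpec,
    x: np.ndarray,
    y: np.ndarray,
    n: int = 3,
    feature_names=None,
    seed: int | None = None,
    seeds=None,
) -> SensitivityReport:
    """Average relative effects over ``n`` retrainings from different seeds.

    Failed retrainings are excluded with a warning; fewer than two successes
    is an error.  The mean is renormalized to sum to one and the standard
    error over the retrainings is reported per input.  ``seeds`` overrides
    the per-retraining seed sequence (e.g. identical seeds give SE = 0).
    """
    from dataclasses import replace

    from .training import train_ann

    if n < 2:
        raise ValueError("need at least 2 retrainings")
    base_seed = spec.seed if seed is None else seed
    if seeds is None:
        seeds = [base_seed + 7919 * i for i in range(n)]
    elif len(seeds) != n:
        raise ValueError("seeds must have length n")
    runs = []
    for i in range(n):
        s = replace(spec, seed=int(seeds[i]))
        try:
            model = train_ann(s, x, y, feature_names=feature_names)
            runs.append(relative_effects(model))
        except Exception as exc:
            warnings.warn(f"retraining {i} failed and was excluded: {exc}")
    if len(runs) < 2:
        raise RuntimeError("fewer than 2 retrainings succeeded")
    eff = np.vstack([r.effects for r in runs])
    mean = eff.mean(axis=0)
    mean = mean / mean.sum()
    se = eff.std(axis=0, ddof=1) / np.sqrt(len(runs))
    return SensitivityReport(runs[0].inputs, mean, se, len(runs))
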