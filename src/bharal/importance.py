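"""Permutation-based relative variable importance.

One covariate at a time is randomly shuffled within its column; the
Pearson correlation between the model's predictions on the original and
the shuffled data measures how much the model relies on that covariate.
Raw importance is one minus the mean correlation over the repetitions,
and raw values are standardized to sum to one.  By default the model is
*not* refit after shuffling (predictions of the original model on
randomized inputs); an optional refit mode re-estimates the model on the
shuffled frame instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .selection import GamFit, ModelFrame, fit_habitat_gam

logger = logging.getLogger("bharal")

__all__ = ["ImportanceTable", "permutation_importance", "plot_importance"]


@dataclass
class ImportanceTable:
    """Raw (1 - mean correlation) and standardized importances."""

    table: pd.DataFrame          # variable, raw, standardized
    n_reps: int
    seed: int
    mode: str                    # "predict" or "refit"

    def __post_init__(self) -> None:
        raw = self.table["raw"].to_numpy()
        if np.any((raw < -1e-9) | (raw > 2 + 1e-9)):
            raise ValueError("raw importance out of [0, 2]")

    def top(self) -> str:
        return str(self.table.loc[self.table["standardized"].idxmax(), "variable"])


def permutation_importance(fit: GamFit, frame: ModelFrame, n_reps: int = 100,
                           seed: int = 0, refit: bool = False,
                           scale: str = "response") -> ImportanceTable:
    """Thuiller-style randomization importance for every model covariate.

    For each variable, ``n_reps`` independent within-column permutations
    are applied; predictions (response scale by default, ``scale="link"``
    for the linear predictor) are correlated with the original
    predictions, and raw importance is 1 minus the mean correlation.  A
    constant prediction vector makes the correlation undefined; the raw
    value is then set to 0 and logged.  Standardized importances sum to 1
    whenever any raw importance is positive.
    """
    if scale not in {"response", "link"}:
        raise ValueError(f"unknown scale {scale!r}")
    rng = np.random.default_rng(seed)
    data = frame.data
    variables = fit.smooth_vars + fit.linear_vars

    def predict(df: pd.DataFrame, model: GamFit) -> np.ndarray:
        return model.predict(df) if scale == "response" else model.predict_link(df)

    base = predict(data, fit)
    base_sd = base.std()
    raws = []
    for v in variables:
        if base_sd == 0:
            logger.warning("constant prediction vector; raw importance of %s -> 0", v)
            raws.append(0.0)
            continue
        corrs = np.empty(n_reps)
        for rep in range(n_reps):
            shuffled = data.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            if refit:
                refit_frame = ModelFrame(shuffled, frame.covariates,
                                         frame.n_presence, frame.n_pseudo_absence)
                model = fit_habitat_gam(refit_frame, fit.smooth_vars,
                                        fit.linear_vars,
                                        alpha=list(fit.alpha))
                pred = predict(data, model)
            else:
                pred = predict(shuffled, fit)
            if pred.std() == 0:
                corrs[rep] = 1.0 if np.allclose(pred, base) else 0.0
            else:
                corrs[rep] = stats.pearsonr(base, pred)[0]
        raws.append(1.0 - float(np.mean(corrs)))
    raws = np.asarray(raws)
    raws = np.where(np.abs(raws) < 1e-15, 0.0, raws)  # exact zero for unused terms
    total = raws.sum()
    standardized = raws / total if total > 0 else np.zeros_like(raws)
    table = pd.DataFrame({"variable": variables, "raw": raws,
                          "standardized": standardized})
    return ImportanceTable(table, n_reps, seed,
                           "refit" if refit else "predict")


def plot_importance(imp: ImportanceTable, ax=None):
    """Horizontal bar chart of standardized importances (percent)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(imp.table) + 1.5))
    t = imp.table.sort_values("standardized")
    ax.barh(t["variable"], 100 * t["standardized"], color="#4477aa")
    ax.set_xlabel("relative importance (%)")
    ax.set_title(f"permutation importance ({imp.n_reps} reps, {imp.mode})")
    ax.figure.tight_layout()
    return ax.figure
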