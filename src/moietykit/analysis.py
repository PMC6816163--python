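"""Repetition statistics, information criteria, and model ranking.

After a model has been optimized many times, this module summarizes the
repetition ensemble (per-parameter mean/sd/min/max, per-isotopologue
calculated-intensity statistics), computes goodness-of-fit criteria from
the residual sum of squares,

    AIC  = 2k + n ln(RSS / n)
    AICc = AIC + (2k^2 + 2k) / (n - k - 1)
    BIC  = n ln(RSS / n) + k ln(n)

and ranks competing models (lower criterion = better).  k is the number of
fitted parameters, n the number of data points; natural logarithms
throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError
from .model import MoietyModel
from .modeling import Dataset, EnergyFunction, OptimizationResult
from .profile import IsotopologueProfile

__all__ = [
    "ParameterStats",
    "ModelAnalysis",
    "rss",
    "information_criteria",
    "summarize_repetitions",
    "rank_models",
    "comparison_table",
]

#: Sentinel criterion value used when RSS is exactly zero (perfect fit on
#: noiseless data); ln(0) is undefined so the criterion is reported as -inf.
PERFECT_FIT = float("-inf")


@dataclass
class ParameterStats:
    name: str
    mean: float
    sd: float
    min: float
    max: float


@dataclass
class ModelAnalysis:
    """Summary of an optimization-repetition ensemble for one model."""

    model_name: str
    k: int
    n: int
    rss: float
    aic: float
    aicc: Optional[float]
    bic: float
    parameter_stats: dict[str, list[ParameterStats]] = field(default_factory=dict)
    intensity_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    best_params: dict[str, np.ndarray] = field(default_factory=dict)
    best_energies: dict[str, float] = field(default_factory=dict)
    criterion_defined: bool = True

    def criterion(self, name: str) -> Optional[float]:
        return {"AIC": self.aic, "AICc": self.aicc, "BIC": self.bic}[name]


def rss(
    observed: IsotopologueProfile | Sequence[IsotopologueProfile],
    calculated: IsotopologueProfile | Sequence[IsotopologueProfile],
) -> float:
    """Residual sum of squares over one or more matched profile pairs."""
    if isinstance(observed, IsotopologueProfile):
        observed, calculated = [observed], [calculated]  # type: ignore[list-item]
    if len(observed) != len(calculated):
        raise GridMismatchError("observed/calculated profile counts differ")
    total = 0.0
    for o, c in zip(observed, calculated):
        o.check_same_grid(c)
        total += float(((o.intensities - c.intensities) ** 2).sum())
    return total


def information_criteria(k: int, n: int, rss_value: float) -> dict[str, Optional[float]]:
    """AIC, AICc and BIC from (k, n, RSS); natural logarithms.

    RSS = 0 yields the -inf sentinel (with a warning); AICc is None when
    n <= k + 1, where the small-sample correction is undefined.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rss_value < 0:
        raise ValueError("RSS must be non-negative")
    if rss_value == 0.0:
        warnings.warn(
            "RSS is exactly zero (perfect fit); information criteria are "
            "reported as -inf",
            stacklevel=2,
        )
        aicc = PERFECT_FIT if n > k + 1 else None
        return {"AIC": PERFECT_FIT, "AICc": aicc, "BIC": PERFECT_FIT}
    log_term = n * math.log(rss_value / n)
    aic = 2 * k + log_term
    aicc = aic + (2 * k * k + 2 * k) / (n - k - 1) if n > k + 1 else None
    bic = log_term + k * math.log(n)
    return {"AIC": aic, "AICc": aicc, "BIC": bic}


def summarize_repetitions(
    result: OptimizationResult,
    model: MoietyModel,
    datasets: Sequence[Dataset],
    k_convention: str = "per_dataset",
) -> ModelAnalysis:
    """Build a :class:`ModelAnalysis` from an optimization result.

    Criteria are computed from the best-energy repetition of each block
    (the criterion estimates the fit quality of the *optimized* model).
    ``k_convention="per_dataset"`` counts every fitted parameter
    (k_model x number of blocks, the split-mode default); ``"model"``
    counts the model's free parameters once.  n is the total number of
    grid observations across datasets.
    """
    if not result.blocks or not any(result.blocks.values()):
        raise ValueError("optimization result contains no repetitions")
    if k_convention not in ("per_dataset", "model"):
        raise ValueError(f"unknown k convention {k_convention!r}")

    energies = {
        ds.name: EnergyFunction(
            model, ds, result.settings.objective, result.settings.renormalize_observed
        )
        for ds in datasets
    }
    names = model.free_parameter_names()
    k_model = model.free_parameter_count

    parameter_stats: dict[str, list[ParameterStats]] = {}
    intensity_stats: dict[str, pd.DataFrame] = {}
    best_params: dict[str, np.ndarray] = {}
    best_energies: dict[str, float] = {}

    combined_mode = "combined" in result.blocks
    total_rss = 0.0
    n = sum(e.n_observations for e in energies.values())

    def _per_dataset_params(block_name: str, rep_params: np.ndarray) -> dict[str, np.ndarray]:
        """Slice a repetition's vector into per-dataset model parameter blocks."""
        if not combined_mode:
            return {block_name: rep_params}
        if result.settings.combined_shared:
            return {ds.name: rep_params for ds in datasets}
        return {
            ds.name: rep_params[i * k_model : (i + 1) * k_model]
            for i, ds in enumerate(datasets)
        }

    for block_name, reps in result.blocks.items():
        arr = np.array([r.params for r in reps])
        parameter_stats[block_name] = [
            ParameterStats(
                name=nm, mean=float(col.mean()), sd=float(col.std(ddof=0)),
                min=float(col.min()), max=float(col.max()),
            )
            for nm, col in zip(
                names * (arr.shape[1] // k_model), arr.T
            )
        ]
        best = min(reps, key=lambda r: r.energy)
        best_params[block_name] = best.params
        best_energies[block_name] = best.energy

        per_ds = _per_dataset_params(block_name, best.params)
        for ds_name, p in per_ds.items():
            total_rss += energies[ds_name].residual_ss(p)

        # per-isotopologue calculated-intensity statistics across repetitions
        for ds_name in ([block_name] if not combined_mode else [d.name for d in datasets]):
            rows = []
            for r in reps:
                for prof in energies[ds_name].calculated_profiles(
                    _per_dataset_params(block_name, r.params)[ds_name]
                ):
                    rows.append(prof.intensities)
            mat = np.array(rows)
            intensity_stats[ds_name] = pd.DataFrame(
                {
                    "mean": mat.mean(axis=0),
                    "sd": mat.std(axis=0, ddof=0),
                    "min": mat.min(axis=0),
                    "max": mat.max(axis=0),
                }
            )

    if k_convention == "per_dataset" and not (combined_mode and result.settings.combined_shared):
        k = k_model * len(result.blocks) if not combined_mode else k_model * len(datasets)
    else:
        k = k_model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        crit = information_criteria(k, n, total_rss)
    return ModelAnalysis(
        model_name=result.model_name,
        k=k,
        n=n,
        rss=total_rss,
        aic=crit["AIC"],
        aicc=crit["AICc"],
        bic=crit["BIC"],
        parameter_stats=parameter_stats,
        intensity_stats=intensity_stats,
        best_params=best_params,
        best_energies=best_energies,
    )


def rank_models(
    analyses: Sequence[ModelAnalysis], criterion: str = "AICc"
) -> pd.DataFrame:
    """Rank models by a criterion, ascending (lower = better).

    Ties break lexicographically by model name; models whose criterion is
    undefined are ranked last and flagged in the ``defined`` column.
    """
    if criterion not in ("AIC", "AICc", "BIC"):
        raise ValueError(f"unknown selection criterion {criterion!r}")
    rows = []
    for a in analyses:
        value = a.criterion(criterion)
        rows.append(
            {
                "model": a.model_name,
                "criterion": criterion,
                "value": value if value is not None else float("nan"),
                "defined": value is not None,
                "k": a.k,
                "n": a.n,
                "RSS": a.rss,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["defined", "value", "model"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame.index = pd.RangeIndex(1, len(frame) + 1, name="rank")
    return frame


def comparison_table(
    rankings: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Compare model rankings obtained under different optimization settings.

    `rankings` maps a settings label to a :func:`rank_models` table; the
    result has one row per model and one column of ranks per label.
    """
    cols = {}
    for label, frame in rankings.items():
        cols[label] = pd.Series(frame.index.values, index=frame["model"].values)
    out = pd.DataFrame(cols)
    out.index.name = "model"
    return out
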