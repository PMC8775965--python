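"""Summary quantities for model evaluation: mean prediction error,
tumor-to-plasma ratio tables and AIC model-comparison tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummary",
    "mean_prediction_error",
    "signed_mean_prediction_error",
    "group_tp_table",
    "binding_ratio_table",
    "aic_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean tumor/plasma ratio for one (group, antibody) arm; for groups with
    both antibody arms, the binding/non-binding ratio of the means."""

    group: str
    antibody: str
    mean_tp_ratio: float
    ratio_binding_over_nonbinding: float | None = None


def _obs_pred(table) -> tuple[np.ndarray, np.ndarray]:
    rows = table.rows if hasattr(table, "rows") else table
    obs = np.asarray(rows["observed"], dtype=float)
    pred = np.asarray(rows["predicted"], dtype=float)
    if obs.size == 0:
        raise ValueError("empty prediction table")
    bad = np.nonzero(obs <= 0)[0]
    if bad.size:
        ids = rows["subject_id"].iloc[bad].tolist() if "subject_id" in rows else bad.tolist()
        raise ValueError(f"non-positive observed concentration in rows {ids}")
    return obs, pred


def mean_prediction_error(table) -> float:
    """Mean absolute percent prediction error,
    ``MPE% = (100/N) * sum |pred_i - obs_i| / obs_i``."""
    obs, pred = _obs_pred(table)
    return float(100.0 * np.mean(np.abs(pred - obs) / obs))


def signed_mean_prediction_error(table) -> float:
    """Signed variant, ``(100/N) * sum (pred_i - obs_i) / obs_i`` (positive =
    overprediction on average)."""
    obs, pred = _obs_pred(table)
    return float(100.0 * np.mean((pred - obs) / obs))


def group_tp_table(cohort) -> list[GroupSummary]:
    """Per-(group, antibody) mean tumor/plasma ratios and, where both arms are
    present, the binding/non-binding ratio of means.

    Ratios are rounded to 2 decimals for reporting; the arm ratio is computed
    from the unrounded means.  A group missing one antibody arm gets no arm
    ratio (never imputed).
    """
    df = pd.DataFrame({
        "group": [r.group for r in cohort],
        "antibody": [r.antibody for r in cohort],
        "tp": [r.observed_tumor_conc / r.observed_plasma_conc for r in cohort],
    })
    means = df.groupby(["group", "antibody"], sort=False)["tp"].mean()
    out: list[GroupSummary] = []
    for (group, antibody), m in means.items():
        ratio = None
        if antibody == "target-binding" and (group, "non-binding") in means.index:
            ratio = round(m / means[(group, "non-binding")], 2)
        out.append(GroupSummary(group=group, antibody=antibody,
                                mean_tp_ratio=round(float(m), 2),
                                ratio_binding_over_nonbinding=ratio))
    return out


def binding_ratio_table(group_means: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Binding/non-binding ratio per group from printed arm means.

    ``group_means`` maps group -> (non-binding mean T/P, binding mean T/P);
    returns the per-group ratio rounded to 2 decimals.
    """
    out = {}
    for group, (nonbind, bind) in group_means.items():
        if nonbind <= 0:
            raise ValueError(f"non-binding mean must be positive for {group}")
        out[group] = round(bind / nonbind, 2)
    return out


def aic_table(fits: Sequence, predictions: Sequence | None = None) -> pd.DataFrame:
    """Model-comparison table sorted by AIC.

    Columns: structure, n_params, loglik, aic, delta_aic (from the best) and,
    when matching prediction tables are supplied, mpe_percent.  All fits must
    be evaluated on the same cohort.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ids0 = set(fits[0].predictions["subject_id"])
    for f in fits[1:]:
        if set(f.predictions["subject_id"]) != ids0:
            raise ValueError("fits evaluated on different cohorts")
    rows = []
    for i, f in enumerate(fits):
        row = {
            "structure": f.model.structure,
            "n_params": f.n_params,
            "loglik": f.loglik,
            "aic": f.aic,
        }
        if predictions is not None:
            row["mpe_percent"] = predictions[i].mpe_percent
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["aic", "n_params"], kind="stable")
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df.reset_index(drop=True)
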