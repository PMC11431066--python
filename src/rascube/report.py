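"""OCCAM-style "Fit": the per-IV-state prediction report for a chosen model.

One row per composite predicting-IV state, carrying the training frequency,
the data and model conditional DV distributions (as percentages), the
predicted DV state (argmax of the *model* conditional; ties go to the lowest
DV state index) and the per-state %Correct — which, for a model prediction,
equals the data conditional probability of the predicted state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CategoricalDataset
from .model import RAFitResults

__all__ = ["FitRow", "build_fit_report", "fit_report_frame"]


@dataclass
class FitRow:
    """One fit-report row."""

    state: tuple[str, ...]
    frequency: float
    data_pct: tuple[float, ...]
    model_pct: tuple[float, ...]
    prediction: str
    pct_correct_state: float


def build_fit_report(
    fitted: RAFitResults,
    train: CategoricalDataset | None = None,
    test: CategoricalDataset | None = None,
    min_frequency: float = 0,
) -> list[FitRow]:
    """Rows sorted by training frequency (descending; ties by state label).

    ``min_frequency=0`` lists every composite state of the predicting IVs,
    including those unobserved in training (whose data conditionals are
    undefined); a positive threshold keeps only the higher-frequency
    combinations.
    """
    if not fitted.converged:
        raise ValueError("fit report requires a converged fit")
    data = fitted.data if train is None else train
    pred_names = list(fitted.predicting_ivs)
    dv_spec = data.spec(fitted.dv)
    table = fitted.conditional_dv_table()
    rows: list[FitRow] = []
    for _, rec in table.iterrows():
        if rec["frequency"] < min_frequency:
            continue
        labels = tuple(
            data.spec(nm).state_label(int(rec[nm])) for nm in pred_names
        )
        model_p = np.array([rec[f"model_p{z}"] for z in range(fitted.dv_card)])
        data_p = np.array([rec[f"data_p{z}"] for z in range(fitted.dv_card)])
        if np.isnan(model_p).any():
            pred_idx = int(np.argmax(data.project_counts([fitted.dv])))
        else:
            pred_idx = int(np.argmax(model_p))
        pc = float(100.0 * data_p[pred_idx]) if not np.isnan(data_p).any() else np.nan
        rows.append(
            FitRow(
                state=labels,
                frequency=float(rec["frequency"]),
                data_pct=tuple(100.0 * data_p),
                model_pct=tuple(100.0 * model_p),
                prediction=dv_spec.state_label(pred_idx),
                pct_correct_state=pc,
            )
        )
    rows.sort(key=lambda r: (-r.frequency, r.state))
    return rows


def fit_report_frame(
    fitted: RAFitResults,
    train: CategoricalDataset | None = None,
    test: CategoricalDataset | None = None,
    min_frequency: float = 0,
) -> pd.DataFrame:
    """The fit report as a DataFrame with Table-style columns."""
    data = fitted.data if train is None else train
    dv_spec = data.spec(fitted.dv)
    dv_labels = [dv_spec.state_label(z) for z in range(fitted.dv_card)]
    rows = build_fit_report(fitted, train=train, test=test, min_frequency=min_frequency)
    recs = []
    for i, r in enumerate(rows, start=1):
        rec: dict = {"row": i}
        for nm, lab in zip(fitted.predicting_ivs, r.state):
            rec[nm] = lab
        rec["frequency"] = r.frequency
        for lab, v in zip(dv_labels, r.data_pct):
            rec[f"data % {lab}"] = round(v, 1)
        for lab, v in zip(dv_labels, r.model_pct):
            rec[f"model % {lab}"] = round(v, 1)
        rec["prediction"] = r.prediction
        rec["%C"] = round(r.pct_correct_state, 1)
        recs.append(rec)
    return pd.DataFrame(recs)
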