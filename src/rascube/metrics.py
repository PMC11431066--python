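"""Model-assessment metrics for directed-system RA.

These are the quantities an OCCAM-style search report carries per model:

* ``Inf`` — normalized information captured,
  [H(p_ind) - H(p_model)] / [H(p_ind) - H(p)]; 0 for the independence
  (bottom) model, 1 for the saturated model (the data).
* ``%dH(DV)`` — percent reduction of the DV's Shannon entropy,
  100 * [H(p(DV)) - H(p_model(DV|IV))] / H(p(DV)).
* ``dBIC`` / ``dAIC`` — bottom-minus-model information criteria, with
  BIC = -2 N sum p ln q + ln(N) df; larger is better.
* likelihood-ratio significance (G^2 against chi-square with delta-df).
* ``%Correct`` on training or test data and ``%Cover`` of the predicting
  IVs' composite state space.

Log bases are intentionally mixed: entropy measures are in bits, while the
likelihood terms of BIC/AIC/G^2 use the natural log, following the standard
log-linear convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CategoricalDataset, entropy
from .model import RAFitResults
from .structures import ModelStructure

__all__ = [
    "MetricRow",
    "information_captured",
    "pct_delta_h_dv",
    "information_criteria",
    "lr_significance",
    "pct_correct",
    "pct_cover",
]


@dataclass
class MetricRow:
    """One search-report row (Table-2 column set)."""

    name: str
    level: int
    inf: float
    pct_dh_dv: float
    delta_bic: float
    delta_aic: float
    pct_correct_train: float
    pct_cover: float
    pct_correct_test: float | None = None
    p_vs_bottom: float | None = None
    incremental_p: float | None = None
    significant: bool = True
    parent: str | None = None
    delta_df: int = 0

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.inf <= 1 + 1e-9):
            raise ValueError(f"Inf out of [0,1]: {self.inf}")
        for label, v in (
            ("%C(Data)", self.pct_correct_train),
            ("%Cover", self.pct_cover),
        ):
            if not (-1e-9 <= v <= 100 + 1e-9):
                raise ValueError(f"{label} out of [0,100]: {v}")


def _h_dv_data(data: CategoricalDataset) -> float:
    return entropy(data.project_counts([data.dv_name]) / data.n)


def _h_dv_given_all_ivs_data(data: CategoricalDataset) -> float:
    """H(DV | all IVs) in the data, via sparse margins."""
    h_joint = entropy(data.marginal_weights(list(data.names)) / data.n)
    h_iv = entropy(data.marginal_weights(list(data.iv_names)) / data.n)
    return h_joint - h_iv


def information_captured(
    data: CategoricalDataset, fitted: RAFitResults, bottom: RAFitResults
) -> float:
    """Normalized information: 0 at independence, 1 at the saturated model.

    Because model and bottom share the IV margin exactly, the joint-entropy
    differences reduce to DV conditional-entropy differences:
    Inf = [H(p(DV)) - H_q(DV|pred)] / [H(p(DV)) - H_data(DV|all IVs)].
    """
    h_dv = entropy(bottom.q_fit) if bottom.fit_scope == (data.dv_name,) else _h_dv_data(data)
    h_model = fitted.h_dv_given_ivs
    h_data = _h_dv_given_all_ivs_data(data)
    num, den = h_dv - h_model, h_dv - h_data
    if den < 1e-12:
        warnings.warn(
            "data carry no DV information (H(p_ind) == H(p)); Inf defined as "
            "1 when the model reproduces the data, else 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0 if abs(h_model - h_data) < 1e-9 else 0.0
    return num / den


def pct_delta_h_dv(data: CategoricalDataset, fitted: RAFitResults) -> float:
    """Percent DV entropy reduction, 100 * dH / H(p(DV))."""
    h_dv = _h_dv_data(data)
    if h_dv <= 0:
        raise ValueError("DV has zero entropy")
    return 100.0 * (h_dv - fitted.h_dv_given_ivs) / h_dv


def information_criteria(
    data: CategoricalDataset, fitted: RAFitResults, bottom: RAFitResults
) -> tuple[float, float]:
    """(dBIC, dAIC), bottom minus model, so larger = better.

    Computed from the log-likelihood and df *differences* directly; the IV
    margin's contribution to both models cancels, which avoids the loss of
    precision of subtracting two astronomically large absolute BICs when the
    IV component's df is huge.
    """
    if not np.isfinite(fitted.cond_loglik) or not np.isfinite(bottom.cond_loglik):
        warnings.warn("infinite log-likelihood; dBIC/dAIC are -inf", RuntimeWarning)
        return -np.inf, -np.inf
    dll = fitted.cond_loglik - bottom.cond_loglik
    ddf = fitted.df - bottom.df
    n = data.n
    return 2.0 * dll - np.log(n) * ddf, 2.0 * dll - 2.0 * ddf


def lr_significance(
    data: CategoricalDataset, fitted: RAFitResults, reference: RAFitResults
) -> float:
    """Upper-tail chi-square p for G^2 = 2(LL_model - LL_reference).

    The reference must be nested within the model: each of its relations
    contained in some model relation.
    """
    for rel in reference.structure.relations:
        if not any(rel <= big for big in fitted.structure.relations):
            raise ValueError(
                f"{reference.name} is not nested within {fitted.name}"
            )
    g2 = max(0.0, 2.0 * (fitted.cond_loglik - reference.cond_loglik))
    ddf = fitted.df - reference.df
    if ddf <= 0:
        return 1.0 if g2 < 1e-8 else 0.0
    return float(stats.chi2.sf(g2, ddf))


def pct_correct(
    fitted: RAFitResults, eval_data: CategoricalDataset | None = None
) -> float:
    """Percent of cases whose argmax-conditional prediction is correct.

    Ties go to the lowest DV state index; composite IV states absent from
    the training data fall back to the training DV marginal's argmax.
    """
    preds = fitted.predict(eval_data)
    n = preds["count"].sum()
    hit = preds.loc[preds["observed"] == preds["predicted"], "count"].sum()
    return 100.0 * float(hit) / float(n)


def pct_cover(
    data: CategoricalDataset, model: ModelStructure | RAFitResults
) -> float:
    """Percent of the predicting IVs' composite state space observed."""
    structure = model.structure if isinstance(model, RAFitResults) else model
    pred = structure.predicting_ivs
    if not pred:
        return 100.0
    observed = len(data.marginal_weights(list(pred)))
    total = 1
    for nm in pred:
        total *= data.spec(nm).cardinality
    return 100.0 * observed / total
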