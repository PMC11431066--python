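"""Statsmodels-style front end: ``RAModel`` and ``RAFitResults``.

``RAModel`` couples a :class:`~rascube.core.CategoricalDataset` with a
:class:`~rascube.structures.ModelStructure`; ``fit()`` returns an
``RAFitResults`` carrying the maximum-entropy joint q, degrees of freedom,
log-likelihood, the convergence record and the DV conditional table, with a
``summary()`` in the style of an OCCAM search row.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import CategoricalDataset, Distribution, entropy
from .fitting import DEFAULT_MAX_ITER, DEFAULT_TOL, dense_ipf, dense_loopless
from .structures import ModelStructure, degrees_of_freedom, has_loops, parse_model

__all__ = ["RAModel", "RAFitResults", "fit_loopless", "fit_ipf"]


class RAModel:
    """A directed-system RA model structure bound to data.

    Parameters
    ----------
    data : CategoricalDataset
        Joint frequency table; must declare exactly one DV.
    structure : ModelStructure or str
        The hypergraph of relations, or its string notation
        (e.g. ``"IV:N2Z5:S3Z5:Z4Z5"``).
    """

    def __init__(self, data: CategoricalDataset, structure: ModelStructure | str):
        if isinstance(structure, str):
            structure = parse_model(structure, data.names, data.dv_name)
        if tuple(structure.var_order) != data.names or structure.dv != data.dv_name:
            structure = ModelStructure(data.names, data.dv_name, structure.predictive)
        self.data = data
        self.structure = structure

    @classmethod
    def from_table(cls, path, variables, structure, freq_col=None) -> "RAModel":
        from .core import read_table

        data = read_table(path, variables=variables, freq_col=freq_col)
        return cls(data, structure)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        method: str = "auto",
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ) -> "RAFitResults":
        """Fit the maximum-entropy joint.

        ``method`` is one of ``"auto"`` (closed form when loopless, else
        IPF), ``"ipf"`` or ``"loopless"``.  The fit runs on the reduced
        predicting-IVs-plus-DV scope; see :mod:`rascube.fitting`.
        """
        data, structure = self.data, self.structure
        scope = structure.predicting_ivs + (structure.dv,)
        reduced = _reduced_structure(structure)
        if method == "auto":
            method = "ipf" if has_loops(reduced) else "loopless"
        if method == "loopless":
            if has_loops(reduced):
                raise ValueError(
                    f"model {structure.name} has loops; fit with method='ipf'"
                )
            dense = dense_loopless(data, reduced, scope)
        elif method == "ipf":
            dense = dense_ipf(data, reduced, scope, tol=tol, max_iter=max_iter)
        else:
            raise ValueError(f"unknown method {method!r}")
        if not dense.converged:
            warnings.warn(
                f"IPF did not converge for {structure.name}: "
                f"max_dev={dense.max_dev:.3g} after {dense.iterations} cycles",
                RuntimeWarning,
                stacklevel=2,
            )
        return RAFitResults(self, dense, tol=tol)


def _reduced_structure(structure: ModelStructure) -> ModelStructure:
    """Same predictive relations, IV component shrunk to the predicting IVs."""
    scope = structure.predicting_ivs + (structure.dv,)
    return ModelStructure(scope, structure.dv, structure.predictive)


class RAFitResults:
    """Fitted maximum-entropy model: q, df, log-likelihood, diagnostics.

    ``q`` (the joint over *all* variables) is materialised lazily from the
    directed-system factorisation q(IVs, DV) = p(IVs) * c(DV | predicting
    IVs); the dense conditional c is available as :attr:`conditional`.
    """

    def __init__(self, model: RAModel, dense, tol: float):
        self.model_spec = model
        self.data: CategoricalDataset = model.data
        self.structure: ModelStructure = model.structure
        self.fit_scope = dense.scope
        self.q_fit: np.ndarray = dense.q
        self.iterations: int = dense.iterations
        self.max_dev: float = dense.max_dev
        self.converged: bool = dense.converged
        self.tol = tol
        self._cache: dict = {}

    # -- structure shortcuts ----------------------------------------------

    @property
    def name(self) -> str:
        return self.structure.name

    @property
    def predicting_ivs(self) -> tuple[str, ...]:
        return self.structure.predicting_ivs

    @property
    def dv(self) -> str:
        return self.structure.dv

    @property
    def dv_card(self) -> int:
        return self.data.spec(self.dv).cardinality

    # -- fitted quantities ------------------------------------------------

    @property
    def df(self) -> int:
        if "df" not in self._cache:
            cards = dict(zip(self.data.names, self.data.cards))
            self._cache["df"] = degrees_of_freedom(self.structure, cards)
        return self._cache["df"]

    @property
    def delta_df(self) -> int:
        cards = dict(zip(self.data.names, self.data.cards))
        return degrees_of_freedom(self.structure, cards, delta=True)

    @property
    def conditional(self) -> np.ndarray:
        """Dense c(DV | predicting IVs); shape = pred cards + (dv_card,).

        Rows (pred states) with zero q-mass are NaN.
        """
        if "conditional" not in self._cache:
            mass = self.q_fit.sum(axis=-1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                c = self.q_fit / mass
            c[np.broadcast_to(mass == 0, c.shape)] = np.nan
            self._cache["conditional"] = c
        return self._cache["conditional"]

    @property
    def q(self) -> Distribution:
        """The maximum-entropy joint over all variables (sparse).

        Supported on the observed IV-component states: a zero observed IV
        margin forces a zero fitted cell.
        """
        if "q" not in self._cache:
            data = self.data
            ivs = [nm for nm in data.names if nm != self.dv]
            iv_codes, w = data.codes_for(ivs)
            uniq, inv = np.unique(iv_codes, axis=0, return_inverse=True)
            wu = np.zeros(len(uniq))
            np.add.at(wu, inv, w)
            p_iv = wu / data.n
            pred_axes = [ivs.index(nm) for nm in self.predicting_ivs]
            cond = self.conditional
            probs: dict[tuple[int, ...], float] = {}
            dv_pos = data.names.index(self.dv)
            for row, piv in zip(uniq, p_iv):
                key = tuple(int(row[a]) for a in pred_axes)
                cz = cond[key] if pred_axes else cond
                full = list(row)
                for z in range(self.dv_card):
                    pz = float(piv * cz[z])
                    if pz <= 0:
                        continue
                    state = full[:dv_pos] + [z] + full[dv_pos:]
                    probs[tuple(state)] = pz
            self._cache["q"] = Distribution(data.names, data.cards, probs)
        return self._cache["q"]

    @property
    def cond_loglik(self) -> float:
        """N * sum over (pred, dv) of p * ln c — the model-dependent part of
        the log-likelihood (the shared IV-margin term is in :attr:`loglik`)."""
        if "cond_loglik" not in self._cache:
            p = self._p_fit_scope()
            c = self.conditional
            mask = p > 0
            vals = np.where(mask, c, 1.0)
            if np.any(mask & ~(vals > 0)):
                self._cache["cond_loglik"] = -np.inf
            else:
                self._cache["cond_loglik"] = float(
                    self.data.n * (p[mask] * np.log(vals[mask])).sum()
                )
        return self._cache["cond_loglik"]

    @property
    def loglik(self) -> float:
        """N * sum p ln q (natural log) over the full joint."""
        w = self.data.marginal_weights([nm for nm in self.data.names if nm != self.dv])
        p = w / self.data.n
        return self.cond_loglik + float(self.data.n * (p * np.log(p)).sum())

    def _p_fit_scope(self) -> np.ndarray:
        if "p_fit" not in self._cache:
            self._cache["p_fit"] = (
                self.data.project_counts(list(self.fit_scope)) / self.data.n
            )
        return self._cache["p_fit"]

    @property
    def h_dv_given_ivs(self) -> float:
        """H_q(DV | predicting IVs) in bits, under the fitted joint."""
        q = self.q_fit
        h_joint = entropy(q)
        h_pred = entropy(q.sum(axis=-1)) if q.ndim > 1 else 0.0
        return h_joint - h_pred

    # -- prediction --------------------------------------------------------

    def predictions(self) -> np.ndarray:
        """argmax of c(DV | pred state) per pred state; ties -> lowest DV
        index; NaN rows (unseen pred states) -> fallback to the training DV
        marginal's argmax."""
        cond = self.conditional
        flat = cond.reshape(-1, self.dv_card)
        pred = np.argmax(np.nan_to_num(flat, nan=-1.0), axis=1)
        marg = self.data.project_counts([self.dv])
        fallback = int(np.argmax(marg))
        pred[np.isnan(flat).any(axis=1)] = fallback
        return pred.reshape(cond.shape[:-1]) if cond.ndim > 1 else pred

    def predict(self, eval_data: CategoricalDataset | None = None) -> pd.DataFrame:
        """Per-case DV predictions for *eval_data* (default: training data)."""
        data = self.data if eval_data is None else eval_data
        codes, w = data.codes_for(list(self.predicting_ivs) + [self.dv])
        pred_map = self.predictions()
        if self.predicting_ivs:
            flat = np.ravel_multi_index(
                codes[:, :-1].T, pred_map.shape
            )
            yhat = pred_map.ravel()[flat]
        else:
            yhat = np.full(len(codes), int(pred_map.ravel()[0]))
        return pd.DataFrame(
            {"observed": codes[:, -1], "predicted": yhat, "count": w}
        )

    def conditional_dv_table(self) -> pd.DataFrame:
        """One row per composite predicting-IV state (full Cartesian product).

        Columns: the pred state indices, training frequency, the data DV
        conditional, the model DV conditional, and an ``observed`` flag.
        Unobserved states have NaN conditionals.
        """
        pred = list(self.predicting_ivs)
        cards = tuple(self.data.spec(nm).cardinality for nm in pred)
        counts = self.data.project_counts(pred + [self.dv])
        freq = counts.sum(axis=-1) if pred else np.array(counts.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            data_cond = counts / counts.sum(axis=-1, keepdims=True)
        model_cond = self.conditional
        n_states = int(np.prod(cards)) if pred else 1
        states = (
            np.stack(np.unravel_index(np.arange(n_states), cards), axis=1)
            if pred
            else np.zeros((1, 0), dtype=int)
        )
        rows = []
        for i in range(n_states):
            key = tuple(states[i])
            rows.append(
                {
                    **{nm: key[j] for j, nm in enumerate(pred)},
                    "frequency": float(freq[key] if pred else freq),
                    **{
                        f"data_p{z}": float(data_cond[key + (z,)])
                        for z in range(self.dv_card)
                    },
                    **{
                        f"model_p{z}": float(model_cond[key + (z,)])
                        for z in range(self.dv_card)
                    },
                    "observed": bool((freq[key] if pred else freq) > 0),
                }
            )
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------

    def summary(self, test_data: CategoricalDataset | None = None) -> str:
        from . import metrics

        bottom = RAModel(
            self.data, ModelStructure.bottom(self.data.names, self.dv)
        ).fit()
        inf = metrics.information_captured(self.data, self, bottom)
        dh = metrics.pct_delta_h_dv(self.data, self)
        dbic, daic = metrics.information_criteria(self.data, self, bottom)
        pc = metrics.pct_correct(self, self.data)
        cover = metrics.pct_cover(self.data, self.structure)
        lines = [
            "Reconstructability Analysis fit",
            "=" * 47,
            f"model:        {self.name}",
            f"df:           {self.df}  (delta vs bottom: {self.delta_df})",
            f"loglik:       {self.loglik:.4f}",
            f"converged:    {self.converged}  (cycles={self.iterations}, "
            f"max_dev={self.max_dev:.2e})",
            "-" * 47,
            f"Inf:          {inf:.3f}",
            f"%dH(DV):      {dh:.1f}",
            f"dBIC:         {dbic:.1f}",
            f"dAIC:         {daic:.1f}",
            f"%C(Data):     {pc:.1f}",
            f"%Cover:       {cover:.1f}",
        ]
        if test_data is not None:
            lines.append(f"%C(Test):     {metrics.pct_correct(self, test_data):.1f}")
        return "\n".join(lines)

    def export(self, path, sep: str = "\t") -> None:
        """Write q's nonzero cells as delimited text with a run header."""
        dist = self.q
        with open(path, "w") as fh:
            fh.write(f"# model={self.name} tol={self.tol} iterations={self.iterations}\n")
            fh.write(sep.join(dist.scope) + sep + "q\n")
            for state in sorted(dist.probs):
                fh.write(
                    sep.join(str(s) for s in state)
                    + sep
                    + f"{dist.probs[state]:.17g}\n"
                )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<RAFitResults {self.name} converged={self.converged}>"


# ---------------------------------------------------------------------------
# spec-style free functions (full-scope contracts / oracles)


def fit_loopless(data: CategoricalDataset, model: ModelStructure) -> RAFitResults:
    """Closed-form fit of a loopless structure (errors on loops)."""
    if has_loops(model):
        raise ValueError(f"model {model.name} has loops; use fit_ipf")
    return RAModel(data, model).fit(method="loopless")


def fit_ipf(
    data: CategoricalDataset,
    model: ModelStructure,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RAFitResults:
    """IPF fit of any structure (loopless or looped)."""
    return RAModel(data, model).fit(method="ipf", tol=tol, max_iter=max_iter)
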