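"""Maximum-entropy fitting of model structures.

A fitted model is the maximum-entropy joint distribution q whose projections
onto every relation of the structure equal the data's projections.  Loopless
(decomposable) structures admit a closed form — a product of relation
projections divided by separator projections along a Graham-reduction
ordering.  Structures with loops require iterative proportional fitting
(IPF): starting from the uniform distribution, q is cyclically rescaled to
match each relation's observed projection until the largest projection
deviation falls below tolerance.

For directed systems the maximum-entropy joint factorises as

    q(all IVs, DV) = p(all IVs) * c(DV | predicting IVs),

because the IV component pins the full IV margin to the data while the
predictive relations only involve the predicting IVs and the DV.  Production
fits therefore run on the (small) predicting-IVs-plus-DV subspace; the
full-scope fitters here double as the literal contract and as oracles for
that reduction.
"""

from __future__ import annotations

import numpy as np

from .core import CategoricalDataset
from .structures import ModelStructure, _rel_string, decompose

__all__ = ["DenseFit", "dense_loopless", "dense_ipf", "DEFAULT_TOL", "DEFAULT_MAX_ITER"]

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 5000


class DenseFit:
    """Raw outcome of a dense fit over an explicit variable scope."""

    __slots__ = ("scope", "cards", "q", "iterations", "max_dev", "converged")

    def __init__(self, scope, cards, q, iterations, max_dev, converged):
        self.scope = tuple(scope)
        self.cards = tuple(cards)
        self.q = q
        self.iterations = iterations
        self.max_dev = max_dev
        self.converged = converged


def _axes_in(scope: tuple[str, ...], rel) -> tuple[int, ...]:
    return tuple(i for i, nm in enumerate(scope) if nm in rel)


def _expand(margin: np.ndarray, scope_len: int, axes: tuple[int, ...]) -> np.ndarray:
    """Reshape a marginal array for broadcasting against the full scope."""
    shape = [1] * scope_len
    for i, a in enumerate(axes):
        shape[a] = margin.shape[i]
    return margin.reshape(shape)


def _data_margin(data: CategoricalDataset, scope, rel) -> np.ndarray:
    names = [nm for nm in scope if nm in rel]
    return data.project_counts(names) / data.n


def _projection(q: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    other = tuple(a for a in range(q.ndim) if a not in axes)
    return q.sum(axis=other)


def dense_loopless(data: CategoricalDataset, model: ModelStructure, scope) -> DenseFit:
    """Closed-form fit of a loopless structure over *scope*.

    q = prod of relation projections / prod of separator projections; cells
    where a separator projection is zero are zero (0/0 -> 0).
    """
    scope = tuple(scope)
    cards = tuple(data.spec(nm).cardinality for nm in scope)
    numerators, separators = decompose(model)
    num = np.ones(cards)
    for rel in numerators:
        if not rel:
            continue
        axes = _axes_in(scope, rel)
        num = num * _expand(_data_margin(data, scope, rel), len(scope), axes)
    den = np.ones(cards)
    for sep in separators:
        if not sep:
            continue
        axes = _axes_in(scope, sep)
        den = den * _expand(_data_margin(data, scope, sep), len(scope), axes)
    q = np.divide(num, den, out=np.zeros(cards), where=den > 0)
    max_dev = _max_margin_dev(q, data, scope, model.relations)
    return DenseFit(scope, cards, q, 0, max_dev, True)


def _max_margin_dev(q, data, scope, relations) -> float:
    dev = 0.0
    for rel in relations:
        if not rel:
            continue
        axes = _axes_in(scope, rel)
        dev = max(dev, float(np.abs(_projection(q, axes) - _data_margin(data, scope, rel)).max()))
    return dev


def dense_ipf(
    data: CategoricalDataset,
    model: ModelStructure,
    scope,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> DenseFit:
    """Iterative proportional fitting over *scope*, uniform initialisation.

    Relations are visited in canonical-name order within each cycle; the
    converged q is order-independent but iteration counts are reproducible.
    """
    scope = tuple(scope)
    cards = tuple(data.spec(nm).cardinality for nm in scope)
    rels = [r for r in model.relations if r]
    rels.sort(key=lambda r: _rel_string(r, scope))
    targets = [_data_margin(data, scope, r) for r in rels]
    axes_list = [_axes_in(scope, r) for r in rels]

    q = np.full(cards, 1.0 / float(np.prod(cards)))
    max_dev = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for target, axes in zip(targets, axes_list):
            cur = _projection(q, axes)
            ratio = np.divide(target, cur, out=np.zeros_like(cur), where=cur > 0)
            q = q * _expand(ratio, len(scope), axes)
        max_dev = max(
            (float(np.abs(_projection(q, a) - t).max()) for t, a in zip(targets, axes_list)),
            default=0.0,
        )
        if max_dev < tol:
            break
    converged = max_dev < tol
    return DenseFit(scope, cards, q, iterations, max_dev, converged)
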