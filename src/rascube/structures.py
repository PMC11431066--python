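"""Directed-system model structures and the lattice of structures.

A model is a hypergraph of relations over the dataset's variables.  Every
directed-system model contains the *IV component* — a single relation over
all and only the IVs — plus zero or more *predictive relations*, each
containing the DV and at least one IV.  The IV component keeps all candidate
models hierarchically nested while remaining agnostic about relations among
the IVs themselves.

The bottom of the lattice is the independence model (IV component plus the
lone DV, written ``IV:Z``); the top is the saturated model whose single
predictive relation contains every variable.  Beam search moves upward
through "parents": structures whose complexity is incrementally increased.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ModelStructure",
    "canonical_name",
    "parse_model",
    "degrees_of_freedom",
    "has_loops",
    "generate_parents",
    "decompose",
]

Relation = frozenset  # relation == frozenset of variable names


def _canonical_predictive(
    predictive: Iterable[frozenset], dv: str, ivs: Sequence[str]
) -> tuple[frozenset, ...]:
    """Minimal form: drop predictive relations subsumed by another."""
    iv_set = set(ivs)
    rels = []
    for r in predictive:
        r = frozenset(r)
        if dv not in r:
            raise ValueError(f"predictive relation {sorted(r)} lacks the DV {dv!r}")
        if not (r - {dv}):
            raise ValueError("predictive relation needs at least one IV")
        if not (r - {dv}) <= iv_set:
            raise ValueError(f"relation {sorted(r)} uses undeclared variables")
        rels.append(r)
    minimal = [r for r in rels if not any(r < s for s in rels)]
    # dedupe, deterministic order
    seen: dict[frozenset, None] = {}
    for r in minimal:
        seen.setdefault(r, None)
    return tuple(seen)


@dataclass(frozen=True)
class ModelStructure:
    """IV component plus predictive relations, in canonical minimal form.

    Parameters
    ----------
    var_order : tuple of str
        All variable names in declared (dataset) order; used for printing.
    dv : str
        The dependent variable's name (must be in *var_order*).
    predictive : tuple of frozenset
        Predictive relations; empty for the independence (bottom) model.
    """

    var_order: tuple[str, ...]
    dv: str
    predictive: tuple[frozenset, ...] = ()

    def __post_init__(self) -> None:
        var_order = tuple(self.var_order)
        if self.dv not in var_order:
            raise ValueError(f"DV {self.dv!r} not among declared variables")
        object.__setattr__(self, "var_order", var_order)
        object.__setattr__(
            self,
            "predictive",
            _canonical_predictive(self.predictive, self.dv, self.iv_names),
        )

    # -- basic views ------------------------------------------------------

    @property
    def iv_names(self) -> tuple[str, ...]:
        return tuple(nm for nm in self.var_order if nm != self.dv)

    @property
    def iv_component(self) -> frozenset:
        return frozenset(self.iv_names)

    @property
    def relations(self) -> tuple[frozenset, ...]:
        """All relations including the IV component (and lone DV at bottom)."""
        if not self.predictive:
            return (self.iv_component, frozenset({self.dv}))
        return (self.iv_component,) + self.predictive

    @property
    def predicting_ivs(self) -> tuple[str, ...]:
        """IVs appearing in at least one predictive relation, declared order."""
        used = set().union(*self.predictive) - {self.dv} if self.predictive else set()
        return tuple(nm for nm in self.iv_names if nm in used)

    @property
    def name(self) -> str:
        return canonical_name(self)

    @property
    def level_hint(self) -> int:
        """Total IV slots across predictive relations (the search level for
        the dyadic-chain models)."""
        return sum(len(r) - 1 for r in self.predictive)

    # -- constructors -----------------------------------------------------

    @classmethod
    def bottom(cls, var_order: Sequence[str], dv: str) -> "ModelStructure":
        return cls(tuple(var_order), dv, ())

    @classmethod
    def saturated(cls, var_order: Sequence[str], dv: str) -> "ModelStructure":
        return cls(tuple(var_order), dv, (frozenset(var_order),))

    def with_predictive(self, predictive: Iterable[frozenset]) -> "ModelStructure":
        return ModelStructure(self.var_order, self.dv, tuple(predictive))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _rel_string(rel: frozenset, var_order: Sequence[str]) -> str:
    order = {nm: i for i, nm in enumerate(var_order)}
    return "".join(sorted(rel, key=lambda nm: order[nm]))


def canonical_name(model: ModelStructure) -> str:
    """Deterministic name ``IV:<rel>:<rel>...``.

    Variables within a relation follow the declared variable order; relations
    are sorted lexicographically, so structures differing only in ordering
    print identically.  The bottom model prints as ``IV:<dv>``.
    """
    if not model.predictive:
        return f"IV:{model.dv}"
    parts = sorted(_rel_string(r, model.var_order) for r in model.predictive)
    return "IV:" + ":".join(parts)


def parse_model(
    text: str, var_order: Sequence[str], dv: str
) -> ModelStructure:
    """Parse Table-2 style notation like ``"IV:W1Z5:N2Z5:S3Z5:Z4Z5"``.

    Relation tokens are concatenations of variable names; they are split by
    greedy longest-match against the declared names, so multi-character names
    such as ``N1`` and ``Z5`` round-trip exactly.
    """
    names = sorted(var_order, key=len, reverse=True)
    tokens = text.strip().split(":")
    if not tokens or tokens[0] != "IV":
        raise ValueError(f"model string must start with 'IV:': {text!r}")
    predictive = []
    for tok in tokens[1:]:
        rel = set()
        i = 0
        while i < len(tok):
            for nm in names:
                if tok.startswith(nm, i):
                    rel.add(nm)
                    i += len(nm)
                    break
            else:
                raise ValueError(f"cannot tokenize {tok!r} at position {i}")
        if rel == {dv}:
            continue  # the lone-DV relation of the bottom model
        predictive.append(frozenset(rel))
    return ModelStructure(tuple(var_order), dv, tuple(predictive))


# ---------------------------------------------------------------------------
# degrees of freedom


def degrees_of_freedom(
    model: ModelStructure,
    cards: Mapping[str, int],
    delta: bool = False,
) -> int:
    """Independent parameters of the hierarchical log-linear model.

    Every nonempty variable subset contained in some relation contributes
    ``prod(card - 1)`` parameters; summing via inclusion-exclusion over the
    relations' intersection lattice avoids enumerating the (possibly huge)
    powerset of the IV component:

    ``df = sum over nonempty relation subsets T of (-1)^(|T|+1) * (prod_{v in
    inter(T)} card(v) - 1)``.

    With ``delta=True`` returns df relative to the independence model.
    """
    rels = list(model.relations)
    k = len(rels)
    df = 0
    for size in range(1, k + 1):
        sign = 1 if size % 2 == 1 else -1
        for combo in itertools.combinations(range(k), size):
            inter = rels[combo[0]]
            for j in combo[1:]:
                inter = inter & rels[j]
                if not inter:
                    break
            prod = 1
            for v in inter:
                prod *= cards[v]
            df += sign * (prod - 1)
    if delta:
        bottom = ModelStructure.bottom(model.var_order, model.dv)
        return df - degrees_of_freedom(bottom, cards)
    return df


# ---------------------------------------------------------------------------
# loops / Graham reduction


def _graham(relations: Sequence[frozenset]):
    """Graham reduction; returns (emptied, separators) where *separators*
    are the intersections recorded when a reduced relation is absorbed into
    another (the denominators of the decomposable closed form)."""
    current = [set(r) for r in relations]
    active = list(range(len(current)))
    separators: list[frozenset] = []
    changed = True
    while changed:
        changed = False
        # absorb relations subsumed by another active relation
        for i in list(active):
            for j in active:
                if i != j and current[i] <= current[j]:
                    separators.append(frozenset(current[i]))
                    active.remove(i)
                    changed = True
                    break
        # delete variables appearing in exactly one active relation
        count: dict[str, int] = {}
        for i in active:
            for v in current[i]:
                count[v] = count.get(v, 0) + 1
        for i in active:
            lone = {v for v in current[i] if count[v] == 1}
            if lone:
                current[i] -= lone
                changed = True
    emptied = all(not current[i] for i in active)
    return emptied, separators


def has_loops(model: ModelStructure) -> bool:
    """True iff Graham reduction fails to empty the relation hypergraph."""
    emptied, _ = _graham(model.relations)
    return not emptied


def decompose(model: ModelStructure):
    """Junction factorisation of a loopless model.

    Returns ``(numerators, separators)`` such that the maximum-entropy joint
    is ``prod p(R) for R in numerators / prod p(S) for S in separators``.
    Raises ``ValueError`` on a model with loops.
    """
    emptied, separators = _graham(model.relations)
    if not emptied:
        raise ValueError(f"model {model.name} has loops; use IPF")
    seps = [s for s in separators if s]
    return list(model.relations), seps


# ---------------------------------------------------------------------------
# parent generation


def generate_parents(model: ModelStructure) -> list[ModelStructure]:
    """Structures whose complexity is incrementally increased from *model*.

    Two moves: (a) add a new dyadic predictive relation ``{X, DV}`` for an IV
    X not yet in any predictive relation; (b) add one IV to an existing
    predictive relation (producing fused relations such as ``N1E3Z5``).
    Results are deduplicated by canonical name and exclude the input model.
    """
    dv = model.dv
    used = set(model.predicting_ivs)
    out: dict[str, ModelStructure] = {}

    def add(predictive):
        try:
            m = model.with_predictive(predictive)
        except ValueError:
            return
        nm = m.name
        if nm != model.name:
            out.setdefault(nm, m)

    for x in model.iv_names:
        if x not in used:
            add(model.predictive + (frozenset({x, dv}),))
    for i, rel in enumerate(model.predictive):
        for x in model.iv_names:
            if x not in rel:
                grown = list(model.predictive)
                grown[i] = rel | {x}
                add(tuple(grown))
    return [out[nm] for nm in sorted(out)]
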