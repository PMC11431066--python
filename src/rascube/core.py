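"""Variables, categorical frequency tables, distributions and entropy arithmetic.

Reconstructability analysis (RA) operates on a joint frequency table over a
set of named categorical variables, one of which is designated the dependent
variable (DV).  Everything downstream — model structures, maximum-entropy
fitting, search — consumes the small algebra defined here: normalisation of
counts to probabilities, projection (marginalisation), and Shannon entropy in
bits.

State codes are 0-based internally; external class codes (e.g. NLCD land-cover
codes) are mapped to states through :attr:`VariableSpec.rebin`, which keeps
the model algebra independent of any particular coding scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "CategoricalDataset",
    "Distribution",
    "to_probability",
    "project",
    "entropy",
    "conditional_entropy",
    "read_table",
    "load_variable_config",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one categorical variable.

    Parameters
    ----------
    name : str
        Short label, unique within a dataset (e.g. ``"N2"``, ``"Z5"``).
    cardinality : int
        Number of states, >= 2.
    role : {"iv", "dv"}
        Whether the variable is a predictor or the predicted variable.
    rebin : mapping, optional
        Total map from raw external codes onto state indices
        ``0..cardinality-1``.  Absent means values are already state indices.
    labels : sequence of str, optional
        Human-readable state names, index-aligned (e.g. WDA/GRS/SHB/MFO/EFO).
    """

    name: str
    cardinality: int
    role: str = "iv"
    rebin: Mapping[int, int] | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.cardinality < 2:
            raise ValueError(f"variable {self.name!r}: cardinality must be >= 2")
        if self.role not in ("iv", "dv"):
            raise ValueError(f"variable {self.name!r}: role must be 'iv' or 'dv'")
        if self.rebin is not None:
            targets = set(self.rebin.values())
            if not targets <= set(range(self.cardinality)):
                raise ValueError(
                    f"variable {self.name!r}: rebin targets outside 0..{self.cardinality - 1}"
                )
            object.__setattr__(self, "rebin", dict(self.rebin))
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != self.cardinality:
                raise ValueError(f"variable {self.name!r}: need one label per state")
            object.__setattr__(self, "labels", labels)

    def state_label(self, state: int) -> str:
        if self.labels is not None:
            return self.labels[state]
        return str(state)


class CategoricalDataset:
    """Joint frequency table over named categorical variables.

    Stores unique state tuples with their counts (sparse in the full product
    state space, which for NLCD-style data is astronomically larger than the
    number of observed cells).
    """

    def __init__(
        self,
        variables: Sequence[VariableSpec],
        codes: np.ndarray,
        weights: np.ndarray,
    ) -> None:
        variables = list(variables)
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if sum(v.role == "dv" for v in variables) != 1:
            raise ValueError("dataset must declare exactly one DV")
        codes = np.asarray(codes, dtype=np.int64)
        weights = np.asarray(weights, dtype=float)
        if codes.ndim != 2 or codes.shape[1] != len(variables):
            raise ValueError("codes must be (cases, n_variables)")
        if codes.shape[0] == 0 or weights.sum() <= 0:
            raise ValueError("empty data")
        if np.any(weights < 0):
            raise ValueError("negative counts")
        cards = np.array([v.cardinality for v in variables])
        if np.any(codes < 0) or np.any(codes >= cards[None, :]):
            raise ValueError("state index out of range for declared cardinality")
        # collapse duplicate tuples
        order = np.lexsort(codes.T[::-1])
        codes, weights = codes[order], weights[order]
        uniq, idx = np.unique(codes, axis=0, return_inverse=True)
        w = np.zeros(len(uniq))
        np.add.at(w, idx, weights)
        keep = w > 0
        self.variables = variables
        self._codes = uniq[keep]
        self._weights = w[keep]
        self.n = float(self._weights.sum())

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[int, ...], float],
        variables: Sequence[VariableSpec],
    ) -> "CategoricalDataset":
        if not counts:
            raise ValueError("empty data")
        codes = np.array(list(counts.keys()), dtype=np.int64)
        weights = np.array(list(counts.values()), dtype=float)
        return cls(variables, codes, weights)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        variables: Sequence[VariableSpec],
        freq_col: str | None = None,
    ) -> "CategoricalDataset":
        """Build from one-row-per-case table; columns matched by name.

        Values are passed through each variable's ``rebin`` map when present.
        An optional trailing frequency column turns the table into an
        aggregated frequency file.
        """
        variables = list(variables)
        cols = []
        for v in variables:
            if v.name not in df.columns:
                raise KeyError(f"column {v.name!r} missing from table")
            raw = df[v.name].to_numpy()
            if v.rebin is not None:
                col = np.empty(len(raw), dtype=np.int64)
                lut = v.rebin
                for i, x in enumerate(raw):
                    try:
                        col[i] = lut[int(x)]
                    except KeyError:
                        raise ValueError(
                            f"variable {v.name!r}: unmapped code {x!r} at row {i}"
                        ) from None
            else:
                col = np.asarray(raw, dtype=np.int64)
            cols.append(col)
        codes = np.column_stack(cols)
        if freq_col is not None:
            weights = df[freq_col].to_numpy(dtype=float)
        else:
            weights = np.ones(len(df))
        return cls(variables, codes, weights)

    # -- accessors --------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def cards(self) -> tuple[int, ...]:
        return tuple(v.cardinality for v in self.variables)

    @property
    def dv_name(self) -> str:
        return next(v.name for v in self.variables if v.role == "dv")

    @property
    def iv_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "iv")

    @property
    def counts(self) -> dict[tuple[int, ...], float]:
        return {tuple(row): w for row, w in zip(self._codes, self._weights)}

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def _axes(self, names: Sequence[str]) -> list[int]:
        pos = {v.name: i for i, v in enumerate(self.variables)}
        try:
            return [pos[nm] for nm in names]
        except KeyError as e:
            raise KeyError(f"unknown variable {e.args[0]!r}") from None

    def ordered_subset(self, names: Iterable[str]) -> tuple[str, ...]:
        """Return *names* re-ordered by the declared variable order."""
        want = set(names)
        unknown = want - set(self.names)
        if unknown:
            raise KeyError(f"unknown variable {sorted(unknown)[0]!r}")
        return tuple(nm for nm in self.names if nm in want)

    def project_counts(self, names: Sequence[str]) -> np.ndarray:
        """Dense marginal count array over *names* (declared order preserved)."""
        axes = self._axes(names)
        cards = [self.variables[a].cardinality for a in axes]
        flat = np.ravel_multi_index(self._codes[:, axes].T, cards)
        out = np.bincount(flat, weights=self._weights, minlength=int(np.prod(cards)))
        return out.reshape(cards)

    def marginal_weights(self, names: Sequence[str]) -> np.ndarray:
        """Counts of the distinct observed states of *names* (sparse marginal).

        Unlike :meth:`project_counts` this never materialises the product
        state space, so it works for the full 20-IV margin.
        """
        axes = self._axes(names)
        if not axes:
            return np.array([self.n])
        uniq, inv = np.unique(self._codes[:, axes], axis=0, return_inverse=True)
        w = np.zeros(len(uniq))
        np.add.at(w, inv, self._weights)
        return w

    def codes_for(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Per-unique-row state columns for *names* plus row weights."""
        axes = self._axes(names)
        return self._codes[:, axes], self._weights.copy()

    def __len__(self) -> int:
        return self._codes.shape[0]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CategoricalDataset({len(self.variables)} variables, "
            f"{len(self)} distinct cells, n={self.n:g})"
        )


@dataclass
class Distribution:
    """Sparse probability distribution over an ordered variable scope."""

    scope: tuple[str, ...]
    cards: tuple[int, ...]
    probs: dict[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scope = tuple(self.scope)
        self.cards = tuple(self.cards)
        total = 0.0
        for state, p in self.probs.items():
            if len(state) != len(self.scope):
                raise ValueError("state tuple length does not match scope")
            if any(s < 0 or s >= c for s, c in zip(state, self.cards)):
                raise ValueError(f"state {state} outside declared cardinalities")
            if p < -_PROB_TOL:
                raise ValueError("negative probability")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total!r}, not 1")

    @classmethod
    def from_dense(
        cls, arr: np.ndarray, scope: Sequence[str], cards: Sequence[int] | None = None
    ) -> "Distribution":
        arr = np.asarray(arr, dtype=float)
        cards = tuple(arr.shape) if cards is None else tuple(cards)
        nz = np.argwhere(arr > 0)
        probs = {tuple(int(i) for i in idx): float(arr[tuple(idx)]) for idx in nz}
        return cls(tuple(scope), cards, probs)

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.cards)
        for state, p in self.probs.items():
            out[state] = p
        return out

    def __getitem__(self, state: tuple[int, ...]) -> float:
        return self.probs.get(tuple(state), 0.0)


# ---------------------------------------------------------------------------
# operations


def to_probability(dataset: CategoricalDataset) -> Distribution:
    """Normalise the joint frequency table by the sample size."""
    if dataset.n <= 0:
        raise ValueError("empty data")
    codes, weights = dataset._codes, dataset._weights
    probs = {tuple(row): float(w / dataset.n) for row, w in zip(codes, weights)}
    return Distribution(dataset.names, dataset.cards, probs)


def project(dist: Distribution, subset: Sequence[str]) -> Distribution:
    """Marginal of *dist* on *subset*, preserving the declared order."""
    pos = {nm: i for i, nm in enumerate(dist.scope)}
    for nm in subset:
        if nm not in pos:
            raise KeyError(f"unknown variable {nm!r}")
    keep = [nm for nm in dist.scope if nm in set(subset)]
    axes = [pos[nm] for nm in keep]
    cards = tuple(dist.cards[a] for a in axes)
    acc: dict[tuple[int, ...], float] = {}
    for state, p in dist.probs.items():
        key = tuple(state[a] for a in axes)
        acc[key] = acc.get(key, 0.0) + p
    return Distribution(tuple(keep), cards, acc)


def entropy(dist: Distribution | np.ndarray) -> float:
    """Shannon entropy in bits; 0*log(0) is taken as 0."""
    if isinstance(dist, Distribution):
        p = np.array(list(dist.probs.values()))
    else:
        p = np.asarray(dist, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(joint: Distribution, given: Sequence[str]) -> float:
    """H(rest | given) = H(joint) - H(marginal on given), in bits."""
    given = list(given)
    if set(given) == set(joint.scope):
        raise ValueError("conditioning on the full scope leaves nothing to predict")
    return entropy(joint) - entropy(project(joint, given))


# ---------------------------------------------------------------------------
# tabular IO


def read_table(
    path_or_buf,
    variables: Sequence[VariableSpec] | None = None,
    freq_col: str | None = None,
    sep: str | None = None,
):
    """Read a delimited row file (comma or tab auto-detected).

    With *variables* given, returns a :class:`CategoricalDataset` (applying
    any rebin maps); otherwise returns the raw :class:`pandas.DataFrame`.
    """
    if sep is None:
        df = pd.read_csv(path_or_buf, sep=None, engine="python")
    else:
        df = pd.read_csv(path_or_buf, sep=sep)
    if variables is None:
        return df
    return CategoricalDataset.from_dataframe(df, variables, freq_col=freq_col)


def write_table(dataset: CategoricalDataset, path, sep: str = "\t") -> None:
    """Write the frequency table as delimited text with a Freq column."""
    df = pd.DataFrame(dataset._codes, columns=list(dataset.names))
    df["Freq"] = dataset._weights
    df.to_csv(path, sep=sep, index=False)


def load_variable_config(source) -> list[VariableSpec]:
    """Parse variable declarations from YAML.

    Expected layout::

        variables:
          - {name: Z4, cardinality: 5, role: iv, rebin: {42: 4, 52: 2}, labels: [...]}
          - {name: Z5, cardinality: 2, role: dv, rebin: {42: 1, ...}}
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        raise TypeError("expected path, stream or mapping")
    entries = doc["variables"] if "variables" in doc else doc
    specs = []
    for entry in entries:
        specs.append(
            VariableSpec(
                name=str(entry["name"]),
                cardinality=int(entry["cardinality"]),
                role=entry.get("role", "iv"),
                rebin={int(k): int(v) for k, v in entry["rebin"].items()}
                if entry.get("rebin")
                else None,
                labels=tuple(entry["labels"]) if entry.get("labels") else None,
            )
        )
    return specs
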