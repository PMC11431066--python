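"""Shared fixtures: small synthetic datasets and structure enumeration."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import rascube as rc


def make_dataset(counts, cards, dv_index=-1, names=None):
    """CategoricalDataset from a counts dict over 0-based state tuples."""
    k = len(cards)
    if names is None:
        names = [chr(ord("A") + i) for i in range(k - 1)] + ["Z"]
    dv_index = dv_index % k
    specs = [
        rc.VariableSpec(nm, c, role="dv" if i == dv_index else "iv")
        for i, (nm, c) in enumerate(zip(names, cards))
    ]
    return rc.CategoricalDataset.from_counts(counts, specs)


def random_dataset(rng, cards, n=200, dv_index=-1, zero_free=True):
    """Random counts over the full product space (strictly positive unless
    zero_free=False)."""
    size = int(np.prod(cards))
    if zero_free:
        w = rng.integers(1, 10, size=size)
    else:
        w = rng.integers(0, 6, size=size)
        if w.sum() == 0:
            w[0] = 1
    states = list(itertools.product(*[range(c) for c in cards]))
    counts = {s: int(c) for s, c in zip(states, w) if c > 0}
    return make_dataset(counts, cards, dv_index=dv_index)


def all_structures(var_order, dv):
    """Every directed-system structure (antichains of predictive relations)."""
    ivs = [nm for nm in var_order if nm != dv]
    rels = [
        frozenset(s) | {dv}
        for r in range(1, len(ivs) + 1)
        for s in itertools.combinations(ivs, r)
    ]
    seen = {}
    for mask in range(2 ** len(rels)):
        chosen = [rels[i] for i in range(len(rels)) if mask >> i & 1]
        if any(a < b for a in chosen for b in chosen):
            continue  # not an antichain; canonical form would collapse it
        m = rc.ModelStructure(tuple(var_order), dv, tuple(chosen))
        seen[m.name] = m
    return list(seen.values())


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def abcz(rng):
    """3 binary IVs + binary DV, random strictly-positive counts."""
    return random_dataset(rng, (2, 2, 2, 2))


@pytest.fixture(scope="session")
def sim_data():
    """Simulated stack run through the full preparation pipeline once."""
    cfg = rc.SimConfig(height=50, width=50, T=5, seed=11)
    stack, _ = rc.simulate_stack(cfg)
    table = rc.apply_row_filters(rc.extract_rows(stack))
    train_df, test_df = rc.stratify_split(table, efo_code=42, seed=13)
    train = rc.recode_and_rebin(rc.KernelRowTable(train_df))
    test = rc.recode_and_rebin(rc.KernelRowTable(test_df))
    return {"config": cfg, "stack": stack, "train": train, "test": test}
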