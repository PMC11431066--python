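"""Seeded patch-succession simulator for NLCD-like raster stacks.

Emulates the clear-cut cycle visible in Pacific-northwest land-cover data:
mature evergreen forest (EFO) patches are harvested to grasses (GRS), regrow
through shrubs (SHB), and return to forest — EFO -> GRS -> SHB -> EFO.
Transitions act on whole patches (not single cells), which induces the
spatial autocorrelation the von Neumann kernel exploits; patch boundaries
supply informative mixed-state rows.  A configurable fraction of patches is
static background (mixed forest or water/developed/agriculture).  Raw NLCD
codes are emitted so the full extract/filter/rebin pipeline is exercised.

The per-patch Markov chain (ages tracked in time steps):

* EFO with age >= maturity_age: harvested with prob ``harvest_prob`` -> GRS;
  otherwise ages one more step.
* GRS -> SHB with prob ``grs_to_shb``.
* SHB -> EFO (age 1) with prob ``shb_to_efo``.

``prob_next_efo`` is the closed-form chain oracle used to check fitted
conditionals against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spacetime import RasterStack

__all__ = ["SimConfig", "simulate_stack", "ground_truth_conditionals", "prob_next_efo"]

EFO, GRS, SHB, MFO, WDA = "EFO", "GRS", "SHB", "MFO", "WDA"


@dataclass
class SimConfig:
    """Simulator parameters.

    Sizes are in cells; ``patch_size`` must divide both grid dimensions.
    Probabilities are per patch per time step.
    """

    height: int = 100
    width: int = 100
    T: int = 5
    patch_size: int = 5
    codes: dict = field(
        default_factory=lambda: {EFO: 42, GRS: 71, SHB: 52, MFO: 43, WDA: 82}
    )
    harvest_prob: float = 0.5
    maturity_age: int = 2
    grs_to_shb: float = 0.8
    shb_to_efo: float = 0.8
    background_frac: float = 0.25
    seed: int = 0
    time_labels: tuple = ()

    def __post_init__(self) -> None:
        for p in (self.harvest_prob, self.grs_to_shb, self.shb_to_efo,
                  self.background_frac):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0,1]")
        if self.maturity_age < 1:
            raise ValueError("maturity_age must be >= 1")
        if self.T < 2:
            raise ValueError("need at least two time slices")
        if self.height % self.patch_size or self.width % self.patch_size:
            raise ValueError("patch_size must divide the grid dimensions")
        if not self.time_labels:
            self.time_labels = tuple(2001 + 5 * t for t in range(self.T))


def simulate_stack(config: SimConfig) -> tuple[RasterStack, pd.DataFrame]:
    """Simulate the stack; returns it with a per-step patch transition log."""
    rng = np.random.default_rng(config.seed)
    ph = config.height // config.patch_size
    pw = config.width // config.patch_size

    background = rng.random((ph, pw)) < config.background_frac
    bg_state = np.where(rng.random((ph, pw)) < 0.5, MFO, WDA)
    init = rng.choice([EFO, GRS, SHB], size=(ph, pw))
    state = np.where(background, bg_state, init)
    age = np.where(
        state == EFO, rng.integers(1, config.maturity_age + 2, size=(ph, pw)), 0
    )

    code_of = np.vectorize(config.codes.__getitem__)
    slices = [code_of(state)]
    log_rows = []
    for t in range(1, config.T):
        u = rng.random((ph, pw))
        new_state = state.copy()
        new_age = age.copy()
        for i in range(ph):
            for j in range(pw):
                if background[i, j]:
                    continue
                s = state[i, j]
                if s == EFO:
                    if age[i, j] >= config.maturity_age and u[i, j] < config.harvest_prob:
                        new_state[i, j], new_age[i, j] = GRS, 0
                    else:
                        new_age[i, j] = age[i, j] + 1
                elif s == GRS:
                    if u[i, j] < config.grs_to_shb:
                        new_state[i, j] = SHB
                elif s == SHB:
                    if u[i, j] < config.shb_to_efo:
                        new_state[i, j], new_age[i, j] = EFO, 1
                if new_state[i, j] != s:
                    log_rows.append(
                        {"step": t, "patch_row": i, "patch_col": j,
                         "from": s, "to": new_state[i, j]}
                    )
        state, age = new_state, new_age
        slices.append(code_of(state))

    ps = config.patch_size
    grid = np.stack([np.kron(s, np.ones((ps, ps), dtype=np.int64)) for s in slices])
    stack = RasterStack(grid.astype(np.int64), config.time_labels)
    log = pd.DataFrame(log_rows, columns=["step", "patch_row", "patch_col", "from", "to"])
    return stack, log


def prob_next_efo(history, config: SimConfig) -> float:
    """Chain-exact P(next state is EFO | observed patch-state history).

    *history* is a sequence of consecutive patch states (class names or raw
    codes), oldest first.  For a trailing EFO run that started inside the
    window the age is known exactly; an all-EFO history is mature when the
    window is at least ``maturity_age`` steps long, and otherwise the
    maturity (hence the harvest hazard) is not identifiable.
    """
    names = {v: k for k, v in config.codes.items()}
    hist = [names.get(s, s) for s in history]
    if not hist:
        raise ValueError("empty history")
    last = hist[-1]
    if last in (MFO, WDA, GRS):
        return 0.0
    if last == SHB:
        return config.shb_to_efo
    if last != EFO:
        raise ValueError(f"unknown state {last!r}")
    run = 0
    for s in reversed(hist):
        if s != EFO:
            break
        run += 1
    entered_in_window = run < len(hist)
    if entered_in_window:
        mature = run >= config.maturity_age
    elif len(hist) >= config.maturity_age:
        mature = True  # age >= window length >= maturity_age
    else:
        raise ValueError("maturity not identifiable from this history")
    return 1.0 - config.harvest_prob if mature else 1.0


def ground_truth_conditionals(config: SimConfig, length: int) -> dict:
    """Oracle table over all patch-state histories of *length* slices.

    Histories whose forest maturity is not identifiable from the window are
    omitted.
    """
    states = [EFO, GRS, SHB, MFO, WDA]
    out = {}

    def rec(prefix):
        if len(prefix) == length:
            try:
                out[tuple(prefix)] = prob_next_efo(prefix, config)
            except ValueError:
                pass
            return
        for s in states:
            rec(prefix + [s])

    rec([])
    return out
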