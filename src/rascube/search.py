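"""OCCAM-style "Search": lattice beam search upward from independence.

Level 0 is the bottom (independence) model.  Each level generates all
parents of the retained models — structures whose complexity is
incrementally increased — fits them, scores them, and keeps the best
``width`` by the chosen sort metric.  Significance bookkeeping records, for
every retained model, the likelihood-ratio p-value against the bottom and
against its recorded parent; a model is flagged significant when both are
below ``alpha`` along its recorded path.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import metrics
from .core import CategoricalDataset
from .metrics import MetricRow
from .model import RAFitResults, RAModel
from .structures import ModelStructure, generate_parents

__all__ = ["SearchConfig", "SearchReport", "beam_search", "select_best"]

log = logging.getLogger(__name__)

SORT_METRICS = ("pct_dh_dv", "delta_bic", "delta_aic", "inf")


@dataclass
class SearchConfig:
    """Beam-search parameters (OCCAM's ``width`` and ``levels``)."""

    width: int = 3
    levels: int = 4
    sort_metric: str = "pct_dh_dv"
    alpha: float = 0.05
    tol: float = 1e-5
    max_iter: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.levels < 0:
            raise ValueError("width >= 1 and levels >= 0 required")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.sort_metric not in SORT_METRICS:
            raise ValueError(f"sort_metric must be one of {SORT_METRICS}")


@dataclass
class SearchReport:
    """Per-model metric rows plus the configuration and data fingerprint."""

    rows: list[MetricRow]
    config: SearchConfig
    data_fingerprint: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.rows])
        return df

    def to_csv(self, path, sep: str = "\t") -> None:
        df = self.to_dataframe()
        # Table-2 style column order, most complex models first
        df = df.sort_values(
            ["level", self.config.sort_metric, "name"],
            ascending=[False, False, True],
        )
        cols = [
            "name",
            "level",
            "inf",
            "pct_dh_dv",
            "delta_bic",
            "pct_correct_train",
            "pct_cover",
            "pct_correct_test",
            "delta_aic",
            "delta_df",
            "p_vs_bottom",
            "incremental_p",
            "significant",
            "parent",
        ]
        out = df[cols].copy()
        for c in ("inf",):
            out[c] = out[c].round(3)
        for c in ("pct_dh_dv", "pct_correct_train", "pct_cover", "pct_correct_test"):
            out[c] = out[c].astype(float).round(1)  # None (no test data) -> NaN
        out.to_csv(path, sep=sep, index=False)

    def best(self, metric: str | None = None) -> MetricRow:
        metric = metric or self.config.sort_metric
        return max(self.rows, key=lambda r: (getattr(r, metric), r.name))

    def row(self, name: str) -> MetricRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


def _fingerprint(data: CategoricalDataset) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(list(data.names)).encode())
    codes, w = data.codes_for(list(data.names))
    h.update(codes.tobytes())
    h.update(w.tobytes())
    return h.hexdigest()[:16]


def beam_search(
    train: CategoricalDataset,
    test: CategoricalDataset | None = None,
    config: SearchConfig | None = None,
) -> SearchReport:
    """Run the beam search and return the full report.

    Duplicate canonical structures reachable from several parents are fitted
    once; incremental significance is evaluated against the recorded
    (best-ranked) parent.
    """
    config = config or SearchConfig()
    if test is not None and (
        test.names != train.names or test.cards != train.cards
    ):
        raise ValueError("train and test variable declarations differ")

    bottom_structure = ModelStructure.bottom(train.names, train.dv_name)
    fits: dict[str, RAFitResults] = {}

    def fit(structure: ModelStructure) -> RAFitResults | None:
        nm = structure.name
        if nm not in fits:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                try:
                    fits[nm] = RAModel(train, structure).fit(
                        tol=config.tol, max_iter=config.max_iter
                    )
                except RuntimeWarning as w:
                    log.warning("skipping %s: %s", nm, w)
                    fits[nm] = None  # type: ignore[assignment]
        return fits[nm]

    bottom = fit(bottom_structure)
    assert bottom is not None

    def make_row(res: RAFitResults, level: int, parent_row: MetricRow | None) -> MetricRow:
        inf = metrics.information_captured(train, res, bottom)
        dh = metrics.pct_delta_h_dv(train, res)
        dbic, daic = metrics.information_criteria(train, res, bottom)
        p_bot = metrics.lr_significance(train, res, bottom)
        if parent_row is None:
            p_inc = 1.0 if level == 0 else p_bot
            parent_name = None
            parent_sig = True
        else:
            p_inc = metrics.lr_significance(train, res, fits[parent_row.name])
            parent_name = parent_row.name
            parent_sig = parent_row.significant
        sig = (
            True
            if level == 0
            else (p_bot < config.alpha and p_inc < config.alpha and parent_sig)
        )
        return MetricRow(
            name=res.name,
            level=level,
            inf=float(np.clip(inf, 0.0, 1.0)) if -1e-6 < inf < 1 + 1e-6 else inf,
            pct_dh_dv=dh,
            delta_bic=dbic,
            delta_aic=daic,
            pct_correct_train=metrics.pct_correct(res, train),
            pct_cover=metrics.pct_cover(train, res),
            pct_correct_test=(
                metrics.pct_correct(res, test) if test is not None else None
            ),
            p_vs_bottom=p_bot,
            incremental_p=p_inc,
            significant=sig,
            parent=parent_name,
            delta_df=res.delta_df,
        )

    bottom_row = make_row(bottom, 0, None)
    all_rows = [bottom_row]
    retained: list[MetricRow] = [bottom_row]

    for level in range(1, config.levels + 1):
        candidates: dict[str, MetricRow] = {}
        for parent_row in retained:
            parent_res = fits[parent_row.name]
            for child in generate_parents(parent_res.structure):
                nm = child.name
                if nm in candidates:
                    continue
                res = fit(child)
                if res is None or not res.converged:
                    continue
                candidates[nm] = make_row(res, level, parent_row)
        if not candidates:
            log.warning("no viable candidates at level %d; stopping", level)
            break
        ranked = sorted(
            candidates.values(),
            key=lambda r: (-getattr(r, config.sort_metric), r.name),
        )
        retained = ranked[: config.width]
        all_rows.extend(retained)
        log.info(
            "level %d: retained %s",
            level,
            ", ".join(r.name for r in retained),
        )

    return SearchReport(all_rows, config, _fingerprint(train))


def select_best(
    report: SearchReport,
    criterion: str = "max_metric_full_cover",
    manual: str | None = None,
) -> str:
    """Pick a model name from a search report.

    ``max_metric_full_cover``: best sort-metric among rows whose predicting
    state space is fully observed (%Cover = 100) — the conservative choice
    when deeper models start to need predictions for unseen IV states.
    ``max_delta_bic``: best dBIC row.  ``manual``: a user-supplied name,
    validated against the report.
    """
    if not report.rows:
        raise ValueError("empty report")
    names = [r.name for r in report.rows]
    if criterion == "manual":
        if manual is None:
            raise ValueError("manual selection requires a model name")
        if manual not in names:
            raise ValueError(
                f"model {manual!r} not in report; available: {', '.join(names)}"
            )
        return manual
    if criterion == "max_delta_bic":
        return max(report.rows, key=lambda r: (r.delta_bic, r.name)).name
    if criterion == "max_metric_full_cover":
        full = [r for r in report.rows if r.pct_cover >= 100.0 - 1e-9]
        if not full:
            raise ValueError(
                f"no rows with full cover; available: {', '.join(names)}"
            )
        metric = report.config.sort_metric
        return max(full, key=lambda r: (getattr(r, metric), r.name)).name
    raise ValueError(f"unknown criterion {criterion!r}")
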