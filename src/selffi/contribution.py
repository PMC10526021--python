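"""Ablation-contribution decomposition over a results table.

Given a table of evaluation metrics for every trained combination of the
three pre-training methods (including the no-pre-train baseline), the
decomposition attributes performance gains to each method m:

* individual improvement  I_m  = M_{m} − M_{baseline}
* additional improvement  A_mp = M_{m+p} − M_{p}   (m joined to partner p)
* total contribution      C_m  = I_m + (1/n) Σ_p A_mp

with n the number of partners for which both M_{m+p} and M_{p} are
available.  The module is pure table arithmetic and decomposes any results
table — the published clinical numbers or a desk-scale synthetic run alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

METHODS = ("pair_instance", "bilateral", "multimodal")
METRICS = ("auc", "accuracy", "f1", "precision", "recall")


def _normalize_key(methods: Iterable[str]) -> frozenset[str]:
    key = frozenset(methods)
    unknown = key - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}")
    return key


@dataclass
class ResultsTable:
    """Mapping from a method combination to its metric vector.

    The empty combination is the no-pre-train baseline and must be present.
    """

    entries: dict[frozenset, dict[str, float]] = field(default_factory=dict)

    def add(self, methods: Iterable[str], metrics: dict[str, float]) -> None:
        key = _normalize_key(methods)
        if key in self.entries:
            raise ValueError(f"duplicate method-set {sorted(key) or ['none']}")
        self.entries[key] = dict(metrics)

    def get(self, methods: Iterable[str], metric: str) -> float:
        key = _normalize_key(methods)
        if key not in self.entries:
            raise KeyError(
                f"results table has no entry for method-set {sorted(key) or ['none']}"
            )
        entry = self.entries[key]
        if metric not in entry:
            raise KeyError(f"metric {metric!r} missing for {sorted(key) or ['none']}")
        return float(entry[metric])

    def has(self, methods: Iterable[str]) -> bool:
        return _normalize_key(methods) in self.entries

    def validate(self) -> None:
        if frozenset() not in self.entries:
            raise ValueError("results table must contain the no-pre-train baseline")

    @staticmethod
    def from_csv(path: str | Path) -> "ResultsTable":
        """Read a results CSV with a ``methods`` column (``+``-joined names,
        ``none`` for the baseline) and one column per metric."""
        df = pd.read_csv(path)
        if "methods" not in df.columns:
            raise ValueError("results CSV needs a 'methods' column")
        table = ResultsTable()
        for _, row in df.iterrows():
            token = str(row["methods"]).strip()
            methods = [] if token in ("", "none") else token.split("+")
            metrics = {m: float(row[m]) for m in df.columns if m != "methods"}
            table.add(methods, metrics)
        table.validate()
        return table


def individual_improvement(table: ResultsTable, method: str, metric: str) -> float:
    """I_m: gain of the single method over the no-pre-train baseline."""
    return table.get([method], metric) - table.get([], metric)


def additional_improvement(table: ResultsTable, method: str, partner: str,
                           metric: str) -> float:
    """A_mp: extra gain of adding ``method`` on top of ``partner`` alone."""
    if method == partner:
        raise ValueError("additional improvement is undefined for a method with itself")
    return table.get([method, partner], metric) - table.get([partner], metric)


def total_contribution(table: ResultsTable, method: str, metric: str) -> float:
    """C_m = I_m + mean over available partners of A_mp."""
    i_m = individual_improvement(table, method, metric)
    addl = []
    for partner in METHODS:
        if partner == method:
            continue
        if table.has([method, partner]) and table.has([partner]):
            addl.append(additional_improvement(table, method, partner, metric))
    if not addl:
        warnings.warn(
            f"no pairwise combinations available for {method!r}; "
            "total contribution equals the individual improvement"
        )
        return i_m
    return i_m + sum(addl) / len(addl)


def contribution_table(table: ResultsTable,
                       metrics: Iterable[str] = METRICS) -> pd.DataFrame:
    """Long-format I/A/C decomposition for every method and metric."""
    table.validate()
    rows = []
    for method in METHODS:
        if not table.has([method]):
            continue
        for metric in metrics:
            row = {
                "method": method,
                "metric": metric,
                "individual_improvement": individual_improvement(table, method, metric),
            }
            for partner in METHODS:
                if partner == method:
                    continue
                if table.has([method, partner]) and table.has([partner]):
                    row[f"additional_vs_{partner}"] = additional_improvement(
                        table, method, partner, metric
                    )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["total_contribution"] = total_contribution(table, method, metric)
            rows.append(row)
    return pd.DataFrame(rows)
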