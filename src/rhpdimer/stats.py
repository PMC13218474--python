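"""Per-simulation metric aggregation and sequence-sensitivity statistics.

A :class:`SimulationMetrics` record gathers one trajectory's headline
numbers (percent of time adsorbed, interacting-residue percentages,
shared-water extrema, interface composition, RMSF group means).  Batches of
records are aggregated per sequence (mean ± sample standard deviation) and
compared across sequences with the Kruskal-Wallis H test — a rank-based
k-sample test chosen because the association metrics are not normally
distributed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import MONOMER_CODES

__all__ = [
    "SimulationMetrics",
    "KWTestResult",
    "aggregate_metrics",
    "kruskal_wallis",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "percent_time_adsorbed",
    "pct_residues_any_atom",
    "pct_residues_backbone",
    "max_shared",
    "sum_shared",
    "mean_shared",
    "mean_union_total",
)


@dataclass
class SimulationMetrics:
    """Headline metrics of one analyzed trajectory."""

    sequence: str
    conformation: str
    replicate: str
    percent_time_adsorbed: float
    pct_residues_any_atom: float
    pct_residues_backbone: float
    max_shared: int
    sum_shared: int
    mean_shared: float
    mean_union_total: float
    interface_composition: dict[str, float] | None = None
    rmsf_interacting: float | None = None
    rmsf_noninteracting: float | None = None

    def to_row(self) -> dict:
        row = {
            "sequence": self.sequence,
            "conformation": self.conformation,
            "replicate": self.replicate,
        }
        for col in METRIC_COLUMNS:
            row[col] = getattr(self, col)
        for c in MONOMER_CODES:
            row[f"iface_{c}"] = (
                self.interface_composition[c]
                if self.interface_composition is not None
                else np.nan
            )
        row["rmsf_interacting"] = (
            np.nan if self.rmsf_interacting is None else self.rmsf_interacting
        )
        row["rmsf_noninteracting"] = (
            np.nan if self.rmsf_noninteracting is None else self.rmsf_noninteracting
        )
        return row


def aggregate_metrics(
    records: list[SimulationMetrics] | pd.DataFrame, by: str = "sequence"
) -> pd.DataFrame:
    """Per-group mean and sample standard deviation (ddof=1) of each metric.

    Groups with a single record get NaN (undefined) standard deviations.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        if not records:
            raise ValueError("no records to aggregate")
        df = pd.DataFrame([r.to_row() for r in records])
    numeric = [c for c in df.columns if c not in ("sequence", "conformation", "replicate")]
    grouped = df.groupby(by)[numeric]
    agg = grouped.agg(["mean", "std", "count"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


@dataclass(frozen=True)
class KWTestResult:
    """Tie-corrected Kruskal-Wallis H statistic with its p-value."""

    H: float
    df: int
    pvalue: float
    group_sizes: tuple[int, ...]
    group_medians: tuple[float, ...]
    method: str

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "df": self.df,
            "pvalue": self.pvalue,
            "group_sizes": list(self.group_sizes),
            "group_medians": list(self.group_medians),
            "method": self.method,
        }


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected H from mid-ranks (the classical rank formula)."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * r.mean() ** 2
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    if tie == 0:
        raise ValueError("all values identical; H test undefined")
    return h / tie


def kruskal_wallis(
    groups: list, method: str = "chi2"
) -> KWTestResult:
    """Kruskal-Wallis H test across k groups of real values.

    ``method='chi2'`` uses the chi-square approximation with k−1 degrees of
    freedom (standard at ~10 observations per group); ``'permutation'``
    computes an exact p-value by enumerating all assignments of the pooled
    values to the group sizes (feasible only for small pooled n).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in arrays):
        raise ValueError("every group needs at least 1 value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; H test undefined")

    h_obs = _h_statistic(arrays)
    df = len(arrays) - 1
    sizes = tuple(len(g) for g in arrays)
    medians = tuple(float(np.median(g)) for g in arrays)

    if method == "chi2":
        p = float(sps.chi2.sf(h_obs, df))
        # cross-check against the library implementation
        h_ref = sps.kruskal(*arrays).statistic
        if not np.isclose(h_obs, h_ref, rtol=1e-10, atol=1e-10):
            raise AssertionError("H statistic disagrees with reference formula")
    elif method == "permutation":
        n = len(pooled)
        if n > 10:
            raise ValueError("exhaustive permutation only supported for pooled n <= 10")
        count_ge = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            regrouped = []
            start = 0
            for s in sizes:
                regrouped.append(pooled[list(perm[start : start + s])])
                start += s
            total += 1
            if _h_statistic(regrouped) >= h_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
    else:
        raise ValueError(f"unknown method {method!r}")
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return KWTestResult(float(h_obs), df, p, sizes, medians, method)
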