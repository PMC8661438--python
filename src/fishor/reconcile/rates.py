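"""Per-branch birth/death rates, rate summaries and the loss-vs-pseudogene
threshold sweep."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fishor.reconcile.dl import ReconciliationResult


def branch_rates(gains: int, losses: int, n_anc: float, t: float) -> tuple[float, float]:
    """Birth and death rates per gene per Myr: b = G/(n_anc*t), d = L/(n_anc*t).

    Returns (nan, nan) when ``n_anc`` is 0 (undefined-marked).
    """
    if t <= 0:
        raise ValueError("branch duration t must be positive")
    if n_anc < 0:
        raise ValueError("n_anc must be non-negative")
    if n_anc == 0:
        return (math.nan, math.nan)
    return gains / (n_anc * t), losses / (n_anc * t)


def events_table(results: list[ReconciliationResult]) -> pd.DataFrame:
    """Aggregate per-branch events over gene families into one table.

    Gains, losses and ancestral copy numbers are summed per branch; rates
    are computed from the pooled counts.
    """
    acc: dict[str, dict] = {}
    for res in results:
        for key, ev in res.events.items():
            row = acc.setdefault(key, {"branch_id": key, "t": ev.t,
                                       "n_anc": 0.0, "gains": 0, "losses": 0})
            row["n_anc"] += ev.n_anc
            row["gains"] += ev.gains
            row["losses"] += ev.losses
    rows = []
    for row in acc.values():
        b, d = (branch_rates(row["gains"], row["losses"], row["n_anc"], row["t"])
                if row["t"] > 0 else (math.nan, math.nan))
        row["b"] = b
        row["d"] = d
        rows.append(row)
    return pd.DataFrame(rows).sort_values("branch_id").reset_index(drop=True)


@dataclass
class RateSummary:
    mean_birth: float
    mean_death: float
    n_branches: int
    excluded: list[str] = field(default_factory=list)
    max_birth: tuple[str, float] | None = None
    max_death: tuple[str, float] | None = None
    per_branch: pd.DataFrame | None = None

    @property
    def empty(self) -> bool:
        return self.n_branches == 0


def summarize_rates(table: pd.DataFrame, min_branch_myr: float = 2.0) -> RateSummary:
    """Mean rates over branches with t >= ``min_branch_myr`` and defined
    rates; short or undefined branches are excluded and listed."""
    excluded = []
    keep = []
    for _, row in table.iterrows():
        if row["t"] < min_branch_myr or not np.isfinite(row["b"]) or not np.isfinite(row["d"]):
            excluded.append(str(row["branch_id"]))
        else:
            keep.append(row)
    if not keep:
        return RateSummary(mean_birth=math.nan, mean_death=math.nan,
                           n_branches=0, excluded=excluded, per_branch=table)
    kept = pd.DataFrame(keep)
    bmax = kept.loc[kept["b"].idxmax()]
    dmax = kept.loc[kept["d"].idxmax()]
    return RateSummary(mean_birth=float(kept["b"].mean()),
                       mean_death=float(kept["d"].mean()),
                       n_branches=len(kept), excluded=excluded,
                       max_birth=(str(bmax["branch_id"]), float(bmax["b"])),
                       max_death=(str(dmax["branch_id"]), float(dmax["d"])),
                       per_branch=table)


def loss_pseudo_sweep(terminal_table: pd.DataFrame,
                      thresholds=None, variant: str = "pseudo_truncated") -> pd.DataFrame:
    """Pearson correlation between inferred losses and observed remnant
    counts on terminal branches, swept over maximum branch-length
    thresholds.

    ``terminal_table`` columns: t, losses, n_pseudo, n_truncated, n_edge.
    ``variant`` selects the response: pseudo_truncated (default),
    pseudo, truncated, or edge. Thresholds with fewer than 3 branches, or
    with degenerate variance, yield NaN.
    """
    if len(terminal_table) < 3:
        raise ValueError("need at least 3 terminal branches")
    if thresholds is None:
        thresholds = list(range(2, 201))
    col = {"pseudo_truncated": None, "pseudo": "n_pseudo",
           "truncated": "n_truncated", "edge": "n_edge"}[variant]
    if col is None:
        response = terminal_table["n_pseudo"] + terminal_table["n_truncated"]
    else:
        response = terminal_table[col]
    losses = terminal_table["losses"].to_numpy(dtype=float)
    resp = response.to_numpy(dtype=float)
    tvals = terminal_table["t"].to_numpy(dtype=float)
    rows = []
    for tau in thresholds:
        mask = tvals <= tau
        n = int(mask.sum())
        if n < 3:
            r = math.nan
        else:
            x = losses[mask]
            y = resp[mask]
            if x.std() == 0 or y.std() == 0:
                r = math.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"threshold": tau, "n_branches": n, "r": r})
    return pd.DataFrame(rows)
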