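"""Stacked mixed-model form of an EMA table.

A day with observed occasions t = 0..n-1 contributes one transition row per
mood channel for every *adjacent* observed pair (t-1, t): the response is the
mood at t, the covariates are all lagged moods at t-1, the contemporaneous
exogenous value e_t, and a constant.  Pairs broken by a skipped prompt are
listwise-deleted, and pairs never span the overnight gap.  Rows are stacked
channel-major within a day (all mood-1 rows, then mood-2, ...), giving

    Y_i = X_i beta + Z_i b_i + eps_i,

with X_i = Z_i of shape k(n_i - 1) x (k^2 + 2k) in the full model: row r for
channel c has the lagged moods in columns [c*k, (c+1)*k), e in column k^2 + c,
and 1 in column k^2 + k + c, zeros elsewhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import EmaDataset, mood_columns

__all__ = ["StackedDay", "StackedData", "IdentifiabilityReport",
           "build_day_design", "stack_dataset", "check_identifiability",
           "dump_stacked"]

logger = logging.getLogger(__name__)


@dataclass
class StackedDay:
    """One day's block of the stacked system (full model: X == Z)."""

    day_index: int
    Y: np.ndarray            # (k * n_transitions,)
    X: np.ndarray            # (k * n_transitions, k^2 + 2k)
    Z: np.ndarray
    n_transitions: int

    @property
    def n_rows(self) -> int:
        return self.Y.shape[0]


@dataclass
class StackedData:
    """Per-day stacked blocks pooled for the likelihood."""

    days: list[StackedDay]
    k: int
    dropped_days: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.days:
            raise ValueError("no day contributed a usable transition")
        for d in self.days:
            if d.n_transitions < 1:
                raise ValueError(f"day {d.day_index} has zero transitions")

    @property
    def q(self) -> int:
        return self.k * self.k + 2 * self.k

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def total_obs(self) -> int:
        return int(sum(d.n_rows for d in self.days))


def build_day_design(day: pd.DataFrame, k: int) -> StackedDay | None:
    """Build one day's (Y, X, Z) block; None if no usable transition survives.

    Only pairs of occasions that are both observed and adjacent in the nominal
    schedule (occasion numbers differing by exactly 1) become rows.
    """
    cols = mood_columns(k)
    missing = [c for c in cols if c not in day.columns]
    if missing:
        raise ValueError(f"day block lacks mood columns {missing} for k={k}")
    occ_all = day["occasion"].to_numpy()
    if np.any(np.diff(occ_all) <= 0):
        raise ValueError("occasions must be sorted strictly increasing within a day")
    obs = day[day["observed"].astype(bool)]
    if len(obs) < 2:
        return None
    occ = obs["occasion"].to_numpy()
    m = obs[cols].to_numpy(dtype=float)
    e = obs["e"].to_numpy(dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("exogenous value missing on an observed occasion")
    pair = np.nonzero(np.diff(occ) == 1)[0]      # indices of the lagged rows
    nt = pair.size
    if nt == 0:
        return None
    lag = m[pair]            # (nt, k) moods at t-1
    resp = m[pair + 1]       # (nt, k) moods at t
    e_t = e[pair + 1]        # contemporaneous with the response
    q = k * k + 2 * k
    X = np.zeros((k * nt, q))
    Y = np.empty(k * nt)
    for c in range(k):
        rows = slice(c * nt, (c + 1) * nt)
        X[rows, c * k:(c + 1) * k] = lag
        X[rows, k * k + c] = e_t
        X[rows, k * k + k + c] = 1.0
        Y[rows] = resp[:, c]
    day_index = int(day["day"].iloc[0])
    return StackedDay(day_index=day_index, Y=Y, X=X, Z=X.copy(), n_transitions=int(nt))


def stack_dataset(data: EmaDataset | pd.DataFrame, k: int | None = None) -> StackedData:
    """Stack every day of an EMA table; days without usable transitions are
    dropped with a warning."""
    if isinstance(data, EmaDataset):
        df = data.df
        k = data.k if k is None else k
    else:
        df = data
        if k is None:
            raise ValueError("k must be given when stacking a bare DataFrame")
    days: list[StackedDay] = []
    dropped: list[int] = []
    for day_idx, block in df.groupby("day", sort=True):
        stacked = build_day_design(block, k)
        if stacked is None:
            dropped.append(int(day_idx))
        else:
            days.append(stacked)
    if dropped:
        logger.warning("dropped %d day(s) with no usable transitions: %s",
                       len(dropped), dropped)
    if not days:
        raise ValueError("no usable transitions in the whole dataset "
                         "(all pairs broken by missingness?)")
    return StackedData(days=days, k=k, dropped_days=dropped)


@dataclass
class IdentifiabilityReport:
    """Rule-of-thumb check: observations must outnumber random effects."""

    total_obs: int
    n_random_effects: int
    n_days: int
    nbar: float              # mean scheduled occasions per retained day
    k: int
    ok: bool
    message: str


def check_identifiability(stacked: StackedData, q: int | None = None) -> IdentifiabilityReport:
    """Warn (never abort) when k * sum(n_i - 1) <= q * N.

    The equivalent design guideline is k < nbar - 2: with nbar occasions per
    day, each extra mood node adds k + 2 random effects per day but only
    nbar - 1 observations.
    """
    q = stacked.q if q is None else q
    total = stacked.total_obs
    n_re = q * stacked.n_days
    nbar = float(np.mean([d.n_transitions + 1 for d in stacked.days]))
    ok = total > n_re
    msg = (f"{total} observations vs {n_re} random effects "
           f"({stacked.n_days} days x {q}); rule of thumb k < nbar - 2 "
           f"gives k < {nbar - 2:.1f} at nbar = {nbar:.1f} occasions/day "
           f"(k = {stacked.k})")
    if not ok:
        warnings.warn("random effects may not be identifiable: " + msg,
                      stacklevel=2)
    return IdentifiabilityReport(total_obs=total, n_random_effects=n_re,
                                 n_days=stacked.n_days, nbar=nbar, k=stacked.k,
                                 ok=ok, message=msg)


def dump_stacked(stacked: StackedData, path) -> None:
    """Debugging dump of the stacked system as plain text (not a public format)."""
    with open(path, "w") as fh:
        fh.write(f"# stacked system: k={stacked.k} q={stacked.q} "
                 f"days={stacked.n_days} total_obs={stacked.total_obs}\n")
        for d in stacked.days:
            fh.write(f"# day {d.day_index} transitions={d.n_transitions}\n")
            np.savetxt(fh, np.column_stack([d.Y, d.X]), fmt="%.10g")
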