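"""Data-generating process for LARMEx mood networks.

Each simulated day gets its own random-effect draw (rejection-sampled so the
day-level AR matrix is stable), a fresh uniform initial mood vector — days
start anew rather than carrying the previous evening's mood across the
overnight gap — and per-occasion uniform exogenous inputs.  The within-day
trajectory then iterates the VAR(1) recursion with Gaussian innovations.
Missingness, when requested, is completely at random at the occasion level:
an EMA prompt is answered or skipped as a whole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .model import DayDraw, ModelSpec, assemble_coefficients

__all__ = [
    "SimConfig",
    "EmaDataset",
    "PoolSample",
    "sample_stable_pool",
    "sample_day_draws",
    "simulate_day",
    "simulate_dataset",
    "apply_missingness",
    "compute_snr",
]


@dataclass
class SimConfig:
    """Settings for one simulated EMA collection.

    Defaults mirror a common intensive-sampling design: 10 prompts per day,
    initial moods uniform on [-0.5, 0.5], exogenous intensities uniform on
    [0, 0.5] (keeping trajectories mostly inside [-1, 1]), and a
    20,000-candidate rejection-sampling pool for the stable day effects.
    """

    spec: ModelSpec
    n_days: int
    n_per_day: int = 10
    candidate_pool: int = 20000
    init_range: tuple[float, float] = (-0.5, 0.5)
    exo_range: tuple[float, float] = (0.0, 0.5)
    missing_rate: float = 0.0
    seed: int | np.random.SeedSequence | None = None
    exo_per_day: bool = False  # hold e constant within a day instead of per occasion

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_per_day < 2:
            raise ValueError("n_per_day must be >= 2 (no transition otherwise)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.candidate_pool < self.n_days:
            raise ValueError("candidate_pool must be >= n_days")


def mood_columns(k: int) -> list[str]:
    return [f"m{j + 1}" for j in range(k)]


@dataclass
class EmaDataset:
    """Long-format EMA table plus (for simulated data) the ground truth.

    ``df`` has one row per occasion with columns
    ``day, occasion, m1..mk, e, observed``.  ``draws`` and ``noiseless`` are
    attached by the simulator and carry the realized day effects and the
    innovation-free trajectories; they are absent for real data.
    """

    df: pd.DataFrame
    k: int
    draws: list[DayDraw] | None = None
    noiseless: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = ["day", "occasion", *mood_columns(self.k), "e", "observed"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"EMA table is missing columns {missing}")
        for _, block in self.df.groupby("day"):
            occ = block["occasion"].to_numpy()
            if np.any(np.diff(occ) <= 0):
                raise ValueError("occasions within a day must be strictly increasing")

    @property
    def n_days(self) -> int:
        return self.df["day"].nunique()

    def observed_fraction(self) -> float:
        return float(self.df["observed"].mean())

    def day_block(self, day: int) -> pd.DataFrame:
        return self.df[self.df["day"] == day]


@dataclass
class PoolSample:
    """Rejection-sampling pool of candidate day effects.

    ``b_candidates`` holds all draws from N(0, G); ``stable_mask`` flags those
    whose summed AR matrix has spectral radius < 1.
    """

    spec: ModelSpec
    b_candidates: np.ndarray        # (n_candidates, q)
    stable_mask: np.ndarray         # (n_candidates,) bool

    @property
    def n_candidates(self) -> int:
        return self.b_candidates.shape[0]

    @property
    def b_stable(self) -> np.ndarray:
        return self.b_candidates[self.stable_mask]

    @property
    def retention_rate(self) -> float:
        return float(self.stable_mask.mean())

    def sign_preserved_mask(self, stable_only: bool = True) -> np.ndarray:
        """Which draws keep every non-zero trait edge's strict sign."""
        spec = self.spec
        k = spec.k
        b = self.b_stable if stable_only else self.b_candidates
        B_net = np.concatenate([spec.beta_ar.ravel(), spec.beta_e]) + b[:, : k * k + k]
        beta_net = np.concatenate([spec.beta_ar.ravel(), spec.beta_e])
        active = beta_net != 0.0
        return np.all(np.sign(B_net[:, active]) == np.sign(beta_net[active]), axis=1)

    def sign_preserved_rate(self, stable_only: bool = True) -> float:
        mask = self.sign_preserved_mask(stable_only=stable_only)
        return float(mask.mean()) if mask.size else float("nan")


def _psd_factor(G: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = G for a PSD matrix (eigen-based, rank-safe)."""
    evals, evecs = np.linalg.eigh(G)
    tol = -1e-10 * max(1.0, float(np.abs(evals).max(initial=1.0)))
    if evals.min(initial=0.0) < tol:
        raise ValueError("G is not positive semi-definite")
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def sample_stable_pool(spec: ModelSpec, candidate_pool: int,
                       rng: np.random.Generator) -> PoolSample:
    """Draw ``candidate_pool`` b-vectors from N(0, G) and flag the stable ones."""
    k, q = spec.k, spec.q
    L = _psd_factor(spec.G)
    b = rng.standard_normal((candidate_pool, q)) @ L.T
    A = spec.beta_ar[None, :, :] + b[:, : k * k].reshape(-1, k, k)
    eigs = np.linalg.eigvals(A)
    stable = np.max(np.abs(eigs), axis=1) < 1.0
    return PoolSample(spec=spec, b_candidates=b, stable_mask=stable)


def sample_day_draws(config: SimConfig, rng: np.random.Generator | None = None,
                     return_pool: bool = False):
    """Rejection-sample ``n_days`` stable day effects.

    Candidates are drawn from N(0, G), those with an unstable summed AR
    matrix are discarded, and the days are sampled from the survivors without
    replacement (so duplicate-day artifacts cannot occur).  Raises if fewer
    than ``n_days`` candidates survive, reporting the retention rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = sample_stable_pool(config.spec, config.candidate_pool, rng)
    b_ok = pool.b_stable
    if b_ok.shape[0] < config.n_days:
        raise RuntimeError(
            f"only {b_ok.shape[0]} of {pool.n_candidates} candidate draws were stable "
            f"(retention {pool.retention_rate:.4f}); need {config.n_days} — "
            "shrink G or enlarge candidate_pool")
    idx = rng.choice(b_ok.shape[0], size=config.n_days, replace=False)
    draws = [DayDraw.from_vector(i, b_ok[j], config.spec.k, stable=True)
             for i, j in enumerate(idx)]
    return (draws, pool) if return_pool else draws


def simulate_day(spec: ModelSpec, draw: DayDraw, n_occ: int,
                 rng: np.random.Generator,
                 init_range: tuple[float, float] = (-0.5, 0.5),
                 exo_range: tuple[float, float] = (0.0, 0.5),
                 exo_per_day: bool = False) -> pd.DataFrame:
    """Simulate one day's trajectory.

    Returns a frame with both the noisy moods (``m1..mk``) and the
    innovation-free trajectory (``m1_clean..``) computed from the same initial
    value and exogenous inputs.  ``n_occ`` occasions yield ``n_occ - 1``
    transitions.
    """
    if n_occ < 2:
        raise ValueError("n_occ must be >= 2: a single occasion has no transition")
    if not draw.stable:
        raise ValueError("refusing to simulate from an unstable day draw")
    k = spec.k
    B_ar, B_e, B_c = assemble_coefficients(spec, draw)
    m0 = rng.uniform(init_range[0], init_range[1], size=k)
    e = rng.uniform(exo_range[0], exo_range[1], size=n_occ)
    if exo_per_day:
        e[:] = e[0]
    sd = math.sqrt(spec.sigma2)
    eps = rng.normal(0.0, sd, size=(n_occ, k)) if sd > 0 else np.zeros((n_occ, k))
    m = np.empty((n_occ, k))
    m_clean = np.empty((n_occ, k))
    m[0] = m_clean[0] = m0
    for t in range(1, n_occ):
        drive = B_e * e[t] + B_c
        m[t] = B_ar @ m[t - 1] + drive + eps[t]
        m_clean[t] = B_ar @ m_clean[t - 1] + drive
    frame = pd.DataFrame({"day": draw.day_index, "occasion": np.arange(n_occ), "e": e,
                          "observed": True})
    for j, col in enumerate(mood_columns(k)):
        frame[col] = m[:, j]
        frame[col + "_clean"] = m_clean[:, j]
    cols = ["day", "occasion", *mood_columns(k), "e", "observed",
            *[c + "_clean" for c in mood_columns(k)]]
    return frame[cols]


def simulate_dataset(config: SimConfig, rng: np.random.Generator | None = None) -> EmaDataset:
    """Simulate a full EMA collection under ``config``.

    One root seed; per-day child streams, so the realization is reproducible
    and days could be regenerated independently.
    """
    spec = config.spec
    if rng is not None:
        ss = np.random.SeedSequence(rng.integers(0, 2**31 - 1))
    elif isinstance(config.seed, np.random.SeedSequence):
        ss = config.seed
    else:
        ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_days + 2)
    draw_rng = np.random.default_rng(streams[0])
    draws = sample_day_draws(config, rng=draw_rng)
    blocks = [
        simulate_day(spec, draw, config.n_per_day, np.random.default_rng(streams[1 + i]),
                     init_range=config.init_range, exo_range=config.exo_range,
                     exo_per_day=config.exo_per_day)
        for i, draw in enumerate(draws)
    ]
    full = pd.concat(blocks, ignore_index=True)
    clean_cols = ["day", "occasion"] + [c + "_clean" for c in mood_columns(spec.k)]
    noiseless = full[clean_cols].rename(
        columns={c + "_clean": c for c in mood_columns(spec.k)})
    public = full[["day", "occasion", *mood_columns(spec.k), "e", "observed"]].copy()
    data = EmaDataset(df=public, k=spec.k, draws=draws, noiseless=noiseless)
    if config.missing_rate > 0:
        data = apply_missingness(data, config.missing_rate,
                                 np.random.default_rng(streams[-1]))
    return data


def apply_missingness(data: EmaDataset, rate: float,
                      rng: np.random.Generator) -> EmaDataset:
    """Mark occasions unobserved independently with probability ``rate`` (MCAR).

    Ground truth (draws, noiseless trajectories) is untouched; mood values stay
    in the table but carry ``observed=False`` and are excluded downstream.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must be in [0, 1)")
    df = data.df.copy()
    if rate > 0:
        keep = rng.uniform(size=len(df)) >= rate
        df["observed"] = df["observed"].to_numpy() & keep
    return EmaDataset(df=df, k=data.k, draws=data.draws, noiseless=data.noiseless)


def compute_snr(spec: ModelSpec, config: SimConfig, n_mc: int = 100_000,
                rng: np.random.Generator | None = None,
                lag_range: tuple[float, float] = (-1.0, 1.0)) -> float:
    """Monte-Carlo signal-to-noise ratio of the data-generating process.

    SNR = Var(B_ar m + B_e e + B_c) / sigma2 — the variance of the noiseless
    one-step signal over the noise variance, not in decibels.  The lagged mood
    vector m is drawn uniformly over the process's operating range
    (``lag_range``, default [-1, 1], the band trajectories mostly stay in),
    the exogenous input from ``config.exo_range``, and the day coefficients
    from the stability-retained random-effect distribution; the one-step
    means are pooled across days, occasions, and all mood channels.  At the
    reference two-mood network with G = 0.03 I this yields roughly
    {12, 6, 2} for sigma2 in {0.01, 0.02, 0.06}.  ``n_mc`` is the minimum
    number of pooled transition values.
    """
    if spec.sigma2 <= 0:
        raise ValueError("SNR is undefined for sigma2 == 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k, n_occ = spec.k, config.n_per_day
    per_day = k * (n_occ - 1)
    n_days = max(1, math.ceil(n_mc / per_day))
    pool = sample_stable_pool(spec, max(config.candidate_pool, 2 * n_days), rng)
    b_ok = pool.b_stable
    if b_ok.shape[0] == 0:
        raise RuntimeError("no stable candidate draws; cannot compute SNR")
    b = b_ok[rng.choice(b_ok.shape[0], size=n_days, replace=True)]
    A = spec.beta_ar[None] + b[:, : k * k].reshape(-1, k, k)
    Be = spec.beta_e[None] + b[:, k * k: k * k + k]
    Bc = spec.beta_c[None] + b[:, k * k + k:]
    e = rng.uniform(config.exo_range[0], config.exo_range[1], size=(n_days, n_occ))
    if config.exo_per_day:
        e = np.repeat(e[:, :1], n_occ, axis=1)
    signal = np.empty((n_occ - 1, n_days, k))
    for t in range(1, n_occ):
        m = rng.uniform(lag_range[0], lag_range[1], size=(n_days, k))
        signal[t - 1] = np.einsum("dij,dj->di", A, m) + Be * e[:, t, None] + Bc
    return float(signal.var()) / spec.sigma2
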