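"""Parameter objects for exogenous linear autoregressive mixed-effects
(LARMEx) affect networks.

The model describes ``k`` mood variables measured several times per day.
Within day ``i`` the moods follow a first-order vector autoregression driven
by a scalar exogenous input ``e`` (stressors, events) and Gaussian
innovations::

    m_t = B_ar @ m_{t-1} + B_e * e_t + B_c + eps_t,   eps_t ~ N(0, sigma2 * I)

Every coefficient is the sum of a subject-level fixed effect (``beta``, the
trait network, constant across days) and a day-level random effect
(``b_i ~ N(0, G)``, the state deviation of day ``i``).  The ``q = k**2 + 2k``
random effects are flattened row-major over the autoregressive matrix, then
the exogenous vector, then the constants; this order matches the columns of
the mixed-model design matrices built in :mod:`larmex.design`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "G_STRUCTURES",
    "ModelSpec",
    "DayDraw",
    "SignPattern",
    "assemble_coefficients",
    "is_stable",
    "spectral_radius",
    "sign_preserved",
    "flatten_effects",
    "unflatten_effects",
    "build_cs_matrix",
    "build_G",
    "reference_two_mood_spec",
    "reference_four_mood_spec",
    "spec_to_dict",
    "spec_from_dict",
]

G_STRUCTURES = ("diagonal", "compound_symmetric", "block_cs_ar_exo_independent")

_PSD_TOL = 1e-10


def flatten_effects(b_ar: np.ndarray, b_e: np.ndarray, b_c: np.ndarray) -> np.ndarray:
    """Flatten (b_ar, b_e, b_c) into the canonical q-vector.

    Order: row-major autoregressive entries, then exogenous, then constants —
    the column order of the design matrices.
    """
    b_ar = np.asarray(b_ar, dtype=float)
    return np.concatenate([b_ar.ravel(order="C"),
                           np.asarray(b_e, dtype=float).ravel(),
                           np.asarray(b_c, dtype=float).ravel()])


def unflatten_effects(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`flatten_effects` for a network of ``k`` moods."""
    b = np.asarray(b, dtype=float).ravel()
    q = k * k + 2 * k
    if b.size != q:
        raise ValueError(f"effect vector has length {b.size}, expected q={q} for k={k}")
    return b[: k * k].reshape(k, k), b[k * k: k * k + k].copy(), b[k * k + k:].copy()


def spectral_radius(B_ar: np.ndarray) -> float:
    """Largest eigenvalue modulus of a square coefficient matrix."""
    B_ar = np.asarray(B_ar, dtype=float)
    if B_ar.ndim != 2 or B_ar.shape[0] != B_ar.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {B_ar.shape}")
    if not np.all(np.isfinite(B_ar)):
        raise ValueError("coefficient matrix contains non-finite entries")
    return float(np.max(np.abs(np.linalg.eigvals(B_ar))))


def is_stable(B_ar: np.ndarray) -> bool:
    """True iff the VAR(1) coefficient matrix is stable (spectral radius < 1).

    Complex eigenvalues are judged by modulus; this is the standard
    stationarity condition for a first-order vector autoregression.
    """
    return spectral_radius(B_ar) < 1.0


@dataclass(frozen=True)
class ModelSpec:
    """Subject-level specification of a LARMEx mood network.

    Parameters
    ----------
    k : int
        Number of mood nodes.
    beta_ar : (k, k) array
        Fixed auto-/cross-lagged coefficients; diagonal entries are
        self-loops, off-diagonal entries cross-lagged edges.
    beta_e : (k,) array
        Fixed contemporaneous effects of the exogenous node on each mood.
    beta_c : (k,) array
        Fixed constants (intercepts).
    G : (q, q) array, q = k**2 + 2k
        Covariance of the day-level random effects, in the canonical
        flattening order.
    sigma2 : float
        Innovation variance; the within-day residual covariance is
        ``sigma2 * I`` (no measurement-error layer).
    G_structure : str
        One of ``diagonal``, ``compound_symmetric``,
        ``block_cs_ar_exo_independent``; a tag describing (and validated
        against) the shape of ``G``.
    """

    k: int
    beta_ar: np.ndarray
    beta_e: np.ndarray
    beta_c: np.ndarray
    G: np.ndarray
    sigma2: float
    G_structure: str = "diagonal"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        object.__setattr__(self, "beta_ar", np.atleast_2d(np.asarray(self.beta_ar, dtype=float)))
        object.__setattr__(self, "beta_e", np.asarray(self.beta_e, dtype=float).ravel())
        object.__setattr__(self, "beta_c", np.asarray(self.beta_c, dtype=float).ravel())
        object.__setattr__(self, "G", np.asarray(self.G, dtype=float))
        k, q = self.k, self.q
        if self.beta_ar.shape != (k, k):
            raise ValueError(f"beta_ar has shape {self.beta_ar.shape}, expected {(k, k)}")
        if self.beta_e.shape != (k,):
            raise ValueError(f"beta_e has shape {self.beta_e.shape}, expected {(k,)}")
        if self.beta_c.shape != (k,):
            raise ValueError(f"beta_c has shape {self.beta_c.shape}, expected {(k,)}")
        if self.G.shape != (q, q):
            raise ValueError(f"G has shape {self.G.shape}, expected {(q, q)} (q = k^2 + 2k)")
        if not np.allclose(self.G, self.G.T, atol=1e-12):
            raise ValueError("G must be symmetric")
        evals = np.linalg.eigvalsh(self.G)
        if evals.min(initial=0.0) < -_PSD_TOL * max(1.0, abs(evals).max(initial=1.0)):
            raise ValueError("G must be positive semi-definite")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.G_structure not in G_STRUCTURES:
            raise ValueError(f"unknown G_structure {self.G_structure!r}; choose from {G_STRUCTURES}")
        if self.G_structure == "diagonal":
            off = self.G - np.diag(np.diag(self.G))
            if np.any(off != 0.0):
                raise ValueError("G_structure='diagonal' requires exactly zero off-diagonal entries")
        if not is_stable(self.beta_ar):
            raise ValueError(
                f"fixed-effect network is unstable: spectral radius "
                f"{spectral_radius(self.beta_ar):.3f} >= 1")

    @property
    def q(self) -> int:
        """Number of random effects, k**2 + 2k."""
        return self.k * self.k + 2 * self.k

    @property
    def beta(self) -> np.ndarray:
        """Fixed effects flattened into the canonical q-vector."""
        return flatten_effects(self.beta_ar, self.beta_e, self.beta_c)


@dataclass(frozen=True)
class DayDraw:
    """One day's realized random effects.

    ``stable`` records whether ``beta_ar + b_ar`` passed the spectral-radius
    check at sampling time (rejection-sampled draws always have it True).
    """

    day_index: int
    b_ar: np.ndarray
    b_e: np.ndarray
    b_c: np.ndarray
    stable: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "b_ar", np.atleast_2d(np.asarray(self.b_ar, dtype=float)))
        object.__setattr__(self, "b_e", np.asarray(self.b_e, dtype=float).ravel())
        object.__setattr__(self, "b_c", np.asarray(self.b_c, dtype=float).ravel())
        k = self.b_ar.shape[0]
        if self.b_ar.shape != (k, k):
            raise ValueError(f"b_ar must be square, got {self.b_ar.shape}")
        if self.b_e.shape != (k,) or self.b_c.shape != (k,):
            raise ValueError("b_e and b_c must be k-vectors matching b_ar")

    @property
    def k(self) -> int:
        return self.b_ar.shape[0]

    @property
    def b(self) -> np.ndarray:
        """The flattened q-vector b_i (row-major b_ar, then b_e, then b_c)."""
        return flatten_effects(self.b_ar, self.b_e, self.b_c)

    @classmethod
    def from_vector(cls, day_index: int, b: np.ndarray, k: int, stable: bool = True) -> "DayDraw":
        b_ar, b_e, b_c = unflatten_effects(b, k)
        return cls(day_index=day_index, b_ar=b_ar, b_e=b_e, b_c=b_c, stable=stable)

    @classmethod
    def zero(cls, k: int, day_index: int = 0) -> "DayDraw":
        return cls(day_index=day_index, b_ar=np.zeros((k, k)),
                   b_e=np.zeros(k), b_c=np.zeros(k), stable=True)


def assemble_coefficients(spec: ModelSpec, draw: DayDraw) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Day-level coefficients B = beta + b_i, entrywise.

    Returns ``(B_ar, B_e, B_c)``; raises on any dimension mismatch, naming
    the offending component.
    """
    if draw.b_ar.shape != spec.beta_ar.shape:
        raise ValueError(
            f"b_ar shape {draw.b_ar.shape} does not match beta_ar {spec.beta_ar.shape}")
    if draw.b_e.shape != spec.beta_e.shape:
        raise ValueError(
            f"b_e shape {draw.b_e.shape} does not match beta_e {spec.beta_e.shape}")
    if draw.b_c.shape != spec.beta_c.shape:
        raise ValueError(
            f"b_c shape {draw.b_c.shape} does not match beta_c {spec.beta_c.shape}")
    return (spec.beta_ar + draw.b_ar, spec.beta_e + draw.b_e, spec.beta_c + draw.b_c)


@dataclass(frozen=True)
class SignPattern:
    """Entrywise signs of the network edges (AR and exogenous coefficients).

    Constants are excluded: they do not appear in a network representation.
    Entries are in {-1, 0, +1}.
    """

    ar_signs: np.ndarray
    e_signs: np.ndarray

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "SignPattern":
        return cls(ar_signs=np.sign(spec.beta_ar).astype(int),
                   e_signs=np.sign(spec.beta_e).astype(int))


def sign_preserved(spec: ModelSpec, draw: DayDraw) -> bool:
    """True iff the day network keeps the trait network's edge signs.

    Checked on the AR and exogenous coefficients only (constants are not
    network edges).  Edges whose fixed effect is exactly zero are excluded;
    a summed coefficient landing exactly on zero counts as *not* preserved
    (strict-sign convention, so no tolerance is needed).
    """
    B_ar, B_e, _ = assemble_coefficients(spec, draw)
    for beta, B in ((spec.beta_ar, B_ar), (spec.beta_e, B_e)):
        mask = beta != 0.0
        if np.any(np.sign(B[mask]) != np.sign(beta[mask])):
            return False
    return True


# ---------------------------------------------------------------------------
# reference networks

def reference_two_mood_spec(g_var: float = 0.03, sigma2: float = 0.02,
                            G_structure: str = "diagonal") -> ModelSpec:
    """Moderately connected two-mood network used throughout the test battery.

    Self-loops +0.3, reciprocal cross-lagged inhibition -0.3, exogenous input
    activating mood 1 (+0.3) and suppressing mood 2 (-0.3), zero constants.
    Random effects independent with common variance ``g_var``; at g_var=0.03
    the innovation variances {0.01, 0.02, 0.06} correspond to signal-to-noise
    ratios of roughly {12, 6, 2}.
    """
    k = 2
    q = k * k + 2 * k
    if G_structure != "diagonal":
        raise ValueError("reference spec is defined with independent random effects")
    return ModelSpec(
        k=k,
        beta_ar=np.array([[0.3, -0.3], [-0.3, 0.3]]),
        beta_e=np.array([0.3, -0.3]),
        beta_c=np.zeros(k),
        G=g_var * np.eye(q),
        sigma2=sigma2,
        G_structure="diagonal",
    )


def reference_four_mood_spec(g_var: float = 0.03, sigma2: float = 0.02,
                             cross: float = 0.15) -> ModelSpec:
    """Four-mood scaling network: two positive- and two negative-valence nodes.

    Self-loops +0.3; within-valence reinforcement ``+cross``; opposite-valence
    suppression ``-cross``; exogenous input activates the positive pair and
    suppresses the negative pair (±0.3).  The off-diagonal magnitude defaults
    to 0.15 so the trait matrix itself is stable (spectral radius 0.75; with
    ±0.3 off-diagonals the rank-one valence pattern reaches eigenvalue 1.2 and
    the process explodes).
    """
    k = 4
    q = k * k + 2 * k
    valence = np.array([1.0, 1.0, -1.0, -1.0])
    beta_ar = cross * np.outer(valence, valence)
    np.fill_diagonal(beta_ar, 0.3)
    return ModelSpec(
        k=k,
        beta_ar=beta_ar,
        beta_e=0.3 * valence,
        beta_c=np.zeros(k),
        G=g_var * np.eye(q),
        sigma2=sigma2,
        G_structure="diagonal",
    )


# ---------------------------------------------------------------------------
# covariance construction + config (de)serialization

def build_cs_matrix(m: int, variance: float, covariance: float = 0.0) -> np.ndarray:
    """Compound-symmetric m x m matrix: shared variance, shared covariance."""
    if m < 1:
        raise ValueError("block size must be >= 1")
    out = np.full((m, m), float(covariance))
    np.fill_diagonal(out, float(variance))
    return out


def _as_block_values(value, default=0.0) -> dict[str, float]:
    if isinstance(value, Mapping):
        unknown = set(value) - {"ar", "e", "c"}
        if unknown:
            raise ValueError(f"unknown G block keys: {sorted(unknown)}")
        return {blk: float(value.get(blk, default)) for blk in ("ar", "e", "c")}
    return {blk: float(value) for blk in ("ar", "e", "c")}


def build_G(k: int, structure: str, variance, covariance=0.0) -> np.ndarray:
    """Build a random-effects covariance from structure + scalar summaries.

    ``variance``/``covariance`` are scalars, or for the block structure
    optionally mappings with keys ``ar``, ``e``, ``c``.
    """
    q = k * k + 2 * k
    if structure == "diagonal":
        cov = _as_block_values(covariance)
        if any(v != 0.0 for v in cov.values()):
            raise ValueError("diagonal structure requires covariance == 0")
        var = _as_block_values(variance)
        diag = np.concatenate([np.full(k * k, var["ar"]),
                               np.full(k, var["e"]), np.full(k, var["c"])])
        return np.diag(diag)
    if structure == "compound_symmetric":
        return build_cs_matrix(q, float(variance), float(covariance))
    if structure == "block_cs_ar_exo_independent":
        var = _as_block_values(variance)
        cov = _as_block_values(covariance)
        blocks = [build_cs_matrix(k * k, var["ar"], cov["ar"]),
                  build_cs_matrix(k, var["e"], cov["e"]),
                  build_cs_matrix(k, var["c"], cov["c"])]
        out = np.zeros((q, q))
        pos = 0
        for blk in blocks:
            m = blk.shape[0]
            out[pos:pos + m, pos:pos + m] = blk
            pos += m
        return out
    raise ValueError(f"unknown G structure {structure!r}")


_SPEC_KEYS = {"k", "beta_ar", "beta_e", "beta_c", "G", "sigma2"}
_G_KEYS = {"structure", "variance", "covariance"}


def spec_to_dict(spec: ModelSpec) -> dict:
    """Serialize a ModelSpec to plain nested containers (YAML/JSON friendly)."""
    k = spec.k
    d: dict = {
        "k": k,
        "beta_ar": spec.beta_ar.tolist(),
        "beta_e": spec.beta_e.tolist(),
        "beta_c": spec.beta_c.tolist(),
        "sigma2": float(spec.sigma2),
        "G": {"structure": spec.G_structure},
    }
    g = spec.G
    if spec.G_structure == "diagonal":
        diag = np.diag(g)
        blocks = {"ar": diag[: k * k], "e": diag[k * k: k * k + k], "c": diag[k * k + k:]}
        var = {name: float(v[0]) for name, v in blocks.items()}
        if any(np.ptp(v) != 0.0 for v in blocks.values()):
            raise ValueError("diagonal G with non-constant block variances is not config-representable")
        if len(set(var.values())) == 1:
            d["G"]["variance"] = var["ar"]
        else:
            d["G"]["variance"] = var
        d["G"]["covariance"] = 0.0
    elif spec.G_structure == "compound_symmetric":
        d["G"]["variance"] = float(g[0, 0])
        d["G"]["covariance"] = float(g[0, 1]) if g.shape[0] > 1 else 0.0
    else:
        starts = {"ar": 0, "e": k * k, "c": k * k + k}
        sizes = {"ar": k * k, "e": k, "c": k}
        d["G"]["variance"] = {n: float(g[s, s]) for n, s in starts.items()}
        d["G"]["covariance"] = {
            n: float(g[s, s + 1]) if sizes[n] > 1 else 0.0 for n, s in starts.items()}
    return d


def spec_from_dict(d: Mapping) -> ModelSpec:
    """Build a ModelSpec from a nested config mapping; unknown keys rejected."""
    unknown = set(d) - _SPEC_KEYS
    if unknown:
        raise ValueError(f"unknown model config keys: {sorted(unknown)}")
    missing = _SPEC_KEYS - set(d)
    if missing:
        raise ValueError(f"missing model config keys: {sorted(missing)}")
    gcfg = d["G"]
    if not isinstance(gcfg, Mapping):
        raise ValueError("G must be a mapping with keys structure/variance/covariance")
    g_unknown = set(gcfg) - _G_KEYS
    if g_unknown:
        raise ValueError(f"unknown G config keys: {sorted(g_unknown)}")
    k = int(d["k"])
    G = build_G(k, gcfg["structure"], gcfg["variance"], gcfg.get("covariance", 0.0))
    return ModelSpec(k=k, beta_ar=d["beta_ar"], beta_e=d["beta_e"], beta_c=d["beta_c"],
                     G=G, sigma2=float(d["sigma2"]), G_structure=gcfg["structure"])
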