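"""Simplex types, Dirichlet parameterizations and basic numerics.

The multinomial model on ``k+1`` cells lives on the k-simplex
``Theta_k = {theta : theta_i >= 0, sum theta_i = 1}``.  Everything in this
package is built from three small value types: a point of the simplex
(:class:`ProbabilityVector`), an observed count vector (:class:`CellCounts`)
and a Dirichlet prior specification (:class:`DirichletSpec`, in either the
raw alpha-vector or the mode/concentration parameterization
``alpha_i = 1 + tau * xi_i``).

All stochastic operations accept ``rng`` as either an integer seed or a
:class:`numpy.random.Generator`; identical seeds give identical output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ProbabilityVector",
    "CellCounts",
    "DirichletSpec",
    "ensure_rng",
    "spawn_seeds",
    "kl_divergence",
    "kl_divergence_many",
    "sample_dirichlet",
    "sample_multinomial",
    "read_counts",
    "write_counts",
]

#: sum-to-one is enforced to this tolerance on construction ...
SIMPLEX_SUM_TOL = 1e-12
#: ... inputs off by more than SIMPLEX_SUM_TOL but within this are
#: renormalized; anything worse is rejected (silent renormalization of
#: genuinely bad input hides upstream errors).
SIMPLEX_RENORM_TOL = 1e-9

RngLike = Union[int, np.random.Generator, None]


def ensure_rng(rng: RngLike) -> np.random.Generator:
    """Return a Generator from a seed, a Generator, or None (OS entropy)."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


class ProbabilityVector:
    """A point of the k-simplex: ``k+1`` entries in [0, 1] summing to 1."""

    __slots__ = ("probs",)

    def __init__(self, probs: Iterable[float]):
        p = np.asarray(list(probs) if not isinstance(probs, np.ndarray) else probs,
                       dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("a probability vector needs at least 2 entries")
        if np.any(p < -SIMPLEX_RENORM_TOL) or np.any(p > 1 + SIMPLEX_RENORM_TOL):
            raise ValueError("entries must lie in [0, 1]")
        p = np.clip(p, 0.0, 1.0)
        s = p.sum()
        if abs(s - 1.0) > SIMPLEX_RENORM_TOL:
            raise ValueError(f"entries sum to {s!r}, not 1")
        if abs(s - 1.0) > SIMPLEX_SUM_TOL:
            p = p / s
        self.probs = p
        self.probs.setflags(write=False)

    @property
    def k(self) -> int:
        return self.probs.size - 1

    def __len__(self) -> int:
        return self.probs.size

    def __iter__(self):
        return iter(self.probs)

    def __getitem__(self, i):
        return self.probs[i]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbabilityVector) and np.array_equal(
            self.probs, other.probs)

    def __repr__(self) -> str:
        return f"ProbabilityVector({self.probs.tolist()})"


class CellCounts:
    """Observed multinomial cell counts ``T = (T_1, ..., T_{k+1})``."""

    __slots__ = ("counts",)

    def __init__(self, counts: Iterable[int]):
        c = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("a count vector needs at least 2 cells")
        if not np.issubdtype(c.dtype, np.integer):
            ci = np.rint(c).astype(np.int64)
            if not np.allclose(c, ci):
                raise ValueError("counts must be integers")
            c = ci
        else:
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        self.counts = c
        self.counts.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return self.counts.size - 1

    def frequencies(self) -> np.ndarray:
        if self.n == 0:
            raise ValueError("empty sample has no frequency vector")
        return self.counts / self.n

    def __len__(self) -> int:
        return self.counts.size

    def __iter__(self):
        return iter(self.counts)

    def __getitem__(self, i):
        return self.counts[i]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.counts, dtype=dtype)

    def __eq__(self, other) -> bool:
        return isinstance(other, CellCounts) and np.array_equal(
            self.counts, other.counts)

    def __repr__(self) -> str:
        return f"CellCounts({self.counts.tolist()})"


class DirichletSpec:
    """A Dirichlet(alpha_1, ..., alpha_{k+1}) prior.

    Besides the raw ``alpha`` vector the spec supports the mode /
    concentration parameterization used for elicitation: when all
    ``alpha_i >= 1`` write ``alpha_i = 1 + tau * xi_i`` with mode ``xi`` on
    the simplex and concentration ``tau = sum(alpha) - (k+1) >= 0``.  The
    ``tau -> 0`` limit is the uniform prior, represented as alpha = (1,...,1).
    """

    __slots__ = ("alpha",)

    def __init__(self, alpha: Iterable[float]):
        a = np.asarray(list(alpha) if not isinstance(alpha, np.ndarray) else alpha,
                       dtype=float)
        if a.ndim != 1 or a.size < 2:
            raise ValueError("alpha needs at least 2 entries")
        if np.any(a <= 0):
            raise ValueError("all alpha_i must be positive")
        self.alpha = a
        self.alpha.setflags(write=False)

    @classmethod
    def uniform(cls, k: int) -> "DirichletSpec":
        """Uniform prior on Theta_k (alpha all ones)."""
        return cls(np.ones(k + 1))

    @classmethod
    def from_mode_concentration(cls, xi, tau: float) -> "DirichletSpec":
        """Dirichlet with mode ``xi`` and concentration ``tau >= 0``."""
        xi = np.asarray(ProbabilityVector(xi))
        if tau < 0:
            raise ValueError("concentration tau must be >= 0")
        return cls(1.0 + tau * xi)

    @property
    def k(self) -> int:
        return self.alpha.size - 1

    @property
    def concentration(self) -> float:
        """tau = sum(alpha) - (k+1); requires all alpha_i >= 1."""
        if np.any(self.alpha < 1 - 1e-12):
            raise ValueError("mode/concentration form needs all alpha_i >= 1")
        return float(self.alpha.sum() - self.alpha.size)

    @property
    def mode(self) -> ProbabilityVector:
        """xi_i = (alpha_i - 1)/tau; requires all alpha_i > 1."""
        tau = self.concentration
        if tau <= 0:
            raise ValueError("the uniform prior (tau = 0) has no unique mode")
        return ProbabilityVector((self.alpha - 1.0) / tau)

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    def __eq__(self, other) -> bool:
        return isinstance(other, DirichletSpec) and np.array_equal(
            self.alpha, other.alpha)

    def __repr__(self) -> str:
        return f"DirichletSpec({self.alpha.tolist()})"


def _as_prob_array(p) -> np.ndarray:
    if isinstance(p, ProbabilityVector):
        return p.probs
    return ProbabilityVector(p).probs


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence KL(p || q) between two cell distributions.

    Natural logarithm; ``0 * log(0/q) = 0``; returns ``inf`` when some
    ``p_i > 0`` has ``q_i = 0`` (support violation).
    """
    p = _as_prob_array(p)
    q = _as_prob_array(q)
    if p.size != q.size:
        raise ValueError(f"dimension mismatch: {p.size} vs {q.size}")
    pos = p > 0
    if np.any(q[pos] == 0):
        return float("inf")
    return float(np.sum(p[pos] * np.log(p[pos] / q[pos])))


def kl_divergence_many(thetas: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise KL(thetas[i] || q[i]) for arrays of shape (N, k+1).

    ``q`` may also be a single vector broadcast against every row.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    q = np.asarray(q, dtype=float)
    if q.ndim == 1:
        q = np.broadcast_to(q, thetas.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = thetas * (np.log(thetas) - np.log(q))
    term = np.where(thetas == 0, 0.0, term)
    # p_i > 0 with q_i = 0 produces +inf via log(0); keep it.
    return term.sum(axis=1)


def sample_dirichlet(spec: DirichletSpec | Sequence[float], size: int,
                     rng: RngLike = None) -> np.ndarray:
    """Draw ``size`` simplex points from a Dirichlet; shape (size, k+1)."""
    alpha = spec.alpha if isinstance(spec, DirichletSpec) else DirichletSpec(spec).alpha
    if size < 1:
        raise ValueError("size must be >= 1")
    return ensure_rng(rng).dirichlet(alpha, size)


def sample_multinomial(theta, n: int, rng: RngLike = None,
                       size: int | None = None) -> CellCounts | np.ndarray:
    """Draw counts ~ multinomial(n, theta).

    With ``size=None`` returns a single :class:`CellCounts`; otherwise an
    integer array of shape (size, k+1).  ``theta`` may also be an (N, k+1)
    array with ``size=None``, giving one draw per row.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    gen = ensure_rng(rng)
    th = np.asarray(theta, dtype=float)
    if th.ndim == 2:
        return gen.multinomial(n, th)
    p = _as_prob_array(theta)
    if size is None:
        return CellCounts(gen.multinomial(n, p))
    return gen.multinomial(n, p, size=size)


# ---------------------------------------------------------------------------
# Plain-text IO for count vectors


def read_counts(path: str | Path) -> CellCounts:
    """Read a count vector from CSV/TSV (one row, or a 'count(s)' column) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        if isinstance(obj, dict):
            obj = obj.get("counts", obj)
        return CellCounts(obj)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("count", "counts"):
        if col in df.columns:
            return CellCounts(df[col].to_numpy())
    if df.shape[0] == 0:  # headerless single row was eaten as the header
        df = pd.read_csv(path, sep=sep, header=None)
    if df.shape[0] == 1:
        row = df.select_dtypes("number")
        return CellCounts(row.iloc[0].to_numpy())
    raise ValueError(
        f"{path}: expected a single row of integers or a 'count' column")


def write_counts(counts: CellCounts, path: str | Path) -> None:
    """Write a count vector; format chosen from the extension (.json/.tsv/.csv)."""
    path = Path(path)
    vals = [int(v) for v in counts]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"counts": vals}) + "\n")
        return
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    header = sep.join(f"cell{i + 1}" for i in range(len(vals)))
    path.write_text(header + "\n" + sep.join(str(v) for v in vals) + "\n")
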