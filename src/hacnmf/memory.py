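"""Incremental non-negative matrix factorisation memory.

The long-term memory is a non-negative matrix ``W`` of shape
``(110,015, R)`` (acoustic rows + 15 meaning rows; R = 70 primitives by
default) whose columns — the *primitives* — are the learned parts that
utterance representations are summed from. Learning is causal and
incremental: each HAC+M vector ``x`` is seen exactly once, and after every
utterance all primitives may change.

One learning step, given the current memory ``W``:

1. infer utterance weights ``h`` by a fixed number of multiplicative
   KL-divergence updates (Lee-Seung) with ``W`` held fixed;
2. compute the one-step multiplicative KL update ``W*`` of ``W`` given
   ``(x, h)``, which for a single input vector is the row scaling
   ``W*_ij = W_ij * x_i / (W h)_i``;
3. blend it in with a per-primitive step size and renormalise every column
   to sum 1: ``W_:,j <- normalise((1 - eta_j) W_:,j + eta_j W*_:,j)`` with
   ``eta_j = eta * h_j / max(h)``.

The per-primitive step size implements the principle that the amount by
which a primitive is updated depends on its contribution to approximating
the current utterance: the most-contributing primitive moves with the full
damping ``eta``, non-contributing ones barely move. (A column-independent
step is degenerate here: with one input vector the multiplicative factor
``x_i / (W h)_i`` is the same for every column, so all primitives would
drift toward the same shape and never specialise.) The damping cap ``eta``
keeps any single utterance from dominating the memory.

The update is non-zero only on the sparse support of ``x``. The
implementation exploits this by storing ``W`` in a factored form
``W = V * diag(s)`` so a learning step touches only the support rows —
O(nnz x R) instead of O(D x R) — while remaining exactly equivalent to the
dense damped update (a test checks this against a naive dense reference).

At test time ``decode`` reconstructs an acoustic-only HAC vector from the
acoustic parts of the primitives (multiplicative KL updates of ``h`` from a
uniform start) and applies the same weights to the meaning parts, yielding
one activation per keyword; activations are normalised to sum to one per
sentence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hac import HACMVector, HACVector
from .lexicon import KEYWORDS

__all__ = [
    "MemoryMatrix",
    "DecodeWeights",
    "ActivationRecord",
    "init_memory",
    "learn_utterance",
    "decode",
    "kl_divergence",
]

_TINY = 1e-300
_REFOLD_EVERY = 64  # full renormalisation cadence (numerical housekeeping)


@dataclass
class DecodeWeights:
    """Non-negative primitive weights for one utterance."""

    h: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.h < 0) or not np.all(np.isfinite(self.h)):
            raise ValueError("decode weights must be finite and non-negative")


@dataclass
class ActivationRecord:
    """Keyword activations for one test sentence."""

    a: np.ndarray
    normalised: bool = True
    keywords: tuple[str, ...] = KEYWORDS

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        if np.any(self.a < 0):
            raise ValueError("activations must be non-negative")
        if self.normalised and abs(self.a.sum() - 1.0) > 1e-9:
            raise ValueError("normalised activations must sum to 1")


class MemoryMatrix:
    """Column-normalised non-negative primitive store, ``W = V diag(s)``.

    Only constructed through :func:`init_memory` or :meth:`load`.
    """

    def __init__(
        self,
        V: np.ndarray,
        acoustic_dim: int,
        meaning_dim: int,
        seed: int,
    ):
        if np.any(V <= 0):
            raise ValueError("memory must be initialised strictly positive")
        self._V = np.asarray(V, dtype=np.float64)
        self._s = 1.0 / self._V.sum(axis=0)
        self._colsum_Va = self._V[:acoustic_dim].sum(axis=0)
        self.acoustic_dim = int(acoustic_dim)
        self.meaning_dim = int(meaning_dim)
        self.seed = int(seed)
        self.utterance_count = 0
        self._growth = 1.0

    # -- views -------------------------------------------------------------

    @property
    def r(self) -> int:
        """Number of primitives (columns)."""
        return self._V.shape[1]

    @property
    def n_rows(self) -> int:
        return self._V.shape[0]

    @property
    def W(self) -> np.ndarray:
        """The full column-normalised memory (materialised copy)."""
        return self._V * self._s

    @property
    def W_acoustic(self) -> np.ndarray:
        return self._V[: self.acoustic_dim] * self._s

    @property
    def W_meaning(self) -> np.ndarray:
        return self._V[self.acoustic_dim :] * self._s

    @property
    def acoustic_colsums(self) -> np.ndarray:
        """Column sums of the acoustic part (maintained incrementally)."""
        return self._colsum_Va * self._s

    def rows(self, indices: np.ndarray) -> np.ndarray:
        """Materialised rows of W (used for sparse-support arithmetic)."""
        return self._V[indices] * self._s

    # -- housekeeping ------------------------------------------------------

    def _refold(self) -> None:
        c = self._V.sum(axis=0)
        self._V /= c
        self._s *= c
        self._colsum_Va = self._V[: self.acoustic_dim].sum(axis=0)
        self._growth = 1.0

    def check_column_normalisation(self, tol: float = 1e-9) -> None:
        colsums = self.W.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > tol):
            raise AssertionError("memory columns drifted from unit sum")

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint container: W plus (R, dims, seed, utterance counter)."""
        np.savez_compressed(
            str(path),
            W=self.W,
            acoustic_dim=self.acoustic_dim,
            meaning_dim=self.meaning_dim,
            seed=self.seed,
            utterance_count=self.utterance_count,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MemoryMatrix":
        with np.load(str(path)) as data:
            mem = cls(
                np.maximum(data["W"], _TINY),
                int(data["acoustic_dim"]),
                int(data["meaning_dim"]),
                int(data["seed"]),
            )
            mem.utterance_count = int(data["utterance_count"])
        return mem


def init_memory(
    r: int,
    seed: int,
    acoustic_dim: int = 110_000,
    meaning_dim: int = 15,
    eps: float = 1e-3,
) -> MemoryMatrix:
    """Fresh memory: i.i.d. uniform entries in (eps, 2*eps), columns normalised."""
    if r < 1:
        raise ValueError("need at least one primitive")
    rng = np.random.default_rng(seed)
    V = eps * (1.0 + rng.random((acoustic_dim + meaning_dim, r)))
    return MemoryMatrix(V, acoustic_dim, meaning_dim, seed)


def _infer_h(
    Wsub: np.ndarray, xv: np.ndarray, colsums: np.ndarray, iters: int
) -> np.ndarray:
    """Multiplicative KL updates of h from a uniform start, W fixed.

    ``Wsub`` holds only the support rows of W; rows where x = 0 contribute
    nothing to the numerator, and the denominator uses the full column sums.
    """
    r = Wsub.shape[1]
    h = np.full(r, 1.0 / r)
    for _ in range(iters):
        Wh = np.maximum(Wsub @ h, _TINY)
        h = h * (Wsub.T @ (xv / Wh)) / colsums
        h = np.maximum(h, _TINY)
    return h


def learn_utterance(
    W: MemoryMatrix,
    x: HACMVector,
    eta: float = 0.4,
    inner_iters: int = 25,
) -> MemoryMatrix:
    """One incremental learning step; updates ``W`` in place and returns it.

    Equivalent to the dense damped update
    ``W_:,j <- normalise((1 - eta_j) W_:,j + eta_j W*_:,j)`` with
    ``W*_ij = W_ij x_i / (W h)_i`` and per-primitive steps
    ``eta_j = eta h_j / max(h)``, but computed on the sparse support of
    ``x`` only.
    """
    if x.dimension != W.n_rows:
        raise ValueError(
            f"input dimension {x.dimension} does not match memory rows {W.n_rows}"
        )
    if not np.all(np.isfinite(x.counts)):
        raise ValueError("non-finite values in input vector")
    if not 0.0 <= eta < 1.0:
        raise ValueError("damping eta must be in [0, 1)")
    if eta == 0.0 or x.nnz == 0:
        W.utterance_count += 1
        return W

    keep = x.counts > 0
    sup = x.indices[keep]
    xv = x.counts[keep]

    Wsub = W.rows(sup)
    ones = np.ones(W.r)  # full column sums are exactly 1 by construction
    h = _infer_h(Wsub, xv, ones, inner_iters)

    Wh = np.maximum(Wsub @ h, _TINY)
    ratio = xv / Wh
    eta_j = eta * h / h.max()  # contribution-weighted step per primitive
    # new column sums: (1 - eta_j) * 1 + eta_j * sum_i W_ij ratio_i
    z = (1.0 - eta_j) + eta_j * (Wsub.T @ ratio)
    # support-row factors relative to the off-support factor (1 - eta_j)
    factor = ((1.0 - eta_j)[None, :] + np.outer(ratio, eta_j)) / (1.0 - eta_j)[None, :]

    amask = sup < W.acoustic_dim
    W._colsum_Va += (W._V[sup[amask]] * (factor[amask] - 1.0)).sum(axis=0)
    W._V[sup] *= factor
    W._s *= (1.0 - eta_j) / z
    W._growth *= max(factor.max(), 1.0)
    W.utterance_count += 1
    if W.utterance_count % _REFOLD_EVERY == 0 or W._growth > 1e100:
        W._refold()
    return W


def decode(
    W: MemoryMatrix, v: HACVector, iters: int = 50
) -> tuple[DecodeWeights, ActivationRecord]:
    """Reconstruct an acoustic-only test vector; read out keyword activations.

    The weights ``h`` minimise D(v || W_a h) by multiplicative updates from a
    uniform start (deterministic); applying them to the meaning rows gives
    one activation per keyword, normalised to sum to one.
    """
    if v.nnz == 0 or v.total <= 0:
        raise ValueError("cannot decode an all-zero vector")
    if isinstance(v, HACMVector):
        if np.any(v.indices >= v.acoustic_dim):
            raise ValueError("test vectors must carry a zero meaning block")
        if v.acoustic_dim != W.acoustic_dim:
            raise ValueError("vector geometry does not match the memory")
    elif v.dimension != W.acoustic_dim:
        raise ValueError("vector geometry does not match the memory")

    sup = v.indices
    xv = v.counts
    Wsub = W.rows(sup)
    h = _infer_h(Wsub, xv, np.maximum(W.acoustic_colsums, _TINY), iters)
    a = W.W_meaning @ h
    total = a.sum()
    if total <= 0:
        raise ArithmeticError("all keyword activations vanished")
    return DecodeWeights(h), ActivationRecord(a / total, normalised=True)


def kl_divergence(x_dense: np.ndarray, W: np.ndarray, h: np.ndarray) -> float:
    """Generalised KL divergence D(x || W h) for dense arguments (test oracle
    support and monitoring; not used in the learning loop)."""
    Wh = np.maximum(W @ h, _TINY)
    x = np.asarray(x_dense, dtype=np.float64)
    mask = x > 0
    return float(
        np.sum(x[mask] * np.log(x[mask] / Wh[mask])) - x.sum() + Wh.sum()
    )
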