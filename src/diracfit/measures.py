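"""Discrete Radon measures: weighted sums of Dirac deltas on a box domain.

The unknown of every reconstruction problem in this package is a measure

    mu = sum_i a_i * delta_{x_i}

with continuous positions ``x_i`` in a compact box ``Omega`` (in physical
units, never pixel indices) and real amplitudes ``a_i``.  For such measures
the total-variation norm of the measure coincides with the L1 norm of the
amplitude vector, which is what makes it the natural sparsity-promoting
regulariser for spike recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Domain", "DiracMeasure", "tv_norm", "prune", "merge_close"]


@dataclass(frozen=True)
class Domain:
    """Compact axis-aligned box ``Omega = prod_k [lower_k, upper_k]``.

    Parameters
    ----------
    lower, upper
        Per-axis bounds in physical units; ``lower[k] < upper[k]`` on every
        axis, ``1 <= dim <= 3``.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.ndim != 1 or lo.shape != hi.shape:
            raise ValueError("lower and upper must be 1D vectors of equal length")
        if not 1 <= lo.size <= 3:
            raise ValueError(f"domain dimension must be 1, 2 or 3, got {lo.size}")
        if not np.all(lo < hi):
            raise ValueError("domain requires lower < upper on every axis")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def volume(self) -> float:
        """Lebesgue volume ``|Omega|``."""
        return float(np.prod(self.upper - self.lower))

    def contains(self, points: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Boolean mask of rows of ``points`` inside the box (inclusive)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all(
            (pts >= self.lower - atol) & (pts <= self.upper + atol), axis=1
        )

    def clip(self, points: np.ndarray) -> np.ndarray:
        return np.clip(np.atleast_2d(points), self.lower, self.upper)


@dataclass(frozen=True)
class DiracMeasure:
    """Finite weighted sum of Diracs: ``positions`` (N, d) and ``amplitudes`` (N,).

    ``N = 0`` represents the zero measure.  Amplitudes may be signed; the
    non-negativity constraint of the Poisson model is enforced by the solver,
    not by this container.
    """

    positions: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size == 0:
            pos = pos.reshape(0, pos.shape[1] if pos.ndim == 2 else 1)
        elif pos.ndim == 1:
            pos = pos[:, None]
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if pos.shape[0] != amp.shape[0]:
            raise ValueError(
                f"{pos.shape[0]} positions but {amp.shape[0]} amplitudes"
            )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)

    @classmethod
    def empty(cls, dim: int) -> "DiracMeasure":
        """The zero measure on a ``dim``-dimensional domain."""
        return cls(np.empty((0, dim)), np.empty(0))

    @property
    def N(self) -> int:
        return self.amplitudes.size

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def tv_norm(self) -> float:
        return tv_norm(self)

    # -- CSV interchange: header x0[,x1[,x2]],amplitude, physical units ----
    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{k}": self.positions[:, k] for k in range(self.dim)}
        cols["amplitude"] = self.amplitudes
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DiracMeasure":
        df = pd.read_csv(path)
        axes = [c for c in df.columns if c.startswith("x")]
        if "amplitude" not in df.columns or not axes:
            raise ValueError(f"{path}: expected columns x0[,x1[,x2]],amplitude")
        return cls(df[axes].to_numpy(), df["amplitude"].to_numpy())


def tv_norm(m: DiracMeasure) -> float:
    """Total-variation norm ``|mu|(Omega) = sum_i |a_i|`` (0 for the zero measure)."""
    return float(np.sum(np.abs(m.amplitudes)))


def prune(m: DiracMeasure, atol: float = 0.0) -> DiracMeasure:
    """Drop spikes with ``|a_i| <= atol``, preserving the order of survivors."""
    if atol < 0:
        raise ValueError("atol must be non-negative")
    keep = np.abs(m.amplitudes) > atol
    return DiracMeasure(m.positions[keep], m.amplitudes[keep])


def merge_close(m: DiracMeasure, radius: float) -> DiracMeasure:
    """Greedily merge spikes within Euclidean distance ``radius``.

    Spikes are scanned in index order; each spike either joins the first
    existing cluster whose representative lies within ``radius`` (the
    representative being the |amplitude|-weighted mean position) or starts a
    new cluster.  Total mass ``sum_i a_i`` is conserved exactly.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if m.N <= 1:
        return m
    reps: list[np.ndarray] = []       # weighted mean positions
    masses: list[float] = []          # signed amplitude sums
    weights: list[float] = []         # |amplitude| sums for the mean
    for x, a in zip(m.positions, m.amplitudes):
        for j, r in enumerate(reps):
            if np.linalg.norm(x - r) <= radius:
                w = abs(a)
                tot = weights[j] + w
                if tot > 0:
                    reps[j] = (weights[j] * r + w * x) / tot
                weights[j] = tot
                masses[j] = masses[j] + a
                break
        else:
            reps.append(np.array(x, dtype=float))
            masses.append(float(a))
            weights.append(abs(float(a)))
    return DiracMeasure(np.array(reps), np.array(masses))
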