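"""Vibratory feature space of a hand-held rod.

When a rod strikes an object, the contact location determines the relative
amplitude with which each resonant bending mode is excited.  The combination
of modal amplitudes — the *vibratory motif* — is unique per location, so the
multidimensional motif space is isomorphic to the physical space of the rod
and can stand in for it when the nervous system localizes touch.

The rod is modeled as a clamped-free (cantilever) Euler–Bernoulli beam of
unit length: the hand clamps the base (position 0) and the tip is free
(position 1).  Only the first five modes are kept, as higher modes fall
outside the mechanoreceptor bandwidth.  Mode shapes are

    phi_n(x) = cosh(b_n x) - cos(b_n x) - a_n (sinh(b_n x) - sin(b_n x)),
    a_n = (cosh b_n + cos b_n) / (sinh b_n + sin b_n),

where ``b_n`` is the n-th root of ``cosh(x) cos(x) = -1``.  Shapes are
normalized to unit peak magnitude, and tool locations are expressed in
percent of tool space (0 = hand, 100 = tip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModeShape",
    "VibratoryMotif",
    "FeatureSpace",
    "cantilever_eigenvalues",
    "mode_shape",
    "motif_for_location",
    "nearest_location",
    "build_feature_space",
]

#: Number of modes within mechanoreceptor bandwidth.
N_MODES = 5

#: Support of the mode-layer tuning grid; motifs must stay inside it.
MODE_AMPLITUDE_SUPPORT = (-1.5, 1.5)

# Grid used to locate and normalize the shape's peak magnitude.
_NORM_GRID = np.linspace(0.0, 1.0, 10001)


def _characteristic(x: float) -> float:
    return np.cosh(x) * np.cos(x) + 1.0


@lru_cache(maxsize=None)
def cantilever_eigenvalues(n_modes: int) -> tuple[float, ...]:
    """First ``n_modes`` roots of the clamped-free characteristic equation.

    Roots of ``cosh(x) cos(x) = -1`` in increasing order.  The n-th root
    lies near ``(2n - 1) * pi / 2``, which brackets the search.

    Parameters
    ----------
    n_modes : int
        Number of eigenvalues, ``>= 1``.

    Returns
    -------
    tuple of float
        Strictly increasing dimensionless eigenvalues ``beta_n * L``.
    """
    if not isinstance(n_modes, (int, np.integer)) or n_modes < 1:
        raise ValueError(f"n_modes must be a positive integer, got {n_modes!r}")
    roots = []
    for n in range(1, n_modes + 1):
        center = (2 * n - 1) * np.pi / 2
        lo, hi = center - 1.0, center + 1.0
        roots.append(brentq(_characteristic, lo, hi, xtol=1e-12, rtol=1e-15))
    return tuple(roots)


def _alpha(beta: float) -> float:
    return (np.cosh(beta) + np.cos(beta)) / (np.sinh(beta) + np.sin(beta))


def _raw_shape(index: int, x: np.ndarray) -> np.ndarray:
    beta = cantilever_eigenvalues(index)[index - 1]
    a = _alpha(beta)
    bx = beta * np.asarray(x, dtype=float)
    return np.cosh(bx) - np.cos(bx) - a * (np.sinh(bx) - np.sin(bx))


@lru_cache(maxsize=None)
def _peak_magnitude(index: int) -> float:
    return float(np.max(np.abs(_raw_shape(index, _NORM_GRID))))


def mode_shape(index: int, x):
    """Normalized clamped-free mode shape ``phi_index`` at position(s) ``x``.

    Parameters
    ----------
    index : int
        Mode number, 1-based.
    x : float or array-like
        Normalized beam position in ``[0, 1]`` (0 = clamped end / hand).

    Returns
    -------
    float or ndarray
        Dimensionless amplitude, normalized so ``max |phi| = 1`` on [0, 1].
    """
    if not isinstance(index, (int, np.integer)) or index < 1:
        raise ValueError(f"mode index must be a positive integer, got {index!r}")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("beam position x must lie in [0, 1]")
    out = _raw_shape(index, arr) / _peak_magnitude(index)
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class ModeShape:
    """A single resonant bending mode of the rod."""

    index: int
    eigenvalue: float
    shape: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def build(cls, index: int) -> "ModeShape":
        beta = cantilever_eigenvalues(index)[index - 1]
        return cls(index=index, eigenvalue=beta, shape=lambda x, i=index: mode_shape(i, x))


@dataclass(frozen=True)
class VibratoryMotif:
    """Modal-amplitude signature of a touch at one rod location."""

    amplitudes: np.ndarray  # shape (5,), dimensionless mode weights
    location: float  # percent of tool space, 0 = hand, 100 = tip

    def __post_init__(self):
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))


def motif_for_location(location: float, scale: float = 1.0, n_modes: int = N_MODES) -> VibratoryMotif:
    """Vibratory motif (mode-amplitude vector) for a touch location.

    Parameters
    ----------
    location : float
        Touch position in percent of tool space, ``[0, 100]``.
    scale : float
        Amplitude scaling applied after unit-peak normalization; the default
        of 1.0 keeps every amplitude within the mode-layer tuning support
        [-1.5, 1.5].
    """
    if not 0.0 <= location <= 100.0:
        raise ValueError(f"location must lie in [0, 100] % tool space, got {location}")
    x = location / 100.0
    amps = np.array([mode_shape(n, x) for n in range(1, n_modes + 1)]) * scale
    return VibratoryMotif(amplitudes=amps, location=float(location))


@dataclass
class FeatureSpace:
    """Grid of locations with their motifs; the vibration-location isomorphism."""

    grid: np.ndarray  # locations in % tool space, ordered
    motifs: np.ndarray  # (len(grid), n_modes) amplitude matrix
    scale: float = 1.0

    def min_motif_gap(self) -> float:
        """Smallest pairwise Euclidean distance between distinct grid motifs."""
        d = self.motifs[:, None, :] - self.motifs[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        iu = np.triu_indices(len(self.grid), k=1)
        return float(dist[iu].min())


def build_feature_space(
    grid_step_pct: float = 1.0,
    scale: float = 1.0,
    n_modes: int = N_MODES,
) -> FeatureSpace:
    """Tabulate motifs on a regular grid of tool locations (default 1% steps)."""
    if grid_step_pct <= 0:
        raise ValueError("grid_step_pct must be positive")
    grid = np.arange(0.0, 100.0 + grid_step_pct / 2, grid_step_pct)
    x = grid / 100.0
    motifs = np.column_stack([mode_shape(n, x) for n in range(1, n_modes + 1)]) * scale
    return FeatureSpace(grid=grid, motifs=motifs, scale=scale)


def nearest_location(motif, space: FeatureSpace) -> float:
    """Grid location whose motif is nearest (Euclidean) to the query.

    Ties break toward the smaller location.  This is the isomorphism lookup:
    for any grid location L, ``nearest_location(motif_for_location(L))`` is L.
    """
    if space is None or len(space.grid) == 0:
        raise ValueError("feature space is empty")
    amps = motif.amplitudes if isinstance(motif, VibratoryMotif) else np.asarray(motif, dtype=float)
    d2 = ((space.motifs - amps[None, :]) ** 2).sum(axis=1)
    return float(space.grid[int(np.argmin(d2))])  # argmin takes first (smaller) on ties
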