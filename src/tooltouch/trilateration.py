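"""Probabilistic trilateration observer for touch on a 1-D sensory surface.

Touch at location L between two landmarks (proximal at X1, distal at X2) is
localized by estimating the distance from each landmark and fusing the two
resulting location beliefs by maximum likelihood.  Each distance estimate
carries Gaussian noise whose SD grows linearly with distance,

    sigma_i = eps_i + d_i * sigma_hat,

so the fused estimate's SD,

    sigma_INT(L) = sqrt(sigma_1^2 sigma_2^2 / (sigma_1^2 + sigma_2^2)),

traces an inverted-U across the surface: most precise at the landmarks
(perceptual anchors), least precise in between.  All positions are in
percent of tool space (0 = hand, 100 = tip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SurfaceFrame",
    "LocationBelief",
    "DistanceEstimate",
    "LocationEstimate",
    "IntegratedEstimate",
    "TrilaterationParams",
    "SegmentedSurface",
    "distance_estimates",
    "location_estimates",
    "integrate_estimates",
    "predicted_sd_curve",
    "multisegment_sd_curve",
]


@dataclass(frozen=True)
class SurfaceFrame:
    """Landmark positions delimiting the localization frame (% tool space)."""

    X1: float = 0.0
    X2: float = 100.0

    def __post_init__(self):
        if not self.X2 > self.X1:
            raise ValueError(f"distal landmark X2={self.X2} must exceed proximal X1={self.X1}")


@dataclass(frozen=True)
class LocationBelief:
    """A Gaussian belief over position: mean (% space) and variance (% space)^2."""

    mean: float
    variance: float

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


@dataclass(frozen=True)
class DistanceEstimate:
    """Gaussian belief over distance from one landmark."""

    mean: float
    variance: float
    anchor: str  # "proximal" | "distal"

    def __post_init__(self):
        if self.mean < 0:
            raise ValueError("distance mean must be non-negative")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


@dataclass(frozen=True)
class LocationEstimate:
    """Landmark-anchored location belief L~_i (distance mapped into surface coordinates)."""

    mean: float
    variance: float
    anchor: str


@dataclass(frozen=True)
class IntegratedEstimate:
    """Maximum-likelihood fusion of the two landmark-anchored estimates."""

    mean: float
    variance: float


@dataclass(frozen=True)
class TrilaterationParams:
    """Behavioral free parameters of the distance-noise law.

    sigma_hat : noise slope, SD (% space) gained per % space of distance.
    eps1, eps2 : landmark-specific intercepts (% space SD), reflecting
        uncertainty in the proximal / distal landmark positions.
    """

    sigma_hat: float
    eps1: float
    eps2: float

    def __post_init__(self):
        if self.sigma_hat < 0 or self.eps1 < 0 or self.eps2 < 0:
            raise ValueError("trilateration parameters must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_hat, self.eps1, self.eps2])


def distance_estimates(
    L: float, params: TrilaterationParams, frame: SurfaceFrame = SurfaceFrame()
) -> tuple[DistanceEstimate, DistanceEstimate]:
    """Noisy distance estimates from the proximal and distal landmarks.

    Means are the true distances d1 = L - X1 and d2 = X2 - L; SDs follow the
    linear law ``eps_i + d_i * sigma_hat``.
    """
    if not frame.X1 <= L <= frame.X2:
        raise ValueError(f"touch location {L} outside frame [{frame.X1}, {frame.X2}]")
    d1 = L - frame.X1
    d2 = frame.X2 - L
    sd1 = params.eps1 + d1 * params.sigma_hat
    sd2 = params.eps2 + d2 * params.sigma_hat
    return (
        DistanceEstimate(mean=d1, variance=sd1**2, anchor="proximal"),
        DistanceEstimate(mean=d2, variance=sd2**2, anchor="distal"),
    )


def location_estimates(
    L: float, params: TrilaterationParams, frame: SurfaceFrame = SurfaceFrame()
) -> tuple[LocationEstimate, LocationEstimate]:
    """Landmark-anchored location estimates L~1 = X1 + d1 and L~2 = X2 - d2."""
    e1, e2 = distance_estimates(L, params, frame)
    return (
        LocationEstimate(mean=frame.X1 + e1.mean, variance=e1.variance, anchor="proximal"),
        LocationEstimate(mean=frame.X2 - e2.mean, variance=e2.variance, anchor="distal"),
    )


def integrate_estimates(e1: LocationEstimate, e2: LocationEstimate) -> IntegratedEstimate:
    """Inverse-variance-weighted (maximum-likelihood) fusion of two Gaussian beliefs.

    mu_INT = (mu1/s1^2 + mu2/s2^2) * s_INT^2 and
    s_INT^2 = s1^2 s2^2 / (s1^2 + s2^2).  A zero-variance input dominates and
    is returned unchanged; two contradictory certain inputs are an error.
    """
    v1, v2 = e1.variance, e2.variance
    if v1 == 0 and v2 == 0:
        if e1.mean != e2.mean:
            raise ValueError("inconsistent evidence: two zero-variance estimates with different means")
        return IntegratedEstimate(mean=e1.mean, variance=0.0)
    if v1 == 0:
        return IntegratedEstimate(mean=e1.mean, variance=0.0)
    if v2 == 0:
        return IntegratedEstimate(mean=e2.mean, variance=0.0)
    v_int = v1 * v2 / (v1 + v2)
    mu_int = (e1.mean / v1 + e2.mean / v2) * v_int
    return IntegratedEstimate(mean=mu_int, variance=v_int)


def predicted_sd_curve(
    params: TrilaterationParams,
    locations,
    frame: SurfaceFrame = SurfaceFrame(),
) -> np.ndarray:
    """SD of the integrated location estimate at each location (vectorized).

    This is the behavioral variance law: the curve the observer's variable
    errors should trace across the surface.
    """
    L = np.asarray(locations, dtype=float)
    if np.any(L < frame.X1) or np.any(L > frame.X2):
        raise ValueError("locations must lie within the surface frame")
    s1 = params.eps1 + (L - frame.X1) * params.sigma_hat
    s2 = params.eps2 + (frame.X2 - L) * params.sigma_hat
    v1, v2 = s1**2, s2**2
    denom = v1 + v2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_int = np.where(denom > 0, v1 * v2 / np.where(denom > 0, denom, 1.0), 0.0)
    return np.sqrt(v_int)


@dataclass(frozen=True)
class SegmentedSurface:
    """A rod partitioned into segments that each trilaterate locally.

    ``breakpoints`` are strictly increasing and include 0 and 100; each of
    the ``len(breakpoints) - 1`` segments carries its own noise parameters
    and uses its own endpoints as landmarks.
    """

    breakpoints: tuple
    params: tuple  # one TrilaterationParams per segment

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        if len(bp) < 2 or any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing with >= 2 entries")
        if bp[0] != 0.0 or bp[-1] != 100.0:
            raise ValueError("breakpoints must start at 0 and end at 100")
        if len(self.params) != len(bp) - 1:
            raise ValueError("need exactly one parameter set per segment")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "params", tuple(self.params))

    @classmethod
    def uniform(cls, n_segments: int, params: TrilaterationParams) -> "SegmentedSurface":
        bp = tuple(np.linspace(0.0, 100.0, n_segments + 1))
        return cls(breakpoints=bp, params=(params,) * n_segments)


def multisegment_sd_curve(surface: SegmentedSurface, locations) -> np.ndarray:
    """Variance law for a multi-segment rod: trilateration runs locally per segment.

    Each location is assigned to its containing segment (a location exactly on
    an interior breakpoint belongs to the segment on its left) and its SD is
    computed with that segment's endpoints as landmarks.  A single segment
    spanning [0, 100] reduces to :func:`predicted_sd_curve`.
    """
    L = np.asarray(locations, dtype=float)
    if np.any(L < surface.breakpoints[0]) or np.any(L > surface.breakpoints[-1]):
        raise ValueError("locations must lie within [0, 100]")
    out = np.empty_like(L)
    bp = surface.breakpoints
    # side="left" puts a breakpoint tie into the left segment
    idx = np.clip(np.searchsorted(bp, L, side="left") - 1, 0, len(bp) - 2)
    for seg in range(len(bp) - 1):
        mask = idx == seg
        if not np.any(mask):
            continue
        frame = SurfaceFrame(X1=bp[seg], X2=bp[seg + 1])
        out[mask] = predicted_sd_curve(surface.params[seg], L[mask], frame)
    return out
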