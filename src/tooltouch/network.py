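"""Three-layer probabilistic population-coding network for tool-centered localization.

The network converts a rod's vibratory motif into a location estimate:

1. *Mode layer* — five subpopulations of Poisson units, each tuned to the
   amplitude of one resonant mode (Gaussian tuning over amplitude).
2. *Feature layer* — units tuned to positions in the vibration-location
   feature space.  Each unit's synaptic weight vector is proportional to the
   mode-layer template of its preferred location; the winner-take-all of the
   synaptic drive selects the effective stimulus, and units emit uninherited
   Poisson spikes around their tuning-curve means.
3. *Distance layer* — two decoding subpopulations anchored at the proximal
   (hand) and distal (tip) landmarks.  Tuning gain falls and tuning width
   grows with distance from the anchor:

       kappa(d) = kappa0 / (1 + beta d)^2
       sigma(d) = (gamma log(d + 1) + 1) sigma0

   so that, under Poisson noise, each subpopulation's location estimate gets
   noisier with distance from its landmark — the neural embodiment of the
   distance-noise law in :mod:`tooltouch.trilateration`.

Log-likelihood decoding reads out each subpopulation with a kernel equal to
the log of its tuning curves; summing both subpopulations' log-likelihoods
implements maximum-likelihood integration of the two distance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import lsq_linear, nnls

from .rod_modes import MODE_AMPLITUDE_SUPPORT, N_MODES, mode_shape

__all__ = [
    "GradientParams",
    "TuningCurve",
    "LayerSpec",
    "PopulationResponse",
    "WeightMatrix",
    "DecoderKernel",
    "NetworkConfig",
    "SimulationResult",
    "gain_gradient",
    "width_gradient",
    "build_layers",
    "mode_template",
    "build_mode_weights",
    "poisson_population_response",
    "mode_layer_response",
    "feature_layer_response",
    "solve_decoder_weights",
    "build_network",
    "decode_ml",
    "decode_integrated",
    "run_simulation",
]

LOG_FLOOR = 1e-12  # tuning floored above 0 before taking logs


@dataclass(frozen=True)
class GradientParams:
    """Distance-dependent gradient of a decoding subpopulation's tuning."""

    kappa0: float = 25.0  # gain at the anchor (spikes per window)
    beta: float = 0.01  # gain decay per unit distance
    sigma0: float = 3.40  # tuning width at the anchor (% space)
    gamma: float = 0.5  # log-width scaling

    def __post_init__(self):
        if min(self.kappa0, self.beta, self.sigma0, self.gamma) <= 0:
            raise ValueError("gradient parameters must be positive")


def gain_gradient(d, g: GradientParams):
    """Peak firing rate at distance ``d`` from the anchor: kappa0 / (1 + beta d)^2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = g.kappa0 / (1.0 + g.beta * d) ** 2
    return float(out) if out.ndim == 0 else out


def width_gradient(d, g: GradientParams):
    """Tuning width at distance ``d``: (gamma log(d+1) + 1) * sigma0 (Weber–Fechner)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = (g.gamma * np.log(d + 1.0) + 1.0) * g.sigma0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TuningCurve:
    """Gaussian tuning: mean rate = gain * exp(-(s - center)^2 / (2 width^2))."""

    center: float
    gain: float
    width: float

    def __post_init__(self):
        if self.gain <= 0 or self.width <= 0:
            raise ValueError("gain and width must be positive")


@dataclass
class LayerSpec:
    """A layer (or decoding subpopulation): per-unit centers, gains, widths.

    The mode layer holds one block of ``centers`` per mode subpopulation
    (``n_subpopulations`` = 5); other layers hold a single population.
    """

    role: str  # "mode" | "feature" | "distance1" | "distance2"
    centers: np.ndarray
    gains: np.ndarray
    widths: np.ndarray
    anchor: Optional[float] = None  # landmark location for distance layers
    n_subpopulations: int = 1

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.gains = np.broadcast_to(np.asarray(self.gains, dtype=float), self.centers.shape).copy()
        self.widths = np.broadcast_to(np.asarray(self.widths, dtype=float), self.centers.shape).copy()
        block = len(self.centers) // self.n_subpopulations
        for s in range(self.n_subpopulations):
            c = self.centers[s * block : (s + 1) * block]
            if np.any(np.diff(c) <= 0):
                raise ValueError(f"{self.role} layer centers must be strictly increasing per subpopulation")

    @property
    def n_units(self) -> int:
        return len(self.centers)

    def tuning(self, i: int) -> TuningCurve:
        return TuningCurve(center=self.centers[i], gain=self.gains[i], width=self.widths[i])

    def mean_rates(self, stimulus) -> np.ndarray:
        """Mean rates of all units for stimulus value(s) along the layer's axis.

        ``stimulus`` may be scalar or an array of trials; the result has
        shape ``(..., n_units)``.
        """
        s = np.asarray(stimulus, dtype=float)[..., None]
        return self.gains * np.exp(-((s - self.centers) ** 2) / (2.0 * self.widths**2))


@dataclass
class PopulationResponse:
    """Spike counts of one layer on one trial (or a batch of trials)."""

    counts: np.ndarray  # integer counts, last axis = units
    role: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")


@dataclass
class WeightMatrix:
    """Non-negative synaptic weights, rows = target units, columns = source units."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("synaptic weights must be non-negative")
        self.weights = np.clip(self.weights, 0.0, None)


@dataclass
class DecoderKernel:
    """Log-tuning kernel h(L) on a candidate-location grid.

    ``kernel[l, i] = log(max(f_i(grid[l]), floor))`` so that ``kernel @ r``
    is the population log-likelihood profile over the grid.
    """

    grid: np.ndarray
    kernel: np.ndarray  # (n_grid, n_units)

    @classmethod
    def from_layer(cls, layer: LayerSpec, grid: np.ndarray) -> "DecoderKernel":
        grid = np.asarray(grid, dtype=float)
        rates = layer.mean_rates(grid)  # (n_grid, n_units)
        return cls(grid=grid, kernel=np.log(np.maximum(rates, LOG_FLOOR)))


# ---------------------------------------------------------------------------
# Layer construction (defaults follow the published parameter table)
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    """Parameters of all layers; defaults are the reference configuration."""

    mode_centers: tuple = (-1.5, 0.02, 1.5)  # (start, step, stop) per mode subpopulation
    feature_centers: tuple = (-40.0, 1.0, 140.0)
    distance1_centers: tuple = (0.0, 1.0, 140.0)
    distance2_centers: tuple = (-40.0, 1.0, 100.0)
    kappa: float = 25.0
    sigma_mode: float = 0.08
    sigma_space: float = 3.40
    beta: float = 0.01
    gamma: float = 0.5
    proximal_anchor: float = 0.0
    distal_anchor: float = 100.0
    input_jitter_sd: float = 0.5  # sensory noise on location (% space)
    amplitude_scale: float = 1.0
    n_modes: int = N_MODES

    def gradient_params(self) -> GradientParams:
        return GradientParams(kappa0=self.kappa, beta=self.beta, sigma0=self.sigma_space, gamma=self.gamma)


def _grid(spec: tuple) -> np.ndarray:
    start, step, stop = spec
    return np.arange(start, stop + step / 2, step)


def build_layers(config: NetworkConfig = NetworkConfig()) -> tuple[LayerSpec, LayerSpec, LayerSpec, LayerSpec]:
    """Construct mode, feature, and the two distance-decoding layers.

    Mode units tile amplitude space identically for each of the five mode
    subpopulations; feature units tile the feature space (extended beyond
    [0, 100] to avoid decoder truncation at the ends); distance units carry
    the gain/width gradients anchored at the hand (distance1) and tip
    (distance2).
    """
    mode_c = _grid(config.mode_centers)
    lo, hi = MODE_AMPLITUDE_SUPPORT
    if mode_c[0] < lo - 1e-9 or mode_c[-1] > hi + 1e-9:
        raise ValueError("mode-layer centers exceed the amplitude support")
    mode = LayerSpec(
        role="mode",
        centers=np.tile(mode_c, config.n_modes),
        gains=config.kappa,
        widths=config.sigma_mode,
        n_subpopulations=config.n_modes,
    )
    feature = LayerSpec(
        role="feature",
        centers=_grid(config.feature_centers),
        gains=config.kappa,
        widths=config.sigma_space,
    )
    g = config.gradient_params()
    layers = []
    for role, spec, anchor in (
        ("distance1", config.distance1_centers, config.proximal_anchor),
        ("distance2", config.distance2_centers, config.distal_anchor),
    ):
        centers = _grid(spec)
        d = np.abs(centers - anchor)
        layers.append(
            LayerSpec(
                role=role,
                centers=centers,
                gains=gain_gradient(d, g),
                widths=width_gradient(d, g),
                anchor=anchor,
            )
        )
    return mode, feature, layers[0], layers[1]


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------


def poisson_population_response(means: np.ndarray, rng: np.random.Generator, role: str = "") -> PopulationResponse:
    """Independent Poisson spike counts around the given mean rates (Fano factor 1)."""
    means = np.asarray(means, dtype=float)
    if np.any(means < 0):
        raise ValueError("mean rates must be non-negative")
    return PopulationResponse(counts=rng.poisson(means), role=role)


def mode_template(location, config: NetworkConfig, mode_layer: LayerSpec) -> np.ndarray:
    """Noise-free mode-layer mean response to touch at ``location`` (% space).

    Evaluates each mode's amplitude at the touch position and each unit's
    Gaussian tuning at that amplitude.  ``location`` may be an array; the
    result has shape ``(..., n_units)`` with the five subpopulation blocks
    concatenated.
    """
    loc = np.asarray(location, dtype=float)
    x = loc / 100.0
    block = mode_layer.n_units // config.n_modes
    parts = []
    for m in range(1, config.n_modes + 1):
        theta = mode_shape(m, x) * config.amplitude_scale
        centers = mode_layer.centers[(m - 1) * block : m * block]
        gains = mode_layer.gains[(m - 1) * block : m * block]
        widths = mode_layer.widths[(m - 1) * block : m * block]
        t = np.asarray(theta, dtype=float)[..., None]
        parts.append(gains * np.exp(-((t - centers) ** 2) / (2.0 * widths**2)))
    return np.concatenate(parts, axis=-1)


def build_mode_weights(config: NetworkConfig, mode_layer: LayerSpec, feature_layer: LayerSpec) -> WeightMatrix:
    """Feature-layer synaptic weights: each row is the (unit-norm) mode template
    of that feature unit's preferred location.

    Feature units preferring locations outside the physical rod ([0, 100])
    have no motif to match and receive zero weights, so they can never win
    the winner-take-all.
    """
    W = np.zeros((feature_layer.n_units, mode_layer.n_units))
    inside = (feature_layer.centers >= 0.0) & (feature_layer.centers <= 100.0)
    templates = mode_template(feature_layer.centers[inside], config, mode_layer)
    norms = np.linalg.norm(templates, axis=-1, keepdims=True)
    W[inside] = templates / np.where(norms > 0, norms, 1.0)
    return WeightMatrix(weights=W)


def mode_layer_response(
    location,
    config: NetworkConfig,
    mode_layer: LayerSpec,
    rng: np.random.Generator,
    jitter: bool = True,
) -> PopulationResponse:
    """Mode-layer spikes for touch at ``location``, with sensory jitter on the
    location (Gaussian, SD ``input_jitter_sd`` % space) applied before the
    motif lookup."""
    loc = np.asarray(location, dtype=float)
    if jitter and config.input_jitter_sd > 0:
        loc = loc + rng.normal(0.0, config.input_jitter_sd, size=loc.shape)
    loc = np.clip(loc, 0.0, 100.0)
    means = mode_template(loc, config, mode_layer)
    return poisson_population_response(means, rng, role="mode")


def feature_layer_response(
    r_mode: PopulationResponse,
    W: WeightMatrix,
    feature_layer: LayerSpec,
    rng: np.random.Generator,
) -> tuple[PopulationResponse, np.ndarray]:
    """Feature-layer spikes given mode-layer input.

    The synaptic drive ``W @ r_mode`` is reduced by winner-take-all (ties to
    the smaller index); all feature units are then driven by Gaussian tuning
    evaluated at the winner's preferred location, with uninherited Poisson
    noise on top.  Returns the response and the winner's preferred
    location(s).
    """
    counts = np.asarray(r_mode.counts, dtype=float)
    if counts.shape[-1] != W.weights.shape[1]:
        raise ValueError(
            f"mode response has {counts.shape[-1]} units but weights expect {W.weights.shape[1]}"
        )
    drive = counts @ W.weights.T  # (..., n_feature)
    winner = np.argmax(drive, axis=-1)  # first max on ties
    winner_loc = feature_layer.centers[winner]
    means = feature_layer.mean_rates(winner_loc)
    return poisson_population_response(means, rng, role="feature"), winner_loc


def solve_decoder_weights(
    feature_layer: LayerSpec,
    distance_layer: LayerSpec,
    grid: Optional[np.ndarray] = None,
) -> tuple[WeightMatrix, float]:
    """Non-negative weights reproducing each distance unit's tuning curve.

    For each decoding unit, solves ``min_w || A w - t ||`` with ``w >= 0``,
    where ``A[l, i]`` is the mean feature response of unit ``i`` to location
    ``l`` and ``t`` is the unit's prespecified gradient tuning curve on the
    same grid.  Returns the weight matrix and the worst per-unit RMS residual
    as a fraction of that unit's peak rate.
    """
    if grid is None:
        grid = feature_layer.centers
    A = feature_layer.mean_rates(grid)  # (n_grid, n_feature)
    T = distance_layer.mean_rates(grid)  # (n_grid, n_distance)
    W = np.empty((distance_layer.n_units, feature_layer.n_units))
    worst = 0.0
    for i in range(distance_layer.n_units):
        try:
            w, rnorm = nnls(A, T[:, i], maxiter=50 * A.shape[1])
        except RuntimeError:
            # Gaussian bases are near-degenerate; fall back to bounded lsq
            sol = lsq_linear(A, T[:, i], bounds=(0.0, np.inf), tol=1e-12)
            w = np.clip(sol.x, 0.0, None)
            rnorm = float(np.linalg.norm(A @ w - T[:, i]))
        W[i] = w
        worst = max(worst, rnorm / np.sqrt(len(grid)) / distance_layer.gains[i])
    if worst > 0.05:
        raise RuntimeError(
            f"decoder weight solve failed: worst relative RMS residual {worst:.3g} exceeds 5%"
        )
    return WeightMatrix(weights=W), worst


def decode_ml(r: PopulationResponse, kernel: DecoderKernel) -> np.ndarray:
    """Maximum log-likelihood location estimate: argmax_L kernel(L) . r.

    Ties break to the smaller grid location.  An all-zero response carries no
    evidence; the grid midpoint is returned for such trials (flagged NaN-free
    but degenerate by construction).
    """
    if len(kernel.grid) == 0:
        raise ValueError("decoder grid is empty")
    counts = np.asarray(r.counts, dtype=float)
    ll = counts @ kernel.kernel.T  # (..., n_grid)
    est = kernel.grid[np.argmax(ll, axis=-1)]
    dead = counts.sum(axis=-1) == 0
    if np.any(dead):
        est = np.where(dead, kernel.grid[len(kernel.grid) // 2], est)
    return est


def decode_integrated(
    r1: PopulationResponse, r2: PopulationResponse, k1: DecoderKernel, k2: DecoderKernel
) -> np.ndarray:
    """Integrated estimate: argmax_L of the summed subpopulation log-likelihoods."""
    if len(k1.grid) != len(k2.grid) or not np.allclose(k1.grid, k2.grid):
        raise ValueError("decoder kernels must share a location grid")
    ll = np.asarray(r1.counts, dtype=float) @ k1.kernel.T + np.asarray(r2.counts, dtype=float) @ k2.kernel.T
    return k1.grid[np.argmax(ll, axis=-1)]


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """Assembled network: layers, solved weights, decoder kernels."""

    config: NetworkConfig
    mode: LayerSpec
    feature: LayerSpec
    distance1: LayerSpec
    distance2: LayerSpec
    W_feature: WeightMatrix
    W_d1: WeightMatrix
    W_d2: WeightMatrix
    kernel1: DecoderKernel
    kernel2: DecoderKernel
    weight_residual: float


def build_network(config: NetworkConfig = NetworkConfig(), grid_step: float = 1.0) -> Network:
    """Build all layers, solve decoder weights, and prepare decoding kernels.

    The decoding grid tiles the feature range (beyond [0, 100]) in
    ``grid_step`` steps; decoded values outside [0, 100] are retained.
    """
    mode, feature, d1, d2 = build_layers(config)
    Wf = build_mode_weights(config, mode, feature)
    W1, res1 = solve_decoder_weights(feature, d1)
    W2, res2 = solve_decoder_weights(feature, d2)
    lo = min(feature.centers[0], d1.centers[0], d2.centers[0])
    hi = max(feature.centers[-1], d1.centers[-1], d2.centers[-1])
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    return Network(
        config=config,
        mode=mode,
        feature=feature,
        distance1=d1,
        distance2=d2,
        W_feature=Wf,
        W_d1=W1,
        W_d2=W2,
        kernel1=DecoderKernel.from_layer(d1, grid),
        kernel2=DecoderKernel.from_layer(d2, grid),
        weight_residual=max(res1, res2),
    )


def simulate_location(net: Network, location: float, n_runs: int, rng: np.random.Generator) -> dict:
    """Simulate ``n_runs`` touches at one location; decode all three estimates."""
    locs = np.full(n_runs, float(location))
    r_mode = mode_layer_response(locs, net.config, net.mode, rng)
    r_feat, _ = feature_layer_response(r_mode, net.W_feature, net.feature, rng)
    rs = np.asarray(r_feat.counts, dtype=float)
    r_d1 = poisson_population_response(rs @ net.W_d1.weights.T, rng, role="distance1")
    r_d2 = poisson_population_response(rs @ net.W_d2.weights.T, rng, role="distance2")
    return {
        "L1": decode_ml(r_d1, net.kernel1),
        "L2": decode_ml(r_d2, net.kernel2),
        "LINT": decode_integrated(r_d1, r_d2, net.kernel1, net.kernel2),
    }


@dataclass
class SimulationResult:
    """Per-location decoded estimates and bias/SD summaries."""

    locations: np.ndarray
    n_runs: int
    estimates: dict  # decoder -> (n_locations, n_runs) array
    summary: "object"  # pandas DataFrame: location, decoder, bias, sd

    def to_frame(self):
        import pandas as pd

        rows = []
        for d, arr in self.estimates.items():
            for j, L in enumerate(self.locations):
                for k in range(self.n_runs):
                    rows.append((L, d, k, arr[j, k]))
        return pd.DataFrame(rows, columns=["location", "decoder", "run", "estimate"])


def run_simulation(
    config: NetworkConfig = NetworkConfig(),
    locations: Sequence[float] = tuple(range(10, 100, 10)),
    n_runs: int = 5000,
    seed: Optional[int] = None,
    allow_unseeded: bool = False,
    net: Optional[Network] = None,
) -> SimulationResult:
    """Full network simulation across touch locations.

    For each location (default 10..90% in steps of 10), ``n_runs`` touches
    are simulated (default 5000): the location is jittered by sensory noise,
    converted to a motif, propagated through all layers, and decoded three
    ways (proximal subpopulation L1, distal L2, integrated LINT).  Bias and
    SD per location and decoder are summarized.
    """
    import pandas as pd

    if seed is None and not allow_unseeded:
        raise ValueError("refusing to run unseeded; pass seed= or allow_unseeded=True")
    rng = np.random.default_rng(seed)
    if net is None:
        net = build_network(config)
    locations = np.asarray(locations, dtype=float)
    est = {k: np.empty((len(locations), n_runs)) for k in ("L1", "L2", "LINT")}
    for j, L in enumerate(locations):
        out = simulate_location(net, L, n_runs, rng)
        for k in est:
            est[k][j] = out[k]
    rows = []
    for k, arr in est.items():
        for j, L in enumerate(locations):
            rows.append(
                {
                    "location": L,
                    "decoder": k,
                    "mean": arr[j].mean(),
                    "bias": arr[j].mean() - L,
                    "sd": arr[j].std(ddof=1),
                }
            )
    summary = pd.DataFrame(rows)
    return SimulationResult(locations=locations, n_runs=n_runs, estimates=est, summary=summary)
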