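"""Synthetic 2D electronic spectroscopy (2DES) datasets.

The generator emulates the statistical structure of absorptive 2DES maps of
small excitonic aggregates, as needed to exercise global lifetime analysis:

* a handful of exciton states producing diagonal peaks and cross peaks,
  each rendered as a 2D Gaussian with principal axes along the diagonal and
  antidiagonal of the (excitation w1, emission w3) plane;
* first-order population kinetics (downhill exciton relaxation on the
  ~100 fs scale plus a slow >1 ps drain) driving the peak amplitudes;
* ultrafast overdamped coherence-dephasing amplitude (~10 fs) at diagonal
  and symmetric cross-peak positions;
* amplitude weighting by a Gaussian laser spectrum at both frequencies;
* additive i.i.d. Gaussian noise referenced to the global signal maximum.

Signals are synthesized directly in the frequency domain: per pixel every
trace is a finite sum of exponentials in the population time t2, i.e. the
forward model lies exactly inside the model class fitted by
:mod:`exciton2des.globalfit`, which makes parameter recovery a clean test
surface.  Ground-state bleach / stimulated emission is positive.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.linalg import expm

from . import __version__

#: Gaussian time-bandwidth product (intensity FWHM convention).
TIME_BANDWIDTH_PRODUCT = 0.441
SPEED_OF_LIGHT_CM_FS = 2.99792458e-5  # cm / fs
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def pulse_bandwidth(duration_fwhm: float) -> float:
    """Transform-limited Gaussian bandwidth (cm^-1) of a pulse of the given
    intensity-FWHM duration (fs): ``dnu = 0.441 / (dt * c)``.

    An 8 fs pulse gives ~1839 cm^-1.
    """
    if not duration_fwhm > 0:
        raise ValueError("pulse duration must be > 0")
    return TIME_BANDWIDTH_PRODUCT / (duration_fwhm * SPEED_OF_LIGHT_CM_FS)


@dataclass
class PeakSpec:
    """One 2D Gaussian feature tied to a named kinetic channel.

    ``scale`` multiplies the channel's amplitude trace for this peak.
    """

    excitation_center: float  # w1, cm^-1
    emission_center: float  # w3, cm^-1
    fwhm_diag: float  # cm^-1, width along the diagonal
    fwhm_antidiag: float  # cm^-1, width along the antidiagonal
    channel: str
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.fwhm_diag > 0 and self.fwhm_antidiag > 0):
            raise ValueError("peak widths must be positive")


@dataclass
class KineticScheme:
    """First-order population network plus overdamped coherence channels.

    ``rate_matrix`` K (fs^-1) generates dp/dt = K p with column-to-row flow:
    K[i, j] >= 0 (i != j) is the rate from channel j into channel i, and
    each diagonal element compensates the outflow of its column (column sums
    <= 0; a strictly negative column sum is terminal loss).
    ``coherence_channels`` maps a channel name to (amplitude, dephasing time
    tau_deph in fs), evaluated as a * exp(-t2 / tau_deph) — non-oscillatory
    overdamped decay.
    """

    channels: list[str]
    rate_matrix: np.ndarray  # (n, n), fs^-1
    initial_populations: np.ndarray  # (n,)
    coherence_channels: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.initial_populations = np.asarray(self.initial_populations, dtype=float)
        n = len(self.channels)
        if len(set(self.channels)) != n:
            raise ValueError("duplicate channel names")
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix shape must match channel count")
        if not np.all(np.isfinite(self.rate_matrix)):
            raise ValueError("rate_matrix must be finite")
        off = self.rate_matrix - np.diag(np.diag(self.rate_matrix))
        if np.any(off < -1e-15):
            raise ValueError("off-diagonal rates must be >= 0")
        colsums = self.rate_matrix.sum(axis=0)
        if np.any(colsums > 1e-12):
            raise ValueError(
                "column sums of rate_matrix must be <= 0 (population is "
                "conserved up to terminal loss)"
            )
        if self.initial_populations.shape != (n,):
            raise ValueError("initial_populations shape must match channel count")
        if np.any(self.initial_populations < 0):
            raise ValueError("initial populations must be >= 0")
        for name, (amp, tau) in self.coherence_channels.items():
            if name in self.channels:
                raise ValueError(f"coherence channel {name!r} shadows a population channel")
            if not tau > 0:
                raise ValueError(f"dephasing time of {name!r} must be > 0")

    @property
    def all_channel_names(self) -> list[str]:
        return list(self.channels) + list(self.coherence_channels)


def solve_kinetics(scheme: KineticScheme, t2_grid: np.ndarray) -> dict[str, np.ndarray]:
    """Exact channel amplitudes over t2 (fs).

    Populations solve dp/dt = K p via the matrix exponential; coherence
    channels are a * exp(-t2 / tau_deph).
    """
    t2 = np.asarray(t2_grid, dtype=float)
    n = len(scheme.channels)
    pops = np.empty((t2.size, n))
    for k, t in enumerate(t2):
        pops[k] = expm(scheme.rate_matrix * t) @ scheme.initial_populations
    out = {name: pops[:, i] for i, name in enumerate(scheme.channels)}
    for name, (amp, tau) in scheme.coherence_channels.items():
        out[name] = amp * np.exp(-t2 / tau)
    return out


@dataclass
class SimulationRecipe:
    """Full ground-truth specification of one synthetic 2DES dataset."""

    name: str
    peaks: list[PeakSpec]
    kinetics: KineticScheme
    t2_grid: np.ndarray  # fs
    omega1: np.ndarray  # cm^-1, ascending (excitation axis)
    omega3: np.ndarray  # cm^-1, ascending (emission axis)
    laser_center: float  # cm^-1
    laser_fwhm: float  # cm^-1
    noise_sigma: float = 0.0  # fraction of max |noiseless signal|
    seed: int = 0

    def __post_init__(self) -> None:
        self.t2_grid = np.asarray(self.t2_grid, dtype=float)
        self.omega1 = np.asarray(self.omega1, dtype=float)
        self.omega3 = np.asarray(self.omega3, dtype=float)
        for nm, ax in (("t2_grid", self.t2_grid), ("omega1", self.omega1), ("omega3", self.omega3)):
            if ax.ndim != 1 or ax.size < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{nm} must be a strictly increasing 1-D grid")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        known = set(self.kinetics.all_channel_names)
        for p in self.peaks:
            if p.channel not in known:
                raise ValueError(
                    f"peak at ({p.excitation_center}, {p.emission_center}) references "
                    f"unknown kinetic channel {p.channel!r}"
                )

    def to_dict(self) -> dict:
        """JSON-serializable ground-truth record (used for provenance)."""
        return {
            "name": self.name,
            "peaks": [
                {
                    "excitation_center": p.excitation_center,
                    "emission_center": p.emission_center,
                    "fwhm_diag": p.fwhm_diag,
                    "fwhm_antidiag": p.fwhm_antidiag,
                    "channel": p.channel,
                    "scale": p.scale,
                }
                for p in self.peaks
            ],
            "kinetics": {
                "channels": list(self.kinetics.channels),
                "rate_matrix": self.kinetics.rate_matrix.tolist(),
                "initial_populations": self.kinetics.initial_populations.tolist(),
                "coherence_channels": {
                    k: list(v) for k, v in self.kinetics.coherence_channels.items()
                },
            },
            "t2_grid": self.t2_grid.tolist(),
            "omega1": self.omega1.tolist(),
            "omega3": self.omega3.tolist(),
            "laser_center": self.laser_center,
            "laser_fwhm": self.laser_fwhm,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class Dataset2DES:
    """Stack of real absorptive 2D maps over population time.

    ``maps[k, i, j]`` is the signal at (t2[k], omega1[i], omega3[j]).
    """

    omega1: np.ndarray
    omega3: np.ndarray
    t2: np.ndarray
    maps: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega1 = np.asarray(self.omega1, dtype=float)
        self.omega3 = np.asarray(self.omega3, dtype=float)
        self.t2 = np.asarray(self.t2, dtype=float)
        self.maps = np.asarray(self.maps, dtype=float)
        expected = (self.t2.size, self.omega1.size, self.omega3.size)
        if self.maps.shape != expected:
            raise ValueError(
                f"maps shape {self.maps.shape} does not match "
                f"(t2, omega1, omega3) sizes {expected}"
            )
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("maps contain non-finite values")

    @property
    def n_pixels(self) -> int:
        return self.omega1.size * self.omega3.size


def _laser_envelope(omega: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    return np.exp(-((omega - center) ** 2) / (2.0 * sigma**2))


def _peak_profiles(recipe: SimulationRecipe) -> np.ndarray:
    """Static spatial profile of each peak, laser weighting included.

    Returns an array of shape (n_peaks, n_omega1, n_omega3).
    """
    w1 = recipe.omega1[:, None]
    w3 = recipe.omega3[None, :]
    laser = _laser_envelope(recipe.omega1, recipe.laser_center, recipe.laser_fwhm)[
        :, None
    ] * _laser_envelope(recipe.omega3, recipe.laser_center, recipe.laser_fwhm)[None, :]
    profiles = np.empty((len(recipe.peaks), recipe.omega1.size, recipe.omega3.size))
    for k, p in enumerate(recipe.peaks):
        if not (
            recipe.omega1[0] <= p.excitation_center <= recipe.omega1[-1]
            and recipe.omega3[0] <= p.emission_center <= recipe.omega3[-1]
        ):
            warnings.warn(
                f"peak center ({p.excitation_center}, {p.emission_center}) cm^-1 "
                "lies outside the frequency axes; the peak is truncated",
                stacklevel=3,
            )
        # rotate into diagonal (u) / antidiagonal (v) coordinates
        d1 = w1 - p.excitation_center
        d3 = w3 - p.emission_center
        u = (d1 + d3) / np.sqrt(2.0)
        v = (d3 - d1) / np.sqrt(2.0)
        sd = p.fwhm_diag * _FWHM_TO_SIGMA
        sa = p.fwhm_antidiag * _FWHM_TO_SIGMA
        profiles[k] = p.scale * np.exp(-(u**2) / (2 * sd**2) - (v**2) / (2 * sa**2)) * laser
    return profiles


def render_map(recipe: SimulationRecipe, t2: float) -> np.ndarray:
    """Noiseless 2D map at a single population time (fs)."""
    traces = solve_kinetics(recipe.kinetics, np.array([float(t2)]))
    profiles = _peak_profiles(recipe)
    amps = np.array([traces[p.channel][0] for p in recipe.peaks])
    return np.tensordot(amps, profiles, axes=1)


def render_stack(recipe: SimulationRecipe) -> np.ndarray:
    """Noiseless map stack over the recipe's full t2 grid."""
    traces = solve_kinetics(recipe.kinetics, recipe.t2_grid)
    profiles = _peak_profiles(recipe)
    amp_matrix = np.stack([traces[p.channel] for p in recipe.peaks], axis=1)  # (nt, np)
    return np.tensordot(amp_matrix, profiles, axes=([1], [0]))


def generate_dataset(recipe: SimulationRecipe) -> Dataset2DES:
    """Render the recipe and add seeded Gaussian noise.

    Noise std = ``noise_sigma`` x global max |noiseless signal|; identical
    seeds give bit-identical datasets.
    """
    if recipe.t2_grid.size == 0:
        raise ValueError("t2 grid is empty")
    stack = render_stack(recipe)
    if recipe.noise_sigma > 0:
        sigma = recipe.noise_sigma * np.abs(stack).max()
        rng = np.random.default_rng(recipe.seed)
        stack = stack + rng.normal(0.0, sigma, size=stack.shape)
    metadata = {
        "generator": f"exciton2des {__version__}",
        "seed": recipe.seed,
        "recipe": recipe.to_dict(),
        "recipe_sha256": recipe.sha256(),
    }
    return Dataset2DES(
        omega1=recipe.omega1.copy(),
        omega3=recipe.omega3.copy(),
        t2=recipe.t2_grid.copy(),
        maps=stack,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Bundled recipes for the four WSCP variants
# ---------------------------------------------------------------------------

#: Experimental-style defaults shared by all bundled recipes.
T2_STEP_FS = 7.5
T2_MAX_FS = 1000.0
LASER_CENTER_CM1 = 15380.0
LASER_FWHM_CM1 = pulse_bandwidth(8.0)  # ~1839 cm^-1, 8 fs pulse
FAST_RELAXATION_FS = 100.0  # downhill exciton relaxation
SLOW_DECAY_FS = 2000.0  # ">1 ps" drain, outside the 1 ps window
COHERENCE_DEPHASING_FS = 10.0  # overdamped coherence decay (Chl b complexes)

#: Exciton-state coordinates (cm^-1) of the bundled complexes.  Chl a
#: complexes show two excitons; Chl b complexes show four.
FIXTURE_STATE_ENERGIES: Mapping[str, tuple[float, ...]] = {
    "Lv-a": (14850.0, 15070.0),
    "Bo-a": (14600.0, 14830.0),
    "Lv-b": (14660.0, 15050.0, 15400.0, 15660.0),
    "Bo-b": (14620.0, 14900.0, 15300.0, 15650.0),
}

_FIXTURE_WIDTHS = {  # (fwhm_diag, fwhm_antidiag), Lv complexes broader
    "Lv-a": (170.0, 100.0),
    "Bo-a": (150.0, 90.0),
    "Lv-b": (180.0, 110.0),
    "Bo-b": (150.0, 90.0),
}
_FIXTURE_NOISE = {"Lv-a": 0.01, "Bo-a": 0.01, "Lv-b": 0.005, "Bo-b": 0.005}
_FIXTURE_SEEDS = {"Lv-a": 11, "Bo-a": 13, "Lv-b": 12, "Bo-b": 14}


def _axes(energies, margin: float, step: float) -> np.ndarray:
    lo = step * np.floor((min(energies) - margin) / step)
    hi = step * np.ceil((max(energies) + margin) / step)
    return np.arange(lo, hi + 0.5 * step, step)


def _chl_a_recipe(name, *, grid_step, grid_margin, t2_grid) -> SimulationRecipe:
    e_lo, e_hi = FIXTURE_STATE_ENERGIES[name]
    fwhm_d, fwhm_a = _FIXTURE_WIDTHS[name]
    k_fast = 1.0 / FAST_RELAXATION_FS
    k_slow = 1.0 / SLOW_DECAY_FS
    kinetics = KineticScheme(
        channels=["upper", "lower", "fed"],
        # upper relaxes downhill into "fed"; directly excited "lower" and the
        # fed population drain slowly
        rate_matrix=np.array(
            [
                [-k_fast, 0.0, 0.0],
                [0.0, -k_slow, 0.0],
                [k_fast, 0.0, -k_slow],
            ]
        ),
        initial_populations=np.array([1.0, 1.0, 0.0]),
    )
    peaks = [
        PeakSpec(e_hi, e_hi, fwhm_d, fwhm_a, "upper", 1.0),
        PeakSpec(e_lo, e_lo, fwhm_d, fwhm_a, "lower", 0.9),
        PeakSpec(e_hi, e_lo, fwhm_d, fwhm_a, "fed", 0.8),  # below-diagonal cross peak
    ]
    axes = _axes((e_lo, e_hi), grid_margin, grid_step)
    return SimulationRecipe(
        name=name,
        peaks=peaks,
        kinetics=kinetics,
        t2_grid=t2_grid,
        omega1=axes,
        omega3=axes.copy(),
        laser_center=LASER_CENTER_CM1,
        laser_fwhm=LASER_FWHM_CM1,
        noise_sigma=_FIXTURE_NOISE[name],
        seed=_FIXTURE_SEEDS[name],
    )


def _chl_b_recipe(name, *, grid_step, grid_margin, t2_grid) -> SimulationRecipe:
    energies = FIXTURE_STATE_ENERGIES[name]
    fwhm_d, fwhm_a = _FIXTURE_WIDTHS[name]
    k_fast = 1.0 / FAST_RELAXATION_FS
    k_slow = 1.0 / SLOW_DECAY_FS
    # channels: s1..s4 (populations of the four excitons, lowest first) and
    # fed2..fed4 (population arriving downhill from each upper exciton)
    channels = [f"s{i}" for i in range(1, 5)] + [f"fed{i}" for i in range(2, 5)]
    n = len(channels)
    K = np.zeros((n, n))
    K[0, 0] = -k_slow  # lowest exciton drains slowly
    for i in range(1, 4):  # s2..s4 relax downhill at the fast rate
        K[i, i] = -k_fast
        K[4 + i - 1, i] = k_fast
        K[4 + i - 1, 4 + i - 1] = -k_slow
    p0 = np.array([1.0] * 4 + [0.0] * 3)
    kinetics = KineticScheme(
        channels=channels,
        rate_matrix=K,
        initial_populations=p0,
        coherence_channels={"coh10": (1.0, COHERENCE_DEPHASING_FS)},
    )
    peaks: list[PeakSpec] = []
    for i, e in enumerate(energies, start=1):
        peaks.append(PeakSpec(e, e, fwhm_d, fwhm_a, f"s{i}", 1.0))
    for i in range(2, 5):  # downhill cross peaks below the diagonal
        peaks.append(
            PeakSpec(energies[i - 1], energies[i - 2], fwhm_d, fwhm_a, f"fed{i}", 0.7)
        )
    for e in energies:  # coherence amplitude on the diagonal
        peaks.append(PeakSpec(e, e, fwhm_d, fwhm_a, "coh10", 0.8))
    for ei in energies:  # symmetric cross-peak coherence pairs
        for ej in energies:
            if ei != ej:
                peaks.append(PeakSpec(ei, ej, fwhm_d, fwhm_a, "coh10", 0.6))
    axes = _axes(energies, grid_margin, grid_step)
    return SimulationRecipe(
        name=name,
        peaks=peaks,
        kinetics=kinetics,
        t2_grid=t2_grid,
        omega1=axes,
        omega3=axes.copy(),
        laser_center=LASER_CENTER_CM1,
        laser_fwhm=LASER_FWHM_CM1,
        noise_sigma=_FIXTURE_NOISE[name],
        seed=_FIXTURE_SEEDS[name],
    )


def fixture_recipes(
    grid_step: float = 10.0,
    grid_margin: float = 350.0,
    t2_step: float = T2_STEP_FS,
    t2_max: float = T2_MAX_FS,
) -> dict[str, SimulationRecipe]:
    """The four bundled complex recipes (Lv-a, Lv-b, Bo-a, Bo-b).

    Defaults reproduce the study conditions: t2 scanned 0-1000 fs in 7.5 fs
    steps, laser centered at 15 380 cm^-1 with the 8 fs transform-limited
    bandwidth, ~100 fs downhill relaxation plus a 2 ps drain, and for the
    Chl b complexes an additional 10 fs overdamped coherence channel.  The
    grid arguments exist so that scaled-down variants can be produced for
    quick exploration; the scientific content is unchanged.
    """
    t2_grid = np.arange(0.0, t2_max + 1e-9, t2_step)
    if t2_grid[-1] > t2_max:
        t2_grid = t2_grid[:-1]
    kw = dict(grid_step=grid_step, grid_margin=grid_margin, t2_grid=t2_grid)
    return {
        "Lv-a": _chl_a_recipe("Lv-a", **kw),
        "Bo-a": _chl_a_recipe("Bo-a", **kw),
        "Lv-b": _chl_b_recipe("Lv-b", **kw),
        "Bo-b": _chl_b_recipe("Bo-b", **kw),
    }
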