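"""Interpretation of 2D decay-associated spectra.

The coordinates of DAS extrema carry the physics: positive diagonal
amplitude paired with negative below-diagonal amplitude in a fast component
is the signature of downhill exciton relaxation, and the emission-frequency
difference of such a pair estimates the relaxation energy gap.  The fastest
(coherence-dephasing) DAS pinpoints the exciton energies themselves; the
number of distinct diagonal extrema counts the excitonic states.  Finally,
an observed/calculated gap ratio converts into an effective transition
dipole via the quadratic dipole-coupling relation (V scales with mu^2 at
fixed geometry, and the gap with V).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .globalfit import DASComponent

PeakKind = Literal["diagonal", "cross_above", "cross_below"]


@dataclass
class DASPeak:
    omega1: float  # excitation, cm^-1
    omega3: float  # emission, cm^-1
    amplitude: float  # signed
    kind: PeakKind


@dataclass
class PeakSet:
    """Classified extrema of one DAS amplitude map."""

    peaks: list[DASPeak]
    diagonal_tolerance: float  # cm^-1
    source_tau: float | None = None  # fs, the DAS component's time constant

    def of_kind(self, kind: PeakKind) -> list[DASPeak]:
        return [p for p in self.peaks if p.kind == kind]


@dataclass
class GapEstimate:
    """Donor/acceptor emission energies of a relaxation signature."""

    donor_energy: float  # cm^-1
    acceptor_energy: float  # cm^-1
    gap: float  # cm^-1, donor - acceptor
    source_component_tau: float | None  # fs


@dataclass
class StateCount:
    n_states: int
    energies: list[float]  # cm^-1, ascending
    connected_pairs: list[tuple[float, float]]  # pairs linked by symmetric cross peaks


@dataclass
class DipoleRescale:
    """Effective dipole from an observed vs calculated excitonic splitting."""

    mu_reference: float  # Debye
    gap_observed: float  # cm^-1
    gap_calculated: float  # cm^-1
    mu_effective: float  # Debye


class NoRelaxationSignatureError(ValueError):
    """No positive-diagonal / negative-below-diagonal pair was found."""


def _classify(w1: float, w3: float, tol: float) -> PeakKind:
    if abs(w3 - w1) <= tol:
        return "diagonal"
    return "cross_above" if w3 > w1 else "cross_below"


def find_extrema(
    das: DASComponent,
    min_prominence: float = 0.2,
    diagonal_tolerance: float | None = None,
    smooth_sigma: float = 1.0,
) -> PeakSet:
    """Locate and classify local extrema of a DAS amplitude map.

    Local maxima (positive) and minima (negative) whose |amplitude| exceeds
    ``min_prominence`` x the global |amplitude| maximum are returned, sorted
    by descending |amplitude| (ties by (w1, w3)).  A light Gaussian smoothing
    (``smooth_sigma`` in grid steps, 0 to disable) suppresses noise-split
    extrema without shifting isolated peaks.  ``diagonal_tolerance`` defaults
    to two grid steps.
    """
    amp = np.asarray(das.amplitude_map, dtype=float)
    if amp.size == 0:
        raise ValueError("empty amplitude map")
    if not np.all(np.isfinite(amp)):
        raise ValueError("amplitude map contains non-finite values")
    if not 0 < min_prominence < 1:
        raise ValueError("min_prominence must be in (0, 1)")
    if smooth_sigma > 0:
        amp = ndimage.gaussian_filter(amp, sigma=smooth_sigma, mode="nearest")
    step = float(das.omega1[1] - das.omega1[0]) if das.omega1.size > 1 else 1.0
    tol = 2.0 * step if diagonal_tolerance is None else float(diagonal_tolerance)
    threshold = min_prominence * np.abs(amp).max()

    peaks: list[DASPeak] = []
    footprint = np.ones((3, 3), dtype=bool)
    is_max = (amp == ndimage.maximum_filter(amp, footprint=footprint, mode="nearest")) & (
        amp >= threshold
    )
    is_min = (amp == ndimage.minimum_filter(amp, footprint=footprint, mode="nearest")) & (
        amp <= -threshold
    )
    for mask in (is_max, is_min):
        for i, j in zip(*np.nonzero(mask)):
            w1 = float(das.omega1[i])
            w3 = float(das.omega3[j])
            peaks.append(
                DASPeak(
                    omega1=w1,
                    omega3=w3,
                    amplitude=float(amp[i, j]),
                    kind=_classify(w1, w3, tol),
                )
            )
    peaks.sort(key=lambda p: (-abs(p.amplitude), p.omega1, p.omega3))
    return PeakSet(peaks=peaks, diagonal_tolerance=tol, source_tau=das.tau)


def estimate_relaxation_gap(
    peakset: PeakSet, column_tolerance: float | None = None
) -> GapEstimate:
    """Relaxation energy gap from a fast-component DAS.

    Pairs every positive diagonal extremum with every negative
    below-diagonal extremum sharing its excitation column (within
    ``column_tolerance``, default the peakset's diagonal tolerance) and
    returns the gap of the strongest pair:
    ``gap = w3(positive diagonal) - w3(negative below diagonal)``.
    """
    tol = peakset.diagonal_tolerance if column_tolerance is None else column_tolerance
    positives = [p for p in peakset.of_kind("diagonal") if p.amplitude > 0]
    negatives = [p for p in peakset.of_kind("cross_below") if p.amplitude < 0]
    pairs = [
        (pos, neg)
        for pos in positives
        for neg in negatives
        if abs(pos.omega1 - neg.omega1) <= tol
    ]
    if not pairs:
        raise NoRelaxationSignatureError(
            "no relaxation signature: need a positive diagonal and a negative "
            "below-diagonal extremum sharing an excitation column"
        )
    pos, neg = max(pairs, key=lambda pn: abs(pn[0].amplitude * pn[1].amplitude))
    return GapEstimate(
        donor_energy=pos.omega3,
        acceptor_energy=neg.omega3,
        gap=pos.omega3 - neg.omega3,
        source_component_tau=peakset.source_tau,
    )


def count_exciton_states(
    das: DASComponent,
    min_prominence: float = 0.2,
    linewidth: float | None = None,
    diagonal_tolerance: float | None = None,
    smooth_sigma: float = 1.0,
) -> StateCount:
    """Count excitonic states from the fastest-component DAS.

    Diagonal extrema are taken as state energies, deduplicated within one
    antidiagonal ``linewidth`` (default: three grid steps).  Also reports
    which diagonal pairs are connected by symmetric cross peaks (extrema
    near both (E_i, E_j) and (E_j, E_i)).
    """
    peakset = find_extrema(
        das,
        min_prominence=min_prominence,
        diagonal_tolerance=diagonal_tolerance,
        smooth_sigma=smooth_sigma,
    )
    step = float(das.omega1[1] - das.omega1[0]) if das.omega1.size > 1 else 1.0
    window = 3.0 * step if linewidth is None else float(linewidth)

    energies: list[float] = []
    for p in peakset.of_kind("diagonal"):  # already sorted by |amplitude|
        e = 0.5 * (p.omega1 + p.omega3)
        if all(abs(e - kept) > window for kept in energies):
            energies.append(e)
    energies.sort()

    crosses = peakset.of_kind("cross_above") + peakset.of_kind("cross_below")
    match_tol = max(window, peakset.diagonal_tolerance)

    def _has_cross(w1: float, w3: float) -> bool:
        return any(
            abs(c.omega1 - w1) <= match_tol and abs(c.omega3 - w3) <= match_tol
            for c in crosses
        )

    connected = [
        (ei, ej)
        for a, ei in enumerate(energies)
        for ej in energies[a + 1 :]
        if _has_cross(ei, ej) and _has_cross(ej, ei)
    ]
    return StateCount(
        n_states=len(energies), energies=energies, connected_pairs=connected
    )


def infer_effective_dipole(
    gap_observed: float, gap_calculated: float, mu_reference: float
) -> DipoleRescale:
    """Effective transition dipole explaining an observed splitting.

    With fixed geometry the coupling scales as mu^2 and the exciton gap as
    the coupling, so ``mu_eff = mu_ref * sqrt(gap_observed / gap_calculated)``.
    """
    for name, v in (
        ("gap_observed", gap_observed),
        ("gap_calculated", gap_calculated),
        ("mu_reference", mu_reference),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be > 0")
    return DipoleRescale(
        mu_reference=mu_reference,
        gap_observed=gap_observed,
        gap_calculated=gap_calculated,
        mu_effective=mu_reference * np.sqrt(gap_observed / gap_calculated),
    )
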