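"""Charge and oligomer-order assignment from isotopic envelopes.

The workflow mirrors how 2D IMS-MS spectra are read by hand: gate the
spectrum at the drift time of one conformer, pick isotopologue centroids in
an analyst-chosen m/z window, read the charge state off the envelope
spacing (~1.0033/z Th), convert the intensity-weighted average m/z to a
neutral mass, and match that mass against n-mer masses with 0..n-1
tyrosine-tyrosine bonds (each bond -2 H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peptide_mass import HYDROGEN_AVG_MASS, MassConvention, mass_from_mz
from .synthetic_spectra import NEUTRON_SPACING, Spectrum2D

__all__ = [
    "Centroid",
    "CentroidList",
    "SpeciesAssignment",
    "EnvelopeError",
    "InsufficientEnvelopeError",
    "ChargeUnassignableError",
    "UnassignedSpeciesError",
    "pick_centroids",
    "infer_charge",
    "average_mz",
    "assign_species",
    "assign_envelope",
]


class EnvelopeError(ValueError):
    """Base class for envelope-analysis failures."""


class InsufficientEnvelopeError(EnvelopeError):
    """Fewer centroids than needed to read an isotope spacing."""


class ChargeUnassignableError(EnvelopeError):
    """No charge state explains the observed envelope spacing."""


class UnassignedSpeciesError(EnvelopeError):
    """No (n, k) candidate lies within the mass tolerance."""

    def __init__(self, message: str, n: int, k: int, residual: float):
        super().__init__(message)
        self.n = n
        self.k = k
        self.residual = residual


@dataclass(frozen=True)
class Centroid:
    mz: float
    intensity: float


@dataclass(frozen=True)
class CentroidList:
    """Picked centroids in one m/z window, optionally drift-gated."""

    centroids: tuple[Centroid, ...]
    window: tuple[float, float]
    drift_gate: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        mzs = [c.mz for c in self.centroids]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("centroid m/z values must be strictly increasing")
        if any(c.intensity <= 0 for c in self.centroids):
            raise ValueError("centroid intensities must be positive")
        lo, hi = self.window
        if any(not lo <= mz <= hi for mz in mzs):
            raise ValueError("centroids must lie inside the window")

    def __len__(self) -> int:
        return len(self.centroids)

    @property
    def mz(self) -> np.ndarray:
        return np.array([c.mz for c in self.centroids])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([c.intensity for c in self.centroids])


@dataclass(frozen=True)
class SpeciesAssignment:
    """A fully assigned envelope: charge, mass, oligomer order, bond count."""

    z: int
    avg_mz: float
    mass: float
    n: int
    k: int
    residual: float
    t_d: float | None = None  # drift centroid of the gated signal, ms
    convention: MassConvention = MassConvention.PHYSICAL


def pick_centroids(
    spectrum: Spectrum2D,
    window: tuple[float, float],
    drift_gate: tuple[float, float] | None = None,
    rel_threshold: float = 0.05,
) -> CentroidList:
    """Pick local-maximum centroids in an m/z window.

    The spectrum is first summed over the drift gate (or all drift times),
    then local maxima above ``rel_threshold`` times the window maximum are
    refined by 3-point parabolic interpolation. Peaks closer than one grid
    step merge into a single centroid — the resolution limit of the grid.
    An empty window yields an empty list.
    """
    lo, hi = window
    sel = (spectrum.mz_axis >= lo) & (spectrum.mz_axis <= hi)
    axis = spectrum.mz_axis[sel]
    profile = spectrum.mz_profile(*(drift_gate or (None, None)))[sel]
    cents: list[Centroid] = []
    if len(axis) >= 3 and profile.max() > 0:
        floor = rel_threshold * profile.max()
        y = profile
        for i in range(1, len(axis) - 1):
            if y[i] >= floor and y[i] > y[i - 1] and y[i] >= y[i + 1]:
                denom = y[i - 1] - 2 * y[i] + y[i + 1]
                delta = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                step = axis[min(i + 1, len(axis) - 1)] - axis[i]
                mz = axis[i] + delta * step
                height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
                cents.append(Centroid(float(mz), float(height)))
    return CentroidList(tuple(cents), window=window, drift_gate=drift_gate)


def infer_charge(
    centroids: CentroidList, z_max: int = 12, max_rel_dev: float = 0.20
) -> int:
    """Read the charge state off the isotope-envelope spacing.

    The median adjacent centroid spacing is compared with 1.0033/z for
    z = 1..z_max; the best z wins (ties toward smaller z) and is accepted
    only if the relative deviation is below ``max_rel_dev``. The median is
    robust to one missed or merged isotopologue peak, and the result is
    invariant to any uniform rescaling of the envelope intensities.
    """
    if len(centroids) < 3:
        raise InsufficientEnvelopeError(
            f"need >= 3 centroids to read a spacing, got {len(centroids)}"
        )
    spacing = float(np.median(np.diff(centroids.mz)))
    devs = [abs(spacing - NEUTRON_SPACING / z) for z in range(1, z_max + 1)]
    z = 1 + int(np.argmin(devs))  # argmin returns the first (smallest z) on ties
    if devs[z - 1] / (NEUTRON_SPACING / z) >= max_rel_dev:
        raise ChargeUnassignableError(
            f"median spacing {spacing:.4f} Th matches no charge in 1..{z_max}"
        )
    return z


def average_mz(centroids: CentroidList) -> float:
    """Intensity-weighted mean m/z of the envelope."""
    if len(centroids) == 0:
        raise EnvelopeError("cannot average an empty centroid list")
    w = centroids.intensity
    return float(np.dot(centroids.mz, w) / w.sum())


def assign_species(
    mass: float,
    monomer_avg_mass: float,
    n_max: int = 4,
    tolerance: float = 1.0,
) -> tuple[int, int, float]:
    """Assign oligomer order n and Tyr-Tyr bond count k to a neutral mass.

    Candidates are ``n * monomer - 2k * m_H`` for 1 <= n <= n_max,
    0 <= k <= n-1; the closest wins, ties toward smaller k. Raises
    :class:`UnassignedSpeciesError` (carrying the best candidate) if the
    best residual exceeds ``tolerance``.
    """
    if mass <= 0 or monomer_avg_mass <= 0:
        raise ValueError("masses must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    best: tuple[float, int, int] | None = None
    for n in range(1, n_max + 1):
        for k in range(0, n):
            resid = abs(mass - (n * monomer_avg_mass - 2 * k * HYDROGEN_AVG_MASS))
            if best is None or resid < best[0] - 1e-12:
                best = (resid, n, k)
    resid, n, k = best
    if resid > tolerance:
        raise UnassignedSpeciesError(
            f"mass {mass:.2f} Da matches no (n <= {n_max}, k) candidate within "
            f"{tolerance} Da (best: n={n}, k={k}, residual={resid:.2f})",
            n=n, k=k, residual=resid,
        )
    return n, k, resid


def assign_envelope(
    spectrum: Spectrum2D,
    window: tuple[float, float],
    monomer_avg_mass: float,
    drift_gate: tuple[float, float] | None = None,
    rel_threshold: float = 0.05,
    z_max: int = 12,
    n_max: int = 4,
    tolerance: float = 1.0,
    convention: "MassConvention | str" = MassConvention.PHYSICAL,
) -> SpeciesAssignment:
    """Full per-envelope pipeline: centroids -> z -> average m/z -> (n, k).

    Also records the intensity-weighted drift centroid inside the gate,
    which serves as the species' measured drift time.
    """
    cents = pick_centroids(spectrum, window, drift_gate, rel_threshold)
    z = infer_charge(cents, z_max=z_max)
    mz = average_mz(cents)
    mass = mass_from_mz(mz, z, convention)
    n, k, resid = assign_species(mass, monomer_avg_mass, n_max=n_max, tolerance=tolerance)

    sel = (spectrum.mz_axis >= window[0]) & (spectrum.mz_axis <= window[1])
    profile = spectrum.intensities[sel].sum(axis=0)
    t_axis = spectrum.drift_axis
    if drift_gate is not None:
        gate = (t_axis >= drift_gate[0]) & (t_axis <= drift_gate[1])
        profile, t_axis = profile[gate], t_axis[gate]
    t_d = float(np.dot(t_axis, profile) / profile.sum()) if profile.sum() > 0 else None

    conv = MassConvention(convention) if not isinstance(convention, MassConvention) else convention
    return SpeciesAssignment(
        z=z, avg_mz=mz, mass=mass, n=n, k=k, residual=resid, t_d=t_d, convention=conv
    )
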