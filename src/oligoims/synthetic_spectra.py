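"""Synthetic 2D (m/z x drift-time) spectra of oligomerizing peptides.

This module is the data stage of the package: it computes isotopic
distributions of arbitrary elemental compositions by convolution of
per-element isotope patterns, and renders seeded, fully reproducible
two-dimensional spectra of configurable species mixtures — oligomers of
order n at charge z, with 2-Da-per-bond cross-link mass losses, uni- or
bimodal Gaussian drift-time profiles per species (compact vs extended
conformers), and additive truncated-Gaussian noise.

Isotope masses and natural abundances come from the NIST table shipped with
:mod:`pyteomics` (``pyteomics.mass.nist_mass``).

Isotopologues are aggregated by nominal mass: each retained peak is the
abundance-weighted centroid of all isotopologues sharing a neutron count,
which is what an instrument resolving the ~1.0034/z Th envelope spacing
(but not the fine structure within one nominal peak) records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass

from .peptide_mass import (
    MassConvention,
    OligomerSpecies,
    mz_from_mass,
    oligomer_composition,
)

__all__ = [
    "IsotopePattern",
    "DriftComponent",
    "SpeciesScenario",
    "Spectrum2D",
    "isotopic_distribution",
    "envelope_mz_peaks",
    "make_scenario",
    "render_spectrum",
    "write_spectrum",
    "read_spectrum",
]

#: Mass difference between adjacent isotopologue peaks (~ 13C - 12C), Da.
NEUTRON_SPACING = 1.0033


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopic distribution of a neutral species.

    ``masses`` are strictly increasing centroid masses (Da), one per nominal
    isotopologue; ``abundances`` are fractions summing to 1.
    """

    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))
        if self.masses.ndim != 1 or self.masses.shape != self.abundances.shape:
            raise ValueError("masses and abundances must be matching 1-d arrays")
        if len(self.masses) and np.any(np.diff(self.masses) <= 0):
            raise ValueError("masses must be strictly increasing")

    @property
    def average_mass(self) -> float:
        return float(np.dot(self.masses, self.abundances))


def _element_pattern(element: str) -> tuple[np.ndarray, np.ndarray]:
    """(offsets, abundance/mass arrays) for one element's natural isotopes.

    Returns abundance ``a[j]`` and abundance-weighted mass moment ``m[j]``
    indexed by neutron offset j from the lightest naturally occurring isotope.
    """
    try:
        table = _pmass.nist_mass[element]
    except KeyError:
        raise ValueError(f"element {element!r} missing from the isotope table") from None
    isotopes = [
        (num, m, ab) for num, (m, ab) in table.items() if num != 0 and ab > 0
    ]
    if not isotopes:
        raise ValueError(f"element {element!r} has no natural-abundance isotopes")
    isotopes.sort()
    base = isotopes[0][0]
    size = isotopes[-1][0] - base + 1
    a = np.zeros(size)
    m = np.zeros(size)
    for num, mass, ab in isotopes:
        a[num - base] = ab
        m[num - base] = ab * mass
    return a, m


def _convolve_moments(
    a1: np.ndarray, m1: np.ndarray, a2: np.ndarray, m2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    # abundance convolves as a product distribution; the mass moment obeys
    # the product rule m12 = m1*a2 + a1*m2 (masses add, abundances multiply)
    a12 = np.convolve(a1, a2)
    m12 = np.convolve(m1, a2) + np.convolve(a1, m2)
    return a12, m12


def _power_pattern(
    a: np.ndarray, m: np.ndarray, count: int, tail_prune: float
) -> tuple[np.ndarray, np.ndarray]:
    """(a, m) convolved with itself ``count`` times, by binary exponentiation."""
    ra, rm = np.array([1.0]), np.array([0.0])
    while count:
        if count & 1:
            ra, rm = _convolve_moments(ra, rm, a, m)
            ra, rm = _trim(ra, rm, tail_prune)
        count >>= 1
        if count:
            a, m = _convolve_moments(a, m, a, m)
            a, m = _trim(a, m, tail_prune)
    return ra, rm


def _trim(a: np.ndarray, m: np.ndarray, tail_prune: float) -> tuple[np.ndarray, np.ndarray]:
    # drop negligible leading/trailing tails to keep the arrays short; the
    # threshold is far below any pattern-level prune the caller applies
    keep = np.nonzero(a > tail_prune)[0]
    if len(keep) == 0:
        return a, m
    lo, hi = keep[0], keep[-1] + 1
    return a[lo:hi].copy(), m[lo:hi].copy()


def isotopic_distribution(
    composition: _pmass.Composition,
    prune_below: float = 1e-4,
) -> IsotopePattern:
    """Isotopic distribution of an elemental composition.

    Convolves the natural-abundance isotope patterns of every element,
    aggregates isotopologues by nominal mass, prunes peaks whose fractional
    abundance falls below ``prune_below`` and renormalizes to sum 1.

    Parameters
    ----------
    composition
        Element-symbol -> atom-count mapping; all counts must be >= 0 with
        at least one positive.
    prune_below
        Fractional-abundance threshold in [0, 1); peaks below it are
        dropped. ``0`` keeps every nominal peak exactly.
    """
    if not 0 <= prune_below < 1:
        raise ValueError("prune_below must be in [0, 1)")
    items = [(el, int(cnt)) for el, cnt in composition.items() if cnt]
    if any(cnt < 0 for _, cnt in items):
        raise ValueError("atom counts must be non-negative")
    if not items:
        raise ValueError("composition is empty")
    # keep internal tails well below the requested prune level
    tail = 0.0 if prune_below == 0 else min(1e-15, prune_below * 1e-6)
    a, m = np.array([1.0]), np.array([0.0])
    for el, cnt in items:
        ea, em = _element_pattern(el)
        ea, em = _power_pattern(ea, em, cnt, tail)
        a, m = _convolve_moments(a, m, ea, em)
        a, m = _trim(a, m, tail)
    mask = a > max(prune_below, 0.0) if prune_below else a > 0
    a, m = a[mask], m[mask]
    masses = m / a
    order = np.argsort(masses)
    return IsotopePattern(masses=masses[order], abundances=a[order] / a.sum())


def envelope_mz_peaks(
    pattern: IsotopePattern,
    z: int,
    convention: "MassConvention | str" = MassConvention.PHYSICAL,
) -> np.ndarray:
    """Map an isotope pattern to (m/z, abundance) pairs at charge ``z``.

    Adjacent peaks are spaced ~ 1.0033/z Th — the signature from which the
    charge state of an envelope is read off.
    """
    mzs = np.array([mz_from_mass(m, z, convention) for m in pattern.masses])
    return np.column_stack([mzs, pattern.abundances])


@dataclass(frozen=True)
class DriftComponent:
    """One Gaussian conformer population in the drift-time dimension."""

    center: float  # ms
    width: float  # ms (Gaussian sigma)
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.center <= 0 or self.width <= 0 or self.amplitude < 0:
            raise ValueError("need center > 0, width > 0, amplitude >= 0")


@dataclass(frozen=True)
class SpeciesScenario:
    """One species to render: composition, charge, and drift profile."""

    species: OligomerSpecies
    composition: _pmass.Composition
    drift_components: tuple[DriftComponent, ...]
    total_intensity: float = 1.0

    def __post_init__(self) -> None:
        if not self.drift_components:
            raise ValueError("at least one drift component is required")
        if self.total_intensity < 0:
            raise ValueError("total_intensity must be >= 0")


def make_scenario(
    monomer_composition: _pmass.Composition,
    species: OligomerSpecies,
    drift_components,
    total_intensity: float = 1.0,
) -> SpeciesScenario:
    """Build a scenario for an (n, k, z) species from the monomer composition."""
    comps = tuple(
        dc if isinstance(dc, DriftComponent) else DriftComponent(*dc)
        for dc in drift_components
    )
    return SpeciesScenario(
        species=species,
        composition=oligomer_composition(monomer_composition, species.n, species.k),
        drift_components=comps,
        total_intensity=total_intensity,
    )


@dataclass
class Spectrum2D:
    """Gridded intensities over m/z (rows) x drift time (columns)."""

    mz_axis: np.ndarray
    drift_axis: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.mz_axis) <= 0) or np.any(np.diff(self.drift_axis) <= 0):
            raise ValueError("axes must be strictly increasing")
        if self.intensities.shape != (len(self.mz_axis), len(self.drift_axis)):
            raise ValueError("intensity matrix shape does not match the axes")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def drift_profile(self, mz_lo: float | None = None, mz_hi: float | None = None) -> np.ndarray:
        """Sum intensities over an m/z window -> 1-d profile vs drift time."""
        sel = np.ones(len(self.mz_axis), dtype=bool)
        if mz_lo is not None:
            sel &= self.mz_axis >= mz_lo
        if mz_hi is not None:
            sel &= self.mz_axis <= mz_hi
        return self.intensities[sel].sum(axis=0)

    def mz_profile(self, t_lo: float | None = None, t_hi: float | None = None) -> np.ndarray:
        """Sum intensities over a drift gate -> 1-d profile vs m/z."""
        sel = np.ones(len(self.drift_axis), dtype=bool)
        if t_lo is not None:
            sel &= self.drift_axis >= t_lo
        if t_hi is not None:
            sel &= self.drift_axis <= t_hi
        return self.intensities[:, sel].sum(axis=1)


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    if hi <= lo or step <= 0:
        raise ValueError("axis range must satisfy hi > lo with step > 0")
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def render_spectrum(
    scenarios,
    mz_range: tuple[float, float],
    drift_range: tuple[float, float],
    mz_step: float = 0.02,
    drift_step: float = 0.05,
    mz_sigma: float = 0.02,
    noise_sd: float = 0.0,
    seed: int | None = None,
    convention: "MassConvention | str" = MassConvention.PHYSICAL,
    prune_below: float = 1e-4,
) -> Spectrum2D:
    """Render a 2D spectrum of a species mixture.

    Each scenario contributes, for every retained isotopologue and every
    drift component, a separable Gaussian peak
    ``abundance * amplitude * total_intensity * N(mz; peak, mz_sigma) * N(t; center, width)``
    normalized so the grid-summed intensity of the noise-free spectrum equals
    ``sum(total_intensity * sum(amplitudes))`` when the grid covers the peaks.
    Additive Gaussian noise with s.d. ``noise_sd * max`` is applied last and
    the result clipped at zero. Identical inputs and seed give bit-identical
    output.

    Raises
    ------
    ValueError
        If the grid does not cover every scenario's envelope (+/-4 mz_sigma)
        and drift components (+/-4 widths); the message lists the species.
    """
    if mz_sigma <= 0:
        raise ValueError("mz_sigma must be positive")
    mz_axis = _axis(*mz_range, mz_step)
    drift_axis = _axis(*drift_range, drift_step)
    intens = np.zeros((len(mz_axis), len(drift_axis)))

    uncovered = []
    for sc in scenarios:
        pattern = isotopic_distribution(sc.composition, prune_below)
        peaks = envelope_mz_peaks(pattern, sc.species.z, convention)
        mz_lo, mz_hi = peaks[0, 0] - 4 * mz_sigma, peaks[-1, 0] + 4 * mz_sigma
        t_lo = min(dc.center - 4 * dc.width for dc in sc.drift_components)
        t_hi = max(dc.center + 4 * dc.width for dc in sc.drift_components)
        if (
            mz_lo < mz_axis[0] or mz_hi > mz_axis[-1]
            or t_lo < drift_axis[0] or t_hi > drift_axis[-1]
        ):
            uncovered.append(sc.species.label)
            continue
        # separable: (sum of isotopologue gaussians) x (sum of drift gaussians)
        mz_vec = np.zeros(len(mz_axis))
        for mz, ab in peaks:
            mz_vec += ab * np.exp(-0.5 * ((mz_axis - mz) / mz_sigma) ** 2)
        mz_vec *= mz_step / (mz_sigma * np.sqrt(2 * np.pi))
        t_vec = np.zeros(len(drift_axis))
        for dc in sc.drift_components:
            t_vec += dc.amplitude * np.exp(
                -0.5 * ((drift_axis - dc.center) / dc.width) ** 2
            ) * drift_step / (dc.width * np.sqrt(2 * np.pi))
        intens += sc.total_intensity * np.outer(mz_vec, t_vec)
    if uncovered:
        raise ValueError(
            "spectrum grid does not cover species: " + ", ".join(uncovered)
        )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        peak = intens.max()
        if peak > 0:
            intens = intens + rng.normal(0.0, noise_sd * peak, intens.shape)
            np.clip(intens, 0.0, None, out=intens)

    meta = {
        "seed": seed,
        "scenario": "; ".join(
            f"{sc.species.label} x{sc.total_intensity:g}" for sc in scenarios
        ),
    }
    return Spectrum2D(mz_axis, drift_axis, intens, meta)


def write_spectrum(path, spectrum: Spectrum2D) -> None:
    """Write a spectrum as TSV: '#'-comments, then mz<TAB>drift_ms<TAB>intensity."""
    buf = io.StringIO()
    if spectrum.metadata.get("seed") is not None:
        buf.write(f"#seed={spectrum.metadata['seed']}\n")
    if spectrum.metadata.get("scenario"):
        buf.write(f"#scenario={spectrum.metadata['scenario']}\n")
    for i, mz in enumerate(spectrum.mz_axis):
        row = spectrum.intensities[i]
        for j, t in enumerate(spectrum.drift_axis):
            buf.write(f"{mz:.10g}\t{t:.10g}\t{row[j]:.12g}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_spectrum(path) -> Spectrum2D:
    """Read a spectrum TSV written by :func:`write_spectrum`.

    Rejects malformed lines, negative intensities (with the line number) and
    files with no data rows.
    """
    meta: dict = {}
    mzs, ts, vals = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 tab-separated columns")
            try:
                mz, t, v = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from None
            if v < 0:
                raise ValueError(f"{path}: line {lineno}: negative intensity")
            mzs.append(mz)
            ts.append(t)
            vals.append(v)
    if not vals:
        raise ValueError(f"{path}: no data rows (header-only or empty file)")
    mz_axis = np.unique(mzs)
    drift_axis = np.unique(ts)
    if len(vals) != len(mz_axis) * len(drift_axis):
        raise ValueError(f"{path}: data rows do not form a complete grid")
    intens = np.asarray(vals).reshape(len(mz_axis), len(drift_axis))
    if "seed" in meta:
        try:
            meta["seed"] = int(meta["seed"])
        except ValueError:
            pass
    return Spectrum2D(mz_axis, drift_axis, intens, meta)
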