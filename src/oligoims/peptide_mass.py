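"""Peptide mass bookkeeping for cross-linked oligomers.

Turns a one-letter amino-acid sequence into an elemental composition and
average/monoisotopic masses, builds compositions of oligomers held together
by tyrosine-tyrosine covalent bonds (each bond removes two hydrogen atoms,
a nominal -2 Da per bond), and converts between neutral mass and m/z.

Two m/z conventions are supported:

``physical``
    The charge carrier is a proton, 1.007276 Da:  M = z*(m/z) - z*m_p.
``nominal``
    The charge carrier weighs exactly 1.000 Da:   M = z*(m/z) - z*1.000.
    This is the convention under which published average-m/z / mass tables
    for these oligomers are internally consistent to +/-0.01 Da, so it is
    what :func:`mass_from_mz` uses when reproducing such tables.

Residue compositions and atomic masses come from the standard tables shipped
with :mod:`pyteomics` (NIST atomic weights and isotopic compositions).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from pyteomics import mass as _pmass

__all__ = [
    "MassConvention",
    "PROTON_MASS",
    "HYDROGEN_AVG_MASS",
    "AB40_SEQUENCE",
    "OligomerSpecies",
    "MassRecord",
    "composition_from_sequence",
    "oligomer_composition",
    "average_mass",
    "monoisotopic_mass",
    "mass_from_mz",
    "mz_from_mass",
    "mass_record",
    "read_sequence",
]

#: Mass of a proton in Da.
PROTON_MASS = 1.00727646688

#: Average atomic mass of hydrogen in Da (two are lost per Tyr-Tyr bond).
HYDROGEN_AVG_MASS = _pmass.calculate_mass(formula="H", average=True)

#: Canonical human amyloid-beta 1-40 sequence (APP residues 672-711).
AB40_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


class MassConvention(str, Enum):
    """Charge-carrier mass used in m/z <-> mass conversion."""

    PHYSICAL = "physical"
    NOMINAL = "nominal"

    @property
    def carrier_mass(self) -> float:
        return PROTON_MASS if self is MassConvention.PHYSICAL else 1.000


def _as_convention(convention: "MassConvention | str") -> MassConvention:
    if isinstance(convention, MassConvention):
        return convention
    try:
        return MassConvention(convention)
    except ValueError:
        raise ValueError(
            f"unknown mass convention {convention!r}; "
            f"expected 'physical' or 'nominal'"
        ) from None


@dataclass(frozen=True)
class OligomerSpecies:
    """An oligomer of ``n`` chains with ``k`` Tyr-Tyr bonds at charge ``z``.

    ``n=1`` is the monomer; ``k`` may not exceed ``n - 1`` (a connected
    network of n chains needs at most n-1 bonds, and the species studied
    here carry at most that many).
    """

    n: int
    k: int = 0
    z: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"oligomer order must be >= 1, got {self.n}")
        if not 0 <= self.k <= self.n - 1:
            raise ValueError(
                f"bond count k={self.k} invalid for order n={self.n} "
                f"(need 0 <= k <= n-1)"
            )
        if self.z < 1:
            raise ValueError(f"charge must be >= 1, got {self.z}")

    @property
    def label(self) -> str:
        base = {1: "MON", 2: "DIM", 3: "TRI", 4: "TET"}.get(self.n, f"OLI{self.n}")
        prefix = "c" if self.k else ""
        return f"{prefix}{base}{self.z}+"


@dataclass(frozen=True)
class MassRecord:
    """Average/monoisotopic mass of a species and its m/z at a given charge."""

    average_mass: float
    monoisotopic_mass: float
    mz: float
    convention: MassConvention

    def __post_init__(self) -> None:
        if not self.average_mass >= self.monoisotopic_mass >= 0:
            raise ValueError(
                "need average_mass >= monoisotopic_mass >= 0, got "
                f"{self.average_mass} / {self.monoisotopic_mass}"
            )
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


def composition_from_sequence(sequence: str) -> _pmass.Composition:
    """Elemental composition of an unmodified linear peptide.

    The composition is the sum of residue compositions plus one water
    (N-terminal H, C-terminal OH).

    Parameters
    ----------
    sequence
        One-letter amino-acid string, canonical 20 codes only.

    Raises
    ------
    ValueError
        For an empty sequence or a non-canonical residue code.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = sorted(set(sequence) - _CANONICAL)
    if bad:
        raise ValueError(
            f"unknown residue code(s) {', '.join(map(repr, bad))} in sequence"
        )
    return _pmass.Composition(sequence=sequence)


def oligomer_composition(
    monomer: _pmass.Composition, n: int, k: int = 0
) -> _pmass.Composition:
    """Composition of an n-mer with k Tyr-Tyr covalent bonds.

    Each bond forms by radical coupling of two tyrosine side chains and
    removes exactly two hydrogen atoms; nothing else changes. The returned
    counts are ``n * monomer - 2k H``.
    """
    if n < 1:
        raise ValueError(f"oligomer order must be >= 1, got {n}")
    if not 0 <= k <= n - 1:
        raise ValueError(f"bond count k={k} invalid for order n={n}")
    comp = _pmass.Composition()
    for el, cnt in monomer.items():
        comp[el] = cnt * n
    if comp.get("H", 0) < 2 * k:
        raise ValueError("monomer does not carry enough hydrogen for 2 per bond")
    if k:
        comp["H"] -= 2 * k
    return comp


def average_mass(comp: _pmass.Composition) -> float:
    """Average (isotope-abundance-weighted) mass of a composition, Da."""
    return _pmass.calculate_mass(composition=comp, average=True)


def monoisotopic_mass(comp: _pmass.Composition) -> float:
    """Monoisotopic mass of a composition, Da."""
    return _pmass.calculate_mass(composition=comp)


def mass_from_mz(
    mz: float, z: int, convention: "MassConvention | str" = MassConvention.PHYSICAL
) -> float:
    """Neutral mass from m/z at charge ``z``: M = z*(m/z) - z*carrier."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return z * mz - z * _as_convention(convention).carrier_mass


def mz_from_mass(
    m: float, z: int, convention: "MassConvention | str" = MassConvention.PHYSICAL
) -> float:
    """m/z of a neutral mass at charge ``z``; inverse of :func:`mass_from_mz`."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if m <= 0:
        raise ValueError("mass must be positive")
    return m / z + _as_convention(convention).carrier_mass


def mass_record(
    comp: _pmass.Composition,
    z: int,
    convention: "MassConvention | str" = MassConvention.PHYSICAL,
) -> MassRecord:
    """Bundle average/monoisotopic mass and m/z for a composition at charge z."""
    conv = _as_convention(convention)
    avg = average_mass(comp)
    return MassRecord(
        average_mass=avg,
        monoisotopic_mass=monoisotopic_mass(comp),
        mz=mz_from_mass(avg, z, conv),
        convention=conv,
    )


def read_sequence(source: str) -> str:
    """Read a peptide sequence from a plain string or single-record FASTA text.

    Lines starting with ``>`` begin a FASTA record; more than one record is
    rejected. Whitespace is stripped and letters upper-cased.
    """
    lines = [ln.strip() for ln in source.strip().splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty sequence input")
    if lines[0].startswith(">"):
        if any(ln.startswith(">") for ln in lines[1:]):
            raise ValueError("expected a single FASTA record")
        seq = "".join(lines[1:])
    else:
        seq = "".join(lines)
    seq = seq.upper()
    composition_from_sequence(seq)  # validates
    return seq
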