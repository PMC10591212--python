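"""Monoisotopic mass arithmetic for singly protonated collagen peptides.

ZooMS reads whole-peptide [M+H]+ masses from MALDI-TOF spectra, so everything
here is monoisotopic and singly charged. Collagen peptides occur as ladders of
hydroxylation states (hydroxyproline/hydroxylysine, +15.994915 Da each);
ancient samples additionally accumulate deamidation (+0.984016 Da on N/Q), and
methionines may oxidise (+15.994915 Da). Modification states are enumerated as
counts only — MALDI cannot localise a modification to a site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

from pyteomics import mass as _ptmass

if TYPE_CHECKING:  # pragma: no cover
    from zoomskit.digest import Peptide

WATER = 18.010565
PROTON = 1.007276

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: residue letter -> monoisotopic residue mass (Da), standard 20 amino acids
RESIDUE_MASSES: dict[str, float] = {
    aa: _ptmass.std_aa_mass[aa] for aa in _STANDARD_AA
}


@dataclass(frozen=True)
class ModificationSpec:
    """A counted (non-localised) post-translational modification."""

    name: str
    targets: frozenset[str]
    delta: float

    def capacity(self, sequence: str) -> int:
        """Number of residues in ``sequence`` this modification can occupy."""
        return sum(1 for c in sequence if c in self.targets)


HYDROXYLATION = ModificationSpec("hydroxylation", frozenset("PK"), 15.994915)
DEAMIDATION = ModificationSpec("deamidation", frozenset("NQ"), 0.984016)
OXIDATION = ModificationSpec("oxidation", frozenset("M"), 15.994915)


@dataclass(frozen=True)
class ModificationCaps:
    """Maximum modification counts enumerated per peptide.

    Hydroxylation dominates collagen MALDI ladders; deamidation and oxidation
    default to 0 and are opted into where relevant.
    """

    max_hydroxylations: int = 3
    max_deamidations: int = 0
    max_oxidations: int = 0

    def __post_init__(self) -> None:
        if min(self.max_hydroxylations, self.max_deamidations, self.max_oxidations) < 0:
            raise ValueError("modification caps must be nonnegative")


@dataclass(frozen=True)
class MassVariant:
    """One modification state of a peptide with its [M+H]+ mass."""

    peptide: "Peptide | None"
    sequence: str
    n_hydroxylations: int
    n_deamidations: int
    n_oxidations: int
    mz: float


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - set(_STANDARD_AA)
    if bad:
        raise ValueError(f"unknown residue letter(s) {sorted(bad)} in {sequence!r}")


def mh(sequence: str, n_oh: int = 0, n_deam: int = 0, n_ox: int = 0) -> float:
    """Monoisotopic [M+H]+ of ``sequence`` with counted modifications.

    Sum of residue masses plus water plus a proton, plus the modification
    deltas. Counts are validated against the residue content (e.g. ``n_oh``
    cannot exceed the number of P and K residues).
    """
    _check_sequence(sequence)
    for n, spec in ((n_oh, HYDROXYLATION), (n_deam, DEAMIDATION), (n_ox, OXIDATION)):
        if n < 0:
            raise ValueError(f"negative {spec.name} count")
        if n > spec.capacity(sequence):
            raise ValueError(
                f"{n} {spec.name}(s) exceeds capacity "
                f"{spec.capacity(sequence)} of {sequence!r}"
            )
    total = sum(RESIDUE_MASSES[c] for c in sequence) + WATER + PROTON
    return (
        total
        + n_oh * HYDROXYLATION.delta
        + n_deam * DEAMIDATION.delta
        + n_ox * OXIDATION.delta
    )


def variant_masses(
    peptide: "Peptide | str", caps: ModificationCaps = ModificationCaps()
) -> list[MassVariant]:
    """Enumerate all modification states of a peptide within ``caps``.

    Accepts a :class:`~zoomskit.digest.Peptide` or a bare sequence. States are
    returned in ascending m/z; adjacent hydroxylation states differ by exactly
    15.994915 Da.
    """
    if isinstance(peptide, str):
        seq, pep = peptide, None
    else:
        seq, pep = peptide.sequence, peptide
    _check_sequence(seq)
    oh_max = min(caps.max_hydroxylations, HYDROXYLATION.capacity(seq))
    de_max = min(caps.max_deamidations, DEAMIDATION.capacity(seq))
    ox_max = min(caps.max_oxidations, OXIDATION.capacity(seq))
    out = [
        MassVariant(pep, seq, oh, de, ox, mh(seq, oh, de, ox))
        for oh, de, ox in itertools.product(
            range(oh_max + 1), range(de_max + 1), range(ox_max + 1)
        )
    ]
    out.sort(key=lambda v: v.mz)
    return out


def match_mass(
    observed: float,
    theoretical: float,
    tol_value: float = 0.2,
    tol_unit: str = "Da",
) -> tuple[bool, float]:
    """Tolerance test between an observed and a theoretical m/z.

    Returns ``(matched, delta)`` with ``delta = observed - theoretical``
    (signed). In ppm mode the tolerance is converted at the theoretical mass.
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    if tol_value <= 0:
        raise ValueError("tolerance must be positive")
    if tol_unit == "Da":
        tol = tol_value
    elif tol_unit == "ppm":
        tol = tol_value * 1e-6 * theoretical
    else:
        raise ValueError(f"unknown tolerance unit {tol_unit!r}")
    delta = observed - theoretical
    return abs(delta) <= tol, delta


def masses_of(variants: Iterable[MassVariant]) -> list[float]:
    """Convenience: the m/z values of an iterable of variants."""
    return [v.mz for v in variants]
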