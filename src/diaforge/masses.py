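"""Monoisotopic mass arithmetic for peptides and y/b fragment ions.

Residue masses are the standard monoisotopic values shipped with
:mod:`pyteomics`; all peptide and fragment m/z values are computed from them
with the usual proton/water constants.  Only singly- and doubly-charged y and b
ions are needed anywhere in this package, but the functions accept any positive
charge.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

PROTON = 1.007276
WATER = 18.010565

#: Monoisotopic residue (amino-acid minus water) masses, standard 20 letters.
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Modification mass deltas by canonical short name (UniMod monoisotopic).
MOD_DELTA: dict[str, float] = {
    "Carbamidomethyl": 57.02146,
    "Oxidation": 15.99491,
    "Phospho": 79.96633,
    "Acetyl": 42.01057,
    "Hydroxylation": 15.99491,
}


class MassError(ValueError):
    """Raised for unknown residues or out-of-range fragment ordinals."""


def _residue_sum(sequence: str) -> float:
    total = 0.0
    for aa in sequence:
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise MassError(f"unknown residue {aa!r} in {sequence!r}") from None
    return total


def neutral_mass(sequence: str, mod_deltas: dict[int, float] | None = None) -> float:
    """Neutral monoisotopic peptide mass (residues + water + modification deltas).

    ``mod_deltas`` maps 1-based residue positions to mass deltas.
    """
    m = _residue_sum(sequence) + WATER
    if mod_deltas:
        for pos, delta in mod_deltas.items():
            if not 1 <= pos <= len(sequence):
                raise MassError(
                    f"modification position {pos} outside sequence of length {len(sequence)}"
                )
            m += delta
    return m


def peptide_mz(sequence: str, charge: int, mod_deltas: dict[int, float] | None = None) -> float:
    """Precursor m/z: (neutral mass + charge protons) / charge."""
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    return (neutral_mass(sequence, mod_deltas) + charge * PROTON) / charge


def fragment_mz(
    sequence: str,
    fragment_type: str,
    ordinal: int,
    charge: int,
    mod_deltas: dict[int, float] | None = None,
) -> float:
    """m/z of a y- or b-ion of the given series ordinal and charge.

    y_k covers the k C-terminal residues (plus water); b_k covers the k
    N-terminal residues.  Modification deltas are applied only to residues the
    fragment covers.
    """
    n = len(sequence)
    if not 1 <= ordinal <= n - 1:
        raise MassError(f"ordinal {ordinal} out of range for length-{n} peptide")
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    if fragment_type == "y":
        covered = range(n - ordinal + 1, n + 1)
        m = _residue_sum(sequence[n - ordinal:]) + WATER
    elif fragment_type == "b":
        covered = range(1, ordinal + 1)
        m = _residue_sum(sequence[:ordinal])
    else:
        raise MassError(f"fragment type must be 'y' or 'b', got {fragment_type!r}")
    if mod_deltas:
        for pos, delta in mod_deltas.items():
            if pos in covered:
                m += delta
    return (m + charge * PROTON) / charge
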