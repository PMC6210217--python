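"""Shared domain types of the DIA assay-library pipeline.

The central container is :class:`AssayLibrary`, a validated
protein → peptide → precursor → transition hierarchy stored flat as a list of
precursors (each carrying its peptide and transitions).  A *transition* is a
(precursor, fragment-ion) m/z pair monitored for quantitation; an *assay
library* is the filtered target list used for extraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from . import masses
from .masses import MassError  # noqa: F401  (re-exported convenience)

MZ_TOL = 1e-4  # Th; agreement required between stored and recomputed m/z

ALLOWED_PRECURSOR_CHARGES = (1, 2, 3, 4)
ALLOWED_FRAGMENT_CHARGES = (1, 2)


class ValidationError(ValueError):
    """An invariant of a domain object is violated; message names the rule."""


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


# ---------------------------------------------------------------------------
# modifications


@dataclass(frozen=True)
class Modification:
    """A residue modification: 1-based position, canonical kind, mass delta."""

    position: int
    kind: str  # "Oxidation", "Carbamidomethyl" or "other:<name>"
    delta: float

    @staticmethod
    def oxidation(position: int) -> "Modification":
        return Modification(position, "Oxidation", masses.MOD_DELTA["Oxidation"])

    @staticmethod
    def carbamidomethyl(position: int) -> "Modification":
        return Modification(position, "Carbamidomethyl", masses.MOD_DELTA["Carbamidomethyl"])

    @staticmethod
    def other(position: int, name: str, delta: float) -> "Modification":
        return Modification(position, f"other:{name}", delta)


_MOD_RE = re.compile(r"\[([+-]\d+(?:\.\d+)?)\]")


def format_modified_sequence(sequence: str, modifications: list[Modification]) -> str:
    """Bracket notation, e.g. ``PEPC[+57.02146]K`` (deltas at 5 decimals)."""
    by_pos = {m.position: m for m in modifications}
    out = []
    for i, aa in enumerate(sequence, start=1):
        out.append(aa)
        if i in by_pos:
            out.append(f"[{by_pos[i].delta:+.5f}]")
    return "".join(out)


def parse_modified_sequence(modseq: str) -> tuple[str, list[Modification]]:
    """Invert :func:`format_modified_sequence`.

    Deltas matching oxidation on M or carbamidomethylation on C are mapped to
    their canonical kinds; any other delta becomes ``other:<delta>``.
    """
    sequence = []
    mods: list[Modification] = []
    i = 0
    while i < len(modseq):
        ch = modseq[i]
        if ch == "[":
            m = _MOD_RE.match(modseq, i)
            if m is None or not sequence:
                raise FormatError(f"malformed modified sequence {modseq!r}")
            delta = float(m.group(1))
            pos = len(sequence)
            aa = sequence[-1]
            if abs(delta - masses.MOD_DELTA["Oxidation"]) < 1e-3 and aa == "M":
                mods.append(Modification.oxidation(pos))
            elif abs(delta - masses.MOD_DELTA["Carbamidomethyl"]) < 1e-3 and aa == "C":
                mods.append(Modification.carbamidomethyl(pos))
            else:
                mods.append(Modification.other(pos, m.group(1), delta))
            i = m.end()
        else:
            sequence.append(ch)
            i += 1
    return "".join(sequence), mods


def count_missed_cleavages(sequence: str) -> int:
    """Internal K/R not followed by P (tryptic rule), C-terminus excluded."""
    return sum(
        1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    )


# ---------------------------------------------------------------------------
# hierarchy


@dataclass
class Peptide:
    sequence: str
    modifications: list[Modification] = field(default_factory=list)
    missed_cleavages: int = 0
    irt: float = 0.0
    protein_ids: list[str] = field(default_factory=list)

    @property
    def modified_sequence(self) -> str:
        return format_modified_sequence(self.sequence, self.modifications)

    def mod_deltas(self) -> dict[int, float]:
        return {m.position: m.delta for m in self.modifications}

    def has_disallowed_modification(self) -> bool:
        """True if any modification is neither Met-oxidation nor Cys-CAM."""
        return any(m.kind not in ("Oxidation", "Carbamidomethyl") for m in self.modifications)

    def validate(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError("peptide sequence must be nonempty")
        for aa in self.sequence:
            if aa not in masses.RESIDUE_MASS:
                raise ValidationError(f"non-standard residue {aa!r} in {self.sequence!r}")
        for m in self.modifications:
            if not 1 <= m.position <= len(self.sequence):
                raise ValidationError(
                    f"modification position {m.position} outside {self.sequence!r}"
                )
            aa = self.sequence[m.position - 1]
            if m.kind == "Oxidation" and aa != "M":
                raise ValidationError("Met-oxidation only on M")
            if m.kind == "Carbamidomethyl" and aa != "C":
                raise ValidationError("Cys-carbamidomethyl only on C")
        if self.missed_cleavages < 0:
            raise ValidationError("missed_cleavages must be non-negative")
        derived = count_missed_cleavages(self.sequence)
        if derived != self.missed_cleavages:
            raise ValidationError(
                f"stored missed_cleavages {self.missed_cleavages} disagrees with "
                f"cleavage rule ({derived}) for {self.sequence!r}"
            )


@dataclass
class Transition:
    fragment_type: str  # "y" or "b"
    ordinal: int
    fragment_charge: int
    mz: float
    library_intensity: float

    @property
    def label(self) -> str:
        return f"{self.fragment_type}{self.ordinal}^{self.fragment_charge}"


@dataclass
class Precursor:
    peptide: Peptide
    charge: int
    mz: float
    decoy: bool = False
    transitions: list[Transition] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, bool]:
        return (self.peptide.modified_sequence, self.charge, self.decoy)

    @property
    def key_str(self) -> str:
        prefix = "DECOY_" if self.decoy else ""
        return f"{prefix}{self.peptide.modified_sequence}/{self.charge}"

    def validate(self) -> None:
        self.peptide.validate()
        if self.charge not in ALLOWED_PRECURSOR_CHARGES:
            raise ValidationError(f"precursor charge 1-4 violated: charge {self.charge}")
        if self.mz <= 0:
            raise ValidationError("precursor m/z must be positive")
        expected = masses.peptide_mz(self.peptide.sequence, self.charge, self.peptide.mod_deltas())
        if abs(self.mz - expected) > MZ_TOL:
            raise ValidationError(
                f"precursor m/z {self.mz:.5f} inconsistent with sequence mass "
                f"({expected:.5f}) for {self.key_str}"
            )
        n = len(self.peptide.sequence)
        for t in self.transitions:
            if t.fragment_type not in ("y", "b"):
                raise ValidationError(f"fragment type must be y or b, got {t.fragment_type!r}")
            if t.fragment_charge not in ALLOWED_FRAGMENT_CHARGES:
                raise ValidationError(f"fragment charge 1-2 violated: charge {t.fragment_charge}")
            if not 3 <= t.ordinal <= n - 1:
                raise ValidationError(
                    f"fragment ordinal must lie in [3, {n - 1}] (ion 3 to last ion -1), "
                    f"got {t.label} for {self.key_str}"
                )
            if t.library_intensity < 0:
                raise ValidationError("library intensity must be non-negative")


@dataclass
class LibrarySpectrum:
    """An annotated MSMS spectrum backing transition selection."""

    peptide: Peptide
    precursor_charge: int
    peaks: list[tuple[float, float, str | None]]  # (mz, intensity, annotation)
    source_rt: float = 0.0

    def validate(self) -> None:
        self.peptide.validate()
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            raise ValidationError("spectrum peaks must be sorted by m/z")
        if any(p[1] < 0 for p in self.peaks):
            raise ValidationError("spectrum intensities must be non-negative")


@dataclass(frozen=True)
class Census:
    n_proteins: int
    n_peptides: int
    n_precursors: int
    n_transitions: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_proteins, self.n_peptides, self.n_precursors, self.n_transitions)

    def __sub__(self, other: "Census") -> "Census":
        return Census(
            self.n_proteins - other.n_proteins,
            self.n_peptides - other.n_peptides,
            self.n_precursors - other.n_precursors,
            self.n_transitions - other.n_transitions,
        )


@dataclass
class AssayLibrary:
    """Flat store of precursors with the protein→…→transition hierarchy implied."""

    precursors: list[Precursor] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def targets(self) -> "AssayLibrary":
        return AssayLibrary([p for p in self.precursors if not p.decoy], list(self.provenance))

    def decoys(self) -> "AssayLibrary":
        return AssayLibrary([p for p in self.precursors if p.decoy], list(self.provenance))

    def validate(self) -> None:
        seen: set[tuple[str, int, bool]] = set()
        for prec in self.precursors:
            prec.validate()
            if prec.key in seen:
                raise ValidationError(f"duplicate precursor {prec.key_str}")
            seen.add(prec.key)

    def copy(self) -> "AssayLibrary":
        precs = []
        for p in self.precursors:
            precs.append(
                replace(
                    p,
                    peptide=replace(
                        p.peptide,
                        modifications=list(p.peptide.modifications),
                        protein_ids=list(p.peptide.protein_ids),
                    ),
                    transitions=[replace(t) for t in p.transitions],
                )
            )
        return AssayLibrary(precs, list(self.provenance))


def census(lib: AssayLibrary) -> Census:
    """Exact distinct counts at all four hierarchy levels."""
    proteins: set[str] = set()
    peptides: set[str] = set()
    n_trans = 0
    for p in lib.precursors:
        prefix = "DECOY_" if p.decoy else ""
        proteins.update(prefix + pid for pid in p.peptide.protein_ids)
        peptides.add(prefix + p.peptide.modified_sequence)
        n_trans += len(p.transitions)
    return Census(len(proteins), len(peptides), len(lib.precursors), n_trans)


# ---------------------------------------------------------------------------
# sample annotation


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    population: str
    sampling_batch: str
    replicate_index: int


def validate_annotations(annot: list[SampleAnnotation]) -> None:
    keys = [(a.population, a.sampling_batch, a.replicate_index) for a in annot]
    if len(set(keys)) != len(keys):
        raise ValidationError("(population, sampling_batch, replicate_index) must be unique")
    ids = [a.sample_id for a in annot]
    if len(set(ids)) != len(ids):
        raise ValidationError("sample_id must be unique")
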