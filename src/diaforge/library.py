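"""In-silico digestion, initial target-list construction, and decoy generation.

Transition selection mirrors the standard library-driven rules: for each
(peptide, charge) the ``top_n`` most intense library-spectrum peaks matching a
theoretical y/b fragment within a tight m/z tolerance are kept, subject to
ordinal bounds (ion 3 to last ion − 1), fragment charge 1–2, and exclusion of
the precursor isolation window.  Decoys are seeded sequence shuffles with the
C-terminal residue fixed, preserving tryptic character and the precursor-mass
distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import masses
from .core import (
    AssayLibrary,
    LibrarySpectrum,
    Peptide,
    Precursor,
    Transition,
    ValidationError,
    count_missed_cleavages,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DigestRule:
    """Tryptic cleavage: after K/R unless followed by P; up to ``max_missed``."""

    cleave_after: frozenset = frozenset("KR")
    suppress_before: frozenset = frozenset("P")
    max_missed: int = 2

    def __post_init__(self):
        if self.max_missed < 0:
            raise ValidationError("max_missed must be >= 0")


@dataclass
class TransitionSettings:
    min_ordinal: int = 3
    max_ordinal_offset: int = 1  # last ion - offset
    fragment_charges: tuple[int, ...] = (1, 2)
    precursor_charges: tuple[int, ...] = (1, 2, 3, 4)
    top_n: int = 5
    mz_match_tol: float = 0.035  # Th
    precursor_exclusion_width: float = 10.0  # Th, full width

    def __post_init__(self):
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.mz_match_tol <= 0 or self.precursor_exclusion_width <= 0:
            raise ValidationError("tolerances must be positive")


def cleavage_sites(sequence: str, rule: DigestRule) -> list[int]:
    """0-based indices i such that the bond after residue i is cleaved."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in rule.cleave_after and sequence[i + 1] not in rule.suppress_before
    ]


def digest_protein(sequence: str, rule: DigestRule | None = None) -> list[Peptide]:
    """All tryptic peptides with 0..max_missed missed cleavages, in N→C order."""
    rule = rule or DigestRule()
    if not sequence:
        raise ValidationError("protein sequence must be nonempty")
    for aa in sequence:
        if aa not in masses.RESIDUE_MASS:
            raise ValidationError(f"non-standard residue {aa!r} in protein sequence")
    sites = cleavage_sites(sequence, rule)
    # Segment boundaries: start indices of fully-cleaved peptides.
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(sequence)]
    peptides = []
    n_seg = len(starts)
    for i in range(n_seg):
        for missed in range(rule.max_missed + 1):
            j = i + missed
            if j >= n_seg:
                break
            sub = sequence[starts[i]:ends[j]]
            peptides.append(
                Peptide(sequence=sub, missed_cleavages=count_missed_cleavages(sub))
            )
    return peptides


def _theoretical_fragments(pep: Peptide, settings: TransitionSettings):
    """Enumerate (type, ordinal, charge, mz) obeying ordinal/charge bounds."""
    n = len(pep.sequence)
    deltas = pep.mod_deltas()
    out = []
    hi = n - settings.max_ordinal_offset
    for ftype in ("y", "b"):
        for ordinal in range(settings.min_ordinal, hi + 1):
            if ordinal > n - 1:
                continue
            for z in settings.fragment_charges:
                out.append(
                    (ftype, ordinal, z, masses.fragment_mz(pep.sequence, ftype, ordinal, z, deltas))
                )
    return out


def select_transitions(
    spectrum: LibrarySpectrum, settings: TransitionSettings | None = None
) -> Precursor | None:
    """Pick the top-N transitions of one library spectrum (None if no peaks)."""
    settings = settings or TransitionSettings()
    if not spectrum.peaks:
        logger.warning(
            "empty spectrum for %s/%d skipped",
            spectrum.peptide.modified_sequence,
            spectrum.precursor_charge,
        )
        return None
    pep = spectrum.peptide
    z = spectrum.precursor_charge
    prec_mz = masses.peptide_mz(pep.sequence, z, pep.mod_deltas())
    half_window = settings.precursor_exclusion_width / 2.0
    frags = _theoretical_fragments(pep, settings)

    # Greedy matching: smallest |dmz| first, each peak and each fragment used once.
    candidates = []
    for pi, (pmz, inten, _ann) in enumerate(spectrum.peaks):
        for fi, (ftype, ordinal, fz, fmz) in enumerate(frags):
            d = abs(pmz - fmz)
            if d <= settings.mz_match_tol:
                candidates.append((d, pi, fi))
    candidates.sort()
    used_peaks: set[int] = set()
    used_frags: set[int] = set()
    matched: list[tuple[float, float, tuple]] = []  # (intensity, fmz, frag)
    for d, pi, fi in candidates:
        if pi in used_peaks or fi in used_frags:
            continue
        used_peaks.add(pi)
        used_frags.add(fi)
        ftype, ordinal, fz, fmz = frags[fi]
        if abs(fmz - prec_mz) <= half_window:
            continue  # inside precursor isolation window
        matched.append((spectrum.peaks[pi][1], fmz, frags[fi]))

    # Top-N by intensity; ties by lower fragment m/z, then y before b.
    matched.sort(key=lambda m: (-m[0], m[1], 0 if m[2][0] == "y" else 1))
    chosen = matched[: settings.top_n]
    if not chosen:
        return None
    transitions = [
        Transition(
            fragment_type=f[0], ordinal=f[1], fragment_charge=f[2], mz=fmz, library_intensity=inten
        )
        for inten, fmz, f in chosen
    ]
    return Precursor(peptide=pep, charge=z, mz=prec_mz, decoy=False, transitions=transitions)


def build_initial_target_list(
    spectra: list[LibrarySpectrum], settings: TransitionSettings | None = None
) -> AssayLibrary:
    """Initial target list from library spectra (before any filtering)."""
    settings = settings or TransitionSettings()
    precursors = []
    seen = set()
    for spec in spectra:
        if spec.precursor_charge not in settings.precursor_charges:
            continue
        prec = select_transitions(spec, settings)
        if prec is not None and prec.key not in seen:
            seen.add(prec.key)
            precursors.append(prec)
    return AssayLibrary(precursors, provenance=["initial"])


# ---------------------------------------------------------------------------
# decoys


def _shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle all but the C-terminal residue."""
    core = list(sequence[:-1])
    rng.shuffle(core)
    return "".join(core) + sequence[-1]


def _positional_swap(sequence: str, offset: int = 8) -> str:
    """Deterministic fallback: rotate the non-terminal residues by ``offset``."""
    core = sequence[:-1]
    k = offset % max(1, len(core))
    return core[k:] + core[:k] + sequence[-1]


def generate_decoys(lib: AssayLibrary, seed: int, max_retries: int = 20) -> AssayLibrary:
    """One scrambled decoy peptide per target peptide (equal in number).

    Decoy fragment m/z are recomputed from the scrambled sequence; library
    intensities are copied from the target so decoys inherit the target
    intensity distribution.  Sequences colliding with any target (or another
    decoy) are reshuffled up to ``max_retries`` times, then fall back to a
    positional +8 residue rotation.
    """
    if not lib.precursors:
        raise ValidationError("cannot generate decoys for an empty library")
    rng = np.random.default_rng(seed)
    target_seqs = {p.peptide.sequence for p in lib.precursors}
    taken = set(target_seqs)
    decoy_by_pepseq: dict[str, str] = {}
    decoys = []
    for prec in lib.precursors:
        if prec.decoy:
            continue
        seq = prec.peptide.sequence
        if len(seq) <= 2:
            warnings.warn(f"peptide {seq!r} too short to scramble; decoy skipped")
            continue
        if seq in decoy_by_pepseq:  # same peptide at another charge
            dseq = decoy_by_pepseq[seq]
        else:
            dseq = None
            for _ in range(max_retries):
                cand = _shuffle_sequence(seq, rng)
                if cand not in taken and cand != seq:
                    dseq = cand
                    break
            if dseq is None:
                cand = _positional_swap(seq)
                if cand in taken or cand == seq:
                    warnings.warn(f"no collision-free decoy for {seq!r}; skipped")
                    continue
                dseq = cand
            taken.add(dseq)
            decoy_by_pepseq[seq] = dseq
        # Modifications follow their residue where possible: keep positions whose
        # residue in the decoy still matches the required target residue.
        dmods = []
        for m in prec.peptide.modifications:
            aa_needed = {"Oxidation": "M", "Carbamidomethyl": "C"}.get(m.kind)
            if aa_needed is None or dseq[m.position - 1] == aa_needed:
                dmods.append(m)
            else:
                pos = dseq.find(aa_needed)
                if pos >= 0:
                    dmods.append(type(m)(pos + 1, m.kind, m.delta))
        dpep = Peptide(
            sequence=dseq,
            modifications=dmods,
            missed_cleavages=count_missed_cleavages(dseq),
            irt=prec.peptide.irt,
            protein_ids=["DECOY_" + pid for pid in prec.peptide.protein_ids],
        )
        deltas = dpep.mod_deltas()
        dtrans = []
        n = len(dseq)
        for t in prec.transitions:
            if not 1 <= t.ordinal <= n - 1:
                continue
            dtrans.append(
                Transition(
                    fragment_type=t.fragment_type,
                    ordinal=t.ordinal,
                    fragment_charge=t.fragment_charge,
                    mz=masses.fragment_mz(dseq, t.fragment_type, t.ordinal, t.fragment_charge, deltas),
                    library_intensity=t.library_intensity,
                )
            )
        decoys.append(
            Precursor(
                peptide=dpep,
                charge=prec.charge,
                mz=masses.peptide_mz(dseq, prec.charge, deltas),
                decoy=True,
                transitions=dtrans,
            )
        )
    return AssayLibrary(decoys, provenance=list(lib.provenance) + ["decoys"])
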