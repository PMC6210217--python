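"""Tab-separated I/O for transition lists, spectral libraries and annotations.

The transition-list dialect follows OpenSWATH-style headers (one row per
transition); shared peptides carry their protein accessions joined by ``;`` in
the ProteinId column.  All files are UTF-8, tab-delimited, ``.`` decimal
separator, m/z serialized at 5 decimals, so that write∘read∘write is
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import (
    AssayLibrary,
    Census,  # noqa: F401
    FormatError,
    LibrarySpectrum,
    Peptide,
    Precursor,
    SampleAnnotation,
    Transition,
    ValidationError,
    count_missed_cleavages,
    parse_modified_sequence,
)

TRANSITION_COLUMNS = [
    "ProteinId",
    "PeptideSequence",
    "ModifiedPeptideSequence",
    "PrecursorMz",
    "PrecursorCharge",
    "ProductMz",
    "FragmentType",
    "FragmentSeriesNumber",
    "FragmentCharge",
    "LibraryIntensity",
    "NormalizedRetentionTime",
    "Decoy",
]

ANNOTATION_COLUMNS = ["sample_id", "population", "sampling_batch", "replicate"]

SPECTRUM_COLUMNS = ["peptide", "charge", "mz", "intensity", "annotation", "source_rt"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")


def read_transition_list(path) -> AssayLibrary:
    """Parse a transition-list TSV into a validated :class:`AssayLibrary`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, TRANSITION_COLUMNS, path)
    precursors: dict[tuple[str, int, bool], Precursor] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            charge = int(row.PrecursorCharge)
        except ValueError:
            raise FormatError(f"row {row_no}: non-integer PrecursorCharge") from None
        if charge not in (1, 2, 3, 4):
            raise ValidationError(
                f"row {row_no}: precursor charge 1-4 violated (charge {charge})"
            )
        decoy = str(row.Decoy) in ("1", "True", "true")
        key = (row.ModifiedPeptideSequence, charge, decoy)
        if key not in precursors:
            sequence, mods = parse_modified_sequence(row.ModifiedPeptideSequence)
            if sequence != row.PeptideSequence:
                raise FormatError(
                    f"row {row_no}: ModifiedPeptideSequence does not match PeptideSequence"
                )
            pep = Peptide(
                sequence=sequence,
                modifications=mods,
                missed_cleavages=count_missed_cleavages(sequence),
                irt=float(row.NormalizedRetentionTime),
                protein_ids=row.ProteinId.split(";"),
            )
            precursors[key] = Precursor(
                peptide=pep, charge=charge, mz=float(row.PrecursorMz), decoy=decoy
            )
        precursors[key].transitions.append(
            Transition(
                fragment_type=row.FragmentType,
                ordinal=int(row.FragmentSeriesNumber),
                fragment_charge=int(row.FragmentCharge),
                mz=float(row.ProductMz),
                library_intensity=float(row.LibraryIntensity),
            )
        )
    lib = AssayLibrary(list(precursors.values()))
    lib.validate()
    return lib


def write_transition_list(lib: AssayLibrary, path) -> None:
    """Write a transition list in deterministic row order.

    Rows sort by (protein id, peptide sequence, precursor m/z, product m/z).
    """
    rows = []
    for prec in lib.precursors:
        protein_id = ";".join(prec.peptide.protein_ids)
        for t in prec.transitions:
            rows.append(
                (
                    protein_id,
                    prec.peptide.sequence,
                    prec.peptide.modified_sequence,
                    f"{prec.mz:.5f}",
                    prec.charge,
                    f"{t.mz:.5f}",
                    t.fragment_type,
                    t.ordinal,
                    t.fragment_charge,
                    f"{t.library_intensity:g}",
                    f"{prec.peptide.irt:g}",
                    int(prec.decoy),
                )
            )
    rows.sort(key=lambda r: (r[0], r[1], float(r[3]), float(r[5]), r[6], r[8]))
    df = pd.DataFrame(rows, columns=TRANSITION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    return [
        SampleAnnotation(
            sample_id=r.sample_id,
            population=r.population,
            sampling_batch=r.sampling_batch,
            replicate_index=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def write_annotations(annot: list[SampleAnnotation], path) -> None:
    df = pd.DataFrame(
        [(a.sample_id, a.population, a.sampling_batch, a.replicate_index) for a in annot],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_spectral_library(path) -> list[LibrarySpectrum]:
    """Long-format spectral library: one peak per row, grouped by (peptide, charge)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, SPECTRUM_COLUMNS, path)
    spectra: dict[tuple[str, int], LibrarySpectrum] = {}
    for row in df.itertuples(index=False):
        key = (row.peptide, int(row.charge))
        if key not in spectra:
            sequence, mods = parse_modified_sequence(row.peptide)
            pep = Peptide(
                sequence=sequence,
                modifications=mods,
                missed_cleavages=count_missed_cleavages(sequence),
            )
            spectra[key] = LibrarySpectrum(
                peptide=pep,
                precursor_charge=int(row.charge),
                peaks=[],
                source_rt=float(row.source_rt),
            )
        ann = row.annotation if row.annotation else None
        spectra[key].peaks.append((float(row.mz), float(row.intensity), ann))
    out = []
    for spec in spectra.values():
        spec.peaks.sort(key=lambda p: p[0])
        spec.validate()
        out.append(spec)
    return out


def write_spectral_library(spectra: list[LibrarySpectrum], path: str | Path) -> None:
    rows = []
    for spec in spectra:
        for mz, intensity, ann in spec.peaks:
            rows.append(
                (
                    spec.peptide.modified_sequence,
                    spec.precursor_charge,
                    f"{mz:.5f}",
                    f"{intensity:g}",
                    ann or "",
                    f"{spec.source_rt:g}",
                )
            )
    pd.DataFrame(rows, columns=SPECTRUM_COLUMNS).to_csv(path, sep="\t", index=False)
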