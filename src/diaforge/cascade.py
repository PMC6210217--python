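"""The seven-step reduction of an initial target list to a curated assay library.

Steps 1–4 are static peptide/precursor rules (allowed PTMs, peptide uniqueness,
≥4 transitions, no missed cleavages).  Steps 5–7 consult a training sample set:
step 5 drops peptides whose dotp stays below threshold in every training
sample, step 6 drops proteins with fewer than two remaining peptides, and step
7 codifies the manual peak-shape curation rules (interference, detectability,
peak-width consistency) with per-population sample aggregation.  After the
curation rules the ≥4-transition and ≥2-peptide constraints are re-applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AssayLibrary, Census, SampleAnnotation, ValidationError, census
from .extract import ChromatogramSet, detect_peak_groups


@dataclass
class CurationSettings:
    rt_window: float = 3.0  # minutes around predicted RT
    detect_min_sn: float = 3.0  # "clearly discernable" operationalized
    width_ratio_max: float = 2.0
    max_interfered_transitions: int = 1
    population_fraction: float = 0.5

    def __post_init__(self):
        for name in ("rt_window", "detect_min_sn", "width_ratio_max", "population_fraction"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class FilterReport:
    """Per-step census accounting; step 0 is the initial library."""

    rows: list[tuple[int, str, Census]] = field(default_factory=list)

    def record(self, step_id: int, label: str, c: Census) -> None:
        self.rows.append((step_id, label, c))

    def to_frame(self) -> pd.DataFrame:
        recs = []
        prev: Census | None = None
        for step_id, label, c in self.rows:
            removed = (prev - c) if prev is not None else Census(0, 0, 0, 0)
            recs.append(
                {
                    "step": step_id,
                    "label": label,
                    "proteins": c.n_proteins,
                    "peptides": c.n_peptides,
                    "precursors": c.n_precursors,
                    "transitions": c.n_transitions,
                    "removed_proteins": removed.n_proteins,
                    "removed_peptides": removed.n_peptides,
                    "removed_precursors": removed.n_precursors,
                    "removed_transitions": removed.n_transitions,
                }
            )
            prev = c
        return pd.DataFrame(recs)


def _prune(lib: AssayLibrary) -> AssayLibrary:
    """Drop precursors with no transitions (orphan cleanup)."""
    lib.precursors = [p for p in lib.precursors if p.transitions]
    return lib


def apply_static_filter(lib: AssayLibrary, step: int) -> AssayLibrary:
    """Steps 1–4 on a copy of the library.

    1: drop peptides with any modification other than Met-oxidation or
       Cys-carbamidomethylation; 2: drop repeated peptides (same plain
       sequence occurring more than once) and peptides shared by >1 protein;
       3: drop precursors with <4 transitions; 4: drop peptides with missed
       cleavages.
    """
    out = lib.copy()
    if step == 1:
        out.precursors = [
            p for p in out.precursors if not p.peptide.has_disallowed_modification()
        ]
    elif step == 2:
        seq_counts: dict[str, int] = {}
        for p in out.precursors:
            seq_counts[p.peptide.sequence] = seq_counts.get(p.peptide.sequence, 0) + 1
        out.precursors = [
            p
            for p in out.precursors
            if seq_counts[p.peptide.sequence] == 1 and len(p.peptide.protein_ids) == 1
        ]
    elif step == 3:
        out.precursors = [p for p in out.precursors if len(p.transitions) >= 4]
    elif step == 4:
        out.precursors = [p for p in out.precursors if p.peptide.missed_cleavages == 0]
    else:
        raise ValidationError(f"static filter step must be 1-4, got {step}")
    out.provenance.append(f"step{step}")
    return _prune(out)


def dotp_filter(
    lib: AssayLibrary, dotp_table: pd.DataFrame, threshold: float = 0.8
) -> AssayLibrary:
    """Step 5: drop peptides with dotp below threshold in EVERY training sample.

    ``dotp_table`` is precursor-key × sample; one sample at or above threshold
    keeps the peptide.
    """
    out = lib.copy()
    missing = [p.key_str for p in out.precursors if p.key_str not in dotp_table.index]
    if missing:
        raise ValidationError(f"dotp table missing precursors: {missing[:5]}")
    keep = []
    for p in out.precursors:
        vals = dotp_table.loc[p.key_str]
        if vals.isna().any():
            raise ValidationError(f"dotp table has missing samples for {p.key_str}")
        if (vals >= threshold).any():
            keep.append(p)
    out.precursors = keep
    out.provenance.append("step5")
    return out


def protein_min_peptides(lib: AssayLibrary, min_peptides: int = 2) -> AssayLibrary:
    """Step 6: drop proteins represented by fewer than ``min_peptides`` peptides."""
    out = lib.copy()
    pep_by_protein: dict[str, set[str]] = {}
    for p in out.precursors:
        for pid in p.peptide.protein_ids:
            pep_by_protein.setdefault(pid, set()).add(p.peptide.modified_sequence)
    good = {pid for pid, peps in pep_by_protein.items() if len(peps) >= min_peptides}
    out.precursors = [
        p for p in out.precursors if all(pid in good for pid in p.peptide.protein_ids)
    ]
    out.provenance.append("step6")
    return out


# ---------------------------------------------------------------------------
# step 7: codified curation


@dataclass
class PeakObservation:
    """Training-set peak evidence for one precursor in one sample."""

    detected: bool
    sn: float
    fwhm: float
    transition_interfered: np.ndarray  # bool per transition


def collect_peak_data(
    lib: AssayLibrary,
    chroms: ChromatogramSet,
    predicted_rts: dict[tuple[str, str], float],
    settings: CurationSettings | None = None,
) -> dict[tuple[str, str], PeakObservation]:
    """Derive per-(precursor, sample) peak evidence from training chromatograms.

    Detection means the best on-target peak group within the RT window reaches
    the S/N threshold.  A transition is interference-flagged when its trace has
    an off-target maximum (outside the peak boundaries, inside the window)
    exceeding its on-target apex.
    """
    settings = settings or CurationSettings()
    out: dict[tuple[str, str], PeakObservation] = {}
    for prec in lib.precursors:
        key = prec.key_str
        n_trans = len(prec.transitions)
        for sample in chroms.sample_ids:
            if (sample, key) not in chroms:
                raise ValidationError(f"missing peak data for ({key}, {sample})")
            traces = chroms.get(sample, key)
            pred = predicted_rts[(sample, key)]
            groups = detect_peak_groups(traces, pred, rt_window=settings.rt_window)
            if not groups:
                out[(key, sample)] = PeakObservation(
                    detected=False,
                    sn=0.0,
                    fwhm=float("nan"),
                    transition_interfered=np.zeros(n_trans, dtype=bool),
                )
                continue
            best = groups[0]  # ordered by apex intensity
            lo, hi = best.boundaries
            in_window = np.abs(traces.times - pred) <= settings.rt_window
            off_target = in_window & ((traces.times < lo) | (traces.times > hi))
            flags = np.zeros(n_trans, dtype=bool)
            for ti in range(min(n_trans, traces.intensities.shape[0])):
                if off_target.any():
                    interf_max = float(traces.intensities[ti, off_target].max())
                    flags[ti] = interf_max > best.apexes[ti]
            out[(key, sample)] = PeakObservation(
                detected=best.sn >= settings.detect_min_sn,
                sn=best.sn,
                fwhm=best.fwhm,
                transition_interfered=flags,
            )
    return out


def _population_samples(annot: list[SampleAnnotation]) -> dict[str, list[str]]:
    pops: dict[str, list[str]] = {}
    for a in annot:
        pops.setdefault(a.population, []).append(a.sample_id)
    return pops


def automated_curation(
    lib: AssayLibrary,
    peakdata: dict[tuple[str, str], PeakObservation],
    annot: list[SampleAnnotation],
    settings: CurationSettings | None = None,
) -> AssayLibrary:
    """Step 7: the four codified peak-shape curation rules, applied in order.

    1. A transition is removed when it is interference-flagged in at least
       ``population_fraction`` of the samples of any one population.
    2. A precursor is removed when it is undetected in at least half the
       samples of any one population.
    3. A precursor is removed when, within any population, the median FWHM of
       the wider half of samples exceeds ``width_ratio_max`` times the median
       of the narrower half.
    4. A precursor is removed when more than ``max_interfered_transitions`` of
       its transitions are interference-flagged in the same sample, in at
       least ``population_fraction`` of the samples of any population.

    The ≥4-transition and ≥2-peptide constraints are re-applied afterwards.
    """
    settings = settings or CurationSettings()
    out = lib.copy()
    pops = _population_samples(annot)

    for prec in out.precursors:
        for sample in (a.sample_id for a in annot):
            if (prec.key_str, sample) not in peakdata:
                raise ValidationError(f"missing peak data for ({prec.key_str}, {sample})")

    def frac_of_any_population(per_sample_flag: dict[str, bool]) -> bool:
        for samples in pops.values():
            flagged = sum(1 for s in samples if per_sample_flag[s])
            if flagged >= settings.population_fraction * len(samples):
                return True
        return False

    # rule 1: per-transition removal
    for prec in out.precursors:
        n_trans = len(prec.transitions)
        drop = []
        for ti in range(n_trans):
            flag = {
                s: bool(peakdata[(prec.key_str, s)].transition_interfered[ti])
                for a in annot
                for s in [a.sample_id]
            }
            if frac_of_any_population(flag):
                drop.append(ti)
        if drop:
            prec.transitions = [t for i, t in enumerate(prec.transitions) if i not in drop]

    # rule 2: undetected precursors
    keep = []
    for prec in out.precursors:
        flag = {a.sample_id: not peakdata[(prec.key_str, a.sample_id)].detected for a in annot}
        if not frac_of_any_population(flag):
            keep.append(prec)
    out.precursors = keep

    # rule 3: inconsistent peak widths
    keep = []
    for prec in out.precursors:
        bad = False
        for samples in pops.values():
            widths = sorted(
                peakdata[(prec.key_str, s)].fwhm
                for s in samples
                if np.isfinite(peakdata[(prec.key_str, s)].fwhm)
            )
            if len(widths) < 2:
                continue
            half = len(widths) // 2
            narrow = float(np.median(widths[:half]))
            wide = float(np.median(widths[half:] if len(widths) % 2 == 0 else widths[half + 1:]))
            if narrow > 0 and wide > settings.width_ratio_max * narrow:
                bad = True
                break
        if not bad:
            keep.append(prec)
    out.precursors = keep

    # rule 4: multiply-interfered precursors (flags from the original evidence)
    keep = []
    for prec in out.precursors:
        flag = {}
        for a in annot:
            obs = peakdata[(prec.key_str, a.sample_id)]
            flag[a.sample_id] = (
                int(obs.transition_interfered.sum()) > settings.max_interfered_transitions
            )
        if not frac_of_any_population(flag):
            keep.append(prec)
    out.precursors = keep

    out.provenance.append("step7")
    out = _prune(out)
    # re-enforce the structural constraints disturbed by transition removal
    out.precursors = [p for p in out.precursors if len(p.transitions) >= 4]
    out = protein_min_peptides(out, 2)
    out.provenance = out.provenance[:-1]  # step6 re-application is part of step 7
    return out


@dataclass
class TrainingData:
    """Scored training-set evidence consumed by steps 5 and 7."""

    dotp_table: pd.DataFrame  # precursor-key × sample
    peakdata: dict[tuple[str, str], PeakObservation]


def run_cascade(
    initial: AssayLibrary,
    training: TrainingData,
    annot: list[SampleAnnotation],
    settings: CurationSettings | None = None,
    dotp_threshold: float = 0.8,
) -> tuple[AssayLibrary, FilterReport]:
    """Apply steps 1–7 in order, recording the census after every step."""
    settings = settings or CurationSettings()
    report = FilterReport()
    report.record(0, "initial", census(initial))
    lib = initial
    for step in (1, 2, 3, 4):
        lib = apply_static_filter(lib, step)
        report.record(step, f"step{step}", census(lib))
    lib = dotp_filter(lib, training.dotp_table, dotp_threshold)
    report.record(5, "step5", census(lib))
    lib = protein_min_peptides(lib, 2)
    report.record(6, "step6", census(lib))
    lib = automated_curation(lib, training.peakdata, annot, settings)
    report.record(7, "step7", census(lib))
    return lib, report
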