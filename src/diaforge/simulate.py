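"""Ground-truth DIA experiment simulator emulating the study design.

The default configuration emulates the emulated field study: 4 populations ×
6 biological replicates × 4 sampling batches, log-normal protein abundances
with designated population-specific fold changes, per-peptide Dirichlet
fragment-intensity profiles, per-sample linear iRT→RT maps with jitter,
Gaussian chromatographic peaks with log-normal width variation, Poisson
baseline, multiplicative intensity noise, and injected interference peaks.
Sixteen iRT standard peptides are spiked, noise-bright, into every sample.

Everything is reproducible from the mandatory seed; all random streams are
children of one :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import masses
from .core import (
    AssayLibrary,
    Census,
    Modification,
    Peptide,
    Precursor,
    SampleAnnotation,
    Transition,
    ValidationError,
    count_missed_cleavages,
)
from .extract import ChromatogramSet, PrecursorTraces
from .library import DigestRule, digest_protein

DEFAULT_POPULATIONS = ("LaBoRo", "LakSol", "WesLag", "BodHar")

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # fwhm = GAUSS_FWHM * sigma


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulator (all units stated)."""

    seed: int  # mandatory
    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (2, 3)
    n_populations: int = 4
    replicates: int = 6
    batches: int = 4
    frac_differential: float = 0.10  # per population, disjoint protein sets
    log2fc_effect: float = 1.5
    abundance_mu: float = 14.0  # log2 counts·min across proteins
    abundance_sigma: float = 1.5
    bio_cv: float = 0.30  # biological replicate coefficient of variation
    peptide_response_sigma: float = 0.3  # ln-scale spread of peptide ionization
    fragment_dirichlet: float = 1.0
    transitions_per_precursor: int = 5
    rt_slope_range: tuple[float, float] = (0.7, 1.3)  # min per iRT unit
    rt_intercept_range: tuple[float, float] = (0.0, 20.0)  # minutes
    rt_jitter_sd: float = 0.1  # minutes, per peptide × sample
    peak_fwhm: float = 0.3  # minutes, log-normal median
    fwhm_sigma: float = 0.25  # ln-scale width variation
    baseline: float = 15.0  # Poisson baseline counts
    noise_sigma: float = 0.15  # ln-scale multiplicative noise per precursor×sample
    transition_noise_sigma: float = 0.05  # extra per-transition noise
    interference_rate: float = 0.03  # per (target precursor, sample)
    interference_multiplier: float = 0.5  # amplitude relative to transition peak
    frac_signal_free: float = 0.05  # fraction of target peptides without signal
    mz_jitter_ppm: float = 8.0
    grid_dt: float = 0.1  # minutes between chromatogram points
    grid_half_width: float = 4.0  # minutes around the mapped RT
    n_irt_standards: int = 16

    def __post_init__(self):
        for name in ("frac_differential", "frac_signal_free"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("abundance_sigma", "bio_cv", "fwhm_sigma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


@dataclass
class GroundTruth:
    """Everything the simulator decided, for use as test oracle."""

    base_log2_abundance: dict[str, float]  # protein -> log2
    true_log2_abundance: dict[tuple[str, str], float]  # (protein, sample) -> log2
    differential: dict[str, dict[str, float]]  # population -> protein -> log2fc
    signal_free: set  # precursor keys without planted signal
    interference: list  # (precursor_key, sample, transition_idx, rt, amplitude_mult)
    rt_maps: dict[str, tuple[float, float]]  # sample -> (slope, intercept)
    peptide_response: dict[str, float]  # modified sequence -> relative response
    fragment_profiles: dict[str, np.ndarray]  # precursor key -> fractions
    irt_standards: list  # (key, irt)
    annotations: list = field(default_factory=list)

    def differential_proteins(self, population: str) -> dict[str, float]:
        return self.differential.get(population, {})


def _random_protein_sequence(rng: np.random.Generator, n_peptides: int) -> str:
    """Random sequence with K/R every 6–15 residues so digestion is productive."""
    non_kr = np.array(list("ACDEFGHILMNQSTVWY"))  # no K/R/P to keep cleavage clean
    parts = []
    for _ in range(n_peptides + 1):
        seg_len = int(rng.integers(6, 16))
        seg = "".join(rng.choice(non_kr, size=seg_len))
        parts.append(seg + ("K" if rng.random() < 0.5 else "R"))
    return "".join(parts)


def _eligible_y_ordinals(sequence: str, prec_mz: float, exclusion_half: float = 5.0):
    n = len(sequence)
    out = []
    for ordinal in range(3, n):  # 3 .. n-1
        mz = masses.fragment_mz(sequence, "y", ordinal, 1)
        if abs(mz - prec_mz) > exclusion_half:
            out.append((ordinal, mz))
    return out


def generate_ground_truth(
    cfg: SimConfig,
) -> tuple[AssayLibrary, GroundTruth, list[SampleAnnotation]]:
    """Build the target library, the truth tables, and the sample annotation."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_seq, rng_design, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    populations = [
        DEFAULT_POPULATIONS[i] if i < len(DEFAULT_POPULATIONS) else f"Pop{i + 1}"
        for i in range(cfg.n_populations)
    ]
    annotations = [
        SampleAnnotation(
            sample_id=f"PS{b + 1}_{pop}_r{r + 1}",
            population=pop,
            sampling_batch=f"PS{b + 1}",
            replicate_index=r + 1,
        )
        for b in range(cfg.batches)
        for pop in populations
        for r in range(cfg.replicates)
    ]

    # --- proteins, peptides, transitions -----------------------------------
    rule = DigestRule()
    seen_peptides: set[str] = set()
    precursors: list[Precursor] = []
    proteins: list[str] = []
    pep_lo, pep_hi = cfg.peptides_per_protein
    for pi in range(cfg.n_proteins):
        protein_id = f"P{pi + 1:04d}"
        want = int(rng_seq.integers(pep_lo, pep_hi + 1))
        chosen: list[Peptide] = []
        for _attempt in range(40):
            seq = _random_protein_sequence(rng_seq, max(want + 2, 4))
            peptides = [
                p
                for p in digest_protein(seq, rule)
                if p.missed_cleavages == 0
                and 7 <= len(p.sequence) <= 18
                and p.sequence not in seen_peptides
            ]
            usable = []
            for pep in peptides:
                mz = masses.peptide_mz(pep.sequence, 2)
                if len(_eligible_y_ordinals(pep.sequence, mz)) >= cfg.transitions_per_precursor:
                    usable.append(pep)
            if len(usable) >= want:
                chosen = usable[:want]
                break
        if not chosen:
            raise ValidationError(
                "infeasible config: digestion yielded no usable peptides"
            )
        proteins.append(protein_id)
        for pep in chosen:
            seen_peptides.add(pep.sequence)
            pep = replace(
                pep,
                irt=float(rng_seq.uniform(0.0, 100.0)),
                protein_ids=[protein_id],
            )
            prec_mz = masses.peptide_mz(pep.sequence, 2)
            ordinals = _eligible_y_ordinals(pep.sequence, prec_mz)
            pick = rng_seq.choice(
                len(ordinals), size=cfg.transitions_per_precursor, replace=False
            )
            profile = rng_seq.dirichlet(
                np.full(cfg.transitions_per_precursor, cfg.fragment_dirichlet)
            )
            transitions = [
                Transition(
                    fragment_type="y",
                    ordinal=ordinals[j][0],
                    fragment_charge=1,
                    mz=ordinals[j][1],
                    library_intensity=float(1000.0 * profile[k]),
                )
                for k, j in enumerate(sorted(int(i) for i in pick))
            ]
            precursors.append(
                Precursor(peptide=pep, charge=2, mz=prec_mz, decoy=False, transitions=transitions)
            )
    lib = AssayLibrary(precursors, provenance=["simulated"])

    # --- design: differential proteins, signal-free targets ----------------
    n_diff = int(np.floor(cfg.frac_differential * cfg.n_proteins))
    order = rng_design.permutation(len(proteins))
    differential: dict[str, dict[str, float]] = {}
    cursor = 0
    for pop in populations:
        block = order[cursor: cursor + n_diff]
        cursor += n_diff
        signs = rng_design.choice([-1.0, 1.0], size=len(block))
        differential[pop] = {
            proteins[i]: float(s * cfg.log2fc_effect) for i, s in zip(block, signs)
        }
    n_free = int(np.floor(cfg.frac_signal_free * len(precursors)))
    free_idx = rng_design.choice(len(precursors), size=n_free, replace=False)
    signal_free = {precursors[int(i)].key_str for i in free_idx}

    # --- per-protein / per-sample abundances --------------------------------
    base = {
        pid: float(rng_design.normal(cfg.abundance_mu, cfg.abundance_sigma))
        for pid in proteins
    }
    bio_sd = np.sqrt(np.log(1.0 + cfg.bio_cv**2)) / np.log(2.0)  # log2 scale
    true_abund: dict[tuple[str, str], float] = {}
    for a in annotations:
        for pid in proteins:
            effect = differential.get(a.population, {}).get(pid, 0.0)
            true_abund[(pid, a.sample_id)] = (
                base[pid] + effect + float(rng_noise.normal(0.0, bio_sd))
            )

    # --- per-sample RT maps -------------------------------------------------
    rt_maps = {
        a.sample_id: (
            float(rng_design.uniform(*cfg.rt_slope_range)),
            float(rng_design.uniform(*cfg.rt_intercept_range)),
        )
        for a in annotations
    }

    # --- peptide responses and fragment profiles ----------------------------
    peptide_response = {
        p.peptide.modified_sequence: float(
            rng_design.lognormal(0.0, cfg.peptide_response_sigma)
        )
        for p in precursors
    }
    fragment_profiles = {
        p.key_str: np.array([t.library_intensity for t in p.transitions]) / 1000.0
        for p in precursors
    }

    # --- interference registry ----------------------------------------------
    interference = []
    for p in precursors:
        if p.key_str in signal_free:
            continue
        for a in annotations:
            if rng_design.random() < cfg.interference_rate:
                ti = int(rng_design.integers(0, len(p.transitions)))
                offset = float(rng_design.uniform(1.0, 2.5)) * (
                    1.0 if rng_design.random() < 0.5 else -1.0
                )
                interference.append(
                    (p.key_str, a.sample_id, ti, offset, cfg.interference_multiplier)
                )

    # --- iRT standards -------------------------------------------------------
    irts = np.linspace(0.0, 100.0, cfg.n_irt_standards)
    irt_standards = [(f"IRT{i + 1:02d}", float(v)) for i, v in enumerate(irts)]

    truth = GroundTruth(
        base_log2_abundance=base,
        true_log2_abundance=true_abund,
        differential=differential,
        signal_free=signal_free,
        interference=interference,
        rt_maps=rt_maps,
        peptide_response=peptide_response,
        fragment_profiles=fragment_profiles,
        irt_standards=irt_standards,
        annotations=annotations,
    )
    return lib, truth, annotations


def _gaussian(times: np.ndarray, apex: float, fwhm: float, area: float) -> np.ndarray:
    sigma = fwhm / GAUSS_FWHM
    height = area / (sigma * np.sqrt(2.0 * np.pi))
    return height * np.exp(-0.5 * ((times - apex) / sigma) ** 2)


def simulate_dia_experiment(
    lib: AssayLibrary, truth: GroundTruth, cfg: SimConfig
) -> ChromatogramSet:
    """Render per-transition chromatograms for every precursor × sample.

    Targets receive a Gaussian peak at the mapped RT (plus jitter) whose
    transition areas follow abundance × peptide response × fragment fraction;
    decoys and signal-free targets receive Poisson baseline only.  Registered
    interferences add an RT-offset Gaussian on one transition.  iRT standards
    are appended bright in every sample.
    """
    ss = np.random.SeedSequence((cfg.seed, 1))
    rng = np.random.default_rng(ss)
    chroms = ChromatogramSet()
    samples = [a.sample_id for a in truth.annotations]
    interf_by_key: dict[tuple[str, str], list] = {}
    for key, sample, ti, offset, mult in truth.interference:
        interf_by_key.setdefault((key, sample), []).append((ti, offset, mult))

    for prec in lib.precursors:
        key = prec.key_str
        n_trans = len(prec.transitions)
        labels = [t.label for t in prec.transitions]
        profile = truth.fragment_profiles.get(
            key.removeprefix("DECOY_"),
            np.full(n_trans, 1.0 / max(1, n_trans)),
        )
        if len(profile) != n_trans:
            profile = np.full(n_trans, 1.0 / max(1, n_trans))
        resp = truth.peptide_response.get(prec.peptide.modified_sequence, 1.0)
        protein = prec.peptide.protein_ids[0] if prec.peptide.protein_ids else None
        has_signal = (not prec.decoy) and key not in truth.signal_free
        for sample in samples:
            slope, intercept = truth.rt_maps[sample]
            rt0 = slope * prec.peptide.irt + intercept
            times = rt0 + np.arange(
                -cfg.grid_half_width, cfg.grid_half_width + cfg.grid_dt / 2, cfg.grid_dt
            )
            inten = rng.poisson(cfg.baseline, size=(n_trans, len(times))).astype(float)
            if has_signal and protein is not None:
                abund = 2.0 ** truth.true_log2_abundance[(protein, sample)]
                tech = float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
                apex = rt0 + float(rng.normal(0.0, cfg.rt_jitter_sd))
                fwhm = float(cfg.peak_fwhm * np.exp(rng.normal(0.0, cfg.fwhm_sigma)))
                areas = (
                    abund
                    * resp
                    * tech
                    * profile
                    * np.exp(rng.normal(0.0, cfg.transition_noise_sigma, size=n_trans))
                )
                for ti in range(n_trans):
                    inten[ti] += _gaussian(times, apex, fwhm, areas[ti])
                for ti, offset, mult in interf_by_key.get((key, sample), []):
                    if ti < n_trans:
                        inten[ti] += _gaussian(times, apex + offset, fwhm, mult * areas[ti])
            chroms.add(PrecursorTraces(key, sample, times, inten, labels))

    # iRT standards: bright, tight, no interference
    std_area = 2.0 ** (cfg.abundance_mu + 1.0)
    for skey, irt in truth.irt_standards:
        for sample in samples:
            slope, intercept = truth.rt_maps[sample]
            rt0 = slope * irt + intercept
            times = rt0 + np.arange(
                -cfg.grid_half_width, cfg.grid_half_width + cfg.grid_dt / 2, cfg.grid_dt
            )
            apex = rt0 + float(rng.normal(0.0, cfg.rt_jitter_sd))
            inten = rng.poisson(cfg.baseline, size=(1, len(times))).astype(float)
            inten[0] += _gaussian(times, apex, cfg.peak_fwhm, std_area)
            chroms.add(PrecursorTraces(f"IRT|{skey}", sample, times, inten, ["y0^1"]))
    return chroms


def simulate_observed_mzs(lib: AssayLibrary, truth: GroundTruth, cfg: SimConfig):
    """Per (transition, sample) observed m/z with uniform ppm jitter.

    Mirrors the instrument mass error the QC report summarizes; jitter is
    bounded by ``cfg.mz_jitter_ppm``.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3)))
    rows = []
    for prec in lib.precursors:
        if prec.decoy:
            continue
        for a in truth.annotations:
            for t in prec.transitions:
                ppm = float(rng.uniform(-cfg.mz_jitter_ppm, cfg.mz_jitter_ppm))
                rows.append(
                    {
                        "sample_id": a.sample_id,
                        "transition": f"{prec.key_str}:{t.label}",
                        "theoretical_mz": t.mz,
                        "observed_mz": t.mz * (1.0 + ppm * 1e-6),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted-violation fixture for the filter cascade


@dataclass
class CascadeFixture:
    library: AssayLibrary
    chromatograms: ChromatogramSet
    annotations: list
    truth: GroundTruth
    config: SimConfig
    expected_census: Census
    planted: dict[str, list[str]]  # violation class -> precursor keys


def _plant_peptide(
    lib: AssayLibrary,
    rng: np.random.Generator,
    protein_id: str,
    seen: set,
    n_transitions: int = 5,
    modifications: list[Modification] | None = None,
    missed: bool = False,
    irt: float | None = None,
) -> Precursor:
    """Create one additional synthetic peptide entry for fixture planting."""
    non_kr = np.array(list("ACDEFGHILMNQSTVWY"))
    while True:
        core = "".join(rng.choice(non_kr, size=11))
        if missed:
            seq = core[:5] + "K" + core[5:] + "R"
        else:
            seq = core + "R"
        if seq not in seen:
            break
    seen.add(seq)
    mods = modifications or []
    pep = Peptide(
        sequence=seq,
        modifications=mods,
        missed_cleavages=count_missed_cleavages(seq),
        irt=irt if irt is not None else float(rng.uniform(10.0, 90.0)),
        protein_ids=[protein_id],
    )
    deltas = pep.mod_deltas()
    mz = masses.peptide_mz(seq, 2, deltas)
    ordinals = [
        (o, masses.fragment_mz(seq, "y", o, 1, deltas))
        for o in range(3, len(seq))
        if abs(masses.fragment_mz(seq, "y", o, 1, deltas) - mz) > 5.0
    ]
    profile = np.array([0.30, 0.25, 0.20, 0.15, 0.10][:n_transitions])
    profile = profile / profile.sum()
    transitions = [
        Transition("y", ordinals[j][0], 1, ordinals[j][1], float(1000.0 * profile[j]))
        for j in range(n_transitions)
    ]
    prec = Precursor(peptide=pep, charge=2, mz=mz, decoy=False, transitions=transitions)
    lib.precursors.append(prec)
    return prec


def make_cascade_fixture(seed: int, violations: bool = True) -> CascadeFixture:
    """Small library with planted violations of every cascade rule.

    The expected post-cascade census comes from the plant registry itself: the
    fixture knows exactly which entries were built to violate which rule, so
    the surviving set is known by construction, independently of the filter
    implementation.
    """
    cfg = SimConfig(
        seed=seed,
        n_proteins=20,
        peptides_per_protein=(2, 2),
        n_populations=2,
        replicates=4,
        batches=1,
        frac_differential=0.0,
        frac_signal_free=0.0,
        interference_rate=0.0,
        fwhm_sigma=0.05,
        noise_sigma=0.05,
        transition_noise_sigma=0.02,
        abundance_sigma=0.8,
        abundance_mu=15.0,
        bio_cv=0.1,
    )
    lib, truth, annot = generate_ground_truth(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    seen = {p.peptide.sequence for p in lib.precursors}
    planted: dict[str, list[str]] = {}
    clean_keys = [p.key_str for p in lib.precursors]

    removed_keys: set[str] = set()
    removed_transitions: dict[str, int] = {}

    if violations:
        # step 1: disallowed PTM (phospho) on an extra peptide of protein P0001
        p = _plant_peptide(
            lib, rng, "P0001", seen,
            modifications=[Modification.other(2, "Phospho", masses.MOD_DELTA["Phospho"])],
        )
        planted["step1_ptm"] = [p.key_str]
        removed_keys.add(p.key_str)

        # step 2a: shared peptide (two proteins)
        p = _plant_peptide(lib, rng, "P0002", seen)
        p.peptide.protein_ids = ["P0002", "P0003"]
        planted["step2_shared"] = [p.key_str]
        removed_keys.add(p.key_str)

        # step 2b: repeated peptide — same sequence at charges 2 and 3
        p = _plant_peptide(lib, rng, "P0004", seen)
        dup = Precursor(
            peptide=replace(
                p.peptide,
                modifications=list(p.peptide.modifications),
                protein_ids=list(p.peptide.protein_ids),
            ),
            charge=3,
            mz=masses.peptide_mz(p.peptide.sequence, 3),
            decoy=False,
            transitions=[replace(t) for t in p.transitions],
        )
        lib.precursors.append(dup)
        planted["step2_repeated"] = [p.key_str, dup.key_str]
        removed_keys.update([p.key_str, dup.key_str])

        # step 3: precursor with only 3 transitions
        p = _plant_peptide(lib, rng, "P0005", seen, n_transitions=3)
        planted["step3_few_transitions"] = [p.key_str]
        removed_keys.add(p.key_str)

        # step 4: missed cleavage
        p = _plant_peptide(lib, rng, "P0006", seen, missed=True)
        planted["step4_missed"] = [p.key_str]
        removed_keys.add(p.key_str)

        # step 5: low dotp in all samples — library intensities reversed
        p = _plant_peptide(lib, rng, "P0007", seen)
        truth.fragment_profiles[p.key_str] = np.array([0.02, 0.02, 0.02, 0.04, 0.90])
        truth.peptide_response[p.peptide.modified_sequence] = 1.0
        planted["step5_low_dotp"] = [p.key_str]
        removed_keys.add(p.key_str)

        # step 6: protein with a single peptide
        p = _plant_peptide(lib, rng, "P0100", seen)
        truth.fragment_profiles[p.key_str] = np.array([t.library_intensity for t in p.transitions]) / 1000.0
        truth.peptide_response[p.peptide.modified_sequence] = 1.0
        planted["step6_single_peptide"] = [p.key_str]
        removed_keys.add(p.key_str)

        def _register_clean(prec: Precursor):
            truth.fragment_profiles[prec.key_str] = (
                np.array([t.library_intensity for t in prec.transitions])
                / sum(t.library_intensity for t in prec.transitions)
            )
            truth.peptide_response[prec.peptide.modified_sequence] = 1.0

        # rule 1 (step 7): one transition interfered in all samples; precursor kept
        p = _plant_peptide(lib, rng, "P0008", seen, n_transitions=5)
        _register_clean(p)
        for a in annot:
            truth.interference.append((p.key_str, a.sample_id, 0, 1.8, 3.0))
        planted["rule1_transition"] = [p.key_str]
        removed_transitions[p.key_str] = 1

        # rule 2 (step 7): undetected (signal-free) in all samples of one population
        p = _plant_peptide(lib, rng, "P0009", seen)
        _register_clean(p)
        truth.signal_free.add(p.key_str)
        planted["rule2_undetected"] = [p.key_str]
        removed_keys.add(p.key_str)
        # its protein P0009 already has 2 clean peptides, so the protein survives

        # rule 3 (step 7): peak widths 4x wider for half of one population
        p = _plant_peptide(lib, rng, "P0010", seen)
        _register_clean(p)
        planted["rule3_width"] = [p.key_str]
        removed_keys.add(p.key_str)
        truth_wide = p.key_str  # widened at render time below

        # rule 4 (step 7): two of five transitions interfered in all samples
        p = _plant_peptide(lib, rng, "P0011", seen, n_transitions=5)
        _register_clean(p)
        for a in annot:
            truth.interference.append((p.key_str, a.sample_id, 1, -1.9, 3.0))
            truth.interference.append((p.key_str, a.sample_id, 3, 1.7, 3.0))
        planted["rule4_two_interfered"] = [p.key_str]
        removed_keys.add(p.key_str)

        # re-applied step 3 after rule 1: 4-transition precursor loses one
        p = _plant_peptide(lib, rng, "P0012", seen, n_transitions=4)
        _register_clean(p)
        for a in annot:
            truth.interference.append((p.key_str, a.sample_id, 2, 2.0, 3.0))
        planted["rule1_then_step3"] = [p.key_str]
        removed_keys.add(p.key_str)
    else:
        truth_wide = None

    # planted proteins absent from the base design need abundances too
    for prec in lib.precursors:
        for pid in prec.peptide.protein_ids:
            if pid not in truth.base_log2_abundance:
                truth.base_log2_abundance[pid] = cfg.abundance_mu
            for a in annot:
                if (pid, a.sample_id) not in truth.true_log2_abundance:
                    truth.true_log2_abundance[(pid, a.sample_id)] = (
                        truth.base_log2_abundance[pid] + float(rng.normal(0.0, 0.1))
                    )

    chroms = simulate_dia_experiment(lib, truth, cfg)

    if violations and truth_wide is not None:
        # widen the rule-3 precursor in the first half of population 1's samples
        pop1 = [a.sample_id for a in annot if a.population == annot[0].population]
        for sample in pop1[: len(pop1) // 2]:
            tr = chroms.get(sample, truth_wide)
            t0 = tr.times[np.argmax(tr.intensities.sum(axis=0))]
            stretched = np.zeros_like(tr.intensities)
            for ti in range(tr.intensities.shape[0]):
                stretched[ti] = np.interp(
                    (tr.times - t0) / 4.0 + t0, tr.times, tr.intensities[ti]
                )
            tr.intensities = stretched

    # expected census by construction: clean entries plus planted survivors
    surviving: list[Precursor] = []
    for prec in lib.precursors:
        if prec.key_str in removed_keys:
            continue
        kept = prec
        if prec.key_str in removed_transitions:
            kept = replace(
                prec, transitions=prec.transitions[removed_transitions[prec.key_str]:]
            )
        surviving.append(kept)
    from .core import census as _census

    expected = _census(AssayLibrary(surviving))
    return CascadeFixture(
        library=lib,
        chromatograms=chroms,
        annotations=annot,
        truth=truth,
        config=cfg,
        expected_census=expected,
        planted=planted,
    )
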