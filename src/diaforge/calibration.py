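"""Ground-truth validation experiments for the scoring and inference stack.

These helpers run the pipeline on simulated data where the truth is known and
measure its realized error rates: the false-discovery proportion among
accepted targets at the q-value cutoff, and end-to-end recovery of planted
population signatures.  They exist so that calibration claims are recomputed,
not asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pipeline
from .core import AssayLibrary
from .library import generate_decoys
from .simulate import SimConfig, generate_ground_truth, simulate_dia_experiment

DEFAULT_Q_CUTOFF = 0.005  # mProphet-style acceptance threshold (FDR < 0.5%)


@dataclass
class FdrExperimentResult:
    seed: int
    n_accepted: int
    n_accepted_signal_free: int
    fdp_percent: float


def realized_fdp(
    seed: int,
    n_proteins: int = 250,
    peptides_per_protein: int = 4,
    frac_signal_free: float = 0.2,
    replicates: int = 2,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> FdrExperimentResult:
    """Realized false-discovery proportion at the q-value cutoff, one seed.

    Simulates a target set (default 1000 peptides of which 200 signal-free)
    plus an equal number of scrambled decoys, runs extraction and scoring, and
    reports the fraction of accepted targets that are signal-free — the
    ground-truth false discoveries the decoy-based q-value is supposed to
    bound.
    """
    cfg = SimConfig(
        seed=seed,
        n_proteins=n_proteins,
        peptides_per_protein=(peptides_per_protein, peptides_per_protein),
        n_populations=1,
        replicates=replicates,
        batches=1,
        frac_differential=0.0,
        frac_signal_free=frac_signal_free,
    )
    lib, truth, _annot = generate_ground_truth(cfg)
    full = AssayLibrary(lib.precursors + generate_decoys(lib, seed=seed).precursors)
    chroms = simulate_dia_experiment(full, truth, cfg)
    scores, _scorer, _models = pipeline.run_scoring(full, chroms, truth.irt_standards, seed=seed)
    targets = scores[~scores["decoy"]]
    accepted = targets[targets["qvalue"] <= q_cutoff]
    n_free = int(accepted["precursor"].isin(truth.signal_free).sum())
    fdp = 100.0 * n_free / len(accepted) if len(accepted) else 0.0
    return FdrExperimentResult(
        seed=seed,
        n_accepted=len(accepted),
        n_accepted_signal_free=n_free,
        fdp_percent=fdp,
    )


def mean_realized_fdp(seeds, **kwargs) -> tuple[float, list[FdrExperimentResult]]:
    """Average realized FDP (%) over seeds."""
    results = [realized_fdp(seed, **kwargs) for seed in seeds]
    return float(np.mean([r.fdp_percent for r in results])), results


@dataclass
class EndToEndResult:
    recovery_percent: float  # planted effects recovered in the combined analysis
    n_planted: int
    n_recovered: int
    opposite_direction_members: list = field(default_factory=list)
    unplanted_members: list = field(default_factory=list)
    comparison_set: object = None
    combined: pd.DataFrame | None = None
    signatures: dict = field(default_factory=dict)


def end_to_end(
    seed: int,
    cfg: SimConfig | None = None,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    combined_fc: float = 1.45,
    batch_fc: float = 2.0,
    alpha: float = 0.05,
) -> EndToEndResult:
    """Full pipeline on the default study design; measures signature recovery.

    Recovery: a planted (population, protein) effect counts as recovered when
    the combined one-vs-rest analysis calls it significant (BH-adjusted
    p < alpha, |FC| ≥ combined_fc) in the planted direction.  Signatures are
    extracted per batch at the per-batch FC threshold and checked against the
    planted truth for members in the wrong direction.
    """
    cfg = cfg or SimConfig(seed=seed)
    lib, truth, annot = generate_ground_truth(cfg)
    full = AssayLibrary(lib.precursors + generate_decoys(lib, seed=seed).precursors)
    chroms = simulate_dia_experiment(full, truth, cfg)
    scores, _scorer, _models = pipeline.run_scoring(full, chroms, truth.irt_standards, seed=seed)
    matrix = pipeline.quantify(scores, full, q_threshold=q_cutoff)

    combined = pipeline.compare_populations(matrix, annot, combined=True)
    lfc_combined = np.log2(combined_fc)
    n_planted = n_recovered = 0
    for pop, effects in truth.differential.items():
        sub = combined[combined["comparison"] == f"{pop} vs rest"].set_index("protein")
        for prot, fc in effects.items():
            n_planted += 1
            if prot not in sub.index:
                continue
            row = sub.loc[prot]
            if (
                row["adj_p"] < alpha
                and abs(row["log2fc"]) >= lfc_combined
                and np.sign(row["log2fc"]) == np.sign(fc)
            ):
                n_recovered += 1

    cs = pipeline.per_batch_comparison_set(matrix, annot)
    signatures = {}
    opposite = []
    unplanted = []
    from .repro import extract_signature

    for pop in sorted(truth.differential):
        up, down = extract_signature(cs, pop, alpha, batch_fc)
        signatures[pop] = (up, down)
        effects = truth.differential[pop]
        for prot in up:
            if prot in effects and effects[prot] < 0:
                opposite.append((pop, prot, "up"))
            elif prot not in effects:
                unplanted.append((pop, prot, "up"))
        for prot in down:
            if prot in effects and effects[prot] > 0:
                opposite.append((pop, prot, "down"))
            elif prot not in effects:
                unplanted.append((pop, prot, "down"))

    return EndToEndResult(
        recovery_percent=100.0 * n_recovered / n_planted if n_planted else 0.0,
        n_planted=n_planted,
        n_recovered=n_recovered,
        opposite_direction_members=opposite,
        unplanted_members=unplanted,
        comparison_set=cs,
        combined=combined,
        signatures=signatures,
    )
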