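"""End-to-end orchestration: calibration → scoring → quantitation → comparison.

These helpers wire the per-module operations into the standard workflow used
by the command-line interface and the reproducibility analyses: fit per-sample
iRT models from the spiked standards, predict retention times for every
library precursor, score peak groups against decoys, build the quantitative
matrix from accepted peaks, summarize proteins, and run the one-vs-rest
population comparisons per sampling batch and combined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AssayLibrary, SampleAnnotation
from .extract import ChromatogramSet
from .irt import IrtRegressor
from .quant import (
    differential_test,
    normalize_medians,
    quant_matrix_from_scores,
    summarize_all_proteins,
)
from .repro import ComparisonSet
from .scoring import score_experiment

IRT_PREFIX = "IRT|"


def fit_irt_models(
    chroms: ChromatogramSet, irt_standards: list[tuple[str, float]]
) -> dict[str, IrtRegressor]:
    """Per-sample iRT→RT calibration from the spiked standards' apexes."""
    irt_by_key = dict(irt_standards)
    models: dict[str, IrtRegressor] = {}
    for sample in chroms.sample_ids:
        pairs = []
        for skey, irt in irt_by_key.items():
            full_key = IRT_PREFIX + skey
            if (sample, full_key) in chroms:
                tr = chroms.get(sample, full_key)
                apex = float(tr.times[int(np.argmax(tr.intensities.sum(axis=0)))])
                pairs.append((irt, apex))
        if len(pairs) >= 3:
            arr = np.asarray(pairs)
            models[sample] = IrtRegressor().fit(arr[:, 0], arr[:, 1])
    return models


def predicted_rt_map(
    lib: AssayLibrary, models: dict[str, IrtRegressor], samples: list[str]
) -> dict[tuple[str, str], float]:
    out = {}
    for sample in samples:
        model = models[sample]
        for prec in lib.precursors:
            out[(sample, prec.key_str)] = float(
                model.slope_ * prec.peptide.irt + model.intercept_
            )
    return out


def compute_dotp_table(
    lib: AssayLibrary,
    chroms: ChromatogramSet,
    predicted: dict[tuple[str, str], float],
    rt_window: float = 3.0,
) -> pd.DataFrame:
    """Best-candidate dotp per (precursor, sample); 0 where nothing detected."""
    from .scoring import collect_candidates

    candidates = collect_candidates(lib, chroms, predicted, rt_window=rt_window)
    # detection order puts the most intense candidate first; its dotp is the
    # one the refine step inspects (a faint baseline bump can have a deceptively
    # high square-root dotp, so "max dotp over candidates" would be wrong)
    table: dict[str, dict[str, float]] = {}
    for c in candidates:
        table.setdefault(c.precursor_key, {}).setdefault(c.sample_id, c.subscores["dotp"])
    samples = chroms.sample_ids
    keys = [p.key_str for p in lib.precursors]
    return pd.DataFrame(
        [[table.get(k, {}).get(s, 0.0) for s in samples] for k in keys],
        index=keys,
        columns=samples,
    )


def prepare_training_data(
    lib: AssayLibrary,
    chroms: ChromatogramSet,
    irt_standards: list[tuple[str, float]],
    rt_window: float = 3.0,
):
    """Training-set evidence (dotp table + peak data) for cascade steps 5 and 7."""
    from .cascade import collect_peak_data

    models = fit_irt_models(chroms, irt_standards)
    samples = [s for s in chroms.sample_ids if s in models]
    predicted = predicted_rt_map(lib, models, samples)
    dotp = compute_dotp_table(lib, chroms, predicted, rt_window=rt_window)
    peakdata = collect_peak_data(lib, chroms, predicted)
    from .cascade import TrainingData

    return TrainingData(dotp_table=dotp, peakdata=peakdata), models


def run_scoring(
    lib: AssayLibrary,
    chroms: ChromatogramSet,
    irt_standards: list[tuple[str, float]],
    seed: int = 0,
    rt_window: float = 3.0,
):
    """Calibrate, detect, and score an experiment; returns (scores, scorer, models)."""
    models = fit_irt_models(chroms, irt_standards)
    samples = [s for s in chroms.sample_ids if s in models]
    predicted = predicted_rt_map(lib, models, samples)
    scores, scorer = score_experiment(lib, chroms, predicted, seed=seed, rt_window=rt_window)
    return scores, scorer, models


def quantify(
    scores: pd.DataFrame, lib: AssayLibrary, q_threshold: float = 0.005
) -> pd.DataFrame:
    """Protein × sample log2 abundance from accepted peak groups."""
    qm = quant_matrix_from_scores(scores, lib, q_threshold=q_threshold)
    qm = normalize_medians(qm)
    return summarize_all_proteins(qm)


def compare_populations(
    protein_matrix: pd.DataFrame,
    annot: list[SampleAnnotation],
    combined: bool = False,
    batch: str | None = None,
) -> pd.DataFrame:
    """One-vs-rest differential table for every population.

    ``batch`` restricts to one sampling batch (separate-PS analysis);
    ``combined`` pools batches with an additive batch term.
    """
    if batch is not None:
        annot = [a for a in annot if a.sampling_batch == batch]
    populations = sorted({a.population for a in annot})
    cols = [a.sample_id for a in annot if a.sample_id in protein_matrix.columns]
    frames = [
        differential_test(protein_matrix[cols], annot, pop, combined=combined)
        for pop in populations
    ]
    return pd.concat(frames, ignore_index=True)


def per_batch_comparison_set(
    protein_matrix: pd.DataFrame, annot: list[SampleAnnotation]
) -> ComparisonSet:
    """Per-(protein, population, batch) log2fc and adjusted p across all batches."""
    batches = sorted({a.sampling_batch for a in annot})
    rows = []
    for batch in batches:
        diff = compare_populations(protein_matrix, annot, combined=False, batch=batch)
        for r in diff.itertuples(index=False):
            rows.append(
                {
                    "protein": r.protein,
                    "population": r.comparison.split(" vs ")[0],
                    "batch": batch,
                    "log2fc": r.log2fc,
                    "adj_p": r.adj_p,
                }
            )
    return ComparisonSet(pd.DataFrame(rows))
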