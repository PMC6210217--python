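"""Label-free quantitation and inference on scored DIA peak areas.

MS2-level median normalization, Tukey median-polish protein summarization
(missing peaks enter as zero intensity before the log transform), one-vs-rest
differential testing with Benjamini–Hochberg correction, and the classical
two-sample power formula for the minimum detectable fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import SampleAnnotation, ValidationError


# ---------------------------------------------------------------------------
# matrix construction & normalization


def quant_matrix_from_scores(
    scores: pd.DataFrame,
    lib,
    q_threshold: float = 0.005,
) -> pd.DataFrame:
    """Transition × sample log2-intensity matrix from accepted peak groups.

    Rows are indexed (protein, precursor, transition index); a precursor whose
    best peak group misses the q cutoff in a sample contributes missing values
    there (treated as zero intensity at summarization, per the missing-peak
    policy).
    """
    by_key = {p.key_str: p for p in lib.precursors}
    acc = scores[(~scores["decoy"]) & (scores["qvalue"] <= q_threshold)]
    samples = sorted(scores["sample_id"].unique())
    rows: dict[tuple, dict[str, float]] = {}
    for r in acc.itertuples(index=False):
        prec = by_key.get(r.precursor)
        if prec is None:
            continue
        protein = ";".join(prec.peptide.protein_ids)
        for ti, area in enumerate(r.areas):
            rows.setdefault((protein, r.precursor, ti), {})[r.sample_id] = np.log2(1.0 + area)
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["protein", "precursor", "transition"])
    mat = pd.DataFrame(
        [[rows[k].get(s, np.nan) for s in samples] for k in rows], index=idx, columns=samples
    )
    return mat


def normalize_medians(qm: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-sample medians by shifting each column to the grand median.

    Each column is shifted by (median of column medians − its own median), so
    within-sample differences are untouched and all column medians end exactly
    equal.
    """
    med = qm.median(axis=0, skipna=True)
    if med.isna().any():
        bad = med[med.isna()].index.tolist()
        raise ValidationError(f"all-missing sample column(s): {bad}")
    grand = float(np.median(med.to_numpy()))
    return qm.add(grand - med, axis=1)


# ---------------------------------------------------------------------------
# median polish


def median_polish(
    mat: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's additive decomposition: overall + row + column effects + residual.

    Row sweep first, then column sweep, iterated until the sum of absolute
    residuals stabilizes to within a relative ``tol`` (the standard stopping
    rule; on even-sized matrices the sweeps can cycle without ever driving the
    per-sweep changes to zero) or ``max_iter`` sweeps complete.
    """
    x = np.asarray(mat, dtype=float).copy()
    nr, nc = x.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    oldsum = 0.0
    for _ in range(max_iter):
        rmed = np.median(x, axis=1)
        x -= rmed[:, None]
        row += rmed
        cshift = np.median(col)
        col -= cshift
        overall += cshift

        cmed = np.median(x, axis=0)
        x -= cmed[None, :]
        col += cmed
        rshift = np.median(row)
        row -= rshift
        overall += rshift

        newsum = float(np.abs(x).sum())
        if newsum == 0.0 or abs(newsum - oldsum) < tol * newsum:
            break
        oldsum = newsum
    return overall, row, col, x


def summarize_protein(transition_rows: pd.DataFrame) -> pd.Series:
    """Per-sample protein abundance = overall effect + column effect.

    Missing peaks are imputed as zero intensity before the log transform, i.e.
    log2(0 + 1) = 0 on the log scale.
    """
    if transition_rows.shape[0] < 1:
        raise ValidationError("need at least one transition row")
    x = transition_rows.to_numpy(dtype=float)
    x = np.where(np.isnan(x), 0.0, x)
    if x.shape[0] == 1:
        return pd.Series(x[0], index=transition_rows.columns)
    overall, _row, col, _resid = median_polish(x)
    return pd.Series(overall + col, index=transition_rows.columns)


def summarize_all_proteins(qm: pd.DataFrame) -> pd.DataFrame:
    """Protein × sample abundance table via per-protein median polish."""
    out = {}
    for protein, grp in qm.groupby(level="protein", sort=True):
        out[protein] = summarize_protein(grp)
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# differential testing


@dataclass
class DiffResult:
    protein: str
    comparison: str  # "<population> vs rest"
    log2fc: float
    se: float
    p: float
    adj_p: float
    n_group: int
    n_rest: int


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, monotone, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_test(
    protein_abundances: pd.DataFrame,
    annot: list[SampleAnnotation],
    population: str,
    combined: bool = False,
) -> pd.DataFrame:
    """One-vs-rest linear-model contrast per protein.

    Fits log2 abundance ~ group (+ sampling batch when ``combined``) by OLS;
    the group coefficient is the log2 fold change (positive = elevated in the
    focal population) and its two-sided t-test gives p.  BH adjustment is
    applied across proteins within the comparison.
    """
    by_id = {a.sample_id: a for a in annot}
    samples = [s for s in protein_abundances.columns if s in by_id]
    if not samples:
        raise ValidationError("no annotated samples in abundance table")
    group = np.array([1.0 if by_id[s].population == population else 0.0 for s in samples])
    n_group = int(group.sum())
    n_rest = len(samples) - n_group
    if n_group < 2 or n_rest < 2:
        raise ValidationError("need at least 2 samples on each side of the contrast")
    X = pd.DataFrame({"const": 1.0, "group": group}, index=samples)
    if combined:
        batches = pd.Series([by_id[s].sampling_batch for s in samples], index=samples)
        dummies = pd.get_dummies(batches, prefix="batch", drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    dof = len(samples) - X.shape[1]
    if dof <= 0:
        raise ValidationError("zero residual degrees of freedom")
    # all proteins share the design, so one solve covers the whole matrix
    Xv = X.to_numpy(dtype=float)
    Y = protein_abundances[samples].to_numpy(dtype=float).T  # samples x proteins
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    beta = XtX_inv @ Xv.T @ Y  # params x proteins
    resid = Y - Xv @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    gi = list(X.columns).index("group")
    se = np.sqrt(sigma2 * XtX_inv[gi, gi])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta[gi] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(np.isfinite(p), p, 1.0)
    df = pd.DataFrame(
        {
            "protein": protein_abundances.index,
            "comparison": f"{population} vs rest",
            "log2fc": beta[gi],
            "se": se,
            "p": p,
            "n_group": n_group,
            "n_rest": n_rest,
        }
    )
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# power analysis


@dataclass
class PowerSettings:
    power: float = 0.8
    fdr: float = 0.01
    cv: float = 0.25  # anticipated biological coefficient of variation
    m_tests: int = 1500

    def __post_init__(self):
        if not 0 < self.power < 1 or not 0 < self.fdr < 1:
            raise ValidationError("power and fdr must lie in (0, 1)")
        if self.cv <= 0:
            raise ValidationError("cv must be positive")


def cv_to_log2_sd(cv: float) -> float:
    """Log2-scale SD implied by a coefficient of variation on the natural scale."""
    return float(np.sqrt(np.log(1.0 + cv**2)) / np.log(2.0))


def min_detectable_fc(n_per_group: int, settings: PowerSettings) -> float:
    """Minimum detectable fold change of a two-sample comparison.

    Δlog2 = (z_{1−α/2} + z_{power}) · √(2σ²/n) with σ the log2-scale SD implied
    by the anticipated CV and α the FDR-level significance; returns 2^Δlog2.
    """
    if n_per_group < 2:
        raise ValidationError("need n >= 2 per group")
    sigma = cv_to_log2_sd(settings.cv)
    z_alpha = stats.norm.ppf(1.0 - settings.fdr / 2.0)
    z_power = stats.norm.ppf(settings.power)
    delta = (z_alpha + z_power) * np.sqrt(2.0 * sigma**2 / n_per_group)
    return float(2.0**delta)


def calibrate_cv_for_fc(target_fc: float, n_per_group: int, settings: PowerSettings) -> float:
    """CV such that the minimum detectable FC at ``n_per_group`` equals ``target_fc``."""
    z_alpha = stats.norm.ppf(1.0 - settings.fdr / 2.0)
    z_power = stats.norm.ppf(settings.power)
    sigma = np.log2(target_fc) / ((z_alpha + z_power) * np.sqrt(2.0 / n_per_group))
    return float(np.sqrt(np.exp((sigma * np.log(2.0)) ** 2) - 1.0))
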