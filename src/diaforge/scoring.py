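"""mProphet-style semi-supervised peak-group scoring and q-value estimation.

Candidate peak groups from targets and scrambled decoys are described by a
small fixed subscore vector; a linear discriminant is trained semi-supervised
(iteration 0 ranks by dotp alone, subsequent iterations take confident targets
as positives and all decoys as negatives) and q-values are estimated by
conservative target–decoy counting with a +1 pseudo-count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import AssayLibrary
from .extract import ChromatogramSet, PeakGroup, PrecursorTraces, detect_peak_groups

logger = logging.getLogger(__name__)

SUBSCORE_NAMES = ["dotp", "coelution", "rt_dev", "log_area", "sn"]


def compute_dotp(library_intensities, observed_areas) -> float:
    """Cosine similarity of square-root-transformed intensity vectors.

    dotp = Σ√(l_i·o_i) / (√Σl_i · √Σo_i); scale-invariant in each argument,
    1.0 for proportional vectors, 0.0 for disjoint supports or an all-zero
    observation.
    """
    l = np.asarray(library_intensities, dtype=float)
    o = np.asarray(observed_areas, dtype=float)
    if l.shape != o.shape or l.size < 2:
        raise ValueError("library and observed vectors must have equal length >= 2")
    if np.any(l < 0) or np.any(o < 0):
        raise ValueError("intensity vectors must be non-negative")
    so = o.sum()
    sl = l.sum()
    if so == 0:
        return 0.0
    if sl == 0:
        raise ValueError("library intensity vector is all-zero")
    return float(np.sqrt(l * o).sum() / (np.sqrt(sl) * np.sqrt(so)))


def _coelution(traces: PrecursorTraces, pg: PeakGroup) -> float:
    """Mean pairwise Pearson correlation of transition traces within boundaries."""
    lo, hi = pg.boundaries
    seg = (traces.times >= lo) & (traces.times <= hi)
    mat = traces.intensities[:, seg]
    n = mat.shape[0]
    if n < 2:
        return 1.0
    sd = mat.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return 0.0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat[ok])
    iu = np.triu_indices(ok.sum(), k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    # pairs with a constant trace contribute 0
    n_pairs = n * (n - 1) // 2
    return float(vals.sum() / n_pairs) if n_pairs else 1.0


def compute_subscores(
    pg: PeakGroup,
    traces: PrecursorTraces,
    library_intensities: np.ndarray,
    predicted_rt: float,
) -> dict[str, float]:
    """The fixed five-subscore vector of one candidate peak group."""
    dotp = compute_dotp(library_intensities, pg.areas)
    return {
        "dotp": dotp,
        "coelution": _coelution(traces, pg),
        "rt_dev": abs(pg.rt_apex - predicted_rt),
        "log_area": float(np.log10(1.0 + pg.areas.sum())),
        "sn": pg.sn,
    }


def estimate_qvalues(target_scores, decoy_scores) -> np.ndarray:
    """q-value per target by target–decoy counting with a +1 pseudo-count.

    raw FDR at threshold s = (1 + #{decoys ≥ s}) · (N_t/N_d) / max(1, #{targets ≥ s});
    q(s) = min over thresholds ≤ s, clipped to [0, 1]; monotone non-increasing
    in score by construction.
    """
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if t.size == 0 or d.size == 0:
        raise ValueError("target and decoy score vectors must be nonempty")
    ratio = t.size / d.size
    order = np.argsort(t)  # ascending
    d_sorted = np.sort(d)
    # counts at each target score threshold
    n_t_ge = t.size - np.arange(t.size)  # targets >= t_sorted[i]
    # handle ties among targets: recompute with searchsorted
    t_sorted = t[order]
    n_t_ge = t.size - np.searchsorted(t_sorted, t_sorted, side="left")
    n_d_ge = d.size - np.searchsorted(d_sorted, t_sorted, side="left")
    raw = (1.0 + n_d_ge) * ratio / np.maximum(1, n_t_ge)
    # q(s) = min of raw over thresholds <= s: running minimum from low scores up
    q_sorted = np.minimum.accumulate(raw)
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class ScoredCandidate:
    precursor_key: str
    sample_id: str
    decoy: bool
    signal_free: bool
    pg: PeakGroup
    subscores: dict[str, float]


class PeakGroupScorer(BaseEstimator):
    """Semi-supervised linear discriminant over peak-group subscores.

    Iteration 0 ranks candidates by dotp alone; each subsequent iteration
    labels targets with current q-value below ``q_train`` as positives and all
    decoys as negatives, fits a linear discriminant with pooled covariance and
    a small ridge, and rescores.  Deterministic for a given seed.

    Attributes
    ----------
    weights_ : ndarray of shape (5,)   discriminant weights per subscore
    means_ : ndarray                   feature standardization means
    scales_ : ndarray                  feature standardization scales
    n_iterations_ : int
    """

    def __init__(self, iterations: int = 3, q_train: float = 0.15, ridge: float = 1e-6,
                 seed: int = 0):
        self.iterations = iterations
        self.q_train = q_train
        self.ridge = ridge
        self.seed = seed

    @staticmethod
    def _matrix(subscore_dicts) -> np.ndarray:
        return np.array([[s[k] for k in SUBSCORE_NAMES] for s in subscore_dicts], dtype=float)

    def fit(self, target_subscores, decoy_subscores):
        """Train on best-candidate subscore dicts of targets and decoys."""
        Xt = self._matrix(target_subscores)
        Xd = self._matrix(decoy_subscores)
        if len(Xt) < 20 or len(Xd) < 20:
            raise ValueError("need at least 20 target and 20 decoy best candidates")
        X = np.vstack([Xt, Xd])
        self.means_ = X.mean(axis=0)
        self.scales_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Zt = (Xt - self.means_) / self.scales_
        Zd = (Xd - self.means_) / self.scales_

        dotp_idx = SUBSCORE_NAMES.index("dotp")
        w = np.zeros(len(SUBSCORE_NAMES))
        w[dotp_idx] = 1.0
        for it in range(self.iterations):
            st = Zt @ w
            sd = Zd @ w
            q = estimate_qvalues(st, sd)
            pos = Zt[q < self.q_train]
            if len(pos) == 0:
                if it == 0:
                    warnings.warn(
                        "no target reached the training q threshold; "
                        "falling back to dotp-only scoring"
                    )
                break
            neg = Zd
            mu_p = pos.mean(axis=0)
            mu_n = neg.mean(axis=0)
            centered = np.vstack([pos - mu_p, neg - mu_n])
            cov = centered.T @ centered / max(1, len(centered) - 2)
            cov += self.ridge * np.eye(cov.shape[0])
            w_new = np.linalg.solve(cov, mu_p - mu_n)
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w = w_new / norm
            if (Zt @ w).mean() < (Zd @ w).mean():
                w = -w  # orient toward targets
        self.weights_ = w
        self.n_iterations_ = self.iterations
        return self

    def decision_function(self, subscore_dicts) -> np.ndarray:
        X = self._matrix(subscore_dicts)
        Z = (X - self.means_) / self.scales_
        return Z @ self.weights_


def train_discriminant(targets, decoys, seed: int = 0, iterations: int = 3) -> PeakGroupScorer:
    """Functional wrapper over :class:`PeakGroupScorer`."""
    return PeakGroupScorer(iterations=iterations, seed=seed).fit(targets, decoys)


# ---------------------------------------------------------------------------
# experiment-level driver


def collect_candidates(
    lib: AssayLibrary,
    chroms: ChromatogramSet,
    predicted_rts: dict[tuple[str, str], float],
    rt_window: float = 3.0,
) -> list[ScoredCandidate]:
    """Detect candidates and compute subscores for every precursor × sample.

    ``predicted_rts`` maps (sample_id, precursor_key) to the RT predicted from
    the sample's iRT calibration.
    """
    out = []
    by_key = {p.key_str: p for p in lib.precursors}
    for (sample, key), traces in chroms.items():
        prec = by_key.get(key)
        if prec is None:
            continue
        pred = predicted_rts[(sample, key)]
        lib_int = np.array([t.library_intensity for t in prec.transitions])
        for pg in detect_peak_groups(traces, pred, rt_window=rt_window):
            subs = compute_subscores(pg, traces, lib_int, pred)
            pg.dotp = subs["dotp"]
            pg.subscores = subs
            out.append(
                ScoredCandidate(
                    precursor_key=key,
                    sample_id=sample,
                    decoy=prec.decoy,
                    signal_free=False,
                    pg=pg,
                    subscores=subs,
                )
            )
    return out


def score_candidates(
    candidates: list[ScoredCandidate], seed: int = 0, iterations: int = 3
) -> tuple[pd.DataFrame, PeakGroupScorer]:
    """Train the discriminant and q-value the best candidate per precursor/sample.

    Returns a table with one row per (precursor, sample): the best-scoring peak
    group with its discriminant score, dotp and q-value, plus the fitted scorer.
    """
    # best candidate per (precursor, sample) at iteration time is defined by the
    # evolving model; select by dotp first for training, then rescore.
    best: dict[tuple[str, str], ScoredCandidate] = {}
    for c in candidates:
        k = (c.sample_id, c.precursor_key)
        if k not in best or c.subscores["dotp"] > best[k].subscores["dotp"]:
            best[k] = c
    t_best = [c for c in best.values() if not c.decoy]
    d_best = [c for c in best.values() if c.decoy]
    scorer = PeakGroupScorer(iterations=iterations, seed=seed)
    scorer.fit([c.subscores for c in t_best], [c.subscores for c in d_best])

    # final rescoring: best candidate per precursor/sample under the final model
    scores = scorer.decision_function([c.subscores for c in candidates])
    final_best: dict[tuple[str, str], tuple[float, ScoredCandidate]] = {}
    for s, c in zip(scores, candidates):
        k = (c.sample_id, c.precursor_key)
        if k not in final_best or s > final_best[k][0]:
            final_best[k] = (float(s), c)
    rows = []
    t_scores = [s for (s, c) in final_best.values() if not c.decoy]
    d_scores = [s for (s, c) in final_best.values() if c.decoy]
    q_t = estimate_qvalues(np.array(t_scores), np.array(d_scores))
    ti = 0
    for (s, c) in final_best.values():
        if c.decoy:
            q = float("nan")  # q-values are defined for targets only
        else:
            q = float(q_t[ti]); ti += 1
        c.pg.discriminant_score = s
        c.pg.qvalue = q
        rows.append(
            {
                "sample_id": c.sample_id,
                "precursor": c.precursor_key,
                "decoy": c.decoy,
                "rt_apex": c.pg.rt_apex,
                "fwhm": c.pg.fwhm,
                "sn": c.pg.sn,
                "dotp": c.subscores["dotp"],
                "coelution": c.subscores["coelution"],
                "rt_dev": c.subscores["rt_dev"],
                "score": s,
                "qvalue": q,
                "total_area": float(c.pg.areas.sum()),
                "areas": c.pg.areas.tolist(),
            }
        )
    return pd.DataFrame(rows), scorer


def score_experiment(
    lib: AssayLibrary,
    chroms: ChromatogramSet,
    predicted_rts: dict[tuple[str, str], float],
    seed: int = 0,
    rt_window: float = 3.0,
) -> tuple[pd.DataFrame, PeakGroupScorer]:
    """Full scoring pass: detect, subscore, train, and q-value an experiment."""
    candidates = collect_candidates(lib, chroms, predicted_rts, rt_window=rt_window)
    return score_candidates(candidates, seed=seed)
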