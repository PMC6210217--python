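"""Isolation-scheme construction, XIC extraction, and peak-group detection.

DIA acquires MS2 spectra over a fixed ladder of precursor isolation windows;
quantitation happens post hoc by extracting per-transition ion chromatograms
(XICs) and detecting candidate chromatographic peak groups near the retention
time predicted from the iRT calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import AssayLibrary, Transition, ValidationError

XIC_TOL = 0.035  # Th, reuses the library m/z-matching tolerance


class ParameterError(ValueError):
    pass


class AssignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# isolation scheme


@dataclass(frozen=True)
class IsolationScheme:
    windows: tuple[tuple[float, float], ...]
    width: float
    edge_overlap: float


def build_isolation_scheme(
    range_low: float, range_high: float, width: float, edge_overlap: float
) -> IsolationScheme:
    """Ladder of fixed-width windows with ``edge_overlap`` Th shared per edge.

    The effective step is ``width − 2·edge_overlap``; enough windows are laid
    down to cover the full precursor range.
    """
    if range_high <= range_low:
        raise ParameterError("range_high must exceed range_low")
    if width <= 2 * edge_overlap:
        raise ParameterError("width must exceed twice the edge overlap")
    step = width - 2 * edge_overlap
    n = math.ceil((range_high - range_low) / step)
    windows = tuple(
        (range_low - edge_overlap + i * step, range_low - edge_overlap + i * step + width)
        for i in range(n)
    )
    return IsolationScheme(windows=windows, width=width, edge_overlap=edge_overlap)


def assign_window(scheme: IsolationScheme, precursor_mz: float) -> int:
    """Index of the window whose center is nearest; ties take the lower index."""
    lo = scheme.windows[0][0]
    hi = scheme.windows[-1][1]
    if not lo <= precursor_mz <= hi:
        raise AssignmentError(f"precursor m/z {precursor_mz} outside scheme range [{lo}, {hi}]")
    centers = np.array([(w[0] + w[1]) / 2 for w in scheme.windows])
    return int(np.argmin(np.abs(centers - precursor_mz)))


# ---------------------------------------------------------------------------
# chromatograms


@dataclass
class Chromatogram:
    """Per-transition time (minutes) / intensity trace."""

    transition: Transition | None
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValidationError("times and intensities must have equal length")
        if len(self.times) < 2:
            raise ValidationError("a chromatogram needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass
class PrecursorTraces:
    """All transition traces of one precursor in one sample on a shared grid."""

    precursor_key: str
    sample_id: str
    times: np.ndarray  # (n_t,)
    intensities: np.ndarray  # (n_transitions, n_t)
    transition_labels: list[str]


class ChromatogramSet:
    """Columnar per-transition time–intensity container for a whole run set."""

    def __init__(self):
        self._data: dict[tuple[str, str], PrecursorTraces] = {}

    def add(self, traces: PrecursorTraces) -> None:
        self._data[(traces.sample_id, traces.precursor_key)] = traces

    def get(self, sample_id: str, precursor_key: str) -> PrecursorTraces:
        return self._data[(sample_id, precursor_key)]

    def __contains__(self, key) -> bool:
        return key in self._data

    def __len__(self) -> int:
        return len(self._data)

    @property
    def sample_ids(self) -> list[str]:
        return sorted({s for s, _ in self._data})

    @property
    def precursor_keys(self) -> list[str]:
        return sorted({p for _, p in self._data})

    def items(self):
        return self._data.items()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sample, key), tr in sorted(self._data.items()):
            for ti, label in enumerate(tr.transition_labels):
                rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": sample,
                            "precursor": key,
                            "transition": label,
                            "time": tr.times,
                            "intensity": tr.intensities[ti],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        df = self.to_frame()
        df["time"] = df["time"].map(lambda v: f"{v:.4f}")
        df["intensity"] = df["intensity"].map(lambda v: f"{v:.4f}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChromatogramSet":
        out = cls()
        for (sample, key), grp in df.groupby(["sample_id", "precursor"], sort=False):
            labels = list(dict.fromkeys(grp["transition"]))
            first = grp[grp["transition"] == labels[0]]
            times = first["time"].to_numpy(dtype=float)
            inten = np.vstack(
                [grp[grp["transition"] == lab]["intensity"].to_numpy(dtype=float) for lab in labels]
            )
            out.add(PrecursorTraces(str(key), str(sample), times, inten, labels))
        return out

    @classmethod
    def read(cls, path) -> "ChromatogramSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def extract_xic(
    spectra_table: pd.DataFrame, transition: Transition, tol: float = XIC_TOL
) -> Chromatogram:
    """Sum, per time point, all peaks within ±tol of the transition m/z.

    ``spectra_table`` holds one window's centroided peaks as columns
    (rt, mz, intensity); times with no matching peak yield intensity 0.
    """
    if spectra_table.empty:
        raise ValidationError("empty window data: no spectra to extract from")
    times = np.unique(spectra_table["rt"].to_numpy(dtype=float))
    mz = spectra_table["mz"].to_numpy(dtype=float)
    sel = np.abs(mz - transition.mz) <= tol
    out = np.zeros(len(times))
    if sel.any():
        sub_rt = spectra_table["rt"].to_numpy(dtype=float)[sel]
        sub_int = spectra_table["intensity"].to_numpy(dtype=float)[sel]
        idx = np.searchsorted(times, sub_rt)
        np.add.at(out, idx, sub_int)
    return Chromatogram(transition=transition, times=times, intensities=out)


# ---------------------------------------------------------------------------
# peak groups


@dataclass
class PeakGroup:
    """A scored candidate chromatographic peak for one precursor in one sample."""

    precursor_key: str
    sample_id: str
    rt_apex: float
    boundaries: tuple[float, float]
    areas: np.ndarray  # per transition
    apexes: np.ndarray  # per transition apex intensity within boundaries
    fwhm: float
    sn: float
    subscores: dict = field(default_factory=dict)
    dotp: float = float("nan")
    discriminant_score: float = float("nan")
    qvalue: float = float("nan")


def _smooth(y: np.ndarray, window: int = 7, order: int = 2) -> np.ndarray:
    if len(y) < window:
        return y.copy()
    return savgol_filter(y, window_length=window, polyorder=order)


def _fwhm(times: np.ndarray, y: np.ndarray, apex_idx: int) -> float:
    """Full width at half maximum with linear interpolation at the crossings."""
    half = y[apex_idx] / 2.0
    lo = apex_idx
    while lo > 0 and y[lo] > half:
        lo -= 1
    hi = apex_idx
    while hi < len(y) - 1 and y[hi] > half:
        hi += 1
    t_lo = times[lo]
    if y[lo] <= half < y[lo + 1]:
        t_lo = np.interp(half, [y[lo], y[lo + 1]], [times[lo], times[lo + 1]])
    t_hi = times[hi]
    if y[hi] <= half < y[hi - 1]:
        t_hi = np.interp(half, [y[hi], y[hi - 1]], [times[hi], times[hi - 1]])
    return float(t_hi - t_lo)


def detect_peak_groups(
    traces: PrecursorTraces,
    predicted_rt: float,
    rt_window: float = 3.0,
    min_sn: float = 1.0,
    max_candidates: int = 10,
) -> list[PeakGroup]:
    """Candidate peak groups on the smoothed summed trace near the predicted RT.

    Local maxima of the Savitzky–Golay-smoothed summed trace inside
    ``predicted_rt ± rt_window`` become candidates; boundaries sit at the
    flanking minima or where the trace falls to 1% of the apex, whichever is
    nearer the apex.  Candidates are ordered by apex intensity and only those
    with signal-to-noise above ``min_sn`` (apex over median absolute intensity
    in the window) are kept.
    """
    times = traces.times
    if len(times) < 5:
        raise ValidationError("traces need at least 5 points for peak detection")
    total = traces.intensities.sum(axis=0)
    smooth = _smooth(total)
    in_window = np.abs(times - predicted_rt) <= rt_window
    if not in_window.any():
        return []
    baseline = float(np.median(np.abs(smooth[in_window])))
    noise = max(baseline, 1e-9)

    is_max = np.zeros(len(times), dtype=bool)
    is_max[1:-1] = (
        (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] > smooth[2:]) & (smooth[1:-1] > 0)
    )
    idxs = np.nonzero(is_max & in_window & (smooth > min_sn * noise))[0]
    candidates = sorted(
        ((float(smooth[i]), int(i), float(smooth[i] / noise)) for i in idxs), reverse=True
    )
    groups = []
    for apex_val, idx, sn in candidates[:max_candidates]:
        lo = idx
        floor = 0.01 * apex_val
        while lo > 0 and smooth[lo - 1] < smooth[lo] and smooth[lo - 1] > floor:
            lo -= 1
        hi = idx
        while hi < len(times) - 1 and smooth[hi + 1] < smooth[hi] and smooth[hi + 1] > floor:
            hi += 1
        if lo == idx or hi == idx:
            continue
        seg = slice(lo, hi + 1)
        areas = np.trapezoid(traces.intensities[:, seg], times[seg], axis=1)
        apexes = traces.intensities[:, seg].max(axis=1)
        groups.append(
            PeakGroup(
                precursor_key=traces.precursor_key,
                sample_id=traces.sample_id,
                rt_apex=float(times[idx]),
                boundaries=(float(times[lo]), float(times[hi])),
                areas=np.maximum(areas, 0.0),
                apexes=apexes,
                fwhm=_fwhm(times, smooth, idx),
                sn=float(sn),
            )
        )
    return groups


# ---------------------------------------------------------------------------
# QC report


@dataclass
class QCReport:
    """Per-sample mass-error and iRT-standard RT-deviation summaries."""

    ppm_errors: pd.DataFrame  # sample_id, transition, ppm
    irt_deviations: pd.DataFrame  # sample_id, irt, observed_rt, fitted_rt, deviation

    def ppm_summary(self) -> pd.DataFrame:
        g = self.ppm_errors.groupby("sample_id")["ppm"]
        return pd.DataFrame(
            {"median_ppm": g.median(), "max_abs_ppm": g.apply(lambda s: s.abs().max())}
        )


def qc_report(
    observed_mzs: pd.DataFrame,
    irt_observations: pd.DataFrame,
    irt_models: dict,
) -> QCReport:
    """Fig-1-style QC: ppm mass errors and iRT-standard RT reproducibility.

    ``observed_mzs`` columns: sample_id, transition, observed_mz, theoretical_mz.
    ``irt_observations`` columns: sample_id, irt, observed_rt.
    ``irt_models`` maps sample_id to a fitted iRT→RT model with ``predict``.
    """
    ppm = observed_mzs.copy()
    ppm["ppm"] = 1e6 * (ppm["observed_mz"] - ppm["theoretical_mz"]) / ppm["theoretical_mz"]
    dev = irt_observations.copy()
    fitted = [
        float(irt_models[s].predict(np.array([[v]]))[0])
        for s, v in zip(dev["sample_id"], dev["irt"])
    ]
    dev["fitted_rt"] = fitted
    dev["deviation"] = dev["observed_rt"] - dev["fitted_rt"]
    return QCReport(
        ppm_errors=ppm[["sample_id", "transition", "ppm"]],
        irt_deviations=dev[["sample_id", "irt", "observed_rt", "fitted_rt", "deviation"]],
    )


def library_window_assignments(lib: AssayLibrary, scheme: IsolationScheme) -> dict[str, int]:
    return {p.key_str: assign_window(scheme, p.mz) for p in lib.precursors}
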