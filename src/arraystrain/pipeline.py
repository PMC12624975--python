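"""Recording-to-metric pipeline for multielectrode arrays.

Stages, in the order they run on a recording session:

1. impedance screening (coating-specific thresholds; strictly-above
   excluded),
2. 300-5000 Hz 2nd-order Butterworth bandpass (zero-phase by default),
3. threshold crossing detection at mean - 4.5 x RMS with a 1 ms lockout,
   snippet extraction 0.5 ms before / 1 ms after the crossing,
4. representative PTPV = mean of the largest 2% of snippet peak-to-peak
   voltages, noise floor = 2 x SD of the trace with snippets excised,
   SNR = PTPV / noise floor,
5. neighbor correlation: mean Pearson correlation of the filtered trace
   with its 3-8 Moore neighbors,
6. eMUA (envelope multi-unit activity): 500-5000 Hz bandpass, full-wave
   rectification, 200 Hz low-pass, resampled to 1 kHz; evoked SNR =
   (peak trial-averaged eMUA in the stimulation window - mean baseline)
   / SD of baseline,
7. session averaging, then within-array min-max normalization to [0, 1]
   over functional electrodes only; session SD retained.

Nonfunctional electrodes and electrodes with no detected events propagate
as missing values (NaN), never as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal as sig

from .synth import IMPEDANCE_THRESHOLDS, RecordingSet

__all__ = [
    "SnippetSet",
    "impedance_screen",
    "bandpass",
    "detect_and_extract",
    "representative_ptpv",
    "noise_floor_snr",
    "neighbor_correlation",
    "emua",
    "evoked_snr",
    "normalize_and_aggregate",
    "session_metrics",
    "process_recording_set",
    "PRE_SAMPLES",
    "POST_SAMPLES",
]

PRE_SAMPLES = 15  # 0.5 ms at 30 kHz before the crossing (16 incl. crossing)
POST_SAMPLES = 30  # 1 ms after
LOCKOUT_SAMPLES = 30  # 1 ms


@dataclass
class SnippetSet:
    """Detected threshold-crossing events and their waveform snippets."""

    indices: np.ndarray  # event sample indices (crossing sample)
    snippets: np.ndarray  # (n_events, PRE+1+POST) uV
    ptpv: np.ndarray  # (n_events,) uV
    threshold: float  # uV

    @property
    def n_events(self) -> int:
        return len(self.indices)

    @property
    def window(self) -> tuple[int, int]:
        """Sample offsets (start, stop) of the snippet around the event."""
        return (-PRE_SAMPLES, POST_SAMPLES + 1)


def impedance_screen(impedances, coating: str = "sirof") -> np.ndarray:
    """Functional mask: True iff Z <= the coating threshold.

    Missing impedances (NaN) exclude the electrode with a warning.
    """
    if coating not in IMPEDANCE_THRESHOLDS:
        raise ValueError(f"unknown coating {coating!r}")
    z = np.asarray(impedances, dtype=float)
    thr = IMPEDANCE_THRESHOLDS[coating]
    missing = ~np.isfinite(z)
    if np.any(missing):
        warnings.warn(f"{int(missing.sum())} electrodes have no impedance "
                      "measurement; excluded", stacklevel=2)
    return np.where(missing, False, z <= thr)


def bandpass(trace: np.ndarray, fs: float = 30_000.0,
             low: float = 300.0, high: float = 5000.0, order: int = 2,
             zero_phase: bool = True) -> np.ndarray:
    """Butterworth bandpass; zero-phase (forward-backward) by default."""
    if fs <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper cutoff")
    sos = sig.butter(order, [low, high], btype="bandpass", fs=fs,
                     output="sos")
    trace = np.asarray(trace, dtype=float)
    min_len = 12 * order
    if trace.shape[-1] <= min_len:
        raise ValueError("trace shorter than the filter warm-up length")
    if zero_phase:
        return sig.sosfiltfilt(sos, trace, axis=-1)
    return sig.sosfilt(sos, trace, axis=-1)


def detect_and_extract(filtered: np.ndarray) -> SnippetSet:
    """Negative threshold crossings at mean - 4.5 RMS, with 1 ms lockout.

    Snippets clipped at the trace edges are discarded.  Empty sets are
    allowed.
    """
    x = np.asarray(filtered, dtype=float)
    rms = float(np.sqrt(np.mean(x**2)))
    thr = float(np.mean(x)) - 4.5 * rms
    below = x < thr
    crossings = np.where(below[1:] & ~below[:-1])[0] + 1
    events = []
    last = -np.inf
    for c in crossings:
        if c - last >= LOCKOUT_SAMPLES:
            events.append(c)
            last = c
    events = [c for c in events
              if c - PRE_SAMPLES >= 0 and c + POST_SAMPLES < len(x)]
    idx = np.asarray(events, dtype=int)
    if len(idx) == 0:
        return SnippetSet(indices=idx, snippets=np.empty((0, PRE_SAMPLES + POST_SAMPLES + 1)),
                          ptpv=np.empty(0), threshold=thr)
    offs = np.arange(-PRE_SAMPLES, POST_SAMPLES + 1)
    snips = x[idx[:, None] + offs[None, :]]
    ptpv = snips.max(axis=1) - snips.min(axis=1)
    return SnippetSet(indices=idx, snippets=snips, ptpv=ptpv, threshold=thr)


def representative_ptpv(snippets: SnippetSet) -> float:
    """Mean of the largest 2% of snippet PTPVs (at least one snippet).

    NaN for an empty snippet set (electrode carries no value, not zero).
    """
    if snippets.n_events == 0:
        return np.nan
    k = max(1, int(np.ceil(0.02 * snippets.n_events)))
    top = np.sort(snippets.ptpv)[-k:]
    return float(np.mean(top))


def noise_floor_snr(filtered: np.ndarray, snippets: SnippetSet
                    ) -> tuple[float, float]:
    """Noise floor (2 x SD with snippet windows excised) and SNR."""
    x = np.asarray(filtered, dtype=float)
    keep = np.ones(len(x), dtype=bool)
    for c in snippets.indices:
        keep[max(0, c - PRE_SAMPLES): c + POST_SAMPLES + 1] = False
    if not np.any(keep):
        raise ValueError("snippets cover the entire trace")
    nf = 2.0 * float(np.std(x[keep]))
    ptpv = representative_ptpv(snippets)
    snr = ptpv / nf if np.isfinite(ptpv) and nf > 0 else np.nan
    return nf, snr


def neighbor_correlation(filtered_block: np.ndarray,
                         neighbors: list[list[int]],
                         connected: np.ndarray | None = None) -> np.ndarray:
    """Per-electrode mean Pearson correlation with its connected neighbors.

    ``filtered_block`` is (n_electrodes, n_samples) already bandpassed.
    Electrodes with no connected neighbors (or unconnected themselves)
    get NaN.
    """
    x = np.asarray(filtered_block, dtype=float)
    n = x.shape[0]
    if connected is None:
        connected = np.ones(n, dtype=bool)
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.sum(xc**2, axis=1))
    out = np.full(n, np.nan)
    for e in range(n):
        if not connected[e]:
            continue
        nbrs = [j for j in neighbors[e] if connected[j]]
        if not nbrs:
            continue
        r = [float(xc[e] @ xc[j] / (norm[e] * norm[j])) for j in nbrs
             if norm[e] > 0 and norm[j] > 0]
        if r:
            out[e] = np.mean(r)
    return out


def emua(raw: np.ndarray, fs: float = 30_000.0,
         band: tuple = (500.0, 5000.0), lowpass: float = 200.0,
         out_fs: float = 1000.0, order: int = 2) -> np.ndarray:
    """Envelope multi-unit activity: bandpass, rectify, low-pass, resample.

    Works on the raw wideband trace; all four parameters are configurable.
    """
    x = bandpass(raw, fs=fs, low=band[0], high=band[1], order=order)
    x = np.abs(x)
    sos = sig.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    x = sig.sosfiltfilt(sos, x, axis=-1)
    step = int(round(fs / out_fs))
    return x[..., ::step]


def evoked_snr(emua_trials: np.ndarray, baseline_window: tuple,
               stim_window: tuple, fs: float = 1000.0) -> float:
    """(peak trial-averaged stimulation eMUA - mean baseline) / SD baseline.

    ``emua_trials`` is (n_trials, n_samples_per_trial) at the eMUA rate.
    """
    x = np.asarray(emua_trials, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    b0, b1 = (int(round(t * fs)) for t in baseline_window)
    s0, s1 = (int(round(t * fs)) for t in stim_window)
    base = x[:, b0:b1]
    mu, sd = float(base.mean()), float(base.std())
    if sd == 0:
        raise ValueError("zero baseline standard deviation")
    avg = x[:, s0:s1].mean(axis=0)
    return (float(avg.max()) - mu) / sd


def _minmax_normalize(values: np.ndarray) -> np.ndarray:
    """x' = (x - min) / max(x - min) over finite entries; NaN preserved.

    Degenerate (all-constant) input maps to zeros with a warning.
    """
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    ok = np.isfinite(v)
    if not np.any(ok):
        return out
    shifted = v[ok] - v[ok].min()
    denom = shifted.max()
    if denom <= 0:
        warnings.warn("degenerate normalization: all values equal",
                      stacklevel=3)
        out[ok] = 0.0
    else:
        out[ok] = shifted / denom
    return out


def session_metrics(rec: RecordingSet, impedances, layout,
                    coating: str = "sirof",
                    zero_phase: bool = True) -> pd.DataFrame:
    """Per-electrode, per-session metric table for one recording set.

    Columns: electrode_id, session, impedance, functional, ptpv,
    noise_floor, snr, neighbor_corr, evoked_snr (NaN without trials).
    Nonfunctional or unconnected electrodes carry NaN metrics.
    """
    imp = np.asarray(impedances, dtype=float)
    functional = impedance_screen(imp, coating)
    connected = layout.table["connected"].to_numpy()
    active = functional & connected
    rows = []
    for k, block in enumerate(rec.data):
        filt = np.full(block.shape, np.nan)
        filt[active] = bandpass(block[active], fs=rec.fs,
                                zero_phase=zero_phase)
        ncorr = neighbor_correlation(np.nan_to_num(filt), layout.neighbors,
                                     connected=active)
        for e in range(block.shape[0]):
            row = {"electrode_id": e, "session": k, "impedance": imp[e],
                   "functional": bool(functional[e]),
                   "connected": bool(connected[e]),
                   "ptpv": np.nan, "noise_floor": np.nan, "snr": np.nan,
                   "neighbor_corr": np.nan, "evoked_snr": np.nan}
            if active[e]:
                snips = detect_and_extract(filt[e])
                row["ptpv"] = representative_ptpv(snips)
                if snips.n_events > 0:
                    nf, snr = noise_floor_snr(filt[e], snips)
                    row["noise_floor"], row["snr"] = nf, snr
                else:
                    row["noise_floor"] = 2.0 * float(np.std(filt[e]))
                row["neighbor_corr"] = ncorr[e]
                if rec.n_trials >= 2:
                    n_ts = int(round(rec.trial_length_s * rec.fs))
                    env = emua(block[e].astype(float), fs=rec.fs)
                    out_fs = 1000.0
                    n_te = int(round(rec.trial_length_s * out_fs))
                    env = env[: rec.n_trials * n_te].reshape(
                        rec.n_trials, n_te)
                    row["evoked_snr"] = evoked_snr(
                        env, rec.baseline_window, rec.stim_window, fs=out_fs)
            rows.append(row)
    return pd.DataFrame(rows)


def normalize_and_aggregate(per_session: pd.DataFrame,
                            metrics: tuple = ("impedance", "ptpv", "snr",
                                              "neighbor_corr", "evoked_snr")
                            ) -> pd.DataFrame:
    """Session-average then min-max normalize within the array.

    Nonfunctional/unconnected electrodes are removed before averaging and
    normalization (they never influence the min/max).  Returns one row per
    electrode with ``<m>_mean``, ``<m>_norm`` and ``<m>_session_sd``.
    """
    df = per_session
    keep = df["functional"] & df["connected"]
    out = pd.DataFrame({
        "electrode_id": np.sort(df["electrode_id"].unique())})
    out["functional"] = out["electrode_id"].map(
        df.groupby("electrode_id")["functional"].first())
    out["connected"] = out["electrode_id"].map(
        df.groupby("electrode_id")["connected"].first())
    active = df[keep]
    for m in metrics:
        if m not in df.columns:
            continue
        g = active.groupby("electrode_id")[m]
        mean = out["electrode_id"].map(g.mean())
        sd = out["electrode_id"].map(g.std())
        out[f"{m}_mean"] = mean
        out[f"{m}_session_sd"] = sd
        out[f"{m}_norm"] = _minmax_normalize(mean.to_numpy())
    return out


def process_recording_set(rec: RecordingSet, impedances, layout,
                          coating: str = "sirof") -> tuple[pd.DataFrame,
                                                           pd.DataFrame]:
    """Full pipeline: (per-session table, epoch-normalized table)."""
    per_session = session_metrics(rec, impedances, layout, coating=coating)
    return per_session, normalize_and_aggregate(per_session)
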