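"""Single-trial alpha-band envelope estimation.

The procedure mirrors the classic amplitude-envelope recipe for
attention studies: broad-band baseline subtraction, 8-13 Hz band-pass,
full-wave rectification, trimming of 200 ms filter warm-up at each epoch
edge, and smoothing by averaging inside a 100 ms window advancing in
50 ms steps. "Alpha power" throughout this package means this rectified,
smoothed amplitude envelope in microvolts (never its square).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .containers import AlphaSeries, EpochSet
from .montage import contralateral, hemisphere_of


def baseline_epochs(epochs: EpochSet,
                    window_ms: tuple[float, float] = (-100.0, 0.0)
                    ) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window_ms``.

    The window is half-open [lo, hi). Applying the operation twice is a
    no-op on the voltages since the window mean is already zero.
    """
    times = epochs.times_ms
    lo, hi = window_ms
    mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
    if not mask.any() or lo < times[0] - 1e-9 or hi > times[-1] + 1e-6:
        raise ValueError(f"baseline window {window_ms} outside epoch")
    means = epochs.voltages[:, :, mask].mean(axis=2, keepdims=True)
    out = epochs.copy()
    out.voltages = (epochs.voltages - means).astype(epochs.voltages.dtype)
    out.baseline_window_ms = (float(lo), float(hi))
    return out


def bandpass_alpha(epochs: EpochSet,
                   band: tuple[float, float] = (8.0, 13.0),
                   order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass to the alpha range.

    A 4th-order Butterworth applied forward and backward (zero net
    phase); edge transients are absorbed by the 200 ms trim downstream.
    """
    lo, hi = band
    nyq = epochs.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError("band edges must satisfy 0 < low < high")
    if hi >= nyq:
        raise ValueError("band high edge must be below Nyquist")
    sos = butter(order, [lo, hi], btype="bandpass", fs=epochs.fs,
                 output="sos")
    out = epochs.copy()
    out.voltages = sosfiltfilt(sos, epochs.voltages, axis=2).astype(
        epochs.voltages.dtype)
    return out


def lowpass_broadband(epochs: EpochSet, cutoff_hz: float = 35.0,
                      order: int = 4) -> EpochSet:
    """Broad-band 35 Hz low-pass (preprocessing for recorded data; the
    synthetic path generates band-limited signals and does not need it)."""
    if cutoff_hz >= epochs.fs / 2.0:
        raise ValueError("cutoff must be below Nyquist")
    sos = butter(order, cutoff_hz, btype="lowpass", fs=epochs.fs,
                 output="sos")
    out = epochs.copy()
    out.voltages = sosfiltfilt(sos, epochs.voltages, axis=2).astype(
        epochs.voltages.dtype)
    return out


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous average over channels."""
    out = epochs.copy()
    out.voltages = (epochs.voltages
                    - epochs.voltages.mean(axis=1, keepdims=True)
                    ).astype(epochs.voltages.dtype)
    return out


def alpha_envelope(filtered: EpochSet, trim_ms: float = 200.0,
                   win_ms: float = 100.0, step_ms: float = 50.0
                   ) -> AlphaSeries:
    """Rectify, trim the epoch edges, and smooth with a moving average.

    Samples are rectified (absolute value), ``trim_ms`` is dropped from
    each end of the epoch, and means are taken over half-open windows
    [t, t + win) advancing by ``step_ms``; a window contributes only if
    it lies fully inside the trimmed support. Grid times are window
    centres.
    """
    times = filtered.times_ms
    dur = times[-1] - times[0] + 1000.0 / filtered.fs
    if dur <= 2 * trim_ms + win_ms:
        raise ValueError("epoch too short for the requested trim/window")
    rect = np.abs(filtered.voltages)
    t_lo = times[0] + trim_ms
    t_hi = times[-1] + 1000.0 / filtered.fs - trim_ms  # exclusive edge
    win_n = int(round(win_ms * filtered.fs / 1000.0))
    step_n = int(round(step_ms * filtered.fs / 1000.0))
    starts = []
    t0 = t_lo
    while t0 + win_ms <= t_hi + 1e-9:
        starts.append(t0)
        t0 += step_ms
    idx0 = np.round((np.asarray(starts) - times[0])
                    * filtered.fs / 1000.0).astype(int)
    acc_dtype = (np.float32 if rect.dtype == np.float32 else np.float64)
    csum = np.cumsum(rect, axis=2, dtype=acc_dtype)
    csum = np.concatenate([np.zeros_like(csum[:, :, :1]), csum], axis=2)
    values = np.stack(
        [(csum[:, :, i + win_n] - csum[:, :, i]) / win_n for i in idx0],
        axis=2)
    grid = np.asarray(starts) + win_ms / 2.0
    return AlphaSeries(values=values.astype(np.float32),
                       grid_times_ms=grid,
                       channel_labels=list(filtered.channel_labels),
                       win_ms=win_ms)


def pretarget_alpha(series: AlphaSeries,
                    electrodes: dict[str, list[str]],
                    window_ms: tuple[float, float] = (-500.0, 0.0)
                    ) -> pd.DataFrame:
    """Per-trial pre-target alpha summaries over hemisphere pools.

    ``electrodes`` maps 'left'/'right' to label lists (the per-session
    selections). Returns columns alpha_left, alpha_right, alpha_pooled
    (all selected electrodes of both hemispheres together) and their
    natural logs.
    """
    mask = series.window_mask(window_ms)
    idx = {h: [series.channel_index(lab) for lab in labs]
           for h, labs in electrodes.items()}
    if set(idx) != {"left", "right"}:
        raise ValueError("electrodes must map exactly 'left' and 'right'")
    out = {}
    for h in ("left", "right"):
        out[f"alpha_{h}"] = series.values[:, idx[h], :][:, :, mask].mean(
            axis=(1, 2))
    both = idx["left"] + idx["right"]
    out["alpha_pooled"] = series.values[:, both, :][:, :, mask].mean(
        axis=(1, 2))
    df = pd.DataFrame(out)
    for col in ("alpha_left", "alpha_right", "alpha_pooled"):
        vals = df[col].to_numpy()
        if (vals <= 0).any():
            raise ValueError(f"non-positive envelope in {col}; "
                             "log transform undefined")
        df["log_" + col] = np.log(vals)
    df.attrs["window_ms"] = tuple(window_ms)
    return df


def posttarget_desync(series: AlphaSeries, trials: pd.DataFrame,
                      electrodes: list[str],
                      window_ms: tuple[float, float] = (50.0, 600.0),
                      reference_ms: tuple[float, float] = (-500.0, 0.0)
                      ) -> pd.DataFrame:
    """Post-target desynchronisation per lateral electrode.

    For each electrode, trials are split by whether the target hemifield
    is contralateral or ipsilateral to the electrode's hemisphere.
    Desynchronisation is the mean envelope in ``window_ms`` minus the
    mean pre-target envelope in ``reference_ms``, computed on the
    trial-averaged waveform of each split. Returns one row per electrode
    with contra, ipsi and their difference (contra - ipsi); strongly
    negative differences mark attention-sensitive electrodes.
    """
    if len(trials) != series.values.shape[0]:
        raise ValueError("trials and series differ in trial count")
    post = series.window_mask(window_ms)
    pre = series.window_mask(reference_ms)
    hemifield = trials["hemifield"].to_numpy()
    rows = []
    for lab in electrodes:
        hemi = hemisphere_of(lab)
        if hemi is None:
            raise ValueError(f"electrode {lab} is midline; hemisphere "
                             "undefined for desynchronisation")
        ci = series.channel_index(lab)
        vals = {}
        for split in ("contra", "ipsi"):
            if split == "contra":
                sel = np.array([contralateral(hf) == hemi
                                for hf in hemifield])
            else:
                sel = np.array([contralateral(hf) != hemi
                                for hf in hemifield])
            if not sel.any():
                raise ValueError(f"no {split}lateral trials for {lab}")
            wave = series.values[sel, ci, :].mean(axis=0)
            vals[split] = wave[post].mean() - wave[pre].mean()
        rows.append({"electrode": lab, "hemisphere": hemi,
                     "contra": vals["contra"], "ipsi": vals["ipsi"],
                     "difference": vals["contra"] - vals["ipsi"]})
    return pd.DataFrame(rows)
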