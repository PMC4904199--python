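"""Trial exclusion rules, transforms and the outlier policy.

Rules applied, in fixed order: response-time bounds (200-1000 ms),
voltage-artifact screens on the broad-band epochs (+/-100 uV in the
purpose-specific window), log transform of alpha summaries, then a
single-pass 3-SD outlier screen on the model's dependent variable
within participant x condition cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet

RT_BOUNDS_MS = (200.0, 1000.0)
ARTIFACT_UV = 100.0


@dataclass
class FilterReport:
    """Per-rule exclusion counts for one table of trials."""

    n_input: int
    no_response: int = 0
    rt_low: int = 0
    rt_high: int = 0
    artifact_pretarget: int = 0
    artifact_desync_window: int = 0
    alpha_outlier: int = 0
    rt_outlier: int = 0
    surviving: int = 0
    rule_order: tuple[str, ...] = (
        "rt", "artifact", "transform", "outlier")

    @property
    def removed(self) -> int:
        return (self.no_response + self.rt_low + self.rt_high
                + self.artifact_pretarget + self.artifact_desync_window
                + self.alpha_outlier + self.rt_outlier)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input, "no_response": self.no_response,
            "rt_low": self.rt_low, "rt_high": self.rt_high,
            "artifact_pretarget": self.artifact_pretarget,
            "artifact_desync_window": self.artifact_desync_window,
            "alpha_outlier": self.alpha_outlier,
            "rt_outlier": self.rt_outlier,
            "surviving": self.surviving,
            "rule_order": list(self.rule_order),
        }


def artifact_mask(epochs: EpochSet, trials: pd.DataFrame, purpose: str,
                  threshold_uv: float = ARTIFACT_UV) -> np.ndarray:
    """True where a trial's broad-band voltage exceeds the screen.

    ``purpose='pretarget'`` scans -500..0 ms on every channel;
    ``purpose='desync'`` scans -100 ms to RT + 100 ms (trials without a
    response use the full post-target extent).
    """
    if purpose not in ("pretarget", "desync"):
        raise ValueError(f"unknown screening purpose {purpose!r}")
    times = epochs.times_ms
    absmax = np.abs(epochs.voltages)
    if purpose == "pretarget":
        win = (times >= -500.0 - 1e-9) & (times < 0.0 - 1e-9)
        return (absmax[:, :, win] > threshold_uv).any(axis=(1, 2))
    rt = trials["rt_ms"].to_numpy(float)
    rt = np.where(np.isfinite(rt), rt, times[-1] - 100.0)
    bad = np.zeros(epochs.n_trials, dtype=bool)
    for i in range(epochs.n_trials):
        win = (times >= -100.0 - 1e-9) & (times <= rt[i] + 100.0 + 1e-9)
        bad[i] = (absmax[i, :, win] > threshold_uv).any()
    return bad


def filter_trials(trials: pd.DataFrame, epochs: EpochSet | None,
                  purpose: str = "pretarget",
                  rt_bounds_ms: tuple[float, float] = RT_BOUNDS_MS,
                  threshold_uv: float = ARTIFACT_UV
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the response-time and voltage-artifact rules.

    ``epochs`` may be None when only behavioural rules are wanted (no
    artifact screen possible). Returns the surviving trials plus a
    report; the input row order is preserved.
    """
    if purpose not in ("pretarget", "desync"):
        raise ValueError(f"unknown screening purpose {purpose!r}")
    if epochs is not None and len(trials) != epochs.n_trials:
        raise ValueError("trials and epochs are misaligned")
    report = FilterReport(n_input=len(trials))
    rt = trials["rt_ms"].to_numpy(float)
    responded = trials["responded"].to_numpy(bool)
    lo, hi = rt_bounds_ms
    miss = ~responded
    rt_low = responded & (rt < lo)
    rt_high = responded & (rt > hi)
    keep = ~(miss | rt_low | rt_high)
    report.no_response = int(miss.sum())
    report.rt_low = int(rt_low.sum())
    report.rt_high = int(rt_high.sum())
    if epochs is not None:
        bad = artifact_mask(epochs, trials, purpose, threshold_uv)
        newly = bad & keep
        if purpose == "pretarget":
            report.artifact_pretarget = int(newly.sum())
        else:
            report.artifact_desync_window = int(newly.sum())
        keep &= ~bad
    report.surviving = int(keep.sum())
    return trials.loc[keep].copy(), report


def transform_alpha(values: np.ndarray | pd.Series) -> np.ndarray:
    """Natural log of envelope values (positively skewed to near-normal)."""
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(f"non-positive alpha at trial index {bad[0]}; "
                         "log transform undefined")
    return np.log(arr)


def remove_outliers(data: pd.DataFrame, value_col: str,
                    group_cols: list[str], k: float = 3.0
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Single-pass k-SD screen within grouping cells.

    Observations farther than ``k`` group SDs from their group mean are
    dropped. Degenerate groups (SD 0, e.g. all-equal values) remove
    nothing. Returns the kept rows and the positional indices removed.
    """
    sizes = data.groupby(group_cols, observed=True)[value_col].transform(
        "size")
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 observations")
    g = data.groupby(group_cols, observed=True)[value_col]
    mean = g.transform("mean")
    sd = g.transform("std")
    vals = data[value_col]
    out = (sd > 0) & ((vals - mean).abs() > k * sd)
    removed = np.flatnonzero(out.to_numpy())
    return data.loc[~out].copy(), removed
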