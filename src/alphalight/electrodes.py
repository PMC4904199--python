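"""Data-driven electrode selection and condition-difference topographies.

Covert attention shifts suppress the alpha envelope over the hemisphere
contralateral to the attended hemifield. Per session and hemisphere, the
four lateral parieto-occipital electrodes showing the strongest
contralateral-versus-ipsilateral post-target desynchronisation are
selected from a fixed pool of eight candidates, individualising the
sensors that feed the pre-target alpha summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .montage import CANDIDATES


@dataclass(frozen=True)
class SelectionResult:
    """Chosen electrodes and the selection metric for all candidates."""

    session_id: str
    chosen: dict[str, list[str]]
    metrics: dict[str, dict[str, float]]
    criterion: str = "signed"

    def to_dict(self) -> dict:
        return {"session_id": self.session_id, "chosen": self.chosen,
                "metrics": self.metrics, "criterion": self.criterion}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(session_id=d["session_id"], chosen=d["chosen"],
                   metrics=d["metrics"], criterion=d["criterion"])


def select_electrodes(desync_table: pd.DataFrame,
                      pools: dict[str, list[str]] | None = None,
                      k: int = 4, session_id: str = "",
                      criterion: str = "signed") -> SelectionResult:
    """Pick the ``k`` most attention-sensitive electrodes per hemisphere.

    ``desync_table`` is the per-electrode output of
    :func:`alphalight.alphapower.posttarget_desync`. With the default
    signed criterion, candidates are ranked by the contralateral minus
    ipsilateral desynchronisation difference ascending, so the strongest
    contralateral suppression ranks first; ``criterion='magnitude'``
    ranks by absolute difference descending instead. Ties break by
    candidate-list order, making the selection deterministic and
    invariant to input row order.
    """
    pools = pools if pools is not None else CANDIDATES
    rows = desync_table.set_index("electrode")["difference"]
    chosen: dict[str, list[str]] = {}
    metrics: dict[str, dict[str, float]] = {}
    for hemi, cands in pools.items():
        if k > len(cands):
            raise ValueError(f"k={k} exceeds pool size {len(cands)}")
        missing = [c for c in cands if c not in rows.index]
        if missing:
            raise ValueError(f"desync table missing candidates: {missing}")
        metrics[hemi] = {c: float(rows[c]) for c in cands}
        if criterion == "signed":
            order = sorted(range(len(cands)),
                           key=lambda i: (rows[cands[i]], i))
        elif criterion == "magnitude":
            order = sorted(range(len(cands)),
                           key=lambda i: (-abs(rows[cands[i]]), i))
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        chosen[hemi] = [cands[i] for i in order[:k]]
    return SelectionResult(session_id=session_id, chosen=chosen,
                           metrics=metrics, criterion=criterion)


def save_topography(topography: pd.Series, path: str | Path) -> None:
    """Write a per-channel map as two-column CSV (channel, value)."""
    topography.rename_axis("channel").rename("value").to_csv(path)


def cumulative_light_topography(low: pd.Series, medium: pd.Series,
                                high: pd.Series) -> pd.Series:
    """Cumulative change in alpha across light levels, per channel:
    (High-Low) + (High-Medium) + (Medium-Low), which algebraically
    equals 2*(High-Low)."""
    for other in (medium, high):
        if not low.index.equals(other.index):
            raise ValueError("condition maps must share one channel set")
    return (high - low) + (high - medium) + (medium - low)
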