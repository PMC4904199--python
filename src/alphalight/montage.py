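"""10-10 montage helpers: channel set, hemisphere lookup, candidate pools."""

from __future__ import annotations

import re

#: A standard 64-channel 10-10 cap (BrainProducts/easycap ordering). It
#: contains all 16 lateral parieto-occipital candidates used for
#: attention-sensitive electrode selection.
CHANNELS_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]

#: Lateral parieto-occipital candidate electrodes per hemisphere.
CANDIDATES = {
    "left": ["P1", "P3", "P5", "P7", "PO3", "PO7", "PO9", "O1"],
    "right": ["P2", "P4", "P6", "P8", "PO4", "PO8", "PO10", "O2"],
}

_NUM_RE = re.compile(r"(\d+)$")


def hemisphere_of(label: str) -> str | None:
    """Hemisphere of a 10-10 label: odd-numbered left, even right.

    Midline electrodes (z suffix, no trailing number) return None.
    """
    m = _NUM_RE.search(label)
    if m is None:
        return None
    return "left" if int(m.group(1)) % 2 == 1 else "right"


def contralateral(hemifield: str) -> str:
    """Hemisphere contralateral to a visual hemifield."""
    if hemifield == "left":
        return "right"
    if hemifield == "right":
        return "left"
    raise ValueError(f"unknown hemifield: {hemifield!r}")
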