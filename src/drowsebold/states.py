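"""Vigilance-state vocabulary shared across the pipeline.

The drowsigram stages each second of a recording into four states derived
from eyelid behaviour: ``awake``, ``likely_drowsy`` and ``drowsy`` come from
PERCLOS thresholds, ``microsleep`` from sustained eye closure. States are
stored as small integer codes; ``UNDEFINED`` marks seconds where no full
PERCLOS window (and no microsleep run) is available.
"""

from __future__ import annotations

import numpy as np

STATE_NAMES: tuple[str, ...] = ("awake", "likely_drowsy", "drowsy", "microsleep")

AWAKE, LIKELY_DROWSY, DROWSY, MICROSLEEP = range(4)
UNDEFINED = -1

STATE_CODES: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

#: Canonical seven functional-network labels (Yeo-style parcellation vocabulary).
NETWORK_NAMES: tuple[str, ...] = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)


def codes_to_names(codes: np.ndarray) -> np.ndarray:
    """Map integer state codes to their names; UNDEFINED maps to ``""``."""
    codes = np.asarray(codes)
    out = np.full(codes.shape, "", dtype=object)
    for name, code in STATE_CODES.items():
        out[codes == code] = name
    return out


def names_to_codes(names) -> np.ndarray:
    """Map state names to integer codes; empty/unknown strings map to UNDEFINED."""
    arr = np.asarray(names, dtype=object)
    out = np.full(arr.shape, UNDEFINED, dtype=np.int64)
    for name, code in STATE_CODES.items():
        out[arr == name] = code
    return out
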