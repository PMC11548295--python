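"""Brunnstrom stage labels and their integer encoding.

The Brunnstrom scale grades motor recovery after stroke on an ordinal
scale; the decision model targets stages I-V, encoded 0-4 in class
indices (stage VI / healthy can be enabled by passing ``n_classes=6``
downstream, but no default profile ships for it).
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("I", "II", "III", "IV", "V")

_STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES)}


def stage_index(stage: str) -> int:
    """Map a stage label ('I'..'V') to its class index (0..4)."""
    try:
        return _STAGE_TO_INDEX[stage]
    except KeyError:
        raise ValueError(f"unknown Brunnstrom stage {stage!r}; expected one of {STAGES}") from None


def stage_label(index: int) -> str:
    """Inverse of :func:`stage_index`."""
    if not 0 <= index < len(STAGES):
        raise ValueError(f"stage index {index} out of range 0..{len(STAGES) - 1}")
    return STAGES[index]
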