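"""Deterministic fan-out of one user seed into per-stage seeds.

Each stochastic stage gets ``(seed + 7919 * offset + counter) % 2**31``
with a fixed stage offset and an optional per-use counter.  The scheme is
recorded in the run manifest so any stage can be replayed in isolation.
"""

from __future__ import annotations

STAGE_OFFSETS = {
    "simulate": 0,
    "leiden": 1,
    "alpha": 2,
    "perm": 3,
}

_PRIME = 7919
_MOD = 2**31


def stage_seed(seed: int, stage: str, counter: int = 0) -> int:
    if stage not in STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    return (int(seed) + _PRIME * STAGE_OFFSETS[stage] + int(counter)) % _MOD
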