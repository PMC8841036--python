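"""Deterministic per-stage seed derivation from one global seed."""

from __future__ import annotations

import numpy as np

_STAGES = ("simulate", "rarefy", "permanova", "mantel", "rf", "network",
           "enrichment")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable sub-seed below 2**31, independent of stage call order."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
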