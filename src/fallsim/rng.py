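"""Common-random-number streams.

Paired strategy comparisons (usual care vs recommended care) must consume
*identical* randomness so that incremental outcomes reflect the strategies
and not sampling noise.  Each stochastic event in a cycle gets its own
Philox-keyed stream derived from ``(base_seed, event_code, cycle)``; a draw
of length n is aligned to individuals by row position, and the two
strategies hold identical row orderings because populations and entry
cohorts are synthesized from the same seed.  The strategy itself never
enters the key, so a parameter-identical pair of runs is bitwise identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EventRng", "EVENTS"]

EVENTS = (
    "entry",
    "gp_contact",
    "screening",
    "uptake",
    "self_referral",
    "mortality_other",
    "mortality_fatal_fall",
    "fall_any",
    "fall_recurrent",
    "fall_ma",
    "fall_second_ma",
    "fall_hosp_1",
    "fall_hosp_2",
    "ltc_admission",
)

_EVENT_CODE = {name: i for i, name in enumerate(EVENTS)}


class EventRng:
    """Stateless-by-key uniform streams for one simulation run."""

    def __init__(self, base_seed: int):
        self.base_seed = int(base_seed)

    def generator(self, event: str, cycle: int) -> np.random.Generator:
        code = _EVENT_CODE[event]
        seq = np.random.SeedSequence(
            entropy=self.base_seed, spawn_key=(code, int(cycle))
        )
        return np.random.Generator(np.random.Philox(seq))

    def uniforms(self, event: str, cycle: int, n: int) -> np.ndarray:
        """n uniforms on [0,1) for ``event`` in ``cycle``, row-aligned."""
        return self.generator(event, cycle).random(n)
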