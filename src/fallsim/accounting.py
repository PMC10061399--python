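"""Per-individual outcome accrual and discounting.

Every individual carries one row in an :class:`OutcomeLedger`: discounted
accumulators for each health, public-cost and societal stream, plus
undiscounted lifetime counters feeding the individual-level equity metrics.
Discounting is end-of-cycle: an amount accrued in cycle t (t = 1, 2, ...)
is multiplied by (1 + r)^-t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "discount_factor", "OutcomeLedger",
    "DISCOUNTED_STREAMS", "PUBLIC_COST_SUBFIELDS", "LIFETIME_COUNTERS",
    "EXIT_NONE", "EXIT_DEATH", "EXIT_LTC", "EXIT_HORIZON",
]

#: subfields partitioning all-cause public sector cost
PUBLIC_COST_SUBFIELDS = (
    "fall_healthcare", "comorbidity_care", "community_care",
    "social_care", "cost_of_dying", "public_ltc",
)

DISCOUNTED_STREAMS = PUBLIC_COST_SUBFIELDS + (
    "qaly", "wellbeing",
    "intervention_public_cost",
    "productivity_value", "participant_toc",
    "oop_expenditure", "co_payment",
    "informal_care_cost", "caregiver_toc",
)

LIFETIME_COUNTERS = (
    "lifetime_qaly", "lifetime_wellbeing", "work_years_since_65",
    "private_expenditure_cum", "private_expenditure_excl_copay_cum",
    "informal_care_value_cum", "caregiver_toc_cum",
)

EXIT_NONE, EXIT_DEATH, EXIT_LTC, EXIT_HORIZON = 0, 1, 2, 3


def discount_factor(rate: float, t: float) -> float:
    """Present-value factor (1 + rate)^-t for an amount accruing at year t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return float((1.0 + rate) ** (-t))


@dataclass
class OutcomeLedger:
    """Struct-of-arrays ledger, row-aligned with a Population."""

    arrays: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, n: int = 0) -> "OutcomeLedger":
        arrays = {name: np.zeros(n) for name in DISCOUNTED_STREAMS + LIFETIME_COUNTERS}
        arrays["exit_kind"] = np.zeros(n, dtype=np.int64)
        arrays["exit_cycle"] = np.zeros(n, dtype=np.int64)
        return cls(arrays)

    def __len__(self) -> int:
        return len(self.arrays["qaly"])

    def extend(self, n_new: int) -> None:
        """Append zeroed rows for a newly entering cohort."""
        for name, arr in self.arrays.items():
            self.arrays[name] = np.concatenate(
                [arr, np.zeros(n_new, dtype=arr.dtype)]
            )

    def add(self, stream: str, mask, amounts) -> None:
        """Accrue ``amounts`` (already discounted by the caller where the
        stream is a discounted one) on the rows selected by ``mask``."""
        self.arrays[stream][mask] += np.asarray(amounts)[mask] if (
            np.ndim(amounts) > 0
        ) else amounts

    @property
    def allcause_public_cost(self) -> np.ndarray:
        """All-cause public sector cost: exact sum of its subfields."""
        return sum(self.arrays[name] for name in PUBLIC_COST_SUBFIELDS)

    def mark_exit(self, mask, kind: int, cycle: int) -> None:
        already = self.arrays["exit_kind"][mask]
        if np.any(already != EXIT_NONE):
            raise RuntimeError("double finalization of exited individuals")
        self.arrays["exit_kind"][mask] = kind
        self.arrays["exit_cycle"][mask] = cycle

    def totals(self) -> dict[str, float]:
        out = {name: float(self.arrays[name].sum()) for name in DISCOUNTED_STREAMS}
        out["allcause_public_cost"] = float(self.allcause_public_cost.sum())
        for name in LIFETIME_COUNTERS:
            out[name] = float(self.arrays[name].sum())
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.arrays)
        df["allcause_public_cost"] = self.allcause_public_cost
        return df
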