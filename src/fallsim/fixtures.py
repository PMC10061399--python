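"""Printed worked-example fixtures.

Small CSV files keyed by (row, column) carry the published headline tables
of the full-scale evaluation — the 40-year societal cost-utility table (T2),
the individual-level lifetime outcome counts for the age-65 cohort (T3), the
SES-quartile DCEA table (T4) and the intervention-usage narrative (USAGE).
They drive worked-example tests and the acceptance recomputations: the
package's accounting/reporting arithmetic is applied to these printed inputs
and must reproduce the printed derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["PrintedFixture", "table_fixture", "FIXTURE_TABLES"]

FIXTURE_TABLES = {
    "T2": "t2_cua.csv",
    "T3": "t3_lifetime.csv",
    "T4": "t4_dcea.csv",
    "USAGE": "usage.csv",
}


@dataclass
class PrintedFixture:
    """Published values of one table, keyed by row and column labels."""

    table_id: str
    frame: pd.DataFrame

    def value(self, row: str, column: str = "value") -> float:
        match = self.frame[(self.frame["row"] == row) & (self.frame["column"] == column)]
        if match.empty:
            raise KeyError((self.table_id, row, column))
        return float(match["value"].iloc[0])

    def rows(self) -> list[str]:
        return list(dict.fromkeys(self.frame["row"]))


def table_fixture(table_id: str) -> PrintedFixture:
    """Load the printed fixture for ``table_id`` in {T2, T3, T4, USAGE}."""
    if table_id not in FIXTURE_TABLES:
        raise KeyError(f"unknown fixture table {table_id!r}")
    ref = resources.files("fallsim").joinpath("data", FIXTURE_TABLES[table_id])
    with ref.open() as fh:
        frame = pd.read_csv(fh)
    return PrintedFixture(table_id=table_id, frame=frame)
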