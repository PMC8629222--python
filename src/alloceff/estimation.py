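"""Population annualization, inflation adjustment, and spending estimation.

These are the bookkeeping steps that turn raw databook entries into
comparable annual quantities: eligible populations screened every *k*
years are divided by *k*; unit costs priced in one year are moved to the
analysis year with a deflator series; current spending is the bottom-up
product unit cost x target population x current coverage unless an
observed figure overrides it; and modelled totals are reconciled against
reported expenditure (e.g. National Health Accounts) program by program.

Reconciliation only *reports* discrepancies — it never rescales the
modelled numbers, because mismatches between bottom-up costing and
accounts data are resolved by analyst judgement, not by formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .databook import CountryDatabook, Intervention

__all__ = [
    "ReconciliationReport",
    "annualize_population",
    "adjust_unit_cost",
    "estimate_current_spend",
    "reconcile_spending",
]

#: Label under which interventions without a program are grouped.
UNASSIGNED_PROGRAM = "(unassigned)"

#: Default relative tolerance before a modelled/reported mismatch is flagged.
DEFAULT_RECONCILIATION_TOLERANCE = 0.25


def annualize_population(eligible: float, interval_years: float) -> float:
    """Convert a population eligible once per ``interval_years`` to persons/year.

    Example: if screening is recommended every three years, a pool of
    300,000 eligible individuals translates to 100,000 requiring the
    service in any one year.
    """
    if eligible < 0:
        raise ValueError(f"eligible population must be >= 0, got {eligible}")
    if not interval_years > 0:
        raise ValueError(f"interval_years must be > 0, got {interval_years}")
    return eligible / interval_years


def adjust_unit_cost(
    cost: float,
    from_year: int,
    to_year: int,
    deflators: Mapping[int, float],
) -> float:
    """Re-express ``cost`` from ``from_year`` prices in ``to_year`` prices.

    Uses the ratio of the supplied price indices:
    ``cost * deflators[to_year] / deflators[from_year]``.
    """
    for year in (from_year, to_year):
        if year not in deflators:
            raise ValueError(f"no deflator index for year {year}")
        if not deflators[year] > 0:
            raise ValueError(f"deflator index for year {year} must be > 0")
    return cost * deflators[to_year] / deflators[from_year]


def estimate_current_spend(iv: Intervention) -> float:
    """Current annual spending on one intervention.

    The observed figure ``current_spend_override`` takes precedence when
    present; otherwise spending is the bottom-up product
    unit_cost x target_population x current_coverage.
    """
    if iv.current_spend_override is not None:
        return iv.current_spend_override
    return iv.unit_cost * iv.target_population * iv.current_coverage


@dataclass
class ReconciliationReport:
    """Modelled vs reported expenditure, overall and per program.

    ``by_program`` maps program label to ``(modelled, reported, ratio)``;
    ``ratio`` is ``nan`` where reported spending is zero.  ``flagged``
    lists programs whose ratio departs from 1 by more than the tolerance.
    ``coverage_of_reported`` is the fraction of total reported expenditure
    that falls in programs represented in the databook.
    """

    total_modelled: float
    total_reported: float
    by_program: dict[str, tuple[float, float, float]]
    coverage_of_reported: float
    flagged: list[str]
    tolerance: float

    def to_frame(self) -> pd.DataFrame:
        """Render as a program,modelled,reported,ratio,flag table."""
        rows = [
            {
                "program": prog,
                "modelled": m,
                "reported": r,
                "ratio": ratio,
                "flag": prog in self.flagged,
            }
            for prog, (m, r, ratio) in sorted(self.by_program.items())
        ]
        return pd.DataFrame(rows, columns=["program", "modelled", "reported", "ratio", "flag"])


def reconcile_spending(
    db: CountryDatabook,
    tolerance: float = DEFAULT_RECONCILIATION_TOLERANCE,
) -> ReconciliationReport:
    """Compare bottom-up modelled spending against reported expenditure.

    Modelled spending per program is the sum of ``estimate_current_spend``
    over the program's interventions.  Programs whose modelled/reported
    ratio differs from 1 by more than ``tolerance`` (relative) are
    flagged, as are programs with modelled spending but zero or missing
    reported expenditure.
    """
    if db.reported_expenditure is None:
        raise ValueError("databook carries no reported_expenditure to reconcile against")

    modelled: dict[str, float] = {}
    for iv in db.interventions:
        prog = iv.program or UNASSIGNED_PROGRAM
        modelled[prog] = modelled.get(prog, 0.0) + estimate_current_spend(iv)

    reported = dict(db.reported_expenditure)
    by_program: dict[str, tuple[float, float, float]] = {}
    flagged: list[str] = []
    for prog in sorted(set(modelled) | set(reported)):
        m = modelled.get(prog, 0.0)
        r = reported.get(prog, 0.0)
        ratio = m / r if r > 0 else math.nan
        by_program[prog] = (m, r, ratio)
        if r > 0:
            if abs(ratio - 1.0) > tolerance:
                flagged.append(prog)
        elif m > 0:
            flagged.append(prog)

    total_reported = sum(reported.values())
    mapped_reported = sum(r for prog, r in reported.items() if prog in modelled)
    return ReconciliationReport(
        total_modelled=sum(modelled.values()),
        total_reported=total_reported,
        by_program=by_program,
        coverage_of_reported=mapped_reported / total_reported if total_reported > 0 else math.nan,
        flagged=flagged,
        tolerance=tolerance,
    )
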