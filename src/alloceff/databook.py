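"""Domain types and file I/O for country intervention databooks.

A *databook* is the tabular dataset of fundable health interventions a
country's benefits-package analysis runs on: one row per intervention with
its unit cost, incremental cost-effectiveness ratio (ICER, currency per
DALY averted), target population, current and maximum coverage, delivery
platform shares, care-package/program labels, financial-risk-protection
(FRP) and equity scores, an optional attributable disease burden, and
flags controlling how the optimizer may treat the line item.

On disk a databook is a flat CSV (one row per intervention) plus an
optional JSON metadata sidecar carrying the country label, currency year,
deflator series and reported program expenditure.  All coverages, shares
and scores are decimal fractions, never percentages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PLATFORMS",
    "Intervention",
    "CountryDatabook",
    "ValidationIssue",
    "DatabookSchemaError",
    "DatabookValidationError",
    "read_databook",
    "write_databook",
    "validate_databook",
]

#: Delivery platform labels, ordered from population-wide to tertiary care.
PLATFORMS = (
    "population",
    "community",
    "health_center",
    "first_level_hospital",
    "referral_hospital",
)

_SHARE_COLUMNS = tuple(f"share_{p}" for p in PLATFORMS)

REQUIRED_COLUMNS = (
    "id",
    "name",
    "care_package",
    "unit_cost",
    "icer",
    "target_population",
    "current_coverage",
) + _SHARE_COLUMNS

OPTIONAL_COLUMN_DEFAULTS = {
    "program": None,
    "max_coverage": 0.8,
    "frp_score": 0.0,
    "equity_score": 0.0,
    "attributable_burden": None,
    "fixed_spend": False,
    "current_spend_override": None,
}

#: Default scale-up target used when a databook does not state one.
DEFAULT_MAX_COVERAGE = 0.8

_SHARE_TOL = 1e-9


class DatabookSchemaError(ValueError):
    """Raised when a databook file lacks a required column."""


class DatabookValidationError(ValueError):
    """Raised when a databook violates a structural invariant."""

    def __init__(self, issues: list["ValidationIssue"]):
        self.issues = issues
        lines = "; ".join(str(i) for i in issues)
        super().__init__(f"databook failed validation ({len(issues)} issue(s)): {lines}")


@dataclass(frozen=True)
class ValidationIssue:
    """One invariant violation: which intervention, which field, which rule."""

    intervention_id: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.intervention_id}] {self.field}: {self.rule}"


@dataclass(frozen=True)
class Intervention:
    """One fundable line item in a health benefits package.

    Parameters
    ----------
    id:
        Short unique identifier.
    name:
        Free-text label.
    care_package:
        Care-package label (e.g. one of the 21 DCP3 packages) used for
        aggregation.
    unit_cost:
        Annual cost to deliver the intervention per person covered
        (currency / person / year), strictly positive.
    icer:
        Incremental cost-effectiveness ratio, currency per DALY averted,
        strictly positive.
    target_population:
        Persons in need or eligible per year.
    current_coverage, max_coverage:
        Fractions of the target population currently reached, and the
        scale-up target (default 0.8).
    platform_shares:
        Map platform label -> fraction of delivery; non-negative, sums
        to 1.
    frp_score, equity_score:
        Financial-risk-protection and equity scores, normalized to [0, 1].
    attributable_burden:
        Optional DALYs/year addressable by this intervention; caps its
        maximum potential impact.  ``None`` means no burden cap.
    fixed_spend:
        If true, spending is held at its current level and the line item
        is excluded from the optimization pool.
    current_spend_override:
        Observed spending (currency); when present it replaces the
        bottom-up product unit_cost x population x coverage.
    """

    id: str
    name: str
    care_package: str
    unit_cost: float
    icer: float
    target_population: float
    current_coverage: float
    platform_shares: Mapping[str, float]
    program: str | None = None
    max_coverage: float = DEFAULT_MAX_COVERAGE
    frp_score: float = 0.0
    equity_score: float = 0.0
    attributable_burden: float | None = None
    fixed_spend: bool = False
    current_spend_override: float | None = None

    def issues(self) -> list[ValidationIssue]:
        """Check every field invariant; return one issue per violation."""
        out: list[ValidationIssue] = []

        def bad(fieldname: str, rule: str) -> None:
            out.append(ValidationIssue(self.id, fieldname, rule))

        if not self.id:
            bad("id", "must be non-empty")
        if not self.unit_cost > 0:
            bad("unit_cost", "must be > 0")
        if not self.icer > 0:
            bad("icer", "must be > 0")
        if not self.target_population >= 0:
            bad("target_population", "must be >= 0")
        if not 0.0 <= self.current_coverage <= 1.0:
            bad("current_coverage", "must lie in [0, 1]")
        if not 0.0 <= self.max_coverage <= 1.0:
            bad("max_coverage", "must lie in [0, 1]")
        for score_name in ("frp_score", "equity_score"):
            v = getattr(self, score_name)
            if not 0.0 <= v <= 1.0:
                bad(score_name, "must lie in [0, 1]")
        if self.attributable_burden is not None and not self.attributable_burden >= 0:
            bad("attributable_burden", "must be >= 0 when present")
        if self.current_spend_override is not None and not self.current_spend_override >= 0:
            bad("current_spend_override", "must be >= 0 when present")

        unknown = set(self.platform_shares) - set(PLATFORMS)
        if unknown:
            bad("platform_shares", f"unknown platform(s): {sorted(unknown)}")
        if any(v < 0 for v in self.platform_shares.values()):
            bad("platform_shares", "shares must be >= 0")
        total = sum(self.platform_shares.values())
        if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=_SHARE_TOL):
            bad("platform_shares", f"shares sum to {total!r}, expected 1")
        return out


@dataclass
class CountryDatabook:
    """A country's full intervention portfolio plus monetary metadata.

    ``deflators`` map calendar year to a price index and drive inflation
    adjustment; ``reported_expenditure`` maps program label to observed
    spending and drives reconciliation against the bottom-up costing.
    """

    interventions: list[Intervention]
    name: str = "unnamed"
    currency_year: int | None = None
    deflators: dict[int, float] = field(default_factory=dict)
    reported_expenditure: dict[str, float] | None = None

    def __iter__(self) -> Iterable[Intervention]:
        return iter(self.interventions)

    def __len__(self) -> int:
        return len(self.interventions)

    def get(self, iv_id: str) -> Intervention:
        for iv in self.interventions:
            if iv.id == iv_id:
                return iv
        raise KeyError(iv_id)

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self.interventions]

    def replace_interventions(self, interventions: list[Intervention]) -> "CountryDatabook":
        """Copy of this databook with a different intervention list."""
        return CountryDatabook(
            interventions=list(interventions),
            name=self.name,
            currency_year=self.currency_year,
            deflators=dict(self.deflators),
            reported_expenditure=None
            if self.reported_expenditure is None
            else dict(self.reported_expenditure),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-intervention table in the documented CSV schema."""
        rows = []
        for iv in self.interventions:
            row: dict[str, object] = {
                "id": iv.id,
                "name": iv.name,
                "care_package": iv.care_package,
                "program": iv.program,
            }
            for p in PLATFORMS:
                row[f"share_{p}"] = iv.platform_shares.get(p, 0.0)
            row.update(
                unit_cost=iv.unit_cost,
                icer=iv.icer,
                target_population=iv.target_population,
                current_coverage=iv.current_coverage,
                max_coverage=iv.max_coverage,
                frp_score=iv.frp_score,
                equity_score=iv.equity_score,
                attributable_burden=iv.attributable_burden,
                fixed_spend=iv.fixed_spend,
                current_spend_override=iv.current_spend_override,
            )
            rows.append(row)
        columns = list(REQUIRED_COLUMNS[:3]) + ["program"] + list(_SHARE_COLUMNS) + [
            "unit_cost",
            "icer",
            "target_population",
            "current_coverage",
            "max_coverage",
            "frp_score",
            "equity_score",
            "attributable_burden",
            "fixed_spend",
            "current_spend_override",
        ]
        return pd.DataFrame(rows, columns=columns)


def validate_databook(db: CountryDatabook) -> list[ValidationIssue]:
    """Report every invariant violation in ``db`` (empty list == valid).

    Collects per-intervention field issues, duplicate ids, the requirement
    that at least one intervention is open to the optimizer, and that the
    deflator series (when present) covers the currency year.
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for iv in db.interventions:
        issues.extend(iv.issues())
        if iv.id in seen:
            issues.append(ValidationIssue(iv.id, "id", "duplicate id"))
        seen.add(iv.id)
    if not db.interventions:
        issues.append(ValidationIssue("<databook>", "interventions", "must contain at least one intervention"))
    elif all(iv.fixed_spend for iv in db.interventions):
        issues.append(
            ValidationIssue("<databook>", "interventions", "at least one intervention must not be fixed_spend")
        )
    if db.deflators and db.currency_year is not None and db.currency_year not in db.deflators:
        issues.append(
            ValidationIssue("<databook>", "deflators", f"missing index for currency_year {db.currency_year}")
        )
    return issues


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _normalize_scores(values: list[float]) -> list[float]:
    """Min-max rescale a score column to [0, 1] when it uses another scale.

    Scores already inside [0, 1] are left untouched so that files written
    by this package round-trip exactly.
    """
    if not values or (min(values) >= 0.0 and max(values) <= 1.0):
        return values
    lo, hi = min(values), max(values)
    if hi == lo:
        return [1.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def _parse_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f", ""}:
        return False
    raise DatabookSchemaError(f"cannot interpret {v!r} as a boolean fixed_spend flag")


def read_databook(path: str | Path) -> CountryDatabook:
    """Read and validate a databook CSV (plus its JSON sidecar if present).

    Missing optional columns are filled with the documented defaults
    (``max_coverage`` 0.8, zero FRP/equity scores, no fixed-spend flag).
    FRP and equity scores supplied on a non-[0,1] scale are min-max
    normalized at load.

    Raises
    ------
    DatabookSchemaError
        If a required column is absent.
    DatabookValidationError
        If any intervention violates an invariant; the error lists the
        intervention id and offending field for each issue.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"id": str, "name": str, "care_package": str, "program": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatabookSchemaError(f"databook {path} is missing required column(s): {', '.join(missing)}")
    for col, default in OPTIONAL_COLUMN_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default

    def opt_float(v: object) -> float | None:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    frp = _normalize_scores([0.0 if pd.isna(v) else float(v) for v in df["frp_score"]])
    equity = _normalize_scores([0.0 if pd.isna(v) else float(v) for v in df["equity_score"]])

    interventions = []
    for i, row in enumerate(df.to_dict("records")):
        shares = {p: float(row[f"share_{p}"]) for p in PLATFORMS if float(row[f"share_{p}"]) != 0.0}
        program = row["program"]
        if program is None or (isinstance(program, float) and math.isnan(program)) or program == "":
            program = None
        mc = opt_float(row["max_coverage"])
        interventions.append(
            Intervention(
                id=str(row["id"]),
                name=str(row["name"]),
                care_package=str(row["care_package"]),
                program=program,
                platform_shares=shares,
                unit_cost=float(row["unit_cost"]),
                icer=float(row["icer"]),
                target_population=float(row["target_population"]),
                current_coverage=float(row["current_coverage"]),
                max_coverage=DEFAULT_MAX_COVERAGE if mc is None else mc,
                frp_score=frp[i],
                equity_score=equity[i],
                attributable_burden=opt_float(row["attributable_burden"]),
                fixed_spend=_parse_bool(row["fixed_spend"]) if row["fixed_spend"] is not None else False,
                current_spend_override=opt_float(row["current_spend_override"]),
            )
        )

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    db = CountryDatabook(
        interventions=interventions,
        name=meta.get("name", path.stem),
        currency_year=meta.get("currency_year"),
        deflators={int(k): float(v) for k, v in meta.get("deflators", {}).items()},
        reported_expenditure=meta.get("reported_expenditure"),
    )
    issues = validate_databook(db)
    if issues:
        raise DatabookValidationError(issues)
    return db


def write_databook(db: CountryDatabook, path: str | Path) -> None:
    """Write ``db`` as CSV plus a ``.meta.json`` sidecar.

    The written pair round-trips: ``read_databook`` on the output
    reproduces ``db`` field for field (floats exactly, via shortest-repr
    serialization).
    """
    issues = validate_databook(db)
    if issues:
        raise DatabookValidationError(issues)
    path = Path(path)
    df = db.to_frame()
    df["fixed_spend"] = df["fixed_spend"].map(lambda b: "true" if b else "false")
    # shortest-repr float serialization so numeric values round-trip exactly
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)
    meta = {
        "name": db.name,
        "currency_year": db.currency_year,
        "deflators": {str(k): v for k, v in db.deflators.items()},
        "reported_expenditure": db.reported_expenditure,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def _copy_with(iv: Intervention, **changes) -> Intervention:
    """Dataclass ``replace`` passthrough kept here so callers need not import dataclasses."""
    return replace(iv, **changes)
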