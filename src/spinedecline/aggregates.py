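"""Age-aggregated summary tables: data model, validation, fixtures and CSV I/O.

The pipeline's only inputs are summary tables published per age group:

* prevalence tables — for a binary imaging finding, each age group carries a
  sample size and a prevalence percentage;
* continuous tables — for muscle fatty-infiltration (FI) percentage, each age
  group carries a sample size, a mean and a standard deviation.

Bundled fixtures hold the published values for eight spinal-column
degenerative features (Brinjikji meta-analysis, decades 20s–50s) and seven
paravertebral-muscle FI endpoints (Crawford: four decades; Valentin: two age
groups), exactly as printed in the source tables.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "AgeGroup",
    "PrevalenceGroup",
    "ContinuousGroup",
    "PrevalenceAggregate",
    "ContinuousAggregate",
    "ValidationError",
    "builtin_fixtures",
    "representative_ages",
    "default_representative_ages",
    "read_aggregate_csv",
    "write_aggregate_csv",
    "DEFAULT_AGE_SCHEMES",
]

#: Age-coding scheme per source study. Brinjikji/Crawford decades are coded
#: on the equally spaced 25/35/45/55 grid (any equally spaced coding yields
#: identical slopes); Valentin's unequal groups use true midpoints.
DEFAULT_AGE_SCHEMES = {
    "brinjikji": "decade-equal-spacing",
    "crawford": "decade-equal-spacing",
    "valentin": "midpoint",
}


class ValidationError(ValueError):
    """An aggregate table violates its schema or value bounds."""


@dataclass(frozen=True)
class AgeGroup:
    """One age stratum with the single age value used to represent it.

    ``representative_age`` is the age assigned to every subject of the group
    when the group enters a regression; it is ``None`` until an age-coding
    scheme has been applied.
    """

    label: str
    age_low: int
    age_high: int
    representative_age: float | None = None

    def __post_init__(self) -> None:
        if self.age_low > self.age_high:
            raise ValidationError(
                f"age group {self.label!r}: age_low {self.age_low} > age_high {self.age_high}"
            )

    @property
    def midpoint(self) -> float:
        return (self.age_low + self.age_high) / 2.0


@dataclass(frozen=True)
class PrevalenceGroup:
    age_group: AgeGroup
    n: int
    prevalence_pct: float
    n_assumed: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.age_group.label!r}: n must be >= 1, got {self.n}")
        if not 0.0 <= self.prevalence_pct <= 100.0:
            raise ValidationError(
                f"group {self.age_group.label!r}: prevalence_pct {self.prevalence_pct} outside [0, 100]"
            )


@dataclass(frozen=True)
class ContinuousGroup:
    age_group: AgeGroup
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.age_group.label!r}: n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"group {self.age_group.label!r}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class PrevalenceAggregate:
    """Age-grouped prevalence of a binary degenerative imaging finding."""

    endpoint: str
    source: str
    groups: tuple[PrevalenceGroup, ...]

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def ages(self) -> tuple[float, ...]:
        if any(g.age_group.representative_age is None for g in self.groups):
            raise ValidationError(f"{self.endpoint!r}: representative ages not assigned")
        return tuple(g.age_group.representative_age for g in self.groups)  # type: ignore[misc]


@dataclass(frozen=True)
class ContinuousAggregate:
    """Age-grouped mean/SD summaries of a continuous outcome (FI %)."""

    endpoint: str
    source: str
    groups: tuple[ContinuousGroup, ...]

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def ages(self) -> tuple[float, ...]:
        if any(g.age_group.representative_age is None for g in self.groups):
            raise ValidationError(f"{self.endpoint!r}: representative ages not assigned")
        return tuple(g.age_group.representative_age for g in self.groups)  # type: ignore[misc]


Aggregate = Union[PrevalenceAggregate, ContinuousAggregate]


def representative_ages(aggregate: Aggregate, scheme: str | Sequence[float] = "midpoint") -> Aggregate:
    """Return a copy of *aggregate* with representative ages assigned.

    ``scheme`` is ``"midpoint"`` (arithmetic midpoint of the group bounds),
    ``"decade-equal-spacing"`` (``age_low + 5``, putting decade groups on an
    equally spaced grid such as 25/35/45/55 even when the last decade is
    printed as e.g. 50–60), or an explicit list of ages, one per group.
    Idempotent: reapplying a scheme yields an equal aggregate.
    """
    groups = aggregate.groups
    if isinstance(scheme, str):
        if scheme == "midpoint":
            ages = [g.age_group.midpoint for g in groups]
        elif scheme == "decade-equal-spacing":
            ages = [g.age_group.age_low + 5.0 for g in groups]
        else:
            raise ValidationError(f"unknown age-coding scheme {scheme!r}")
    else:
        ages = [float(a) for a in scheme]
        if len(ages) != len(groups):
            raise ValidationError(
                f"explicit age list has {len(ages)} entries for {len(groups)} groups"
            )
    new_groups = tuple(
        replace(g, age_group=replace(g.age_group, representative_age=a))
        for g, a in zip(groups, ages)
    )
    return replace(aggregate, groups=new_groups)


def default_representative_ages(aggregate: Aggregate) -> Aggregate:
    """Assign representative ages using the source study's default scheme."""
    scheme = DEFAULT_AGE_SCHEMES.get(aggregate.source, "midpoint")
    return representative_ages(aggregate, scheme)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_BASE_COLS = ["source", "endpoint", "age_low", "age_high", "n"]


def _rows_to_aggregates(df: pd.DataFrame, origin: str) -> list[Aggregate]:
    missing = [c for c in _BASE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{origin}: missing columns {missing}")
    has_prev = "prevalence_pct" in df.columns
    has_cont = "mean" in df.columns or "sd" in df.columns
    if has_prev and has_cont:
        raise ValidationError(f"{origin}: ambiguous table kind (both prevalence_pct and mean/sd present)")
    if not has_prev and not has_cont:
        raise ValidationError(f"{origin}: need either a prevalence_pct column or mean,sd columns")
    if has_cont and not {"mean", "sd"}.issubset(df.columns):
        raise ValidationError(f"{origin}: continuous tables need both mean and sd columns")

    out: list[Aggregate] = []
    for (source, endpoint), sub in df.groupby(["source", "endpoint"], sort=False):
        groups: list = []
        for idx, row in sub.iterrows():
            label = f"{int(row.age_low)}-{int(row.age_high)}"
            try:
                ag = AgeGroup(label, int(row.age_low), int(row.age_high))
                if has_prev:
                    assumed = bool(int(row["assumed_n"])) if "assumed_n" in sub.columns else False
                    groups.append(
                        PrevalenceGroup(ag, int(row.n), float(row.prevalence_pct), assumed)
                    )
                else:
                    groups.append(ContinuousGroup(ag, int(row.n), float(row["mean"]), float(row.sd)))
            except ValidationError as exc:
                raise ValidationError(f"{origin}, row {idx} ({endpoint!r}): {exc}") from exc
        cls = PrevalenceAggregate if has_prev else ContinuousAggregate
        out.append(cls(endpoint=str(endpoint), source=str(source), groups=tuple(groups)))
    return out


def read_aggregate_csv(path: str | Path) -> list[Aggregate]:
    """Read one or more aggregates from a CSV file (one row per age group)."""
    df = pd.read_csv(path)
    return _rows_to_aggregates(df, origin=str(path))


def write_aggregate_csv(aggregates: Aggregate | Iterable[Aggregate], path: str | Path) -> None:
    """Write aggregates to CSV in the same schema ``read_aggregate_csv`` expects."""
    if isinstance(aggregates, (PrevalenceAggregate, ContinuousAggregate)):
        aggregates = [aggregates]
    aggregates = list(aggregates)
    kinds = {type(a) for a in aggregates}
    if len(kinds) > 1:
        raise ValidationError("cannot mix prevalence and continuous aggregates in one CSV")
    rows = []
    for agg in aggregates:
        for g in agg.groups:
            row = {
                "source": agg.source,
                "endpoint": agg.endpoint,
                "age_low": g.age_group.age_low,
                "age_high": g.age_group.age_high,
                "n": g.n,
            }
            if isinstance(g, PrevalenceGroup):
                row["prevalence_pct"] = g.prevalence_pct
                row["assumed_n"] = int(g.n_assumed)
            else:
                row["mean"] = g.mean
                row["sd"] = g.sd
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def builtin_fixtures() -> dict[str, Aggregate]:
    """The published summary tables bundled with the package, keyed by endpoint.

    Returns all 8 spinal-column prevalence endpoints plus 3 Crawford and
    4 Valentin muscle FI endpoints. Representative ages are *not* assigned;
    call :func:`default_representative_ages` (or choose a scheme) first.
    The two Brinjikji endpoints whose youngest groups had no published sample
    size (facet degeneration, spondylolisthesis) carry the assumed n=100 with
    ``n_assumed`` flags set, so reports can disclose the imputation.
    """
    data = importlib.resources.files("spinedecline") / "data"
    out: dict[str, Aggregate] = {}
    for name in ("prevalence.csv", "continuous.csv"):
        with importlib.resources.as_file(data / name) as p:
            for agg in read_aggregate_csv(p):
                out[agg.endpoint] = agg
    return out
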