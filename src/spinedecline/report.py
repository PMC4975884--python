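"""Combined decline-rate report: every endpoint's yearly decline with 95% CI,
ordered fastest-to-slowest, plus pairwise CI-separation flags.

Endpoint (a) is flagged "separated above" endpoint (b) when a's CI lower
bound exceeds b's CI upper bound — the criterion used in the underlying
studies' prose for claiming a clearly faster decline. Bounds are compared
after rounding to 3 decimals, the precision of the machine outputs.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass

from .aggregates import (
    ContinuousAggregate,
    PrevalenceAggregate,
    builtin_fixtures,
    default_representative_ages,
    representative_ages,
)
from .montecarlo import DEFAULT_ITERATIONS, MCResult, mc_confidence_interval, run_mc
from .reconstruct import RngSpec, expand_prevalence
from .regression import MarginalEffect, average_marginal_effect, fit_logistic

logger = logging.getLogger(__name__)

__all__ = [
    "DeclineRow",
    "DeclineReport",
    "build_report",
    "export_report",
    "fit_all_prevalence",
    "run_all_mc",
    "run_default_pipeline",
]


@dataclass(frozen=True)
class DeclineRow:
    endpoint: str
    source: str
    estimate: float  # %/year
    ci_low: float
    ci_high: float
    method: str  # "logistic-AME" | "MC-gaussian"

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "source": self.source,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
        }


@dataclass(frozen=True)
class DeclineReport:
    rows: tuple[DeclineRow, ...]  # sorted by estimate, descending
    #: separated[(a, b)] is True when a's CI lies wholly above b's
    separated: dict[tuple[str, str], bool]

    @property
    def fastest(self) -> str:
        return self.rows[0].endpoint

    @property
    def slowest(self) -> str:
        return self.rows[-1].endpoint

    def separated_above(self, endpoint: str) -> set[str]:
        """Endpoints whose CI upper bound lies below *endpoint*'s lower bound."""
        return {b for (a, b), flag in self.separated.items() if a == endpoint and flag}

    def to_dict(self) -> dict:
        return {
            "rows": [r.to_dict() for r in self.rows],
            "separated": [list(k) for k, v in sorted(self.separated.items()) if v],
        }


def _separation(rows: list[DeclineRow]) -> dict[tuple[str, str], bool]:
    out: dict[tuple[str, str], bool] = {}
    for a in rows:
        for b in rows:
            if a.endpoint == b.endpoint:
                continue
            out[(a.endpoint, b.endpoint)] = round(a.ci_low, 3) > round(b.ci_high, 3)
    return out


def build_report(rows: list[DeclineRow]) -> DeclineReport:
    """Assemble the comparison report from per-endpoint decline rows."""
    seen = set()
    for r in rows:
        if r.endpoint in seen:
            raise ValueError(f"duplicate endpoint {r.endpoint!r}")
        seen.add(r.endpoint)
    ordered = tuple(sorted(rows, key=lambda r: r.estimate, reverse=True))
    return DeclineReport(rows=ordered, separated=_separation(list(ordered)))


def export_report(report: DeclineReport, fmt: str) -> str:
    """Serialize the report: ``json`` (lossless), ``csv`` (rows only), or
    ``plot-data`` (estimate + whisker bounds per endpoint, report order)."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(
            buf, fieldnames=["endpoint", "source", "estimate", "ci_low", "ci_high", "method"]
        )
        writer.writeheader()
        for r in report.rows:
            writer.writerow(r.to_dict())
        return buf.getvalue()
    if fmt == "plot-data":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["endpoint", "estimate", "whisker_low", "whisker_high"])
        for r in report.rows:
            writer.writerow([r.endpoint, f"{r.estimate:.3f}", f"{r.ci_low:.3f}", f"{r.ci_high:.3f}"])
        return buf.getvalue()
    raise ValueError(f"unknown report format {fmt!r}")


def report_from_json(text: str) -> DeclineReport:
    """Rebuild a report from its JSON export (round-trip of rows + flags)."""
    data = json.loads(text)
    rows = [DeclineRow(**r) for r in data["rows"]]
    report = build_report(rows)
    stored = {tuple(k) for k in data["separated"]}
    derived = {k for k, v in report.separated.items() if v}
    if stored != derived:
        raise ValueError("stored separation flags are inconsistent with the stored CIs")
    return report


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def fit_all_prevalence(
    fixtures: dict | None = None, age_scheme: str | None = None
) -> dict[str, tuple[MarginalEffect, int]]:
    """Logistic-AME decline rate for every prevalence endpoint.

    Returns ``{endpoint: (MarginalEffect, n)}``.
    """
    fixtures = fixtures if fixtures is not None else builtin_fixtures()
    out: dict[str, tuple[MarginalEffect, int]] = {}
    for name, agg in fixtures.items():
        if not isinstance(agg, PrevalenceAggregate):
            continue
        agg = (
            default_representative_ages(agg)
            if age_scheme is None
            else representative_ages(agg, age_scheme)
        )
        records = expand_prevalence(agg)
        fit = fit_logistic(records, "linear-age", endpoint=name)
        out[name] = (average_marginal_effect(fit, records), agg.total_n)
        logger.info("fitted %s: AME %.3f %%/year", name, out[name][0].estimate)
    return out


def run_all_mc(
    seed: int,
    iterations: int = DEFAULT_ITERATIONS,
    fixtures: dict | None = None,
) -> dict[str, MCResult]:
    """Monte Carlo decline rate for every continuous endpoint."""
    fixtures = fixtures if fixtures is not None else builtin_fixtures()
    rng = RngSpec(seed)
    out: dict[str, MCResult] = {}
    for name, agg in fixtures.items():
        if not isinstance(agg, ContinuousAggregate):
            continue
        agg = default_representative_ages(agg)
        out[name] = run_mc(agg, iterations=iterations, rng=rng)
        logger.info("simulated %s: mean b %.3f %%/year", name, out[name].b_mean)
    return out


def run_default_pipeline(
    seed: int, iterations: int = DEFAULT_ITERATIONS, ci_method: str = "normal"
) -> tuple[DeclineReport, dict[str, tuple[MarginalEffect, int]], dict[str, MCResult]]:
    """Full default analysis: all 8 prevalence + 7 muscle endpoints."""
    fixtures = builtin_fixtures()
    ame = fit_all_prevalence(fixtures)
    mc = run_all_mc(seed, iterations, fixtures)
    rows = [
        DeclineRow(name, fixtures[name].source, m.estimate, m.ci_low, m.ci_high, "logistic-AME")
        for name, (m, _) in ame.items()
    ]
    for name, res in mc.items():
        ci = mc_confidence_interval(res, ci_method)
        rows.append(DeclineRow(name, fixtures[name].source, ci.point, ci.ci_low, ci.ci_high, "MC-gaussian"))
    return build_report(rows), ame, mc
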