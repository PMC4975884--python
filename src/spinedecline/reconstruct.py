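"""Synthetic individual-level records reconstructed from aggregate tables.

Binary outcomes are expanded deterministically: each age group contributes
exactly ``round(n * prevalence/100)`` positive subjects (round half away from
zero), everyone in a group sharing the group's representative age.
Continuous outcomes are drawn as plain normal variates ``N(mean_j, sd_j)``,
``n_j`` per group, with no truncation at 0 or 100 FI% — truncating would bias
the group means the draws are meant to reproduce.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .aggregates import (
    AgeGroup,
    ContinuousAggregate,
    ContinuousGroup,
    PrevalenceAggregate,
    ValidationError,
    representative_ages,
)

__all__ = [
    "IndividualRecord",
    "RngSpec",
    "binary_counts",
    "expand_prevalence",
    "draw_continuous",
    "recovery_generator",
    "records_to_arrays",
]


class IndividualRecord(NamedTuple):
    """One synthetic subject: representative age and outcome (0/1 or FI %)."""

    age: float
    outcome: float


@dataclass(frozen=True)
class RngSpec:
    """A named, reproducible random stream.

    Identical ``(seed, stream)`` pairs yield bit-identical draws; distinct
    stream names on the same seed yield statistically independent streams, so
    any endpoint/iteration can be regenerated in isolation.
    """

    seed: int
    stream: str = ""

    def child(self, suffix: str) -> "RngSpec":
        stream = f"{self.stream}/{suffix}" if self.stream else suffix
        return RngSpec(self.seed, stream)

    def generator(self) -> np.random.Generator:
        digest = hashlib.sha256(self.stream.encode("utf-8")).digest()
        # two 31-bit words derived from the stream name keep the key stable
        # across platforms and python hash randomization
        key = tuple(
            int.from_bytes(digest[i : i + 4], "big") & 0x7FFFFFFF for i in (0, 4)
        )
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=key))


def binary_counts(n: int, prevalence_pct: float) -> tuple[int, int]:
    """Split ``n`` subjects into (positive, negative) counts for a prevalence.

    Uses round-half-away-from-zero on ``n * prevalence/100``, the rule that
    reproduces the published worked examples (101/273 at 37%, 314/604 at 52%).
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0.0 <= prevalence_pct <= 100.0:
        raise ValidationError(f"prevalence_pct {prevalence_pct} outside [0, 100]")
    n_pos = int(math.floor(n * prevalence_pct / 100.0 + 0.5))
    return n_pos, n - n_pos


def expand_prevalence(aggregate: PrevalenceAggregate) -> list[IndividualRecord]:
    """Deterministically expand a prevalence table into 0/1 subject records."""
    records: list[IndividualRecord] = []
    for g, age in zip(aggregate.groups, aggregate.ages):
        n_pos, n_neg = binary_counts(g.n, g.prevalence_pct)
        records.extend(IndividualRecord(age, 1.0) for _ in range(n_pos))
        records.extend(IndividualRecord(age, 0.0) for _ in range(n_neg))
    return records


def draw_continuous(aggregate: ContinuousAggregate, rng: RngSpec) -> list[IndividualRecord]:
    """Draw one synthetic sample: ``n_j`` normal variates per age group."""
    gen = rng.generator()
    records: list[IndividualRecord] = []
    for g, age in zip(aggregate.groups, aggregate.ages):
        draws = gen.normal(g.mean, g.sd, size=g.n)
        records.extend(IndividualRecord(age, float(v)) for v in draws)
    return records


def recovery_generator(
    true_slope: float,
    true_intercept: float,
    noise_sd: float,
    groups: list[tuple[AgeGroup, int]],
    endpoint: str = "recovery",
) -> ContinuousAggregate:
    """Fabricate a continuous aggregate from a known linear age trend.

    Group means are set exactly on the line ``intercept + slope * age`` (age =
    group midpoint unless already assigned), all SDs to ``noise_sd``, so the
    downstream Monte Carlo pipeline should recover ``true_slope``.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if len(groups) < 2:
        raise ValidationError("need at least 2 age groups: slope is unidentifiable from one")
    cgroups = []
    for ag, n in groups:
        age = ag.representative_age if ag.representative_age is not None else ag.midpoint
        mean = true_intercept + true_slope * age
        cgroups.append(ContinuousGroup(ag, n, mean, noise_sd))
    agg = ContinuousAggregate(endpoint=endpoint, source="synthetic", groups=tuple(cgroups))
    ages = [g.age_group.representative_age if g.age_group.representative_age is not None
            else g.age_group.midpoint for g in agg.groups]
    return representative_ages(agg, ages)


def records_to_arrays(records: list[IndividualRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Split records into (ages, outcomes) float arrays for regression."""
    arr = np.asarray(records, dtype=float)
    if arr.size == 0:
        return np.empty(0), np.empty(0)
    return arr[:, 0], arr[:, 1]
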