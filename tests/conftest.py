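"""Shared fixtures and published reference values used across the suite."""

import pytest

from spinedecline import builtin_fixtures, default_representative_ages

# Published totals per endpoint (sum of age-group sample sizes).
PRINTED_TOTALS = {
    "disk degeneration": 1603,
    "disk signal loss": 613,
    "disk height loss": 572,
    "disk bulge": 430,
    "disk protrusion": 1408,
    "annular fissure": 996,
    "facet degeneration": 849,
    "spondylolisthesis": 284,
    "MF+ES (C)": 80,
    "MF (C)": 80,
    "ES (C)": 80,
    "psoas (V)": 24,
    "MF+ES (V)": 24,
    "MF (V)": 24,
    "ES (V)": 24,
}

# Published logistic decline rates: endpoint -> (b(age), se(b), ci_low, ci_high),
# all in percentage points per year.
PRINTED_LOGISTIC = {
    "disk degeneration": (1.429, 0.106, 1.221, 1.637),
    "disk signal loss": (1.939, 0.238, 1.472, 2.405),
    "disk height loss": (1.065, 0.224, 0.626, 1.505),
    "disk bulge": (0.985, 0.224, 0.545, 1.425),
    "disk protrusion": (0.247, 0.140, -0.027, 0.522),
    "annular fissure": (0.146, 0.157, -0.162, 0.455),
    "facet degeneration": (1.050, 0.218, 0.624, 1.477),
    "spondylolisthesis": (0.288, 0.131, 0.032, 0.544),
}

# Published Monte Carlo summaries: endpoint -> (n, b mean, b SD, se mean, se SD).
PRINTED_MC = {
    "MF+ES (C)": (80, 0.169, 0.060, 0.055, 0.005),
    "MF (C)": (80, 0.244, 0.071, 0.068, 0.006),
    "ES (C)": (80, 0.132, 0.059, 0.051, 0.005),
    "psoas (V)": (24, 0.044, 0.024, 0.024, 0.004),
    "MF (V)": (24, 0.105, 0.048, 0.048, 0.007),
    "ES (V)": (24, 0.072, 0.034, 0.034, 0.005),
    "MF+ES (V)": (24, 0.088, 0.040, 0.040, 0.006),
}

# Published results-text 95% CIs (2-decimal): endpoint -> (low, high).
PRINTED_MC_CIS = {
    "MF+ES (C)": (0.06, 0.28),
    "MF (C)": (0.11, 0.37),
    "ES (C)": (0.03, 0.23),
    "psoas (V)": (-0.01, 0.09),
    "MF (V)": (0.01, 0.21),
    "ES (V)": (0.00, 0.14),
    "MF+ES (V)": (0.01, 0.17),
}


@pytest.fixture(scope="session")
def fixtures():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def aged_fixtures(fixtures):
    """Bundled aggregates with default representative ages assigned."""
    return {k: default_representative_ages(v) for k, v in fixtures.items()}
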