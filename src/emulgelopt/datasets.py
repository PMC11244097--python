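"""Bundled reference dataset: the nine-run ciclopirox olamine emulgel study.

This module carries the published summary numbers of the formulation
study the package's defaults emulate — the fitted response-surface
equations in both coded and actual parameterizations, the per-run
particle-size percentile summaries (means and standard deviations of
five laser-diffraction measurements), and the reported multi-response
optimum.  They serve three roles:

* generating truths for :mod:`emulgelopt.simulate` (synthetic worlds),
* fixtures for refitting/round-trip tests,
* inputs for reproducing the study's desk-computable results.

Responses and units: ``ph`` (pH units), ``d50`` (µm), ``t_sol_gel``
(°C), ``flux`` (mg/cm² cumulative over 6 h), ``firmness`` (N),
``work_of_shear`` (N·s).
"""

from __future__ import annotations

import pandas as pd

from ._poly import Poly
from .design import EMULGEL_FACTOR_SPACE, generate_ccd

__all__ = [
    "RESPONSES",
    "UNITS",
    "ACTUAL_MODELS",
    "CODED_MODELS",
    "MODEL_FAMILIES",
    "particle_percentiles",
    "OPTIMUM",
    "reference_design",
]

RESPONSES = ("ph", "d50", "t_sol_gel", "flux", "firmness", "work_of_shear")

UNITS = {
    "ph": "pH",
    "d50": "µm",
    "t_sol_gel": "°C",
    "flux": "mg/cm²",
    "firmness": "N",
    "work_of_shear": "N·s",
}

#: Model family reported as significant for each response.
MODEL_FAMILIES = {
    "ph": "quadratic",
    "d50": "linear",
    "t_sol_gel": "quadratic",
    "flux": "linear",
    "firmness": "quadratic",
    "work_of_shear": "quadratic",
}

# Terms are exponent tuples over (X1 = oil %, X2 = polysorbate %):
# (0,0)=1, (1,0)=X1, (0,1)=X2, (1,1)=X1*X2, (2,0)=X1², (0,2)=X2².

#: Published actual-factor equations (prediction form).
ACTUAL_MODELS: dict[str, Poly] = {
    "ph": {
        (0, 0): 8.7681, (1, 0): 0.0110, (0, 1): 0.0308,
        (1, 1): -0.00013, (2, 0): -0.00015, (0, 2): -0.0023,
    },
    "d50": {(0, 0): 0.5209, (1, 0): -0.0017, (0, 1): -0.0181},
    "t_sol_gel": {
        (0, 0): 16.4028, (1, 0): -0.2604, (0, 1): -1.0625,
        (1, 1): -0.0013, (2, 0): 0.0052, (0, 2): 0.0533,
    },
    "flux": {(0, 0): 1.5979, (1, 0): 0.0020, (0, 1): -0.0352},
    "firmness": {
        (0, 0): 1.1347, (1, 0): 0.0079, (0, 1): 0.4109,
        (1, 1): -0.0010, (2, 0): -0.00002, (0, 2): -0.0311,
    },
    "work_of_shear": {
        (0, 0): 1.8356, (1, 0): 0.0012, (0, 1): 0.6723,
        (1, 1): -0.0021, (2, 0): 0.00012, (0, 2): -0.0497,
    },
}

#: Published coded-factor equations (relative-impact form; printed at 2 dp).
CODED_MODELS: dict[str, Poly] = {
    "ph": {(0, 0): 9.04, (1, 0): 0.03, (0, 1): 0.02, (1, 1): -0.01, (2, 0): -0.06, (0, 2): -0.06},
    "d50": {(0, 0): 0.38, (1, 0): -0.03, (0, 1): -0.09},
    "t_sol_gel": {(0, 0): 9.11, (1, 0): 0.92, (0, 1): -2.83, (1, 1): -0.13, (2, 0): 2.08, (0, 2): 1.33},
    "flux": {(0, 0): 1.48, (1, 0): 0.04, (0, 1): -0.18},
    "firmness": {(0, 0): 2.48, (1, 0): 0.04, (0, 1): 0.35, (1, 1): -0.10, (2, 0): -0.01, (0, 2): -0.78},
    "work_of_shear": {(0, 0): 3.78, (1, 0): -0.05, (0, 1): 0.56, (1, 1): -0.21, (2, 0): 0.05, (0, 2): -1.24},
}

_PERCENTILE_ROWS = [
    # run, d10_mean, d10_sd, d50_mean, d50_sd, d90_mean, d90_sd  (µm, n = 5)
    ("E-1", 0.309, 0.011, 0.461, 0.009, 0.900, 0.010),
    ("E-2", 0.377, 0.043, 0.512, 0.019, 1.002, 0.050),
    ("E-3", 0.338, 0.043, 0.422, 0.032, 0.737, 0.029),
    ("E-4", 0.192, 0.016, 0.295, 0.015, 0.499, 0.015),
    ("E-5", 0.151, 0.010, 0.240, 0.016, 0.413, 0.008),
    ("E-6", 0.221, 0.010, 0.336, 0.015, 0.557, 0.011),
    ("E-7", 0.252, 0.015, 0.374, 0.026, 0.659, 0.027),
    ("E-8", 0.282, 0.013, 0.434, 0.028, 0.884, 0.014),
    ("E-9", 0.252, 0.020, 0.381, 0.028, 0.664, 0.021),
]


def particle_percentiles() -> pd.DataFrame:
    """Per-run D10/D50/D90 summaries (mean and SD over 5 measurements, µm)."""
    return pd.DataFrame(
        _PERCENTILE_ROWS,
        columns=["run_id", "d10_mean", "d10_sd", "d50_mean", "d50_sd", "d90_mean", "d90_sd"],
    ).set_index("run_id")


#: Reported optimum of the desirability optimization.
OPTIMUM = {
    "mineral_oil": 38.27,
    "polysorbate_80": 6.56,
    "hydrogel": 55.17,
    "desirability": 0.646,
    "predicted": {"d50": 0.337, "t_sol_gel": 9.1, "flux": 1.44},
}


def reference_design():
    """The nine-run face-centered CCD with completed formulations (E-1 … E-9)."""
    return generate_ccd(EMULGEL_FACTOR_SPACE)
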