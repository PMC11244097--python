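"""Synthetic emulgel worlds: every input the analysis pipeline consumes.

The generators emulate the measurement campaign of the reference study
so the whole pipeline is testable offline:

* replicate response tables — per-run truth from the reference
  actual-factor response equations plus additive Gaussian replicate
  noise at the magnitude of the study's reported standard deviations,
* release profiles — stretched-exponential release
  Q(t) = Q∞(1 − e^(−(kt)^β)) forward-simulated through the
  sampling/replacement protocol with multiplicative assay noise on
  concentrations (β = 1 is exact first-order; the default β = 2/3 adds
  the mild diffusion-dominated curvature that real profiles show when
  summarized by a first-order fit),
* rheology sweeps — logistic sol→gel step in G′(T) with multiplicative
  noise,
* particle-size percentile tables — per-measurement D10/D50/D90 from a
  lognormal droplet-size law.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections.abc import Mapping

import numpy as np
import pandas as pd

from ._poly import Poly, evaluate
from . import datasets
from .design import DesignTable
from .release import ReleaseProfile, RheoSweep

__all__ = [
    "GeneratorConfig",
    "simulate_responses",
    "simulate_release",
    "simulate_rheosweep",
    "simulate_particles",
    "default_release_params",
]

#: Default replicate noise SD per response, scaled to the study's reported
#: replicate standard deviations (D50 SDs ~0.01–0.03 µm; texture/pH/flux
#: spreads of similar relative size).
DEFAULT_NOISE_SD = {
    "ph": 0.02,
    "d50": 0.02,
    "t_sol_gel": 0.3,
    "flux": 0.05,
    "firmness": 0.05,
    "work_of_shear": 0.08,
}

#: Replicates per run: particle size was measured 5 times per sample,
#: texture in triplicate; triplicate is the default elsewhere.
DEFAULT_REPLICATES = {"d50": 5}
DEFAULT_REPLICATES_FALLBACK = 3


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic world.

    ``true_models`` are actual-factor coefficient sets used as generating
    truth (defaults: the reference study equations, so downstream fits
    have a printed ground truth).
    """

    true_models: Mapping[str, Poly] = field(default_factory=lambda: dict(datasets.ACTUAL_MODELS))
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    replicates: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    seed: int = 0
    release_noise_cv: float = 0.01
    release_shape: float = 2.0 / 3.0
    rheology_noise_cv: float = 0.01

    def n_replicates(self, response: str) -> int:
        return int(self.replicates.get(response, DEFAULT_REPLICATES_FALLBACK))

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _check_physical(response: str, run_id: str, value: float) -> None:
    if response == "d50" and value <= 0:
        raise ValueError(f"non-physical D50 {value:.4f} µm predicted for run {run_id}")
    if response == "ph" and not (0.0 < value < 14.0):
        raise ValueError(f"non-physical pH {value:.4f} predicted for run {run_id}")
    if response in ("flux", "firmness", "work_of_shear") and value < 0:
        raise ValueError(f"negative {response} {value:.4f} predicted for run {run_id}")


def simulate_responses(design: DesignTable, config: GeneratorConfig) -> pd.DataFrame:
    """Replicate response table: columns run_id, replicate_id, response_name, value.

    value = truth(actual factors) + Normal(0, noise_sd); deterministic per
    (config, seed).  Errors if a generating model predicts a non-physical
    value at any run.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for response in config.true_models:
        coefs = config.true_models[response]
        sd = float(config.noise_sd.get(response, 0.0))
        if sd < 0:
            raise ValueError("noise_sd must be non-negative")
        reps = config.n_replicates(response)
        for run in design.runs:
            truth = float(evaluate(coefs, list(run.actual)))
            _check_physical(response, run.run_id, truth)
            draws = truth + sd * rng.standard_normal(reps)
            for j, v in enumerate(draws, start=1):
                rows.append((run.run_id, j, response, float(v)))
    return pd.DataFrame(rows, columns=["run_id", "replicate_id", "response_name", "value"])


def default_release_params(design: DesignTable, q_inf: float = 2.4, duration: float = 6.0,
                           area: float = 1.33, shape: float = 2.0 / 3.0) -> dict[str, tuple[float, float]]:
    """Per-run (Q∞, k) such that the true 6-h flux matches the reference
    flux surface at each run's composition: k solves
    Q∞(1 − e^(−(kT)^shape)) = flux·area for the generator's release law."""
    out = {}
    flux_coefs = datasets.ACTUAL_MODELS["flux"]
    for run in design.runs:
        target_q = float(evaluate(flux_coefs, list(run.actual))) * area
        frac = target_q / q_inf
        if not 0 < frac < 1:
            raise ValueError(f"run {run.run_id}: 6-h target {target_q:.3f} mg not below Q∞ {q_inf}")
        k = (-np.log1p(-frac)) ** (1.0 / shape) / duration
        out[run.run_id] = (q_inf, float(k))
    return out


def simulate_release(
    q_inf: float,
    k: float,
    times=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    medium_volume: float = 50.0,
    sample_volume: float = 1.0,
    diffusion_area: float = 1.33,
    dose: float = 10.0,
    noise_cv: float = 0.0,
    shape: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[ReleaseProfile, np.ndarray]:
    """Forward-simulate a sampled release experiment.

    The true released mass follows the stretched-exponential (Weibull)
    law Q(t) = Q∞(1 − e^(−(kt)^shape)); ``shape = 1`` (the default here)
    is exact first-order kinetics, while the generator configuration
    defaults to shape 2/3, the mild diffusion-dominated departure from
    first-order that reproduces the goodness-of-fit level seen when
    first-order models are fitted to real emulgel release data.  At each
    sampling time the measured concentration reflects all mass removed
    by earlier withdrawals, and a V_s aliquot is then withdrawn and
    replaced with fresh medium.  Multiplicative Gaussian noise (CV
    ``noise_cv``) is applied to the sampled concentrations.  Returns the
    profile and the true cumulative-release series, which the sampling
    correction in :func:`~emulgelopt.release.cumulative_release` must
    recover exactly in the noiseless case.
    """
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    if q_inf > dose:
        raise ValueError("Q∞ cannot exceed the dose")
    if shape <= 0:
        raise ValueError("shape must be positive")
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] <= 0 or np.any(np.diff(t) <= 0):
        raise ValueError("sampling schedule must be strictly increasing and start above 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    true_q = q_inf * (1.0 - np.exp(-((k * t) ** shape)))
    removed = 0.0
    conc = []
    for qn in true_q:
        c = (qn - removed) / medium_volume
        conc.append(c)
        removed += c * sample_volume
    conc = np.asarray(conc)
    if noise_cv > 0:
        conc = conc * (1.0 + noise_cv * rng.standard_normal(conc.size))
        conc = np.clip(conc, 0.0, None)
    profile = ReleaseProfile(
        times=tuple(t),
        concentrations=tuple(float(c) for c in conc),
        medium_volume=medium_volume,
        sample_volume=sample_volume,
        diffusion_area=diffusion_area,
        dose=dose,
    )
    return profile, true_q


def simulate_rheosweep(
    t_transition: float,
    g_sol: float = 10.0,
    g_gel: float = 1.0e4,
    width: float = 1.0,
    temperatures=None,
    noise_cv: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> RheoSweep:
    """Logistic sol→gel step in G′ over a temperature schedule.

    The poloxamer system gels on warming: G′ rises from ``g_sol`` to
    ``g_gel`` around ``t_transition`` over a scale ``width`` (°C).  The
    default schedule is the protocol's 40 → 0 °C at 1 °C steps.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if temperatures is None:
        temperatures = np.arange(40.0, -1.0, -1.0)
    t = np.asarray(temperatures, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    g = g_sol + (g_gel - g_sol) / (1.0 + np.exp(-(t - t_transition) / width))
    if noise_cv > 0:
        g = g * (1.0 + noise_cv * rng.standard_normal(g.size))
    return RheoSweep(temperatures=tuple(t), storage_modulus=tuple(float(v) for v in g))


_Z = {"d10": -1.2815515655446004, "d50": 0.0, "d90": 1.2815515655446004}


def simulate_particles(
    median: float,
    sigma: float,
    n_measurements: int = 5,
    noise_cv: float = 0.02,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-measurement D10/D50/D90 from a lognormal droplet-size law.

    Percentiles come from the lognormal quantile function
    D_q = median·exp(σ z_q) with small multiplicative measurement noise;
    the summary (mean/SD per percentile) mirrors a particle-size report
    table.  Column order within a measurement is forced to stay monotone
    (D10 < D50 < D90), which the quantile construction guarantees for
    noise small relative to σ.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_measurements + 1):
        vals = {}
        for name, z in _Z.items():
            v = median * np.exp(sigma * z)
            if noise_cv > 0:
                v *= 1.0 + noise_cv * rng.standard_normal()
            vals[name] = float(v)
        ordered = sorted(vals.values())
        rows.append((i, *ordered))
    return pd.DataFrame(rows, columns=["measurement", "d10", "d50", "d90"])
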