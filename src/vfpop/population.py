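"""Virtual-subject sampling, rejection filtering and adaptive resampling.

A virtual subject is created by independently scaling each of the 16 model
inputs by a multiplicative factor ``r**a``, with ``r ~ U(1, Rmax)`` and the
sign exponent ``a`` equal to -1 or +1 with probability 1/2 each.  Factors
therefore span ``[1/Rmax, Rmax]`` with, on average, as many subjects above
as below each nominal value.  Subjects are simulated and kept only when
their voice measures pass the normal-phonation filter (rejection sampling);
the attempted count is recorded so the success rate can be estimated.

Success histograms of the accepted factors (on the log-factor axis) can be
fitted with a smooth density and used as an importance-sampling proposal,
which raises the success rate several-fold at broad ranges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import NOMINAL_VALUES, PARAM_NAMES, SimConfig
from .measures import (
    NormalPhonationCriteria,
    VoiceMeasures,
    classify_normal,
    evaluate_parameters,
)

__all__ = [
    "RMAX_GRID",
    "VirtualSubject",
    "PopulationSample",
    "ParameterHistogram",
    "FittedDensity",
    "draw_factor",
    "sample_factors",
    "sample_subject",
    "generate_population",
    "estimate_success_rate",
    "success_histograms",
    "fit_density",
    "fit_all_densities",
    "adaptive_success_rate",
    "convergence_check",
    "nominal_array",
]

#: The five sampling ranges of the study design.
RMAX_GRID = (1.10, 1.20, 1.50, 2.00, 5.00)


def nominal_array() -> np.ndarray:
    return np.array([NOMINAL_VALUES[k] for k in PARAM_NAMES], dtype=float)


@dataclass
class VirtualSubject:
    subject_id: int
    params: np.ndarray          # 16 values, g-cm-ms units
    factors: np.ndarray         # params / nominal, in [1/rmax, rmax]
    measures: VoiceMeasures
    passed: bool


@dataclass
class PopulationSample:
    """Accepted virtual subjects plus the rejection bookkeeping."""

    rmax: float
    seed: int
    attempted: int
    subjects: list[VirtualSubject] = field(default_factory=list)
    exhausted: bool = False     # max_attempts hit before n_target accepted

    @property
    def accepted(self) -> int:
        return len(self.subjects)

    @property
    def success_rate(self) -> float:
        return self.accepted / self.attempted if self.attempted else math.nan

    def factor_matrix(self) -> np.ndarray:
        return np.array([s.factors for s in self.subjects])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row: dict = {"subject_id": s.subject_id}
            row.update({name: s.params[i] for i, name in enumerate(PARAM_NAMES)})
            row.update({f"factor_{name}": s.factors[i]
                        for i, name in enumerate(PARAM_NAMES)})
            m = s.measures
            row.update(f0_hz=m.f0, mean_flow_cm3s=m.mean_flow,
                       ac_flow_cm3s=m.ac_flow, max_flow_cm3s=m.max_flow,
                       mfdr_ls2=m.mfdr, hrf_db=m.hrf, h1h2_db=m.h1h2,
                       oq=m.oq, sq=m.sq, oscillating=m.oscillating,
                       pass_normal=s.passed)
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, csv_path, sidecar_path=None) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        if sidecar_path is not None:
            meta = {"rmax": self.rmax, "seed": self.seed,
                    "attempted": self.attempted, "accepted": self.accepted}
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def draw_factor(rmax: float, rng: np.random.Generator) -> float:
    """One multiplicative factor r**a with r ~ U(1, rmax), a = +-1 equiprobable."""
    if rmax < 1:
        raise ValueError("rmax must be >= 1")
    r = rng.uniform(1.0, rmax)
    a = -1.0 if rng.random() < 0.5 else 1.0
    return float(r ** a)


def sample_factors(rmax: float, rng: np.random.Generator, n: int = 16) -> np.ndarray:
    if rmax < 1:
        raise ValueError("rmax must be >= 1")
    r = rng.uniform(1.0, rmax, n)
    a = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    return r ** a


def sample_subject(nominal: np.ndarray, rmax: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Scale each of the 16 nominal parameters by an independent factor."""
    factors = sample_factors(rmax, rng, len(nominal))
    return nominal * factors, factors


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # per-subject substream: deterministic and independent of evaluation order
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _default_evaluate(config: SimConfig | None):
    def evaluate(params: np.ndarray) -> VoiceMeasures:
        return evaluate_parameters(params, config)
    return evaluate


def generate_population(nominal: np.ndarray | None = None,
                        rmax: float = 1.5,
                        n_target: int = 1000,
                        criteria: NormalPhonationCriteria | None = None,
                        seed: int = 0,
                        max_attempts: int | None = None,
                        evaluate=None,
                        config: SimConfig | None = None) -> PopulationSample:
    """Rejection-sample virtual subjects until ``n_target`` pass the filter.

    ``evaluate`` maps a 16-parameter array to :class:`VoiceMeasures`;
    the default runs the full simulate -> measure pipeline.  Reproducible
    from ``seed``: subject ``i`` always uses the same parameter draw.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    nominal = nominal_array() if nominal is None else np.asarray(nominal, float)
    criteria = criteria or NormalPhonationCriteria()
    evaluate = evaluate or _default_evaluate(config)
    max_attempts = max_attempts if max_attempts is not None else 200 * n_target

    sample = PopulationSample(rmax=rmax, seed=seed, attempted=0)
    for i in range(max_attempts):
        rng = _subject_rng(seed, i)
        params, factors = sample_subject(nominal, rmax, rng)
        measures = evaluate(params)
        passed, _ = classify_normal(measures, criteria)
        sample.attempted += 1
        if passed:
            sample.subjects.append(VirtualSubject(
                subject_id=i, params=params, factors=factors,
                measures=measures, passed=True))
            if sample.accepted >= n_target:
                return sample
    sample.exhausted = True
    return sample


def estimate_success_rate(nominal: np.ndarray | None = None,
                          rmax: float = 5.0,
                          n_attempts: int = 3000,
                          criteria: NormalPhonationCriteria | None = None,
                          seed: int = 0,
                          evaluate=None,
                          config: SimConfig | None = None) -> PopulationSample:
    """Simulate a fixed number of attempts; the sample's ``success_rate``
    estimates the probability of normal phonation under uniform sampling."""
    sample = generate_population(nominal, rmax, n_target=n_attempts,
                                 criteria=criteria, seed=seed,
                                 max_attempts=n_attempts, evaluate=evaluate,
                                 config=config)
    sample.exhausted = False
    return sample


@dataclass
class ParameterHistogram:
    name: str
    rmax: float
    edges: np.ndarray   # bin edges on the log-factor axis
    counts: np.ndarray


@dataclass
class FittedDensity:
    """Sampleable density over the log-factor axis of one parameter.

    Built as a monotone piecewise-linear CDF through (smoothed) histogram
    bin masses, which is shape-agnostic and exactly invertible.
    """

    name: str
    edges: np.ndarray
    masses: np.ndarray      # normalized bin masses, sum to 1
    _cdf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._cdf = np.concatenate([[0.0], np.cumsum(self.masses)])
        self._cdf /= self._cdf[-1]

    def cdf(self, x) -> np.ndarray:
        return np.interp(x, self.edges, self._cdf)

    def ppf(self, q) -> np.ndarray:
        return np.interp(q, self._cdf, self.edges)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw log-factors by inverse-CDF sampling."""
        return self.ppf(rng.random(n))


def success_histograms(sample: PopulationSample, n_bins: int = 25) -> dict[str, ParameterHistogram]:
    """Per-parameter histograms of accepted subjects' factors (log axis)."""
    if sample.accepted < 1:
        raise ValueError("sample has no accepted subjects")
    log_rmax = math.log(sample.rmax) if sample.rmax > 1 else 1e-12
    edges = np.linspace(-log_rmax, log_rmax, n_bins + 1)
    logf = np.log(sample.factor_matrix())
    out = {}
    for i, name in enumerate(PARAM_NAMES):
        counts, _ = np.histogram(logf[:, i], bins=edges)
        out[name] = ParameterHistogram(name=name, rmax=sample.rmax,
                                       edges=edges, counts=counts)
    return out


def fit_density(hist: ParameterHistogram, smooth_width: int = 3) -> FittedDensity:
    """Smooth the bin masses (moving average) and normalize to a density."""
    total = hist.counts.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    masses = hist.counts.astype(float) / total
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        smoothed = np.convolve(masses, kernel, mode="same")
        # renormalize: 'same' convolution loses mass at the edges
        masses = smoothed / smoothed.sum()
    return FittedDensity(name=hist.name, edges=hist.edges, masses=masses)


def fit_all_densities(sample: PopulationSample, n_bins: int = 25,
                      smooth_width: int = 3) -> dict[str, FittedDensity]:
    return {name: fit_density(h, smooth_width)
            for name, h in success_histograms(sample, n_bins).items()}


def adaptive_success_rate(nominal: np.ndarray | None = None,
                          densities: dict[str, FittedDensity] | None = None,
                          rmax: float = 5.0,
                          criteria: NormalPhonationCriteria | None = None,
                          n_samples: int = 2000,
                          seed: int = 0,
                          evaluate=None,
                          config: SimConfig | None = None) -> PopulationSample:
    """Success rate when factors are drawn from fitted densities.

    Same simulate -> measure -> classify pipeline as uniform sampling, but
    each parameter's factor is drawn from its fitted success density.
    """
    if not densities:
        raise ValueError("densities must be provided")
    nominal = nominal_array() if nominal is None else np.asarray(nominal, float)
    criteria = criteria or NormalPhonationCriteria()
    evaluate = evaluate or _default_evaluate(config)

    sample = PopulationSample(rmax=rmax, seed=seed, attempted=0)
    for i in range(n_samples):
        rng = _subject_rng(seed, i)
        q = rng.random(len(PARAM_NAMES))
        logf = np.array([densities[name].ppf(q[j])
                         for j, name in enumerate(PARAM_NAMES)])
        factors = np.exp(logf)
        params = nominal * factors
        measures = evaluate(params)
        passed, _ = classify_normal(measures, criteria)
        sample.attempted += 1
        if passed:
            sample.subjects.append(VirtualSubject(
                subject_id=i, params=params, factors=factors,
                measures=measures, passed=True))
    return sample


def convergence_check(nominal: np.ndarray | None = None,
                      rmax: float = 1.5,
                      n_grid: tuple[int, ...] = (250, 500, 1000),
                      criteria: NormalPhonationCriteria | None = None,
                      seed: int = 0,
                      evaluate=None,
                      config: SimConfig | None = None,
                      delta: float = 0.01,
                      top_k: int = 5,
                      rel_tol: float = 0.05) -> pd.DataFrame:
    """Median sensitivities of the top input-output pairs vs population size.

    Generates one population of ``max(n_grid)`` subjects, computes per-subject
    sensitivities, and reports the per-pair median over the first ``n``
    subjects for each ``n``; a pair is flagged converged when successive
    medians differ by less than ``rel_tol`` relative.
    """
    from .sensitivity import OUTPUT_NAMES, population_sensitivity

    n_grid = tuple(sorted(n_grid))
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    sample = generate_population(nominal, rmax, n_target=n_grid[-1],
                                 criteria=criteria, seed=seed,
                                 evaluate=evaluate, config=config)
    tensor = population_sensitivity(sample, delta=delta, evaluate=evaluate,
                                    config=config)
    s, valid = tensor.s, tensor.valid
    # rank pairs by |median| over the full sample
    full_med = np.full((16, len(OUTPUT_NAMES)), np.nan)
    for i in range(16):
        for j in range(len(OUTPUT_NAMES)):
            v = s[valid[:, i, j], i, j]
            if v.size:
                full_med[i, j] = np.median(v)
    order = np.dstack(np.unravel_index(
        np.argsort(-np.abs(np.nan_to_num(full_med)).ravel()), full_med.shape))[0]
    rows = []
    for i, j in order[:top_k]:
        prev = None
        for n in n_grid:
            v = s[:n][valid[:n, i, j], i, j]
            med = float(np.median(v)) if v.size else math.nan
            conv = (prev is not None and np.isfinite(med) and np.isfinite(prev)
                    and abs(med - prev) <= rel_tol * max(abs(med), abs(prev), 1e-12))
            rows.append({"input": PARAM_NAMES[i], "output": OUTPUT_NAMES[j],
                         "n": n, "median": med, "converged": bool(conv)})
            prev = med
    return pd.DataFrame(rows)
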