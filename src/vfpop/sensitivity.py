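"""Non-dimensional sensitivities: per-subject Monte Carlo and designed experiments.

The local sensitivity of output ``F`` to input ``x`` at a sampled point is
the logarithmic derivative ``S* = (dF/F)/(dx/x)``, estimated by a +1%
forward difference: parameter ``x`` is scaled by ``(1 + delta)`` with all
other inputs held fixed, and ``S* = ((F_pert - F_base)/F_base)/delta``.
``S* = 1`` means a 1% input change produces a 1% output change.

Applied to every accepted subject of a virtual population this yields a
distribution of sensitivity values per input-output pair and sampling
range; the module also provides the three designed-experiment alternatives
(one-at-a-time variation, Cotter's screening design, and a D-optimal
quadratic response-surface method) for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PARAM_NAMES, SimConfig
from .measures import VoiceMeasures, evaluate_parameters
from .population import PopulationSample, VirtualSubject, nominal_array

__all__ = [
    "OUTPUT_NAMES",
    "SensitivityTensor",
    "QuadraticSurface",
    "measures_vector",
    "local_sensitivity",
    "population_sensitivity",
    "summarize_pairs",
    "pair_mean_sd",
    "classify_consistency",
    "rank_inputs",
    "oat_analysis",
    "cotter_design",
    "cotter_indices",
    "rsm_candidates",
    "quadratic_model_matrix",
    "d_optimal_design",
    "factor_map",
    "evaluate_design",
    "fit_rsm",
    "rsm_sensitivity",
    "validate_rsm",
]

#: The six model outputs whose sensitivities are tracked.
OUTPUT_NAMES = ("f0", "mean_flow", "max_flow", "mfdr", "oq", "sq")

N_PARAMS = len(PARAM_NAMES)
N_OUTPUTS = len(OUTPUT_NAMES)


def measures_vector(m: VoiceMeasures) -> np.ndarray:
    """The six tracked outputs as a vector (NaN when not oscillating)."""
    return np.array([getattr(m, name) for name in OUTPUT_NAMES], dtype=float)


def _default_evaluate(config: SimConfig | None):
    def evaluate(params: np.ndarray) -> VoiceMeasures:
        # sensitivity outputs are all time-domain; skip the spectral step
        return evaluate_parameters(params, config, spectral=False)
    return evaluate


def local_sensitivity(subject: VirtualSubject | np.ndarray,
                      delta: float = 0.01,
                      evaluate=None,
                      config: SimConfig | None = None,
                      base: VoiceMeasures | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference S* for all 16 inputs x 6 outputs of one subject.

    Returns ``(s, valid)`` of shape (16, 6).  A record is invalid when the
    perturbed run fails to oscillate or the base output is zero/NaN.
    """
    evaluate = evaluate or _default_evaluate(config)
    if isinstance(subject, VirtualSubject):
        params = subject.params
        base = base or subject.measures
    else:
        params = np.asarray(subject, dtype=float)
    if base is None:
        base = evaluate(params)
    f_base = measures_vector(base)
    base_ok = np.isfinite(f_base) & (f_base != 0)

    s = np.zeros((N_PARAMS, N_OUTPUTS))
    valid = np.zeros((N_PARAMS, N_OUTPUTS), dtype=bool)
    if not base.oscillating:
        return s, valid
    for i in range(N_PARAMS):
        p = params.copy()
        p[i] *= 1.0 + delta
        m = evaluate(p)
        if not m.oscillating:
            continue
        f = measures_vector(m)
        ok = base_ok & np.isfinite(f)
        with np.errstate(divide="ignore", invalid="ignore"):
            s[i] = np.where(ok, (f - f_base) / f_base / delta, 0.0)
        valid[i] = ok
    return s, valid


@dataclass
class SensitivityTensor:
    """S* values for one population: (subject, input, output) plus validity."""

    rmax: float
    subject_ids: np.ndarray
    s: np.ndarray       # (n_subjects, 16, 6)
    valid: np.ndarray   # same shape, bool

    def to_dataframe(self) -> pd.DataFrame:
        n = self.s.shape[0]
        idx = pd.MultiIndex.from_product(
            [range(n), PARAM_NAMES, OUTPUT_NAMES],
            names=["subject_idx", "input", "output"])
        df = pd.DataFrame({"s_star": self.s.ravel(), "valid": self.valid.ravel()},
                          index=idx).reset_index()
        df["subject_id"] = self.subject_ids[df.pop("subject_idx")]
        df["rmax"] = self.rmax
        return df[["rmax", "subject_id", "input", "output", "s_star", "valid"]]


def population_sensitivity(sample: PopulationSample, delta: float = 0.01,
                           evaluate=None, config: SimConfig | None = None,
                           ) -> SensitivityTensor:
    """Local sensitivities of every accepted subject in a population."""
    if sample.accepted < 1:
        raise ValueError("sample has no accepted subjects")
    evaluate = evaluate or _default_evaluate(config)
    n = sample.accepted
    s = np.zeros((n, N_PARAMS, N_OUTPUTS))
    valid = np.zeros((n, N_PARAMS, N_OUTPUTS), dtype=bool)
    for k, subj in enumerate(sample.subjects):
        s[k], valid[k] = local_sensitivity(subj, delta=delta, evaluate=evaluate)
    ids = np.array([subj.subject_id for subj in sample.subjects])
    return SensitivityTensor(rmax=sample.rmax, subject_ids=ids, s=s, valid=valid)


def classify_consistency(mean: float, sd: float) -> str:
    """Consistency class of a pair: 'consistent' when |mean| >= 2 sd,
    'within-1sd' when |mean| < sd, else 'within-2sd'.

    A zero-effect pair (mean = sd = 0, e.g. an input absent from the
    dynamics) sits at the apex of the shaded wedge and is classed
    'within-1sd': it has no consistent significant effect.
    """
    if mean == 0.0 and sd == 0.0:
        return "within-1sd"
    if abs(mean) < sd:
        return "within-1sd"
    if abs(mean) < 2.0 * sd:
        return "within-2sd"
    return "consistent"


def pair_mean_sd(tensor: SensitivityTensor) -> pd.DataFrame:
    """Per-pair mean, standard deviation and consistency class at one range."""
    rows = []
    for i, inp in enumerate(PARAM_NAMES):
        for j, out in enumerate(OUTPUT_NAMES):
            v = tensor.s[tensor.valid[:, i, j], i, j]
            if v.size == 0:
                rows.append({"input": inp, "output": out, "mean": math.nan,
                             "sd": math.nan, "n": 0, "class": "unavailable"})
                continue
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
            rows.append({"input": inp, "output": out, "mean": mean, "sd": sd,
                         "n": int(v.size), "class": classify_consistency(mean, sd)})
    return pd.DataFrame(rows)


def summarize_pairs(tensors: list[SensitivityTensor]) -> pd.DataFrame:
    """Per-pair percentile summary: median/5th/95th computed within each
    range then averaged across ranges, plus per-range mean/sd/class columns."""
    if not tensors:
        raise ValueError("need at least one tensor")
    rows = []
    for i, inp in enumerate(PARAM_NAMES):
        for j, out in enumerate(OUTPUT_NAMES):
            p5s, meds, p95s = [], [], []
            per_range: dict = {}
            n_valid = n_invalid = 0
            for t in tensors:
                v = t.s[t.valid[:, i, j], i, j]
                n_valid += v.size
                n_invalid += int(t.s.shape[0] - v.size)
                tag = f"{t.rmax:g}"
                if v.size == 0:
                    per_range[f"mean_{tag}"] = math.nan
                    per_range[f"sd_{tag}"] = math.nan
                    per_range[f"class_{tag}"] = "unavailable"
                    continue
                p5s.append(np.percentile(v, 5))
                meds.append(np.median(v))
                p95s.append(np.percentile(v, 95))
                mean = float(v.mean())
                sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
                per_range[f"mean_{tag}"] = mean
                per_range[f"sd_{tag}"] = sd
                per_range[f"class_{tag}"] = classify_consistency(mean, sd)
            row = {"input": inp, "output": out,
                   "p5": float(np.mean(p5s)) if p5s else math.nan,
                   "median": float(np.mean(meds)) if meds else math.nan,
                   "p95": float(np.mean(p95s)) if p95s else math.nan,
                   "n_valid": n_valid, "n_invalid": n_invalid,
                   "available": bool(meds)}
            row.update(per_range)
            rows.append(row)
    return pd.DataFrame(rows)


def rank_inputs(summaries: pd.DataFrame) -> list[str]:
    """Inputs ordered most-to-least influential: by the mean over outputs of
    the absolute averaged median sensitivity.  Ties break lexicographically."""
    score = (summaries.assign(abs_med=summaries["median"].abs())
             .groupby("input")["abs_med"].mean())
    return sorted(score.index, key=lambda k: (-score[k], k))


# ---------------------------------------------------------------------------
# Designed-experiment methods
# ---------------------------------------------------------------------------

def oat_analysis(nominal: np.ndarray | None = None,
                 percent_range: float = 0.07,
                 evaluate=None, config: SimConfig | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-at-a-time variation: 16 x 2 runs at nominal*(1 +- percent_range).

    Sensitivity per pair is the normalized central difference
    ``(F_hi - F_lo) / (2 * percent_range * F_nominal)``.  A pair is
    unavailable when either endpoint (or the nominal run) fails the
    oscillation check.  OAT cannot detect interactions: varying one input
    never reveals terms involving two inputs.
    """
    if percent_range <= 0:
        raise ValueError("percent_range must be positive")
    nominal = nominal_array() if nominal is None else np.asarray(nominal, float)
    evaluate = evaluate or _default_evaluate(config)

    base = evaluate(nominal)
    f_base = measures_vector(base)
    design_rows, sens_rows = [], []
    for i, name in enumerate(PARAM_NAMES):
        results = {}
        for lvl, sign in (("low", -1.0), ("high", 1.0)):
            p = nominal.copy()
            p[i] *= 1.0 + sign * percent_range
            m = evaluate(p)
            results[lvl] = m
            design_rows.append({"input": name, "level": lvl,
                                "factor": 1.0 + sign * percent_range,
                                "oscillating": m.oscillating})
        f_lo = measures_vector(results["low"])
        f_hi = measures_vector(results["high"])
        usable = (base.oscillating and results["low"].oscillating
                  and results["high"].oscillating)
        for j, out in enumerate(OUTPUT_NAMES):
            ok = usable and np.isfinite(f_base[j]) and f_base[j] != 0 \
                and np.isfinite(f_lo[j]) and np.isfinite(f_hi[j])
            val = ((f_hi[j] - f_lo[j]) / (2.0 * percent_range * f_base[j])
                   if ok else math.nan)
            sens_rows.append({"input": name, "output": out,
                              "s_star": val, "available": bool(ok)})
    return pd.DataFrame(design_rows), pd.DataFrame(sens_rows)


def cotter_design(n_params: int, low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Cotter's systematic fractional factorial: 2n+2 runs.

    Row 0: all low.  Rows 1..n: parameter j high, rest low.  Rows n+1..2n:
    parameter j low, rest high.  Row 2n+1: all high.
    """
    low = np.broadcast_to(np.asarray(low, float), (n_params,)).copy()
    high = np.broadcast_to(np.asarray(high, float), (n_params,)).copy()
    if not np.all(low < high):
        raise ValueError("need low < high per parameter")
    rows = [low.copy()]
    for j in range(n_params):
        r = low.copy(); r[j] = high[j]
        rows.append(r)
    for j in range(n_params):
        r = high.copy(); r[j] = low[j]
        rows.append(r)
    rows.append(high.copy())
    return np.array(rows)


def cotter_indices(responses: np.ndarray) -> pd.DataFrame:
    """Odd/even-order effect indices from the 2n+2 Cotter responses.

    For input j with all-low response y0, one-high responses y_h(j),
    one-low responses y_l(j) and all-high response y1:
    C_odd(j)  = 1/4 [(y1 - y_l(j)) + (y_h(j) - y0)]   (odd-order effects)
    C_even(j) = 1/4 [(y1 - y_l(j)) - (y_h(j) - y0)]   (even-order/interactions)
    Ranking uses |C_odd| + |C_even|.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim != 1 or y.size < 4 or y.size % 2 != 0:
        raise ValueError("expected 2n+2 responses")
    if not np.all(np.isfinite(y)):
        raise ValueError("all responses must be valid; Cotter's method "
                         "fails when any run fails")
    n = (y.size - 2) // 2
    y0, y1 = y[0], y[-1]
    y_high = y[1:n + 1]
    y_low = y[n + 1:2 * n + 1]
    c_odd = 0.25 * ((y1 - y_low) + (y_high - y0))
    c_even = 0.25 * ((y1 - y_low) - (y_high - y0))
    total = np.abs(c_odd) + np.abs(c_even)
    names = PARAM_NAMES[:n] if n <= N_PARAMS else [f"x{j}" for j in range(n)]
    return pd.DataFrame({"input": list(names), "c_odd": c_odd,
                         "c_even": c_even, "total": total})


# --- D-optimal quadratic response surface ----------------------------------

def quadratic_model_matrix(Z: np.ndarray) -> np.ndarray:
    """Full second-order model matrix: intercept, linear, pure quadratic and
    pairwise interaction terms (153 columns for 16 inputs)."""
    Z = np.atleast_2d(np.asarray(Z, float))
    n, k = Z.shape
    cols = [np.ones(n)]
    cols.extend(Z[:, j] for j in range(k))
    cols.extend(Z[:, j] ** 2 for j in range(k))
    for j in range(k):
        for l in range(j + 1, k):
            cols.append(Z[:, j] * Z[:, l])
    return np.column_stack(cols)


def n_quadratic_terms(k: int) -> int:
    return 1 + 2 * k + k * (k - 1) // 2


def rsm_candidates(n_params: int = N_PARAMS, n_sobol: int = 4096,
                   seed: int = 0) -> np.ndarray:
    """Candidate set on the [-1, 1] hypercube: scrambled Sobol points plus
    the centre and the +-1 axis points."""
    from scipy.stats import qmc
    sob = qmc.Sobol(d=n_params, scramble=True, rng=np.random.default_rng(seed))
    pts = 2.0 * sob.random(n_sobol) - 1.0
    axis = [np.zeros(n_params)]
    for j in range(n_params):
        for s in (-1.0, 1.0):
            z = np.zeros(n_params); z[j] = s
            axis.append(z)
    return np.vstack([pts, np.array(axis)])


def d_optimal_design(candidates: np.ndarray, n_points: int,
                     max_exchange_passes: int = 20,
                     ridge: float = 1e-9) -> np.ndarray:
    """Indices of a D-optimal subset for the full quadratic model.

    Greedy sequential construction (maximizing the determinant gain
    ``1 + x' M^-1 x`` of the information matrix) followed by Fedorov
    exchange passes.  Deterministic for a given candidate set.
    """
    X = quadratic_model_matrix(candidates)
    nc, p = X.shape
    if n_points >= nc:
        return np.arange(nc)
    if n_points < 1:
        raise ValueError("n_points must be >= 1")

    scale = ridge * np.mean(np.sum(X ** 2, axis=1))
    Minv = np.eye(p) / scale
    chosen: list[int] = []
    in_design = np.zeros(nc, dtype=bool)
    for _ in range(n_points):
        V = X @ Minv
        gains = np.einsum("ij,ij->i", V, X)
        gains[in_design] = -np.inf
        k = int(np.argmax(gains))
        chosen.append(k)
        in_design[k] = True
        # Sherman-Morrison rank-1 update
        v = Minv @ X[k]
        Minv -= np.outer(v, v) / (1.0 + X[k] @ v)

    def info_inv(idx):
        M = X[idx].T @ X[idx] + scale * np.eye(p)
        return np.linalg.inv(M)

    idx = np.array(chosen)
    Minv = info_inv(idx)
    for _ in range(max_exchange_passes):
        Xd = X[idx]
        g_out = np.einsum("ij,ij->i", X @ Minv, X)      # candidate leverages
        g_in = np.einsum("ij,ij->i", Xd @ Minv, Xd)     # design leverages
        D = Xd @ Minv @ X.T                             # cross terms
        # Fedorov delta for swapping design row j with candidate k
        delta = (g_out[None, :] - g_in[:, None]
                 - (g_in[:, None] * g_out[None, :] - D ** 2))
        delta[:, idx] = -np.inf
        j, k = np.unravel_index(np.argmax(delta), delta.shape)
        if delta[j, k] <= 1e-10:
            break
        idx[j] = k
        Minv = info_inv(idx)
    return np.sort(idx)


def log_det_information(candidates: np.ndarray, idx: np.ndarray) -> float:
    X = quadratic_model_matrix(candidates[idx])
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return logdet if sign > 0 else -math.inf


def factor_map(rmax: float) -> tuple[float, float]:
    """Linear map between normalized coordinate z in [-1, 1] and the
    multiplicative factor range [1/rmax, rmax]: factor = c + s*z."""
    lo, hi = 1.0 / rmax, rmax
    return (hi + lo) / 2.0, (hi - lo) / 2.0


def z_of_nominal(rmax: float) -> float:
    c, s = factor_map(rmax)
    return (1.0 - c) / s


def evaluate_design(Z: np.ndarray, rmax: float,
                    nominal: np.ndarray | None = None,
                    evaluate=None, config: SimConfig | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate every design point; returns (responses (n, 6), valid (n,))."""
    nominal = nominal_array() if nominal is None else np.asarray(nominal, float)
    evaluate = evaluate or _default_evaluate(config)
    c, s = factor_map(rmax)
    Z = np.atleast_2d(Z)
    Y = np.full((Z.shape[0], N_OUTPUTS), np.nan)
    ok = np.zeros(Z.shape[0], dtype=bool)
    for i, z in enumerate(Z):
        m = evaluate(nominal * (c + s * z))
        if m.oscillating:
            Y[i] = measures_vector(m)
            ok[i] = np.all(np.isfinite(Y[i]))
    return Y, ok


@dataclass
class QuadraticSurface:
    """Per-output least-squares quadratic response surface over z-space."""

    coefs: np.ndarray          # (n_terms, n_outputs)
    outputs: tuple[str, ...]
    n_params: int
    rmax: float
    residual_rms: np.ndarray   # per output

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return quadratic_model_matrix(np.atleast_2d(Z)) @ self.coefs

    def gradient(self, z: np.ndarray) -> np.ndarray:
        """Analytic gradient d(output)/dz at one point: (n_params, n_outputs)."""
        k = self.n_params
        z = np.asarray(z, float)
        lin = self.coefs[1:k + 1]
        quad = self.coefs[k + 1:2 * k + 1]
        grad = lin + 2.0 * quad * z[:, None]
        pos = 2 * k + 1
        for j in range(k):
            for l in range(j + 1, k):
                b = self.coefs[pos]
                grad[j] += b * z[l]
                grad[l] += b * z[j]
                pos += 1
        return grad


def fit_rsm(Z: np.ndarray, responses: np.ndarray,
            valid: np.ndarray | None = None,
            rmax: float = 1.10) -> QuadraticSurface:
    """Least-squares fit of the full quadratic model to design responses."""
    Z = np.atleast_2d(np.asarray(Z, float))
    Y = np.atleast_2d(np.asarray(responses, float))
    if Y.ndim == 1:
        Y = Y[:, None]
    if valid is not None:
        Z, Y = Z[valid], Y[valid]
    k = Z.shape[1]
    p = n_quadratic_terms(k)
    if Z.shape[0] < p:
        raise ValueError(f"need >= {p} valid responses, have {Z.shape[0]}")
    X = quadratic_model_matrix(Z)
    coefs, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"rank-deficient quadratic fit: rank {rank} < {p} terms")
    resid = Y - X @ coefs
    rms = np.sqrt(np.mean(resid ** 2, axis=0))
    outputs = OUTPUT_NAMES if Y.shape[1] == N_OUTPUTS else tuple(
        f"y{j}" for j in range(Y.shape[1]))
    return QuadraticSurface(coefs=coefs, outputs=outputs, n_params=k,
                            rmax=rmax, residual_rms=rms)


def rsm_sensitivity(surface: QuadraticSurface,
                    at: np.ndarray | None = None) -> pd.DataFrame:
    """Non-dimensional S* from the analytic slope of the fitted surface.

    Defaults to the nominal point (factor 1 for every input).  With the
    linear factor map ``f = c + s*z``, ``S* = (f_j / F) * dF/dz_j / s``.
    """
    c, s = factor_map(surface.rmax)
    k = surface.n_params
    z = np.full(k, z_of_nominal(surface.rmax)) if at is None else np.asarray(at, float)
    F = surface.predict(z)[0]
    grad = surface.gradient(z)
    f = c + s * z
    rows = []
    for i in range(k):
        for j, out in enumerate(surface.outputs):
            ok = np.isfinite(F[j]) and F[j] != 0
            val = (f[i] / F[j]) * grad[i, j] / s if ok else math.nan
            name = PARAM_NAMES[i] if k == N_PARAMS else f"x{i}"
            rows.append({"input": name, "output": out, "s_star": val,
                         "available": bool(ok)})
    return pd.DataFrame(rows)


def validate_rsm(surface: QuadraticSurface,
                 n_points: int = 100, seed: int = 0,
                 nominal: np.ndarray | None = None,
                 evaluate=None, config: SimConfig | None = None) -> dict:
    """Prediction error at random in-range points against fresh simulations.

    Reports the mean over points of the maximum over outputs of the relative
    error ("average maximum error"), plus per-output mean errors.  Failed
    simulations are excluded and counted.
    """
    rng = np.random.default_rng(seed)
    Z = rng.uniform(-1.0, 1.0, (n_points, surface.n_params))
    Y, ok = evaluate_design(Z, surface.rmax, nominal=nominal,
                            evaluate=evaluate, config=config)
    pred = surface.predict(Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(pred - Y) / np.abs(Y)
    rel = rel[ok]
    max_per_point = rel.max(axis=1)
    return {
        "avg_max_error": float(max_per_point.mean()) if rel.size else math.nan,
        "per_output_mean_error": {
            out: float(rel[:, j].mean()) if rel.size else math.nan
            for j, out in enumerate(surface.outputs)},
        "n_valid": int(ok.sum()),
        "n_failed": int((~ok).sum()),
    }
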