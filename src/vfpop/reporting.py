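"""Figures, result archives and the end-to-end study pipeline.

Renders the study's visualizations -- the multi-dimensional sensitivity
distribution (MDSD) grid, the mean-vs-standard-deviation consistency plot
and the success-rate curves -- and orchestrates the full pipeline
(population generation -> measures -> sensitivities -> summaries -> figures)
for each configured sampling range, with every stage seeded and archived as
CSV/JSON so figures can be regenerated from the archive alone.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .model import SimConfig
from .measures import NormalPhonationCriteria
from .population import (
    RMAX_GRID,
    PopulationSample,
    fit_all_densities,
    adaptive_success_rate,
    generate_population,
    nominal_array,
)
from .sensitivity import (
    OUTPUT_NAMES,
    SensitivityTensor,
    pair_mean_sd,
    population_sensitivity,
    rank_inputs,
    summarize_pairs,
)

logger = logging.getLogger("vfpop")

__all__ = [
    "RunConfig",
    "ResultsArchive",
    "mdsd_panel_matrix",
    "plot_mdsd",
    "plot_mean_sd",
    "plot_success",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Study configuration; defaults reproduce the full study design."""

    # simulation block
    dt_ms: float = 0.01
    duration_ms: float = 1500.0
    transient_ms: float = 500.0
    x_init_cm: float = 0.01
    rho: float = 0.00113
    # population block
    rmax_grid: tuple[float, ...] = RMAX_GRID
    n_target: int = 1000
    seed: int = 0
    max_attempts: int | None = None
    # sensitivity block
    delta: float = 0.01
    outputs: tuple[str, ...] = OUTPUT_NAMES
    # adaptive resampling block
    resample: bool = False
    n_resample: int = 2000
    # output
    out_dir: str = "results"

    def sim_config(self) -> SimConfig:
        return SimConfig(dt=self.dt_ms, duration=self.duration_ms,
                         transient=self.transient_ms,
                         x_init=(self.x_init_cm, self.x_init_cm),
                         rho=self.rho)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["rmax_grid"] = list(d["rmax_grid"])
        d["outputs"] = list(d["outputs"])
        blocks = {
            "simulation": {k: d[k] for k in
                           ("dt_ms", "duration_ms", "transient_ms", "x_init_cm", "rho")},
            "population": {k: d[k] for k in
                           ("rmax_grid", "n_target", "seed", "max_attempts")},
            "sensitivity": {k: d[k] for k in ("delta", "outputs")},
            "resampling": {k: d[k] for k in ("resample", "n_resample")},
            "output": {"out_dir": d["out_dir"]},
        }
        text = yaml.safe_dump(blocks, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        blocks = yaml.safe_load(Path(path).read_text())
        flat: dict = {}
        for block in blocks.values():
            flat.update(block or {})
        if "rmax_grid" in flat and flat["rmax_grid"] is not None:
            flat["rmax_grid"] = tuple(flat["rmax_grid"])
        if "outputs" in flat and flat["outputs"] is not None:
            flat["outputs"] = tuple(flat["outputs"])
        known = set(cls.__dataclass_fields__)
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


@dataclass
class ResultsArchive:
    root: Path
    manifest: dict = field(default_factory=dict)
    complete: bool = False

    def write_manifest(self) -> None:
        self.manifest["complete"] = self.complete
        (self.root / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def mdsd_panel_matrix(values_per_range: list[np.ndarray], n_bins: int = 50,
                      clip: tuple[float, float] | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram image for one input-output pair: one normalized column of
    vertical bins per sampling range.  Returns (matrix (n_bins, n_ranges),
    bin_edges); each column sums to 1 (empty columns stay 0)."""
    pooled = np.concatenate([v for v in values_per_range if v.size])
    if pooled.size == 0:
        raise ValueError("no sensitivity values to plot")
    lo, hi = clip if clip is not None else np.percentile(pooled, [1, 99])
    if not hi > lo:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    cols = []
    for v in values_per_range:
        counts, _ = np.histogram(np.clip(v, lo, hi), bins=edges)
        total = counts.sum()
        cols.append(counts / total if total else counts.astype(float))
    return np.column_stack(cols), edges


def plot_mdsd(tensors: list[SensitivityTensor], path,
              input_order: list[str] | None = None,
              output_order: list[str] | None = None,
              n_bins: int = 50) -> Path:
    """Multi-dimensional sensitivity distribution plot.

    Outputs as rows (ranked by mean sensitivity), inputs as columns (most to
    least influential); each panel shows one grayscale histogram column per
    Rmax, darkest where sensitivity values are most common.  The sensitivity
    axis of each row is clipped at the pooled 1st-99th percentile.
    """
    from .model import PARAM_NAMES
    if not tensors or not any(t.valid.any() for t in tensors):
        raise ValueError("no sensitivity data to plot")
    summ = summarize_pairs(tensors)
    if input_order is None:
        input_order = rank_inputs(summ)
    if output_order is None:
        med = summ.groupby("output")["median"].apply(lambda s: s.abs().mean())
        output_order = sorted(med.index, key=lambda k: -med[k])
    pidx = {n: i for i, n in enumerate(PARAM_NAMES)}
    oidx = {n: j for j, n in enumerate(OUTPUT_NAMES)}

    nrows, ncols = len(output_order), len(input_order)
    fig, axes = plt.subplots(nrows, ncols,
                             figsize=(1.1 * ncols + 1, 1.4 * nrows + 1),
                             squeeze=False)
    for r, out in enumerate(output_order):
        j = oidx[out]
        # common clip per output row so panels share a scale
        pooled = np.concatenate([
            t.s[t.valid[:, i, j], i, j] for t in tensors
            for i in range(len(PARAM_NAMES))])
        clip = tuple(np.percentile(pooled, [1, 99])) if pooled.size else (0, 1)
        for c, inp in enumerate(input_order):
            i = pidx[inp]
            vals = [t.s[t.valid[:, i, j], i, j] for t in tensors]
            ax = axes[r][c]
            try:
                img, edges = mdsd_panel_matrix(vals, n_bins=n_bins, clip=clip)
                ax.imshow(1.0 - img / max(img.max(), 1e-12), cmap="gray",
                          aspect="auto", origin="lower",
                          extent=(-0.5, len(tensors) - 0.5, edges[0], edges[-1]))
            except ValueError:
                pass
            ax.set_xticks([])
            if c == 0:
                ax.set_ylabel(out, fontsize=8)
            else:
                ax.set_yticks([])
            if r == 0:
                ax.set_title(inp, fontsize=8)
    fig.suptitle("Sensitivity distributions per input-output pair "
                 f"(columns per panel: Rmax = {[t.rmax for t in tensors]})",
                 fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_mean_sd(mean_sd: pd.DataFrame, path, label_outside: bool = True) -> Path:
    """Mean vs standard deviation of S* per pair, with consistency shading.

    Dark wedge: |mean| < sd (erratic pairs); light wedge: |mean| < 2 sd.
    Pairs outside the shading have effects consistent across the population.
    """
    df = mean_sd.dropna(subset=["mean", "sd"])
    if df.empty:
        raise ValueError("no pair summaries to plot")
    mmax = max(1.05 * df["mean"].abs().max(), 0.1)
    smax = max(1.05 * df["sd"].max(), 0.1)
    fig, ax = plt.subplots(figsize=(7, 5))
    xs = np.linspace(-mmax, mmax, 200)
    ax.fill_between(xs, np.abs(xs) / 2.0, smax, color="0.75", zorder=0)
    ax.fill_between(xs, np.abs(xs), smax, color="0.55", zorder=1)
    ax.scatter(df["mean"], df["sd"], s=14, color="k", zorder=2)
    if label_outside:
        for _, row in df.iterrows():
            if abs(row["mean"]) >= 2 * row["sd"]:
                ax.annotate(f"{row['input']}→{row['output']}",
                            (row["mean"], row["sd"]), fontsize=7,
                            textcoords="offset points", xytext=(3, 3))
    ax.set_xlim(-mmax, mmax)
    ax.set_ylim(0, smax)
    ax.set_xlabel("mean sensitivity")
    ax.set_ylabel("standard deviation of sensitivity")
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_success(curves: pd.DataFrame, path) -> Path:
    """Success rate vs Rmax for uniform (solid) and adaptive (dashed) sampling.

    ``curves`` needs columns rmax, uniform_rate and optionally adaptive_rate;
    at least two rmax points are required to show a trend.
    """
    if len(curves) < 2:
        raise ValueError("need success rates at >= 2 rmax values")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curves["rmax"], 100 * curves["uniform_rate"], "k-o",
            label="uniform sampling")
    if "adaptive_rate" in curves and curves["adaptive_rate"].notna().any():
        ax.plot(curves["rmax"], 100 * curves["adaptive_rate"], "k--s",
                label="adaptive resampling")
    ax.set_xlabel("Rmax")
    ax.set_ylabel("subjects with normal phonation (%)")
    ax.legend()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> ResultsArchive:
    """Run the full study: per range, generate a population, compute the
    sensitivity tensor and summaries, optionally resample adaptively, and
    render the figures.  Fully seeded; stages are archived as they finish."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    archive = ResultsArchive(root=root, manifest={
        "config": yaml.safe_load(config.to_yaml()), "seeds": {}, "stages": []})
    sim = config.sim_config()
    criteria = NormalPhonationCriteria()
    nominal = nominal_array()
    tensors: list[SensitivityTensor] = []
    curve_rows = []
    try:
        for k, rmax in enumerate(config.rmax_grid):
            seed = config.seed + 1000 * k
            archive.manifest["seeds"][f"rmax_{rmax:g}"] = seed
            logger.info("rmax=%g: generating %d subjects (seed %d)",
                        rmax, config.n_target, seed)
            pop = generate_population(
                nominal, rmax, config.n_target, criteria, seed=seed,
                max_attempts=config.max_attempts, config=sim)
            logger.info("rmax=%g: accepted %d / attempted %d (rate %.4f)",
                        rmax, pop.accepted, pop.attempted, pop.success_rate)
            tag = f"rmax_{rmax:g}"
            pop.write(root / f"population_{tag}.csv", root / f"population_{tag}.json")
            tensor = population_sensitivity(pop, delta=config.delta, config=sim)
            tensor.to_dataframe().to_csv(root / f"sensitivity_{tag}.csv", index=False)
            tensors.append(tensor)
            pair_mean_sd(tensor).to_csv(root / f"pair_mean_sd_{tag}.csv", index=False)
            row = {"rmax": rmax, "uniform_rate": pop.success_rate,
                   "adaptive_rate": math.nan}
            if config.resample and pop.accepted >= 10:
                densities = fit_all_densities(pop)
                ad = adaptive_success_rate(nominal, densities, rmax, criteria,
                                           n_samples=config.n_resample,
                                           seed=seed + 1, config=sim)
                row["adaptive_rate"] = ad.success_rate
            curve_rows.append(row)
            archive.manifest["stages"].append(tag)

        summaries = summarize_pairs(tensors)
        summaries.to_csv(root / "pair_summaries.csv", index=False)
        curves = pd.DataFrame(curve_rows)
        curves.to_csv(root / "success_rates.csv", index=False)

        plot_mdsd(tensors, root / "mdsd.png")
        plot_mdsd(tensors, root / "mdsd.svg")
        mid = tensors[len(tensors) // 2]
        plot_mean_sd(pair_mean_sd(mid), root / "mean_vs_sd.png")
        if len(curves) >= 2:
            plot_success(curves, root / "success_rates.png")
        archive.complete = True
    finally:
        archive.write_manifest()
    return archive
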