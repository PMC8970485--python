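"""Config-driven drivers chaining the modules into complete experiments.

Three in-silico experiments mirror the study designs this package supports:

* ``monoculture_size_sweep`` — one auxotroph, fully supplemented, grown at a
  fixed λ (and, as a control, at a fixed density) across droplet sizes;
  includes a λ-variability sub-run comparing endpoint spread at λ=5 vs λ=20.
* ``biculture_interaction_levels`` — the cross-feeding pair under the three
  supplementation scenarios (low/medium/high interaction) across droplet
  sizes, with composition ratios and trend labels.
* ``ode_regime_map`` — a grid over the secretion (α) and requirement (β)
  coefficients, classifying each cell's density sweep as Type 1 / Type 2 /
  mixed / none.

Each driver takes an :class:`ExperimentSpec`, writes CSV outputs (and
convenience plots) into ``output_dir`` when one is given, and returns its
tables; runs are deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import crossfeed_ode as ode
from . import population_stats as ps
from .droplet_model import DropletClass, density_for_lambda
from .synthetic_data import (
    LogisticKernel,
    SyntheticPlateConfig,
    generate_droplet_ensemble,
    generate_endpoint_table,
)

__all__ = [
    "ExperimentSpec",
    "run_experiment",
    "run_monoculture_size_sweep",
    "run_biculture_interaction_levels",
    "run_lambda_variability",
    "run_ode_regime_map",
    "DEFAULT_REGIME_ALPHAS",
    "DEFAULT_REGIME_BETAS",
]

log = logging.getLogger("dropcult")

EXPERIMENT_NAMES = (
    "monoculture_size_sweep",
    "biculture_interaction_levels",
    "lambda_variability",
    "ode_regime_map",
)

SWEEP_DIAMETERS_UM = (55.0, 100.0, 150.0)
BASE_LAMBDA = 5.0

# Default (α, β) grids for the regime map: α in mM/(cells·mL⁻¹)/hr, β in
# mM/(cells·mL⁻¹).  Chosen to span the qualitative regimes within the 48-h
# observation window: with weak secretion (small α) the lag stretches with
# dilution at an unchanged post-bootstrap rate (Type 1); with a high
# requirement (large β) growth is capped at the slow exchange-limited rate
# α/β, and in larger droplets the slowed growth overflows the window, so the
# apparent rate declines while the apparent lag stalls (Type 2).  Cells with
# an extreme cap fail to establish appreciable co-growth within the window
# (none) — the in-silico analogue of co-growth failure under the most
# strenuous interaction.
DEFAULT_REGIME_ALPHAS = (2e-10, 6e-10, 2e-9)
DEFAULT_REGIME_BETAS = (8e-10, 2.5e-9, 1.6e-8)
REGIME_DIAMETERS_UM = (55.0, 75.0, 100.0)


@dataclass(frozen=True)
class ExperimentSpec:
    """Named experiment plus nested parameter overrides.

    ``parameters`` is merged over each driver's defaults; unknown keys raise.
    ``seed`` feeds every stochastic component; ODE-only runs are inherently
    deterministic.
    """

    name: str
    parameters: Mapping[str, Any] = field(default_factory=dict)
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(
                f"unknown experiment {self.name!r}; expected one of {EXPERIMENT_NAMES}"
            )


def _merge(defaults: dict[str, Any], overrides: Mapping[str, Any]) -> dict[str, Any]:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(overrides)
    return merged


def _outdir(spec: ExperimentSpec) -> Path | None:
    if spec.output_dir is None:
        return None
    p = Path(spec.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_csv(frame: pd.DataFrame, outdir: Path | None, name: str) -> None:
    if outdir is not None:
        path = outdir / name
        frame.to_csv(path, index=False)
        log.info("wrote %s (%d rows)", path, len(frame))


def _plot_fit_parameters(
    fits: pd.DataFrame, outdir: Path | None, name: str, hue: str = "strain"
) -> None:
    """Convenience K/r/τ-vs-diameter panels; all analysis reads the CSVs."""
    if outdir is None:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharex=True)
    for label, grp in fits.groupby(hue):
        grp = grp.sort_values("diameter_um")
        for ax, col in zip(axes, ("K", "r", "tau")):
            ax.plot(grp["diameter_um"], grp[col], marker="o", label=str(label))
    for ax, (col, unit) in zip(
        axes, (("K", "fold"), ("r", "hr$^{-1}$"), ("tau", "h"))
    ):
        ax.set_xlabel("diameter (μm)")
        ax.set_ylabel(f"{col} ({unit})")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / name, dpi=120)
    plt.close(fig)


def run_experiment(spec: ExperimentSpec) -> dict[str, Any]:
    """Dispatch an :class:`ExperimentSpec` to its driver."""
    driver = {
        "monoculture_size_sweep": run_monoculture_size_sweep,
        "biculture_interaction_levels": run_biculture_interaction_levels,
        "lambda_variability": run_lambda_variability,
        "ode_regime_map": run_ode_regime_map,
    }[spec.name]
    return driver(spec)


# ---------------------------------------------------------------------------
# Monoculture size sweep
# ---------------------------------------------------------------------------

def run_monoculture_size_sweep(spec: ExperimentSpec) -> dict[str, Any]:
    """Monoculture kinetics across droplet sizes, fixed-λ and fixed-density.

    The ODE model provides deterministic fold-change curves per diameter; the
    synthetic generator provides endpoint summaries per diameter at the
    configured λ.  Returns ``{"fits": table, "summaries": table}``.
    """
    p = _merge(
        {
            "diameters_um": SWEEP_DIAMETERS_UM,
            "base_lambda": BASE_LAMBDA,
            "t_end_h": 48.0,
            "endpoint_droplets": 2000,
            "viability": 0.7,
        },
        spec.parameters,
    )
    outdir = _outdir(spec)
    strain = ode.monoculture_strain()
    medium = ode.medium_for_scenario("all")

    tables = []
    for mode in ("fixed_lambda", "fixed_density"):
        log.info("monoculture sweep: %s", mode)
        table = ode.sweep_density(
            p["diameters_um"], mode, p["base_lambda"], [strain], medium,
            t_end_h=p["t_end_h"],
        )
        table.insert(0, "mode", mode)
        tables.append(table)
    fits = pd.concat(tables, ignore_index=True)
    _write_csv(fits, outdir, "monoculture_fits.csv")
    _plot_fit_parameters(fits, outdir, "monoculture_fits.png", hue="mode")

    # endpoint variability per diameter via the synthetic ensemble
    summaries = []
    for d in p["diameters_um"]:
        fit_row = fits[
            (fits["mode"] == "fixed_lambda") & (fits["diameter_um"] == d)
        ].iloc[0]
        cfg = SyntheticPlateConfig(
            droplet=DropletClass(d, {strain.name: p["base_lambda"]}),
            kinetics={
                strain.name: LogisticKernel(
                    K=max(fit_row["K"], 1.0), r=fit_row["r"], tau=fit_row["tau"]
                )
            },
            viability_by_strain={strain.name: p["viability"]},
            droplets_per_well=p["endpoint_droplets"],
            duration_h=p["t_end_h"],
            seed=spec.seed,
        )
        ens = generate_droplet_ensemble(cfg)
        summary = ps.summarize(generate_endpoint_table(ens), channel="green")
        summaries.append(
            {"diameter_um": d, "n": summary.n, "mean": summary.mean,
             "sd": summary.sd}
        )
    summary_table = pd.DataFrame(summaries)
    _write_csv(summary_table, outdir, "monoculture_endpoint_summaries.csv")
    return {"fits": fits, "summaries": summary_table}


# ---------------------------------------------------------------------------
# λ variability (endpoint sd at λ=5 vs λ=20)
# ---------------------------------------------------------------------------

def run_lambda_variability(spec: ExperimentSpec) -> dict[str, Any]:
    """Endpoint-spread comparison between two encapsulation means.

    Both pools share the same absolute droplet capacity (same medium), so the
    high-λ pool averages founder heterogeneity over more cells and shows a
    narrower endpoint distribution.  Returns the per-replicate sd table and
    the median percent sd reduction.
    """
    p = _merge(
        {
            "diameter_um": 100.0,
            "lambda_low": 5.0,
            "lambda_high": 20.0,
            "viability": 0.7,
            "kernel": LogisticKernel(K=269.7, r=0.69, tau=2.0),
            "n_droplets": 2000,
            "n_replicates": 100,
        },
        spec.parameters,
    )
    outdir = _outdir(spec)
    strain = "S1_dIlvD"
    rows = []
    seeds = np.random.SeedSequence(spec.seed).spawn(p["n_replicates"])
    for rep, ss in enumerate(seeds):
        child = np.random.default_rng(ss)
        sds = {}
        for label, lam in (("low", p["lambda_low"]), ("high", p["lambda_high"])):
            cfg = SyntheticPlateConfig(
                droplet=DropletClass(p["diameter_um"], {strain: lam}),
                kinetics={strain: p["kernel"]},
                viability_by_strain={strain: p["viability"]},
                reference_lambda_by_strain={strain: p["lambda_low"]},
                droplets_per_well=p["n_droplets"],
                seed=spec.seed,  # unused: rng passed explicitly
            )
            ens = generate_droplet_ensemble(cfg, rng=child)
            summary = ps.summarize(generate_endpoint_table(ens), channel="green")
            sds[label] = summary.sd
        rows.append(
            {
                "replicate": rep,
                "sd_low_lambda": sds["low"],
                "sd_high_lambda": sds["high"],
                "sd_reduction_pct": 100.0 * (1.0 - sds["high"] / sds["low"]),
            }
        )
    table = pd.DataFrame(rows)
    _write_csv(table, outdir, "lambda_variability.csv")
    median_reduction = float(table["sd_reduction_pct"].median())
    log.info("median endpoint sd reduction: %.1f%%", median_reduction)
    return {"replicates": table, "median_sd_reduction_pct": median_reduction}


# ---------------------------------------------------------------------------
# Bi-culture interaction levels
# ---------------------------------------------------------------------------

def run_biculture_interaction_levels(spec: ExperimentSpec) -> dict[str, Any]:
    """The cross-feeding pair under the three supplementation scenarios.

    For each scenario (isoleucine / valine+leucine / none) the density sweep
    over droplet sizes is simulated and fit; composition ratios (S1 fold over
    S2 fold) and trend labels are derived per scenario.
    """
    p = _merge(
        {
            "diameters_um": SWEEP_DIAMETERS_UM,
            "base_lambda": BASE_LAMBDA,
            "scenarios": ("isoleucine", "valine_leucine", "none"),
            "alpha_s1": ode.ALPHA_HIGH,
            "alpha_s2": ode.ALPHA_HIGH,
            "beta": ode.BETA_DEFAULT,
            "secretion_scale": None,
            "t_end_h": 48.0,
        },
        spec.parameters,
    )
    outdir = _outdir(spec)
    strains = ode.default_strains(
        alpha_s1=p["alpha_s1"], alpha_s2=p["alpha_s2"], beta=p["beta"],
        secretion_scale=p["secretion_scale"],
    )
    s1, s2 = strains
    fit_tables = []
    ratios = []
    labels = {}
    for scenario in p["scenarios"]:
        log.info("bi-culture scenario: %s", scenario)
        medium = ode.medium_for_scenario(scenario)
        table = ode.sweep_density(
            p["diameters_um"], "fixed_lambda", p["base_lambda"], strains,
            medium, t_end_h=p["t_end_h"],
        )
        table.insert(0, "scenario", scenario)
        fit_tables.append(table)
        for d in p["diameters_um"]:
            sub = table[table["diameter_um"] == d].set_index("strain")
            ratios.append(
                {
                    "scenario": scenario,
                    "diameter_um": d,
                    "ratio_s1_over_s2": ps.composition_ratio(
                        sub.loc[s1.name, "K"], sub.loc[s2.name, "K"]
                    ),
                }
            )
        try:
            labels[scenario] = ode.classify_trend(table).label
        except ValueError:
            labels[scenario] = "none"
    fits = pd.concat(fit_tables, ignore_index=True)
    ratio_table = pd.DataFrame(ratios)
    _write_csv(fits, outdir, "biculture_fits.csv")
    _write_csv(ratio_table, outdir, "biculture_composition_ratios.csv")
    for scenario, grp in fits.groupby("scenario"):
        _plot_fit_parameters(grp, outdir, f"biculture_fits_{scenario}.png")
    if outdir is not None:
        (outdir / "biculture_trend_labels.json").write_text(
            json.dumps(labels, indent=2)
        )
    return {"fits": fits, "ratios": ratio_table, "trend_labels": labels}


# ---------------------------------------------------------------------------
# Regime map over (α, β)
# ---------------------------------------------------------------------------

def run_ode_regime_map(spec: ExperimentSpec) -> dict[str, Any]:
    """Trend classification over a grid of secretion and requirement levels.

    For each (α, β) cell a fixed-λ density sweep of the unsupplemented
    bi-culture is simulated, fit, and classified.  Cells whose fits fail are
    labeled 'none'.  Returns the label grid and the underlying fit tables.
    """
    p = _merge(
        {
            "alphas": DEFAULT_REGIME_ALPHAS,
            "betas": DEFAULT_REGIME_BETAS,
            "diameters_um": REGIME_DIAMETERS_UM,
            "base_lambda": BASE_LAMBDA,
            "t_end_h": 48.0,
        },
        spec.parameters,
    )
    if len(p["alphas"]) < 3 or len(p["betas"]) < 3:
        raise ValueError("regime map needs >= 3 alpha and >= 3 beta values")
    outdir = _outdir(spec)
    medium = ode.medium_for_scenario("none")
    rows = []
    fit_tables = []
    for alpha in p["alphas"]:
        for beta in p["betas"]:
            strains = ode.default_strains(
                alpha_s1=alpha, alpha_s2=alpha, beta=beta, secretion_scale={}
            )
            try:
                table = ode.sweep_density(
                    p["diameters_um"], "fixed_lambda", p["base_lambda"],
                    strains, medium, t_end_h=p["t_end_h"],
                )
                cls = ode.classify_trend(table)
                label = cls.label
                d_r, d_tau = cls.delta_r_rel, cls.delta_tau_rel
            except (ValueError, RuntimeError) as exc:
                log.warning("regime cell (%.2g, %.2g) unfit: %s", alpha, beta, exc)
                table = pd.DataFrame()
                label, d_r, d_tau = "none", float("nan"), float("nan")
            if len(table):
                table.insert(0, "beta", beta)
                table.insert(0, "alpha", alpha)
                fit_tables.append(table)
            rows.append(
                {"alpha": alpha, "beta": beta, "label": label,
                 "delta_r_rel": d_r, "delta_tau_rel": d_tau}
            )
            log.info("regime cell alpha=%.2g beta=%.2g -> %s", alpha, beta,
                     rows[-1]["label"])
    grid = pd.DataFrame(rows)
    fits = (
        pd.concat(fit_tables, ignore_index=True) if fit_tables else pd.DataFrame()
    )
    _write_csv(grid, outdir, "regime_map.csv")
    _write_csv(fits, outdir, "regime_map_fits.csv")
    return {"grid": grid, "fits": fits}
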