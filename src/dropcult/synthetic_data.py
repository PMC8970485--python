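"""Seeded generator of droplet ensembles, plate-reader wells, and endpoints.

This module fabricates the two kinds of raw data the analysis consumes:

* well time series — each well of a microplate holds 10⁴–10⁶ droplets whose
  pooled fluorescence is read every 10 minutes; the generator averages
  per-droplet trajectories, adds a background offset and multiplicative
  lognormal measurement noise;
* per-droplet endpoint tables — droplet area plus per-channel total
  intensity at a chosen time, emulating image-analysis output.

Each droplet's trajectory is driven by its sampled founder cells: founder
counts are Poisson(λ) thinned by a viability probability, droplets with no
viable founder (or, in an obligate bi-culture, no viable partner) stay flat,
and per-founder heterogeneity perturbs both the growth rate and the saturated
signal.  Because the perturbations average over the founders, their effect
shrinks as 1/√n — raising λ narrows the endpoint distribution, which is the
mechanism behind the observed droplet-to-droplet variability reduction.

All randomness flows from a single integer seed; identical configurations
yield bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .droplet_model import DropletClass
from .population_stats import DropletEndpoint

__all__ = [
    "LogisticKernel",
    "SyntheticPlateConfig",
    "DropletEnsemble",
    "generate_droplet_ensemble",
    "aggregate_well_signal",
    "generate_plate",
    "generate_endpoint_table",
    "flat_fraction",
]

#: Fixed synthetic pixel scale: 1 px = 1 μm², so a droplet's projected area
#: in pixels is (π/4)·d².
PIXELS_PER_UM2 = 1.0

#: Channels assigned to strains in configuration order.
CHANNEL_ORDER = ("green", "red")


@dataclass(frozen=True)
class LogisticKernel:
    """Per-strain growth kernel: fold change K, rate r (hr⁻¹), lag τ (h).

    K is interpreted as the well-average fold change when droplets are seeded
    at the reference founder count (λ·viability); individual droplets with
    more or fewer founders share the same absolute saturated signal and hence
    realize a correspondingly smaller or larger fold change.
    """

    K: float
    r: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.K < 1 or self.r < 0 or self.tau < 0:
            raise ValueError("kernel requires K >= 1, r >= 0, tau >= 0")


@dataclass(frozen=True)
class SyntheticPlateConfig:
    """Everything needed to fabricate one plate's worth of droplet data.

    Attributes
    ----------
    droplet : DropletClass
        Droplet size and per-strain λ.
    kinetics : mapping
        Strain → LogisticKernel.  Strains listed here must match the droplet's
        λ mapping; channels (green, red) are assigned in mapping order.
    viability_by_strain : mapping
        Probability that a founder cell can grow (default 1).
    reference_lambda_by_strain : mapping or None
        λ at which each kernel's K is anchored.  Defaults to the configured λ;
        set it to a common reference when comparing different λ in the same
        medium, so the absolute per-droplet capacity stays fixed.
    partner_required : bool
        If True (obligate cross-feeding), a droplet grows only when every
        strain has at least one viable founder.
    rate_cv, capacity_cv : float
        Per-founder coefficients of variation of growth rate and saturated
        signal; per-droplet effects scale as cv/√n_founders.
    endpoint_noise_cv : float
        λ-independent per-droplet multiplicative measurement noise (droplet
        segmentation / brightness variability in image analysis).  Applied
        to the whole trajectory, so it cancels in per-droplet fold change
        but widens endpoint distributions.
    background : float or None
        Plate-reader background offset (a.u.); None → 5% of the largest
        strain capacity.
    noise_sd : float
        Sd of the multiplicative lognormal measurement noise.
    read_interval_min, duration_h : float
        Read cadence (default 10 min) and total duration (default 24 h).
    """

    droplet: DropletClass
    kinetics: Mapping[str, LogisticKernel]
    viability_by_strain: Mapping[str, float] = field(default_factory=dict)
    reference_lambda_by_strain: Mapping[str, float] | None = None
    partner_required: bool = False
    rate_cv: float = 0.2
    capacity_cv: float = 0.3
    endpoint_noise_cv: float = 0.1
    background: float | None = None
    noise_sd: float = 0.01
    read_interval_min: float = 10.0
    duration_h: float = 24.0
    n_wells: int = 3
    droplets_per_well: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.kinetics) != set(self.droplet.lambda_by_strain):
            raise ValueError("kinetics strains must match the droplet's lambda map")
        if self.read_interval_min <= 0 or self.duration_h <= 0:
            raise ValueError("read interval and duration must be positive")
        if min(self.noise_sd, self.rate_cv, self.capacity_cv,
               self.endpoint_noise_cv) < 0:
            raise ValueError("noise and variability parameters must be >= 0")
        if self.droplets_per_well < 1 or self.n_wells < 1:
            raise ValueError("need at least one droplet and one well")
        for strain, p in self.viability_by_strain.items():
            if not 0 <= p <= 1:
                raise ValueError(f"viability for {strain!r} must be in [0,1]")

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self.droplet.lambda_by_strain)

    def viability(self, strain: str) -> float:
        return float(self.viability_by_strain.get(strain, 1.0))

    def reference_lambda(self, strain: str) -> float:
        if self.reference_lambda_by_strain is not None:
            return float(self.reference_lambda_by_strain[strain])
        return float(self.droplet.lambda_by_strain[strain])

    def capacity_au(self, strain: str) -> float:
        """Absolute saturated signal per droplet for one strain (a.u.)."""
        return self.kinetics[strain].K * self.reference_lambda(strain) * self.viability(strain)

    def time_grid_h(self) -> np.ndarray:
        dt = self.read_interval_min / 60.0
        return np.arange(0.0, self.duration_h + 0.5 * dt, dt)

    def channel_by_strain(self) -> dict[str, str]:
        return {s: CHANNEL_ORDER[i] for i, s in enumerate(self.strains)}

    def background_au(self) -> float:
        if self.background is not None:
            return float(self.background)
        return 0.05 * max(self.capacity_au(s) for s in self.strains)


@dataclass(frozen=True)
class DropletEnsemble:
    """Per-droplet trajectories plus founder-cell provenance for one pool."""

    time_h: np.ndarray
    signals: Mapping[str, np.ndarray]          # strain → (n_droplets, n_times)
    founders_total: Mapping[str, np.ndarray]
    founders_viable: Mapping[str, np.ndarray]
    config: SyntheticPlateConfig

    @property
    def n_droplets(self) -> int:
        return next(iter(self.signals.values())).shape[0]

    def fold_change(self, strain: str) -> np.ndarray:
        """Per-droplet fold-change matrix (flat droplets stay at 1)."""
        sig = self.signals[strain]
        init = sig[:, :1]
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(init > 0, sig / np.where(init > 0, init, 1.0), 1.0)
        return fc


def _logistic_matrix(
    t: np.ndarray, K: np.ndarray, r: np.ndarray, tau: float
) -> np.ndarray:
    # fold-change kernel: flat at 1 through the lag, then logistic (the
    # lag-modified logistic itself dips below 1 for t < τ, which a real
    # culture's signal does not)
    z = np.clip(-r[:, None] * (t[None, :] - tau), -700.0, 700.0)
    return np.maximum(K[:, None] / (1.0 + (K[:, None] - 1.0) * np.exp(z)), 1.0)


def generate_droplet_ensemble(
    cfg: SyntheticPlateConfig,
    rng: np.random.Generator | None = None,
    n_droplets: int | None = None,
) -> DropletEnsemble:
    """Sample one pool of droplets and their per-strain signal trajectories.

    Per droplet and strain: founder totals ~ Poisson(λ), viable founders ~
    Binomial(total, viability); a droplet with no viable founder of a strain
    contributes no signal in that channel (non-viable cells are treated as
    non-fluorescent), and in an obligate bi-culture any missing partner stops
    growth of all strains in that droplet.  Growing droplets follow a
    logistic trajectory whose rate and saturated signal carry per-founder
    perturbations averaged over the founders.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.droplets_per_well if n_droplets is None else n_droplets
    t = cfg.time_grid_h()
    totals: dict[str, np.ndarray] = {}
    viables: dict[str, np.ndarray] = {}
    for s in cfg.strains:
        tot = rng.poisson(cfg.droplet.lambda_by_strain[s], size=n)
        p = cfg.viability(s)
        totals[s] = tot
        viables[s] = rng.binomial(tot, p) if p < 1.0 else tot.copy()

    if cfg.partner_required and len(cfg.strains) > 1:
        community_ok = np.all(
            np.stack([viables[s] >= 1 for s in cfg.strains]), axis=0
        )
    else:
        community_ok = None

    signals: dict[str, np.ndarray] = {}
    for s in cfg.strains:
        kern = cfg.kinetics[s]
        n_v = viables[s]
        grows = n_v >= 1
        if community_ok is not None:
            grows = grows & community_ok
        # per-founder heterogeneity averages over the droplet's founders
        denom = np.sqrt(np.maximum(n_v, 1))
        r_d = kern.r * (1.0 + cfg.rate_cv * rng.standard_normal(n) / denom)
        r_d = np.clip(r_d, 0.0, None)
        cap = cfg.capacity_au(s) * (
            1.0 + cfg.capacity_cv * rng.standard_normal(n) / denom
        )
        cap = np.clip(cap, 1e-12, None)
        with np.errstate(divide="ignore"):
            K_d = np.where(n_v > 0, cap / np.maximum(n_v, 1), 1.0)
        K_d = np.clip(K_d, 1.0, None)
        sig = np.where(
            grows[:, None],
            n_v[:, None] * _logistic_matrix(t, K_d, r_d, kern.tau),
            n_v[:, None].astype(float),
        )
        if cfg.endpoint_noise_cv > 0:
            # static per-droplet factor: cancels in fold change, persists in
            # endpoint intensities
            gain = 1.0 + cfg.endpoint_noise_cv * rng.standard_normal(n)
            sig = sig * np.clip(gain, 0.05, None)[:, None]
        signals[s] = sig
    return DropletEnsemble(
        time_h=t, signals=signals, founders_total=totals,
        founders_viable=viables, config=cfg,
    )


def flat_fraction(ensemble: DropletEnsemble, strain: str | None = None) -> float:
    """Fraction of droplets showing no growth of the given strain (or of any)."""
    cfg = ensemble.config
    if strain is not None:
        strains = [strain]
    else:
        strains = list(cfg.strains)
    flat = np.ones(ensemble.n_droplets, dtype=bool)
    for s in strains:
        sig = ensemble.signals[s]
        flat &= np.isclose(sig[:, -1], sig[:, 0])
    return float(np.mean(flat))


def aggregate_well_signal(
    ensemble: DropletEnsemble,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Pooled plate-reader readout: background + mean droplet signal + noise.

    Returns one raw series per channel.  Noise is multiplicative lognormal
    with sd ``config.noise_sd``; pass ``rng=None`` for a noise stream derived
    from the config seed (offset so it does not replay the encapsulation
    stream).
    """
    cfg = ensemble.config
    rng = np.random.default_rng(cfg.seed + 1_000_003) if rng is None else rng
    out: dict[str, np.ndarray] = {}
    bg = cfg.background_au()
    for s, channel in cfg.channel_by_strain().items():
        mean_sig = ensemble.signals[s].mean(axis=0)
        if cfg.noise_sd > 0:
            noise = np.exp(cfg.noise_sd * rng.standard_normal(mean_sig.size))
        else:
            noise = 1.0
        out[channel] = (bg + mean_sig) * noise
    return out


def generate_plate(
    cfg: SyntheticPlateConfig,
) -> tuple[pd.DataFrame, list[DropletEnsemble]]:
    """Generate ``n_wells`` independent wells from one seeded config.

    Returns a long-format table (well, strain, channel, time_h, value) of raw
    fluorescence plus the underlying per-well ensembles.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_wells)
    frames = []
    ensembles = []
    channel_of = cfg.channel_by_strain()
    for w, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        ens = generate_droplet_ensemble(cfg, rng=rng)
        raw = aggregate_well_signal(ens, rng=rng)
        ensembles.append(ens)
        for s in cfg.strains:
            frames.append(
                pd.DataFrame(
                    {
                        "well": f"W{w + 1}",
                        "strain": s,
                        "channel": channel_of[s],
                        "time_h": ens.time_h,
                        "value": raw[channel_of[s]],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True), ensembles


def generate_endpoint_table(
    ensemble: DropletEnsemble, at_time_h: float | None = None
) -> list[DropletEndpoint]:
    """Per-droplet endpoints at ``at_time_h`` (default: the final read).

    Droplet area comes from the configured diameter at the fixed synthetic
    pixel scale (1 px = 1 μm²); per-channel intensities are the droplet's
    strain signals at the requested time.  Deterministic given the ensemble.
    """
    cfg = ensemble.config
    t = ensemble.time_h
    if at_time_h is None:
        idx = len(t) - 1
    else:
        if not (t[0] <= at_time_h <= t[-1]):
            raise ValueError(
                f"at_time_h={at_time_h} outside trajectory span [{t[0]}, {t[-1]}]"
            )
        idx = int(np.argmin(np.abs(t - at_time_h)))
    area_px = math.pi / 4.0 * cfg.droplet.diameter_um**2 * PIXELS_PER_UM2
    channel_of = cfg.channel_by_strain()
    endpoints = []
    for i in range(ensemble.n_droplets):
        intensity = {
            channel_of[s]: float(ensemble.signals[s][i, idx]) for s in cfg.strains
        }
        endpoints.append(
            DropletEndpoint(droplet_id=i, area_px=area_px, intensity=intensity)
        )
    return endpoints
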