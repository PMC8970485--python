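"""Per-droplet endpoint statistics: distributions, variability, comparisons.

Image analysis of cultivated droplets yields, per droplet, a projected area
and a total fluorescence per channel.  Normalizing total intensity by droplet
area gives a size-comparable per-droplet density proxy (a.u./pixel); this
module summarizes populations of such endpoints, compares them with Student's
two-sample t-test, quantifies the variability reduction obtained by raising
the encapsulation mean λ, and computes bi-culture composition ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DropletEndpoint",
    "PopulationSummary",
    "summarize",
    "compare_populations",
    "sd_reduction",
    "composition_ratio",
    "endpoints_to_frame",
    "endpoints_from_frame",
]

CHANNELS = ("green", "red")
DEFAULT_BINS = 20


@dataclass(frozen=True)
class DropletEndpoint:
    """Endpoint measurement of one droplet: area and per-channel intensity."""

    droplet_id: int
    area_px: float
    intensity: Mapping[str, float]      # channel → total fluorescence, a.u.

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError(f"area must be positive, got {self.area_px}")

    @property
    def normalized(self) -> dict[str, float]:
        """Per-channel intensity divided by droplet area (a.u./pixel)."""
        return {c: v / self.area_px for c, v in self.intensity.items()}

    def normalized_value(self, channel: str = "total") -> float:
        """Area-normalized intensity of one channel, or the channel sum."""
        if channel == "total":
            return sum(self.intensity.values()) / self.area_px
        return self.intensity[channel] / self.area_px


@dataclass(frozen=True)
class PopulationSummary:
    """Sample statistics of a droplet population's normalized intensities.

    Keeps the raw per-droplet values so that downstream two-sample tests can
    be run on the same data the summary describes.
    """

    n: int
    mean: float
    sd: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    values: np.ndarray
    channel: str = "total"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary needs at least one droplet")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if int(np.sum(self.bin_counts)) != self.n:
            raise ValueError("histogram counts must sum to n")


def summarize(
    endpoints: Sequence[DropletEndpoint],
    channel: str = "total",
    bins: int | Sequence[float] = DEFAULT_BINS,
) -> PopulationSummary:
    """Mean, sample sd, and histogram of area-normalized intensity.

    ``channel`` selects 'green', 'red', or 'total' (the channel sum, used for
    bi-culture endpoints).  The sd is the sample standard deviation (ddof=1);
    a single droplet gives sd 0.
    """
    if len(endpoints) == 0:
        raise ValueError("endpoints must be non-empty")
    values = np.array([e.normalized_value(channel) for e in endpoints])
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    counts, edges = np.histogram(values, bins=bins)
    return PopulationSummary(
        n=values.size, mean=mean, sd=sd, bin_edges=edges, bin_counts=counts,
        values=values, channel=channel,
    )


def compare_populations(
    a: PopulationSummary, b: PopulationSummary
) -> tuple[float, float]:
    """Student's two-sample t-test (pooled variance), two-tailed.

    Returns ``(t, p)``.  Two zero-variance samples with equal means compare
    as identical (t=0, p=1).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both populations need n >= 2")
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean - b.mean), 0.0
    t, p = stats.ttest_ind(a.values, b.values, equal_var=True)
    return float(t), float(p)


def sd_reduction(
    pop_low_lambda: PopulationSummary, pop_high_lambda: PopulationSummary
) -> float:
    """Percent decrease in droplet-to-droplet sd from the low-λ to high-λ pool.

    Raising λ averages founder-cell heterogeneity over more cells per droplet,
    narrowing the endpoint distribution; the return value is
    100·(1 − sd_high/sd_low).
    """
    if pop_low_lambda.sd <= 0:
        raise ValueError("sd of the low-lambda population must be positive")
    return 100.0 * (1.0 - pop_high_lambda.sd / pop_low_lambda.sd)


def composition_ratio(fold_increase_s1: float, fold_increase_s2: float) -> float:
    """Ratio of the two strains' fold increases; >1 means S1-dominated."""
    if fold_increase_s2 <= 0:
        raise ValueError("denominator fold increase must be positive")
    return fold_increase_s1 / fold_increase_s2


# ---------------------------------------------------------------------------
# CSV interchange: droplet_id, area_px, green_total, red_total
# ---------------------------------------------------------------------------

def endpoints_to_frame(endpoints: Sequence[DropletEndpoint]) -> pd.DataFrame:
    records = [
        {
            "droplet_id": e.droplet_id,
            "area_px": e.area_px,
            "green_total": e.intensity.get("green", 0.0),
            "red_total": e.intensity.get("red", 0.0),
        }
        for e in endpoints
    ]
    return pd.DataFrame.from_records(
        records, columns=["droplet_id", "area_px", "green_total", "red_total"]
    )


def endpoints_from_frame(frame: pd.DataFrame) -> list[DropletEndpoint]:
    return [
        DropletEndpoint(
            droplet_id=int(row.droplet_id),
            area_px=float(row.area_px),
            intensity={"green": float(row.green_total), "red": float(row.red_total)},
        )
        for row in frame.itertuples(index=False)
    ]


def summary_to_dict(summary: PopulationSummary) -> dict:
    """JSON-ready form of a PopulationSummary (histogram included)."""
    return {
        "n": summary.n,
        "channel": summary.channel,
        "mean": summary.mean,
        "sd": summary.sd,
        "bin_edges": summary.bin_edges.tolist(),
        "bin_counts": summary.bin_counts.tolist(),
    }
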