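"""Posterior draw containers, the MCMC protocol, and HPD summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "hpd_interval",
    "summarize_samples",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol: per-chain iteration count, burn-in, thinning.

    ``population_default`` is the full-length protocol used in the original
    analysis (100,000 iterations per chain, first 20,000 discarded, keep every
    fifth sample => 16,000 kept per chain, 64,000 across four chains);
    ``ageratio_default`` keeps 15,000 per chain (60,000 total).  Tests and the
    simulation experiments run the same machinery at reduced scale.
    """

    chains: int = 4
    iterations: int = 100_000
    burnin: int = 20_000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burnin) // self.thin

    @property
    def total_kept(self) -> int:
        return self.chains * self.kept_per_chain

    @staticmethod
    def population_default() -> "MCMCConfig":
        return MCMCConfig(chains=4, iterations=100_000, burnin=20_000, thin=5)

    @staticmethod
    def ageratio_default() -> "MCMCConfig":
        return MCMCConfig(chains=4, iterations=20_000, burnin=5_000, thin=1)

    @staticmethod
    def reduced(chains: int = 4, kept: int = 1000, burnin: int = 1000,
                thin: int = 1) -> "MCMCConfig":
        return MCMCConfig(chains=chains, iterations=burnin + kept * thin,
                          burnin=burnin, thin=thin)


@dataclass
class PosteriorDraws:
    """Kept MCMC samples, one array per quantity with leading (chain, draw)
    axes, plus coordinate metadata (district/year labels, design term names)."""

    data: dict[str, np.ndarray]
    config: MCMCConfig
    coords: dict[str, list] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def __contains__(self, name: str) -> bool:
        return name in self.data

    def names(self) -> list[str]:
        return list(self.data)

    def stacked(self, name: str) -> np.ndarray:
        """Samples with chains concatenated: shape (chain*draw, ...)."""
        arr = self.data[name]
        return arr.reshape((-1,) + arr.shape[2:])


def hpd_interval(samples, mass: float = 0.90) -> tuple[float, float]:
    """Shortest contiguous interval over the sorted samples containing
    ``ceil(mass * n)`` of them (ties broken toward the lowest start)."""
    if not (0.0 < mass < 1.0):
        raise ValueError("interval mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an HPD interval")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    start = int(np.argmin(widths))
    return float(x[start]), float(x[start + k - 1])


def summarize_samples(samples, masses=(0.50, 0.90)) -> dict:
    """Median plus HPD intervals at the requested masses."""
    x = np.asarray(samples, dtype=float).ravel()
    out = {"median": float(np.median(x))}
    for mass in masses:
        lo, hi = hpd_interval(x, mass)
        out[f"hpd{int(round(mass * 100))}_low"] = lo
        out[f"hpd{int(round(mass * 100))}_high"] = hi
    return out


def summary_table(draws: PosteriorDraws, names: list[str] | None = None) -> pd.DataFrame:
    """Flat CSV-ready summary (quantity, median, hpd50, hpd90) over scalar and
    vector quantities."""
    rows = []
    for name in names or draws.names():
        arr = draws.stacked(name)
        if arr.ndim == 1:
            rows.append({"quantity": name, **summarize_samples(arr)})
        else:
            flat = arr.reshape(arr.shape[0], -1)
            labels = draws.coords.get(name)
            for j in range(flat.shape[1]):
                label = labels[j] if labels and j < len(labels) else j
                rows.append({"quantity": f"{name}[{label}]",
                             **summarize_samples(flat[:, j])})
    return pd.DataFrame(rows)
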