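"""Heterogeneous neutral mutation-rate maps and mutation overlays.

Per-window neutral rates are drawn independently from a normal
distribution (mean ``mean_rate``, SD ``sigma_rel * mean_rate``) and
truncated below at zero.  In configurations with non-neutral exonic
mutations, the non-neutral rate is subtracted from the window rate over
exon-overlapping intervals (floored at zero), so the *total* rate stays
constant along the genome.

Because mutations are overlaid on stored genealogical summaries rather
than re-simulated, one set of genealogies can be re-used across many
maps: for each window the expected per-site diversity or divergence is
``2 * rate * Tbar`` (twice the mean pairwise coalescence time times the
local rate), realized by Poisson sampling over the window's callable
sites.  A map that is shared identically by all branches induces
correlations between every pair of landscapes that grow with the
relative SD of the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import StatDescriptor
from .landscapes import Landscape, WindowGrid

logger = logging.getLogger(__name__)

__all__ = ["MutationRateMap", "build_map", "overlay_mutations", "SIGMA_REL_GRID"]

#: Relative-SD grid of the study design (sigma / mean rate).
SIGMA_REL_GRID = (0.005, 0.007, 0.011, 0.016, 0.023, 0.033, 0.048, 0.070, 0.103, 0.150)


@dataclass
class MutationRateMap:
    """Per-window neutral mutation rates (per site per generation)."""

    grid: WindowGrid
    rates: np.ndarray  # per-window total neutral rate draw
    mean_rate: float
    sigma_rel: float
    exon_fraction: np.ndarray  # fraction of each window covered by exons
    nonneutral_rate: float = 0.0

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.exon_fraction = np.asarray(self.exon_fraction, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    def effective_rates(self) -> np.ndarray:
        """Window-average neutral rate after the exonic subtraction.

        Exon-overlapping intervals carry ``max(rate - nonneutral, 0)``;
        the rest of the window carries the drawn rate.
        """
        exonic = np.maximum(self.rates - self.nonneutral_rate, 0.0)
        return self.rates * (1.0 - self.exon_fraction) + exonic * self.exon_fraction

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {"start": self.grid.starts, "end": self.grid.ends, "rate": self.rates}
        ).to_csv(path, sep="\t", index=False)


def build_map(
    grid: WindowGrid,
    mean_rate: float = 2e-8,
    sigma_rel: float = 0.0,
    exons: np.ndarray | None = None,
    nonneutral_rate: float = 0.0,
    seed: int | None = None,
) -> MutationRateMap:
    """Draw a seeded per-window neutral mutation-rate map.

    Window rates are i.i.d. Normal(mean_rate, sigma_rel * mean_rate),
    truncated below at 0 (at the study's sigma grid the truncation is
    essentially never triggered); exonic intervals get the non-neutral
    subtraction rule.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    rng = np.random.default_rng(seed)
    rates = np.full(grid.n_windows, float(mean_rate))
    if sigma_rel > 0:
        rates = rng.normal(mean_rate, sigma_rel * mean_rate, grid.n_windows)
        n_trunc = int((rates < 0).sum())
        if n_trunc:
            logger.warning("truncated %d negative window rates at 0", n_trunc)
        rates = np.maximum(rates, 0.0)
    ef = np.zeros(grid.n_windows)
    if exons is not None and len(exons):
        ex = np.asarray(exons, dtype=np.int64).reshape(-1, 2)
        for s, e in ex:
            i0, i1 = int(s // grid.window_size), int((e - 1) // grid.window_size)
            for i in range(i0, min(i1, grid.n_windows - 1) + 1):
                ef[i] += max(0, min(e, grid.ends[i]) - max(s, grid.starts[i]))
        ef /= grid.sizes
    if nonneutral_rate > 0 and np.any(rates[ef > 0] < nonneutral_rate):
        logger.warning("non-neutral rate exceeds some window rates; exonic neutral rate floored at 0")
    return MutationRateMap(grid, rates, mean_rate, sigma_rel, ef, nonneutral_rate)


def overlay_mutations(
    coal_times: pd.DataFrame,
    rate_map: MutationRateMap,
    callable_lengths: np.ndarray | None = None,
    seed: int | None = None,
) -> dict:
    """Overlay a mutation-rate map onto stored coalescence-time summaries.

    ``coal_times`` is the windows x statistics table of mean pairwise
    coalescence times from the neutral simulator.  For every window and
    statistic the expected per-site value is ``2 * rate * Tbar``; the
    realized value is Poisson over the window's callable sites divided
    by the callable length.  Returns a dict of statistic label to
    :class:`~divland.landscapes.Landscape`.
    """
    grid = rate_map.grid
    if len(coal_times) != grid.n_windows:
        raise ValueError("coalescence summaries do not match the map's grid")
    if callable_lengths is None:
        callable_lengths = grid.sizes.astype(float)
    callable_lengths = np.asarray(callable_lengths, dtype=float)
    rng = np.random.default_rng(seed)
    eff = rate_map.effective_rates()
    out = {}
    for label in coal_times.columns:
        tbar = coal_times[label].to_numpy(dtype=float)
        expected = 2.0 * eff * tbar
        counts = rng.poisson(np.where(np.isnan(expected), 0.0, expected) * callable_lengths)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = counts / callable_lengths
        vals = np.where(np.isnan(tbar) | (callable_lengths <= 0), np.nan, np.minimum(vals, 1.0))
        desc = StatDescriptor.from_label(label)
        out[label] = Landscape(desc, grid, vals, callable_lengths / grid.sizes)
    return out
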