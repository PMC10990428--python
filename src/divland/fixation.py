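"""Diffusion-approximation substitution rates by mutation class.

The fixation probability of a new mutant allele with per-copy selection
coefficient s in a diploid Wright-Fisher population of size N is the
classic diffusion result

    u(s) = (1 - e^{-2s}) / (1 - e^{-4Ns}),        u(0) = 1/(2N).

The per-site per-generation substitution rate of a mutation class with
rate mu_c and fitness-effect density f(s) is then 2N mu_c E_f[u(s)]:
exactly mu_c for neutral mutations, suppressed below mu_c for
deleterious ones (except the effectively-neutral mass with |4Ns| < 1)
and amplified (toward 2s per copy) for beneficial ones.  Integrals over
the gamma (deleterious) and exponential (beneficial) fitness-effect
distributions are evaluated by adaptive quadrature, split at the
drift barrier s = 1/(4N) where the integrand changes character.

For a lineage whose population size changes through time the rates are
duration-weighted averages over an explicit (N, duration) schedule.
The default human-lineage schedule interpolates geometrically between
the two published sizes (root 125,089; human branch 7,672).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.stats import expon, gamma as gamma_dist

__all__ = [
    "fixation_probability",
    "SubstitutionRates",
    "expected_substitution_rates",
    "fixation_fractions",
    "human_lineage_schedule",
]


def fixation_probability(s, N):
    """Kimura fixation probability of a new semidominant mutant.

    ``s`` is the per-allele-copy selection coefficient (heterozygote
    advantage s, homozygote 2s). Vectorized over ``s``; numerically
    stable for |4Ns| large in either direction.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    s = np.asarray(s, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    out = np.empty_like(s)
    x = 4.0 * N * s
    tiny = np.abs(x) < 1e-8
    out[tiny] = 1.0 / (2.0 * N)
    strong_pos = x > 700
    out[strong_pos] = -np.expm1(-2.0 * s[strong_pos])
    strong_neg = x < -700
    out[strong_neg] = 0.0
    mid = ~(tiny | strong_pos | strong_neg)
    out[mid] = np.expm1(-2.0 * s[mid]) / np.expm1(-x[mid])
    return float(out[0]) if scalar else out


@dataclass
class SubstitutionRates:
    """Per-site per-generation substitution rates within exons, by class."""

    neutral: float
    deleterious: float
    beneficial: float
    counts: dict = field(default_factory=dict)  # empirical class counts, if any

    @property
    def total_exon(self) -> float:
        return self.neutral + self.deleterious + self.beneficial

    @property
    def beneficial_fraction(self) -> float:
        """Share of exon substitutions driven by beneficial mutations."""
        t = self.total_exon
        return self.beneficial / t if t > 0 else 0.0

    def exon_to_neutral_ratio(self, neutral_rate: float) -> float:
        """Total exon substitution rate relative to the neutral rate."""
        return self.total_exon / neutral_rate

    def to_dict(self, neutral_rate: float | None = None) -> dict:
        d = {
            "neutral": self.neutral,
            "deleterious": self.deleterious,
            "beneficial": self.beneficial,
            "total_exon": self.total_exon,
            "beneficial_fraction": self.beneficial_fraction,
        }
        if neutral_rate is not None:
            d["exon_to_neutral_ratio"] = self.exon_to_neutral_ratio(neutral_rate)
        if self.counts:
            d["counts"] = dict(self.counts)
        return d


def _mean_fix_factor_deleterious(shape: float, mean_s: float, N: float) -> float:
    """E[2N u(-s)] over s ~ Gamma(shape, mean=mean_s), relative to neutral."""
    scale = mean_s / shape
    f = lambda s: gamma_dist.pdf(s, shape, scale=scale) * 2.0 * N * fixation_probability(-s, N)
    cut = 1.0 / (4.0 * N)
    v1, _ = integrate.quad(f, 0.0, cut, limit=200)
    v2, _ = integrate.quad(f, cut, 50.0 * cut, limit=200)
    v3, _ = integrate.quad(f, 50.0 * cut, np.inf, limit=200)
    return v1 + v2 + v3


def _mean_fix_factor_beneficial(mean_s: float, N: float) -> float:
    """E[2N u(s)] over s ~ Exp(mean=mean_s), relative to neutral."""
    f = lambda s: expon.pdf(s, scale=mean_s) * 2.0 * N * fixation_probability(s, N)
    cut = 1.0 / (4.0 * N)
    v1, _ = integrate.quad(f, 0.0, cut, limit=200)
    v2, _ = integrate.quad(f, cut, np.inf, limit=200)
    return v1 + v2


def expected_substitution_rates(dfe, total_rate: float, N_lineage) -> SubstitutionRates:
    """Expected per-class substitution rates within exons.

    Parameters
    ----------
    dfe
        A :class:`~divland.simulator.DFEConfig`: fractions of
        deleterious/beneficial mutations within exons and their fitness-
        effect distributions.
    total_rate
        Total per-site mutation rate within exons.
    N_lineage
        Diploid effective size: a scalar, or a sequence of
        ``(N, duration)`` segments whose rates are duration-averaged.
    """
    if np.isscalar(N_lineage):
        schedule = [(float(N_lineage), 1.0)]
    else:
        schedule = [(float(n), float(d)) for n, d in N_lineage]
    if any(n <= 0 or d < 0 for n, d in schedule):
        raise ValueError("schedule requires positive N and non-negative durations")
    total_dur = sum(d for _, d in schedule)
    if total_dur <= 0:
        raise ValueError("schedule has zero total duration")

    mu_d = total_rate * dfe.frac_deleterious
    mu_b = total_rate * dfe.frac_beneficial
    mu_n = total_rate - mu_d - mu_b

    r_d = r_b = 0.0
    for N, dur in schedule:
        w = dur / total_dur
        if mu_d > 0:
            r_d += w * mu_d * _mean_fix_factor_deleterious(dfe.gamma_shape, abs(dfe.mean_s_del), N)
        if mu_b > 0:
            r_b += w * mu_b * _mean_fix_factor_beneficial(dfe.mean_s_ben, N)
    return SubstitutionRates(neutral=mu_n, deleterious=r_d, beneficial=r_b)


def fixation_fractions(records, branches: Sequence[str], exon_length: int, generations: float) -> SubstitutionRates:
    """Empirical per-class fixation rates from forward-simulation records.

    Counts fixations on the given root-to-tip branch path over
    ``generations`` total generations and ``exon_length`` exonic bp;
    field-for-field comparable with :func:`expected_substitution_rates`.
    Note neutral fixations here are exonic-neutral only if the records
    were restricted to exons by the caller.
    """
    branches = list(branches)
    if not branches:
        raise ValueError("empty branch path")
    if exon_length <= 0 or generations <= 0:
        raise ValueError("exon_length and generations must be positive")
    counts = {"neutral": 0, "deleterious": 0, "beneficial": 0}
    for rec in records:
        if rec.branch in branches:
            counts[rec.mutation_class] += 1
    denom = exon_length * generations
    return SubstitutionRates(
        neutral=counts["neutral"] / denom,
        deleterious=counts["deleterious"] / denom,
        beneficial=counts["beneficial"] / denom,
        counts=counts,
    )


def human_lineage_schedule(
    root_ne: float = 125_089,
    tip_ne: float = 7_672,
    root_split: float = 480_000,
    tip_split: float = 240_000,
    internal_splits: Sequence[float] = (320_000,),
) -> list[tuple[float, float]]:
    """(N, duration) schedule for the root-to-human lineage.

    Only the root and tip branch sizes are published; intermediate
    branches get sizes interpolated log-linearly in time between the two,
    evaluated at each segment's midpoint.  Default split times: root
    (orangutan) 480k generations ago, gorilla 320k, chimpanzee 240k,
    i.e. 12/8/6 Myr at 25-year generations.
    """
    bounds = [root_split, *sorted(internal_splits, reverse=True), tip_split]
    if any(b <= tip_split for b in internal_splits) or root_split <= tip_split:
        raise ValueError("splits must satisfy root_split > internal > tip_split")
    lo, hi = math.log(tip_ne), math.log(root_ne)

    def n_at(t: float) -> float:
        frac = (root_split - t) / (root_split - tip_split)
        return math.exp(hi - frac * (hi - lo))

    sched = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sched.append((n_at((a + b) / 2.0), a - b))
    sched.append((float(tip_ne), float(tip_split)))
    return sched
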