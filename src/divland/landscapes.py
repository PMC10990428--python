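"""Windowed nucleotide diversity and divergence with callable-site masks.

Statistics are computed in non-overlapping windows (1 Mb in the study
design).  Nucleotide diversity pi is the mean pairwise difference per
callable site among a population's sampled alleles, using the unbiased
per-site estimator 2c(n-c)/(n(n-1)) for a site with c derived copies
out of n called alleles.  Absolute divergence dXY is the mean pairwise
difference per callable site between cross-population allele pairs,
c_A(n_B-c_B) + c_B(n_A-c_A) over n_A n_B pairs.  Monomorphic callable
sites contribute to denominators only.

Masks: a site enters any statistic only if callable in *all*
populations; windows whose jointly-callable fraction falls below a
threshold (40% in the main analyses, 5% in the site-type-partitioned
ones) are dropped.

Site types for the gene-conversion analysis: with one representative
allele per species across four species, a biallelic site is W-W/S-S if
both observed states are weak (A/T) or both strong (G/C), W-S if one of
each; sites showing three or more states carry multiple mutations and
are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import StatDescriptor, diversity as _pi, divergence as _dxy

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "CallableMask",
    "AlleleTable",
    "Landscape",
    "windowed_diversity",
    "windowed_divergence",
    "apply_window_filter",
    "classify_site_type",
    "polarize_by_outgroup",
    "partitioned_divergence",
    "exon_density",
]

WEAK = frozenset("AT")
STRONG = frozenset("GC")
NUCLEOTIDES = frozenset("ACGT")

# site-type classes
WW_SS = "WW_SS"
WS = "WS"
MULTI_EXCLUDED = "multi_excluded"
INVARIANT = "invariant"


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping, contiguous, sorted windows tiling ``[0, length)``.

    Intervals are 0-based half-open; the last window may be short.
    """

    chrom: str
    length: int
    window_size: int

    def __post_init__(self):
        if self.window_size <= 0 or self.length <= 0:
            raise ValueError("window_size and length must be positive")

    @property
    def n_windows(self) -> int:
        return -(-self.length // self.window_size)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.window_size

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window_size, self.length)

    @property
    def sizes(self) -> np.ndarray:
        return self.ends - self.starts

    def window_index(self, pos0: np.ndarray) -> np.ndarray:
        """Window index of 0-based positions."""
        pos0 = np.asarray(pos0)
        if np.any((pos0 < 0) | (pos0 >= self.length)):
            raise ValueError("position outside chromosome")
        return (pos0 // self.window_size).astype(np.int64)


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _intersect_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


class CallableMask:
    """Per-population callable intervals (0-based half-open)."""

    def __init__(self, intervals: Mapping[str, np.ndarray]):
        self._iv = {p: _merge_intervals(np.asarray(v, dtype=np.int64).reshape(-1, 2)) for p, v in intervals.items()}

    @property
    def populations(self) -> list[str]:
        return list(self._iv)

    def intervals(self, pop: str) -> np.ndarray:
        return self._iv[pop]

    def intersect_all(self, pops: Iterable[str] | None = None) -> np.ndarray:
        """Intervals callable in every population."""
        pops = list(pops) if pops is not None else self.populations
        iv = self._iv[pops[0]]
        for p in pops[1:]:
            iv = _intersect_two(iv, self._iv[p])
        return iv

    @staticmethod
    def callable_per_window(intervals: np.ndarray, grid: WindowGrid) -> np.ndarray:
        """Number of callable bp in each window of the grid."""
        out = np.zeros(grid.n_windows, dtype=np.int64)
        ws, we = grid.starts, grid.ends
        for s, e in intervals:
            i0 = int(np.searchsorted(we, s, side="right"))
            i1 = int(np.searchsorted(ws, e, side="left"))
            for i in range(i0, i1):
                out[i] += max(0, min(e, we[i]) - max(s, ws[i]))
        return out

    @staticmethod
    def site_callable(intervals: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Boolean mask: is each 0-based position inside the intervals?"""
        if len(intervals) == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(intervals[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos0[ok] < intervals[idx[ok], 1]
        return ok

    @classmethod
    def from_bed_files(cls, paths: Mapping[str, str]) -> "CallableMask":
        from .io import read_bed

        return cls({p: read_bed(path) for p, path in paths.items()})


class AlleleTable:
    """Biallelic SNP table bridging VCF and the windowed statistics.

    Per site: 1-based position, ref/alt nucleotide states, per-population
    derived (alt) allele count and called-allele count, and an optional
    outgroup allele ('' where missing).
    """

    def __init__(
        self,
        positions: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        alt_counts: Mapping[str, np.ndarray],
        called: Mapping[str, np.ndarray],
        sample_counts: Mapping[str, int],
        outgroup: np.ndarray | None = None,
    ):
        self.positions = np.asarray(positions, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        self.ref = np.asarray(ref, dtype="U1")
        self.alt = np.asarray(alt, dtype="U1")
        for arr in (self.ref, self.alt):
            bad = ~np.isin(arr, list("ACGT"))
            if bad.any():
                raise ValueError(f"non-nucleotide allele state {arr[bad][:3]}")
        self.alt_counts = {p: np.asarray(v, dtype=np.int64) for p, v in alt_counts.items()}
        self.called = {p: np.asarray(v, dtype=np.int64) for p, v in called.items()}
        self.sample_counts = dict(sample_counts)
        for p, c in self.called.items():
            if np.any(c > 2 * self.sample_counts[p]):
                raise ValueError(f"called alleles exceed 2x sample count in {p!r}")
            if np.any(self.alt_counts[p] > c):
                raise ValueError(f"alt count exceeds called count in {p!r}")
        self.outgroup = (
            np.asarray(outgroup, dtype="U1") if outgroup is not None else np.full(len(self.positions), "", dtype="U1")
        )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def populations(self) -> list[str]:
        return list(self.alt_counts)

    @property
    def pos0(self) -> np.ndarray:
        """0-based positions (VCF positions are 1-based)."""
        return self.positions - 1

    def majority_allele(self, pop: str) -> np.ndarray:
        """Representative allele per site for a population: the majority
        allele among its called copies; '' on ties or no data."""
        c, n = self.alt_counts[pop], self.called[pop]
        out = np.where(2 * c > n, self.alt, self.ref)
        out = np.where((2 * c == n) | (n == 0), "", out)
        return out.astype("U1")


@dataclass
class Landscape:
    """Per-window values of one statistic, with missingness as NaN."""

    descriptor: StatDescriptor
    grid: WindowGrid
    values: np.ndarray  # float, NaN = missing
    callable_frac: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.callable_frac = np.asarray(self.callable_frac, dtype=float)
        if len(self.values) != self.grid.n_windows or len(self.callable_frac) != self.grid.n_windows:
            raise ValueError("landscape length must match the grid")
        ok = self.values[~np.isnan(self.values)]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValueError("per-site rates must lie in [0, 1]")

    @property
    def label(self) -> str:
        return self.descriptor.label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.chrom,
                "start": self.grid.starts,
                "end": self.grid.ends,
                "stat": self.descriptor.kind,
                "taxa": "|".join(sorted(self.descriptor.taxa)),
                "value": self.values,
                "callable_frac": self.callable_frac,
            }
        )


def _joint_callable(alleles: AlleleTable, mask: CallableMask, grid: WindowGrid):
    joint = mask.intersect_all()
    per_window = CallableMask.callable_per_window(joint, grid)
    site_ok = CallableMask.site_callable(joint, alleles.pos0)
    return per_window, site_ok


def _accumulate(grid: WindowGrid, pos0: np.ndarray, contrib: np.ndarray, denom: np.ndarray) -> np.ndarray:
    num = np.zeros(grid.n_windows)
    np.add.at(num, grid.window_index(pos0), contrib)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num / denom
    vals[denom == 0] = np.nan
    return vals


def windowed_diversity(alleles: AlleleTable, mask: CallableMask, grid: WindowGrid, pop: str) -> Landscape:
    """Nucleotide diversity per window for one population."""
    if pop not in alleles.populations:
        raise ValueError(f"unknown population {pop!r}")
    if alleles.sample_counts[pop] < 1:
        raise ValueError(f"empty sample for {pop!r}")
    denom, site_ok = _joint_callable(alleles, mask, grid)
    c = alleles.alt_counts[pop].astype(float)
    n = alleles.called[pop].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * c * (n - c) / (n * (n - 1.0))
    h = np.where(n >= 2, h, 0.0)
    h = np.where(site_ok, h, 0.0)
    vals = _accumulate(grid, alleles.pos0, h, denom)
    return Landscape(_pi(pop), grid, vals, denom / grid.sizes)


def windowed_divergence(
    alleles: AlleleTable, mask: CallableMask, grid: WindowGrid, pop_a: str, pop_b: str
) -> Landscape:
    """Absolute divergence dXY per window between two populations."""
    if pop_a == pop_b:
        raise ValueError("divergence requires two distinct populations")
    for p in (pop_a, pop_b):
        if p not in alleles.populations:
            raise ValueError(f"unknown population {p!r}")
    denom, site_ok = _joint_callable(alleles, mask, grid)
    ca, na = alleles.alt_counts[pop_a].astype(float), alleles.called[pop_a].astype(float)
    cb, nb = alleles.alt_counts[pop_b].astype(float), alleles.called[pop_b].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (ca * (nb - cb) + cb * (na - ca)) / (na * nb)
    d = np.where((na >= 1) & (nb >= 1), d, 0.0)
    d = np.where(site_ok, d, 0.0)
    vals = _accumulate(grid, alleles.pos0, d, denom)
    return Landscape(_dxy(pop_a, pop_b), grid, vals, denom / grid.sizes)


def apply_window_filter(landscape: Landscape, threshold: float) -> Landscape:
    """Mask windows whose callable fraction is *less than* ``threshold``.

    A fraction exactly equal to the threshold is kept.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    vals = landscape.values.copy()
    vals[landscape.callable_frac < threshold] = np.nan
    return replace(landscape, values=vals)


def classify_site_type(states: Sequence[str]) -> str:
    """Classify a site from one representative allele per species.

    Two observed states that are both weak (A/T) or both strong (G/C)
    imply a single W-W or S-S mutation; one weak and one strong imply a
    single W-S mutation; three or more states imply multiple mutations
    (excluded); a single state is invariant.
    """
    states = [s.upper() for s in states]
    for s in states:
        if s not in NUCLEOTIDES:
            raise ValueError(f"non-nucleotide state {s!r}")
    distinct = set(states)
    if len(distinct) == 1:
        return INVARIANT
    if len(distinct) > 2:
        return MULTI_EXCLUDED
    a, b = distinct
    if (a in WEAK) == (b in WEAK):
        return WW_SS
    return WS


def polarize_by_outgroup(outgroup_allele: str) -> str:
    """Ancestral W/S state from the outgroup allele ('' = missing)."""
    s = outgroup_allele.upper()
    if s == "" or s == ".":
        return "excluded"
    if s not in NUCLEOTIDES:
        raise ValueError(f"non-nucleotide outgroup allele {outgroup_allele!r}")
    return "ancestrally_weak" if s in WEAK else "ancestrally_strong"


def partitioned_divergence(
    alleles: AlleleTable,
    mask: CallableMask,
    grid: WindowGrid,
    pair_a: tuple[str, str],
    pair_b: tuple[str, str],
    site_class: str,
    threshold: float = 0.05,
) -> tuple[Landscape, Landscape]:
    """Both dXY landscapes of a four-species comparison, restricted to
    sites of one W/S class, with the 5% callable-fraction filter.

    Sites are classified from the four species' representative (majority)
    alleles; sites with a within-species tie or no data in any of the
    four species are excluded, as are multi-mutation sites.
    """
    if site_class not in (WW_SS, WS):
        raise ValueError("site_class must be WW_SS or WS")
    pops = list(pair_a) + list(pair_b)
    if len(set(pops)) != 4:
        raise ValueError("the four populations must be distinct")
    reps = np.stack([alleles.majority_allele(p) for p in pops])
    informative = (reps != "").all(axis=0)
    cls = np.array(
        [classify_site_type(reps[:, i]) if informative[i] else "" for i in range(len(alleles))]
    )
    keep = cls == site_class

    sub = AlleleTable(
        alleles.positions[keep],
        alleles.ref[keep],
        alleles.alt[keep],
        {p: alleles.alt_counts[p][keep] for p in alleles.populations},
        {p: alleles.called[p][keep] for p in alleles.populations},
        alleles.sample_counts,
        alleles.outgroup[keep],
    ) if keep.any() else None

    out = []
    for pair in (pair_a, pair_b):
        if sub is None:
            denom, _ = _joint_callable(alleles, mask, grid)
            vals = np.where(denom > 0, 0.0, np.nan)
            land = Landscape(_dxy(*pair), grid, vals, denom / grid.sizes)
        else:
            land = windowed_divergence(sub, mask, grid, *pair)
        out.append(apply_window_filter(land, threshold))
    return out[0], out[1]


def exon_density(exons: np.ndarray, mask: CallableMask, grid: WindowGrid) -> np.ndarray:
    """Fraction of jointly-callable bp per window that fall within exons."""
    joint = mask.intersect_all()
    exonic = _intersect_two(joint, _merge_intervals(np.asarray(exons, dtype=np.int64).reshape(-1, 2)))
    call_bp = CallableMask.callable_per_window(joint, grid).astype(float)
    exon_bp = CallableMask.callable_per_window(exonic, grid).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = exon_bp / call_bp
    dens[call_bp == 0] = np.nan
    return dens


def landscapes_to_tsv(landscapes: Iterable[Landscape], path: str) -> None:
    pd.concat([l.to_frame() for l in landscapes]).to_csv(path, sep="\t", index=False, na_rep="NA")


def landscapes_from_tsv(path: str) -> list[Landscape]:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    out = []
    for (stat, taxa), g in df.groupby(["stat", "taxa"], sort=False):
        g = g.sort_values("start")
        grid = WindowGrid(str(g["chrom"].iloc[0]), int(g["end"].max()), int(g["end"].iloc[0] - g["start"].iloc[0]))
        taxa_set = str(taxa).split("|")
        desc = _pi(taxa_set[0]) if stat == "diversity" else _dxy(*taxa_set)
        out.append(Landscape(desc, grid, g["value"].to_numpy(), g["callable_frac"].to_numpy()))
    return out
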