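"""Species-tree simulation of diversity and divergence landscapes.

Two engines share one configuration language:

* :func:`simulate_forward` — an individual-based, diploid Wright-Fisher
  simulation run along the species tree.  Each branch is a single
  population of constant size; splits happen in a single generation with
  both daughters starting as replicas of the parent; there is no contact
  between populations post-split.  Beneficial and deleterious mutations
  are restricted to exons, with gamma- and exponential-distributed
  fitness effects; everything else is neutral.  Fitness is
  multiplicative across sites and additive within a site (genotype
  fitness 1, 1+s, 1+2s for a per-copy coefficient s).  Every mutation
  that reaches frequency 1 within a branch is recorded as a
  :class:`FixationRecord`.

* :func:`simulate_neutral_windows` — a fast neutral mode under the
  multispecies coalescent (msprime).  Each window is represented by k
  independent recombination-free genealogies, where k scales with the
  window's genetic map length (1 cM of window map length gives k = 10,
  floor 1), reproducing the higher coalescent noise of low-recombination
  windows.  The stored per-window mean pairwise coalescence times can be
  re-used across mutation-rate maps via
  :func:`divland.mutation_maps.overlay_mutations`.

Desk-scale runs use Q-rescaling: dividing population sizes and times by
Q while multiplying mutation, recombination and selection coefficients
by Q preserves the compound parameters 4*Ne*mu, 4*Ne*r and 4*Ne*s that
govern the dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import SpeciesTree, diversity, divergence
from .landscapes import Landscape, WindowGrid

logger = logging.getLogger(__name__)

__all__ = [
    "RecombinationMap",
    "DFEConfig",
    "SimulationConfig",
    "FixationRecord",
    "SimResult",
    "rescale",
    "simulate_forward",
    "simulate_neutral_windows",
]

NEUTRAL, DELETERIOUS, BENEFICIAL = "neutral", "deleterious", "beneficial"
_CLS_NAME = {0: NEUTRAL, 1: DELETERIOUS, 2: BENEFICIAL}


class RecombinationMap:
    """Piecewise-constant crossover rates (per bp per generation).

    Intervals must tile ``[0, length)``.
    """

    def __init__(self, starts, ends, rates):
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.rates = np.asarray(rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if self.starts[0] != 0 or np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError("intervals must tile the chromosome contiguously from 0")

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    @classmethod
    def uniform(cls, length: int, rate: float) -> "RecombinationMap":
        return cls([0], [length], [rate])

    def scaled(self, q: float) -> "RecombinationMap":
        return RecombinationMap(self.starts, self.ends, self.rates * q)

    def total_morgans(self) -> float:
        return float(np.sum((self.ends - self.starts) * self.rates))

    def _cum(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum((self.ends - self.starts) * self.rates)])

    def sample_positions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Crossover positions sampled proportionally to local map length."""
        cum = self._cum()
        u = rng.uniform(0.0, cum[-1], n)
        idx = np.searchsorted(cum, u, side="right") - 1
        idx = np.clip(idx, 0, len(self.rates) - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (u - cum[idx]) / (cum[idx + 1] - cum[idx])
        frac = np.nan_to_num(frac)
        return self.starts[idx] + frac * (self.ends[idx] - self.starts[idx])

    def window_morgans(self, grid: WindowGrid) -> np.ndarray:
        """Genetic map length (Morgans) of each window."""
        out = np.zeros(grid.n_windows)
        for s, e, r in zip(self.starts, self.ends, self.rates):
            i0, i1 = int(s // grid.window_size), int((e - 1) // grid.window_size)
            for i in range(i0, min(i1, grid.n_windows - 1) + 1):
                ov = min(e, grid.ends[i]) - max(s, grid.starts[i])
                if ov > 0:
                    out[i] += ov * r
        return out

    def window_mean_rate(self, grid: WindowGrid) -> np.ndarray:
        return self.window_morgans(grid) / grid.sizes

    def to_tsv(self, path: str) -> None:
        pd.DataFrame({"start": self.starts, "end": self.ends, "rate_per_bp": self.rates}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str) -> "RecombinationMap":
        df = pd.read_csv(path, sep="\t")
        return cls(df["start"], df["end"], df["rate_per_bp"])


@dataclass(frozen=True)
class DFEConfig:
    """Distribution of fitness effects of new exonic mutations.

    ``frac_deleterious``/``frac_beneficial`` are the fractions of exonic
    mutations in each class (the remainder is neutral).  Deleterious
    effects are gamma-distributed with shape ``gamma_shape`` and mean
    ``mean_s_del`` (< 0, parameterized so mean = shape/rate); beneficial
    effects are exponential with mean ``mean_s_ben`` (> 0).  Selection
    coefficients are per allele copy.
    """

    frac_deleterious: float = 0.0
    frac_beneficial: float = 0.0
    gamma_shape: float = 0.16
    mean_s_del: float = -0.03
    mean_s_ben: float = 0.01

    def __post_init__(self):
        if self.frac_deleterious < 0 or self.frac_beneficial < 0:
            raise ValueError("class fractions must be non-negative")
        if self.frac_deleterious + self.frac_beneficial > 1 + 1e-12:
            raise ValueError("class fractions must sum to at most 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.frac_deleterious > 0 and not self.mean_s_del < 0:
            raise ValueError("mean deleterious effect must be negative")
        if self.frac_beneficial > 0 and not self.mean_s_ben > 0:
            raise ValueError("mean beneficial effect must be positive")

    @classmethod
    def best_fit(cls) -> "DFEConfig":
        """The best-fitting parameter combination of the study design:
        total exonic rate 2e-8 split as 60% deleterious (gamma, shape
        0.16, mean -0.03) and 1e-12 beneficial (exponential, mean 0.01)."""
        return cls(
            frac_deleterious=1.2e-8 / 2e-8,
            frac_beneficial=1e-12 / 2e-8,
            gamma_shape=0.16,
            mean_s_del=-0.03,
            mean_s_ben=0.01,
        )


@dataclass
class SimulationConfig:
    """Complete forward-simulation configuration.

    ``Q`` records the rescaling factor already applied to the tree,
    mutation and recombination rates; selection coefficients are
    multiplied by ``Q`` when drawn.  ``burnin_factor`` x (root Ne)
    generations of burn-in precede the tree traversal.
    """

    tree: SpeciesTree
    grid: WindowGrid
    mu: float = 2e-8
    dfe: DFEConfig = field(default_factory=DFEConfig)
    exons: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    recomb_map: RecombinationMap | None = None
    Q: float = 1.0
    burnin_factor: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mutation rate must be positive")
        if self.Q < 1:
            raise ValueError("Q must be at least 1")
        self.exons = np.asarray(self.exons, dtype=np.int64).reshape(-1, 2)
        if len(self.exons) and (self.exons.min() < 0 or self.exons.max() > self.grid.length):
            raise ValueError("exon intervals must lie within the chromosome")
        if self.recomb_map is None:
            self.recomb_map = RecombinationMap.uniform(self.grid.length, 0.0)


def _scale_tree(tree: SpeciesTree, q: float) -> SpeciesTree:
    nodes = {}
    for name in tree.node_names:
        ne = tree.ne(name) / q
        if ne < 2:
            raise ValueError(f"rescaling by {q} drives Ne of {name!r} below 2")
        nodes[name] = (
            tree.parent(name),
            round(tree.branch_length(name) / q),
            max(2, round(ne)),
            tree.samples(name) if tree.is_tip(name) and name in tree.sample_counts() else None,
        )
    return SpeciesTree(nodes)


def rescale(config: SimulationConfig, q: float) -> SimulationConfig:
    """Q-rescale a configuration: Ne and times / q; mu, r (and s, at draw
    time) x q.  The products 4*Ne*mu, 4*Ne*r and 4*Ne*s are preserved to
    within rounding."""
    if q < 1:
        raise ValueError("Q must be at least 1")
    if q == 1:
        return replace(config)
    return replace(
        config,
        tree=_scale_tree(config.tree, q),
        mu=config.mu * q,
        recomb_map=config.recomb_map.scaled(q),
        Q=config.Q * q,
    )


@dataclass(frozen=True)
class FixationRecord:
    """A mutation that reached frequency 1 within one branch."""

    branch: str
    position: float
    mutation_class: str
    s: float
    generation: int

    def __post_init__(self):
        if (self.s == 0) != (self.mutation_class == NEUTRAL):
            raise ValueError("class must be neutral iff s == 0")


@dataclass
class SimResult:
    """Landscapes, fixation records and (neutral mode) coalescence times."""

    landscapes: dict
    fixations: list
    config: object
    seed: int | None
    coal_times: pd.DataFrame | None = None  # windows x statistics, generations
    genotypes: list | None = None  # neutral mode, optional site-level output
    sample_order: dict | None = None  # neutral mode: tips, counts, haplotype->pop

    def pi(self, pop: str) -> Landscape:
        return self.landscapes[diversity(pop).label]

    def dxy(self, a: str, b: str) -> Landscape:
        return self.landscapes[divergence(a, b).label]

    def fixations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"branch": f.branch, "pos": f.position, "class": f.mutation_class, "s": f.s, "generation": f.generation}
                for f in self.fixations
            ]
        )


# ----------------------------------------------------------------------
# forward Wright-Fisher engine
# ----------------------------------------------------------------------


class _PopState:
    __slots__ = ("N", "H", "pos", "s", "cls", "fixed")

    def __init__(self, N: int):
        self.N = N
        self.H = np.zeros((2 * N, 0), dtype=bool)
        self.pos = np.empty(0)
        self.s = np.empty(0)
        self.cls = np.empty(0, dtype=np.int8)
        self.fixed: dict[float, tuple[float, int]] = {}  # pos -> (s, cls)

    def copy(self) -> "_PopState":
        new = _PopState(self.N)
        new.H = self.H.copy()
        new.pos = self.pos.copy()
        new.s = self.s.copy()
        new.cls = self.cls.copy()
        new.fixed = dict(self.fixed)
        return new


class _ForwardEngine:
    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.L = config.grid.length
        ex = config.exons
        self.ex_starts, self.ex_ends = ex[:, 0], ex[:, 1]
        self.lam = config.recomb_map.total_morgans()
        self.records: list[FixationRecord] = []

    def _in_exon(self, pos: np.ndarray) -> np.ndarray:
        if len(self.ex_starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(self.ex_starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < self.ex_ends[idx[ok]]
        return ok

    def _draw_mutations(self, n: int):
        """Positions, selection coefficients and classes of n new mutations."""
        cfg, rng = self.cfg, self.rng
        pos = rng.uniform(0.0, self.L, n)
        s = np.zeros(n)
        cls = np.zeros(n, dtype=np.int8)
        exonic = self._in_exon(pos)
        u = rng.random(n)
        dele = exonic & (u < cfg.dfe.frac_deleterious)
        bene = exonic & ~dele & (u < cfg.dfe.frac_deleterious + cfg.dfe.frac_beneficial)
        if dele.any():
            shape = cfg.dfe.gamma_shape
            s[dele] = -rng.gamma(shape, abs(cfg.dfe.mean_s_del) / shape, dele.sum()) * cfg.Q
            cls[dele] = 1
        if bene.any():
            s[bene] = rng.exponential(cfg.dfe.mean_s_ben, bene.sum()) * cfg.Q
            cls[bene] = 2
        return pos, s, cls

    def step(self, state: _PopState, n_child: int, branch: str, gen: int) -> _PopState:
        rng = self.rng
        H, n_par = state.H, state.N
        # fitness-weighted parent choice
        sel = np.nonzero(state.s)[0]
        if sel.size:
            g = H[0::2][:, sel].astype(np.int8) + H[1::2][:, sel]
            w = np.prod(np.clip(1.0 + g * state.s[sel], 1e-9, None), axis=1)
            p = w / w.sum()
            parents = rng.choice(n_par, size=(n_child, 2), p=p)
        else:
            parents = rng.integers(0, n_par, size=(n_child, 2))
        new_h = np.empty((2 * n_child, H.shape[1]), dtype=bool)
        for gam in (0, 1):
            par = parents[:, gam]
            phase = rng.integers(0, 2, n_child)
            nco = rng.poisson(self.lam, n_child) if self.lam > 0 else np.zeros(n_child, dtype=int)
            rows = 2 * np.arange(n_child) + gam
            simple = nco == 0
            new_h[rows[simple]] = H[2 * par[simple] + phase[simple]]
            single = nco == 1
            if single.any():
                # one crossover: start haplotype up to the breakpoint, the other after
                co = self.cfg.recomb_map.sample_positions(rng, int(single.sum()))
                left = H[2 * par[single] + phase[single]]
                right = H[2 * par[single] + 1 - phase[single]]
                after = state.pos[None, :] >= co[:, None]
                new_h[rows[single]] = np.where(after, right, left)
            for i in np.nonzero(nco >= 2)[0]:
                co = np.sort(self.cfg.recomb_map.sample_positions(rng, nco[i]))
                src = (np.searchsorted(co, state.pos) + phase[i]) % 2
                new_h[rows[i]] = np.where(src == 0, H[2 * par[i]], H[2 * par[i] + 1])

        out = _PopState(n_child)
        out.fixed = state.fixed  # caller copies at splits
        n_mut = rng.poisson(2 * n_child * self.cfg.mu * self.L)
        if n_mut:
            mpos, ms, mcls = self._draw_mutations(n_mut)
            cols = np.zeros((2 * n_child, n_mut), dtype=bool)
            cols[rng.integers(0, 2 * n_child, n_mut), np.arange(n_mut)] = True
            new_h = np.concatenate([new_h, cols], axis=1)
            out.pos = np.concatenate([state.pos, mpos])
            out.s = np.concatenate([state.s, ms])
            out.cls = np.concatenate([state.cls, mcls])
        else:
            out.pos, out.s, out.cls = state.pos, state.s, state.cls

        cnt = new_h.sum(axis=0)
        fixed = cnt == 2 * n_child
        if fixed.any():
            for j in np.nonzero(fixed)[0]:
                out.fixed = dict(out.fixed) if out.fixed is state.fixed else out.fixed
                out.fixed[float(out.pos[j])] = (float(out.s[j]), int(out.cls[j]))
                self.records.append(
                    FixationRecord(branch, float(out.pos[j]), _CLS_NAME[int(out.cls[j])], float(out.s[j]), gen)
                )
        keep = ~fixed & (cnt > 0)
        out.H = new_h[:, keep]
        out.pos, out.s, out.cls = out.pos[keep], out.s[keep], out.cls[keep]
        return out

    def evolve(self, state: _PopState, n: int, length: int, branch: str, gen0: int) -> _PopState:
        for t in range(length):
            state = self.step(state, n, branch, gen0 + t)
        return state


def simulate_forward(config: SimulationConfig, seed: int | None = None) -> SimResult:
    """Run the forward Wright-Fisher simulation over the species tree.

    Burn-in of ``burnin_factor * root_Ne`` generations at the root, then
    a pre-order traversal evolving each branch for its length at its Ne;
    both daughters of a split start as replicas of the parent state.
    Landscapes are computed from the tips' segregating sites plus
    branch-fixed differences, using each tip's sample count.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    eng = _ForwardEngine(config, rng)
    tree = config.tree

    root_ne = int(round(tree.ne(tree.root)))
    if root_ne < 2:
        raise ValueError("root Ne must be at least 2")
    burnin = int(round(config.burnin_factor * root_ne))
    state = _PopState(root_ne)
    state.H = np.zeros((2 * root_ne, 0), dtype=bool)
    logger.info("burn-in: %d generations at N=%d", burnin, root_ne)
    state = eng.evolve(state, root_ne, burnin, tree.root, 0)

    tip_states: dict[str, _PopState] = {}

    def traverse(node: str, state: _PopState, gen: int) -> None:
        children = tree.children(node)
        if not children:
            tip_states[node] = state
            return
        for child in children:
            n_child = int(round(tree.ne(child)))
            if n_child < 2:
                raise ValueError(f"branch {child!r} has Ne < 2 after rescaling")
            length = int(round(tree.branch_length(child)))
            st = state.copy()
            st = eng.evolve(st, n_child, length, child, gen)
            traverse(child, st, gen + length)

    traverse(tree.root, state, burnin)

    landscapes = _tip_landscapes(tip_states, tree, config.grid, rng)
    return SimResult(landscapes=landscapes, fixations=eng.records, config=config, seed=seed)


def _sample_freqs(state: _PopState, n_samp: int, rng: np.random.Generator):
    n_samp = min(n_samp, state.N)
    idx = rng.choice(state.N, n_samp, replace=False)
    rows = np.concatenate([2 * idx, 2 * idx + 1])
    counts = state.H[rows].sum(axis=0)
    return counts, 2 * n_samp


def _tip_landscapes(tip_states, tree: SpeciesTree, grid: WindowGrid, rng) -> dict:
    samples = tree.sample_counts()
    tips = sorted(tip_states)
    freqs = {}
    for tip in tips:
        freqs[tip] = (_sample_freqs(tip_states[tip], samples.get(tip, tip_states[tip].N), rng), tip_states[tip])
    out = {}
    for tip in tips:
        (counts, n_alleles), st = freqs[tip]
        c = counts.astype(float)
        h = 2 * c * (n_alleles - c) / (n_alleles * (n_alleles - 1.0)) if n_alleles >= 2 else np.zeros_like(c)
        vals = np.zeros(grid.n_windows)
        if len(st.pos):
            np.add.at(vals, grid.window_index(np.floor(st.pos).astype(np.int64)), h)
        vals /= grid.sizes
        out[diversity(tip).label] = Landscape(diversity(tip), grid, vals, np.ones(grid.n_windows))
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            (ca, na), sta = freqs[a]
            (cb, nb), stb = freqs[b]
            pa = {float(p): c / na for p, c in zip(sta.pos, ca)}
            pb = {float(p): c / nb for p, c in zip(stb.pos, cb)}
            for p in sta.fixed:
                pa[p] = 1.0
            for p in stb.fixed:
                pb[p] = 1.0
            vals = np.zeros(grid.n_windows)
            for p in set(pa) | set(pb):
                fa, fb = pa.get(p, 0.0), pb.get(p, 0.0)
                d = fa * (1 - fb) + fb * (1 - fa)
                if d:
                    vals[int(p // grid.window_size)] += d
            vals /= grid.sizes
            out[divergence(a, b).label] = Landscape(divergence(a, b), grid, vals, np.ones(grid.n_windows))
    return out


# ----------------------------------------------------------------------
# neutral multispecies-coalescent mode
# ----------------------------------------------------------------------


def _demography(tree: SpeciesTree):
    import msprime

    dem = msprime.Demography()
    for name in tree.node_names:
        dem.add_population(name=name, initial_size=tree.ne(name))
    internals = [n for n in tree.node_names if not tree.is_tip(n)]
    for name in sorted(internals, key=tree.node_time):
        dem.add_population_split(time=tree.node_time(name), derived=tree.children(name), ancestral=name)
    dem.sort_events()
    return dem


def simulate_neutral_windows(
    tree: SpeciesTree,
    grid: WindowGrid,
    recomb_map: RecombinationMap | None = None,
    samples: Mapping[str, int] | None = None,
    seed: int | None = None,
    loci_per_cm: float = 10.0,
    mutation_rate: float | np.ndarray | None = None,
) -> SimResult:
    """Neutral landscapes via per-window multispecies-coalescent genealogies.

    Each window gets ``k = max(1, round(loci_per_cm * window map length
    in cM))`` independent recombination-free genealogies; the stored
    summary per window is the mean pairwise coalescence time (in
    generations) for every population and pair, averaged over the k
    loci.  If ``mutation_rate`` is given (scalar or per-window array),
    site-level genotypes are also generated by dropping mutations on the
    genealogies, for use by the synthetic-data generator.
    """
    import msprime

    samples = dict(samples) if samples is not None else tree.sample_counts()
    for tip, n in samples.items():
        if n < 1:
            raise ValueError(f"zero samples for tip {tip!r}")
    if recomb_map is None:
        recomb_map = RecombinationMap.uniform(grid.length, 1e-8)
    dem = _demography(tree)
    cm = recomb_map.window_morgans(grid) * 100.0
    k_per_window = np.maximum(1, np.round(loci_per_cm * cm)).astype(int)
    rates = None
    if mutation_rate is not None:
        rates = np.broadcast_to(np.asarray(mutation_rate, dtype=float), (grid.n_windows,))

    tips = sorted(samples)
    pairs = [(a, b) for i, a in enumerate(tips) for b in tips[i + 1 :]]
    labels = [diversity(t).label for t in tips] + [divergence(a, b).label for a, b in pairs]

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(int(k_per_window.sum()) * 2, dtype=np.uint32).astype(np.int64) % (2**31 - 1) + 1

    rows = []
    genotypes = [] if rates is not None else None
    seed_i = 0
    sample_spec = [msprime.SampleSet(samples[t], population=t, ploidy=2) for t in tips]
    for w in range(grid.n_windows):
        k = k_per_window[w]
        locus_len = grid.sizes[w] / k
        acc = np.zeros(len(labels))
        wsites = []
        for j in range(k):
            ts = msprime.sim_ancestry(
                samples=sample_spec,
                demography=dem,
                sequence_length=locus_len,
                ploidy=2,
                discrete_genome=False,
                random_seed=int(child_seeds[seed_i]),
            )
            seed_i += 1
            name_to_set = {}
            for i in range(ts.num_populations):
                nm = ts.population(i).metadata.get("name")
                if nm in tips:
                    name_to_set[nm] = ts.samples(population=i)
            sets = [name_to_set[t] for t in tips]
            div = ts.diversity(sets, mode="branch")  # 2 x mean pairwise TMRCA
            idx_pairs = [(tips.index(a), tips.index(b)) for a, b in pairs]
            dxy = ts.divergence(sets, indexes=idx_pairs, mode="branch") if idx_pairs else np.empty(0)
            acc += np.concatenate([np.atleast_1d(div), np.atleast_1d(dxy)]) / 2.0
            if rates is not None:
                mts = msprime.sim_mutations(
                    ts,
                    rate=rates[w],
                    random_seed=int(child_seeds[seed_i]),
                    model=msprime.BinaryMutationModel(),
                    discrete_genome=False,
                )
                seed_i += 1
                g = mts.genotype_matrix()
                sitepos = grid.starts[w] + j * locus_len + np.array([s.position for s in mts.sites()])
                wsites.append((sitepos, g))
            else:
                seed_i += 1
        rows.append(acc / k)
        if genotypes is not None:
            genotypes.append(wsites)

    coal = pd.DataFrame(rows, columns=labels)
    hap_pops = [t for t in tips for _ in range(2 * samples[t])]
    return SimResult(
        landscapes={},
        fixations=[],
        config=None,
        seed=seed,
        coal_times=coal,
        genotypes=genotypes,
        sample_order={"tips": tips, "samples": samples, "hap_pops": hap_pops},
    )
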