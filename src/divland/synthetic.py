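"""Self-contained synthetic dataset with the structure of the empirical inputs.

Generates, from a seed, everything the empirical-analysis path consumes:
a multi-population VCF of biallelic nucleotide SNPs with an ancestral
(outgroup) allele on a fraction of sites, per-population callable-site
masks in BED (with a configurable share of windows pushed below the 40%
callable threshold), an exon annotation BED, a recombination map TSV
with elevated rates toward the chromosome ends, and a truth JSON
recording the tree, the per-window mutation rates, the target callable
fractions and the generator's internally computed landscapes, so
recovery tests can compare the file-based pipeline against the truth.

Variation is simulated with the package's neutral multispecies-
coalescent mode on the default ten-population great-apes tree with the
published sample counts (9, 13, 10, 6, 4, 4, 3, 27, 5, 5).  Nucleotide
assignment is uniform over ordered ref/alt pairs — no transition bias
and no CpG model, the simplest scheme exercising the weak/strong
machinery — and the outgroup allele, where present, equals the true
simulated ancestral state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demography import SpeciesTree, great_apes_tree
from .landscapes import WindowGrid
from .mutation_maps import build_map
from .simulator import RecombinationMap, simulate_neutral_windows

__all__ = ["SyntheticDatasetSpec", "generate_dataset"]

_NUC = np.array(list("ACGT"))


@dataclass
class SyntheticDatasetSpec:
    """Parameters of the synthetic dataset generator."""

    tree: SpeciesTree = field(default_factory=great_apes_tree)
    chrom: str = "chr1"
    window_size: int = 1_000_000
    n_windows: int = 8
    mean_mutation_rate: float = 2e-8
    sigma_rel: float = 0.07
    outgroup_fraction: float = 0.7
    low_callable_prob: float = 0.1  # windows forced below the 40% threshold
    mean_exon_density: float = 0.05
    exon_block: int = 2_000
    base_recomb_rate: float = 1e-8

    def __post_init__(self):
        for f in (self.outgroup_fraction, self.low_callable_prob):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if any(n < 1 for n in self.tree.sample_counts().values()):
            raise ValueError("sample counts must be at least 1")

    @property
    def grid(self) -> WindowGrid:
        return WindowGrid(self.chrom, self.window_size * self.n_windows, self.window_size)


def _recomb_profile(spec: SyntheticDatasetSpec, rng) -> RecombinationMap:
    # elevated rates toward the chromosome ends ("smiley" profile)
    w = spec.n_windows
    x = np.linspace(-1, 1, w)
    rates = spec.base_recomb_rate * (0.3 + 3.0 * x**2) * rng.lognormal(0.0, 0.3, w)
    g = spec.grid
    return RecombinationMap(g.starts, g.ends, rates)


def _exon_profile(spec: SyntheticDatasetSpec, rng) -> np.ndarray:
    """Exon intervals with smoothly varying per-window density."""
    g = spec.grid
    i = np.arange(g.n_windows)
    dens = spec.mean_exon_density * (0.4 + 1.2 * 0.5 * (1 + np.sin(4 * np.pi * i / max(g.n_windows, 2))))
    dens *= rng.lognormal(0.0, 0.25, g.n_windows)
    dens = np.clip(dens, 0.005, 0.3)
    blocks = []
    for wi in range(g.n_windows):
        target = int(dens[wi] * g.sizes[wi])
        n_blocks = max(1, target // spec.exon_block)
        spacing = g.sizes[wi] // n_blocks
        for b in range(n_blocks):
            s = g.starts[wi] + b * spacing + int(rng.integers(0, max(1, spacing - spec.exon_block)))
            blocks.append((s, min(s + spec.exon_block, g.ends[wi])))
    return np.asarray(blocks, dtype=np.int64)


def _callable_design(spec: SyntheticDatasetSpec, rng):
    """Target jointly-callable fraction per window and mask intervals.

    The joint callable region of a window is one contiguous block at a
    random offset (wrapping into two intervals when it crosses the
    window end); each population's own mask adds a small disjoint
    population-specific extension inside the non-callable remainder, so
    intersecting across populations recovers the joint region exactly.
    """
    g = spec.grid
    pops = sorted(spec.tree.sample_counts())
    frac = np.where(
        rng.random(g.n_windows) < spec.low_callable_prob,
        rng.uniform(0.05, 0.38, g.n_windows),
        0.40 + 0.60 * rng.beta(4.0, 2.4, g.n_windows),
    )
    joint = []
    per_pop = {p: [] for p in pops}
    for wi in range(g.n_windows):
        lw = int(g.sizes[wi])
        nbp = int(round(frac[wi] * lw))
        off = int(rng.integers(0, lw))
        s0 = g.starts[wi]
        if off + nbp <= lw:
            ivs = [(s0 + off, s0 + off + nbp)]
        else:
            ivs = [(s0, s0 + off + nbp - lw), (s0 + off, s0 + lw)]
        joint.extend(ivs)
        # disjoint per-population extras in the non-callable remainder
        gap_start = (off + nbp) % lw
        gap_len = lw - nbp
        extra = 200
        for k, p in enumerate(pops):
            per_pop[p].extend(ivs)
            if gap_len > (len(pops) + 1) * extra:
                es = s0 + (gap_start + (k + 1) * extra) % lw
                if es + extra <= s0 + lw:
                    per_pop[p].append((es, es + extra))
    return frac, np.asarray(joint, dtype=np.int64), {p: np.asarray(v, dtype=np.int64) for p, v in per_pop.items()}


def _internal_landscapes(positions, counts, called, pops, grid):
    """Unbiased pi and dXY per window from per-site allele counts."""
    out = {}
    widx = grid.window_index(positions) if len(positions) else np.empty(0, dtype=int)
    for p in pops:
        c, n = counts[p].astype(float), float(called[p])
        h = 2 * c * (n - c) / (n * (n - 1)) if n >= 2 else np.zeros_like(c)
        vals = np.zeros(grid.n_windows)
        np.add.at(vals, widx, h)
        out[f"pi:{p}"] = (vals / grid.sizes).tolist()
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            ca, na = counts[a].astype(float), float(called[a])
            cb, nb = counts[b].astype(float), float(called[b])
            d = (ca * (nb - cb) + cb * (na - ca)) / (na * nb)
            vals = np.zeros(grid.n_windows)
            np.add.at(vals, widx, d)
            out["dxy:" + "|".join(sorted([a, b]))] = (vals / grid.sizes).tolist()
    return out


def _write_vcf(path, chrom, positions, ref, alt, outgroup, genotypes, sample_names):
    """Minimal standards-compliant VCF 4.2 with phased per-sample GT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral (outgroup) allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names) + "\n")
        for i in range(len(positions)):
            info = f"AA={outgroup[i]}" if outgroup[i] else "."
            gts = "\t".join(f"{genotypes[i, 2*k]}|{genotypes[i, 2*k+1]}" for k in range(len(sample_names)))
            fh.write(f"{chrom}\t{positions[i]}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t{info}\tGT\t{gts}\n")


def generate_dataset(spec: SyntheticDatasetSpec, seed: int, outdir: str) -> dict:
    """Generate the full synthetic dataset; bit-identical for a fixed seed.

    Returns a dict with the written file paths and the truth record.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_rec, s_exon, s_mask, s_map, s_sim, s_nuc = [np.random.default_rng(c) for c in ss.spawn(6)]
    sim_seed = int(s_sim.integers(1, 2**31 - 1))

    grid = spec.grid
    recomb = _recomb_profile(spec, s_rec)
    exons = _exon_profile(spec, s_exon)
    frac, joint_iv, pop_iv = _callable_design(spec, s_mask)
    rate_map = build_map(
        grid,
        spec.mean_mutation_rate,
        spec.sigma_rel,
        seed=int(s_map.integers(0, 2**31 - 1)),
    )

    sim = simulate_neutral_windows(
        spec.tree, grid, recomb, seed=sim_seed, mutation_rate=rate_map.rates
    )
    pops = sim.sample_order["tips"]
    samples = sim.sample_order["samples"]
    hap_pops = np.array(sim.sample_order["hap_pops"])

    # flatten per-window loci into one site table
    pos_list, g_list = [], []
    for wsites in sim.genotypes:
        for sp, gm in wsites:
            if len(sp):
                pos_list.append(sp)
                g_list.append(gm)
    if pos_list:
        positions = np.concatenate(pos_list)
        G = np.concatenate(g_list, axis=0)
    else:  # pragma: no cover - degenerate empty dataset
        positions = np.empty(0)
        G = np.empty((0, len(hap_pops)), dtype=np.int8)
    pos_int = positions.astype(np.int64)
    order = np.argsort(pos_int, kind="stable")
    pos_int, G = pos_int[order], G[order]
    uniq = np.concatenate([[True], np.diff(pos_int) > 0])
    pos_int, G = pos_int[uniq], G[uniq]

    # nucleotide assignment: uniform over ordered (ref, alt) pairs
    n_sites = len(pos_int)
    ref_i = s_nuc.integers(0, 4, n_sites)
    alt_i = (ref_i + s_nuc.integers(1, 4, n_sites)) % 4
    ref, alt = _NUC[ref_i], _NUC[alt_i]
    has_outgroup = s_nuc.random(n_sites) < spec.outgroup_fraction
    outgroup = np.where(has_outgroup, ref, "")

    counts = {p: G[:, hap_pops == p].sum(axis=1) for p in pops}
    called = {p: 2 * samples[p] for p in pops}
    internal = _internal_landscapes(pos_int, counts, called, pops, grid)

    # write outputs
    paths = {}
    sample_names = [f"{p}_{k+1}" for p in pops for k in range(samples[p])]
    paths["vcf"] = str(out / "variants.vcf")
    _write_vcf(paths["vcf"], spec.chrom, pos_int + 1, ref, alt, outgroup, G, sample_names)
    from .io import write_bed, write_populations
    from .landscapes import _merge_intervals

    paths["masks"] = {}
    for p in pops:
        mpath = str(out / f"mask_{p}.bed")
        write_bed(_merge_intervals(pop_iv[p]), spec.chrom, mpath)
        paths["masks"][p] = mpath
    paths["exons"] = str(out / "exons.bed")
    write_bed(exons, spec.chrom, paths["exons"])
    paths["recomb_map"] = str(out / "recomb_map.tsv")
    recomb.to_tsv(paths["recomb_map"])
    paths["populations"] = str(out / "populations.tsv")
    write_populations({p: [s for s in sample_names if s.rsplit("_", 1)[0] == p] for p in pops}, paths["populations"])
    paths["tree"] = str(out / "tree.nwk")
    paths["tree_params"] = str(out / "tree_params.tsv")
    spec.tree.to_files(paths["tree"], paths["tree_params"])

    truth = {
        "seed": seed,
        "sim_seed": sim_seed,
        "chrom": spec.chrom,
        "window_size": spec.window_size,
        "n_windows": spec.n_windows,
        "sample_counts": {p: samples[p] for p in pops},
        "window_mutation_rates": rate_map.rates.tolist(),
        "callable_fraction": frac.tolist(),
        "recomb_rates": recomb.rates.tolist(),
        "mean_coal_times": {c: sim.coal_times[c].tolist() for c in sim.coal_times.columns},
        "internal_landscapes": internal,
        "n_sites": int(n_sites),
    }
    paths["truth"] = str(out / "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth_record"] = truth
    return paths
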