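import numpy as np
import pytest

from divland.demography import SpeciesTree
from divland.landscapes import AlleleTable, CallableMask, WindowGrid


@pytest.fixture
def abc_tree():
    """Tips A,B split 100 generations ago; C split 1000 generations ago."""
    return SpeciesTree(
        {
            "root": (None, 0, 1000, None),
            "AB": ("root", 900, 800, None),
            "A": ("AB", 100, 500, 4),
            "B": ("AB", 100, 400, 3),
            "C": ("root", 1000, 600, 2),
        }
    )


@pytest.fixture
def vwxy_tree():
    """Balanced four-tip tree ((V,W),(X,Y))."""
    return SpeciesTree(
        {
            "root": (None, 0, 1000, None),
            "VW": ("root", 500, 800, None),
            "XY": ("root", 700, 900, None),
            "V": ("VW", 500, 500, 2),
            "W": ("VW", 500, 400, 2),
            "X": ("XY", 300, 600, 2),
            "Y": ("XY", 300, 700, 2),
        }
    )


def random_tree(rng: np.random.Generator, n_tips: int) -> SpeciesTree:
    """Random ultrametric topology by sequential pair merging."""
    tips = [f"t{i}" for i in range(n_tips)]
    nodes = {t: [None, 0.0, float(rng.integers(100, 1000)), 2] for t in tips}
    active = {t: 0.0 for t in tips}  # node -> time
    counter = 0
    t = 0.0
    while len(active) > 1:
        t += float(rng.integers(10, 200))
        a, b = rng.choice(sorted(active), size=2, replace=False)
        name = f"n{counter}"
        counter += 1
        nodes[a][0] = name
        nodes[a][1] = t - active.pop(a)
        nodes[b][0] = name
        nodes[b][1] = t - active.pop(b)
        nodes[name] = [None, 0.0, float(rng.integers(100, 1000)), None]
        active[name] = t
    return SpeciesTree({k: tuple(v) for k, v in nodes.items()})


def table_from_haplotypes(positions, haps: dict, ref=None, alt=None, outgroup=None):
    """Build an AlleleTable from explicit 0/1 haplotype matrices.

    ``haps`` maps population name to an (n_haplotypes, n_sites) 0/1
    array; haplotypes 2k, 2k+1 form individual k.
    """
    positions = np.asarray(positions)
    n = len(positions)
    ref = np.full(n, "A") if ref is None else np.asarray(ref)
    alt = np.full(n, "T") if alt is None else np.asarray(alt)
    alt_counts = {p: h.sum(axis=0) for p, h in haps.items()}
    called = {p: np.full(n, h.shape[0]) for p, h in haps.items()}
    samples = {p: -(-h.shape[0] // 2) for p, h in haps.items()}
    return AlleleTable(positions, ref, alt, alt_counts, called, samples, outgroup)


def full_mask(pops, length):
    return CallableMask({p: np.array([[0, length]]) for p in pops})


def brute_force_pi(haps: np.ndarray, site_in_window, n_callable) -> float:
    """Mean pairwise difference over all haplotype pairs / callable sites."""
    n = haps.shape[0]
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum((haps[i] != haps[j]) & site_in_window))
            npairs += 1
    return total / npairs / n_callable


def brute_force_dxy(ha: np.ndarray, hb: np.ndarray, site_in_window, n_callable) -> float:
    total = 0
    npairs = 0
    for i in range(ha.shape[0]):
        for j in range(hb.shape[0]):
            total += int(np.sum((ha[i] != hb[j]) & site_in_window))
            npairs += 1
    return total / npairs / n_callable
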