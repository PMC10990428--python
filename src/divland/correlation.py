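"""Correlations between landscapes, covariance decomposition, and PCA.

All pairwise Spearman correlations between windowed landscapes are
organized against the phylogenetic distance dT between the statistics'
MRCA nodes, split by comparison type (pi-pi, pi-dXY, dXY-dXY), with
flags for pairs of divergences that share tree branches (excluded from
the main analyses, since dT is then a poor predictor of correlation)
and for statistics involving a low-Ne population.

The covariance decomposition follows from writing windowed divergence at
split time t as D_i(t) = pi_i(t) + R_i * t + eps_i (ancestral diversity
plus substitutions plus zero-mean noise), which by bilinearity gives

    Cov(D(t), X) = Cov(pi(t), X) + t * Cov(R, X) + Cov(eps, X)

for any genomic feature X: the covariance changes linearly with split
time, with slope equal to the covariance between the feature and the
local substitution rate.  :class:`CovarianceDecomposition` estimates the
slope by ordinary least squares over divergence pairs.

PCA embeds simulations and data as rows of the runs x correlations
matrix (column-centered, no variance scaling, since Spearman
correlations are already on a common scale).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .demography import SpeciesTree, StatDescriptor, phylo_distance, shares_branches
from .landscapes import WindowGrid

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "CorrelationRecord",
    "all_pairwise_correlations",
    "records_to_frame",
    "FeatureVector",
    "CovarianceDecomposition",
    "pca_embedding",
]

LOW_NE_THRESHOLD = 8e3


def spearman(x, y) -> float | None:
    """Spearman rank correlation with average ranks for ties.

    Windows missing (NaN) in either vector are dropped pairwise; with
    fewer than 3 complete pairs the correlation is undefined (None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("landscapes must share a grid")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        logger.warning("fewer than 3 complete pairs; correlation undefined")
        return None
    rho = stats.spearmanr(x[ok], y[ok]).statistic
    return float(rho)


@dataclass(frozen=True)
class CorrelationRecord:
    """One pairwise landscape comparison."""

    stat_a: StatDescriptor
    stat_b: StatDescriptor
    rho: float | None
    dt: float
    comparison: str  # pi_pi | pi_dxy | dxy_dxy
    shares_branches: bool
    low_ne: bool


def _comparison_type(a: StatDescriptor, b: StatDescriptor) -> str:
    kinds = sorted([a.kind, b.kind])
    if kinds == ["diversity", "diversity"]:
        return "pi_pi"
    if kinds == ["divergence", "divergence"]:
        return "dxy_dxy"
    return "pi_dxy"


def all_pairwise_correlations(
    landscapes,
    tree: SpeciesTree,
    low_ne_threshold: float = LOW_NE_THRESHOLD,
    exclude_shared_branches: bool = False,
) -> list[CorrelationRecord]:
    """Spearman correlation of every unordered pair of landscapes.

    Each record carries dT, the comparison type, the shared-branch flag
    and the low-Ne flag (any tip involved with species Ne below the
    threshold).  With ``exclude_shared_branches`` the flagged pairs are
    dropped, the main-figure convention.
    """
    landscapes = list(landscapes)
    labels = [l.label for l in landscapes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate landscape descriptors")
    records = []
    for la, lb in itertools.combinations(landscapes, 2):
        a, b = la.descriptor, lb.descriptor
        shared = shares_branches(tree, a, b)
        if exclude_shared_branches and shared:
            continue
        rho = spearman(la.values, lb.values)
        low = any(tree.ne(t) < low_ne_threshold for t in (a.taxa | b.taxa))
        records.append(
            CorrelationRecord(
                a, b, rho, phylo_distance(tree, a, b), _comparison_type(a, b), shared, low
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "statA": r.stat_a.label,
                "statB": r.stat_b.label,
                "type": r.comparison,
                "dT": r.dt,
                "rho": np.nan if r.rho is None else r.rho,
                "shares_branches": r.shares_branches,
                "low_ne": r.low_ne,
            }
            for r in records
        ]
    )


@dataclass
class FeatureVector:
    """Per-window genomic feature (exon density, mean recombination rate...)."""

    name: str
    grid: WindowGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_windows:
            raise ValueError("feature must be defined on the landscape grid")


class CovarianceDecomposition:
    """Covariance of divergence landscapes with a genomic feature, vs time.

    Parameters
    ----------
    divergences
        Divergence landscapes (one per population pair).
    split_times
        Split time t of each pair, in generations (same order).
    feature
        The per-window feature X on the same grid.
    middle_half
        Restrict to the interior 50% of windows by index (excludes
        chromosome-end effects such as biased gene conversion).
    """

    def __init__(
        self,
        divergences,
        split_times,
        feature: FeatureVector,
        middle_half: bool = False,
    ):
        self.divergences = list(divergences)
        self.split_times = np.asarray(split_times, dtype=float)
        if len(self.divergences) != len(self.split_times):
            raise ValueError("one split time per divergence landscape")
        if len(self.divergences) < 2:
            raise ValueError("need at least two divergences at distinct times")
        self.feature = feature
        self.middle_half = middle_half
        n = feature.grid.n_windows
        self._keep = slice(n // 4, n - n // 4) if middle_half else slice(None)

    def fit(self) -> "CovarianceDecompositionResults":
        x = self.feature.values[self._keep]
        rows = []
        for land, t in zip(self.divergences, self.split_times):
            d = land.values[self._keep]
            ok = ~(np.isnan(d) | np.isnan(x))
            if ok.sum() < 3:
                cov = cor = np.nan
            else:
                cov = float(np.cov(d[ok], x[ok], ddof=1)[0, 1])
                cor = float(np.corrcoef(d[ok], x[ok])[0, 1])
            rows.append({"pair": land.label, "t": t, "cov": cov, "cor": cor})
        series = pd.DataFrame(rows).sort_values("t").reset_index(drop=True)
        good = series.dropna(subset=["cov"])
        if good["t"].nunique() < 2:
            raise ValueError("slope undefined: all split times equal")
        import statsmodels.api as sm

        X = sm.add_constant(good["t"].to_numpy())
        ols = sm.OLS(good["cov"].to_numpy(), X).fit()
        return CovarianceDecompositionResults(self, series, ols)


class CovarianceDecompositionResults:
    """OLS fit of Cov(D(t), X) against split time t.

    ``slope`` estimates Cov(R, X), the covariance between the feature
    and the per-window substitution rate.
    """

    def __init__(self, model: CovarianceDecomposition, series: pd.DataFrame, ols):
        self.model = model
        self.series = series
        self._ols = ols
        self.intercept, self.slope = ols.params
        self.bse = dict(zip(("intercept", "slope"), ols.bse))
        self.pvalues = dict(zip(("intercept", "slope"), ols.pvalues))

    def conf_int(self, alpha: float = 0.05):
        lo, hi = self._ols.conf_int(alpha)[1]
        return float(lo), float(hi)

    def summary(self) -> str:
        lines = [
            "Covariance decomposition: Cov(D(t), X) = a + t * Cov(R, X)",
            f"feature: {self.model.feature.name}"
            + ("  (middle half of windows)" if self.model.middle_half else ""),
            f"pairs: {len(self.series)}",
            f"slope Cov(R,X): {self.slope:.4g}  (se {self.bse['slope']:.3g}, p {self.pvalues['slope']:.3g})",
            f"intercept:      {self.intercept:.4g}  (se {self.bse['intercept']:.3g})",
            "",
            self.series.to_string(index=False),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - diagnostic figure
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.series["t"], self.series["cov"])
        tt = np.linspace(0, self.series["t"].max(), 50)
        ax.plot(tt, self.intercept + self.slope * tt)
        ax.set_xlabel("split time t (generations)")
        ax.set_ylabel("Cov(D(t), X)")
        return ax


def pca_embedding(matrix: pd.DataFrame, data_row: str | None = None, n_components: int = 2):
    """Column-centered PCA of the runs x correlations matrix.

    Missing entries are imputed by the column mean (logged).  No
    variance scaling is applied.  Returns ``(coords, explained,
    distances)`` where ``coords`` holds the top components per row and
    ``distances`` the Euclidean distance in the original (centered,
    imputed) space from ``data_row`` to every other row, ascending.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two correlation columns")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows")
    X = matrix.to_numpy(dtype=float).copy()
    nmiss = int(np.isnan(X).sum())
    if nmiss:
        logger.warning("imputing %d missing correlations by column mean", nmiss)
        mu = np.nanmean(X, axis=0)
        ii = np.where(np.isnan(X))
        X[ii] = mu[ii[1]]
    Xc = X - X.mean(axis=0)
    n_components = min(n_components, min(Xc.shape) - 0)
    u, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    coords = pd.DataFrame(
        (u * sv)[:, :n_components],
        index=matrix.index,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    total_var = (sv**2).sum()
    explained = sv[:n_components] ** 2 / total_var if total_var > 0 else np.zeros(n_components)
    distances = None
    if data_row is not None:
        ref = Xc[list(matrix.index).index(data_row)]
        d = np.linalg.norm(Xc - ref, axis=1)
        distances = pd.Series(d, index=matrix.index).drop(data_row).sort_values()
    return coords, explained, distances
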