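"""Random-Forest regression kernel with out-of-bag accounting.

This module is the computational core every later stage calls. Individual
regression trees come from scikit-learn, but everything the analysis
depends on — bootstrap sampling, out-of-bag (OOB) prediction, percent
variance explained (PVE) and permutation importance — is computed here from
per-tree bootstrap records, with one pinned definition:

* each tree is grown on a bootstrap sample of size n drawn with replacement
  (so ~36% of individuals are out of bag for that tree), with ``mtry``
  candidate predictors per split and a minimum leaf size of 5;
* the OOB prediction for an individual is the mean over trees for which it
  was out of bag, and PVE = 100 * (1 - OOB MSE / var(y));
* the importance of SNP j is the mean over trees of the increase in that
  tree's OOB squared error when column j is permuted among the tree's OOB
  samples, expressed as a percent of the forest's baseline OOB MSE.

Importance and PVE may both be negative: a negative importance marks a SNP
whose inclusion adds noise, and a negative PVE a model worse than the mean.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RFConfig",
    "RFFit",
    "fit_rf",
    "permutation_importance",
    "tune_mtry",
    "default_mtry_grid",
    "derive_seed",
]

_MAX_SEED = 2**31 - 1


def derive_seed(master: int, *keys) -> int:
    """Deterministically derive a sub-seed from a master seed and context keys.

    Strings are hashed with crc32 so that ("purge", step, rep) style keys are
    stable across runs and platforms. The result is always below 2**31.
    """
    ints = tuple(
        int(k) if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
        for k in keys
    )
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=ints)
    return int(ss.generate_state(1)[0]) % _MAX_SEED


@dataclass
class RFConfig:
    """Forest hyperparameters.

    ``mtry`` is the number of candidate SNPs per split: an integer, "sqrt"
    (floor of the square root of p, the default), "third" (p/3, the R
    regression-forest convention, often stronger when signal is sparse), or
    "tune" to pick the best value from ``default_mtry_grid`` by mean OOB PVE.
    """

    n_trees: int = 1500
    mtry: int | str = "sqrt"
    seed: int = 0
    min_node_size: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.mtry, str) and self.mtry not in ("sqrt", "third", "tune"):
            raise ValueError("mtry must be a positive int, 'sqrt', 'third' or 'tune'")
        if isinstance(self.mtry, int) and self.mtry < 1:
            raise ValueError("mtry must be a positive int, 'sqrt', 'third' or 'tune'")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry == "sqrt":
            return max(1, min(p, int(math.isqrt(p))))
        if self.mtry == "third":  # the R regression-forest convention
            return max(1, min(p, p // 3))
        if self.mtry == "tune":
            raise ValueError("mtry='tune' must be resolved via tune_mtry first")
        if self.mtry > p:
            raise ValueError(f"mtry={self.mtry} exceeds number of SNPs p={p}")
        return int(self.mtry)


@dataclass
class RFFit:
    """A fitted forest with its OOB records.

    ``oob_pred`` holds NaN for individuals that were never out of bag (they
    are excluded from the OOB MSE, never imputed); ``importance`` is the
    permutation importance per SNP in percent of baseline OOB MSE.
    """

    config: RFConfig
    snp_ids: list[str] | None
    oob_pred: np.ndarray
    oob_mse: float
    pve: float
    importance: np.ndarray | None
    n_never_oob: int
    trees: list = field(repr=False, default_factory=list)
    oob_indices: list = field(repr=False, default_factory=list)

    def importance_by_snp(self) -> dict[str, float]:
        if self.importance is None:
            raise ValueError("fit was computed without importance")
        ids = self.snp_ids or [str(j) for j in range(self.importance.size)]
        return dict(zip(ids, self.importance.tolist()))


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, GenotypeMatrix):
        return np.ascontiguousarray(X.values, dtype=np.float32), list(X.snp_ids)
    arr = np.ascontiguousarray(np.asarray(X), dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    return arr, None


def fit_rf(X, y, config: RFConfig | None = None, compute_importance: bool = True) -> RFFit:
    """Fit a regression forest and compute OOB prediction, PVE and importance.

    X may be a GenotypeMatrix (its imputed values are used) or a plain
    individuals-x-SNPs array; y is the (possibly structure-adjusted) trait.
    Fully deterministic given ``config.seed``.
    """
    config = config or RFConfig()
    X32, snp_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = X32.shape
    if y.shape != (n,):
        raise ValueError("y length does not match X rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if n < 10:
        raise ValueError(f"need at least 10 individuals, got {n}")
    if p < 2:
        raise ValueError(f"need at least 2 SNPs, got {p}")
    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        raise ValueError("constant phenotype")
    mtry = config.resolve_mtry(p)

    rng = np.random.default_rng(config.seed)
    trees: list[DecisionTreeRegressor] = []
    oob_lists: list[np.ndarray] = []
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, dtype=np.int64)
    for _ in range(config.n_trees):
        boot = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, _MAX_SEED))
        oob = np.nonzero(np.bincount(boot, minlength=n) == 0)[0]
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=config.min_node_size,
            random_state=tree_seed,
        )
        tree.fit(X32[boot], y[boot])
        if oob.size:
            pred = tree.tree_.predict(np.ascontiguousarray(X32[oob])).ravel()
            pred_sum[oob] += pred
            pred_cnt[oob] += 1
        trees.append(tree)
        oob_lists.append(oob)

    covered = pred_cnt > 0
    n_never = int(n - covered.sum())
    if n_never:
        logger.info("%d individual(s) never out of bag; excluded from OOB MSE", n_never)
    if not covered.any():
        raise ValueError("no individual was ever out of bag; increase n_trees")
    oob_pred = np.full(n, np.nan)
    oob_pred[covered] = pred_sum[covered] / pred_cnt[covered]
    oob_mse = float(np.mean((y[covered] - oob_pred[covered]) ** 2))
    pve = 100.0 * (1.0 - oob_mse / var_y)

    fit = RFFit(
        config=config,
        snp_ids=snp_ids,
        oob_pred=oob_pred,
        oob_mse=oob_mse,
        pve=pve,
        importance=None,
        n_never_oob=n_never,
        trees=trees,
        oob_indices=oob_lists,
    )
    if compute_importance:
        fit.importance = permutation_importance(
            fit, X32, y, seed=derive_seed(config.seed, "importance")
        )
    return fit


def permutation_importance(fit: RFFit, X, y, seed: int) -> np.ndarray:
    """Permutation importance of every SNP, in percent of baseline OOB MSE.

    For each tree and each SNP the tree actually splits on, the SNP's values
    are shuffled among that tree's OOB samples and the tree's OOB squared
    error recomputed; the error increase is averaged over all trees (trees
    that never use a SNP contribute zero) and scaled by 100 / baseline OOB
    MSE. Negative values are meaningful: permuting the SNP *improved* the
    prediction, so the SNP is noise.
    """
    X32, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    p = X32.shape[1]
    rng = np.random.default_rng(seed)
    deltas = np.zeros(p)
    for tree, oob in zip(fit.trees, fit.oob_indices):
        if oob.size == 0:
            continue
        Xo = np.ascontiguousarray(X32[oob])
        yo = y[oob]
        tr = tree.tree_
        base_mse = float(np.mean((yo - tr.predict(Xo).ravel()) ** 2))
        used = np.unique(tr.feature[tr.feature >= 0])
        for j in used:
            col = Xo[:, j].copy()
            Xo[:, j] = col[rng.permutation(col.size)]
            perm_mse = float(np.mean((yo - tr.predict(Xo).ravel()) ** 2))
            Xo[:, j] = col
            deltas[j] += perm_mse - base_mse
    return deltas / len(fit.trees) / fit.oob_mse * 100.0


def default_mtry_grid(p: int) -> list[int]:
    """Candidate mtry values: half, one and two times sqrt(p), clipped to [1, p]."""
    s = math.sqrt(p)
    return sorted({min(p, max(1, g)) for g in (int(s / 2), int(s), int(2 * s))})


def tune_mtry(X, y, grid=None, config: RFConfig | None = None, n_seeds: int = 3) -> int:
    """Pick the mtry maximizing mean OOB PVE over ``n_seeds`` replicate fits.

    Ties break to the smaller mtry. The replicate seeds derive from
    ``config.seed`` so the whole search is reproducible.
    """
    config = config or RFConfig()
    X32, _ = _as_matrix(X)
    p = X32.shape[1]
    if grid is None:
        grid = default_mtry_grid(p)
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ValueError("empty mtry grid")
    if grid[-1] > p:
        raise ValueError(f"grid value {grid[-1]} exceeds p={p}")

    best_mtry, best_pve = None, -np.inf
    for m in grid:
        pves = []
        for s in range(n_seeds):
            cfg = RFConfig(
                n_trees=config.n_trees,
                mtry=m,
                seed=derive_seed(config.seed, "tune", m, s),
                min_node_size=config.min_node_size,
            )
            pves.append(fit_rf(X32, y, cfg, compute_importance=False).pve)
        mean_pve = float(np.mean(pves))
        logger.info("tune_mtry: mtry=%d mean PVE=%.2f", m, mean_pve)
        if mean_pve > best_pve:
            best_mtry, best_pve = m, mean_pve
    return int(best_mtry)
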