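"""Backward purging of SNP subsets and random-subset baselines.

Because a forest models interactions implicitly, a SNP's importance depends
on which other SNPs are in the model; ranking once on the full model and
cutting is therefore not enough. The backward purge starts from the top-k
SNPs of a full-model fit (k=50 by default, generous enough to keep SNPs
whose main effect is weak but whose interactions matter), refits the forest
several times at each step, averages the per-SNP importances, and removes
the least important SNP — down to two SNPs, recording PVE the whole way.

The random baselines fit forests on uniformly drawn SNP combinations of
fixed sizes; their mean PVE per size is the yardstick the purged subsets
must beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import RFConfig, RFFit, derive_seed, fit_rf
from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PurgeStep",
    "PurgeTrajectory",
    "BaselineTable",
    "backward_purge",
    "select_top",
    "random_baseline",
]


@dataclass
class PurgeStep:
    snp_set: list[str]
    mean_pve: float
    mean_importance: dict[str, float]
    purged_snp: str | None  # None on the final (min_k) step


@dataclass
class PurgeTrajectory:
    steps: list[PurgeStep]
    start_k: int
    replicates: int
    full_fit: RFFit = field(repr=False, default=None)  # type: ignore[assignment]

    def sizes(self) -> list[int]:
        return [len(s.snp_set) for s in self.steps]

    def pve_by_size(self) -> pd.Series:
        return pd.Series(
            {len(s.snp_set): s.mean_pve for s in self.steps}, name="mean_pve"
        ).sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subset_size": len(s.snp_set),
                "mean_pve": s.mean_pve,
                "purged_snp": "" if s.purged_snp is None else s.purged_snp,
                "snp_set": ",".join(s.snp_set),
            }
            for s in self.steps
        ]
        return pd.DataFrame(rows)


@dataclass
class BaselineTable:
    table: pd.DataFrame  # columns: subset_size, rep, snp_set, pve

    def summary(self) -> pd.Series:
        """Mean PVE per subset size."""
        return self.table.groupby("subset_size")["pve"].mean()


def _resolve(X, snp_ids):
    if isinstance(X, GenotypeMatrix):
        return np.ascontiguousarray(X.values, dtype=np.float32), list(X.snp_ids)
    arr = np.ascontiguousarray(np.asarray(X), dtype=np.float32)
    ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(arr.shape[1])]
    if len(ids) != arr.shape[1]:
        raise ValueError("snp_ids length does not match X columns")
    return arr, ids


def _top_by_importance(imp: np.ndarray, ids: list[str], k: int) -> list[int]:
    # sort by importance descending; ties break to the lexicographically
    # smaller SNP id for determinism
    order = sorted(range(len(ids)), key=lambda j: (-imp[j], ids[j]))
    return sorted(order[:k])


def backward_purge(
    X,
    y,
    start_k: int = 50,
    replicates: int = 3,
    min_k: int = 2,
    config: RFConfig | None = None,
    snp_ids=None,
) -> PurgeTrajectory:
    """Purge the least important SNP step by step, from start_k down to min_k.

    The starting set is the top ``start_k`` SNPs by permutation importance
    from one full-model fit. At each step the forest is refit ``replicates``
    times with distinct derived seeds; importances and PVE are averaged, and
    the SNP with the smallest mean importance is removed (ties break to the
    lexicographically smaller id). The recorded trajectory holds, per subset
    size, the set, its mean PVE and the purged SNP.
    """
    config = config or RFConfig()
    X32, ids = _resolve(X, snp_ids)
    if start_k < min_k:
        raise ValueError(f"start_k={start_k} below min_k={min_k}")
    if min_k < 2:
        raise ValueError("min_k must be >= 2")
    if start_k > X32.shape[1]:
        raise ValueError(f"start_k={start_k} exceeds p={X32.shape[1]}")

    full_cfg = RFConfig(config.n_trees, config.mtry, derive_seed(config.seed, "full"),
                        config.min_node_size)
    full_fit = fit_rf(X32, y, full_cfg)
    full_fit.snp_ids = ids
    current = _top_by_importance(full_fit.importance, ids, start_k)

    steps: list[PurgeStep] = []
    step_no = 0
    while True:
        sub_ids = [ids[j] for j in current]
        Xs = np.ascontiguousarray(X32[:, current])
        imps = np.zeros(len(current))
        pves = []
        for r in range(replicates):
            cfg = RFConfig(
                config.n_trees,
                config.mtry,
                derive_seed(config.seed, "purge", step_no, r),
                config.min_node_size,
            )
            f = fit_rf(Xs, y, cfg)
            imps += f.importance
            pves.append(f.pve)
        imps /= replicates
        mean_pve = float(np.mean(pves))

        if len(current) <= min_k:
            steps.append(PurgeStep(sub_ids, mean_pve, dict(zip(sub_ids, imps)), None))
            break
        worst = min(range(len(current)), key=lambda j: (imps[j], sub_ids[j]))
        steps.append(
            PurgeStep(sub_ids, mean_pve, dict(zip(sub_ids, imps)), sub_ids[worst])
        )
        logger.info(
            "purge step %d: size %d, mean PVE %.2f, removed %s",
            step_no, len(current), mean_pve, sub_ids[worst],
        )
        del current[worst]
        step_no += 1

    return PurgeTrajectory(steps, start_k=start_k, replicates=replicates, full_fit=full_fit)


def select_top(trajectory: PurgeTrajectory, k: int) -> list[str]:
    """The SNP set recorded at the trajectory step of size k."""
    for s in trajectory.steps:
        if len(s.snp_set) == k:
            return list(s.snp_set)
    raise ValueError(
        f"k={k} outside trajectory range "
        f"[{len(trajectory.steps[-1].snp_set)}, {trajectory.start_k}]"
    )


def random_baseline(
    X,
    y,
    sizes=(2, 5, 10, 15, 20),
    reps: int = 10,
    config: RFConfig | None = None,
    snp_ids=None,
) -> BaselineTable:
    """Fit forests on uniformly drawn SNP combinations of the given sizes.

    Each draw samples ``size`` distinct SNPs without replacement; the table
    records every (size, rep) PVE, and ``summary()`` gives the mean PVE per
    size. These "random models" quantify how much phenotypic variance an
    arbitrary SNP combination of equal size explains.
    """
    config = config or RFConfig()
    X32, ids = _resolve(X, snp_ids)
    p = X32.shape[1]
    sizes = sorted(set(int(s) for s in sizes))
    if sizes and sizes[-1] > p:
        raise ValueError(f"subset size {sizes[-1]} exceeds p={p}")

    rows = []
    for size in sizes:
        for rep in range(reps):
            draw_rng = np.random.default_rng(derive_seed(config.seed, "draw", size, rep))
            cols = np.sort(draw_rng.choice(p, size=size, replace=False))
            cfg = RFConfig(
                config.n_trees,
                min(config.mtry, size) if isinstance(config.mtry, int) else config.mtry,
                derive_seed(config.seed, "baseline", size, rep),
                config.min_node_size,
            )
            f = fit_rf(X32[:, cols], y, cfg, compute_importance=False)
            rows.append(
                {
                    "subset_size": size,
                    "rep": rep,
                    "snp_set": ",".join(ids[c] for c in cols),
                    "pve": f.pve,
                }
            )
    return BaselineTable(pd.DataFrame(rows))
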