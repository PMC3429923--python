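"""Population-structure adjustment of a phenotype.

Admixed population samples confound ancestry with trait values whenever the
trait tracks the same geography the clusters do (a latitudinal cline, for
example). To strip that signal before marker-based prediction, the trait is
regressed on the ancestry proportions by ordinary least squares and replaced
by the general mean plus the residuals. Because Q rows sum to one, only the
first K-1 cluster columns enter the design next to the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AncestryMatrix, PhenotypeVector

__all__ = ["AdjustedPhenotype", "adjust_phenotype"]


@dataclass
class AdjustedPhenotype:
    """Structure-adjusted trait: general mean + OLS residuals.

    ``r_squared_structure`` is the share of trait variance absorbed by the
    ancestry regression; the adjusted vector keeps the original mean and can
    only lose variance.
    """

    individual_ids: list[str]
    values: np.ndarray
    r_squared_structure: float
    name: str = "trait_adjusted"

    def as_phenotype(self) -> PhenotypeVector:
        return PhenotypeVector(self.individual_ids, self.values, name=self.name)


def adjust_phenotype(y: PhenotypeVector, Q: AncestryMatrix) -> AdjustedPhenotype:
    """Regress a phenotype on ancestry proportions; return mean + residuals.

    The design is an intercept plus the first K-1 columns of Q (the Kth is
    exactly collinear through the row-sum constraint). Raises if the reduced
    design is still rank deficient, naming the offending cluster columns.
    """
    if y.individual_ids != Q.individual_ids:
        raise ValueError("phenotype and Q individual ids differ")
    n, K = Q.q.shape
    if n <= K:
        raise ValueError(f"need more individuals ({n}) than clusters ({K})")

    yv = y.values
    design = np.column_stack([np.ones(n), Q.q[:, : K - 1]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "ancestry design is rank deficient beyond the row-sum constraint "
            f"(rank {rank} < {design.shape[1]}); check Q columns "
            f"{Q.cluster_ids[: K - 1]}"
        )
    coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
    fitted = design @ coef
    resid = yv - fitted

    tss = float(np.sum((yv - yv.mean()) ** 2))
    rss = float(np.sum(resid**2))
    r2 = 0.0 if tss == 0.0 else max(0.0, min(1.0, 1.0 - rss / tss))

    adjusted = yv.mean() + resid
    return AdjustedPhenotype(
        individual_ids=list(y.individual_ids),
        values=adjusted,
        r_squared_structure=r2,
        name=f"{y.name}_adjusted",
    )
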