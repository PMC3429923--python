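"""Synthetic admixed genotype-phenotype datasets with known architecture.

The generator produces the kind of data the pipeline targets: a range-wide
sample of individuals admixed among K source populations, genotyped at a
few hundred biallelic SNPs, with a continuous trait built from additive
effects at a known causal subset, optional pairwise epistasis of either
sign, an optional ancestry-linked cline (structure confounding), and
Gaussian residual noise scaled to hit a target signal share.

Allele frequencies follow the Balding-Nichols model: each SNP has an
ancestral frequency f ~ Uniform(0.05, 0.95) and per-population frequencies
f_k ~ Beta(f(1-F)/F, (1-f)(1-F)/F), so the differentiation parameter F
plays the role of F_ST. Individual admixture proportions are
Dirichlet(alpha) rows; genotypes are Binomial(2, q_i . f) draws — the
standard minimal model of an admixed sample, without linkage.

Defaults mirror the scale of a real range-wide conifer association panel:
410 individuals, 339 SNPs, K=3 clusters, ~20 causal SNPs and a 0.4 signal
share. The generator draws no LD blocks along chromosomes: loci are
independent within populations, so admixture is the only source of
between-locus correlation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import AncestryMatrix, Dataset, PhenotypeVector, build_genotype_matrix

logger = logging.getLogger(__name__)

__all__ = ["SimParams", "EpistaticPair", "SimTruth", "simulate_dataset"]

EPISTASIS_MODELS = ("product", "complementation", "redundancy")


@dataclass(frozen=True)
class EpistaticPair:
    """A planted interaction between two SNP indices.

    Models (all codes centered before scaling by gamma):
    product — (g_a - mean)(g_b - mean), a synergistic cross-product with no
    marginal coding; complementation — 1 iff both loci carry an alternate
    allele (both needed); redundancy — 1 iff either locus does (either
    suffices).
    """

    snp_a: int
    snp_b: int
    gamma: float
    model: str = "product"

    def __post_init__(self) -> None:
        if self.snp_a == self.snp_b:
            raise ValueError("epistatic pair members must be distinct")
        if self.model not in EPISTASIS_MODELS:
            raise ValueError(f"unknown epistasis model {self.model!r}")


@dataclass
class SimParams:
    n: int = 410
    p: int = 339
    K: int = 3
    fst: float = 0.1
    dirichlet_alpha: float = 0.2
    n_causal: int = 20
    beta_sd: float = 1.0
    epistatic_pairs: list[EpistaticPair] = field(default_factory=list)
    structure_effect: np.ndarray | None = None  # cline coefficients, length K
    h2_target: float = 0.4
    intercept: float = 250.0  # Julian-day-like trait location
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must lie in (0, 1)")
        if self.n_causal > self.p:
            raise ValueError("n_causal exceeds p")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.structure_effect is not None:
            self.structure_effect = np.asarray(self.structure_effect, dtype=float)
            if self.structure_effect.shape != (self.K,):
                raise ValueError("structure_effect must have length K")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_ids: list[str]
    betas: dict[str, float]
    epistatic_pairs: list[tuple[str, str, float, str]]
    variance_shares: dict[str, float]  # additive/epistatic/structure/noise
    q: np.ndarray
    noise_sd: float

    def to_json(self, path) -> None:
        payload = {
            "causal_ids": self.causal_ids,
            "betas": self.betas,
            "epistatic_pairs": [list(t) for t in self.epistatic_pairs],
            "variance_shares": self.variance_shares,
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _epistasis_code(ga: np.ndarray, gb: np.ndarray, model: str) -> np.ndarray:
    if model == "product":
        code = (ga - ga.mean()) * (gb - gb.mean())
    elif model == "complementation":
        code = ((ga >= 1) & (gb >= 1)).astype(float)
    else:  # redundancy
        code = ((ga >= 1) | (gb >= 1)).astype(float)
    return code - code.mean()


def _draw_column(rng, Q: np.ndarray, fst: float) -> np.ndarray:
    K = Q.shape[1]
    f = rng.uniform(0.05, 0.95)
    if fst > 0:
        a = f * (1 - fst) / fst
        b = (1 - f) * (1 - fst) / fst
        fk = rng.beta(a, b, size=K)
    else:
        fk = np.full(K, f)
    p_ind = Q @ fk
    return rng.binomial(2, np.clip(p_ind, 0.0, 1.0))


def simulate_dataset(params: SimParams) -> tuple[Dataset, SimTruth]:
    """Generate one admixed dataset plus its ground truth, reproducibly.

    The phenotype is intercept + additive + epistatic + structure + noise,
    with the noise variance solved so that the non-noise components jointly
    account for ``h2_target`` of the total component variance. SNPs that
    come out monomorphic in the sample are redrawn (bounded retries).
    Variance shares in the returned truth are each component's marginal
    variance over the sum of the four component variances (covariances
    between components are not attributed).
    """
    rng = np.random.default_rng(params.seed)
    n, p, K = params.n, params.p, params.K

    Q = rng.dirichlet(np.full(K, params.dirichlet_alpha), size=n)
    G = np.empty((n, p), dtype=np.int8)
    for j in range(p):
        for attempt in range(50):
            col = _draw_column(rng, Q, params.fst)
            if np.unique(col).size >= 2:
                break
        else:
            raise RuntimeError(f"SNP {j} stayed monomorphic after 50 redraws")
        if attempt:
            logger.debug("SNP %d redrawn %d time(s)", j, attempt)
        G[:, j] = col

    snp_ids = [f"snp{j:04d}" for j in range(p)]
    ind_ids = [f"ind{i:04d}" for i in range(n)]

    causal_idx = np.sort(rng.choice(p, size=params.n_causal, replace=False))
    # every causal SNP carries a genuinely small-to-moderate effect: magnitude
    # bounded away from zero (a zero-heavy Gaussian would plant "causal" SNPs
    # indistinguishable from noise, contradicting the stated architecture)
    betas = params.beta_sd * rng.uniform(0.5, 1.5, size=params.n_causal)
    betas *= rng.choice((-1.0, 1.0), size=params.n_causal)
    Gc = G[:, causal_idx].astype(float)
    additive = (Gc - Gc.mean(axis=0)) @ betas if params.n_causal else np.zeros(n)

    epistatic = np.zeros(n)
    for pair in params.epistatic_pairs:
        code = _epistasis_code(
            G[:, pair.snp_a].astype(float), G[:, pair.snp_b].astype(float), pair.model
        )
        epistatic += pair.gamma * code

    structure = (
        Q @ params.structure_effect
        if params.structure_effect is not None
        else np.zeros(n)
    )
    structure = structure - structure.mean()

    var_add = float(np.var(additive))
    var_epi = float(np.var(epistatic))
    var_str = float(np.var(structure))
    var_sig = var_add + var_epi + var_str
    if var_sig > 0:
        noise_var = var_sig * (1 - params.h2_target) / params.h2_target
    else:
        noise_var = 1.0  # null architecture: the trait is pure noise
    noise_sd = float(np.sqrt(noise_var))
    noise = rng.normal(0.0, noise_sd, size=n)

    y = params.intercept + additive + epistatic + structure + noise

    total = var_sig + noise_var
    shares = {
        "additive": var_add / total,
        "epistatic": var_epi / total,
        "structure": var_str / total,
        "noise": noise_var / total,
    }

    raw = G.astype(float)
    if params.missing_rate > 0:
        mask = rng.random((n, p)) < params.missing_rate
        # never blank out so much that a column loses both classes
        raw[mask] = np.nan
    geno = build_genotype_matrix(ind_ids, snp_ids, raw, drop_monomorphic=True)

    dataset = Dataset(
        genotypes=geno,
        phenotype=PhenotypeVector(ind_ids, y, name="trait"),
        ancestry=AncestryMatrix(ind_ids, Q),
    )
    truth = SimTruth(
        causal_ids=[snp_ids[j] for j in causal_idx],
        betas={snp_ids[j]: float(b) for j, b in zip(causal_idx, betas)},
        epistatic_pairs=[
            (snp_ids[pr.snp_a], snp_ids[pr.snp_b], pr.gamma, pr.model)
            for pr in params.epistatic_pairs
        ],
        variance_shares=shares,
        q=Q,
        noise_sd=noise_sd,
    )
    return dataset, truth
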