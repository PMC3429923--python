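"""Tabular input/output and dataset assembly.

All inputs are plain TSV with a header row and individual identifiers in the
first column: a genotype matrix in additive coding (0/1/2 copies of the
minor allele, missing allowed), a continuous phenotype, and optionally an
ancestry-proportion (Q) matrix with one column per cluster. The three tables
are joined on individual id into a single canonical ordering (sorted ids) so
that row order in the input files never matters.

Missing genotypes are imputed once, at load, by the per-SNP mode (ties break
to the lower code); the pre-imputation values are retained for analyses that
must respect missingness, such as the genotypic LD test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("NA", "-9", "")

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "AncestryMatrix",
    "Dataset",
    "build_genotype_matrix",
    "load_dataset",
    "write_dataset",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs in additive coding.

    ``values`` is the complete (mode-imputed) int8 matrix used by the
    forest; ``missing`` marks entries that were missing before imputation.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.missing is None:
            self.missing = np.zeros(self.values.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, p = self.values.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual identifiers")
        if len(set(self.snp_ids)) != p:
            raise ValueError("duplicate SNP identifiers")
        ok = np.isin(self.values, (0, 1, 2))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype code {self.values[i, j]} at individual "
                f"{self.individual_ids[i]!r}, SNP {self.snp_ids[j]!r} is not 0/1/2"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def raw(self) -> np.ndarray:
        """Float matrix with NaN restored at originally-missing entries."""
        out = self.values.astype(float)
        out[self.missing] = np.nan
        return out

    def column(self, snp_id: str) -> np.ndarray:
        """Raw (pre-imputation) genotype column for one SNP, NaN = missing."""
        j = self.snp_ids.index(snp_id)
        col = self.values[:, j].astype(float)
        col[self.missing[:, j]] = np.nan
        return col

    def subset(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            snp_ids=list(snp_ids),
            values=self.values[:, idx].copy(),
            missing=self.missing[:, idx].copy(),
        )


@dataclass
class PhenotypeVector:
    individual_ids: list[str]
    values: np.ndarray
    name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.individual_ids) != self.values.size:
            raise ValueError("phenotype ids and values do not align")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual identifiers in phenotype")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype contains non-finite values")


@dataclass
class AncestryMatrix:
    """Admixture proportions (Q matrix): rows are individuals, columns are
    clusters; each row sums to one."""

    individual_ids: list[str]
    q: np.ndarray
    cluster_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or len(self.individual_ids) != self.q.shape[0]:
            raise ValueError("Q ids and matrix do not align")
        if self.q.shape[1] < 1:
            raise ValueError("Q needs at least one cluster column")
        if self.cluster_ids is None:
            self.cluster_ids = [f"cluster{k + 1}" for k in range(self.q.shape[1])]
        if np.any(self.q < 0.0) or np.any(self.q > 1.0):
            raise ValueError("Q entries must lie in [0, 1]")
        bad = np.abs(self.q.sum(axis=1) - 1.0) > 1e-6
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"Q row for individual {self.individual_ids[i]!r} sums to "
                f"{self.q[i].sum():.8f}, not 1"
            )

    @property
    def K(self) -> int:
        return self.q.shape[1]


@dataclass
class Dataset:
    """A genotype matrix, a phenotype and (optionally) a Q matrix, joined on
    individual id and stored in one canonical row order."""

    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    ancestry: AncestryMatrix | None = None

    def __post_init__(self) -> None:
        if self.genotypes.individual_ids != self.phenotype.individual_ids:
            raise ValueError("genotype and phenotype individual ids differ")
        if self.ancestry is not None and (
            self.ancestry.individual_ids != self.genotypes.individual_ids
        ):
            raise ValueError("Q individual ids differ from genotype ids")

    @property
    def n(self) -> int:
        return self.genotypes.n

    @property
    def p(self) -> int:
        return self.genotypes.p


def _impute_mode(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Per-SNP mode imputation; ties break to the lower genotype code."""
    out = values.copy()
    for j in np.nonzero(missing.any(axis=0))[0]:
        col = values[:, j]
        obs = col[~missing[:, j]]
        counts = np.bincount(obs, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the first (lowest) on ties
        out[missing[:, j], j] = mode
    return out


def build_genotype_matrix(
    individual_ids,
    snp_ids,
    raw: np.ndarray,
    drop_monomorphic: bool = True,
) -> GenotypeMatrix:
    """Validate, filter and impute a raw genotype matrix.

    ``raw`` is float with NaN marking missing genotypes. Columns with fewer
    than two distinct observed values are dropped with a warning (or
    rejected if ``drop_monomorphic`` is False); remaining missing entries
    are mode-imputed.
    """
    raw = np.asarray(raw, dtype=float)
    missing = np.isnan(raw)
    vals = np.where(missing, 0, raw)
    if not np.isin(vals, (0, 1, 2)).all():
        bad = np.argwhere(~np.isin(vals, (0, 1, 2)) & ~missing)[0]
        raise ValueError(
            f"genotype value {raw[bad[0], bad[1]]!r} at row {individual_ids[bad[0]]!r}, "
            f"column {snp_ids[bad[1]]!r} is not 0/1/2 or missing"
        )
    vals = vals.astype(np.int8)

    keep = []
    for j in range(vals.shape[1]):
        obs = vals[~missing[:, j], j]
        if obs.size == 0 or np.unique(obs).size < 2:
            if not drop_monomorphic:
                raise ValueError(f"SNP {snp_ids[j]!r} is monomorphic")
            keep.append(False)
        else:
            keep.append(True)
    keep_arr = np.asarray(keep)
    n_dropped = int((~keep_arr).sum())
    if n_dropped:
        dropped = [s for s, k in zip(snp_ids, keep) if not k]
        logger.warning("dropping %d monomorphic SNP(s): %s", n_dropped, dropped)
    vals = vals[:, keep_arr]
    missing = missing[:, keep_arr]
    snp_ids = [s for s, k in zip(snp_ids, keep) if k]

    n_miss = int(missing.sum())
    if n_miss:
        logger.info("imputing %d missing genotype(s) by per-SNP mode", n_miss)
        vals = _impute_mode(vals, missing)
    return GenotypeMatrix(list(individual_ids), list(snp_ids), vals, missing)


def _read_table(path, missing_tokens) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={0: str},
        na_values=list(missing_tokens),
        keep_default_na=False,
        float_precision="round_trip",
    )
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate individual id {dup!r}")
    return df


def load_dataset(
    geno_path,
    pheno_path,
    q_path=None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    transpose: bool = False,
    drop_monomorphic: bool = True,
) -> Dataset:
    """Read genotype/phenotype(/Q) TSVs and assemble a joined Dataset.

    Genotype files have individuals as rows and SNPs as columns (set
    ``transpose=True`` for the other orientation). Individuals are joined on
    id and ordered canonically (sorted ids); individuals lacking a phenotype
    are dropped with a logged count. Missing genotype tokens default to
    "NA", "-9" and the empty cell.
    """
    gdf = _read_table(geno_path, missing_tokens)
    if transpose:
        gdf = gdf.T
        gdf.index = gdf.index.astype(str)
    try:
        graw = gdf.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        # locate the offending cell for a useful message
        for i, row in enumerate(gdf.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{geno_path}: unparseable genotype {v!r} at individual "
                        f"{gdf.index[i]!r}, SNP {gdf.columns[j]!r}"
                    ) from exc
        raise

    pdf = _read_table(pheno_path, missing_tokens)
    trait_name = str(pdf.columns[0])
    pheno = pd.to_numeric(pdf.iloc[:, 0], errors="coerce")

    ids = [i for i in gdf.index if i in pheno.index and np.isfinite(pheno[i])]
    n_dropped = gdf.shape[0] - len(ids)
    if n_dropped:
        logger.info("dropped %d individual(s) without a usable phenotype", n_dropped)
    if not ids:
        raise ValueError("no individuals remain after joining genotype and phenotype")
    ids = sorted(ids)

    order = [list(gdf.index).index(i) for i in ids]
    geno = build_genotype_matrix(
        ids, [str(c) for c in gdf.columns], graw[order], drop_monomorphic
    )
    phen = PhenotypeVector(ids, pheno.loc[ids].to_numpy(), name=trait_name)

    anc = None
    if q_path is not None:
        qdf = _read_table(q_path, missing_tokens)
        missing_q = [i for i in ids if i not in qdf.index]
        if missing_q:
            raise ValueError(f"Q matrix lacks individuals: {missing_q[:5]}")
        anc = AncestryMatrix(
            ids,
            qdf.loc[ids].to_numpy(dtype=float),
            cluster_ids=[str(c) for c in qdf.columns],
        )
    return Dataset(geno, phen, anc)


def write_dataset(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write a Dataset back to TSV (genotype.tsv, phenotype.tsv, q.tsv).

    Originally-missing genotypes are written as "NA", so a load/write cycle
    round-trips exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    g = dataset.genotypes
    gdf = pd.DataFrame(g.raw(), index=g.individual_ids, columns=g.snp_ids)
    gdf = gdf.astype(object).where(~np.isnan(g.raw()), "NA")
    gdf = gdf.map(lambda v: v if isinstance(v, str) else str(int(v)))
    paths["genotype"] = out / "genotype.tsv"
    gdf.to_csv(paths["genotype"], sep="\t", index_label="individual")

    pdf = pd.DataFrame(
        {dataset.phenotype.name: dataset.phenotype.values},
        index=dataset.phenotype.individual_ids,
    )
    paths["phenotype"] = out / "phenotype.tsv"
    pdf.to_csv(paths["phenotype"], sep="\t", index_label="individual")

    if dataset.ancestry is not None:
        qdf = pd.DataFrame(
            dataset.ancestry.q,
            index=dataset.ancestry.individual_ids,
            columns=dataset.ancestry.cluster_ids,
        )
        paths["q"] = out / "q.tsv"
        qdf.to_csv(paths["q"], sep="\t", index_label="individual")
    return paths
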