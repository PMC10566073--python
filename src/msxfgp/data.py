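"""Genotype/phenotype CSV I/O and a synthetic genotype-phenotype simulator.

File conventions: comma-separated UTF-8 with a mandatory header row; the
first column carries the sample identifier.  The genotype file is samples x
markers with numeric cells — integer allele dosages (0/1/2 diploid, 0-4
tetraploid) or continuous PCA-reduced features.  The phenotype file has the
sample id plus one numeric quantitative-trait column.  Missing cells are an
input error, never imputed; any required transformation of the trait
(log10, standardization) is the caller's responsibility.

The simulator draws independent markers with uniform minor-allele
frequencies, binomial allele dosages, sparse Gaussian causal effects and an
additive phenotype whose noise variance is set from the *realized* genetic
variance so the requested narrow-sense heritability holds in-sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenoPhenoDataset",
    "SimulationSpec",
    "read_genotype_csv",
    "read_phenotype_csv",
    "align_samples",
    "write_selected_genotype",
    "write_genotype_csv",
    "write_phenotype_csv",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class GenoPhenoDataset:
    """Aligned genotype matrix and phenotype vector with identifiers."""

    sample_ids: list[str]
    marker_ids: list[str]
    genotypes: np.ndarray
    phenotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n or self.phenotypes.size != n:
            raise ValueError("sample ids, genotype rows and phenotypes disagree in length")
        if len(self.marker_ids) != m:
            raise ValueError("marker ids do not match genotype columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker identifiers")
        if np.isnan(self.genotypes).any() or np.isnan(self.phenotypes).any():
            raise ValueError("missing values are not allowed")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one simulated genotype-phenotype dataset.

    ``ploidy_code_max`` is the largest dosage code (2 for diploid 0/1/2,
    4 for tetraploid 0-4); ``heritability`` is the fraction of phenotypic
    variance carried by the additive genetic values.
    """

    n_samples: int = 200
    n_markers: int = 200
    n_causal: int = 10
    heritability: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    ploidy_code_max: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_markers < 1:
            raise ValueError("need at least 2 samples and 1 marker")
        if not 0 < self.n_causal <= self.n_markers:
            raise ValueError("n_causal must lie in [1, n_markers]")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must be ordered within (0, 0.5]")
        if self.ploidy_code_max < 1:
            raise ValueError("ploidy_code_max must be >= 1")


def _read_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def read_genotype_csv(path, max_code: int | None = None) -> pd.DataFrame:
    """Load a samples x markers genotype CSV into a validated DataFrame.

    ``max_code`` enables integer-dosage validation: every cell must then be
    an integer in ``[0, max_code]``.  Without it, any finite numeric matrix
    (e.g. PCA-reduced features) is accepted.
    """
    frame = _read_frame(path)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no marker columns found")
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate marker ids {dupes}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if frame.isna().any().any() or bad.any().any():
        cell = np.argwhere((numeric.isna()).to_numpy())[0]
        raise ValueError(
            f"{path}: missing or non-numeric cell at sample "
            f"{frame.index[cell[0]]!r}, marker {frame.columns[cell[1]]!r}"
        )
    if max_code is not None:
        values = numeric.to_numpy()
        out_of_range = (values < 0) | (values > max_code) | (values != np.floor(values))
        if out_of_range.any():
            cell = np.argwhere(out_of_range)[0]
            raise ValueError(
                f"{path}: cell at sample {frame.index[cell[0]]!r}, marker "
                f"{frame.columns[cell[1]]!r} has value {values[tuple(cell)]}, "
                f"outside integer codes [0, {max_code}]"
            )
    return numeric


def read_phenotype_csv(path) -> pd.Series:
    """Load a phenotype CSV (sample id + one numeric trait column)."""
    frame = _read_frame(path)
    if frame.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one trait column, got {frame.shape[1]}")
    if frame.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    series = pd.to_numeric(frame.iloc[:, 0], errors="coerce")
    if series.isna().any():
        missing = series.index[series.isna()].tolist()
        raise ValueError(f"{path}: missing or non-numeric phenotype for samples {missing}")
    return series


def align_samples(genotypes: pd.DataFrame, phenotypes: pd.Series) -> GenoPhenoDataset:
    """Inner-join genotypes and phenotypes on sample id.

    Samples present on only one side are dropped with a logged count; an
    empty intersection is fatal.  The join is order-insensitive: the output
    follows the genotype row order restricted to the shared ids.
    """
    shared = [s for s in genotypes.index if s in set(phenotypes.index)]
    if not shared:
        raise ValueError("no samples shared between genotype and phenotype files")
    dropped = (len(genotypes.index) - len(shared)) + (len(phenotypes.index) - len(shared))
    if dropped:
        logger.info("align_samples: dropped %d unmatched sample(s)", dropped)
    geno = genotypes.loc[shared]
    pheno = phenotypes.loc[shared]
    return GenoPhenoDataset(
        sample_ids=list(geno.index),
        marker_ids=list(geno.columns),
        genotypes=geno.to_numpy(dtype=float),
        phenotypes=pheno.to_numpy(dtype=float),
    )


def write_selected_genotype(dataset: GenoPhenoDataset, mask, path) -> None:
    """Write the genotype CSV restricted to the selected marker columns."""
    # SelectionMask exposes .flags; note a bare ndarray also has a (different)
    # .flags attribute, so duck-typing on it would be wrong
    raw = mask.flags if hasattr(mask, "selected_indices") else mask
    flags = np.asarray(raw, dtype=bool)
    if flags.size != dataset.n_markers:
        raise ValueError("mask length does not match the number of markers")
    if not flags.any():
        raise ValueError("refusing to write a genotype file with zero markers")
    cols = [m for m, keep in zip(dataset.marker_ids, flags) if keep]
    frame = pd.DataFrame(
        dataset.genotypes[:, flags], index=dataset.sample_ids, columns=cols
    )
    frame.index.name = "sample"
    frame.to_csv(path)


def write_genotype_csv(dataset: GenoPhenoDataset, path) -> None:
    """Write the full genotype matrix as CSV (samples x markers)."""
    frame = pd.DataFrame(
        dataset.genotypes, index=dataset.sample_ids, columns=dataset.marker_ids
    )
    frame.index.name = "sample"
    frame.to_csv(path)


def write_phenotype_csv(dataset: GenoPhenoDataset, path, trait: str = "trait") -> None:
    """Write the phenotype vector as CSV (sample id + one trait column)."""
    frame = pd.DataFrame({trait: dataset.phenotypes}, index=dataset.sample_ids)
    frame.index.name = "sample"
    frame.to_csv(path)


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[GenoPhenoDataset, np.ndarray, np.ndarray]:
    """Simulate an additive genotype-phenotype dataset.

    Per marker j an allele frequency ``p_j ~ U(maf_range)`` is drawn and
    dosages sampled as ``Binomial(ploidy_code_max, p_j)``.  ``n_causal``
    markers receive effects ``beta ~ N(0, 1)``; the phenotype is
    ``y = G[:, causal] @ beta + eps`` with the noise variance chosen so
    that var(genetic) / var(y) matches the requested heritability for the
    realized genetic values.  Returns the dataset together with the causal
    marker indices and their true effects.
    """
    rng = np.random.default_rng(spec.seed)
    p = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_markers)
    genotypes = rng.binomial(
        spec.ploidy_code_max, p, size=(spec.n_samples, spec.n_markers)
    ).astype(float)
    causal = np.sort(rng.choice(spec.n_markers, size=spec.n_causal, replace=False))
    for _ in range(100):
        effects = rng.normal(0.0, 1.0, size=spec.n_causal)
        genetic = genotypes[:, causal] @ effects
        var_g = float(np.var(genetic))
        if var_g > 0:
            break
    else:  # pragma: no cover - requires pathologically monomorphic markers
        raise RuntimeError("could not realize non-zero genetic variance")
    var_e = var_g * (1.0 - spec.heritability) / spec.heritability
    phenotypes = genetic + rng.normal(0.0, np.sqrt(var_e), size=spec.n_samples)
    width = max(4, len(str(spec.n_samples)))
    dataset = GenoPhenoDataset(
        sample_ids=[f"S{i + 1:0{width}d}" for i in range(spec.n_samples)],
        marker_ids=[f"M{j + 1:0{max(4, len(str(spec.n_markers)))}d}" for j in range(spec.n_markers)],
        genotypes=genotypes,
        phenotypes=phenotypes,
    )
    return dataset, causal, effects
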