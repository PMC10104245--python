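"""Synthetic genotype/phenotype data with the additive structure LMFI assumes.

Genotypes are additive-coded counts in {0, 1, 2}: each variant j draws an
allele frequency p_j uniformly from a configurable range and each sample
draws Binomial(2, p_j) — Hardy–Weinberg sampling without linkage, which is
sufficient for an additive model. Continuous phenotypes are sparse linear
signals X·β + w0 + ε; binary phenotypes are Bernoulli draws through the
sigmoid of the same kind of linear signal. Ground-truth effects are retained
so oracle accuracies can be computed.

The default demo scale (m=300 samples, n=2048 variants, K=5 phenotypes,
3 continuous + 2 binary) mirrors the shape of the genotype study the
pipeline targets while keeping a full secure session tractable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

DEFAULT_M = 300
DEFAULT_N = 2048
DEFAULT_KINDS = ("continuous", "continuous", "continuous", "binary", "binary")


@dataclass
class PhenotypeTruth:
    kind: str
    causal_idx: np.ndarray
    beta: np.ndarray          # dense effect vector, length n
    intercept: float
    noise_std: float


@dataclass
class GenoDataset:
    X: np.ndarray                       # m × n additive genotype codes {0,1,2}
    phenotypes: pd.DataFrame            # m × K, binary columns in {0,1}
    kinds: list[str]
    truth: list[PhenotypeTruth] = field(default_factory=list)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variants(self) -> int:
        return self.X.shape[1]


def gen_genotypes(m: int, n: int, maf_range: tuple[float, float] = (0.05, 0.5),
                  seed: int = 0) -> np.ndarray:
    """Binomial(2, p_j) genotype matrix with per-variant allele frequencies."""
    if m < 1 or n < 1:
        raise ParameterError("need at least one sample and one variant")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, n)
    return rng.binomial(2, p, size=(m, n)).astype(np.int64)


def _sparse_effects(n: int, n_causal: int, effect_std: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if n_causal > n:
        raise ParameterError("n_causal cannot exceed the variant count")
    idx = rng.choice(n, size=n_causal, replace=False)
    beta = np.zeros(n)
    beta[idx] = rng.normal(0.0, effect_std, n_causal)
    return np.sort(idx), beta


def gen_continuous_phenotype(X: np.ndarray, n_causal: int = 20,
                             effect_std: float = 0.5, noise_std: float = 0.05,
                             seed: int = 0) -> tuple[np.ndarray, PhenotypeTruth]:
    """y = X·β + w0 + ε with a sparse Gaussian β and Gaussian noise."""
    rng = np.random.default_rng(seed)
    idx, beta = _sparse_effects(X.shape[1], n_causal, effect_std, rng)
    w0 = rng.normal(0.0, 1.0)
    y = X @ beta + w0 + rng.normal(0.0, noise_std, X.shape[0])
    return y, PhenotypeTruth("continuous", idx, beta, w0, noise_std)


def gen_binary_phenotype(X: np.ndarray, n_causal: int = 20,
                         effect_std: float = 0.5,
                         seed: int = 0) -> tuple[np.ndarray, PhenotypeTruth]:
    """y ~ Bernoulli(sigmoid(X·β + w0)); the intercept is redrawn (and finally
    forced) until both classes are present."""
    rng = np.random.default_rng(seed)
    idx, beta = _sparse_effects(X.shape[1], n_causal, effect_std, rng)
    lin = X @ beta
    for _ in range(100):
        w0 = -np.median(lin) + rng.normal(0.0, 0.5)
        prob = 1.0 / (1.0 + np.exp(-(lin + w0)))
        y = rng.binomial(1, prob)
        if 0 < y.sum() < len(y):
            return y.astype(np.int64), PhenotypeTruth("binary", idx, beta, w0, 0.0)
    y[0], y[1] = 0, 1  # degenerate draw: force both classes
    return y.astype(np.int64), PhenotypeTruth("binary", idx, beta, w0, 0.0)


def gen_dataset(m: int = DEFAULT_M, n: int = DEFAULT_N,
                kinds: tuple[str, ...] = DEFAULT_KINDS,
                maf_range: tuple[float, float] = (0.05, 0.5),
                n_causal: int = 20, effect_std: float = 0.5,
                noise_std: float = 0.05, seed: int = 0) -> GenoDataset:
    """A full dataset: genotypes plus one column per phenotype kind."""
    X = gen_genotypes(m, n, maf_range, seed)
    n_causal = min(n_causal, n)
    cols, truths = {}, []
    for k, kind in enumerate(kinds):
        sub = seed * 1009 + 7 * k + 1
        if kind == "continuous":
            y, t = gen_continuous_phenotype(X, n_causal, effect_std, noise_std, sub)
        elif kind == "binary":
            y, t = gen_binary_phenotype(X, n_causal, effect_std, sub)
        else:
            raise ParameterError(f"unknown phenotype kind {kind!r}")
        cols[f"phenotype_{k}"] = y
        truths.append(t)
    return GenoDataset(X, pd.DataFrame(cols), list(kinds), truths, seed)


def fixture_small() -> dict:
    """Fixed toy inputs for exact tests: the 2×4 matrix with product [10, 26]
    and a 4-sample binary toy whose pairwise-comparison AUC is 0.75."""
    return {
        "M": np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]]),
        "z": np.ones(4),
        "expected_product": np.array([10.0, 26.0]),
        "auc_y": np.array([1, 1, 0, 0]),
        "auc_scores": np.array([4.0, 2.0, 3.0, 1.0]),
        "expected_auc": 0.75,
    }


def write_dataset(ds: GenoDataset, geno_path, pheno_path) -> None:
    """Delimited-text output: samples × variants with a variant-ID header."""
    gdf = pd.DataFrame(ds.X, columns=[f"v{j}" for j in range(ds.n_variants)])
    gdf.insert(0, "sample", [f"s{i}" for i in range(ds.n_samples)])
    gdf.to_csv(geno_path, sep="\t", index=False)
    pdf = ds.phenotypes.copy()
    pdf.insert(0, "sample", [f"s{i}" for i in range(ds.n_samples)])
    pdf.to_csv(pheno_path, sep="\t", index=False)


def read_genotypes(path) -> np.ndarray:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns[0].lower() in ("sample", "id", "sample_id"):
        df = df.drop(columns=df.columns[0])
    return df.to_numpy(dtype=np.float64)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns[0].lower() in ("sample", "id", "sample_id"):
        df = df.drop(columns=df.columns[0])
    return df
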