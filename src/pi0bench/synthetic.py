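"""Correlated two-condition gene-expression simulator with known truth.

The generative model is a two-group microarray study: M genes measured on
n1 control and n2 treatment arrays.  Expression of every gene is normal with
common within-condition standard deviation sigma.  A fraction pi0 of genes
are null (equal means in both conditions); each remaining gene receives a
mean shift in the treatment condition drawn once from
Normal(effect_mean, effect_sd^2).  Genes are partitioned into blocks of k
with a common pairwise correlation rho (an equicorrelated covariance);
blocks are mutually independent, arrays are mutually independent, and null
and differentially expressed genes never share a block.  Per-gene two-sided
pooled-variance t-tests turn a study into a vector of p-values.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SimulationConfig",
    "ExpressionStudy",
    "PValueSet",
    "build_group_covariance",
    "simulate_study",
    "compute_pvalues",
    "uniform_grid_pvalues",
    "bum_mixture_pvalues",
]


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one in-silico comparative expression experiment.

    Parameters
    ----------
    M : total number of genes (simultaneous tests).
    pi0 : proportion of true null (non-differentially expressed) genes,
        in [0, 1].  The number of null genes is ``round(pi0 * M)``.
    rho : common pairwise correlation of expression noise between genes of
        the same block, in [0, 1).
    k : block size — number of genes per correlated group (>= 1); a
        remainder group smaller than k is allowed.
    n1, n2 : number of arrays in the control and treatment condition (>= 2).
    sigma : within-condition standard deviation of expression (> 0).
    effect_mean : mean of the effect-size distribution for differentially
        expressed genes (the typical mean shift, in units of sigma).
    effect_sd : standard deviation of the effect-size distribution.
    seed : RNG seed; identical configs produce bit-identical studies.
    """

    M: int = 10_000
    pi0: float = 0.8
    rho: float = 0.0
    k: int = 5
    n1: int = 8
    n2: int = 8
    sigma: float = 1.0
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.M >= 1):
            raise ValueError("M must be >= 1")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must be in [0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (self.k >= 1):
            raise ValueError("k must be >= 1")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("n1 and n2 must be >= 2")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")
        if not (self.effect_sd >= 0):
            raise ValueError("effect_sd must be >= 0")

    @property
    def m0(self) -> int:
        """Number of true null genes, round(pi0 * M)."""
        return int(round(self.pi0 * self.M))

    def digest(self) -> str:
        """Short hex digest identifying this configuration."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ExpressionStudy:
    """Simulated expression matrix together with per-gene ground truth."""

    values: np.ndarray          # M x (n1 + n2)
    condition: np.ndarray       # length n1+n2, "control"/"treatment"
    is_null: np.ndarray         # length M, bool
    true_effect: np.ndarray     # length M, 0 exactly where is_null
    config: SimulationConfig

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class PValueSet:
    """A vector of p-values with test provenance.

    The values are kept in gene order; estimators sort internally.
    """

    p: np.ndarray
    df: int
    config_digest: str = ""
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("p must be one-dimensional")
        if np.any(self.p < 0) or np.any(self.p > 1) or np.any(np.isnan(self.p)):
            raise ValueError("p-values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.p.size


# ---------------------------------------------------------------------------
# block covariance
# ---------------------------------------------------------------------------

def build_group_covariance(k: int, rho: float, sigma: float = 1.0) -> np.ndarray:
    """Equicorrelated k x k covariance: sigma^2 on the diagonal, rho*sigma^2 off it.

    Only rho in [0, 1) is accepted — the benchmark tunes the correlation
    strength from 0 upward, so negative rho is rejected even where the
    matrix would remain positive definite.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    if not (sigma > 0):
        raise ValueError("sigma must be > 0")
    cov = np.full((k, k), rho * sigma**2)
    np.fill_diagonal(cov, sigma**2)
    return cov


def _block_sizes(M: int, m0: int, k: int) -> tuple[list[int], list[int]]:
    """Partition null and alternative genes into blocks of at most k.

    Null genes come first.  Within each truth class, full blocks of k are
    formed and any remainder becomes one smaller block, so a block never
    mixes null and differentially expressed genes.
    """
    def split(count: int) -> list[int]:
        sizes = [k] * (count // k)
        if count % k:
            sizes.append(count % k)
        return sizes

    return split(m0), split(M - m0)


def _sample_block_noise(rng: np.random.Generator, sizes: Sequence[int],
                        rho: float, sigma: float, n_arrays: int) -> np.ndarray:
    """Noise matrix (sum(sizes) x n_arrays) with equicorrelated blocks.

    Correlation acts across genes within a block; arrays are independent.
    Sampling goes through the lower Cholesky factor of the block covariance;
    blocks of equal size share one factor, so they are drawn in a single
    batched multiply.
    """
    total = int(np.sum(sizes))
    out = np.empty((total, n_arrays))
    sizes = np.asarray(sizes, dtype=int)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for s in np.unique(sizes):
        idx = np.flatnonzero(sizes == s)
        z = rng.standard_normal((idx.size, s, n_arrays))
        if s == 1 or rho == 0.0:
            noise = sigma * z
        else:
            L = np.linalg.cholesky(build_group_covariance(int(s), rho, sigma))
            noise = np.einsum("ij,bjn->bin", L, z)
        for b, block in zip(idx, noise):
            out[offsets[b]:offsets[b] + s] = block
    return out


def simulate_study(config: SimulationConfig) -> ExpressionStudy:
    """Simulate one two-condition expression study under *config*.

    round(pi0*M) genes are null (identical means in both conditions);
    every other gene has control mean 0 and a treatment mean drawn once from
    Normal(effect_mean, effect_sd^2).  Noise within each block of k genes is
    multivariate normal with the equicorrelated covariance, independently
    per array; blocks are independent.  Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    M, m0 = config.M, config.m0
    n_arrays = config.n1 + config.n2

    is_null = np.zeros(M, dtype=bool)
    is_null[:m0] = True
    true_effect = np.zeros(M)
    true_effect[m0:] = rng.normal(config.effect_mean, config.effect_sd,
                                  size=M - m0)

    null_sizes, alt_sizes = _block_sizes(M, m0, config.k)
    noise = _sample_block_noise(rng, null_sizes + alt_sizes, config.rho,
                                config.sigma, n_arrays)

    means = np.zeros((M, n_arrays))
    means[:, config.n1:] = true_effect[:, None]

    condition = np.array(["control"] * config.n1 + ["treatment"] * config.n2)
    return ExpressionStudy(values=means + noise, condition=condition,
                           is_null=is_null, true_effect=true_effect,
                           config=config)


def compute_pvalues(study: ExpressionStudy) -> PValueSet:
    """Per-gene two-sided pooled-variance (equal-variance) two-sample t-test.

    Degrees of freedom are n1 + n2 - 2.  A gene with zero pooled variance is
    a probability-zero degeneracy under the model: it yields p = 1 when the
    group means are also equal (flagged in ``degenerate``) and raises
    otherwise.
    """
    cfg = study.config
    ctrl = study.values[:, study.condition == "control"]
    trt = study.values[:, study.condition == "treatment"]
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise ValueError("each condition needs at least 2 arrays")

    v1 = ctrl.var(axis=1, ddof=1)
    v2 = trt.var(axis=1, ddof=1)
    pooled = ((ctrl.shape[1] - 1) * v1 + (trt.shape[1] - 1) * v2)
    zero_var = pooled == 0.0
    if np.any(zero_var):
        diff = ctrl.mean(axis=1) - trt.mean(axis=1)
        if np.any(zero_var & (diff != 0)):
            bad = np.flatnonzero(zero_var & (diff != 0))
            raise FloatingPointError(
                f"zero pooled variance with unequal means for genes {bad[:5]}"
            )
    with warnings.catch_warnings():
        if np.any(zero_var):  # constant genes trip scipy's precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(trt, ctrl, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    p[zero_var] = 1.0  # equal constant samples: no evidence against the null

    return PValueSet(p=p, df=ctrl.shape[1] + trt.shape[1] - 2,
                     config_digest=cfg.digest(),
                     degenerate=zero_var if np.any(zero_var) else None)


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def uniform_grid_pvalues(M: int) -> PValueSet:
    """The exact uniform grid p_(i) = (i - 0.5)/M — the ideal complete null."""
    return PValueSet(p=(np.arange(1, M + 1) - 0.5) / M, df=0,
                     config_digest=f"uniform_grid_{M}")


def bum_mixture_pvalues(M: int, w: float = 0.7, a: float = 0.2,
                        seed: int = 0) -> PValueSet:
    """Draw M p-values from the beta-uniform mixture w*U(0,1) + (1-w)*Beta(a, 1)."""
    if not (0.0 <= w <= 1.0 and 0.0 < a <= 1.0):
        raise ValueError("need 0 <= w <= 1 and 0 < a <= 1")
    rng = np.random.default_rng(seed)
    from_uniform = rng.random(M) < w
    p = np.where(from_uniform, rng.random(M), rng.beta(a, 1.0, size=M))
    return PValueSet(p=p, df=0, config_digest=f"bum_{w}_{a}_{seed}")
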