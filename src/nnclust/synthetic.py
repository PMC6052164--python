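"""Seeded synthetic data generators.

Gaussian blob panels (with optional equicorrelated features and injected
outliers) exercise the clustering path; a toy case/control biallelic
genotype panel with allelic chi-square ranking exercises the SNP-selection
workflow at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.stats import chi2

from nnclust.core import DataMatrix

__all__ = [
    "BlobSpec",
    "GenotypeSpec",
    "GenotypePanel",
    "gaussian_blobs",
    "inject_outliers",
    "genotype_panel",
    "allelic_chi_square",
    "rank_snps_allelic",
]


@dataclass(frozen=True)
class BlobSpec:
    """Gaussian mixture specification.

    ``centers`` may be given explicitly (K x p); otherwise K centers are
    auto-spaced on distinct coordinate axes, pairwise at least
    ``separation * noise_sd`` apart.
    ``correlation`` is a common pairwise correlation rho in [0, 1) giving
    every cluster the equicorrelation covariance
    ``noise_sd**2 * ((1 - rho) I + rho J)``.
    """

    n_per_cluster: tuple[int, ...]
    p: int
    separation: float = 6.0
    noise_sd: float = 1.0
    correlation: float = 0.0
    centers: npt.NDArray[np.float64] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cluster) < 1 or any(n < 1 for n in self.n_per_cluster):
            raise ValueError("n_per_cluster must be positive integers")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError(f"correlation must be in [0, 1), got {self.correlation}")
        object.__setattr__(self, "n_per_cluster", tuple(int(n) for n in self.n_per_cluster))
        if self.centers is not None:
            centers = np.asarray(self.centers, dtype=np.float64)
            if centers.shape != (len(self.n_per_cluster), self.p):
                raise ValueError(
                    f"centers must be {len(self.n_per_cluster)} x {self.p}, got {centers.shape}"
                )
            object.__setattr__(self, "centers", centers)

    @property
    def K(self) -> int:
        return len(self.n_per_cluster)

    @property
    def n(self) -> int:
        return sum(self.n_per_cluster)

    def resolved_centers(self) -> npt.NDArray[np.float64]:
        # Auto-spaced centers sit on distinct coordinate axes (wrapping with a
        # growing radius once K > p) so no single feature carries all of the
        # between-cluster signal; pairwise distances are >= separation*noise_sd.
        if self.centers is not None:
            return self.centers
        centers = np.zeros((self.K, self.p))
        for k in range(self.K):
            centers[k, k % self.p] = self.separation * self.noise_sd * (1 + k // self.p)
        return centers


def gaussian_blobs(spec: BlobSpec) -> tuple[DataMatrix, npt.NDArray[np.int64]]:
    """Sample labeled points from per-cluster multivariate normals."""
    rng = np.random.default_rng(spec.seed)
    centers = spec.resolved_centers()
    rho, sd, p = spec.correlation, spec.noise_sd, spec.p
    cov = sd**2 * ((1 - rho) * np.eye(p) + rho * np.ones((p, p)))
    chol = np.linalg.cholesky(cov)

    rows, labels = [], []
    for k, n_k in enumerate(spec.n_per_cluster):
        z = rng.standard_normal((n_k, p))
        rows.append(centers[k] + z @ chol.T)
        labels.append(np.full(n_k, k, dtype=np.int64))
    return DataMatrix(np.vstack(rows)), np.concatenate(labels)


def inject_outliers(
    M: DataMatrix,
    fraction: float,
    magnitude: float,
    rng: np.random.Generator,
) -> tuple[DataMatrix, npt.NDArray[np.int64]]:
    """Displace ``floor(fraction * n)`` randomly chosen rows.

    Each chosen row moves along an independent random direction by
    ``magnitude * sd`` where sd is the global standard deviation of the
    matrix entries. Rows are displaced in place (labels stay aligned);
    the displaced row indices are returned.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError(f"fraction must be in [0, 0.5], got {fraction}")
    n_out = int(np.floor(fraction * M.n))
    if n_out == 0:
        return M, np.empty(0, dtype=np.int64)
    idx = rng.choice(M.n, size=n_out, replace=False)
    idx = np.sort(idx).astype(np.int64)
    direction = rng.standard_normal((n_out, M.p))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    values = M.values.copy()
    values[idx] += direction * magnitude * M.values.std()
    return DataMatrix(values, feature_names=M.feature_names), idx


@dataclass(frozen=True)
class GenotypeSpec:
    """Case/control biallelic panel: n_cases + n_controls samples, m SNPs.

    Genotypes are minor-allele counts Binomial(2, f). Each SNP draws a base
    minor-allele frequency uniformly from ``freq_range``; the ``n_causal``
    SNPs with smallest index shift the case frequency by ``delta``.
    """

    n_cases: int
    n_controls: int
    m: int
    n_causal: int = 0
    delta: float = 0.0
    freq_range: tuple[float, float] = (0.1, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both phenotype groups must be non-empty")
        if not 0 <= self.n_causal <= self.m:
            raise ValueError("n_causal must be in [0, m]")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"freq_range must lie inside (0, 1), got {self.freq_range}")
        if not (0.0 < lo + self.delta and hi + self.delta < 1.0):
            raise ValueError("delta pushes case frequencies outside (0, 1)")


@dataclass(frozen=True)
class GenotypePanel:
    genotypes: npt.NDArray[np.int8]  # n x m, entries in {0,1,2}
    phenotype: npt.NDArray[np.int8]  # length n, 1 = case, 0 = control
    causal_snps: npt.NDArray[np.int64]
    frequencies: npt.NDArray[np.float64]  # per-SNP control minor-allele frequency
    seed: int

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]


def genotype_panel(spec: GenotypeSpec) -> GenotypePanel:
    """Generate a labeled case/control genotype matrix per the spec."""
    rng = np.random.default_rng(spec.seed)
    freqs = rng.uniform(*spec.freq_range, size=spec.m)
    case_freqs = freqs.copy()
    causal = np.arange(spec.n_causal, dtype=np.int64)
    case_freqs[causal] += spec.delta

    g_cases = rng.binomial(2, case_freqs, size=(spec.n_cases, spec.m))
    g_controls = rng.binomial(2, freqs, size=(spec.n_controls, spec.m))
    genotypes = np.vstack([g_cases, g_controls]).astype(np.int8)
    phenotype = np.concatenate(
        [np.ones(spec.n_cases, dtype=np.int8), np.zeros(spec.n_controls, dtype=np.int8)]
    )
    return GenotypePanel(
        genotypes=genotypes,
        phenotype=phenotype,
        causal_snps=causal,
        frequencies=freqs,
        seed=spec.seed,
    )


def allelic_chi_square(panel: GenotypePanel) -> tuple[npt.NDArray[np.float64], npt.NDArray[np.float64]]:
    """Per-SNP 1-df chi-square on the 2x2 allele-count table, no continuity correction.

    Allele counts per group: minor = sum of genotypes, major = 2 * group size
    minus minor. Monomorphic SNPs (an allele absent overall) get chi2 = 0,
    p = 1 by convention.
    """
    case = panel.phenotype == 1
    g = panel.genotypes.astype(np.float64)
    minor_case = g[case].sum(axis=0)
    minor_ctrl = g[~case].sum(axis=0)
    n_case_alleles = 2.0 * case.sum()
    n_ctrl_alleles = 2.0 * (~case).sum()
    major_case = n_case_alleles - minor_case
    major_ctrl = n_ctrl_alleles - minor_ctrl

    # chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on [[a, b], [c, d]]
    a, b, c, d = minor_case, major_case, minor_ctrl, major_ctrl
    total = n_case_alleles + n_ctrl_alleles
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, total * (a * d - b * c) ** 2 / denom, 0.0)
    pvalues = np.where(denom > 0, chi2.sf(stat, df=1), 1.0)
    return stat, pvalues


def rank_snps_allelic(
    panel: GenotypePanel, top_m: int | None = None
) -> tuple[npt.NDArray[np.int64], npt.NDArray[np.float64]]:
    """Rank SNPs by ascending allelic-association p-value.

    Ties (including all monomorphic SNPs at p = 1) break by SNP index.
    Returns the top ``top_m`` SNP indices (all if None) and their p-values.
    """
    if top_m is not None and top_m < 1:
        raise ValueError("top_m must be >= 1")
    _, pvalues = allelic_chi_square(panel)
    order = np.argsort(pvalues, kind="stable")  # stable sort -> index tiebreak
    if top_m is not None:
        order = order[:top_m]
    return order.astype(np.int64), pvalues[order]
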