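"""Population-genetic summaries: pairwise Weir-Cockerham F_ST and genotype PCA.

F_ST uses the Weir & Cockerham (1984) theta estimator for two populations
and two alleles, with the multi-locus mean taken as the ratio of summed
variance components sum(a) / sum(a + b + c) rather than a mean of per-locus
ratios.  Small negative per-locus or mean values are possible and reported
unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridzone.datamodel import MISSING, GenotypeMatrix, Group


@dataclass
class FstResult:
    group_pair: tuple[str, str]
    per_locus_theta: pd.Series  # indexed by locus_id, NaN where undefined
    mean_fst: float
    n_loci: int  # loci contributing to the mean


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_fraction: np.ndarray
    loadings: pd.DataFrame  # loci/traits x components


def weir_cockerham_fst(
    matrix: GenotypeMatrix, group1: Group, group2: Group
) -> FstResult:
    """Per-locus and mean pairwise theta between two groups.

    A locus contributes only when both groups have >= 2 samples with
    non-missing calls there.  Polarization does not change theta.
    """
    mask1 = matrix.group_mask(group1)
    mask2 = matrix.group_mask(group2)
    if not mask1.any() or not mask2.any():
        raise ValueError("both groups need at least one sample")

    calls1 = matrix.calls[mask1].astype(float)
    calls2 = matrix.calls[mask2].astype(float)
    a_sum = np.zeros(matrix.n_loci)
    abc_sum = np.zeros(matrix.n_loci)
    theta = np.full(matrix.n_loci, np.nan)
    contributing = np.zeros(matrix.n_loci, dtype=bool)

    for j in range(matrix.n_loci):
        c1 = calls1[:, j]
        c2 = calls2[:, j]
        c1 = c1[c1 != MISSING]
        c2 = c2[c2 != MISSING]
        n1, n2 = c1.size, c2.size
        if n1 < 2 or n2 < 2:
            continue
        a, b, c = _wc_components(c1, c2)
        a_sum[j] = a
        abc_sum[j] = a + b + c
        contributing[j] = True
        if abc_sum[j] != 0:
            theta[j] = a / abc_sum[j]

    if not contributing.any():
        raise ValueError("no loci with enough called samples in both groups")
    mean_fst = float(a_sum[contributing].sum() / abc_sum[contributing].sum())
    return FstResult(
        group_pair=(group1.value, group2.value),
        per_locus_theta=pd.Series(theta, index=matrix.locus_ids),
        mean_fst=mean_fst,
        n_loci=int(contributing.sum()),
    )


def _wc_components(c1: np.ndarray, c2: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) a, b, c variance components, r = 2 populations.

    c1, c2 are vectors of diploid allele-dose calls (0/1/2) for the two
    samples at one biallelic locus.
    """
    r = 2
    n_i = np.array([c1.size, c2.size], dtype=float)
    p_i = np.array([c1.sum() / (2 * c1.size), c2.sum() / (2 * c2.size)])
    h_i = np.array([(c1 == 1).mean(), (c2 == 1).mean()])

    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return float(a), float(b), float(c)


def genotype_pca(matrix: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of the genotype matrix (mean-centred; missing imputed to locus mean).

    Explained fractions are eigenvalue shares of the total variance; scores
    are returned for all retained components.
    """
    if matrix.n_samples < 2 or matrix.n_loci < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 loci")
    X = matrix.calls.astype(float)
    miss = matrix.missing_mask()
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    X -= X.mean(axis=0)
    if np.allclose(X, 0):
        raise ValueError("constant genotype matrix: no variance for PCA")

    u, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    k = n_components or min(matrix.n_samples, matrix.n_loci, 10)
    k = min(k, s.size)
    # deterministic sign: largest-magnitude loading of each component positive
    for i in range(k):
        jmax = np.argmax(np.abs(vt[i]))
        if vt[i, jmax] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :k] * s[:k]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        explained_fraction=explained[:k],
        loadings=pd.DataFrame(vt[:k].T, index=matrix.locus_ids, columns=comp_names),
    )
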