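"""Per-individual ancestry: ML hybrid index, interspecific heterozygosity
and hybrid-class assignment on a diagnostic-locus set.

The hybrid index h is the proportion of an individual's alleles derived from
the B-type parental taxon.  Its likelihood treats loci as independent: with
B-polarized parental allele frequencies (p_A, p_B) at locus l and
q_l(h) = h * p_B,l + (1 - h) * p_A,l, the genotype (count g of B-associated
alleles) is Binomial(2, q_l).  The log-likelihood is concave in h (each term
is the log of an affine function of h), so the maximizer is found by root
finding on the score function, which also yields machine-precision agreement
with the closed-form allele-counting estimator when every locus is fixed.

Interspecific heterozygosity H is the proportion of scored diagnostic loci
at which the individual carries one allele of each parental origin
(polarized call = 1).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from hybridzone.datamodel import MISSING, GenotypeMatrix, Group

_EPS = 1e-12


class HybridClass(enum.Enum):
    PURE_A = "PURE_A"
    BACKCROSS_A = "BACKCROSS_A"
    MULTIGEN = "MULTIGEN"
    F1 = "F1"
    BACKCROSS_B = "BACKCROSS_B"
    PURE_B = "PURE_B"


@dataclass
class ClassThresholds:
    """Hybrid-class decision thresholds on the (h, H) unit square.

    Defaults follow the standard scheme: F1 when h is mid-range
    (0.25 <= h <= 0.75) with H >= 0.85; multigeneration hybrids occupy the
    same h window at lower H; backcrosses sit at h <= 0.25 / h >= 0.75 with
    H < 0.85; h exactly 0 or 1 is pure.  Boundary h = 0.25 / 0.75 with low
    H resolves to the backcross class.
    """

    f1_h_lo: float = 0.25
    f1_h_hi: float = 0.75
    f1_het_min: float = 0.85
    multigen_h_lo: float = 0.25
    multigen_h_hi: float = 0.75
    backcross_a_h_max: float = 0.25
    backcross_b_h_min: float = 0.75
    het_max: float = 0.85


@dataclass
class AncestryEstimate:
    sample_id: str
    h: float
    h_support_lo: float
    h_support_hi: float
    het: float
    n_loci_used: int
    hybrid_class: Optional[HybridClass]
    boundary_f1: bool = False


def polarize(
    matrix: GenotypeMatrix,
    freqs: pd.DataFrame,
    locus_set: Sequence[str],
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Recode calls as the count of the B-associated allele.

    The B-associated allele at a locus is whichever allele is more frequent
    in the PARENTAL_B group, so after polarization code 2 means homozygous
    for B ancestry (genotype aa), 0 homozygous A (AA), 1 heterozygous (Aa).

    Returns the polarized matrix (restricted to ``locus_set``) and the
    matching B-polarized frequency table (columns p_a, p_b are frequencies
    of the B-associated allele in each parental group).
    """
    sub = matrix.subset_loci_by_id(locus_set)
    f = freqs.loc[list(locus_set)].copy()
    p_a = f["p_a"].to_numpy(float)
    p_b = f["p_b"].to_numpy(float)
    if np.isnan(p_a).any() or np.isnan(p_b).any():
        bad = f.index[np.isnan(p_a) | np.isnan(p_b)].tolist()
        raise ValueError(f"cannot polarize loci with undefined frequencies: {bad}")
    tied = p_a == p_b
    if tied.any():
        raise ValueError(
            f"cannot polarize loci with p_A == p_B: {f.index[tied].tolist()}"
        )

    flip = p_b < p_a  # alt allele is A-associated; flip 0 <-> 2
    calls = sub.calls.copy()
    flip_cols = np.flatnonzero(flip)
    for j in flip_cols:
        col = calls[:, j]
        nm = col != MISSING
        col[nm] = 2 - col[nm]
    f["flipped"] = flip
    f.loc[flip, ["p_a", "p_b"]] = 1.0 - f.loc[flip, ["p_a", "p_b"]]
    out = GenotypeMatrix(
        samples=sub.samples, loci=sub.loci, calls=calls, depth=sub.depth
    )
    return out, f


def _loglik_terms(h, g, p_a, p_b):
    """Log-likelihood of genotypes g (0/1/2) at mixing proportion h."""
    q = np.clip(p_a + h * (p_b - p_a), _EPS, 1 - _EPS)
    return (
        g * np.log(q)
        + (2 - g) * np.log1p(-q)
        + np.log(np.where(g == 1, 2.0, 1.0))
    )


def _score(h, g, p_a, p_b):
    """Derivative of the log-likelihood in h (monotone decreasing)."""
    d = p_b - p_a
    q = np.clip(p_a + h * d, _EPS, 1 - _EPS)
    return float(np.sum(d * (g / q - (2 - g) / (1 - q))))


def ml_hybrid_index(
    calls: np.ndarray,
    freqs: pd.DataFrame,
    support_units: float = 2.0,
) -> tuple[float, float, float]:
    """Maximum-likelihood hybrid index for one individual.

    Parameters
    ----------
    calls : 1-D array of B-polarized genotype codes (MISSING allowed).
    freqs : B-polarized frequency table aligned with ``calls`` (columns
        p_a, p_b are frequencies of the B-associated allele).
    support_units : half-width, in log-likelihood units, of the reported
        support interval (default 2).

    Returns ``(h, lo, hi)`` where [lo, hi] is the support interval.  Raises
    if every call is missing.
    """
    calls = np.asarray(calls)
    keep = calls != MISSING
    if not keep.any():
        raise ValueError("all diagnostic calls missing; hybrid index undefined")
    g = calls[keep].astype(float)
    p_a = freqs["p_a"].to_numpy(float)[keep]
    p_b = freqs["p_b"].to_numpy(float)[keep]

    # Concave log-likelihood: locate the root of the score, else a boundary.
    lo, hi = 0.0, 1.0
    s_lo, s_hi = _score(lo, g, p_a, p_b), _score(hi, g, p_a, p_b)
    if s_lo <= 0:
        h_hat = 0.0
    elif s_hi >= 0:
        h_hat = 1.0
    else:
        h_hat = brentq(_score, lo, hi, args=(g, p_a, p_b), xtol=1e-12)

    ln_max = float(np.sum(_loglik_terms(h_hat, g, p_a, p_b)))

    def drop(h):
        return float(np.sum(_loglik_terms(h, g, p_a, p_b))) - (ln_max - support_units)

    lo_s = 0.0 if drop(0.0) >= 0 else brentq(drop, 0.0, h_hat, xtol=1e-9)
    hi_s = 1.0 if drop(1.0) >= 0 else brentq(drop, h_hat, 1.0, xtol=1e-9)
    return h_hat, lo_s, hi_s


def counting_hybrid_index(calls: np.ndarray) -> float:
    """Allele-counting hybrid index: B-allele count / (2 x scored loci)."""
    calls = np.asarray(calls)
    keep = calls != MISSING
    if not keep.any():
        raise ValueError("all diagnostic calls missing")
    g = calls[keep]
    return float(g.sum() / (2 * g.size))


def interspecific_heterozygosity(calls: np.ndarray) -> float:
    """Proportion of scored loci heterozygous for alleles of both origins."""
    calls = np.asarray(calls)
    keep = calls != MISSING
    if not keep.any():
        raise ValueError("all diagnostic calls missing; heterozygosity undefined")
    return float((calls[keep] == 1).sum() / keep.sum())


def classify_hybrid(
    h: float,
    het: float,
    thresholds: ClassThresholds | None = None,
) -> tuple[HybridClass, bool]:
    """Assign a hybrid class from (h, H).  Total on the unit square.

    Returns ``(hybrid_class, boundary_f1)``; the flag marks F1-like
    assignments made outside the central h window (high H at extreme h).
    """
    t = thresholds or ClassThresholds()
    if h == 0.0:
        return HybridClass.PURE_A, False
    if h == 1.0:
        return HybridClass.PURE_B, False
    if het >= t.f1_het_min:
        if t.f1_h_lo <= h <= t.f1_h_hi:
            return HybridClass.F1, False
        return HybridClass.F1, True
    if h <= t.backcross_a_h_max:
        return HybridClass.BACKCROSS_A, False
    if h >= t.backcross_b_h_min:
        return HybridClass.BACKCROSS_B, False
    return HybridClass.MULTIGEN, False


def estimate_ancestry(
    polarized: GenotypeMatrix,
    freqs: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
    groups: Sequence[Group] | None = None,
) -> pd.DataFrame:
    """Hybrid index, heterozygosity and class for each sample.

    ``groups`` restricts estimation to samples in those groups (default: all
    samples).  Samples with no scored diagnostic call get NaN estimates and
    no class.
    """
    rows = []
    for i, sample in enumerate(polarized.samples):
        if groups is not None and sample.group not in groups:
            continue
        calls = polarized.calls[i]
        n_used = int((calls != MISSING).sum())
        if n_used == 0:
            rows.append(
                (sample.sample_id, np.nan, np.nan, np.nan, np.nan, 0, None, False)
            )
            continue
        h, lo, hi = ml_hybrid_index(calls, freqs)
        het = interspecific_heterozygosity(calls)
        cls, boundary = classify_hybrid(h, het, thresholds)
        rows.append(
            (sample.sample_id, h, lo, hi, het, n_used, cls.value, boundary)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "h", "h_support_lo", "h_support_hi",
            "het", "n_loci_used", "hybrid_class", "boundary_f1",
        ],
    )
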