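"""Per-locus genomic clines versus neutral admixture.

A genomic cline describes how a locus's genotype frequencies change with
genome-wide admixture (the hybrid index h) rather than with geography.  Each
locus is fitted with a three-category multinomial logistic regression of the
polarized genotype (AA / Aa / aa) on h:

    log P(Aa)/P(AA) = b0 + b1 h        log P(aa)/P(AA) = c0 + c1 h

(optionally quadratic in h).  The fitted log-likelihood is compared with a
neutral-admixture model in which individual i's genotype is
Binomial(2, q_i) with q_i = h_i p_B + (1 - h_i) p_A, i.e. genotype
frequencies are determined by the individual's hybrid index and the parental
allele frequencies alone.  Significance of the likelihood-ratio statistic is
assessed by parametric bootstrap from the neutral model, and the same null
simulations yield a genotype excess/deficit summary (e.g. "AA Aa+ aa-":
heterozygote excess, aa deficit).  Family-wise significance is controlled
two ways: a Benjamini-Yekutieli-style adjusted alpha (nominal alpha divided
by the k-th harmonic number) and Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from hybridzone.datamodel import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12
_COEF_BOUND = 30.0
GENOTYPE_LABELS = ("AA", "Aa", "aa")


@dataclass
class ClineFit:
    locus_id: str
    coefficients: np.ndarray  # (b0, b1[, b2], c0, c1[, c2])
    lnl_fit: float
    lnl_neutral: float
    lr: float
    converged: bool = True
    clipped: bool = False
    n_used: int = 0


@dataclass
class ClineTestResult:
    locus_id: str
    delta: float
    lr: float
    p_raw: float
    alpha_by: float
    p_bh: float
    significant_by: bool
    significant_bh: bool
    deviation: str
    low_confidence: bool = False


def neutral_loglik(
    calls: np.ndarray,
    h: np.ndarray,
    p_a: float,
    p_b: float,
) -> float:
    """Log-likelihood of one locus's calls under neutral admixture.

    Each non-missing sample contributes log Binomial(2, q_i) at its genotype,
    with q_i = h_i * p_B + (1 - h_i) * p_A.  Genotypes that are impossible
    under q (probability 0) contribute a floored log(1e-12) and are counted
    in a warning.
    """
    calls = np.asarray(calls)
    keep = calls != MISSING
    g = calls[keep].astype(np.int64)
    q = h[keep] * p_b + (1.0 - h[keep]) * p_a
    probs = _genotype_probs(q)
    terms = probs[np.arange(g.size), g]
    n_floored = int((terms <= _PROB_FLOOR).sum())
    if n_floored:
        warnings.warn(
            f"{n_floored} genotype(s) impossible under the neutral model; "
            "floored probability used",
            stacklevel=2,
        )
    return float(np.log(np.maximum(terms, _PROB_FLOOR)).sum())


def _genotype_probs(q: np.ndarray) -> np.ndarray:
    """(n, 3) neutral genotype probabilities for B-allele dose 0/1/2."""
    q = np.asarray(q, dtype=float)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=1)


def _design(h: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(h), h]
    if degree == 2:
        cols.append(h**2)
    return np.stack(cols, axis=1)


def _nll_and_grad(theta: np.ndarray, X: np.ndarray, g: np.ndarray):
    k = X.shape[1]
    eta1 = X @ theta[:k]
    eta2 = X @ theta[k:]
    zeros = np.zeros_like(eta1)
    log_z = logsumexp(np.stack([zeros, eta1, eta2], axis=1), axis=1)
    nll = log_z.sum() - eta1[g == 1].sum() - eta2[g == 2].sum()
    p1 = np.exp(eta1 - log_z)
    p2 = np.exp(eta2 - log_z)
    grad = np.concatenate([X.T @ (p1 - (g == 1)), X.T @ (p2 - (g == 2))])
    return nll, grad


def _hessian(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    k = X.shape[1]
    eta1 = X @ theta[:k]
    eta2 = X @ theta[k:]
    log_z = logsumexp(
        np.stack([np.zeros_like(eta1), eta1, eta2], axis=1), axis=1
    )
    p1 = np.exp(eta1 - log_z)
    p2 = np.exp(eta2 - log_z)
    H = np.empty((2 * k, 2 * k))
    H[:k, :k] = X.T @ (X * (p1 * (1 - p1))[:, None])
    H[k:, k:] = X.T @ (X * (p2 * (1 - p2))[:, None])
    off = X.T @ (X * (-p1 * p2)[:, None])
    H[:k, k:] = off
    H[k:, :k] = off.T
    return H


def _fit_core(X: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Maximize the multinomial cline likelihood (convex NLL).

    Damped Newton with backtracking and coefficient clipping at +/-30;
    falls back to bounded L-BFGS-B if Newton stalls off the boundary.
    Returns (theta, nll, converged).
    """
    k2 = 2 * X.shape[1]
    theta = np.zeros(k2)
    nll, grad = _nll_and_grad(theta, X, g)
    ridge = 1e-9 * np.eye(k2)
    converged = False
    for _ in range(60):
        on_bound = (np.abs(theta) >= _COEF_BOUND - 1e-9) & (theta * grad < 0)
        if np.max(np.abs(grad[~on_bound]), initial=0.0) < 1e-7:
            converged = True
            break
        try:
            step = np.linalg.solve(_hessian(theta, X) + ridge, grad)
        except np.linalg.LinAlgError:
            break
        t, improved = 1.0, False
        for _ in range(40):
            cand = np.clip(theta - t * step, -_COEF_BOUND, _COEF_BOUND)
            nll_new, grad_new = _nll_and_grad(cand, X, g)
            if nll_new < nll:
                improved = True
                break
            t *= 0.5
        if not improved:
            # stationary up to clipping: accept if on the boundary
            converged = bool(np.any(np.abs(theta) >= _COEF_BOUND - 1e-9))
            break
        theta, nll, grad = cand, nll_new, grad_new
    if not converged:
        res = minimize(
            _nll_and_grad, theta, args=(X, g), jac=True,
            method="L-BFGS-B",
            bounds=[(-_COEF_BOUND, _COEF_BOUND)] * k2,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        if res.fun <= nll:
            theta, nll = res.x, float(res.fun)
        converged = bool(res.success) or bool(
            np.any(np.abs(theta) >= _COEF_BOUND - 1e-6)
        )
    return theta, float(nll), converged


def fit_multinomial_cline(
    calls: np.ndarray,
    h: np.ndarray,
    locus_id: str = "",
    degree: int = 1,
    lnl_neutral: float | None = None,
    p_a: float | None = None,
    p_b: float | None = None,
) -> ClineFit:
    """ML fit of the multinomial logistic cline for one locus.

    Complete separation is handled by bounding every coefficient at
    |coef| <= 30; a fit on the bound is flagged ``clipped``.  If neutral
    parameters (or a precomputed ``lnl_neutral``) are given, the
    likelihood-ratio statistic LR = 2 (lnL_fit - lnL_neutral) is filled in
    (tiny negatives from convergence tolerance are clamped to 0).
    """
    calls = np.asarray(calls)
    keep = calls != MISSING
    g = calls[keep].astype(np.int64)
    hv = np.asarray(h, dtype=float)[keep]
    if g.size < 3:
        raise ValueError(f"locus {locus_id}: need >=3 non-missing calls")
    if np.allclose(hv, hv[0]):
        raise ValueError(f"locus {locus_id}: hybrid index does not vary")

    X = _design(hv, degree)
    coef, nll, converged = _fit_core(X, g)
    clipped = bool(np.any(np.abs(coef) >= _COEF_BOUND - 1e-6))
    lnl_fit = -nll

    if lnl_neutral is None and p_a is not None and p_b is not None:
        lnl_neutral = neutral_loglik(calls, np.asarray(h, dtype=float), p_a, p_b)
    if lnl_neutral is not None:
        lr = 2.0 * (lnl_fit - lnl_neutral)
        if -1e-6 < lr < 0:
            lr = 0.0
    else:
        lnl_neutral = np.nan
        lr = np.nan
    return ClineFit(
        locus_id=locus_id,
        coefficients=coef,
        lnl_fit=lnl_fit,
        lnl_neutral=float(lnl_neutral),
        lr=lr,
        converged=converged,
        clipped=clipped,
        n_used=int(g.size),
    )


def _simulate_null(
    keep_h: np.ndarray,
    q: np.ndarray,
    n_sims: int,
    rng: np.random.Generator,
    degree: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Simulate genotypes under neutrality and refit the cline each time.

    Returns (LR statistics, genotype-class counts per sim (n_sims, 3),
    number of non-convergent refits).
    """
    n = keep_h.size
    probs = _genotype_probs(q)
    lrs = np.full(n_sims, np.nan)
    counts = np.zeros((n_sims, 3), dtype=np.int64)
    n_fail = 0
    # inverse-CDF draw so one uniform matrix drives all sims
    cum = probs.cumsum(axis=1)
    u = rng.random((n_sims, n))
    g_all = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    log_probs = np.log(np.maximum(probs, _PROB_FLOOR))
    X = _design(keep_h, degree)
    rows = np.arange(n)
    for s in range(n_sims):
        g = g_all[s]
        counts[s] = np.bincount(g, minlength=3)
        lnl_neutral = float(log_probs[rows, g].sum())
        _, nll, converged = _fit_core(X, g)
        if not converged:
            n_fail += 1
            continue
        lrs[s] = max(2.0 * (-nll - lnl_neutral), 0.0)
    return lrs, counts, n_fail


def cline_significance(
    fit: ClineFit,
    calls: np.ndarray,
    h: np.ndarray,
    p_a: float,
    p_b: float,
    n_sims: int = 1000,
    seed: int = 0,
    degree: int = 1,
) -> tuple[float, bool]:
    """Parametric-bootstrap p-value for departure from neutral introgression.

    Simulates ``n_sims`` datasets from the neutral model at each sample's h,
    refits the cline, and reports the add-one empirical p
    (1 + #{LR_s >= LR_obs}) / (n_sims + 1).  Returns (p_raw, low_confidence)
    where the flag marks >5% non-convergent refits.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    calls = np.asarray(calls)
    keep = calls != MISSING
    hv = np.asarray(h, dtype=float)[keep]
    q = hv * p_b + (1 - hv) * p_a
    rng = np.random.default_rng(seed)
    lrs, _, n_fail = _simulate_null(hv, q, n_sims, rng, degree)
    ok = ~np.isnan(lrs)
    p_raw = (1.0 + np.sum(lrs[ok] >= fit.lr)) / (n_sims + 1.0)
    low_confidence = n_fail > 0.05 * n_sims
    if low_confidence:
        warnings.warn(
            f"{fit.locus_id}: {n_fail}/{n_sims} null refits failed; "
            "p-value low confidence",
            stacklevel=2,
        )
    return float(p_raw), low_confidence


def deviation_summary(
    calls: np.ndarray,
    h: np.ndarray,
    p_a: float,
    p_b: float,
    n_sims: int = 1000,
    seed: int = 0,
    degree: int = 1,
) -> str:
    """Genotype excess/deficit string relative to the neutral simulations.

    Each genotype class's observed count is compared with the simulated null
    distribution of that count: "+" above the 97.5th percentile, "-" below
    the 2.5th, nothing otherwise; rendered e.g. "AA Aa+ aa-".
    """
    calls = np.asarray(calls)
    keep = calls != MISSING
    hv = np.asarray(h, dtype=float)[keep]
    q = hv * p_b + (1 - hv) * p_a
    rng = np.random.default_rng(seed)
    _, counts, _ = _simulate_null(hv, q, n_sims, rng, degree)
    obs = np.bincount(calls[keep].astype(np.int64), minlength=3)
    return _render_deviation(obs, counts)


def _render_deviation(obs_counts: np.ndarray, sim_counts: np.ndarray) -> str:
    lo = np.percentile(sim_counts, 2.5, axis=0)
    hi = np.percentile(sim_counts, 97.5, axis=0)
    parts = []
    for label, o, l, u in zip(GENOTYPE_LABELS, obs_counts, lo, hi):
        mark = "+" if o > u else ("-" if o < l else "")
        parts.append(label + mark)
    return " ".join(parts)


def by_alpha(k: int, alpha: float = 0.05) -> float:
    """Adjusted alpha for k tests: alpha divided by the k-th harmonic number.

    This is the Benjamini-Yekutieli-style divided nominal level used when a
    single significance threshold is applied to a family of correlated
    tests.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    harmonic = np.sum(1.0 / np.arange(1, k + 1))
    return float(alpha / harmonic)


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries are excluded from the ranking and propagate as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(p[ok], method="fdr_bh")
        out[ok] = adj
    return out


def cline_analysis(
    polarized: GenotypeMatrix,
    freqs: pd.DataFrame,
    h: np.ndarray | pd.Series,
    diff: pd.DataFrame | None = None,
    n_sims: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    degree: int = 1,
    sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the full cline test over every locus of a polarized matrix.

    Parameters
    ----------
    polarized : B-polarized diagnostic-locus matrix.
    freqs : B-polarized frequency table aligned with the matrix loci.
    h : per-sample hybrid index, aligned with matrix rows (after masking).
    diff : optional differential table supplying the delta column.
    sample_mask : optional boolean row mask (e.g. the admixed group only).
    seed : base seed; locus s gets child seed spawned deterministically.

    Returns a Table-4-like DataFrame with one row per testable locus.
    Non-convergent observed fits are excluded from the significance ranking
    (p and adjusted columns NaN).
    """
    calls = polarized.calls
    hv = np.asarray(h, dtype=float)
    if sample_mask is not None:
        calls = calls[sample_mask]
        if hv.shape[0] == polarized.n_samples:
            hv = hv[sample_mask]
    ss = np.random.SeedSequence(seed)
    locus_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(polarized.n_loci)]

    rows = []
    sims_cache = {}
    for j, locus in enumerate(polarized.loci):
        col = calls[:, j]
        p_a = float(freqs["p_a"].iloc[j])
        p_b = float(freqs["p_b"].iloc[j])
        delta = float(diff["delta"].loc[locus.locus_id]) if diff is not None else np.nan
        keep = col != MISSING
        if keep.sum() < 3 or np.allclose(hv[keep], hv[keep][0]):
            logger.warning("locus %s untestable; skipped", locus.locus_id)
            continue
        fit = fit_multinomial_cline(
            col, hv, locus_id=locus.locus_id, degree=degree, p_a=p_a, p_b=p_b
        )
        # one null-simulation pass serves both the p-value and the summary
        hk = hv[keep]
        q = hk * p_b + (1 - hk) * p_a
        rng = np.random.default_rng(locus_seeds[j])
        lrs, counts, n_fail = _simulate_null(hk, q, n_sims, rng, degree)
        ok = ~np.isnan(lrs)
        if fit.converged:
            p_raw = (1.0 + np.sum(lrs[ok] >= fit.lr)) / (n_sims + 1.0)
        else:
            p_raw = np.nan
        obs = np.bincount(col[keep].astype(np.int64), minlength=3)
        deviation = _render_deviation(obs, counts)
        rows.append(
            {
                "locus_id": locus.locus_id,
                "delta": delta,
                "lr": fit.lr,
                "p_raw": p_raw,
                "deviation": deviation,
                "low_confidence": n_fail > 0.05 * n_sims,
                "converged": fit.converged,
            }
        )

    table = pd.DataFrame(rows)
    if table.empty:
        return table
    k = int(table["p_raw"].notna().sum())
    table["alpha_by"] = by_alpha(max(k, 1), alpha)
    table["p_bh"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant_by"] = table["p_raw"] < table["alpha_by"]
    table["significant_bh"] = table["p_bh"] < alpha
    return table
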