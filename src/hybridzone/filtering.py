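"""SNP filtering and the interspecies allele-frequency differential (delta).

Filters are applied in a fixed order -- depth masking, call rate, minor
allele frequency, group presence -- because depth masking changes the call
rate, so it must run first.  The differential delta for a biallelic locus is
|p_A - p_B|, the two-allele reduction of the Gregorius-Roberds distance
(1/2) * sum_i |p_A,i - p_B,i|; delta = 1 marks a fixed difference, decided on
the observed parental allele sets being disjoint rather than on a floating
comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridzone.datamodel import MISSING, GenotypeMatrix, Group

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Locus-retention thresholds.

    min_depth : per-call read depth below which a call is masked to missing
        (applied only when depth data exist).
    min_call_fraction : minimum fraction of samples with a non-missing call.
    min_maf : minimum minor allele frequency over all non-missing calls.
    require_group_presence : retain a locus only if it has at least one
        non-missing call in each of the three groups.
    """

    min_depth: int = 20
    min_call_fraction: float = 0.80
    min_maf: float = 0.05
    require_group_presence: bool = True
    maf_scope: str = "overall"  # "overall" or "parental"

    def __post_init__(self) -> None:
        if not 0 < self.min_call_fraction <= 1:
            raise ValueError("min_call_fraction must be in (0, 1]")
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
        if self.maf_scope not in ("overall", "parental"):
            raise ValueError("maf_scope must be 'overall' or 'parental'")


def filter_loci(
    matrix: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply depth, call-rate, MAF and group-presence filters in that order.

    Returns the filtered matrix and a report DataFrame with one row per
    filter (filter, removed, retained).  Raises if zero loci survive.
    """
    if params is None:
        params = FilterParams()

    calls = matrix.calls.copy()
    depth = matrix.depth
    report_rows: list[tuple[str, int, int]] = []

    if params.min_depth > 0:
        if depth is None:
            warnings.warn(
                "depth filter requested but matrix carries no depth data; "
                "skipping",
                stacklevel=2,
            )
        else:
            calls[depth < params.min_depth] = MISSING

    keep = np.ones(matrix.n_loci, dtype=bool)
    n_samples = matrix.n_samples

    called = calls != MISSING
    call_frac = called.sum(axis=0) / n_samples
    fail = keep & (call_frac < params.min_call_fraction)
    keep &= ~fail
    report_rows.append(("call_rate", int(fail.sum()), int(keep.sum())))

    # MAF over all non-missing calls (optionally parental groups only)
    if params.maf_scope == "parental":
        rows = matrix.group_mask(Group.PARENTAL_A) | matrix.group_mask(
            Group.PARENTAL_B
        )
        maf_called = called[rows]
        maf_calls = calls[rows]
    else:
        maf_called = called
        maf_calls = calls
    with np.errstate(invalid="ignore"):
        alt_copies = np.where(maf_called, maf_calls, 0).sum(axis=0)
        total_copies = 2 * maf_called.sum(axis=0)
        p_alt = np.divide(
            alt_copies,
            total_copies,
            out=np.full(matrix.n_loci, np.nan),
            where=total_copies > 0,
        )
    maf = np.minimum(p_alt, 1.0 - p_alt)
    fail = keep & ~(maf >= params.min_maf)  # NaN fails too
    keep &= ~fail
    report_rows.append(("maf", int(fail.sum()), int(keep.sum())))

    if params.require_group_presence:
        fail = np.zeros(matrix.n_loci, dtype=bool)
        for group in Group:
            rows = matrix.group_mask(group)
            if rows.any():
                fail |= ~called[rows].any(axis=0)
            else:
                raise ValueError(
                    f"group presence filter requires samples in {group.value}"
                )
        fail &= keep
        keep &= ~fail
        report_rows.append(("group_presence", int(fail.sum()), int(keep.sum())))

    report = pd.DataFrame(report_rows, columns=["filter", "removed", "retained"])
    if not keep.any():
        raise ValueError("no loci survive filtering")
    for _, row in report.iterrows():
        logger.info(
            "filter %s: removed %d, retained %d",
            row["filter"], row["removed"], row["retained"],
        )

    out = GenotypeMatrix(
        samples=matrix.samples,
        loci=[matrix.loci[i] for i in np.flatnonzero(keep)],
        calls=calls[:, keep],
        depth=None if depth is None else depth[:, keep],
    )
    return out, report


def estimate_parental_freqs(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Alternate-allele frequency per locus in each parental group.

    Returns a DataFrame indexed by locus_id with columns p_a, p_b (NaN where
    a group has no non-missing call) and n_a, n_b (non-missing allele copies
    counted).  Admixed-candidate samples never contribute.
    """
    rows_a = matrix.group_mask(Group.PARENTAL_A)
    rows_b = matrix.group_mask(Group.PARENTAL_B)
    if not rows_a.any() or not rows_b.any():
        raise ValueError("need at least one sample in each parental group")

    out = {}
    for label, rows in (("a", rows_a), ("b", rows_b)):
        sub = matrix.calls[rows]
        called = sub != MISSING
        copies = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        p = np.divide(
            alt, copies, out=np.full(matrix.n_loci, np.nan), where=copies > 0
        )
        out[f"p_{label}"] = p
        out[f"n_{label}"] = copies
    return pd.DataFrame(out, index=pd.Index(matrix.locus_ids, name="locus_id"))


def allele_freq_differential(freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-locus differential delta = |p_A - p_B|, with a fixed-difference flag.

    ``fixed`` is True only when the observed parental allele sets are
    disjoint (one group shows only the reference allele, the other only the
    alternate), which is the counting semantics of delta = 1.  Undefined
    frequencies propagate as NaN delta.
    """
    p_a = freqs["p_a"].to_numpy(float)
    p_b = freqs["p_b"].to_numpy(float)
    delta = np.abs(p_a - p_b)
    fixed = ((p_a == 0.0) & (p_b == 1.0)) | ((p_a == 1.0) & (p_b == 0.0))
    fixed &= (freqs["n_a"].to_numpy() > 0) & (freqs["n_b"].to_numpy() > 0)
    return pd.DataFrame({"delta": delta, "fixed": fixed}, index=freqs.index)


def select_differentiated(diff: pd.DataFrame, threshold: float) -> list[str]:
    """Locus ids with delta >= threshold.

    threshold = 1 uses the exact fixed-difference flag (disjoint observed
    alleles) rather than a floating comparison.  An empty selection warns
    but is not an error.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if threshold == 1:
        mask = diff["fixed"].to_numpy(bool)
    else:
        delta = diff["delta"].to_numpy(float)
        mask = np.where(np.isnan(delta), False, delta >= threshold)
    ids = list(diff.index[mask])
    if not ids:
        warnings.warn(
            f"no loci reach delta >= {threshold}", stacklevel=2
        )
    return ids
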