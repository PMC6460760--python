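"""Plumage-score analysis: trait proportions, phenotype hybrid index,
scaled PCA and geographic hybrid-zone profiling.

Six integer-scored plumage traits are converted to proportions of their
trait maxima; higher values are more B-like (the *P. eximius* pole).  The
plumage hybrid index is the unweighted mean of available trait proportions.
Because rump colour cannot always be scored, the PCA runs in two variants:
ALL_TRAITS (drop individuals missing rump) and NO_RUMP (drop the trait).
"""

from __future__ import annotations

import enum
import os
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from hybridzone.popgen import PcaResult

TRAIT_NAMES = (
    "head", "cheek_patch", "chest", "upper_abdomen", "lower_abdomen", "rump"
)
TRAIT_MAXIMA = {
    "head": 4,
    "cheek_patch": 2,
    "chest": 4,
    "upper_abdomen": 4,
    "lower_abdomen": 4,
    "rump": 4,
}


class PcaVariant(enum.Enum):
    ALL_TRAITS = "ALL_TRAITS"
    NO_RUMP = "NO_RUMP"


@dataclass
class ZoneProfile:
    """Geographic extent of the hybrid zone from plumage hybrid indices."""

    table: pd.DataFrame  # sample_id, index, latitude, longitude, in_zone
    zone_lat_bounds: Optional[tuple[float, float]]  # (south, north)
    zone_lon_bounds: Optional[tuple[float, float]]
    intermediate_band: tuple[float, float]


def read_plumage_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read the plumage TSV (NA allowed for rump only) and validate ranges."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in ("sample_id", *TRAIT_NAMES) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    for trait in TRAIT_NAMES:
        col = df[trait]
        if trait != "rump" and col.isna().any():
            bad = df.loc[col.isna(), "sample_id"].tolist()
            raise ValueError(f"{path}: trait {trait} missing for {bad}")
    _validate_scores(df)
    return df


def _validate_scores(df: pd.DataFrame) -> None:
    for trait in TRAIT_NAMES:
        col = df[trait].astype(float)
        bad = col.notna() & ((col < 0) | (col > TRAIT_MAXIMA[trait]))
        if bad.any():
            sid = df.loc[bad, "sample_id"].iloc[0]
            raise ValueError(
                f"score out of range for trait {trait!r} "
                f"(sample {sid}): allowed 0..{TRAIT_MAXIMA[trait]}"
            )


def score_to_proportions(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trait proportions score / trait_max; NaN preserved for rump."""
    _validate_scores(df)
    out = df.copy()
    for trait in TRAIT_NAMES:
        out[trait] = df[trait].astype(float) / TRAIT_MAXIMA[trait]
    return out


def plumage_hybrid_index(
    proportions: pd.DataFrame, exclude_traits: Sequence[str] | None = None
) -> pd.Series:
    """Mean of available, non-excluded trait proportions per individual.

    Missing rump simply averages over the remaining traits.  All traits
    excluded or missing is an error.
    """
    exclude = set(exclude_traits or ())
    unknown = exclude - set(TRAIT_NAMES)
    if unknown:
        raise ValueError(f"unknown trait(s) to exclude: {sorted(unknown)}")
    traits = [t for t in TRAIT_NAMES if t not in exclude]
    if not traits:
        raise ValueError("all traits excluded")
    sub = proportions[traits]
    if sub.isna().all(axis=1).any():
        bad = proportions.loc[sub.isna().all(axis=1), "sample_id"].tolist()
        raise ValueError(f"no scorable traits for {bad}")
    idx = sub.mean(axis=1, skipna=True)
    idx.index = proportions["sample_id"].values
    return idx.rename("plumage_hybrid_index")


def plumage_pca(
    proportions: pd.DataFrame, variant: PcaVariant = PcaVariant.ALL_TRAITS
) -> PcaResult:
    """PCA of trait proportions, centred and scaled to unit variance.

    ALL_TRAITS drops individuals whose rump could not be scored; NO_RUMP
    drops the rump trait and keeps every individual.  Component signs are
    fixed by forcing the largest-magnitude loading positive.
    """
    if variant is PcaVariant.NO_RUMP:
        traits = [t for t in TRAIT_NAMES if t != "rump"]
        sub = proportions.dropna(subset=traits)
    else:
        traits = list(TRAIT_NAMES)
        sub = proportions.dropna(subset=traits)
    if len(sub) < 3:
        raise ValueError("need >= 3 individuals after exclusions")
    X = sub[traits].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    zero_var = np.isclose(sd, 0)
    if zero_var.any():
        name = traits[int(np.flatnonzero(zero_var)[0])]
        raise ValueError(f"zero-variance trait {name!r}: cannot scale")
    Z = (X - X.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    for i in range(vt.shape[0]):
        jmax = np.argmax(np.abs(vt[i]))
        if vt[i, jmax] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    comp_names = [f"PC{i + 1}" for i in range(vt.shape[0])]
    return PcaResult(
        scores=pd.DataFrame(
            u * s, index=sub["sample_id"].values, columns=comp_names
        ),
        explained_fraction=explained,
        loadings=pd.DataFrame(vt.T, index=traits, columns=comp_names),
    )


def zone_profile(
    table: pd.DataFrame,
    band: tuple[float, float] = (0.2, 0.8),
    lat_bin_width: float = 0.25,
) -> ZoneProfile:
    """Locate the hybrid zone from plumage hybrid indices and coordinates.

    ``table`` needs columns sample_id, index (plumage hybrid index),
    latitude, longitude.  An individual qualifies for the zone if its index
    is strictly inside ``band``, or if it shares a latitude bin (width
    ``lat_bin_width`` degrees) with both a low-index (< 0.1) and a
    high-index (> 0.9) individual -- i.e. both parental phenotypes co-occur
    there.  Latitude bounds are the min/max latitude of qualifying
    individuals; longitude bounds are taken over in-band individuals within
    those latitude bounds.
    """
    t = table.copy()
    lo, hi = band
    in_band = (t["index"] > lo) & (t["index"] < hi)

    bins = np.floor(t["latitude"].to_numpy(float) / lat_bin_width)
    co_occur = np.zeros(len(t), dtype=bool)
    for b in np.unique(bins[~np.isnan(bins)]):
        rows = bins == b
        idx = t.loc[rows, "index"]
        if (idx < 0.1).any() and (idx > 0.9).any():
            co_occur |= rows
    qualifying = (in_band | co_occur) & t["latitude"].notna().to_numpy()
    t["in_zone"] = qualifying

    if not qualifying.any():
        warnings.warn("no individuals qualify for the hybrid zone", stacklevel=2)
        return ZoneProfile(t, None, None, band)

    lats = t.loc[qualifying, "latitude"]
    lat_bounds = (float(lats.min()), float(lats.max()))
    in_zone_band = in_band & qualifying & t["longitude"].notna().to_numpy()
    if in_zone_band.any():
        lons = t.loc[in_zone_band, "longitude"]
        lon_bounds = (float(lons.min()), float(lons.max()))
    else:
        lon_bounds = None
    return ZoneProfile(t, lat_bounds, lon_bounds, band)
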