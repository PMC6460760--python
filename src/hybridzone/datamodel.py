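"""Core data model: samples, loci and the genotype matrix.

Genotypes are biallelic SNP calls coded as the count of the designated
alternate allele (0, 1, 2) with ``MISSING`` (-1) for no-calls.  Polarization
to "count of the B-associated allele" is an ancestry-stage concern and never
happens at this layer, so I/O round trips are lossless.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Sentinel for a missing genotype call.  Kept negative so any arithmetic
#: on un-masked calls fails loudly rather than silently.
MISSING: int = -1


class Group(enum.Enum):
    """Sampling group of an individual relative to the hybrid zone."""

    PARENTAL_A = "PARENTAL_A"
    PARENTAL_B = "PARENTAL_B"
    ADMIXED_CANDIDATE = "ADMIXED_CANDIDATE"

    @classmethod
    def parse(cls, label: str) -> "Group":
        """Parse a group label, accepting common aliases (case-insensitive)."""
        key = label.strip().lower()
        try:
            return _GROUP_ALIASES[key]
        except KeyError:
            raise ValueError(
                f"unknown group label {label!r}; expected one of "
                f"{sorted(_GROUP_ALIASES)}"
            ) from None


_GROUP_ALIASES = {
    "parental_a": Group.PARENTAL_A,
    "a": Group.PARENTAL_A,
    "pure_a": Group.PARENTAL_A,
    "parental_b": Group.PARENTAL_B,
    "b": Group.PARENTAL_B,
    "pure_b": Group.PARENTAL_B,
    "admixed_candidate": Group.ADMIXED_CANDIDATE,
    "admixed": Group.ADMIXED_CANDIDATE,
    "hybrid": Group.ADMIXED_CANDIDATE,
}


class Sex(enum.Enum):
    M = "M"
    F = "F"
    U = "U"


@dataclass
class SampleMeta:
    sample_id: str
    group: Optional[Group] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    sex: Sex = Sex.U


@dataclass
class LocusMeta:
    """A biallelic locus.  Alleles may be nucleotides or symbolic "0"/"1"."""

    locus_id: str
    ref_allele: str = "0"
    alt_allele: str = "1"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"locus {self.locus_id}: ref and alt alleles must differ"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of biallelic genotype calls.

    Attributes
    ----------
    samples : list of SampleMeta
        Row metadata, in matrix order.
    loci : list of LocusMeta
        Column metadata, in matrix order.
    calls : ndarray of int16, shape (n_samples, n_loci)
        Count of the alternate allele per call: 0, 1, 2 or MISSING.
    depth : ndarray of int32 or None
        Per-call read depth when available; depth 0 implies MISSING.
    """

    samples: list[SampleMeta]
    loci: list[LocusMeta]
    calls: np.ndarray
    depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in matrix")
        lids = [l.locus_id for l in self.loci]
        if len(set(lids)) != len(lids):
            raise ValueError("duplicate locus_id in matrix")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape does not match calls")
            if (self.depth < 0).any():
                raise ValueError("negative depth")
            if (self.calls[self.depth == 0] != MISSING).any():
                raise ValueError("depth 0 with a non-missing call")

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def group_mask(self, group: Group) -> np.ndarray:
        """Boolean row mask of samples assigned to ``group``."""
        return np.array([s.group == group for s in self.samples], dtype=bool)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_loci(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to loci at integer positions ``keep``."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=self.samples,
            loci=[self.loci[i] for i in keep],
            calls=self.calls[:, keep].copy(),
            depth=None if self.depth is None else self.depth[:, keep].copy(),
        )

    def subset_loci_by_id(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {l.locus_id: i for i, l in enumerate(self.loci)}
        try:
            keep = [index[lid] for lid in locus_ids]
        except KeyError as exc:
            raise KeyError(f"locus {exc.args[0]!r} not in matrix") from None
        return self.subset_loci(keep)

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            loci=self.loci,
            calls=self.calls[keep, :].copy(),
            depth=None if self.depth is None else self.depth[keep, :].copy(),
        )

    def locus_index(self) -> dict[str, int]:
        return {l.locus_id: i for i, l in enumerate(self.loci)}
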