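"""Readers and writers for the genotype, metadata and plumage tables.

VCF parsing goes through :mod:`cyvcf2`; only biallelic SNP records are kept
(records with two or more ALT alleles, or with indel alleles, are dropped and
counted).  The genotype TSV dialect is: header row of locus ids, first column
``sample_id``, cells in {0, 1, 2, NA}.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import numpy as np
import pandas as pd

from hybridzone.datamodel import (
    MISSING,
    GenotypeMatrix,
    Group,
    LocusMeta,
    SampleMeta,
    Sex,
)

logger = logging.getLogger(__name__)


class EmptyDatasetError(ValueError):
    """Raised when a source yields zero usable samples or loci."""


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Genotype code is the count of the first ALT allele; ``./.`` maps to
    MISSING.  Multi-allelic and non-SNP records are dropped with a logged
    count.  Per-call DP is attached when the FORMAT carries it.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except OSError as exc:
        raise IOError(f"cannot read VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    loci: list[LocusMeta] = []
    call_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    any_depth = False
    n_dropped = 0

    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1 or len(variant.REF) != 1 or len(alts[0]) != 1:
            n_dropped += 1
            continue
        locus_id = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}:{variant.POS}"
        )
        loci.append(LocusMeta(locus_id, variant.REF, alts[0]))
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(variant.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING
        call_cols.append(gt)
        dp = variant.format("DP")
        if dp is not None:
            dp = dp.reshape(-1).astype(np.int32)
            dp[dp < 0] = 0
            depth_cols.append(dp)
            any_depth = True
        else:
            depth_cols.append(np.zeros(len(sample_ids), dtype=np.int32))

    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)
    if not loci or not sample_ids:
        raise EmptyDatasetError(f"no usable biallelic SNP records in {path}")

    calls = np.column_stack(call_cols)
    depth = np.column_stack(depth_cols) if any_depth else None
    if depth is not None:
        calls = calls.copy()
        calls[depth == 0] = MISSING
    samples = [SampleMeta(sid) for sid in sample_ids]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls, depth=depth)


def read_genotype_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    """Read the package's genotype TSV dialect.

    Raises a parse error naming the offending row or cell on ragged rows or
    cells outside {0, 1, 2, NA}.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise EmptyDatasetError(f"{path}: empty file")
        cols = header.split("\t")
        locus_ids = cols[1:]
        n_loci = len(locus_ids)
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_loci + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row for sample "
                    f"{fields[0]!r}: {len(fields) - 1} cells, expected {n_loci}"
                )
            sid = fields[0]
            row = np.empty(n_loci, dtype=np.int16)
            for j, cell in enumerate(fields[1:]):
                if cell == "NA":
                    row[j] = MISSING
                elif cell in ("0", "1", "2"):
                    row[j] = int(cell)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: invalid genotype {cell!r} for "
                        f"sample {sid!r} at locus {locus_ids[j]!r}"
                    )
            sample_ids.append(sid)
            rows.append(row)

    if not rows or n_loci == 0:
        raise EmptyDatasetError(f"{path}: empty dataset (no samples or loci)")
    return GenotypeMatrix(
        samples=[SampleMeta(sid) for sid in sample_ids],
        loci=[LocusMeta(lid) for lid in locus_ids],
        calls=np.vstack(rows),
    )


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write calls as the genotype TSV dialect (MISSING rendered as NA)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.locus_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            cells = [
                "NA" if c == MISSING else str(int(c)) for c in matrix.calls[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_sample_metadata(
    path: str | os.PathLike, matrix: GenotypeMatrix
) -> GenotypeMatrix:
    """Attach group / coordinates / sex from a metadata TSV to ``matrix``.

    Columns: sample_id, group, latitude, longitude, sex (latitude, longitude
    and sex may be empty or NA).  Every sample in the matrix must appear in
    the metadata; duplicate ids and unknown group labels are fatal.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise ValueError(
            f"{path}: metadata must have columns {sorted(required)}"
        )
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s) {dups}")
    meta = meta.set_index("sample_id")

    missing = [sid for sid in matrix.sample_ids if sid not in meta.index]
    if missing:
        raise ValueError(
            f"{path}: metadata missing sample(s) {missing}"
        )

    def _opt_float(value) -> Optional[float]:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if isinstance(value, str) and value.strip() in ("", "NA"):
            return None
        return float(value)

    for sample in matrix.samples:
        row = meta.loc[sample.sample_id]
        sample.group = Group.parse(str(row["group"]))
        sample.latitude = _opt_float(row.get("latitude"))
        sample.longitude = _opt_float(row.get("longitude"))
        sex = row.get("sex")
        if sex is not None and isinstance(sex, str) and sex.strip() in ("M", "F"):
            sample.sex = Sex(sex.strip())
        else:
            sample.sex = Sex.U
    return matrix


def write_sample_metadata(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tlatitude\tlongitude\tsex\n")
        for s in matrix.samples:
            group = s.group.value if s.group is not None else "NA"
            lat = "NA" if s.latitude is None else repr(s.latitude)
            lon = "NA" if s.longitude is None else repr(s.longitude)
            fh.write(f"{s.sample_id}\t{group}\t{lat}\t{lon}\t{s.sex.value}\n")
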