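"""End-to-end orchestration: simulate/load -> filter -> delta sets ->
ancestry -> genomic clines -> F_ST -> PCA -> plumage, with a JSON run
manifest recording seeds, versions and per-stage counts.

Every stochastic stage derives its seed from the single run seed, so a rerun
with an identical config reproduces every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

import hybridzone
from hybridzone.ancestry import ClassThresholds, estimate_ancestry, polarize
from hybridzone.clines import cline_analysis
from hybridzone.datamodel import GenotypeMatrix, Group
from hybridzone.filtering import (
    FilterParams,
    allele_freq_differential,
    estimate_parental_freqs,
    filter_loci,
    select_differentiated,
)
from hybridzone.io import (
    read_genotype_tsv,
    read_sample_metadata,
    read_vcf,
    write_genotype_tsv,
    write_sample_metadata,
)
from hybridzone.plumage import (
    PcaVariant,
    plumage_hybrid_index,
    plumage_pca,
    read_plumage_tsv,
    score_to_proportions,
    zone_profile,
)
from hybridzone.popgen import genotype_pca, weir_cockerham_fst
from hybridzone.simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run (YAML-serializable)."""

    seed: int
    outdir: str = "hybridzone_run"
    # inputs: either real files or a simulation block
    genotypes: Optional[str] = None  # genotype TSV
    vcf: Optional[str] = None
    metadata: Optional[str] = None
    plumage: Optional[str] = None
    simulate: Optional[dict] = None  # SimConfig fields (seed defaults to run seed)
    # analysis settings
    filter_params: dict = field(default_factory=dict)
    delta_thresholds: list[float] = field(default_factory=lambda: [1.0, 0.8])
    class_thresholds: dict = field(default_factory=dict)
    n_sims: int = 1000
    cline_degree: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError(f"{path}: config must set an explicit seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _threshold_label(threshold: float) -> str:
    return f"delta{threshold:.2f}".replace(".", "p")


def stage_simulate(config: RunConfig, outdir: Path) -> dict[str, str]:
    """Generate a synthetic dataset and write it as the run's input files."""
    sim_kwargs = dict(config.simulate or {})
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimConfig(**sim_kwargs)
    data = simulate_dataset(sim)
    simdir = outdir / "sim"
    simdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": str(simdir / "genotypes.tsv"),
        "metadata": str(simdir / "metadata.tsv"),
        "plumage": str(simdir / "plumage.tsv"),
        "truth": str(simdir / "truth.tsv"),
        "true_freqs": str(simdir / "true_freqs.tsv"),
    }
    write_genotype_tsv(data.matrix, paths["genotypes"])
    write_sample_metadata(data.matrix, paths["metadata"])
    plum = data.plumage.merge(data.geography, on="sample_id")
    plum.to_csv(paths["plumage"], sep="\t", index=False, na_rep="NA")
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    data.true_freqs.to_csv(paths["true_freqs"], sep="\t")
    return paths


def load_inputs(config: RunConfig) -> tuple[GenotypeMatrix, Optional[pd.DataFrame]]:
    if config.vcf:
        matrix = read_vcf(config.vcf)
    elif config.genotypes:
        matrix = read_genotype_tsv(config.genotypes)
    else:
        raise ValueError("config provides neither genotypes nor vcf nor simulate")
    if not config.metadata:
        raise ValueError("config must provide sample metadata")
    read_sample_metadata(config.metadata, matrix)
    plum = read_plumage_tsv(config.plumage) if config.plumage else None
    if plum is not None and config.plumage:
        raw = pd.read_csv(config.plumage, sep="\t", dtype={"sample_id": str})
        for col in ("latitude", "longitude"):
            if col in raw.columns:
                plum[col] = raw[col]
    return matrix, plum


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage; returns the manifest (also written to the outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": hybridzone.__version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    if config.simulate is not None:
        paths = stage_simulate(config, outdir)
        config = dataclasses.replace(
            config,
            genotypes=paths["genotypes"],
            metadata=paths["metadata"],
            plumage=paths["plumage"],
            simulate=None,
        )
        manifest["stages"]["simulate"] = paths

    matrix, plum = load_inputs(config)
    manifest["inputs"] = {
        name: {"path": p, "sha256": _sha256(p)}
        for name, p in (
            ("genotypes", config.genotypes),
            ("metadata", config.metadata),
            ("plumage", config.plumage),
        )
        if p
    }
    manifest["stages"]["load"] = {
        "n_samples": matrix.n_samples,
        "n_loci": matrix.n_loci,
    }

    # --- filtering and delta -------------------------------------------
    params = FilterParams(**config.filter_params)
    filtered, report = filter_loci(matrix, params)
    report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    freqs = estimate_parental_freqs(filtered)
    diff = allele_freq_differential(freqs)
    freqs.join(diff).to_csv(outdir / "allele_freq_differential.tsv", sep="\t")
    manifest["stages"]["filter"] = {
        "n_loci_retained": filtered.n_loci,
        "report": report.to_dict("records"),
    }

    # --- F_ST and genotype PCA -----------------------------------------
    fst_rows = []
    pairs = [
        (Group.PARENTAL_A, Group.PARENTAL_B),
        (Group.PARENTAL_A, Group.ADMIXED_CANDIDATE),
        (Group.PARENTAL_B, Group.ADMIXED_CANDIDATE),
    ]
    for g1, g2 in pairs:
        res = weir_cockerham_fst(filtered, g1, g2)
        fst_rows.append(
            {
                "group1": g1.value,
                "group2": g2.value,
                "n_loci": res.n_loci,
                "mean_fst": res.mean_fst,
            }
        )
    fst_table = pd.DataFrame(fst_rows)
    fst_table.to_csv(outdir / "fst.tsv", sep="\t", index=False)
    manifest["stages"]["fst"] = fst_rows

    pca = genotype_pca(filtered)
    pca.scores.to_csv(outdir / "genotype_pca_scores.tsv", sep="\t")
    pd.DataFrame(
        {"component": pca.scores.columns, "explained_fraction": pca.explained_fraction}
    ).to_csv(outdir / "genotype_pca_scree.tsv", sep="\t", index=False)
    manifest["stages"]["genotype_pca"] = {
        "explained_fraction": [float(x) for x in pca.explained_fraction[:5]]
    }

    # --- per-threshold ancestry + clines -------------------------------
    thresholds = ClassThresholds(**config.class_thresholds)
    for threshold in config.delta_thresholds:
        label = _threshold_label(threshold)
        locus_set = select_differentiated(diff, threshold)
        manifest["stages"][f"locus_set_{label}"] = {"n_loci": len(locus_set)}
        if not locus_set:
            continue
        polarized, pol_freqs = polarize(filtered, freqs, locus_set)
        anc = estimate_ancestry(polarized, pol_freqs, thresholds)
        anc.to_csv(outdir / f"ancestry_{label}.tsv", sep="\t", index=False)
        _triangle_plot(anc, outdir / f"triangle_{label}.png")

        admixed = polarized.group_mask(Group.ADMIXED_CANDIDATE)
        h_by_sample = anc.set_index("sample_id")["h"]
        h_admixed = h_by_sample.loc[
            [s.sample_id for s, m in zip(polarized.samples, admixed) if m]
        ].to_numpy()
        clines = cline_analysis(
            polarized,
            pol_freqs,
            h_admixed,
            diff=diff,
            n_sims=config.n_sims,
            seed=config.seed,
            alpha=config.alpha,
            degree=config.cline_degree,
            sample_mask=admixed,
        )
        clines.to_csv(outdir / f"clines_{label}.tsv", sep="\t", index=False)
        manifest["stages"][f"clines_{label}"] = {
            "n_tested": int(len(clines)),
            "n_significant_by": int(clines["significant_by"].sum())
            if len(clines)
            else 0,
        }

    # --- plumage -------------------------------------------------------
    if plum is not None:
        props = score_to_proportions(plum[["sample_id", *hybridzone.TRAIT_NAMES]])
        index = plumage_hybrid_index(props)
        plum_out = pd.DataFrame(
            {"sample_id": index.index, "plumage_hybrid_index": index.values}
        )
        for col in ("latitude", "longitude"):
            if col in plum.columns:
                plum_out[col] = plum.set_index("sample_id").loc[
                    plum_out["sample_id"], col
                ].values
        plum_out.to_csv(outdir / "plumage_index.tsv", sep="\t", index=False)
        for variant in (PcaVariant.ALL_TRAITS, PcaVariant.NO_RUMP):
            try:
                res = plumage_pca(props, variant)
            except ValueError as exc:
                logger.warning("plumage PCA %s skipped: %s", variant.value, exc)
                continue
            res.loadings.to_csv(
                outdir / f"plumage_pca_loadings_{variant.value}.tsv", sep="\t"
            )
            pd.DataFrame(
                {
                    "component": res.scores.columns,
                    "explained_fraction": res.explained_fraction,
                }
            ).to_csv(
                outdir / f"plumage_pca_scree_{variant.value}.tsv",
                sep="\t",
                index=False,
            )
            manifest["stages"][f"plumage_pca_{variant.value}"] = {
                "explained_fraction": [float(x) for x in res.explained_fraction]
            }
        if {"latitude", "longitude"}.issubset(plum_out.columns):
            zp = zone_profile(
                plum_out.rename(columns={"plumage_hybrid_index": "index"})
            )
            zp.table.to_csv(outdir / "zone_profile.tsv", sep="\t", index=False)
            manifest["stages"]["zone_profile"] = {
                "lat_bounds": zp.zone_lat_bounds,
                "lon_bounds": zp.zone_lon_bounds,
            }
            _score_vs_coordinate_plots(plum_out, outdir)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _triangle_plot(anc: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot([0, 0.5, 1], [0, 1, 0], color="grey", lw=0.8, ls="--")
    ax.scatter(anc["h"], anc["het"], s=18, alpha=0.8)
    ax.set_xlabel("hybrid index (h)")
    ax.set_ylabel("interspecific heterozygosity (H)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _score_vs_coordinate_plots(plum_out: pd.DataFrame, outdir: Path) -> None:
    for coord in ("latitude", "longitude"):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(plum_out[coord], plum_out["plumage_hybrid_index"], s=18)
        ax.set_xlabel(coord)
        ax.set_ylabel("plumage hybrid index")
        fig.tight_layout()
        fig.savefig(outdir / f"plumage_index_vs_{coord}.png", dpi=120)
        plt.close(fig)
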