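"""Ground-truthed hybrid-zone simulator.

Generates genotype, plumage and geography data with the statistical
structure the analysis assumes: two parental populations with a small core
of fixed differences (delta = 1) and strongly differentiated loci
(delta >= 0.8) among mostly weakly differentiated loci; admixed individuals
built by explicit Mendelian pedigrees (F1, F2, backcrosses, deeper
hybrid x hybrid generations) with per-allele origin tracking, so every
individual carries its *realized* genome-wide ancestry fraction and
interspecific heterozygosity as ground truth; optional transmission
distortion at chosen loci (the B-origin allele transmitted with probability
1/2 + b from origin-heterozygous parents), which produces exactly the
genotype-frequency departures the genomic-cline test targets; plumage trait
scores monotone in ancestry with trait-specific noise; and a latitudinal
zone structure with intermediates confined to a band.

Loci are unlinked and mutation-free: every downstream model treats loci as
independent and exchangeable, and the simulator matches that assumption.
The whole dataset is a pure function of :class:`SimConfig` (seed included).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from hybridzone.datamodel import (
    MISSING,
    GenotypeMatrix,
    Group,
    LocusMeta,
    SampleMeta,
)
from hybridzone.plumage import TRAIT_MAXIMA, TRAIT_NAMES

ORIGIN_A, ORIGIN_B = 0, 1


@dataclass
class PedigreeClass:
    """Pedigree recipe label: PURE_A/PURE_B, F1, F2, BC1_A/BC1_B,
    BC2_A/BC2_B, or MULTIGEN_K (K successive hybrid x hybrid generations;
    MULTIGEN_2 is an F2)."""

    name: str

    _VALID = {"PURE_A", "PURE_B", "F1", "F2", "BC1_A", "BC1_B", "BC2_A", "BC2_B"}

    def __post_init__(self) -> None:
        if self.name in self._VALID:
            return
        if re.fullmatch(r"MULTIGEN_\d+", self.name) and self.multigen_k >= 2:
            return
        raise ValueError(f"unknown pedigree class {self.name!r}")

    @property
    def multigen_k(self) -> Optional[int]:
        if self.name.startswith("MULTIGEN_"):
            return int(self.name.split("_")[1])
        return None

    @property
    def expected_ancestry(self) -> float:
        """Pedigree-expectation of the B ancestry fraction."""
        return {
            "PURE_A": 0.0, "PURE_B": 1.0, "F1": 0.5, "F2": 0.5,
            "BC1_A": 0.25, "BC1_B": 0.75, "BC2_A": 0.125, "BC2_B": 0.875,
        }.get(self.name, 0.5)


def _default_class_counts() -> dict[str, int]:
    # a small admixed-candidate group dominated by backcrosses and deeper
    # hybrids, as in a mature bimodal hybrid zone
    return {"F1": 2, "F2": 2, "BC1_A": 4, "BC1_B": 4, "MULTIGEN_3": 4}


@dataclass
class SimConfig:
    """Simulation conditions.

    The defaults mirror the structure of the motivating study system: 40 + 21
    parental reference individuals and a small admixed group genotyped at a
    locus panel in which a few percent of loci are fixed between the parental
    taxa, roughly a tenth are strongly differentiated (delta >= 0.8) and the
    rest are weakly differentiated; ~5% missing genotype calls; plumage
    scores tracking ancestry with modest noise; a hybrid zone confined to a
    latitude band.
    """

    seed: int
    n_loci: int = 300
    frac_fixed: float = 0.03
    frac_high: float = 0.09  # fraction with 0.8 <= delta < 1
    diff_beta_params: tuple[float, float] = (1.0, 10.0)
    n_parental_a: int = 40
    n_parental_b: int = 21
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    missing_rate: float = 0.05
    distorted_loci: list[tuple[int, float]] = field(default_factory=list)
    plumage_noise_sd: float = 0.05
    n_rump_missing: int = 0
    lat_range: tuple[float, float] = (-32.0, -25.5)
    zone_lat_band: tuple[float, float] = (-30.1, -27.9)
    lon_range: tuple[float, float] = (148.0, 153.0)
    zone_lon_band: tuple[float, float] = (150.6, 151.4)
    geo_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.frac_fixed <= 1:
            raise ValueError("frac_fixed must be in [0, 1]")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")
        if self.frac_fixed + self.frac_high > 1:
            raise ValueError("frac_fixed + frac_high exceeds 1")
        for locus, b in self.distorted_loci:
            if not -0.5 <= b <= 0.5:
                raise ValueError(f"distortion bias {b} at locus {locus} outside [-0.5, 0.5]")
        for name, count in self.class_counts.items():
            PedigreeClass(name)
            if count < 0:
                raise ValueError(f"negative count for class {name}")


@dataclass
class _Indiv:
    """Two haplotypes: allele values (1 = alternate) and parental origins."""

    alleles: np.ndarray  # (2, n_loci) uint8
    origins: np.ndarray  # (2, n_loci) uint8

    @property
    def ancestry_fraction(self) -> float:
        return float((self.origins == ORIGIN_B).mean())

    @property
    def origin_heterozygosity(self) -> float:
        return float((self.origins[0] != self.origins[1]).mean())

    @property
    def calls(self) -> np.ndarray:
        return self.alleles.sum(axis=0).astype(np.int16)


def simulate_parental_freqs(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """True parental alternate-allele frequencies per locus.

    Fixed loci get (p_A, p_B) = (0, 1); strongly differentiated loci draw a
    true delta uniformly in [0.8, 0.98); the remainder diverge weakly, with
    the divergence drawn from Beta(diff_beta_params).
    Returns a DataFrame indexed by locus_id with p_a, p_b, delta_true, kind.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_loci
    n_fixed = round(config.frac_fixed * n)
    n_high = round(config.frac_high * n)
    n_weak = n - n_fixed - n_high

    p_a = np.empty(n)
    p_b = np.empty(n)
    kind = np.array(["fixed"] * n_fixed + ["high"] * n_high + ["weak"] * n_weak)
    p_a[:n_fixed] = 0.0
    p_b[:n_fixed] = 1.0
    delta_high = rng.uniform(0.8, 0.98, size=n_high)
    base_high = rng.uniform(0.0, 1.0 - delta_high)
    p_a[n_fixed:n_fixed + n_high] = base_high
    p_b[n_fixed:n_fixed + n_high] = base_high + delta_high
    eps = rng.beta(*config.diff_beta_params, size=n_weak)
    base = rng.uniform(0.15, 0.85, size=n_weak)
    p_a[n_fixed + n_high:] = np.clip(base - eps / 2, 0.0, 1.0)
    p_b[n_fixed + n_high:] = np.clip(base + eps / 2, 0.0, 1.0)

    ids = [f"L{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "p_a": p_a,
            "p_b": p_b,
            "delta_true": np.abs(p_a - p_b),
            "kind": kind,
        },
        index=pd.Index(ids, name="locus_id"),
    )


def _draw_parental(freqs: pd.DataFrame, side: str, rng: np.random.Generator) -> _Indiv:
    p = freqs["p_b" if side == "B" else "p_a"].to_numpy(float)
    alleles = (rng.random((2, p.size)) < p).astype(np.uint8)
    origin = ORIGIN_B if side == "B" else ORIGIN_A
    origins = np.full((2, p.size), origin, dtype=np.uint8)
    return _Indiv(alleles, origins)


def sample_parental_genotypes(
    freqs: pd.DataFrame,
    n: int,
    side: str,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg draws of ``n`` individuals from one parental side."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    prefix = id_prefix or side
    indivs = [_draw_parental(freqs, side, rng) for _ in range(n)]
    calls = np.vstack([ind.calls for ind in indivs])
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    group = Group.PARENTAL_A if side == "A" else Group.PARENTAL_B
    samples = [SampleMeta(f"{prefix}{i + 1:04d}", group=group) for i in range(n)]
    loci = [LocusMeta(lid) for lid in freqs.index]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def _gamete(
    parent: _Indiv, bias: np.ndarray | None, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = parent.alleles.shape[1]
    p_copy1 = np.full(n, 0.5)
    if bias is not None:
        het_origin = parent.origins[0] != parent.origins[1]
        copy1_is_b = parent.origins[1] == ORIGIN_B
        biased = het_origin & (bias != 0)
        p_copy1 = np.where(
            biased, np.where(copy1_is_b, 0.5 + bias, 0.5 - bias), 0.5
        )
    take1 = (rng.random(n) < p_copy1).astype(np.intp)
    cols = np.arange(n)
    return parent.alleles[take1, cols], parent.origins[take1, cols]


def breed(
    parent1: _Indiv,
    parent2: _Indiv,
    rng: np.random.Generator,
    distorted_loci: list[tuple[int, float]] | None = None,
) -> _Indiv:
    """Mendelian cross: one unlinked gamete from each parent.

    At a distorted locus, an origin-heterozygous parent transmits its
    B-origin allele with probability 1/2 + b.
    """
    n = parent1.alleles.shape[1]
    if parent2.alleles.shape[1] != n:
        raise ValueError("parents must share the locus set")
    bias = None
    if distorted_loci:
        bias = np.zeros(n)
        for locus, b in distorted_loci:
            bias[locus] = b
    a1, o1 = _gamete(parent1, bias, rng)
    a2, o2 = _gamete(parent2, bias, rng)
    return _Indiv(np.vstack([a1, a2]), np.vstack([o1, o2]))


def _make_class(
    cls: PedigreeClass,
    freqs: pd.DataFrame,
    rng: np.random.Generator,
    distorted: list[tuple[int, float]],
) -> _Indiv:
    def pure(side: str) -> _Indiv:
        return _draw_parental(freqs, side, rng)

    def f1() -> _Indiv:
        return breed(pure("A"), pure("B"), rng, distorted)

    def gen(k: int) -> _Indiv:
        # generation k of successive hybrid x hybrid crosses; gen 1 = F1
        if k == 1:
            return f1()
        return breed(gen(k - 1), gen(k - 1), rng, distorted)

    name = cls.name
    if name == "PURE_A":
        return pure("A")
    if name == "PURE_B":
        return pure("B")
    if name == "F1":
        return f1()
    if name == "F2":
        return gen(2)
    if name == "BC1_A":
        return breed(f1(), pure("A"), rng, distorted)
    if name == "BC1_B":
        return breed(f1(), pure("B"), rng, distorted)
    if name == "BC2_A":
        return breed(breed(f1(), pure("A"), rng, distorted), pure("A"), rng, distorted)
    if name == "BC2_B":
        return breed(breed(f1(), pure("B"), rng, distorted), pure("B"), rng, distorted)
    return gen(cls.multigen_k)


def simulate_class_sample(
    config: SimConfig,
    freqs: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "H",
    group: Group = Group.ADMIXED_CANDIDATE,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Build the requested pedigree classes; returns (matrix, truth table).

    The truth table records, per individual, the pedigree class and the
    *realized* genome-wide B-ancestry fraction and origin-heterozygosity
    (per-allele origin bookkeeping, not the pedigree expectation).
    """
    if not config.class_counts:
        raise ValueError("class_counts is empty")
    rng = rng or np.random.default_rng(config.seed)
    if freqs is None:
        freqs = simulate_parental_freqs(config, rng)

    samples, rows, calls_rows = [], [], []
    i = 0
    for name in sorted(config.class_counts):
        cls = PedigreeClass(name)
        for _ in range(config.class_counts[name]):
            ind = _make_class(cls, freqs, rng, config.distorted_loci)
            i += 1
            sid = f"{id_prefix}{i:04d}"
            samples.append(SampleMeta(sid, group=group))
            calls_rows.append(ind.calls)
            rows.append(
                {
                    "sample_id": sid,
                    "pedigree_class": name,
                    "h_true": ind.ancestry_fraction,
                    "het_true": ind.origin_heterozygosity,
                }
            )
    calls = np.vstack(calls_rows)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    matrix = GenotypeMatrix(
        samples=samples,
        loci=[LocusMeta(lid) for lid in freqs.index],
        calls=calls,
    )
    return matrix, pd.DataFrame(rows)


def simulate_plumage(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Integer plumage scores monotone in ancestry with per-trait noise.

    Each trait's latent value is the individual's true ancestry fraction
    plus Gaussian noise, clipped to [0, 1], scaled by the trait maximum and
    rounded.  Cheek patch gets extra noise at low ancestry (the A-side taxon
    is variable there); rump is set missing for ``n_rump_missing``
    individuals.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = len(truth)
    h = truth["h_true"].to_numpy(float)
    out = {"sample_id": truth["sample_id"].to_numpy()}
    for trait in TRAIT_NAMES:
        sd = np.full(n, config.plumage_noise_sd)
        if trait == "cheek_patch":
            sd = np.where(h < 0.25, sd + 0.15, sd)
        latent = np.clip(h + rng.normal(0.0, 1.0, size=n) * sd, 0.0, 1.0)
        out[trait] = np.rint(latent * TRAIT_MAXIMA[trait]).astype(float)
    df = pd.DataFrame(out)
    if config.n_rump_missing > 0:
        drop = rng.choice(n, size=min(config.n_rump_missing, n), replace=False)
        df.loc[drop, "rump"] = np.nan
    return df


def simulate_zone_geography(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Coordinates with a latitudinal replacement of A by B.

    A-like individuals (ancestry <= 0.2) sit north of the zone band, B-like
    (>= 0.8) south of it, intermediates inside it; intermediate individuals
    are also confined to the configured longitude band ("inland" vs
    "coastal" structure), with low-admixture B-like individuals placed in
    the coastal (eastern) stratum.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    h = truth["h_true"].to_numpy(float)
    n = h.size
    lat_s, lat_n = min(config.lat_range), max(config.lat_range)
    band_s, band_n = min(config.zone_lat_band), max(config.zone_lat_band)
    lon_w, lon_e = min(config.lon_range), max(config.lon_range)
    zlon_w, zlon_e = min(config.zone_lon_band), max(config.zone_lon_band)

    lat = np.empty(n)
    lon = np.empty(n)
    for i, a in enumerate(h):
        if a <= 0.2:
            lat[i] = rng.uniform(band_n, lat_n)
            lon[i] = rng.uniform(lon_w, zlon_e)
        elif a >= 0.8:
            lat[i] = rng.uniform(lat_s, band_s)
            lon[i] = rng.uniform(zlon_w, lon_e)
        else:
            lat[i] = rng.uniform(band_s, band_n)
            lon[i] = rng.uniform(zlon_w, zlon_e)
    lat += rng.normal(0.0, config.geo_noise_sd, size=n)
    return pd.DataFrame(
        {"sample_id": truth["sample_id"].to_numpy(), "latitude": lat, "longitude": lon}
    )


@dataclass
class SimulatedDataset:
    matrix: GenotypeMatrix  # parental A + parental B + admixed, with groups
    truth: pd.DataFrame  # per-individual class, h_true, het_true
    plumage: pd.DataFrame
    geography: pd.DataFrame
    true_freqs: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full dataset: parental panels, pedigree-classed admixed individuals,
    plumage scores and coordinates.  Pure function of the config."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_parental_freqs(config, rng)

    mat_a = sample_parental_genotypes(
        freqs, config.n_parental_a, "A", rng, config.missing_rate
    )
    mat_b = sample_parental_genotypes(
        freqs, config.n_parental_b, "B", rng, config.missing_rate
    )
    mat_h, truth_h = simulate_class_sample(config, freqs, rng)

    samples = mat_a.samples + mat_b.samples + mat_h.samples
    calls = np.vstack([mat_a.calls, mat_b.calls, mat_h.calls])
    matrix = GenotypeMatrix(samples=samples, loci=mat_a.loci, calls=calls)

    truth_a = pd.DataFrame(
        {
            "sample_id": mat_a.sample_ids,
            "pedigree_class": "PURE_A",
            "h_true": 0.0,
            "het_true": 0.0,
        }
    )
    truth_b = pd.DataFrame(
        {
            "sample_id": mat_b.sample_ids,
            "pedigree_class": "PURE_B",
            "h_true": 1.0,
            "het_true": 0.0,
        }
    )
    truth = pd.concat([truth_a, truth_b, truth_h], ignore_index=True)

    plumage = simulate_plumage(truth, config)
    geography = simulate_zone_geography(truth, config)
    geo = geography.set_index("sample_id")
    for s in matrix.samples:
        s.latitude = float(geo.loc[s.sample_id, "latitude"])
        s.longitude = float(geo.loc[s.sample_id, "longitude"])
    return SimulatedDataset(matrix, truth, plumage, geography, freqs)
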