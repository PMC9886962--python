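"""Synthetic genotype / environment / phenotype generator.

Emulates the sampling design of a rangeland collection: a set of populations
(one per collection site, sites grouped into soil zones), individuals that are
admixed between two ancestral gene pools (e.g. the sativa and falcata
backgrounds of cultivated alfalfa), a minority of loci whose site-level allele
frequency tracks an environmental predictor through a logistic link, block-wise
linkage disequilibrium along chromosomes, and phenotypes that depend linearly
on an individual's ancestry proportion.

The generator returns, alongside the data, a :class:`TruthRecord` holding the
quantities the analysis stages are supposed to recover (true ancestry
proportions, planted adaptive loci, LD block length, phenotype slopes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from grazescan.io import MISSING, EnvTable, GenotypeMatrix

SOIL_ZONES = ("Brown", "Dark Brown", "Black", "Grey Wooded")

#: predictor name -> (mean, within-zone SD, between-zone SD)
DEFAULT_ENV_SPEC = {
    "K": (420.0, 80.0, 150.0),          # soil potassium, mg/kg
    "P": (15.0, 4.0, 6.0),              # soil phosphorus, mg/kg
    "S": (11.0, 3.0, 5.0),              # soil sulfur, mg/kg
    "pH": (7.4, 0.25, 0.4),
    "summer_extreme_temp": (35.0, 1.0, 2.5),   # deg C
    "winter_extreme_temp": (-38.0, 1.5, 3.0),  # deg C
    "precipitation": (380.0, 30.0, 80.0),      # mm, May-September
}

#: trait -> (intercept, slope on sativa ancestry proportion, noise SD)
DEFAULT_PHENO_SPEC = {
    "forage_yield_g": (180.0, 100.0, 40.0),
    "fall_height_cm": (10.0, 6.0, 1.5),
    "days_to_flower_gdd": (820.0, -90.0, 30.0),
    "regrowth_g": (45.0, 45.0, 12.0),
    "cp_pct": (18.5, -2.2, 0.5),
}


@dataclass
class SimConfig:
    """Parameters of a synthetic study.

    Defaults reproduce the design of a 14-site collection of ~10 genotypes
    per site across four soil zones, two ancestral gene pools at moderate
    divergence, and a small minority of environment-coupled loci.
    """

    n_pops: int = 14
    n_per_pop: int = 10
    n_loci: int = 2000
    n_chrom: int = 8
    chrom_length_bp: int = 80_000_000
    fst: float = 0.3
    #: concentration of the per-population Beta prior on individual ancestry
    admixture_alpha: float = 30.0
    n_adaptive: int = 20
    #: log-odds change in site allele frequency per SD of the coupled predictor
    adaptive_slope: float = 1.5
    block_len_bp: int = 50_000
    #: per-locus probability of refreshing the block latent allele (controls
    #: within-block r-squared)
    block_refresh: float = 0.1
    missing_rate: float = 0.0
    env_spec: dict = field(default_factory=lambda: dict(DEFAULT_ENV_SPEC))
    pheno_spec: dict = field(default_factory=lambda: dict(DEFAULT_PHENO_SPEC))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_per_pop", "n_loci", "n_chrom", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive cannot exceed n_loci")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Generator-side ground truth, consumed only by recovery tests."""

    true_Q: np.ndarray  # individuals x 2, columns (sativa, falcata)
    adaptive_loci: list  # (locus index, predictor name, slope)
    block_len_bp: int
    pheno_slopes: dict  # trait -> slope on sativa ancestry
    #: individuals x loci generator allele frequencies (recovery tests only)
    gen_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.true_Q.sum(axis=1), 1.0):
            raise ValueError("true_Q rows must sum to 1")
        idx = [i for i, _, _ in self.adaptive_loci]
        if len(idx) != len(set(idx)):
            raise ValueError("adaptive locus indices must be unique")

    def to_dict(self) -> dict:
        return {
            "true_Q": self.true_Q.tolist(),
            "adaptive_loci": [
                {"locus": int(i), "predictor": p, "slope": float(s)}
                for i, p, s in self.adaptive_loci
            ],
            "block_len_bp": int(self.block_len_bp),
            "pheno_slopes": {k: float(v) for k, v in self.pheno_slopes.items()},
        }


def simulate_ancestral_freqs(
    n_loci: int, fst: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Allele frequencies of two gene pools diverged to a target FST.

    Balding-Nichols style: a common ancestral frequency p is drawn per locus,
    and each pool draws its frequency from Beta with mean p and variance
    ``fst * p * (1 - p)``. At ``fst == 0`` the pools are identical.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    if fst == 0.0:
        return p_anc.copy(), p_anc.copy()
    c = (1.0 - fst) / fst
    pools = []
    for _ in range(2):
        p = rng.beta(c * p_anc, c * (1.0 - p_anc))
        pools.append(np.clip(p, 1e-4, 1.0 - 1e-4))
    return pools[0], pools[1]


def simulate_temperature_series(
    n_days: int,
    mean: float = 12.0,
    amplitude: float = 14.0,
    seed: int = 0,
    diurnal_range: float = 10.0,
    noise_sd: float = 1.5,
) -> pd.DataFrame:
    """Daily Tmax/Tmin: seasonal sinusoid plus noise, Tmax >= Tmin always."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    day = np.arange(n_days)
    mid = mean + amplitude * np.sin(2 * np.pi * day / 365.0)
    mid = mid + rng.normal(0.0, noise_sd, size=n_days)
    half = np.abs(diurnal_range / 2.0 + rng.normal(0.0, noise_sd / 2.0, size=n_days))
    return pd.DataFrame({"day": day + 1, "tmax": mid + half, "tmin": mid - half})


def _place_loci(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sorted random positions on n_chrom chromosomes; REF/ALT bases."""
    chroms = rng.integers(0, cfg.n_chrom, size=cfg.n_loci)
    pos = rng.integers(1, cfg.chrom_length_bp + 1, size=cfg.n_loci)
    order = np.lexsort((pos, chroms))
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=cfg.n_loci)
    alt_i = (ref_i + rng.integers(1, 4, size=cfg.n_loci)) % 4
    return pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chroms[order]],
            "pos": pos[order],
            "ref": bases[ref_i],
            "alt": bases[alt_i],
        }
    )


def _block_ids(loci: pd.DataFrame, block_len_bp: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each locus to an LD block; block boundaries follow a Poisson
    process with mean spacing block_len_bp along each chromosome."""
    block = np.zeros(len(loci), dtype=int)
    next_id = 0
    for chrom in pd.unique(loci["chrom"]):
        idx = np.flatnonzero((loci["chrom"] == chrom).to_numpy())
        pos = loci["pos"].to_numpy()[idx]
        boundary = pos[0] + rng.exponential(block_len_bp)
        for j, p in zip(idx, pos):
            while p >= boundary:
                boundary += rng.exponential(block_len_bp)
                next_id += 1
            block[j] = next_id
        next_id += 1
    return block


def _simulate_environment(cfg: SimConfig, sites: list[str], rng: np.random.Generator) -> EnvTable:
    zone_of_site = {s: SOIL_ZONES[i % len(SOIL_ZONES)] for i, s in enumerate(sites)}
    cols = {}
    for name, (mean, sd, zone_sd) in cfg.env_spec.items():
        zone_offset = {z: rng.normal(0.0, zone_sd) for z in SOIL_ZONES}
        cols[name] = [
            mean + zone_offset[zone_of_site[s]] + rng.normal(0.0, sd) for s in sites
        ]
    data = pd.DataFrame(cols, index=pd.Index(sites, name="site"))
    zones = pd.Series({s: zone_of_site[s] for s in sites}, name="zone")
    return EnvTable(data, zones=zones)


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, EnvTable, pd.DataFrame, TruthRecord]:
    """Generate a full synthetic study.

    Returns
    -------
    (GenotypeMatrix, EnvTable, phenotype DataFrame indexed by id, TruthRecord)

    Notes
    -----
    * Neutral locus, individual i: allele frequency ``q_i p_A + (1-q_i) p_B``.
    * Adaptive locus: all individuals at a site share the frequency
      ``expit(logit(p_anc) + slope * z_site)`` where z is the coupled
      predictor standardized over sites.
    * Haplotype alleles within an LD block reuse a shared latent uniform per
      individual and chromosome copy, refreshed per locus with probability
      ``block_refresh``; dosage is the sum over the two copies.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pops * cfg.n_per_pop

    sites = [f"site{p + 1:02d}" for p in range(cfg.n_pops)]
    pop_of_ind = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)
    individuals = pd.DataFrame(
        {
            "id": [f"g{i + 1:04d}" for i in range(n)],
            "population": [f"pop{p + 1:02d}" for p in pop_of_ind],
            "site": [sites[p] for p in pop_of_ind],
        }
    )

    # ancestry: per-population mean on a gradient, Beta-distributed individuals
    pop_means = np.linspace(0.15, 0.9, cfg.n_pops)
    rng.shuffle(pop_means)
    a = cfg.admixture_alpha
    q_sativa = rng.beta(
        a * pop_means[pop_of_ind], a * (1.0 - pop_means[pop_of_ind])
    )
    q_sativa = np.clip(q_sativa, 1e-6, 1.0 - 1e-6)
    true_Q = np.column_stack([q_sativa, 1.0 - q_sativa])

    p_A, p_B = simulate_ancestral_freqs(cfg.n_loci, cfg.fst, rng)
    loci = _place_loci(cfg, rng)
    # loci inside an LD block share one haplotype allele (below), which only
    # induces correlation if they also share allele frequencies: copy the
    # first member's pool frequencies across each block
    block = _block_ids(loci, cfg.block_len_bp, rng)
    first_of_block = pd.Series(np.arange(cfg.n_loci)).groupby(block).transform("first")
    p_A, p_B = p_A[first_of_block], p_B[first_of_block]
    env = _simulate_environment(cfg, sites, rng)

    # plant adaptive loci: site-level frequency driven by one predictor
    adaptive_idx = rng.choice(cfg.n_loci, size=cfg.n_adaptive, replace=False)
    predictors = list(cfg.env_spec.keys())
    adaptive = []
    # individual x locus allele frequency
    F = q_sativa[:, None] * p_A[None, :] + (1.0 - q_sativa[:, None]) * p_B[None, :]
    env_std = (env.data - env.data.mean()) / env.data.std(ddof=0)
    p_mid = 0.5 * (p_A + p_B)
    for li in adaptive_idx:
        pred = predictors[rng.integers(0, len(predictors))]
        z = env_std[pred].to_numpy()  # per site
        f_site = expit(logit(np.clip(p_mid[li], 0.02, 0.98)) + cfg.adaptive_slope * z)
        F[:, li] = f_site[pop_of_ind]
        adaptive.append((int(li), pred, float(cfg.adaptive_slope)))

    # haplotype sampling with block-wise latent reuse
    dosages = np.zeros((n, cfg.n_loci), dtype=np.int8)
    for copy in range(2):
        u_block = {}
        u = np.empty((n, cfg.n_loci))
        for j in range(cfg.n_loci):
            b = block[j]
            if b not in u_block:
                u_block[b] = rng.random(n)
            fresh = rng.random(n) < cfg.block_refresh
            col = u_block[b].copy()
            col[fresh] = rng.random(int(fresh.sum()))
            u[:, j] = col
        dosages += (u < F).astype(np.int8)

    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = MISSING

    G = GenotypeMatrix(dosages, loci, individuals)

    # phenotypes: affine in sativa ancestry plus noise
    pheno = {"id": individuals["id"]}
    slopes = {}
    for trait, (intercept, slope, noise_sd) in cfg.pheno_spec.items():
        pheno[trait] = intercept + slope * q_sativa + rng.normal(0.0, noise_sd, size=n)
        slopes[trait] = slope
    pheno_df = pd.DataFrame(pheno).set_index("id")

    truth = TruthRecord(
        true_Q=true_Q,
        adaptive_loci=adaptive,
        block_len_bp=cfg.block_len_bp,
        pheno_slopes=slopes,
        gen_freqs=F,
    )
    return G, env, pheno_df, truth
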