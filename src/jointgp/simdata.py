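"""Synthetic two-population cohorts with a polygenic ordinal hip trait.

The generator emulates the structure the joint-population analysis assumes:
two Labrador-like populations descended from a common founder pool, diverged
by Wright-Fisher drift to a target F_ST (~0.03 by default), genotyped on a
shared SNP panel with distance-decaying linkage disequilibrium, and phenotyped
for a polygenic liability that is expressed as a Norberg angle per hip and
discretised to the UK-scheme 0-6 score.

Pipeline
--------
1. ``generate_founder_haplotypes`` - a small set of ancestral haplotypes is
   recombined through several generations of random mating; limited founder
   number creates background LD and recombination makes it decay with
   distance (uniform crossover rate per bp).
2. ``diverge_populations`` - two populations drift independently for
   ``drift_generations`` at ``effective_size`` diploids per generation
   (binomial resampling with re-pairing and recombination).  The expected
   differentiation is approximately ``1 - (1 - 1/(2 Ne))**g``, which is how
   the defaults (Ne = 100, g = 6) are calibrated to F_ST around 0.03.
3. ``simulate_trait`` - ``n_qtl`` markers get Gaussian effects; the genetic
   values are rescaled so the heritability of the left/right-mean trait is
   ``target_h2`` on the underlying (angle) scale; dog-level and hip-level
   residuals are balanced so the left/right score correlation is about 0.6.
   Larger liability means a smaller Norberg angle and hence a larger score.

All randomness descends from the single ``SimConfig.seed`` through
deterministically spawned substreams: identical configs give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genio import GenotypeDataset, ScoreScale, angle_to_score

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "generate_founder_haplotypes",
    "diverge_populations",
    "simulate_trait",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults are desk-scale: 600 + 150 dogs, 2,000 SNPs on 38 autosome-like
    chromosomes, drift calibrated for F_ST ~ 0.03, h2 = 0.3, and an angle
    distribution whose derived scores are concentrated at 2 or below.
    """

    n_pop1: int = 600
    n_pop2: int = 150
    n_snps: int = 2000
    n_chromosomes: int = 38
    chrom_length_bp: int = 60_000_000
    n_qtl: int = 200
    target_h2: float = 0.3
    drift_generations: int = 6
    effective_size: int = 100
    sex_effect: float = 0.05
    origin_effect: float = 0.0
    angle_mean: float = 104.0
    angle_sd: float = 9.0
    # within-dog liability correlation; 0.70 yields a derived left/right
    # *score* correlation of ~0.6 after discretisation
    lr_correlation: float = 0.70
    recomb_rate_per_bp: float = 1e-8
    n_ancestral_haplotypes: int = 40
    founder_generations: int = 20
    hidden_qtl: bool = False
    seed: int = 0

    def __post_init__(self):
        counts = dict(
            n_pop1=self.n_pop1, n_pop2=self.n_pop2, n_snps=self.n_snps,
            n_chromosomes=self.n_chromosomes, chrom_length_bp=self.chrom_length_bp,
            effective_size=self.effective_size,
        )
        for k, v in counts.items():
            if v <= 0:
                raise ValueError(f"{k} must be positive")
        if not (0.0 <= self.target_h2 <= 1.0):
            raise ValueError("target_h2 must be in [0, 1]")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        if self.n_qtl < 0 or self.drift_generations < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.lr_correlation < 1.0):
            raise ValueError("lr_correlation must be in [0, 1)")


@dataclass
class HaplotypePool:
    """Phased haplotypes (2N x m, uint8) plus the shared marker map."""

    haplotypes: np.ndarray
    marker_map: pd.DataFrame
    recomb_fraction: np.ndarray  # per-adjacent-SNP crossover probability; 0.5 across chromosomes


@dataclass
class SimulatedCohort:
    genotypes: GenotypeDataset
    phenotypes: pd.DataFrame
    true_breeding_values: np.ndarray
    qtl_effects: pd.DataFrame
    realized_h2: float
    realized_fst: float
    config: SimConfig


def _marker_map(config: SimConfig) -> pd.DataFrame:
    """Distribute n_snps over chromosomes, remainder to the first ones."""
    base, rem = divmod(config.n_snps, config.n_chromosomes)
    rows = []
    for c in range(config.n_chromosomes):
        m_c = base + (1 if c < rem else 0)
        if m_c == 0:
            continue
        pos = np.linspace(1, config.chrom_length_bp, m_c + 2)[1:-1]
        pos = np.unique(np.round(pos).astype(np.int64))
        while len(pos) < m_c:  # collision guard for extreme densities
            pos = np.unique(np.concatenate([pos, [pos[-1] + 1]]))
        for p in pos[:m_c]:
            rows.append((f"snp{c + 1}_{p}", str(c + 1), int(p)))
    mm = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    mm["allele1"] = "A"
    mm["allele2"] = "B"
    return mm


def _recomb_fractions(mm: pd.DataFrame, rate: float) -> np.ndarray:
    """Crossover probability between consecutive SNPs; 0.5 across chromosome ends."""
    pos = mm["pos"].to_numpy(float)
    chrom = mm["chrom"].to_numpy(object)
    c = np.empty(len(mm))
    c[0] = 0.5
    dist = np.diff(pos)
    c[1:] = np.minimum(rate * dist, 0.5)
    c[1:][chrom[1:] != chrom[:-1]] = 0.5
    return c


def _recombine(haps: np.ndarray, n_children: int, cfrac: np.ndarray, rng) -> np.ndarray:
    """Produce child haplotypes as recombinant mosaics of random parent pairs."""
    nh = haps.shape[0]
    pa = rng.integers(0, nh, size=n_children)
    pb = rng.integers(0, nh, size=n_children)
    cross = rng.random((n_children, len(cfrac))) < cfrac
    which = np.cumsum(cross, axis=1) % 2
    return np.where(which == 0, haps[pa], haps[pb]).astype(np.uint8)


def generate_founder_haplotypes(config: SimConfig) -> HaplotypePool:
    """Founder haplotype pool with distance-decaying LD, frequencies in (0, 1).

    A small number of ancestral haplotypes is dropped through
    ``founder_generations`` rounds of random mating with recombination at
    ``recomb_rate_per_bp``; long-range random LD created by the limited
    ancestral pool decays each generation, short-range LD persists.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mm = _marker_map(config)
    cfrac = _recomb_fractions(mm, config.recomb_rate_per_bp)
    m = len(mm)
    freqs = rng.uniform(0.1, 0.9, size=m)
    ancestral = (rng.random((config.n_ancestral_haplotypes, m)) < freqs).astype(np.uint8)
    pool_size = max(2 * config.effective_size, config.n_ancestral_haplotypes)
    haps = ancestral
    for _ in range(config.founder_generations):
        haps = _recombine(haps, pool_size, cfrac, rng)
    # rescue loci lost to drift (or absent from the ancestral set) with a
    # single low-frequency variant so every frequency lies in (0, 1)
    p = haps.mean(axis=0)
    for j in np.flatnonzero((p == 0) | (p == 1)):
        i = rng.integers(0, pool_size)
        haps[i, j] ^= 1
    return HaplotypePool(haps, mm, cfrac)


def _drift(haps: np.ndarray, generations: int, ne: int, cfrac: np.ndarray, rng) -> np.ndarray:
    for _ in range(generations):
        haps = _recombine(haps, 2 * ne, cfrac, rng)
    return haps


def diverge_populations(pool: HaplotypePool, config: SimConfig) -> GenotypeDataset:
    """Two populations drifted independently from the founder pool.

    Each population drifts for ``drift_generations`` at ``effective_size``
    diploids and is then expanded by one generation of random mating to
    ``n_pop`` individuals.  Raises if drift has fixed every marker.
    """
    rng1 = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rng2 = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    dosages, ids, meta_rows = [], [], []
    for label, n_pop, rng in (("POP1", config.n_pop1, rng1), ("POP2", config.n_pop2, rng2)):
        haps = _drift(pool.haplotypes, config.drift_generations, config.effective_size,
                      pool.recomb_fraction, rng)
        h1 = _recombine(haps, n_pop, pool.recomb_fraction, rng)
        h2 = _recombine(haps, n_pop, pool.recomb_fraction, rng)
        dosages.append((h1 + h2).astype(float))
        sexes = rng.choice(["M", "F"], size=n_pop)
        for i in range(n_pop):
            ids.append(f"{label}_{i + 1:04d}")
            meta_rows.append({"sex": sexes[i], "origin": label})
    X = np.vstack(dosages)
    p = X.mean(axis=0) / 2.0
    if np.all((p == 0) | (p == 1)):
        raise ValueError(
            "excess drift: every marker is monomorphic in the sampled cohort "
            f"(drift_generations={config.drift_generations}, Ne={config.effective_size})"
        )
    meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="sample_id"))
    return GenotypeDataset(np.array(ids, object), meta, pool.marker_map.copy(), X)


def simulate_trait(
    genotypes: GenotypeDataset,
    config: SimConfig,
    scale: ScoreScale | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Polygenic liability -> per-hip Norberg angles -> UK-scheme scores.

    Returns ``(phenotypes, true_breeding_values, qtl_effects)``.  The liability
    is expressed in score units; the angle of each hip is the affine map
    ``angle = upper_healthy - band_width * liability`` so that larger genetic
    liability gives a smaller angle and a larger score.  Residual variance is
    split into a dog-level and a hip-level part such that (i) the heritability
    of the left/right mean is ``target_h2`` and (ii) the left/right
    correlation is ``lr_correlation``.
    """
    scale = scale or ScoreScale()
    band = (scale.upper_healthy - scale.lower_severe) / 6.0  # degrees per score unit
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n, m = genotypes.dosages.shape
    h2, rho = config.target_h2, config.lr_correlation
    sd_liab = config.angle_sd / band              # per-hip liability sd, score units
    t_var = sd_liab ** 2                          # per-hip total variance
    vg = t_var * h2 * (1.0 + rho) / 2.0
    if vg > rho * t_var + 1e-12:
        raise ValueError(
            f"target_h2={h2} incompatible with lr_correlation={rho}: "
            "required dog-level residual variance is negative"
        )
    if h2 > 0 and config.n_qtl == 0:
        raise ValueError("target_h2 > 0 requires n_qtl > 0")

    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    effects = rng.standard_normal(config.n_qtl)
    g_raw = genotypes.dosages[:, qtl_idx] @ effects
    sd_raw = g_raw.std()
    if vg > 0 and sd_raw > 0:
        scale_a = np.sqrt(vg) / sd_raw
        effects = effects * scale_a
        g = (g_raw - g_raw.mean()) * scale_a
    else:
        effects = np.zeros(config.n_qtl)
        g = np.zeros(n)
    var_dog = max(rho * t_var - g.var(), 0.0)
    var_hip = max((1.0 - rho) * t_var, 0.0)
    e_dog = rng.standard_normal(n) * np.sqrt(var_dog)
    e_left = rng.standard_normal(n) * np.sqrt(var_hip)
    e_right = rng.standard_normal(n) * np.sqrt(var_hip)

    meta = genotypes.sample_meta
    sex_term = np.where(meta["sex"].to_numpy() == "F", config.sex_effect, 0.0)
    origin_term = np.where(meta["origin"].to_numpy() == "POP2", config.origin_effect, 0.0)
    mu = (scale.upper_healthy - config.angle_mean) / band
    liab_l = mu + sex_term + origin_term + g + e_dog + e_left
    liab_r = mu + sex_term + origin_term + g + e_dog + e_right
    angle_l = scale.upper_healthy - band * liab_l
    angle_r = scale.upper_healthy - band * liab_r
    score_l = np.asarray(angle_to_score(angle_l, scale), float)
    score_r = np.asarray(angle_to_score(angle_r, scale), float)

    pheno = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "sex": meta["sex"].to_numpy(),
            "origin": meta["origin"].to_numpy(),
            "angle_left": angle_l,
            "angle_right": angle_r,
            "score_left": score_l,
            "score_right": score_r,
            "score_mean": (score_l + score_r) / 2.0,
            "true_bv": g,
        }
    )
    qtl = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids[qtl_idx],
            "effect": effects,
        }
    )
    return pheno, g, qtl


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """End-to-end cohort simulation; records realized F_ST and h2."""
    from .relmat import fst as _fst

    pool = generate_founder_haplotypes(config)
    genotypes = diverge_populations(pool, config)
    pheno, g, qtl = simulate_trait(genotypes, config)
    if config.hidden_qtl and config.n_qtl > 0:
        keep = ~np.isin(genotypes.snp_ids, qtl["snp_id"].to_numpy())
        genotypes = genotypes.subset_snps(genotypes.snp_ids[keep])
    labels = genotypes.sample_meta["origin"].to_numpy()
    try:
        _, realized_fst = _fst(genotypes, labels)
    except ValueError:
        realized_fst = float("nan")
    # realized h2 of the mean trait: Var(g) over total variance of the mean angle
    # mapped back to liability units (fixed-effect variance is negligible here)
    band_var = np.var(
        (pheno[["angle_left", "angle_right"]].to_numpy().mean(axis=1)), ddof=1
    )
    vg = float(np.var(g, ddof=1))
    scale = ScoreScale()
    band = (scale.upper_healthy - scale.lower_severe) / 6.0
    realized_h2 = vg / (band_var / band ** 2) if band_var > 0 else float("nan")
    return SimulatedCohort(genotypes, pheno, g, qtl, realized_h2, realized_fst, config)
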