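"""Haplotype-block estimation and genome coverage of SNP subsets.

Blocks are found with a simplified Gabriel et al. procedure, the approach
behind PLINK's --blocks: for every intra-chromosomal SNP pair within a span
limit, two-SNP haplotype frequencies are estimated from unphased genotypes by
EM, D' is computed, and a one-sided 90% confidence interval for |D'| is
obtained by likelihood profiling over a D' grid (Haploview-style).  A pair is

* in *strong LD*       when CI_low >= 0.70 and CI_high >= 0.98;
* showing *strong recombination* when CI_high < 0.90;

(thresholds configurable).  Candidate spans whose informative pairs are at
least 95% strong-LD — with the outermost pair itself strong-LD — are accepted
greedily, longest first, without overlap; ties break to the leftmost start.

Genome coverage of a SNP subset is the summed bp span of blocks containing at
least one subset SNP divided by the total span of all blocks (the block span
is the denominator, not the chromosome length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeDataset

__all__ = [
    "HaplotypeBlockSet",
    "BlockCIParams",
    "em_haplotype_freqs",
    "dprime_confidence_interval",
    "estimate_blocks",
    "coverage_fraction",
    "write_blocks",
]


@dataclass(frozen=True)
class BlockCIParams:
    """Thresholds of the Gabriel-style pair classification."""

    strong_low: float = 0.70     # lower CI bound for strong LD
    strong_high: float = 0.98    # upper CI bound for strong LD
    recomb_high: float = 0.90    # upper CI bound below this = strong recombination
    strong_fraction: float = 0.95
    ci_mass: float = 0.05        # one-sided 5% tails -> 90% interval
    grid: int = 201


@dataclass
class HaplotypeBlockSet:
    """Non-overlapping blocks (chromosome, start bp, end bp, member SNPs)."""

    table: pd.DataFrame  # chrom, start, end, n_snps, snp_ids (list)

    @property
    def total_span(self) -> float:
        if len(self.table) == 0:
            return 0.0
        return float((self.table["end"] - self.table["start"] + 1).sum())

    def span_by_chromosome(self) -> pd.Series:
        spans = self.table["end"] - self.table["start"] + 1
        return spans.groupby(self.table["chrom"]).sum()


def em_haplotype_freqs(geno_i: np.ndarray, geno_j: np.ndarray,
                       max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """EM haplotype frequencies (f11, f12, f21, f22) for two unphased SNPs.

    Dosages in {0,1,2} (missing dropped pairwise); "1" denotes the first
    allele of each SNP.  Only double heterozygotes are ambiguous; with none
    present the EM solution equals direct haplotype counting.
    """
    ok = ~(np.isnan(geno_i) | np.isnan(geno_j))
    gi, gj = geno_i[ok].astype(int), geno_j[ok].astype(int)
    n = len(gi)
    if n == 0:
        raise ValueError("no complete genotype pairs")
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi, gj), 1)
    # known haplotype contributions; x = P(coupling | double het)
    f = np.array([0.25, 0.25, 0.25, 0.25])
    ndh = counts[1, 1]
    base = np.array(
        [
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],   # hap 11
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0],   # hap 12
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],   # hap 21
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],   # hap 22
        ],
        dtype=float,
    )
    for _ in range(max_iter):
        p_coupling = f[0] * f[3]
        p_repulsion = f[1] * f[2]
        tot = p_coupling + p_repulsion
        x = 0.5 if tot <= 0 else p_coupling / tot
        new = base + ndh * np.array([x, 1 - x, 1 - x, x])
        new /= 2.0 * n
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def _dprime(f: np.ndarray) -> float:
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    D = f[0] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    return 0.0 if dmax <= 0 else D / dmax


def dprime_confidence_interval(
    geno_i: np.ndarray, geno_j: np.ndarray, params: BlockCIParams = BlockCIParams()
) -> tuple[float, float, float]:
    """(|D'| MLE, CI low, CI high) by likelihood profiling over a |D'| grid.

    Allele frequencies are fixed at their sample values; the multinomial
    likelihood of the nine two-SNP genotype classes is evaluated on a grid of
    |D'| in the sign orientation of the EM estimate, normalised, and the
    5th/95th percentile of the resulting profile taken as the bounds
    (Haploview's approach).
    """
    ok = ~(np.isnan(geno_i) | np.isnan(geno_j))
    gi, gj = geno_i[ok].astype(int), geno_j[ok].astype(int)
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi, gj), 1)
    n = counts.sum()
    pA = (2 * (counts[2, :].sum()) + counts[1, :].sum()) / (2 * n)
    pB = (2 * (counts[:, 2].sum()) + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic SNP in pair")
    f = em_haplotype_freqs(geno_i, geno_j)
    dp = _dprime(f)
    sign = 1.0 if dp >= 0 else -1.0
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    grid = np.linspace(0.0, 1.0, params.grid)
    loglik = np.full(len(grid), -np.inf)
    for idx, dprime_val in enumerate(grid):
        D = sign * dprime_val * dmax
        f11 = pA * pB + D
        f12 = pA * (1 - pB) - D
        f21 = (1 - pA) * pB - D
        f22 = (1 - pA) * (1 - pB) + D
        h = np.clip(np.array([f11, f12, f21, f22]), 1e-12, None)
        # genotype-class probabilities from haplotype pairs
        P = np.zeros((3, 3))
        P[2, 2] = h[0] ** 2
        P[2, 1] = 2 * h[0] * h[1]
        P[2, 0] = h[1] ** 2
        P[1, 2] = 2 * h[0] * h[2]
        P[1, 1] = 2 * (h[0] * h[3] + h[1] * h[2])
        P[1, 0] = 2 * h[1] * h[3]
        P[0, 2] = h[2] ** 2
        P[0, 1] = 2 * h[2] * h[3]
        P[0, 0] = h[3] ** 2
        loglik[idx] = np.sum(counts * np.log(np.clip(P, 1e-300, None)))
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cum = np.cumsum(w)
    low = float(grid[np.searchsorted(cum, params.ci_mass)])
    high = float(grid[min(np.searchsorted(cum, 1.0 - params.ci_mass), len(grid) - 1)])
    return abs(dp), low, high


def estimate_blocks(
    d: GenotypeDataset,
    max_span_bp: int = 200_000,
    ci_params: BlockCIParams = BlockCIParams(),
) -> HaplotypeBlockSet:
    """Gabriel-style haplotype blocks from unphased genotypes.

    Pairs within ``max_span_bp`` on the same chromosome are classified by the
    D' confidence interval; maximal spans whose informative pairs are >= 95%
    strong-LD (outermost pair included) are accepted longest-first without
    overlap.  Chromosomes with fewer than two SNPs yield no blocks.  Requires
    at least 10 individuals for meaningful CIs.
    """
    if d.n_samples < 10:
        raise ValueError("need >= 10 individuals for block estimation")
    mm = d.marker_map
    for chrom, grp in mm.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise ValueError(f"marker map unsorted on chromosome {chrom}")
    X = d.dosages
    rows = []
    for chrom, grp in mm.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        m = len(idx)
        if m < 2:
            continue
        # classify all in-span pairs: +1 strong LD, -1 strong recomb, 0 uninformative
        cls = {}
        for a in range(m):
            for b in range(a + 1, m):
                if pos[b] - pos[a] > max_span_bp:
                    break
                try:
                    _, lo, hi = dprime_confidence_interval(X[:, idx[a]], X[:, idx[b]], ci_params)
                except ValueError:
                    cls[(a, b)] = 0
                    continue
                if lo >= ci_params.strong_low and hi >= ci_params.strong_high:
                    cls[(a, b)] = 1
                elif hi < ci_params.recomb_high:
                    cls[(a, b)] = -1
                else:
                    cls[(a, b)] = 0
        # candidate spans: endpoints in strong LD
        cand = []
        for (a, b), v in cls.items():
            if v != 1:
                continue
            pairs = [cls.get((i, j), 0) for i in range(a, b + 1) for j in range(i + 1, b + 1)
                     if (i, j) in cls]
            informative = [v2 for v2 in pairs if v2 != 0]
            if not informative:
                continue
            frac = sum(v2 == 1 for v2 in informative) / len(informative)
            if frac >= ci_params.strong_fraction:
                cand.append((pos[b] - pos[a], pos[a], a, b))
        cand.sort(key=lambda t: (-t[0], t[1]))
        used = np.zeros(m, bool)
        for span, start, a, b in cand:
            if used[a:b + 1].any():
                continue
            used[a:b + 1] = True
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[a]),
                    "end": int(pos[b]),
                    "n_snps": b - a + 1,
                    "snp_ids": list(grp["snp_id"].iloc[a:b + 1]),
                }
            )
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "snp_ids"])
    if len(table):
        table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
    return HaplotypeBlockSet(table)


def coverage_fraction(blocks: HaplotypeBlockSet, subset_snp_ids) -> tuple[float, pd.Series]:
    """Fraction of total block span covered by blocks holding >= 1 subset SNP.

    Returns ``(genome_wide, per_chromosome)``; the denominator is the summed
    span of all blocks.  Raises when no blocks exist (coverage undefined).
    """
    if len(blocks.table) == 0:
        raise ValueError("no haplotype blocks: coverage undefined")
    subset = set(subset_snp_ids)
    spans = (blocks.table["end"] - blocks.table["start"] + 1).astype(float)
    hit = blocks.table["snp_ids"].apply(lambda ids: bool(subset.intersection(ids)))
    genome = float(spans[hit].sum() / spans.sum())
    per_chrom = spans[hit].groupby(blocks.table["chrom"]).sum().reindex(
        spans.groupby(blocks.table["chrom"]).sum().index, fill_value=0.0
    ) / spans.groupby(blocks.table["chrom"]).sum()
    return genome, per_chrom


def write_blocks(blocks: HaplotypeBlockSet, path) -> None:
    """PLINK .blocks.det-style TSV (chr, bp1, bp2, kb, nsnps, snps)."""
    tab = blocks.table.copy()
    tab["kb"] = (tab["end"] - tab["start"] + 1) / 1000.0
    tab["snps"] = tab["snp_ids"].apply("|".join)
    tab[["chrom", "start", "end", "kb", "n_snps", "snps"]].to_csv(
        path, sep="\t", index=False,
        header=["CHR", "BP1", "BP2", "KB", "NSNPS", "SNPS"],
    )
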