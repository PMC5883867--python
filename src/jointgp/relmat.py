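"""Genomic relationships: VanRaden GRM, PCA stratification, F_ST, LD consistency.

The genomic relationship matrix follows VanRaden's Method 1,

    G = Z Z' / (2 * sum_i p_i (1 - p_i)),

with Z the dosage matrix column-centred by twice the allele frequency.  Missing
dosages are mean-imputed before centring (so they contribute zero to Z).  A
small ridge (0.01 by default downstream) is added to the diagonal to guarantee
invertibility in mixed-model equations.

Population differentiation uses the Weir & Cockerham (1984) theta estimator
with ratio-of-averages aggregation, matching PLINK's --fst behaviour for two
populations.  Cross-population LD consistency is the Pearson correlation,
across shared intra-chromosomal SNP pairs within a window, of the signed
genotype-dosage correlations computed separately in each population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeDataset, allele_frequencies

__all__ = [
    "GRM",
    "PCAResult",
    "compute_grm",
    "grm_group_summary",
    "pca",
    "split_by_pc",
    "fst",
    "ld_consistency",
    "write_grm",
    "read_grm",
]


@dataclass
class GRM:
    """Genomic relationship matrix with its construction provenance.

    ``matrix`` includes the ridge on the diagonal; ``allele_freqs`` are the
    frequencies used for centring (in-sample or supplied), ``snp_ids`` the
    markers that entered Z.
    """

    matrix: np.ndarray
    sample_ids: np.ndarray
    allele_freqs: np.ndarray
    snp_ids: np.ndarray
    ridge: float = 0.0

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} absent from GRM") from None

    def block(self, row_ids, col_ids=None) -> np.ndarray:
        ri = self.index_of(row_ids)
        ci = ri if col_ids is None else self.index_of(col_ids)
        return self.matrix[np.ix_(ri, ci)]


def compute_grm(
    d: GenotypeDataset,
    freqs: np.ndarray | None = None,
    ridge: float = 0.0,
) -> GRM:
    """VanRaden Method 1 GRM; ``freqs`` supplies external allele frequencies.

    With in-sample frequencies and zero ridge the matrix is doubly centred:
    the sum of all entries is 0.  Raises if no SNP is polymorphic under the
    chosen frequencies (zero scaling denominator).
    """
    p = allele_frequencies(d) if freqs is None else np.asarray(freqs, dtype=float)
    if len(p) != d.n_snps:
        raise ValueError("allele frequency vector length mismatch")
    denom = 2.0 * np.nansum(p * (1.0 - p))
    if not denom > 0:
        raise ValueError("all SNPs monomorphic: zero VanRaden denominator")
    X = d.dosages.copy()
    # mean-fill missing with 2p so they contribute 0 after centring
    miss = np.isnan(X)
    if miss.any():
        X[miss] = np.broadcast_to(2.0 * p, X.shape)[miss]
    Z = X - 2.0 * p
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    if ridge:
        G[np.diag_indices_from(G)] += ridge
    return GRM(G, d.sample_ids.copy(), p, d.snp_ids.copy(), float(ridge))


def grm_group_summary(g: GRM, groups: dict) -> pd.DataFrame:
    """Mean/sd of diagonal and off-diagonal GRM entries by group and group pair.

    ``groups`` maps group label -> iterable of sample ids partitioning the
    samples.  Off-diagonal summaries within a singleton group are reported as
    NaN.  The diagonal reported here includes any ridge in ``g``.
    """
    labels = list(groups)
    idx = {k: g.index_of(v) for k, v in groups.items()}
    all_idx = np.concatenate(list(idx.values()))
    if len(all_idx) != len(set(all_idx)) or len(all_idx) != len(g.sample_ids):
        raise ValueError("groups must partition the GRM samples")
    rows = []
    for k in labels:
        di = np.diag(g.matrix)[idx[k]]
        rows.append({"group": k, "kind": "diagonal", "mean": di.mean(), "sd": di.std(ddof=1) if di.size > 1 else np.nan, "n": di.size})
    for i, a in enumerate(labels):
        for b in labels[i:]:
            if a == b:
                ia = idx[a]
                if len(ia) < 2:
                    mean = sd = np.nan
                    n = 0
                else:
                    sub = g.matrix[np.ix_(ia, ia)]
                    vals = sub[np.triu_indices(len(ia), k=1)]
                    mean, sd, n = vals.mean(), vals.std(ddof=1) if vals.size > 1 else np.nan, vals.size
            else:
                vals = g.matrix[np.ix_(idx[a], idx[b])].ravel()
                mean, sd, n = vals.mean(), vals.std(ddof=1) if vals.size > 1 else np.nan, vals.size
            rows.append({"group": f"{a}-{b}", "kind": "off_diagonal", "mean": mean, "sd": sd, "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray          # n x k, eigenvector * sqrt(eigenvalue)
    explained_fraction: np.ndarray
    sample_ids: np.ndarray
    eigenvalues: np.ndarray


def pca(d: GenotypeDataset, k: int = 10, standardize: str = "plink") -> PCAResult:
    """Principal components of the marker matrix.

    ``standardize='plink'`` divides each centred dosage column by
    sqrt(2 p (1-p)) (variance standardisation, PLINK's --pca convention);
    ``standardize='vanraden'`` uses the global VanRaden scaling, i.e. the
    eigendecomposition of the ridge-free GRM.  Scores are eigenvectors scaled
    by the square root of their eigenvalues; explained fractions are
    eigenvalues over the trace.
    """
    n = d.n_samples
    if k >= n:
        raise ValueError("k must be < number of samples")
    p = allele_frequencies(d)
    X = d.dosages.copy()
    miss = np.isnan(X)
    if miss.any():
        X[miss] = np.broadcast_to(2.0 * p, X.shape)[miss]
    Z = X - 2.0 * p
    if standardize == "plink":
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = np.sqrt(2.0 * p * (1.0 - p))
        poly = sd > 0
        Z = Z[:, poly] / sd[poly]
        K = (Z @ Z.T) / poly.sum()
    elif standardize == "vanraden":
        K = (Z @ Z.T) / (2.0 * np.nansum(p * (1.0 - p)))
    else:
        raise ValueError(f"unknown standardization {standardize!r}")
    K = (K + K.T) / 2.0
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > 1e-9 * max(evals.max(), 1.0)))
    if k > rank:
        k = rank
    trace = np.sum(np.clip(evals, 0, None))
    scores = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0, None))
    return PCAResult(scores, np.clip(evals[:k], 0, None) / trace, d.sample_ids.copy(), evals[:k])


def split_by_pc(result: PCAResult, which_pc: int = 0, groups: int = 2) -> list:
    """Partition samples into contiguous rank blocks along one PC score.

    Samples are ranked by the chosen component's score (ties broken by sample
    id) and cut into ``groups`` near-equal blocks, larger blocks first.
    Returns a list of sample-id arrays.
    """
    if groups < 2:
        raise ValueError("need at least 2 groups")
    score = result.scores[:, which_pc]
    order = np.lexsort((result.sample_ids.astype(str), score))
    n = len(order)
    base, rem = divmod(n, groups)
    sizes = [base + (1 if i < rem else 0) for i in range(groups)]
    out, start = [], 0
    for s in sizes:
        out.append(result.sample_ids[order[start:start + s]])
        start += s
    return out


# ---------------------------------------------------------------------------
# F_ST (Weir & Cockerham 1984, two populations)
# ---------------------------------------------------------------------------

def fst(d: GenotypeDataset, pop_labels) -> tuple[pd.DataFrame, float]:
    """Weir-Cockerham theta per SNP and the genome-wide ratio-of-averages mean.

    ``pop_labels`` is a per-sample array with exactly two distinct labels.
    Per-SNP variance components a (between), b (within, between-individual)
    and c (heterozygote) follow Weir & Cockerham (1984); the mean is
    sum(a) / sum(a+b+c) over SNPs with defined components.
    """
    pop_labels = np.asarray(pop_labels)
    pops = np.unique(pop_labels)
    if len(pops) != 2:
        raise ValueError(f"need exactly two populations, got {list(pops)}")
    masks = [pop_labels == p for p in pops]
    if any(m.sum() == 0 for m in masks):
        raise ValueError("a population is empty")
    r = 2
    X = d.dosages
    n_i = np.stack([np.sum(~np.isnan(X[m]), axis=0) for m in masks])      # 2 x m
    with np.errstate(invalid="ignore"):
        p_i = np.stack([np.nanmean(X[m], axis=0) / 2.0 for m in masks])
        h_i = np.stack([np.nanmean(X[m] == 1.0, axis=0) for m in masks])
    valid = (n_i >= 2).all(axis=0)
    nsum = n_i.sum(axis=0)
    nbar = nsum / r
    nc = (nsum - (n_i ** 2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / nsum
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / nsum
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        theta = a / (a + b + c)
    defined = valid & np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & ((a + b + c) != 0)
    per_snp = pd.DataFrame(
        {
            "snp_id": d.snp_ids,
            "a": a, "b": b, "c": c,
            "theta": np.where(defined, theta, np.nan),
        }
    )
    if defined.sum() == 0:
        raise ValueError("no SNP with defined F_ST components")
    mean_fst = float(a[defined].sum() / (a + b + c)[defined].sum())
    return per_snp, mean_fst


# ---------------------------------------------------------------------------
# Cross-population LD consistency
# ---------------------------------------------------------------------------

def _pair_indices(marker_map: pd.DataFrame, window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = [], []
    for _, grp in marker_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        gi = grp.index.to_numpy()
        for a in range(len(pos)):
            b = np.searchsorted(pos, pos[a] + window_bp, side="right")
            ii.append(np.full(b - a - 1, gi[a]))
            jj.append(gi[a + 1:b])
    if not ii:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(ii).astype(int), np.concatenate(jj).astype(int)


def _dosage_corr(X: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    Xc = X - np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(Xc), 0.0, Xc)
    sd = np.sqrt((Xc ** 2).mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (Xc[:, ii] * Xc[:, jj]).mean(axis=0)
        return num / (sd[ii] * sd[jj])


def ld_consistency(
    a: GenotypeDataset,
    b: GenotypeDataset,
    window_bp: int = 1_000_000,
    maf_floor: float = 0.05,
) -> tuple[float, int]:
    """Correlation of signed pairwise LD (genotype r) between two populations.

    Both datasets must carry the same marker map.  For each intra-chromosome
    SNP pair within ``window_bp`` whose MAF exceeds ``maf_floor`` in both
    populations, the signed dosage correlation r is computed in each
    population with a consistent reference allele; the returned value is the
    Pearson correlation across pairs of the two r vectors, with the pair
    count.  Allele orientation is harmonised internally, so flipping a SNP's
    coding in one input does not change the result.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not a.marker_map[["chrom", "pos"]].equals(b.marker_map[["chrom", "pos"]]):
        raise ValueError("datasets must share a marker map")
    # harmonise orientation of b onto a's allele1
    Xb = b.dosages.copy()
    swap = (
        (a.marker_map["allele1"].to_numpy(object) == b.marker_map["allele2"].to_numpy(object))
        & (a.marker_map["allele2"].to_numpy(object) == b.marker_map["allele1"].to_numpy(object))
    )
    Xb[:, swap] = 2.0 - Xb[:, swap]
    pa = allele_frequencies(a)
    pb = np.nanmean(Xb, axis=0) / 2.0
    ok = (np.minimum(pa, 1 - pa) > maf_floor) & (np.minimum(pb, 1 - pb) > maf_floor)
    mm = a.marker_map.loc[ok].reset_index(drop=True)
    ii, jj = _pair_indices(mm, window_bp)
    if len(ii) == 0:
        raise ValueError("no qualifying SNP pairs in window")
    ra = _dosage_corr(a.dosages[:, ok.to_numpy() if hasattr(ok, "to_numpy") else ok], ii, jj)
    rb = _dosage_corr(Xb[:, ok.to_numpy() if hasattr(ok, "to_numpy") else ok], ii, jj)
    good = np.isfinite(ra) & np.isfinite(rb)
    if good.sum() < 2:
        raise ValueError("too few informative pairs")
    corr = float(np.corrcoef(ra[good], rb[good])[0, 1])
    return corr, int(good.sum())


# ---------------------------------------------------------------------------
# GRM I/O: full symmetric TSV and GCTA-style lower triangle
# ---------------------------------------------------------------------------

def write_grm(g: GRM, prefix) -> None:
    from pathlib import Path

    prefix = Path(prefix)
    pd.DataFrame(g.matrix, index=g.sample_ids, columns=g.sample_ids).to_csv(
        prefix.with_suffix(".grm.tsv"), sep="\t"
    )
    pd.Series(g.sample_ids).to_csv(
        prefix.with_suffix(".grm.id"), sep="\t", index=False, header=False
    )


def read_grm(prefix) -> GRM:
    """Read a GRM written by :func:`write_grm`, or GCTA lower-triangle text."""
    from pathlib import Path

    prefix = Path(prefix)
    full = prefix.with_suffix(".grm.tsv")
    if full.exists():
        df = pd.read_csv(full, sep="\t", index_col=0)
        ids = df.index.to_numpy(object)
        return GRM(df.to_numpy(float), ids, np.array([]), np.array([]), 0.0)
    tri = prefix.with_suffix(".grm.gz") if prefix.with_suffix(".grm.gz").exists() else prefix.with_suffix(".grm")
    ids = pd.read_csv(prefix.with_suffix(".grm.id"), sep="\t", header=None).iloc[:, -1].astype(str).to_numpy(object)
    n = len(ids)
    M = np.zeros((n, n))
    tab = pd.read_csv(tri, sep=r"\s+", header=None, names=["i", "j", "nsnp", "val"])
    M[tab["i"] - 1, tab["j"] - 1] = tab["val"]
    M = M + np.tril(M, -1).T
    return GRM(M, ids, np.array([]), np.array([]), 0.0)
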