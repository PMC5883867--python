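"""Single-SNP linear mixed-model association and SNP-subset preselection.

Each SNP is tested in the model

    y = W a + x_i b_i + u + e,   u ~ N(0, G sg2),  e ~ N(0, I se2),

i.e. the GBLUP model plus one SNP dosage covariate.  The polygenic variance
ratio lambda = sg2/se2 is estimated once on the null model (no SNP) and held
fixed across SNPs; the training G is eigendecomposed once, y, W and every x_i
are rotated into the eigenbasis, and each SNP reduces to weighted least
squares with weights 1/(lambda d_j + 1).  Significance is Wald's test,
t_i = b_i / se(b_i), with t_i^2 referred to a chi-square with one degree of
freedom.  SNP effects from the scan are used only to *rank* SNPs; prediction
always re-estimates effects jointly through GBLUP on the selected subset.

``subset_prediction_experiment`` nests the scan inside cross-validation: for
each fold the scan runs on training records only, the top (or random) fraction
of SNPs is selected, the relationship matrix is rebuilt from that subset alone
(joint allele frequencies restricted to the subset), the model is refitted and
the held-out fold predicted — the leakage-avoiding protocol in which ranking
never sees validation phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeDataset, allele_frequencies
from .relmat import GRM, compute_grm
from .varcomp import GBLUP, build_design
from .predict import CVConfig, make_folds, compute_metrics, _design_like

__all__ = [
    "GWASResult",
    "SNPSubset",
    "fit_lmm_gwas",
    "select_subset",
    "subset_prediction_experiment",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45,
                     0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95,
                     0.98, 1.00)


@dataclass
class GWASResult:
    """Per-SNP effects, Wald statistics and significance ranks.

    ``table`` columns: snp_id, chrom, pos, beta, se, wald, p, rank (ascending
    p, ties broken by genome order); SNPs constant in the training set carry
    NaN statistics and no rank.
    """

    table: pd.DataFrame
    lambda_ratio: float
    n_train: int

    def ranked_snp_ids(self) -> np.ndarray:
        """SNP ids by ascending p; untestable (constant) SNPs follow in genome order."""
        ranked = self.table.dropna(subset=["rank"]).sort_values("rank")
        unranked = self.table[self.table["rank"].isna()]
        return np.concatenate([ranked["snp_id"].to_numpy(object),
                               unranked["snp_id"].to_numpy(object)])


@dataclass
class SNPSubset:
    mode: str            # "preselected" | "random"
    fraction: float
    snp_ids: np.ndarray
    seed: int | None = None
    source: str | None = None


def fit_lmm_gwas(
    geno: GenotypeDataset,
    pheno: pd.DataFrame,
    grm: GRM,
    sample_ids=None,
    response: str = "score_mean",
    covariates: tuple = ("sex", "origin"),
    lambda_ratio: float | None = None,
    per_snp_lambda: bool = False,
) -> GWASResult:
    """Mixed-model scan of every SNP on the training samples.

    ``lambda_ratio`` (sg2/se2) defaults to the null-model AI-REML estimate on
    the same training set.  With ``per_snp_lambda`` the ratio is re-optimised
    for each SNP by maximising the rotated restricted likelihood (slower;
    ranking is insensitive to it at desk scale).  With ``lambda_ratio=0`` the
    scan reduces to ordinary least squares.
    """
    indexed = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    if sample_ids is None:
        sample_ids = [s for s in indexed.index if s in set(geno.sample_ids)]
    sample_ids = list(sample_ids)
    meta = indexed.loc[sample_ids]
    y = meta[response].to_numpy(float)
    W, _ = build_design(meta, covariates)
    n, k = W.shape
    G = grm.block(sample_ids)
    if lambda_ratio is None:
        fit = GBLUP(y, W, G).fit()
        lambda_ratio = fit.sigma_g2 / fit.sigma_e2 if fit.sigma_e2 > 0 else np.inf
    d, U = np.linalg.eigh((G + G.T) / 2.0)
    d = np.clip(d, 0.0, None)
    yt, Wt = U.T @ y, U.T @ W

    gsub = geno.subset_samples(sample_ids)
    X = gsub.dosages.copy()
    p = allele_frequencies(gsub)
    miss = np.isnan(X)
    if miss.any():
        X[miss] = np.broadcast_to(2.0 * p, X.shape)[miss]
    nonconst = X.std(axis=0) > 0
    Xt = U.T @ X

    def _scan(lam, cols=slice(None)):
        w = 1.0 / (lam * d + 1.0)
        sw = np.sqrt(w)
        Ww, yw = Wt * sw[:, None], yt * sw
        Q, _ = np.linalg.qr(Ww)
        yr = yw - Q @ (Q.T @ yw)
        Xw = Xt[:, cols] * sw[:, None]
        Xr = Xw - Q @ (Q.T @ Xw)
        xx = np.einsum("ij,ij->j", Xr, Xr)
        xy = Xr.T @ yr
        yy = float(yr @ yr)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = xy / xx
            rss = yy - beta * xy
            s2 = rss / (n - k - 1)
            se = np.sqrt(s2 / xx)
        return beta, se

    if per_snp_lambda:
        from scipy.optimize import minimize_scalar

        beta = np.full(X.shape[1], np.nan)
        se = np.full(X.shape[1], np.nan)
        for j in np.flatnonzero(nonconst):
            Wj = np.column_stack([Wt, Xt[:, j]])

            def negll(loglam):
                lam = np.exp(loglam)
                w = 1.0 / (lam * d + 1.0)
                Wjw = Wj * np.sqrt(w)[:, None]
                yw = yt * np.sqrt(w)
                B = Wjw.T @ Wjw
                bet = np.linalg.solve(B, Wjw.T @ yw)
                r = yw - Wjw @ bet
                nk = n - Wj.shape[1]
                s2 = max(float(r @ r) / nk, 1e-300)
                _, ld = np.linalg.slogdet(B)
                return 0.5 * (-np.sum(np.log(w)) + ld + nk * np.log(s2))

            res = minimize_scalar(negll, bounds=(-8, 8), method="bounded")
            bj, sj = _scan(np.exp(res.x), cols=[j])
            beta[j], se[j] = bj[0], sj[0]
    else:
        beta, se = _scan(lambda_ratio)

    beta = np.where(nonconst, beta, np.nan)
    se = np.where(nonconst, se, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (beta / se) ** 2
    pval = stats.chi2.sf(wald, df=1)
    tab = pd.DataFrame(
        {
            "snp_id": gsub.snp_ids,
            "chrom": gsub.marker_map["chrom"].to_numpy(),
            "pos": gsub.marker_map["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "wald": wald,
            "p": pval,
        }
    )
    ok = tab["p"].notna().to_numpy()
    order = np.lexsort((np.flatnonzero(ok), tab["p"].to_numpy()[ok]))
    ranks = np.full(len(tab), np.nan)
    ranks[np.flatnonzero(ok)[order]] = np.arange(1, ok.sum() + 1)
    tab["rank"] = ranks
    return GWASResult(tab, float(lambda_ratio), n)


def select_subset(
    source,
    fraction: float,
    mode: str = "preselected",
    seed: int | None = None,
) -> SNPSubset:
    """Select floor(fraction * m) SNPs by significance rank or at random.

    ``source`` is a :class:`GWASResult` (preselected mode) or any SNP-id
    sequence / :class:`GenotypeDataset` (random mode).  Preselected subsets
    are nested: the top-k at a smaller fraction is a prefix of the top-k at a
    larger one.  Ties in p are broken by genome order, deterministically.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if mode == "preselected":
        if not isinstance(source, GWASResult):
            raise TypeError("preselected mode requires a GWASResult")
        ranked = source.ranked_snp_ids()
        m = len(source.table)
        n_sel = int(np.floor(fraction * m))
        if n_sel == 0:
            raise ValueError(f"fraction {fraction} selects 0 of {m} SNPs")
        return SNPSubset("preselected", fraction, ranked[: min(n_sel, len(ranked))])
    if mode == "random":
        if isinstance(source, GWASResult):
            ids = source.table["snp_id"].to_numpy(object)
        elif isinstance(source, GenotypeDataset):
            ids = source.snp_ids
        else:
            ids = np.asarray(list(source), object)
        m = len(ids)
        n_sel = int(np.floor(fraction * m))
        if n_sel == 0:
            raise ValueError(f"fraction {fraction} selects 0 of {m} SNPs")
        rng = np.random.default_rng(seed)
        return SNPSubset("random", fraction, rng.choice(ids, size=n_sel, replace=False), seed)
    raise ValueError(f"unknown mode {mode!r}")


def subset_prediction_experiment(
    geno: GenotypeDataset,
    pheno: pd.DataFrame,
    fractions=None,
    modes=("preselected", "random"),
    cv: CVConfig | None = None,
    random_replicates: int = 20,
    ridge: float = 0.01,
    full_freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Prediction accuracy as a function of SNP-subset size and selection mode.

    One k-fold pass (no outer replication, matching the preselection design):
    per fold, the GWA scan ranks SNPs on training records only; for each
    fraction the GRM is rebuilt from the selected subset with the cohort-wide
    allele frequencies restricted to it, GBLUP is refitted and the held-out
    fold predicted.  Random subsets are redrawn ``random_replicates`` times.
    Returns tidy records (mode, fraction, replicate, fold, validation origin,
    rho, mse, slope, h2, n_snps).
    """
    fractions = tuple(fractions) if fractions is not None else DEFAULT_FRACTIONS
    cv = cv or CVConfig(scheme="joint", replicates=1)
    ph = pheno.reset_index(drop=True)
    indexed = ph.set_index("sample_id")
    origins = list(pd.unique(ph["origin"]))
    if full_freqs is None:
        full_freqs = allele_frequencies(geno)
    freq_of = pd.Series(full_freqs, index=geno.snp_ids)
    folds = make_folds(ph["sample_id"].to_numpy(object), ph["origin"].to_numpy(object),
                       k=cv.k, seed=cv.seed)
    full_grm = compute_grm(geno, freqs=full_freqs, ridge=ridge)
    rows = []
    for fold in range(1, cv.k + 1):
        val_ids = folds.fold_ids(fold)
        train_ids = folds.assignment.index[(folds.assignment != fold)].to_numpy(object)
        if cv.scheme == "pop1-only":
            train_ids = train_ids[(indexed.loc[train_ids, "origin"] == origins[0]).to_numpy()]
        elif cv.scheme == "pop2-only":
            train_ids = train_ids[(indexed.loc[train_ids, "origin"] == origins[1]).to_numpy()]
        scan = fit_lmm_gwas(geno, ph, full_grm, sample_ids=list(train_ids),
                            response=cv.response, covariates=cv.covariates)
        _, names = build_design(indexed.loc[list(train_ids)], cv.covariates)
        W_val = _design_like(indexed.loc[list(val_ids)], names)
        obs = indexed.loc[list(val_ids), cv.response].to_numpy(float)
        vorigin = indexed.loc[list(val_ids), "origin"].to_numpy(object)

        def _evaluate(subset: SNPSubset, replicate: int):
            sub = geno.subset_snps(subset.snp_ids)
            freqs = freq_of.loc[sub.snp_ids].to_numpy()
            try:
                g = compute_grm(sub, freqs=freqs, ridge=ridge)
                fit = GBLUP.from_phenotypes(ph, g, response=cv.response,
                                            covariates=cv.covariates,
                                            sample_ids=list(train_ids)).fit()
                pred = fit.predict(g, val_ids, W_val=W_val)
            except (np.linalg.LinAlgError, ValueError):
                return  # singular subset GRM: fold failure, excluded
            h2 = fit.heritability().h2
            for org in origins:
                mask = vorigin == org
                if mask.sum() < 3:
                    continue
                met = compute_metrics(obs[mask], pred[mask])
                rows.append(
                    {
                        "mode": subset.mode, "fraction": subset.fraction,
                        "replicate": replicate, "fold": fold,
                        "validation_origin": org, "rho": met.rho,
                        "mse": met.mse, "slope": met.slope, "h2": h2,
                        "n_snps": len(subset.snp_ids),
                    }
                )

        for frac in fractions:
            if "preselected" in modes:
                _evaluate(select_subset(scan, frac, "preselected"), 1)
            if "random" in modes:
                reps = 1 if frac >= 1.0 else random_replicates
                for r in range(1, reps + 1):
                    sub = select_subset(geno, frac, "random",
                                        seed=cv.seed + 1000 * fold + 10 * r + int(frac * 100))
                    _evaluate(sub, r)
    return pd.DataFrame(rows)
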