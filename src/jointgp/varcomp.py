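"""GBLUP mixed model fitted by average-information REML.

Model
-----
The univariate genomic BLUP model is

    y = W a + u + e,   u ~ N(0, G sg2),   e ~ N(0, I se2)

with y the (ordinal, treated as continuous) hip-score phenotype, W a
fixed-effect design (intercept, sex, origin), and G a genomic relationship
matrix.  The restricted likelihood is maximised over (sg2, se2) by
average-information (AI) updates with safeguards:

* the AI step is halved whenever it would decrease the restricted
  log-likelihood, and a single EM step replaces any AI proposal of a negative
  component;
* components are floored at ``1e-8 * var(y)``;
* convergence is declared when the max-absolute change of the *normalised*
  components theta = (sg2, se2) / (sg2 + se2) falls below 1e-5.

Implementation detail: G (the training block, ridge included) is
eigendecomposed once, G = U D U'; rotating y and W by U' makes
V = sg2 G + se2 I diagonal, so each iteration costs O(n k^2) for k fixed
effects.  The inverse of the final AI matrix is reported as the sampling
covariance of the variance-component estimates; heritability and its
standard error follow by the delta method,

    h2 = sg2 / (sg2 + se2),
    d h2/d sg2 =  se2 / (sg2 + se2)^2,
    d h2/d se2 = -sg2 / (sg2 + se2)^2.

The `GBLUP` class is the model (data + design), `fit()` returns
:class:`GBLUPResults` carrying estimates, their uncertainty, BLUPs and
prediction for held-out individuals via the conditional-expectation form

    u_val = G[val, train] G[train, train]^{-1} u_train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import GRM

__all__ = [
    "GBLUP",
    "GBLUPResults",
    "HeritabilityEstimate",
    "MixedModelSpec",
    "fit_aireml",
    "heritability",
    "blup_predict",
    "build_design",
    "restricted_loglik",
]

_FLOOR_FACTOR = 1e-8


def build_design(
    meta: pd.DataFrame,
    covariates=("sex", "origin"),
) -> tuple[np.ndarray, list]:
    """Fixed-effect design: intercept plus dummy-coded covariates.

    Covariate columns that are constant in the data (e.g. origin in a
    single-origin training set, which would be aliased with the intercept)
    are dropped automatically.
    """
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in meta.columns:
            continue
        levels = pd.unique(meta[cov].astype(str))
        if len(levels) < 2:
            continue  # aliased with intercept
        for lev in sorted(levels)[1:]:
            cols.append((meta[cov].astype(str) == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    W = np.column_stack(cols)
    # drop any remaining aliased columns
    q, r = np.linalg.qr(W)
    keep = np.abs(np.diag(r)) > 1e-10
    if not keep.all():
        W = W[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return W, names


@dataclass
class MixedModelSpec:
    """Phenotype vector, fixed-effect design and GRM block for one training set."""

    y: np.ndarray
    W: np.ndarray
    G: np.ndarray
    sample_ids: np.ndarray
    fixed_names: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, float).ravel()
        self.W = np.atleast_2d(np.asarray(self.W, float))
        n = len(self.y)
        if self.W.shape[0] != n or self.G.shape != (n, n):
            raise ValueError("y, W and G dimensions disagree")
        if np.isnan(self.y).any():
            raise ValueError("phenotype vector contains NaN")


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float


class GBLUP:
    """Genomic BLUP model for one phenotype and one relationship matrix.

    Parameters
    ----------
    y : array-like
        Phenotypes of the training individuals.
    W : ndarray
        Fixed-effect design matrix (full column rank after aliasing).
    grm : GRM or ndarray
        Relationship matrix covering at least the training individuals
        (ridge already applied).
    sample_ids : array-like, optional
        Training sample ids; required when ``grm`` is a :class:`GRM` whose
        order differs from ``y``.
    """

    def __init__(self, y, W, grm, sample_ids=None, fixed_names=None):
        if isinstance(grm, GRM):
            if sample_ids is None:
                sample_ids = grm.sample_ids
            G = grm.block(sample_ids)
            self._full_grm = grm
        else:
            G = np.asarray(grm, float)
            self._full_grm = None
            if sample_ids is None:
                sample_ids = np.arange(G.shape[0])
        self.spec = MixedModelSpec(
            np.asarray(y, float), W, G, np.asarray(sample_ids, object),
            list(fixed_names) if fixed_names else [],
        )

    @classmethod
    def from_phenotypes(
        cls,
        pheno: pd.DataFrame,
        grm: GRM,
        response: str = "score_mean",
        covariates=("sex", "origin"),
        sample_ids=None,
    ) -> "GBLUP":
        """Build the model from a phenotype table (columns sample_id, sex, origin, ...)."""
        df = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
        if sample_ids is None:
            sample_ids = [s for s in df.index if s in set(grm.sample_ids)]
        df = df.loc[list(sample_ids)]
        W, names = build_design(df, covariates)
        return cls(df[response].to_numpy(float), W, grm, np.asarray(sample_ids, object), names)

    def fit(self, start=None, max_iter: int = 100, tol: float = 1e-5) -> "GBLUPResults":
        return fit_aireml(self.spec, start=start, max_iter=max_iter, tol=tol, model=self)


def _rotated_quantities(d, Wt, yt, sg2, se2):
    """Core REML quantities in the eigenbasis of G (d = eigenvalues)."""
    v = sg2 * d + se2
    if np.any(v <= 0):
        raise np.linalg.LinAlgError("V not positive definite")
    vinv = 1.0 / v
    WtV = Wt * vinv[:, None]
    B = Wt.T @ WtV                       # W' V^-1 W
    L = np.linalg.cholesky(B)
    beta = np.linalg.solve(B, WtV.T @ yt)
    Py = vinv * (yt - Wt @ beta)
    quad = float(yt @ Py)
    logdetV = float(np.sum(np.log(v)))
    logdetB = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (logdetV + logdetB + quad)
    return v, vinv, WtV, B, beta, Py, ll


def _apply_P(vec, vinv, WtV, B):
    return vinv * vec - WtV @ np.linalg.solve(B, WtV.T @ vec)


def restricted_loglik(spec: MixedModelSpec, sg2: float, se2: float) -> float:
    """Restricted log-likelihood (up to a constant) at given components.

    Direct evaluation used by brute-force oracles; the iterative fitter uses
    the same expression in the eigenbasis of G.
    """
    d, U = np.linalg.eigh((spec.G + spec.G.T) / 2.0)
    yt, Wt = U.T @ spec.y, U.T @ spec.W
    return _rotated_quantities(d, Wt, yt, sg2, se2)[-1]


def fit_aireml(
    spec: MixedModelSpec,
    start=None,
    max_iter: int = 100,
    tol: float = 1e-5,
    model: GBLUP | None = None,
) -> "GBLUPResults":
    """Maximise the restricted likelihood by AI updates with EM fallback."""
    y, W, G = spec.y, spec.W, spec.G
    n, k = W.shape[0], W.shape[1]
    vary = float(np.var(y, ddof=1)) if n > 1 else 1.0
    if vary <= 0:
        vary = 1.0
    floor = _FLOOR_FACTOR * vary
    d, U = np.linalg.eigh((G + G.T) / 2.0)
    if d.min() <= 0:
        # PSD up to round-off is fine; a truly indefinite G is a user error
        if d.min() < -1e-8 * max(d.max(), 1.0):
            raise np.linalg.LinAlgError("G block not positive semi-definite")
        d = np.clip(d, 1e-12, None)
    yt, Wt = U.T @ y, U.T @ W

    # degenerate data: y in the column span of W leaves no variance to split
    resid_ols = yt - Wt @ np.linalg.lstsq(Wt, yt, rcond=None)[0]
    if float(resid_ols @ resid_ols) / max(n - k, 1) < floor:
        sg2 = se2 = floor
        _, _, _, _, beta, Py, ll = _rotated_quantities(d, Wt, yt, sg2, se2)
        return GBLUPResults(
            spec=spec, model=model, sigma_g2=sg2, sigma_e2=se2, alpha_hat=beta,
            u_hat=sg2 * (U @ (d * Py)), ai_covariance=np.full((2, 2), np.nan),
            loglik_restricted=ll,
            theta_trace=pd.DataFrame([{"iter": 0, "sg2": sg2, "se2": se2, "loglik": ll}]),
            converged=True, boundary=True, n_iter=0,
        )

    sg2, se2 = (start if start is not None else (vary / 2.0, vary / 2.0))
    sg2, se2 = max(float(sg2), floor), max(float(se2), floor)
    trace = []
    converged = False
    boundary = False
    v = vinv = WtV = B = beta = Py = None
    ll = -np.inf
    AI = np.eye(2)

    for it in range(max_iter):
        v, vinv, WtV, B, beta, Py, ll = _rotated_quantities(d, Wt, yt, sg2, se2)
        theta = np.array([sg2, se2]) / (sg2 + se2)
        trace.append({"iter": it, "sg2": sg2, "se2": se2, "loglik": ll})

        # first derivatives: dl/ds_i = -0.5 [tr(P V_i) - y'P V_i P y]
        yPGPy = float(Py @ (d * Py))  # y'P G P y
        yPPy = float(Py @ Py)
        # tr(P G) = sum d/v - tr(B^-1 W'V^-1 D V^-1 W)
        WtVD = WtV * d[:, None]
        trPG = float(np.sum(d * vinv) - np.trace(np.linalg.solve(B, WtV.T @ WtVD)))
        trP = float(np.sum(vinv) - np.trace(np.linalg.solve(B, WtV.T @ WtV)))
        grad = -0.5 * np.array([trPG - yPGPy, trP - yPPy])

        # average information: AI_ij = 0.5 y'P V_i P V_j P y
        PGPy = _apply_P(d * Py, vinv, WtV, B)
        PPy = _apply_P(Py, vinv, WtV, B)
        AI = 0.5 * np.array(
            [
                [float((d * Py) @ PGPy), float((d * Py) @ PPy)],
                [float((d * Py) @ PPy), float(Py @ PPy)],
            ]
        )

        # propose AI step, EM fallback on negative proposal, halve on ll decrease
        try:
            step = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            step = None
        new = None
        if step is not None:
            cand = np.array([sg2, se2]) + step
            if np.all(cand > 0):
                new = cand
        if new is None:
            # EM update: s_i <- s_i + s_i^2 (y'P V_i P y - tr(P V_i)) / n
            new = np.array(
                [
                    sg2 + sg2 ** 2 * (yPGPy - trPG) / n,
                    se2 + se2 ** 2 * (yPPy - trP) / n,
                ]
            )
        new = np.maximum(new, floor)
        # step-halving: require the restricted likelihood not to decrease
        for _ in range(30):
            try:
                ll_new = _rotated_quantities(d, Wt, yt, new[0], new[1])[-1]
            except np.linalg.LinAlgError:
                ll_new = -np.inf
            if ll_new >= ll - 1e-10:
                break
            new = np.maximum((new + np.array([sg2, se2])) / 2.0, floor)
        sg2_new, se2_new = float(new[0]), float(new[1])
        theta_new = np.array([sg2_new, se2_new]) / (sg2_new + se2_new)
        delta = float(np.max(np.abs(theta_new - theta)))
        sg2, se2 = sg2_new, se2_new
        if delta < tol:
            converged = True
            break

    v, vinv, WtV, B, beta, Py, ll = _rotated_quantities(d, Wt, yt, sg2, se2)
    trace.append({"iter": len(trace), "sg2": sg2, "se2": se2, "loglik": ll})
    if sg2 <= floor * 1.001 or se2 <= floor * 1.001:
        boundary = True
    try:
        ai_cov = np.linalg.inv(AI)
        if np.linalg.cond(AI) > 1e8:
            boundary = True
    except np.linalg.LinAlgError:
        ai_cov = np.full((2, 2), np.nan)
        boundary = True
    # BLUPs: u = sg2 G P (y - W beta); in rotated space P y is Py
    u_hat = sg2 * (U @ (d * Py))
    return GBLUPResults(
        spec=spec,
        model=model,
        sigma_g2=sg2,
        sigma_e2=se2,
        alpha_hat=beta,
        u_hat=u_hat,
        ai_covariance=ai_cov,
        loglik_restricted=ll,
        theta_trace=pd.DataFrame(trace),
        converged=converged,
        boundary=boundary,
        n_iter=len(trace) - 1,
    )


@dataclass
class GBLUPResults:
    """AI-REML fit: variance components, their AI sampling covariance, BLUPs."""

    spec: MixedModelSpec
    model: GBLUP | None
    sigma_g2: float
    sigma_e2: float
    alpha_hat: np.ndarray
    u_hat: np.ndarray
    ai_covariance: np.ndarray
    loglik_restricted: float
    theta_trace: pd.DataFrame
    converged: bool
    boundary: bool
    n_iter: int

    @property
    def params(self) -> pd.Series:
        names = self.spec.fixed_names or [f"b{i}" for i in range(len(self.alpha_hat))]
        return pd.Series(
            np.concatenate([self.alpha_hat, [self.sigma_g2, self.sigma_e2]]),
            index=names + ["sigma_g2", "sigma_e2"],
        )

    def heritability(self) -> HeritabilityEstimate:
        return heritability(self)

    def predict(self, grm: GRM | None = None, validation_ids=None, W_val=None):
        grm = grm or (self.model._full_grm if self.model else None)
        if grm is None:
            raise ValueError("a full GRM covering validation individuals is required")
        return blup_predict(self, grm, validation_ids, W_val=W_val)

    def summary(self) -> str:
        h = self.heritability()
        lines = [
            "GBLUP / AI-REML fit",
            "=" * 46,
            f"n obs            {len(self.spec.y):>10d}",
            f"iterations       {self.n_iter:>10d}   converged: {self.converged}",
            f"restricted logL  {self.loglik_restricted:>12.4f}",
            "-" * 46,
            f"sigma_g^2  {self.sigma_g2:>10.4f}  (se {np.sqrt(max(self.ai_covariance[0, 0], 0)):.4f})",
            f"sigma_e^2  {self.sigma_e2:>10.4f}  (se {np.sqrt(max(self.ai_covariance[1, 1], 0)):.4f})",
            f"h^2        {h.h2:>10.4f}  (se {h.se:.4f})",
            "-" * 46,
        ]
        for name, val in self.params.items():
            if name not in ("sigma_g2", "sigma_e2"):
                lines.append(f"{name:<16s} {val:>10.4f}")
        if self.boundary:
            lines.append("warning: boundary/identifiability flag set")
        return "\n".join(lines)


def heritability(fit: GBLUPResults) -> HeritabilityEstimate:
    """h2 = sg2/(sg2+se2) with delta-method SE from the AI covariance."""
    sg2, se2 = fit.sigma_g2, fit.sigma_e2
    tot = sg2 + se2
    if tot <= 0:
        raise ValueError("total variance is zero")
    h2 = sg2 / tot
    dg = se2 / tot ** 2
    de = -sg2 / tot ** 2
    C = fit.ai_covariance
    var = dg * dg * C[0, 0] + de * de * C[1, 1] + 2 * dg * de * C[0, 1]
    return HeritabilityEstimate(h2=float(h2), se=float(np.sqrt(max(var, 0.0))))


def blup_predict(
    fit: GBLUPResults,
    grm: GRM,
    validation_ids,
    W_val: np.ndarray | None = None,
):
    """Predicted scores for held-out individuals.

    Genomic part by conditional expectation,
    ``u_val = G[val,train] G[train,train]^{-1} u_train``; the fixed-effect part
    (``W_val @ alpha_hat``) is added when a validation design is supplied,
    otherwise only the intercept is used.  Training and validation ids must be
    disjoint.
    """
    train_ids = fit.spec.sample_ids
    validation_ids = np.asarray(validation_ids, object)
    if set(validation_ids) & set(train_ids):
        raise ValueError("validation ids overlap the training set")
    G_vt = grm.block(validation_ids, train_ids)
    G_tt = grm.block(train_ids)
    u_val = G_vt @ np.linalg.solve(G_tt, fit.u_hat)
    if W_val is None:
        fixed = np.full(len(validation_ids), fit.alpha_hat[0])
    else:
        W_val = np.atleast_2d(np.asarray(W_val, float))
        fixed = W_val @ fit.alpha_hat
    return fixed + u_val
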