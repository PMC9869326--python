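"""Feature extraction over the compendium's fold-change matrix.

Across many comparisons, a gene's vector of log2 fold-changes is a
behavioural fingerprint: genes responding to the same regulation tend to
move together. This module finds genes whose fold-change profile predicts a
per-comparison response variable — another gene's fold-changes (gaussian),
a binary study label (binomial) or a multi-class category (multinomial) —
by combining an elastic-net regression (mixing parameter 0.5, penalty by
10-fold cross-validation at the 1-SE rule) with a univariate association
per gene (Spearman / Wilcoxon rank-sum / one-way ANOVA, BH-corrected).

Genes must be detected (not necessarily DE) in at least 70% of the
comparisons to enter the matrix: sparse genes, observed only in a few
studies, would otherwise over-predict responses that happen to co-occur in
those same studies. Cells where a gene was not detected carry a 0
fold-change behind an explicit mask.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import KFold

from .core import Compendium, bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "FoldChangeMatrix",
    "FeatureResult",
    "build_fc_matrix",
    "elastic_net_extract",
    "univariate_assoc",
    "extract_features",
    "predictor_importance",
]

ALPHA_MIX = 0.5  # elastic-net mixing (1 = lasso, 0 = ridge)


@dataclasses.dataclass
class FoldChangeMatrix:
    """Genes x comparisons log2 fold-changes with a detection mask."""

    values: pd.DataFrame  # genes x comparisons, 0-filled where undetected
    mask: pd.DataFrame  # True where the gene was detected
    detection_fraction: pd.Series

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def comparisons(self) -> list:
        return list(self.values.columns)


@dataclasses.dataclass
class FeatureResult:
    table: pd.DataFrame  # per-gene enet_coefficient, stat, p, fdr
    family: str
    response_description: str = ""


def build_fc_matrix(c: Compendium, min_detect: float = 0.70) -> FoldChangeMatrix:
    """Assemble the genes x comparisons log2FC matrix, filtered by detection."""
    if len(c) == 0:
        raise ValueError("compendium is empty")
    cols = {}
    masks = {}
    for comp in c:
        lfc = comp.log2fc_series()
        detected = lfc.index.isin(comp.detected_genes)
        cols[comp.id] = lfc.where(detected)
        masks[comp.id] = pd.Series(detected, index=lfc.index)
    values = pd.DataFrame(cols)
    mask = (
        pd.DataFrame(masks)
        .reindex(values.index)
        .astype("boolean")
        .fillna(False)
        .astype(bool)
    )
    mask &= values.notna()
    frac = mask.mean(axis=1)
    keep = frac >= min_detect
    if not keep.any():
        raise ValueError(
            f"no gene detected in >= {min_detect:.0%} of comparisons; "
            "lower min_detect"
        )
    values = values.loc[keep].fillna(0.0)
    mask = mask.loc[keep]
    return FoldChangeMatrix(
        values=values, mask=mask, detection_fraction=frac[keep]
    )


def _one_se_alpha(alphas, mse_mean, mse_se):
    """Largest penalty whose mean CV error is within 1 SE of the minimum."""
    best = int(np.argmin(mse_mean))
    cutoff = mse_mean[best] + mse_se[best]
    ok = np.flatnonzero(mse_mean <= cutoff)
    return alphas[ok[np.argmax(alphas[ok])]]


def elastic_net_extract(
    X,
    y,
    family: str = "gaussian",
    n_folds: int = 10,
    n_alphas: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Elastic-net coefficients at the CV 1-SE penalty.

    ``X`` is comparisons x genes (a transposed :class:`FoldChangeMatrix`
    slice or any ndarray); ``y`` the per-comparison response. For the
    multinomial family the returned per-gene coefficient is the maximum
    absolute coefficient across classes. A constant response yields the
    zero vector with a warning.
    """
    X = np.asarray(
        X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float
    )
    n, p = X.shape
    y = np.asarray(y)
    if len(y) != n:
        raise ValueError("response not aligned with comparisons")
    if family == "gaussian":
        y = y.astype(float)
        if np.ptp(y) == 0:
            logger.warning("constant response; returning zero coefficients")
            return np.zeros(p)
        # glmnet-style alpha path on the standardized problem
        Xs = X - X.mean(axis=0)
        ys = y - y.mean()
        alpha_max = np.max(np.abs(Xs.T @ ys)) / (n * ALPHA_MIX)
        alphas = np.geomspace(alpha_max, alpha_max * 1e-3, n_alphas)
        kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
        mse = np.zeros((n_alphas, kf.get_n_splits()))
        for f, (tr, te) in enumerate(kf.split(X)):
            for a, alph in enumerate(alphas):
                # path fits need ranking precision only, not final precision
                m = ElasticNet(
                    alpha=alph, l1_ratio=ALPHA_MIX, max_iter=2000, tol=1e-3
                ).fit(X[tr], y[tr])
                mse[a, f] = np.mean((m.predict(X[te]) - y[te]) ** 2)
        mse_mean = mse.mean(axis=1)
        mse_se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
        alpha_1se = _one_se_alpha(alphas, mse_mean, mse_se)
        final = ElasticNet(
            alpha=alpha_1se, l1_ratio=ALPHA_MIX, max_iter=20000
        ).fit(X, y)
        return final.coef_.copy()
    if family in ("binomial", "multinomial"):
        classes = np.unique(y)
        if len(classes) < 2:
            logger.warning("constant response; returning zero coefficients")
            return np.zeros(p)
        if family == "binomial" and len(classes) != 2:
            raise ValueError("binomial family needs exactly two classes")
        # C is the inverse penalty; pick by CV at the 1-SE rule on deviance
        Cs = np.geomspace(1e-3, 1e2, 20)
        kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
        dev = np.full((len(Cs), kf.get_n_splits()), np.nan)
        for f, (tr, te) in enumerate(kf.split(X)):
            if len(np.unique(y[tr])) < len(classes):
                continue
            for i, C in enumerate(Cs):
                m = _logistic(C, seed).fit(X[tr], y[tr])
                prob = np.clip(m.predict_proba(X[te]), 1e-12, 1)
                idx = np.searchsorted(m.classes_, y[te])
                dev[i, f] = -2 * np.mean(np.log(prob[np.arange(len(te)), idx]))
        ok_folds = ~np.isnan(dev).all(axis=0)
        dev = dev[:, ok_folds]
        dev_mean = dev.mean(axis=1)
        dev_se = dev.std(axis=1, ddof=1) / np.sqrt(max(dev.shape[1], 1))
        best = int(np.argmin(dev_mean))
        cutoff = dev_mean[best] + dev_se[best]
        okC = np.flatnonzero(dev_mean <= cutoff)
        C_1se = Cs[okC[np.argmin(Cs[okC])]]  # smallest C = strongest penalty
        final = _logistic(C_1se, seed).fit(X, y)
        coef = np.abs(final.coef_)
        return coef.max(axis=0) if coef.ndim == 2 else np.abs(coef)
    raise ValueError(f"unknown family {family!r}")


def _logistic(C, seed):
    # a float l1_ratio selects the elastic-net penalty under saga
    return LogisticRegression(
        l1_ratio=ALPHA_MIX,
        C=C,
        solver="saga",
        max_iter=3000,
        random_state=seed,
    )


def univariate_assoc(X, y, family: str = "gaussian") -> pd.DataFrame:
    """Per-gene univariate association with the response.

    gaussian -> Spearman rho; binomial -> Wilcoxon rank-sum; multinomial ->
    one-way ANOVA F. Returns stat, p and BH FDR per gene (NaN for
    degenerate groups).
    """
    genes = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"g{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xv = np.asarray(
        X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float
    )
    y = np.asarray(y)
    stats_, ps = np.full(Xv.shape[1], np.nan), np.full(Xv.shape[1], np.nan)
    if family == "gaussian":
        yf = y.astype(float)
        for j in range(Xv.shape[1]):
            if np.ptp(Xv[:, j]) == 0 or np.ptp(yf) == 0:
                continue
            stats_[j], ps[j] = stats.spearmanr(Xv[:, j], yf)
    elif family == "binomial":
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("binomial family needs exactly two classes")
        g1, g2 = (Xv[y == cls] for cls in classes)
        if min(len(g1), len(g2)) >= 2:
            for j in range(Xv.shape[1]):
                stats_[j], ps[j] = stats.ranksums(g1[:, j], g2[:, j])
    elif family == "multinomial":
        groups = [Xv[y == cls] for cls in np.unique(y)]
        if all(len(g) >= 2 for g in groups):
            for j in range(Xv.shape[1]):
                cols = [g[:, j] for g in groups]
                if all(np.ptp(col) == 0 for col in cols):
                    continue
                stats_[j], ps[j] = stats.f_oneway(*cols)
    else:
        raise ValueError(f"unknown family {family!r}")
    fdr = np.full_like(ps, np.nan)
    ok = ~np.isnan(ps)
    if ok.any():
        fdr[ok] = bh_fdr(ps[ok])
    return pd.DataFrame(
        {"gene": genes, "stat": stats_, "pvalue": ps, "fdr": fdr}
    ).set_index("gene")


def extract_features(
    fc: FoldChangeMatrix,
    y,
    family: str = "gaussian",
    seed: int = 0,
    response_description: str = "",
) -> FeatureResult:
    """Elastic net + univariate association against a response variable."""
    X = fc.values.T  # comparisons x genes
    coefs = elastic_net_extract(X, y, family=family, seed=seed)
    uni = univariate_assoc(X, y, family=family)
    tab = uni.copy()
    tab.insert(0, "enet_coefficient", coefs)
    tab = tab.sort_values(
        ["fdr", "pvalue"], kind="mergesort", na_position="last"
    )
    return FeatureResult(
        table=tab, family=family, response_description=response_description
    )


def predictor_importance(
    c: "Compendium | FoldChangeMatrix",
    min_detect: float = 0.70,
    max_genes: int = 2000,
    seed: int = 0,
) -> pd.Series:
    """How well each gene's fold-changes predict every other gene's.

    For each target gene i an elastic net predicts its fold-change vector
    from all other genes; cell (i, j) of the gene-by-gene matrix is the
    absolute coefficient of predictor j, and a gene's importance is its
    column sum. Genes beyond ``max_genes`` are subsampled uniformly at
    random (seeded) to bound the O(genes^2) fit cost. Returns a descending
    Series.
    """
    fc = c if isinstance(c, FoldChangeMatrix) else build_fc_matrix(c, min_detect)
    genes = fc.genes
    rng = np.random.default_rng(seed)
    if len(genes) > max_genes:
        keep = sorted(rng.choice(len(genes), size=max_genes, replace=False))
        genes = [genes[i] for i in keep]
    V = fc.values.loc[genes].to_numpy().T  # comparisons x genes
    p = len(genes)
    importance = np.zeros(p)
    for i in range(p):
        others = np.delete(np.arange(p), i)
        coef = elastic_net_extract(
            V[:, others], V[:, i], family="gaussian", seed=seed
        )
        importance[others] += np.abs(coef)
    return pd.Series(importance, index=genes).sort_values(ascending=False)
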