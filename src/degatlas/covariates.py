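"""Covariate construction from mixed sample metadata.

Sample metadata mixes continuous variables (age, time to freezing, ...) and
categorical ones (sex, tissue, sequencing strategy, ...). To fold both into
one design-reduction step, continuous columns are "doubled" (Escoffier
transform: min–max rescale to [-1, 1], then split into two complementary
columns summing to 1) and categorical columns are disjunctively (one-hot)
coded. The concatenated nonnegative table then enters a correspondence
analysis (CA); because every variable contributes constant row mass, the
variables are weighted equally. The number of retained components is picked
at the scree-plot elbow, operationalised as the point of maximum
perpendicular distance to the chord joining the first and last eigenvalues.
The retained row principal coordinates are the covariates controlled for in
each differential-expression design.

Missing metadata is imputed first: continuous values by the stratum mean
(stratified by sex when a sex column is present, else the global mean),
categorical values by a literal ``"unknown"`` level.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from pandas.api.types import is_numeric_dtype

logger = logging.getLogger(__name__)

__all__ = [
    "CAResult",
    "impute_metadata",
    "escoffier_transform",
    "disjunctive_code",
    "correspondence_analysis",
    "select_components",
    "build_covariates",
]


@dataclasses.dataclass
class CAResult:
    """Correspondence-analysis decomposition of a nonnegative table."""

    eigenvalues: np.ndarray  # descending, = squared singular values
    row_scores: np.ndarray  # samples x components, principal coordinates
    total_inertia: float  # = chi^2 / grand total = sum(eigenvalues)
    k_selected: int

    def __post_init__(self):
        if abs(self.eigenvalues.sum() - self.total_inertia) > 1e-8 * max(
            1.0, self.total_inertia
        ):
            raise ValueError("eigenvalue sum does not match total inertia")
        if not (1 <= self.k_selected <= max(1, len(self.eigenvalues))):
            raise ValueError("k_selected out of range")


def impute_metadata(
    meta: pd.DataFrame, strata_column: str | None = "sex"
) -> pd.DataFrame:
    """Impute missing metadata values.

    Continuous columns get the mean within the stratum defined by
    ``strata_column`` (falling back to the global mean when the stratum
    column is absent, itself incomplete, or a stratum has no observed
    value); categorical columns get the literal level ``"unknown"``.
    """
    out = meta.copy()
    strata = None
    if strata_column is not None and strata_column in out.columns:
        col = out[strata_column]
        if not is_numeric_dtype(col) and not col.isna().any():
            strata = col
    for name in out.columns:
        col = out[name]
        if is_numeric_dtype(col):
            if col.isna().all():
                raise ValueError(
                    f"continuous column {name!r} is entirely missing"
                )
            if col.isna().any():
                if strata is not None and name != strata_column:
                    filled = col.fillna(col.groupby(strata).transform("mean"))
                    # strata with no observed value fall back to global mean
                    out[name] = filled.fillna(col.mean())
                else:
                    out[name] = col.fillna(col.mean())
        else:
            if col.isna().any():
                out[name] = (
                    col.astype(object).where(~col.isna(), "unknown")
                )
    return out


def escoffier_transform(x) -> np.ndarray:
    """Double a continuous vector for correspondence analysis.

    The vector is min–max rescaled to z in [-1, 1] and coded as the two
    complementary columns ((1+z)/2, (1-z)/2), so each row sums to 1 and the
    variable carries the same mass as a disjunctively coded categorical.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in continuous column")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant continuous column cannot be doubled")
    z = 2.0 * (x - lo) / (hi - lo) - 1.0
    return np.column_stack([(1.0 + z) / 2.0, (1.0 - z) / 2.0])


def disjunctive_code(x) -> pd.DataFrame:
    """One-hot indicator expansion; columns in sorted level order."""
    s = pd.Series(x).astype(str)
    levels = sorted(s.unique())
    if len(levels) < 2:
        raise ValueError("categorical column has fewer than two levels")
    return pd.get_dummies(s, dtype=float)[levels]


def correspondence_analysis(M) -> CAResult:
    """Classical correspondence analysis of a nonnegative table.

    With P = M / total, row masses r and column masses c, the standardized
    residual matrix S = Dr^{-1/2} (P - r c^T) Dc^{-1/2} is decomposed by
    SVD; eigenvalues are the squared singular values, their sum the total
    inertia chi^2 / total, and row principal coordinates are
    Dr^{-1/2} U diag(s).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D table")
    if (M < 0).any():
        raise ValueError("negative entries in CA input")
    total = M.sum()
    if total <= 0:
        raise ValueError("grand total must be positive")
    r = M.sum(axis=1) / total
    c = M.sum(axis=0) / total
    if (r == 0).any():
        raise ValueError(f"all-zero row(s) {np.flatnonzero(r == 0).tolist()}")
    if (c == 0).any():
        raise ValueError(
            f"all-zero column(s) {np.flatnonzero(c == 0).tolist()}"
        )
    P = M / total
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    # the trivial dimension is already removed by centring; keep at most
    # min(nrow, ncol) - 1 axes
    k_max = max(1, min(M.shape) - 1)
    sv = sv[:k_max]
    U = U[:, :k_max]
    eig = sv**2
    row_scores = (U * sv) / np.sqrt(r)[:, None]
    total_inertia = float((S**2).sum())
    # guard: tiny negative round-off in the truncated tail
    eig = np.clip(eig, 0.0, None)
    k = select_components(eig)
    return CAResult(
        eigenvalues=eig,
        row_scores=row_scores,
        total_inertia=float(eig.sum()) if eig.size else total_inertia,
        k_selected=k,
    )


def select_components(eigenvalues) -> int:
    """Scree elbow: maximum perpendicular distance to the first–last chord.

    The elbow is the scree point farthest (perpendicularly) from the chord
    joining (1, lambda_1) and (m, lambda_m); the components *before* the
    elbow are retained, so k = elbow index - 1 (at least 1). Ties break
    toward the smaller index; a linear scree (all distances zero) or fewer
    than three eigenvalues yields k = 1.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    m = lam.size
    if m == 0:
        raise ValueError("no eigenvalues")
    if m <= 2:
        return 1
    x = np.arange(1, m + 1, dtype=float)
    p1 = np.array([x[0], lam[0]])
    p2 = np.array([x[-1], lam[-1]])
    chord = p2 - p1
    norm = np.hypot(*chord)
    if norm == 0:
        return 1
    # perpendicular distance of each scree point to the chord
    d = np.abs(chord[0] * (p1[1] - lam) - (p1[0] - x) * chord[1]) / norm
    if np.all(d < 1e-12):
        return 1
    return max(1, int(np.argmax(d)))


def build_covariates(
    meta: pd.DataFrame,
    drop_variables=(),
    strata_column: str | None = "sex",
    k_override: int | None = None,
) -> np.ndarray:
    """Metadata -> CA covariate matrix for the DE design.

    Pipeline: impute, drop the condition variable (and anything listed in
    ``drop_variables``), double/one-hot each remaining column, run CA on the
    concatenation and keep the first k row-score columns at the scree elbow
    (or ``k_override``). Constant / single-level columns are dropped with a
    warning. With no usable column the covariate matrix is empty
    (intercept-only design).
    """
    drop = set(drop_variables)
    meta = impute_metadata(meta, strata_column=strata_column)
    blocks = []
    for name in meta.columns:
        if name in drop:
            continue
        col = meta[name]
        try:
            if is_numeric_dtype(col):
                blocks.append(escoffier_transform(col.to_numpy()))
            else:
                blocks.append(disjunctive_code(col).to_numpy())
        except ValueError as exc:
            logger.warning("dropping metadata column %r: %s", name, exc)
    if not blocks:
        logger.warning("no usable metadata columns; intercept-only design")
        return np.empty((len(meta), 0))
    M = np.concatenate(blocks, axis=1)
    try:
        ca = correspondence_analysis(M)
    except ValueError as exc:
        # e.g. all remaining columns identical across samples
        logger.warning("correspondence analysis failed (%s); no covariates", exc)
        return np.empty((len(meta), 0))
    k = k_override if k_override is not None else ca.k_selected
    k = min(k, ca.row_scores.shape[1])
    cov = ca.row_scores[:, :k]
    # drop numerically null axes (zero inertia) to keep designs full rank
    keep = ca.eigenvalues[:k] > 1e-12
    return cov[:, keep]
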