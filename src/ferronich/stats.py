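"""Multivariate community statistics.

Implements the ecology toolkit used to compare gene repertoires across
sample groupings: per-column data transformations, Bray-Curtis similarity,
rank-based analysis of similarities (ANOSIM) with permutation significance,
similarity-percentage decomposition (SIMPER), non-metric multidimensional
scaling (NMDS, Kruskal stress-1), and PCA of an environmental matrix.

Bray-Curtis similarity between samples j and k over p variables:

    S_jk = 100 * 2 * sum_i min(y_ij, y_ik) / sum_i (y_ij + y_ik)

and the dissimilarity is 100 - S_jk.  ANOSIM ranks all n(n-1)/2
dissimilarities (midranks for ties) and computes

    R = (rbar_between - rbar_within) / (M/2),   M = n(n-1)/2,

with significance (t+1)/(T+1) from T random label permutations, t of which
reach an R at least as large as observed.  SIMPER decomposes the average
between-group dissimilarity into per-variable contributions

    delta_jk(i) = 100 * |y_ij - y_ik| / sum_i (y_ij + y_ik),

whose sum over i equals 100 - S_jk exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "SimilarityMatrix",
    "AnosimResult",
    "SimperTable",
    "NmdsEmbedding",
    "PcaResult",
    "transform_matrix",
    "bray_curtis",
    "anosim",
    "simper",
    "nmds",
    "pca",
    "ols_r2",
]


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def transform_matrix(df: pd.DataFrame, spec: str | dict[str, str]) -> pd.DataFrame:
    """Elementwise per-column transforms: log -> log10(x+1), sqrt, exp, none.

    ``spec`` is one transform name for every column, or a column -> name map
    (missing columns default to 'none').
    """
    out = df.astype(float).copy()
    for col in out.columns:
        t = spec if isinstance(spec, str) else spec.get(col, "none")
        x = out[col].to_numpy()
        if t in ("log", "sqrt") and (x < 0).any():
            bad = out.index[np.nonzero(x < 0)[0][0]]
            raise ValueError(f"negative value under {t} at row {bad!r}, column {col!r}")
        if t == "log":
            out[col] = np.log10(x + 1.0)
        elif t == "sqrt":
            out[col] = np.sqrt(x)
        elif t == "exp":
            out[col] = np.exp(x)
        elif t == "none":
            pass
        else:
            raise ValueError(f"unknown transform {t!r} for column {col!r}")
    return out


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    ids: list[str]
    S: np.ndarray  # symmetric, in [0, 100], diagonal 100

    @property
    def dissimilarity(self) -> np.ndarray:
        return 100.0 - self.S

    def condensed_dissimilarity(self) -> np.ndarray:
        return squareform(self.dissimilarity, checks=False)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.S, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def bray_curtis(matrix: pd.DataFrame) -> SimilarityMatrix:
    """Bray-Curtis similarities (0..100) between all sample rows."""
    Y = matrix.to_numpy(dtype=float)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (Y < 0).any():
        raise ValueError("abundances must be nonnegative")
    mins = np.minimum(Y[:, None, :], Y[None, :, :]).sum(axis=2)
    rowsum = Y.sum(axis=1)
    denom = rowsum[:, None] + rowsum[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        S = 100.0 * 2.0 * mins / denom
    if np.isnan(S).any():
        warnings.warn("pair of all-zero samples: similarity defined as 0")
        S = np.nan_to_num(S, nan=0.0)
    np.fill_diagonal(S, 100.0)
    return SimilarityMatrix(ids=list(matrix.index), S=S)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    R: float
    r_between: float
    r_within: float
    M: int
    n_perm: int
    n_extreme: int
    significance: float  # (t+1)/(T+1)
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> tuple[float, float, float]:
    M = len(ranks)
    r_w = float(ranks[within].mean())
    r_b = float(ranks[~within].mean())
    return (r_b - r_w) / (M / 2.0), r_b, r_w


def anosim(
    similarity: SimilarityMatrix,
    labels: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
    pairwise: bool = False,
) -> AnosimResult:
    """Rank-based test for differences between a priori sample groups.

    Dissimilarities are ranked ascending with midranks for ties; the observed
    labeling is not counted among the t extreme permutations, but the +1
    terms keep the significance in (0, 1].
    """
    ids = similarity.ids
    groups = np.array([labels[i] for i in ids])
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    d = similarity.dissimilarity[iu, ju]
    ranks = rankdata(d)  # midranks
    rng = np.random.default_rng(seed)

    within = groups[iu] == groups[ju]
    R, r_b, r_w = _anosim_r(ranks, within)

    # Vectorized permutations: one boolean within-mask per permuted labeling.
    perms = np.array([rng.permutation(groups) for _ in range(n_perm)])
    w = perms[:, iu] == perms[:, ju]  # (T, M)
    nw = w.sum(axis=1).astype(float)
    M = len(ranks)
    sum_w = (ranks[None, :] * w).sum(axis=1)
    r_w_perm = sum_w / nw
    r_b_perm = (ranks.sum() - sum_w) / (M - nw)
    R_perm = (r_b_perm - r_w_perm) / (M / 2.0)
    t = int((R_perm >= R - 1e-12).sum())
    result = AnosimResult(
        R=R,
        r_between=r_b,
        r_within=r_w,
        M=M,
        n_perm=n_perm,
        n_extreme=t,
        significance=(t + 1) / (n_perm + 1),
    )
    if pairwise:
        for a_i in range(len(uniq)):
            for b_i in range(a_i + 1, len(uniq)):
                a, b = uniq[a_i], uniq[b_i]
                keep = [i for i, g in zip(ids, groups) if g in (a, b)]
                sub_idx = [ids.index(i) for i in keep]
                sub = SimilarityMatrix(
                    ids=keep, S=similarity.S[np.ix_(sub_idx, sub_idx)]
                )
                sub_labels = {i: labels[i] for i in keep}
                r = anosim(sub, sub_labels, n_perm=n_perm, seed=seed)
                result.pairwise.append((a, b, r.R, r.significance))
    return result


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass
class SimperTable:
    table: pd.DataFrame  # per-gene rows sorted by mean contribution, descending
    overall_dissimilarity: float
    group_pair: tuple[str, str]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def simper(
    matrix: pd.DataFrame,
    labels: dict[str, str],
    group_pair: tuple[str, str],
) -> SimperTable:
    """Decompose the average between-group Bray-Curtis dissimilarity into
    per-gene contributions over all cross-group sample pairs."""
    a, b = group_pair
    if a == b:
        raise ValueError("group_pair must name two distinct groups")
    ia = [s for s in matrix.index if labels.get(s) == a]
    ib = [s for s in matrix.index if labels.get(s) == b]
    if not ia or not ib:
        raise ValueError(f"both groups need >= 1 sample (got {len(ia)}, {len(ib)})")

    Ya = matrix.loc[ia].to_numpy(dtype=float)  # (na, p)
    Yb = matrix.loc[ib].to_numpy(dtype=float)  # (nb, p)
    diff = np.abs(Ya[:, None, :] - Yb[None, :, :])  # (na, nb, p)
    denom = (Ya[:, None, :] + Yb[None, :, :]).sum(axis=2)  # (na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = 100.0 * diff / denom[:, :, None]
    if np.isnan(contrib).any():
        warnings.warn("pair of all-zero samples: contributions defined as 0")
        contrib = np.nan_to_num(contrib, nan=0.0)
    contrib = contrib.reshape(-1, matrix.shape[1])  # (pairs, p)

    mean_c = contrib.mean(axis=0)
    sd_c = contrib.std(axis=0, ddof=0)  # population SD over pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            sd_c > 0, mean_c / np.where(sd_c > 0, sd_c, 1.0),
            np.where(mean_c > 0, np.inf, 0.0),
        )
    overall = float(mean_c.sum())
    order = np.argsort(-mean_c, kind="stable")
    cum = 100.0 * np.cumsum(mean_c[order]) / overall if overall > 0 else np.zeros(len(order))
    tab = pd.DataFrame(
        {
            "mean_contribution": mean_c[order],
            "sd": sd_c[order],
            "ratio": ratio[order],
            f"mean_abundance_{a}": Ya.mean(axis=0)[order],
            f"mean_abundance_{b}": Yb.mean(axis=0)[order],
            "cumulative_pct": cum,
        },
        index=pd.Index(np.array(matrix.columns)[order], name="gene"),
    )
    return SimperTable(table=tab, overall_dissimilarity=overall, group_pair=(a, b))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsEmbedding:
    coordinates: np.ndarray  # (n, dims)
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool
    ids: list[str] = field(default_factory=list)


def kruskal_stress(coords: np.ndarray, dissim_condensed: np.ndarray) -> float:
    """Stress-1 of an embedding against the isotonic fit to the input order."""
    d = pdist(coords)
    dhat = _isotonic_disparities(d, dissim_condensed)
    denom = float((d**2).sum())
    if denom == 0:
        return 1.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _isotonic_disparities(d: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Monotone (PAVA) regression of embedding distances on the dissimilarity
    order.  Ties are treated in the secondary (Kruskal) sense: pairs with
    equal input dissimilarity share one disparity, so degenerate all-tied
    inputs cannot trivially reach zero stress."""
    from scipy.optimize import isotonic_regression

    uD, inv = np.unique(D, return_inverse=True)
    w = np.bincount(inv).astype(float)
    block_means = np.bincount(inv, weights=d) / w
    fit = isotonic_regression(block_means, weights=w).x
    return fit[inv]


def nmds(
    similarity: SimilarityMatrix,
    dims: int = 2,
    n_restarts: int = 20,
    max_iter: int = 1000,
    seed: int = 0,
    tol: float = 1e-10,
) -> NmdsEmbedding:
    """Non-metric MDS minimizing Kruskal stress-1.

    Each restart starts from seeded random coordinates and alternates an
    isotonic (pool-adjacent-violators) fit of disparities (secondary tie
    treatment) with a Guttman majorization update; an update that would
    increase stress is step-halved toward the current configuration and the
    restart stops when no improvement is possible.  The best of
    ``n_restarts`` is returned.
    """
    D = similarity.condensed_dissimilarity()
    n = len(similarity.ids)
    if n < dims + 1:
        raise ValueError("need at least dims + 1 samples")
    iu, ju = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)

    best_X, best_stress, any_converged = None, np.inf, False
    for _ in range(n_restarts):
        X = rng.normal(size=(n, dims))
        stress = kruskal_stress(X, D)
        converged = False
        for _ in range(max_iter):
            d = pdist(X)
            dhat = _isotonic_disparities(d, D)
            # Guttman transform with unit weights
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = np.zeros((n, n))
            B[iu, ju] = -ratio
            B[ju, iu] = -ratio
            np.fill_diagonal(B, -B.sum(axis=1))
            X_new = B @ X / n
            new_stress = kruskal_stress(X_new, D)
            # step-halve if majorization overshoots the nonmetric objective
            halvings = 0
            while new_stress > stress and halvings < 8:
                X_new = (X_new + X) / 2.0
                new_stress = kruskal_stress(X_new, D)
                halvings += 1
            if new_stress > stress:
                converged = True
                break
            if stress - new_stress < tol:
                X, stress = X_new, new_stress
                converged = True
                break
            X, stress = X_new, new_stress
        if stress < best_stress:
            best_X, best_stress = X, stress
        any_converged = any_converged or converged

    if not any_converged:
        warnings.warn("NMDS did not converge in any restart")
    # center and principal-axis-align for reproducible presentation
    Xc = best_X - best_X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    Xc = Xc @ vt.T
    return NmdsEmbedding(
        coordinates=Xc,
        stress=float(kruskal_stress(Xc, D)),
        n_restarts=n_restarts,
        converged=any_converged,
        ids=list(similarity.ids),
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray


def pca(env_table: pd.DataFrame, normalize: bool = True) -> PcaResult:
    """PCA by eigen-decomposition of the covariance (or, with ``normalize``,
    correlation) matrix; components ordered by decreasing variance, sign fixed
    so each component's largest-magnitude loading is positive."""
    X = env_table.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 variables")
    Xc = X - X.mean(axis=0)
    if normalize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = env_table.columns[np.nonzero(sd == 0)[0][0]]
            raise ValueError(f"constant variable {bad!r} cannot be z-scored")
        Xc = Xc / sd
    C = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.abs(eigvec[:, k]).argmax()
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    comps = [f"PC{k+1}" for k in range(eigvec.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(eigvec, index=env_table.columns, columns=comps),
        scores=pd.DataFrame(Xc @ eigvec, index=env_table.index, columns=comps),
        variance_explained=eigval / eigval.sum(),
    )


def ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of a simple linear regression of y on x."""
    from scipy.stats import linregress

    return float(linregress(np.asarray(x, float), np.asarray(y, float)).rvalue ** 2)
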