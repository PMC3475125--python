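"""Discrimination-threshold calibration and emission modification.

Gene families often cross-react: homologous families of the same fold score
well against each other's profiles.  This layer raises specificity in three
steps: (1) subgroup the training set with Markov clustering on a k-mer
similarity graph, (2) pick a bit-score discrimination threshold by n-fold
cross-validation, maximizing the fold-averaged Matthews correlation
coefficient, and (3) re-estimate match emissions against the false-positive
alignment so that match scores become log2(p_TP / p_FP), then recalibrate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .profile_hmm import (
    MultipleAlignment,
    ProfileModel,
    build_profile,
    score_sequence,
    viterbi_match_path,
)

__all__ = [
    "ClusterAssignment",
    "CrossValidationResult",
    "ModifiedProfile",
    "kmer_similarity_graph",
    "mcl_cluster",
    "compute_mcc",
    "crossvalidate_threshold",
    "modify_emissions",
    "calibrate_family",
    "write_calibration_tsv",
]


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]
    n_clusters: int
    inflation: float


@dataclass
class FoldResult:
    tp_scores: np.ndarray
    fp_scores: np.ndarray
    mcc_curve: np.ndarray  # MCC at each pooled candidate threshold


@dataclass
class CrossValidationResult:
    n_folds: int
    per_fold: list[FoldResult]
    candidate_thresholds: np.ndarray
    mean_mcc_curve: np.ndarray
    chosen_threshold: float
    max_mean_mcc: float
    sensitivity: float
    specificity: float
    discriminative: bool = True
    fold_membership: list[list[int]] = field(default_factory=list)


@dataclass
class ModifiedProfile:
    """Profile whose match scores are log2(p_TP/p_FP) instead of log2(p_TP/null)."""

    base: ProfileModel
    fp_emissions: np.ndarray
    recalibrated_threshold: float | None = None

    @property
    def gene_id(self) -> str:
        return self.base.gene_id

    @property
    def subgroup_id(self) -> str:
        return self.base.subgroup_id

    def match_score_matrix(self) -> np.ndarray:
        return np.log2(self.base.match_emissions / self.fp_emissions)

    def score(self, sequence: str) -> float:
        return score_sequence(self.base, sequence, match_scores=self.match_score_matrix())


# ---------------------------------------------------------------------------
# Subgroup clustering
# ---------------------------------------------------------------------------

def kmer_similarity_graph(sequences: list[str], k: int = 3) -> np.ndarray:
    """Cosine similarity of k-mer count vectors; diagonal set to 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(sequences)
    counts: list[dict[str, int]] = []
    norms = np.zeros(n)
    for s in sequences:
        d: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            d[w] = d.get(w, 0) + 1
        counts.append(d)
        norms[len(counts) - 1] = math.sqrt(sum(v * v for v in d.values()))
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 or norms[j] == 0:
                warnings.warn(f"sequence shorter than k={k}; similarity set to 0")
                continue
            a, b = counts[i], counts[j]
            if len(b) < len(a):
                a, b = b, a
            dot = sum(v * b.get(w, 0) for w, v in a.items())
            sim[i, j] = sim[j, i] = dot / (norms[i] * norms[j])
    np.fill_diagonal(sim, 1.0)
    return sim


def mcl_cluster(
    similarity: np.ndarray,
    ids: list[str] | None = None,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Markov clustering: alternate expansion (squaring) and inflation
    (elementwise power + column normalization) until convergence; clusters
    are the connected components of the converged attractor matrix."""
    sim = np.asarray(similarity, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(sim, sim.T, atol=1e-9):
        raise ValueError("similarity must be symmetric")
    if (sim < 0).any():
        raise ValueError("similarity must be nonnegative")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    n = sim.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]

    M = sim.copy()
    np.fill_diagonal(M, np.maximum(M.diagonal(), 1.0))  # self-loops stabilize
    colsum = M.sum(axis=0)
    M = M / colsum
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = np.power(M, inflation)  # inflation
        s = M.sum(axis=0)
        s[s == 0] = 1.0
        M = M / s
        M[M < 1e-12] = 0.0
        s = M.sum(axis=0)
        s[s == 0] = 1.0
        M = M / s
        if np.abs(M - prev).max() < tol:
            break

    adj = (M > 1e-6) | (M.T > 1e-6)
    np.fill_diagonal(adj, True)
    labels = _connected_components(adj)
    assignment = {ids[i]: int(labels[i]) for i in range(n)}
    return ClusterAssignment(
        assignment=assignment, n_clusters=int(labels.max()) + 1, inflation=inflation
    )


def _connected_components(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    labels = np.full(n, -1, dtype=int)
    cur = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = cur
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u])[0]:
                if labels[v] < 0:
                    labels[v] = cur
                    stack.append(v)
        cur += 1
    return labels


# ---------------------------------------------------------------------------
# MCC and threshold cross-validation
# ---------------------------------------------------------------------------

def compute_mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion-matrix counts must be nonnegative")
    if tp + fp + tn + fn == 0:
        raise ValueError("all-zero confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _mcc_curve(tp_scores: np.ndarray, fp_scores: np.ndarray, candidates: np.ndarray):
    """MCC at each candidate threshold (predict positive when score >= c)."""
    out = np.empty(len(candidates))
    n_pos, n_neg = len(tp_scores), len(fp_scores)
    for i, c in enumerate(candidates):
        tp = int((tp_scores >= c).sum())
        fp = int((fp_scores >= c).sum())
        out[i] = compute_mcc(tp, fp, n_neg - fp, n_pos - tp)
    return out


def assign_folds(n_items: int, n_folds: int, seed: int) -> list[list[int]]:
    """Seeded shuffle followed by round-robin fold assignment."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(int(idx))
    return folds


def crossvalidate_threshold(
    positives: MultipleAlignment,
    negatives: list[str],
    n_folds: int = 5,
    seed: int = 0,
    pseudocount_weight: float = 1.0,
    scorer_factory=None,
) -> CrossValidationResult:
    """Pick the discrimination threshold by n-fold cross-validation.

    Each fold holds out part of the positive training alignment; a profile
    built from the remaining rows scores the held-out positives (TP scores)
    and all negatives (FP scores).  The threshold is the midpoint of the
    score interval bracketing the maximum of the fold-averaged MCC curve,
    ties broken toward the higher (more specific) score.

    ``scorer_factory(train_alignment) -> callable(str) -> float`` overrides
    profile construction + scoring (used for emission-modified recalibration).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if positives.n_rows < n_folds:
        raise ValueError("fewer positive sequences than folds")

    folds = assign_folds(positives.n_rows, n_folds, seed)
    per_fold_scores: list[tuple[np.ndarray, np.ndarray]] = []
    for test_idx in folds:
        train_idx = [i for i in range(positives.n_rows) if i not in set(test_idx)]
        train_aln = positives.subset(train_idx)
        if scorer_factory is None:
            prof = build_profile(train_aln, pseudocount_weight)
            scorer = lambda s, p=prof: score_sequence(p, s)
        else:
            scorer = scorer_factory(train_aln)
        tp = np.array([scorer(positives.ungapped(i)) for i in test_idx])
        fp = np.array([scorer(s) for s in negatives])
        per_fold_scores.append((tp, fp))

    candidates = np.unique(np.concatenate([np.concatenate(fs) for fs in per_fold_scores]))
    per_fold = [
        FoldResult(tp, fp, _mcc_curve(tp, fp, candidates)) for tp, fp in per_fold_scores
    ]
    mean_curve = np.mean([f.mcc_curve for f in per_fold], axis=0)
    max_mcc = float(mean_curve.max())
    # highest candidate achieving the max (ties toward specificity)
    best_i = int(np.nonzero(np.isclose(mean_curve, max_mcc))[0][-1])
    c_star = candidates[best_i]
    if best_i > 0:
        chosen = float((candidates[best_i - 1] + c_star) / 2.0)
    else:
        chosen = float(c_star)

    # Fold-averaged sensitivity/specificity at the chosen threshold.
    sens, spec = [], []
    for f in per_fold:
        n_pos, n_neg = len(f.tp_scores), len(f.fp_scores)
        tp = int((f.tp_scores >= chosen).sum())
        fp = int((f.fp_scores >= chosen).sum())
        sens.append(tp / n_pos if n_pos else 0.0)
        spec.append((n_neg - fp) / n_neg if n_neg else 1.0)

    return CrossValidationResult(
        n_folds=n_folds,
        per_fold=per_fold,
        candidate_thresholds=candidates,
        mean_mcc_curve=mean_curve,
        chosen_threshold=chosen,
        max_mean_mcc=max_mcc,
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        discriminative=max_mcc >= 0.5,
        fold_membership=folds,
    )


# ---------------------------------------------------------------------------
# Emission modification from the FP alignment
# ---------------------------------------------------------------------------

def estimate_fp_emissions(
    profile: ProfileModel,
    fp_alignment: MultipleAlignment,
    pseudocount_weight: float = 1.0,
) -> np.ndarray:
    from .profile_hmm import AA_INDEX

    K = profile.n_match
    if fp_alignment.n_cols != K:
        raise ValueError(
            f"FP alignment has {fp_alignment.n_cols} columns, profile has {K} match states"
        )
    # Dirichlet shrinkage toward the null: with no FP evidence at a state the
    # FP emission equals the null and the modified score reduces to the base
    # score; FP counts pull it away only where the decoys are consistent.
    em = np.tile(20.0 * pseudocount_weight * profile.null_emissions, (K, 1))
    for row in fp_alignment.rows:
        for k, ch in enumerate(row):
            j = AA_INDEX.get(ch)
            if j is not None:
                em[k, j] += 1.0
    em /= em.sum(axis=1, keepdims=True)
    return em


def align_fps_to_profile(profile: ProfileModel, fp_sequences: list[str]) -> MultipleAlignment:
    """Align false positives to the profile via their Viterbi match-state path."""
    rows = []
    for s in fp_sequences:
        _, assigned = viterbi_match_path(profile, s)
        rows.append(assigned)
    return MultipleAlignment(
        ids=tuple(f"fp{i}" for i in range(len(rows))), rows=tuple(rows)
    )


def modify_emissions(
    profile: ProfileModel,
    fp_alignment: MultipleAlignment,
    pseudocount_weight: float = 1.0,
) -> ModifiedProfile:
    """Replace the match-score denominator with per-state FP frequencies."""
    fp_em = estimate_fp_emissions(profile, fp_alignment, pseudocount_weight)
    return ModifiedProfile(base=profile, fp_emissions=fp_em)


@dataclass
class CalibrationResult:
    profile: ProfileModel  # threshold set from base CV
    base_cv: CrossValidationResult
    modified: ModifiedProfile | None  # None when no FP crossed the base threshold
    modified_cv: CrossValidationResult | None
    n_fp_used: int


def calibrate_family(
    positives: MultipleAlignment,
    negatives: list[str],
    n_folds: int = 5,
    seed: int = 0,
    pseudocount_weight: float = 1.0,
    modify: bool = True,
    gene_id: str = "gene",
    subgroup_id: str = "sg0",
) -> CalibrationResult:
    """Full calibration: base CV threshold, then FP-based emission modification
    with a recalibrated threshold (CV re-run with the modified scorer)."""
    base_cv = crossvalidate_threshold(
        positives, negatives, n_folds, seed, pseudocount_weight
    )
    profile = build_profile(
        positives, pseudocount_weight, gene_id=gene_id, subgroup_id=subgroup_id
    )
    profile.threshold = base_cv.chosen_threshold

    if not modify:
        return CalibrationResult(profile, base_cv, None, None, 0)

    fp_seqs = [s for s in negatives if score_sequence(profile, s) >= profile.threshold]
    if not fp_seqs:
        return CalibrationResult(profile, base_cv, None, None, 0)

    fp_aln = align_fps_to_profile(profile, fp_seqs)
    modified = modify_emissions(profile, fp_aln, pseudocount_weight)

    def scorer_factory(train_aln: MultipleAlignment):
        fold_prof = build_profile(train_aln, pseudocount_weight)
        fold_fp_aln = align_fps_to_profile(fold_prof, fp_seqs)
        fold_mod = modify_emissions(fold_prof, fold_fp_aln, pseudocount_weight)
        return lambda s: fold_mod.score(s)

    mod_cv = crossvalidate_threshold(
        positives, negatives, n_folds, seed, pseudocount_weight,
        scorer_factory=scorer_factory,
    )
    modified.recalibrated_threshold = mod_cv.chosen_threshold
    return CalibrationResult(profile, base_cv, modified, mod_cv, len(fp_seqs))


def write_calibration_tsv(cv: CrossValidationResult, gene_id: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tfold\tsensitivity\tspecificity\tmax_mcc\tchosen_threshold\n")
        for i, f in enumerate(cv.per_fold):
            n_pos, n_neg = len(f.tp_scores), len(f.fp_scores)
            tp = int((f.tp_scores >= cv.chosen_threshold).sum())
            fp = int((f.fp_scores >= cv.chosen_threshold).sum())
            sens = tp / n_pos if n_pos else 0.0
            spec = (n_neg - fp) / n_neg if n_neg else 1.0
            fh.write(
                f"{gene_id}\t{i}\t{sens:.4f}\t{spec:.4f}\t"
                f"{f.mcc_curve.max():.4f}\t{cv.chosen_threshold:.4f}\n"
            )
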