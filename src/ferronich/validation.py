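"""Self-validation experiments: algebraic identities, oracle equivalences,
and recovery rates on synthetic data with known ground truth.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline, and returns the measured quantity.  The exhaustive oracles
here (path enumeration, pathway enumeration, hand path-sums) are written
independently of the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import hmm_mode, molevo, stats, synthetic as syn
from .profile_hmm import (
    AA_INDEX, AMINO_ACIDS, MultipleAlignment, ProfileModel, build_profile,
    score_sequence,
)

__all__ = [
    "simper_braycurtis_identity",
    "anosim_construction_checks",
    "anosim_type1_error_rate",
    "planted_effect_recovery",
    "hmm_mode_benefit",
    "separable_cv_mcc",
    "brute_force_viterbi",
    "viterbi_oracle_equivalence",
    "nmds_stress_checks",
    "dnds_recovery",
    "brute_force_pathway_counts",
    "ng86_pathway_equivalence",
    "patristic_checks",
    "simulate_null_counts",
    "simulate_planted_counts",
]


# ---------------------------------------------------------------------------
# Community-statistics identities and error rates
# ---------------------------------------------------------------------------

def simper_braycurtis_identity(
    n_matrices: int = 100, n_samples: int = 10, n_genes: int = 20, seed: int = 0
) -> float:
    """Max |sum_i delta_jk(i) - (100 - S_jk)| over all cross-group pairs of
    random count matrices; zero up to round-off by construction of the two
    formulas."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        Y = rng.integers(0, 30, size=(n_samples, n_genes)).astype(float)
        ids = [f"s{i}" for i in range(n_samples)]
        df = pd.DataFrame(Y, index=ids, columns=[f"g{j}" for j in range(n_genes)])
        labels = {s: ("A" if i < n_samples // 2 else "B") for i, s in enumerate(ids)}
        S = stats.bray_curtis(df).S
        ia = [i for i, s in enumerate(ids) if labels[s] == "A"]
        ib = [i for i, s in enumerate(ids) if labels[s] == "B"]
        # per-pair contributions recomputed directly from the definition
        for j in ia:
            for k in ib:
                denom = (Y[j] + Y[k]).sum()
                if denom == 0:
                    continue
                contrib = 100.0 * np.abs(Y[j] - Y[k]) / denom
                worst = max(worst, abs(contrib.sum() - (100.0 - S[j, k])))
    return worst


def anosim_construction_checks(n_perm: int = 199, seed: int = 0):
    """R on maximal-separation and constant dissimilarities.

    The separation case uses 2 groups x 8 samples with strictly distinct
    dissimilarities (every between-group dissimilarity above every
    within-group one), so only a permutation reproducing the exact partition
    could tie the observed R = 1; the significance then sits at its minimum
    (t+1)/(T+1) = 1/(T+1) whenever no sampled permutation does.
    """
    n = 16
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    labels = {s: ("A" if i < n // 2 else "B") for i, s in enumerate(ids)}
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < n // 2) == (j < n // 2)
            d = rng.uniform(5, 15) if same else rng.uniform(60, 90)
            D[i, j] = D[j, i] = d
    r_max = stats.anosim(stats.SimilarityMatrix(ids, 100.0 - D), labels, n_perm, seed)

    Sc = np.full((n, n), 50.0)
    np.fill_diagonal(Sc, 100.0)
    r_const = stats.anosim(stats.SimilarityMatrix(ids, Sc), labels, n_perm, seed)
    return r_max, r_const


def simulate_null_counts(spec: syn.CommunitySimSpec) -> tuple[pd.DataFrame, dict]:
    """Truth-count matrix straight from the community count model (no
    sequence simulation), with group labels."""
    rng = np.random.default_rng(syn.child_seed(spec.seed, 2))
    genes = [f"g{j}" for j in range(spec.n_genes)]
    rows, labels = {}, {}
    for g in range(spec.n_groups):
        grp = f"G{g}"
        for j in range(spec.samples_per_group):
            sid = f"{grp}_s{j}"
            labels[sid] = grp
            counts = []
            for gene in genes:
                mean = spec.baseline_mean
                planted = spec.planted_genes.get(gene)
                if planted is not None and planted[0] == grp:
                    mean *= planted[1]
                if mean <= 0:
                    counts.append(0)
                else:
                    counts.append(
                        int(rng.negative_binomial(
                            spec.dispersion, spec.dispersion / (spec.dispersion + mean)
                        ))
                    )
            rows[sid] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=genes), labels


simulate_planted_counts = simulate_null_counts  # same model; spec carries the effects


def anosim_type1_error_rate(
    n_datasets: int = 500, n_perm: int = 199, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of ANOSIM at level alpha on matrices with no group
    structure (2 groups x 8 samples)."""
    rej = 0
    for rep in range(n_datasets):
        spec = syn.CommunitySimSpec(
            n_groups=2, samples_per_group=8, n_genes=20, seed=seed * 1000 + rep
        )
        df, labels = simulate_null_counts(spec)
        sim = stats.bray_curtis(stats.transform_matrix(df, "log"))
        res = stats.anosim(sim, labels, n_perm=n_perm, seed=seed + rep)
        rej += res.significance <= alpha
    return rej / n_datasets


def planted_effect_recovery(
    n_datasets: int = 100,
    effect: float = 4.0,
    n_planted: int = 5,
    top_n: int = 7,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[float, float]:
    """(ANOSIM rejection rate, fraction of datasets placing all planted genes
    in the SIMPER top ``top_n`` by the mean/SD ratio) for communities with
    one group's genes planted at the given effect multiplier."""
    n_sig = n_top = 0
    genes = [f"g{j}" for j in range(20)]
    planted = {g: ("G0", effect) for g in genes[:n_planted]}
    for rep in range(n_datasets):
        spec = syn.CommunitySimSpec(
            n_groups=2, samples_per_group=8, n_genes=20,
            planted_genes=planted, seed=seed * 1000 + rep,
        )
        df, labels = simulate_planted_counts(spec)
        tr = stats.transform_matrix(df, "log")
        sim = stats.bray_curtis(tr)
        res = stats.anosim(sim, labels, n_perm=n_perm, seed=seed + rep)
        n_sig += res.significance <= 0.05
        st = stats.simper(tr, labels, ("G0", "G1"))
        top = set(st.table.sort_values("ratio", ascending=False).head(top_n).index)
        n_top += set(genes[:n_planted]) <= top
    return n_sig / n_datasets, n_top / n_datasets


# ---------------------------------------------------------------------------
# HMM-ModE benefit and separable-regime calibration
# ---------------------------------------------------------------------------

def _fp_at_matched_sensitivity(pos: np.ndarray, neg: np.ndarray, sens: float) -> int:
    k = int(np.ceil(sens * len(pos)))
    thr = np.sort(pos)[::-1][k - 1]
    return int((neg >= thr).sum())


def hmm_mode_benefit(
    n_families: int = 50,
    divergence_decoy: float = 0.3,
    sensitivity: float = 0.9,
    seed: int = 0,
) -> float:
    """Fraction of simulated families (related-family decoys) where the
    emission-modified profile yields FP count <= the unmodified profile at
    matched sensitivity."""
    n_le = 0
    for rep in range(n_families):
        fam = syn.simulate_protein_family(
            syn.FamilySimSpec(
                divergence_decoy=divergence_decoy, decoy_mode="related_family",
                n_decoy=20, seed=seed * 1000 + rep, gene_id=f"fam{rep}",
            )
        )
        negatives = [s for _, s in fam.decoys]
        cal = hmm_mode.calibrate_family(
            fam.alignment, negatives, n_folds=5, seed=seed + rep,
            gene_id=fam.gene_id,
        )
        pos = np.array([score_sequence(cal.profile, s) for _, s in fam.positives])
        neg = np.array([score_sequence(cal.profile, s) for _, s in fam.decoys])
        fp_base = _fp_at_matched_sensitivity(pos, neg, sensitivity)
        if cal.modified is None:
            fp_mod = fp_base
        else:
            mpos = np.array([cal.modified.score(s) for _, s in fam.positives])
            mneg = np.array([cal.modified.score(s) for _, s in fam.decoys])
            fp_mod = _fp_at_matched_sensitivity(mpos, mneg, sensitivity)
        n_le += fp_mod <= fp_base
    return n_le / n_families


def separable_cv_mcc(n_families: int = 10, seed: int = 0) -> float:
    """Minimum fold-averaged maximal MCC across families in the separable
    regime (shuffled-ancestor decoys, low divergence); expected 1."""
    worst = 1.0
    for rep in range(n_families):
        fam = syn.simulate_protein_family(
            syn.FamilySimSpec(
                divergence_true=0.05, decoy_mode="shuffled_ancestor",
                seed=seed * 500 + rep, gene_id=f"sep{rep}",
            )
        )
        cv = hmm_mode.crossvalidate_threshold(
            fam.alignment, [s for _, s in fam.decoys], n_folds=5, seed=seed + rep
        )
        worst = min(worst, cv.max_mean_mcc)
    return worst


# ---------------------------------------------------------------------------
# Viterbi oracle
# ---------------------------------------------------------------------------

def brute_force_viterbi(profile: ProfileModel, seq: str) -> float:
    """Exhaustive maximization over all local state paths (free entry to any
    match state, free exit from any match state); independent of the DP."""
    K = profile.n_match
    L = len(seq)
    em = profile.match_score_matrix()
    ei = profile.insert_score_matrix()
    with np.errstate(divide="ignore"):
        lt = {
            n: np.log2(getattr(profile, n))
            for n in ("t_mm", "t_mi", "t_md", "t_ii", "t_im", "t_dd", "t_dm")
        }

    def esc(mat, k, ch):
        j = AA_INDEX.get(ch)
        return 0.0 if j is None else mat[k, j]

    best = [-np.inf]

    def walk(state, k, i, score):
        if state == "M":
            best[0] = max(best[0], score)
            if k + 1 < K:
                if i < L:
                    walk("M", k + 1, i + 1, score + lt["t_mm"][k] + esc(em, k + 1, seq[i]))
                    walk("I", k, i + 1, score + lt["t_mi"][k] + esc(ei, k, seq[i]))
                walk("D", k + 1, i, score + lt["t_md"][k])
        elif state == "I":
            if i < L:
                walk("I", k, i + 1, score + lt["t_ii"][k] + esc(ei, k, seq[i]))
                walk("M", k + 1, i + 1, score + lt["t_im"][k] + esc(em, k + 1, seq[i]))
        else:
            if k + 1 < K:
                if i < L:
                    walk("M", k + 1, i + 1, score + lt["t_dm"][k] + esc(em, k + 1, seq[i]))
                walk("D", k + 1, i, score + lt["t_dd"][k])

    for i0 in range(L):
        for k0 in range(K):
            walk("M", k0, i0 + 1, esc(em, k0, seq[i0]))
    return best[0]


def toy_profile_suite(seed: int = 0, n_cases: int = 40):
    """Random toy profiles (<= 4 match states) and sequences (<= 6 residues)."""
    rng = np.random.default_rng(seed)
    cases = []
    while len(cases) < n_cases:
        K = int(rng.integers(1, 5))
        n_rows = int(rng.integers(2, 5))
        ncols = K + int(rng.integers(0, 3))
        rows = [
            "".join(
                AMINO_ACIDS[rng.integers(20)] if rng.random() > 0.3 else "-"
                for _ in range(ncols)
            )
            for _ in range(n_rows)
        ]
        rows = [AMINO_ACIDS[rng.integers(20)] + r[1:] for r in rows]
        try:
            prof = build_profile(
                MultipleAlignment(
                    tuple(f"s{i}" for i in range(n_rows)), tuple(rows)
                )
            )
        except Exception:
            continue
        if prof.n_match > 4:
            continue
        L = int(rng.integers(1, 7))
        seq = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(L))
        cases.append((prof, seq))
    return cases


def viterbi_oracle_equivalence(seed: int = 0, n_cases: int = 40) -> float:
    """Max |Viterbi - exhaustive enumeration| over the toy fixture suite."""
    worst = 0.0
    for prof, seq in toy_profile_suite(seed, n_cases):
        worst = max(worst, abs(score_sequence(prof, seq) - brute_force_viterbi(prof, seq)))
    return worst


# ---------------------------------------------------------------------------
# NMDS stress checks
# ---------------------------------------------------------------------------

def nmds_stress_checks(seed: int = 0) -> tuple[float, float, float]:
    """(3-point stress, 10-point self-recovery stress, 4-equidistant stress)."""
    from scipy.spatial.distance import pdist, squareform

    D3 = np.array([[0, 30, 40], [30, 0, 50], [40, 50, 0]], float)
    s3 = stats.nmds(
        stats.SimilarityMatrix(["a", "b", "c"], 100 - D3),
        n_restarts=10, seed=seed,
    ).stress

    rng = np.random.default_rng(seed)
    X = rng.normal(size=(10, 2))
    D10 = squareform(pdist(X))
    D10 = 90.0 * D10 / D10.max()
    s10 = stats.nmds(
        stats.SimilarityMatrix([f"p{i}" for i in range(10)], 100 - D10),
        n_restarts=20, seed=seed + 1,
    ).stress

    D4 = np.full((4, 4), 40.0)
    np.fill_diagonal(D4, 0.0)
    s4 = stats.nmds(
        stats.SimilarityMatrix(list("abcd"), 100 - D4), n_restarts=10, seed=seed + 2
    ).stress
    return s3, s10, s4


# ---------------------------------------------------------------------------
# dN/dS recovery and pathway oracle
# ---------------------------------------------------------------------------

def dnds_recovery(
    omegas=(0.2, 1.0, 3.0), n_codons: int = 300, n_reps: int = 50, seed: int = 0
) -> dict[float, float]:
    """Mean estimated omega per planted omega over replicate codon pairs."""
    out = {}
    for w_i, omega in enumerate(omegas):
        ests = []
        for rep in range(n_reps):
            s1, s2 = syn.simulate_codon_pair(
                syn.CodonPairSimSpec(
                    n_codons=n_codons, omega=omega, branch_length=0.3,
                    seed=seed * 10000 + w_i * 1000 + rep,
                )
            )
            est = molevo.dnds_pairwise_ng86(s1, s2)
            if est.omega is not None:
                ests.append(est.omega)
        out[omega] = float(np.mean(ests))
    return out


def brute_force_pathway_counts(c1: str, c2: str):
    """Average (syn, nonsyn) differences over minimal mutational pathways by
    direct permutation enumeration, skipping stop-codon intermediates."""
    from .synthetic import CODON_TABLE, STOP_CODONS

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            if CODON_TABLE.get(cur, "*") == CODON_TABLE.get(nxt, "*"):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, ok))
    valid = [(s, n) for s, n, ok in results if ok]
    if not valid:
        valid = [(s, n) for s, n, _ in results]
    return (
        float(np.mean([s for s, _ in valid])),
        float(np.mean([n for _, n in valid])),
    )


def ng86_pathway_equivalence() -> float:
    """Max |implementation - enumeration| over ALL 2- and 3-difference sense
    codon pairs."""
    worst = 0.0
    for c1 in syn.SENSE_CODONS:
        for c2 in syn.SENSE_CODONS:
            nd = sum(a != b for a, b in zip(c1, c2))
            if nd not in (2, 3):
                continue
            sd_i, nd_i = molevo.ng86_difference_counts(c1, c2)
            sd_o, nd_o = brute_force_pathway_counts(c1, c2)
            worst = max(worst, abs(sd_i - sd_o), abs(nd_i - nd_o))
    return worst


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

def patristic_checks(n_trees: int = 100, seed: int = 0) -> tuple[float, float]:
    """(hand-check mean for the 3-leaf example, max |module - simulator
    truth| over random trees)."""
    # 3-leaf tree with pairwise distances (0.2, 0.4, 0.4)
    names, D = molevo.patristic_distances("((a:0.1,b:0.1):0.1,c:0.2);")
    idx = {n: i for i, n in enumerate(names)}
    hand = (D[idx["a"], idx["b"]] + D[idx["a"], idx["c"]] + D[idx["b"], idx["c"]]) / 3.0

    worst = 0.0
    rng = np.random.default_rng(seed)
    for rep in range(n_trees):
        n_taxa = int(rng.integers(4, 12))
        tr = syn.simulate_tree(n_taxa, seed=seed * 1000 + rep)
        names, Dm = molevo.patristic_distances(tr.newick)
        order = [names.index(t) for t in tr.taxa]
        worst = max(worst, float(np.abs(tr.distances - Dm[np.ix_(order, order)]).max()))
    return float(hand), worst
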