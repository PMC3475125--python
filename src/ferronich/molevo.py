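"""Per-gene evolutionary summaries.

Two quantities per gene: the phylogenetic spread, i.e. the average patristic
(branch-length path) distance among the genomes carrying the gene, and the
average pairwise dN/dS estimated with the Nei-Gojobori (1986) counting
method with Jukes-Cantor correction.  A gene with mean dN/dS > 1 is classed
as under positive selection, < 1 purifying, = 1 neutral.

The counting estimator replaces maximum-likelihood pairwise estimation; it
is self-contained and exhaustively checkable (pathway counts for 2- and
3-difference codons can be enumerated by brute force).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .profile_hmm import MultipleAlignment
from .synthetic import CODON_TABLE, STOP_CODONS

__all__ = [
    "PhylospreadResult",
    "DnDsEstimate",
    "patristic_distances",
    "phylogenetic_spread",
    "codon_align_from_protein",
    "ng86_site_counts",
    "ng86_difference_counts",
    "dnds_pairwise_ng86",
    "gene_dnds_summary",
]


# ---------------------------------------------------------------------------
# Patristic distances and phylogenetic spread
# ---------------------------------------------------------------------------

def patristic_distances(tree: str | Path) -> tuple[list[str], np.ndarray]:
    """Leaf x leaf matrix of branch-length path distances from a newick tree.

    ``tree`` is a newick string or a path to one.  Distances are computed by
    a root-path traversal: d(a, b) = depth(a) + depth(b) - 2 * depth(lca).
    """
    import dendropy

    text = str(tree)
    if "(" not in text:  # looks like a path
        text = Path(tree).read_text()
    t = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    for edge in t.preorder_edge_iter():
        if edge.head_node is not t.seed_node and edge.length is None:
            raise ValueError("tree has a missing branch length")

    leaves = [lf for lf in t.leaf_node_iter()]
    names = [lf.taxon.label for lf in leaves]
    if len(set(names)) != len(names):
        raise ValueError("leaf labels must be unique")

    # depth of every node from the root
    depth: dict = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    # ancestor sets for LCA by walking up
    def ancestors(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    anc = {lf: ancestors(lf) for lf in leaves}
    anc_sets = {lf: set(id(x) for x in anc[lf]) for lf in leaves}
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sj = anc_sets[leaves[j]]
            lca = next(x for x in anc[leaves[i]] if id(x) in sj)
            d = depth[leaves[i]] + depth[leaves[j]] - 2.0 * depth[lca]
            D[i, j] = D[j, i] = d
    return names, D


@dataclass
class PhylospreadResult:
    gene_id: str
    P: float | None  # average pairwise patristic distance; None if < 2 genomes
    n_genomes: int


def phylogenetic_spread(
    presence: dict[str, set[str]],
    leaf_ids: list[str],
    distances: np.ndarray,
) -> list[PhylospreadResult]:
    """Average patristic distance among the genomes carrying each gene."""
    index = {name: i for i, name in enumerate(leaf_ids)}
    out = []
    for gene in sorted(presence):
        genomes = sorted(presence[gene])
        missing = [g for g in genomes if g not in index]
        if missing:
            raise ValueError(f"genome ids not in tree: {missing}")
        if len(genomes) < 2:
            out.append(PhylospreadResult(gene, None, len(genomes)))
            continue
        idx = [index[g] for g in genomes]
        pairs = [
            distances[a, b] for a, b in itertools.combinations(idx, 2)
        ]
        out.append(PhylospreadResult(gene, float(np.mean(pairs)), len(genomes)))
    return out


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

def codon_align_from_protein(
    protein_alignment: MultipleAlignment,
    coding_sequences: dict[str, str],
) -> dict[str, str]:
    """Back-translate a protein alignment into a codon alignment.

    Each residue column expands to its source codon; gaps expand to '---'.
    The CDS must translate to the ungapped protein row exactly.
    """
    out = {}
    for rid, row in zip(protein_alignment.ids, protein_alignment.rows):
        cds = coding_sequences.get(rid)
        if cds is None:
            raise ValueError(f"no CDS for {rid}")
        ungapped = [c for c in row if c not in "-."]
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"CDS length {len(cds)} != 3 x protein length {len(ungapped)} for {rid}"
            )
        codons, aligned, k = [], [], 0
        for col, ch in enumerate(row):
            if ch in "-.":
                aligned.append("---")
                continue
            codon = cds[3 * k : 3 * k + 3]
            aa = CODON_TABLE.get(codon, "X")
            if aa != ch and ch != "X":
                raise ValueError(
                    f"translation mismatch for {rid} at column {col}: "
                    f"codon {codon} -> {aa}, protein has {ch}"
                )
            aligned.append(codon)
            k += 1
        out[rid] = "".join(aligned)
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986 pairwise dN/dS
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    At each position the three alternative nucleotides are classified;
    changes producing stop codons are inaccessible and removed from the
    denominator, so the per-codon counts always sum to exactly 3.
    """
    syn = 0.0
    for pos in range(3):
        n_syn, n_valid = 0, 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if CODON_TABLE[alt] == CODON_TABLE[codon]:
                n_syn += 1
        syn += (n_syn / n_valid) if n_valid else 0.0
    return syn, 3.0 - syn


def ng86_site_counts(seq: str) -> tuple[float, float]:
    """Total (S, N) site counts of a gapless coding sequence."""
    S = N = 0.0
    for i in range(0, len(seq), 3):
        s, n = _codon_site_counts(seq[i : i + 3])
        S += s
        N += n
    return S, N


def ng86_difference_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal mutational pathways; pathways through stop codons are
    excluded (if every pathway is blocked, all pathways are used)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TABLE.get(cur, "*") == CODON_TABLE.get(nxt, "*"):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, blocked))
    valid = [(s, n) for s, n, b in paths if not b]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    sd = float(np.mean([s for s, _ in valid]))
    nd = float(np.mean([n for _, n in valid]))
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        return None
    if p >= 0.75:
        return None  # correction undefined
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class PairwiseDnDs:
    dN: float | None
    dS: float | None
    omega: float | None
    n_codons: int


def dnds_pairwise_ng86(seq1: str, seq2: str, min_codons: int = 30) -> PairwiseDnDs:
    """Nei-Gojobori counting dN/dS for one aligned codon sequence pair.

    Gap- or ambiguity-containing codons are skipped; proportions are
    Jukes-Cantor corrected; omega is None when dS is 0 or a correction is
    undefined (p >= 3/4).
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    if len(seq1) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_comp = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1, n1 = _codon_site_counts(c1)
        s2, n2 = _codon_site_counts(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = ng86_difference_counts(c1, c2)
        Sd += sd
        Nd += nd
        n_comp += 1
    if n_comp < min_codons:
        raise ValueError(f"only {n_comp} comparable codons; need >= {min_codons}")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    omega = None
    if dN is not None and dS is not None and dS > 0:
        omega = dN / dS
    return PairwiseDnDs(dN=dN, dS=dS, omega=omega, n_codons=n_comp)


@dataclass
class DnDsEstimate:
    gene_id: str
    mean_dN: float | None
    mean_dS: float | None
    mean_omega: float | None
    n_pairs: int  # pairs with a defined omega
    n_undefined: int
    selection_class: str  # positive | purifying | neutral | undefined


def gene_dnds_summary(
    gene_id: str,
    codon_sequences: dict[str, str],
    min_codons: int = 30,
) -> DnDsEstimate:
    """Average pairwise NG86 dN/dS over all unordered sequence pairs of a
    gene; pairs with undefined omega are excluded and counted."""
    ids = sorted(codon_sequences)
    if len(ids) < 2:
        return DnDsEstimate(gene_id, None, None, None, 0, 0, "undefined")
    omegas, dns, dss, undef = [], [], [], 0
    for a, b in itertools.combinations(ids, 2):
        est = dnds_pairwise_ng86(codon_sequences[a], codon_sequences[b], min_codons)
        if est.omega is None:
            undef += 1
            continue
        omegas.append(est.omega)
        dns.append(est.dN)
        dss.append(est.dS)
    if not omegas:
        return DnDsEstimate(gene_id, None, None, None, 0, undef, "undefined")
    mean_omega = float(np.mean(omegas))
    if mean_omega > 1.0:
        cls = "positive"
    elif mean_omega < 1.0:
        cls = "purifying"
    else:
        cls = "neutral"
    return DnDsEstimate(
        gene_id=gene_id,
        mean_dN=float(np.mean(dns)),
        mean_dS=float(np.mean(dss)),
        mean_omega=mean_omega,
        n_pairs=len(omegas),
        n_undefined=undef,
        selection_class=cls,
    )


def write_selection_tsv(
    spreads: list[PhylospreadResult],
    estimates: list[DnDsEstimate],
    path: str | Path,
) -> None:
    sp = {s.gene_id: s for s in spreads}
    rows = []
    for e in estimates:
        s = sp.get(e.gene_id)
        rows.append(
            {
                "gene": e.gene_id,
                "n_genomes": s.n_genomes if s else "",
                "P": f"{s.P:.6f}" if s and s.P is not None else "NA",
                "n_pairs": e.n_pairs,
                "dN": f"{e.mean_dN:.6f}" if e.mean_dN is not None else "NA",
                "dS": f"{e.mean_dS:.6f}" if e.mean_dS is not None else "NA",
                "omega": f"{e.mean_omega:.6f}" if e.mean_omega is not None else "NA",
                "class": e.selection_class,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
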