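"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: protein families
with tunable divergence plus confounding decoys, genome collections with
group-specific planted gene content, fragmented nucleotide reads with uneven
per-sample depth, codon sequence pairs evolved at a chosen dN/dS, and random
trees with an independently computed patristic-distance truth matrix.

All generators are deterministic under a fixed seed.  One global seed
expands to per-component child seeds by fixed arithmetic
(``child = (seed * 1_000_003 + k) mod 2^31``) so partial reruns reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .profile_hmm import AMINO_ACIDS, MultipleAlignment, write_fasta

__all__ = [
    "child_seed",
    "FamilySimSpec",
    "FamilySim",
    "simulate_protein_family",
    "CommunitySimSpec",
    "GenomeCollection",
    "simulate_genome_collection",
    "simulate_metagenome_reads",
    "CodonPairSimSpec",
    "simulate_codon_pair",
    "TreeSim",
    "simulate_tree",
    "back_translate",
    "SENSE_CODONS",
    "CODON_TABLE",
    "STOP_CODONS",
]


def child_seed(seed: int, k: int) -> int:
    """Fixed-arithmetic expansion of one global seed into component seeds."""
    return (seed * 1_000_003 + k) % (2**31)


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySimSpec:
    ancestor_length: int = 80
    n_true: int = 12
    n_decoy: int = 12
    divergence_true: float = 0.1
    divergence_decoy: float = 0.3
    decoy_mode: Literal["shuffled_ancestor", "related_family"] = "shuffled_ancestor"
    seed: int = 0
    gene_id: str = "gene"

    def validate(self) -> None:
        if self.ancestor_length < 10:
            raise ValueError("ancestor_length must be >= 10")
        for name in ("divergence_true", "divergence_decoy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_true < 1 or self.n_decoy < 0:
            raise ValueError("n_true >= 1 and n_decoy >= 0 required")
        if self.decoy_mode not in ("shuffled_ancestor", "related_family"):
            raise ValueError(f"unknown decoy_mode: {self.decoy_mode}")


@dataclass
class FamilySim:
    spec: FamilySimSpec
    ancestor: str
    positives: list[tuple[str, str]]
    decoys: list[tuple[str, str]]

    @property
    def gene_id(self) -> str:
        return self.spec.gene_id

    @property
    def alignment(self) -> MultipleAlignment:
        """Column-true alignment: substitution-only evolution keeps columns."""
        return MultipleAlignment(
            ids=tuple(i for i, _ in self.positives),
            rows=tuple(s for _, s in self.positives),
        )

    @property
    def labels(self) -> dict[str, bool]:
        """sequence id -> True for family members, False for decoys."""
        d = {i: True for i, _ in self.positives}
        d.update({i: False for i, _ in self.decoys})
        return d

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.positives, out / f"{self.gene_id}_pos.fasta")
        write_fasta(self.decoys, out / f"{self.gene_id}_neg.fasta")
        write_fasta(self.positives, out / f"{self.gene_id}_pos.aln.fasta")


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < divergence)[0]
    for i in hits:
        alternatives = AMINO_ACIDS.replace(out[i], "")
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def simulate_protein_family(spec: FamilySimSpec) -> FamilySim:
    """Positives mutated from a random ancestor (substitution-only, so the
    true alignment is the identity column map); decoys are either residue
    permutations of the ancestor or a related family at higher divergence."""
    spec.validate()
    rng = np.random.default_rng(child_seed(spec.seed, 1))
    aa = np.array(list(AMINO_ACIDS))
    ancestor = "".join(aa[rng.integers(20, size=spec.ancestor_length)])
    positives = [
        (f"{spec.gene_id}_tp{i}", _mutate(ancestor, spec.divergence_true, rng))
        for i in range(spec.n_true)
    ]
    decoys = []
    if spec.decoy_mode == "related_family":
        # A coherent confounding family: its own ancestor sits at
        # divergence_decoy from the true ancestor, and members diversify
        # around it at the same within-family divergence as the positives —
        # the homologous-fold, different-function situation that makes
        # cross-reacting false positives consistent.
        decoy_ancestor = _mutate(ancestor, spec.divergence_decoy, rng)
    for i in range(spec.n_decoy):
        if spec.decoy_mode == "shuffled_ancestor":
            s = "".join(rng.permutation(list(ancestor)))
        else:
            s = _mutate(decoy_ancestor, spec.divergence_true, rng)
        decoys.append((f"{spec.gene_id}_fp{i}", s))
    return FamilySim(spec=spec, ancestor=ancestor, positives=positives, decoys=decoys)


# ---------------------------------------------------------------------------
# Genome collections with planted group effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySimSpec:
    n_groups: int = 2
    samples_per_group: int = 8
    n_genes: int = 20
    planted_genes: dict = field(default_factory=dict)  # gene -> (group, effect >= 0)
    baseline_mean: float = 10.0
    dispersion: float = 5.0
    n_background: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 1 or self.samples_per_group < 1 or self.n_genes < 1:
            raise ValueError("n_groups, samples_per_group, n_genes must be >= 1")
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for gene, (group, effect) in self.planted_genes.items():
            if effect < 0:
                raise ValueError(f"planted effect for {gene} must be >= 0")


@dataclass
class GenomeCollection:
    samples: list[tuple[str, list[tuple[str, str]]]]  # (sample_id, protein records)
    truth: pd.DataFrame  # samples x genes drawn counts
    labels: dict[str, str]  # sample -> group

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, recs in self.samples:
            write_fasta(recs, out / f"{sid}.fasta")
        self.truth.to_csv(out / "truth_counts.tsv", sep="\t")
        with open(out / "labels.tsv", "w") as fh:
            fh.write("sample_id\tgroup\n")
            for sid, grp in self.labels.items():
                fh.write(f"{sid}\t{grp}\n")


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_genome_collection(
    spec: CommunitySimSpec, family_bank: list[FamilySim]
) -> GenomeCollection:
    """Per-sample protein FASTA with per-gene member counts drawn from a
    negative binomial whose mean is baseline_mean x planted effect for the
    sample's group, plus shuffled background decoys; the truth table records
    the drawn counts."""
    spec.validate()
    if len(family_bank) < spec.n_genes:
        raise ValueError(
            f"family bank has {len(family_bank)} families; need {spec.n_genes}"
        )
    bank = family_bank[: spec.n_genes]
    genes = [f.gene_id for f in bank]
    rng = np.random.default_rng(child_seed(spec.seed, 2))

    groups = [f"G{g}" for g in range(spec.n_groups)]
    samples, labels = [], {}
    truth = pd.DataFrame(
        0,
        index=[f"{g}_s{j}" for g in groups for j in range(spec.samples_per_group)],
        columns=genes,
        dtype=int,
    )
    for g in groups:
        for j in range(spec.samples_per_group):
            sid = f"{g}_s{j}"
            labels[sid] = g
            recs: list[tuple[str, str]] = []
            for fam in bank:
                mean = spec.baseline_mean
                planted = spec.planted_genes.get(fam.gene_id)
                if planted is not None and planted[0] == g:
                    mean *= planted[1]
                count = _negbin(rng, mean, spec.dispersion)
                truth.loc[sid, fam.gene_id] = count
                members = fam.positives
                for m in range(count):
                    mid, mseq = members[rng.integers(len(members))]
                    recs.append((f"{sid}|{fam.gene_id}|{m}|{mid}", mseq))
            for b in range(spec.n_background):
                fam = bank[rng.integers(len(bank))]
                shuffled = "".join(rng.permutation(list(fam.ancestor)))
                recs.append((f"{sid}|bg{b}", shuffled))
            samples.append((sid, recs))
    return GenomeCollection(samples=samples, truth=truth, labels=labels)


# ---------------------------------------------------------------------------
# Metagenome reads
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_metagenome_reads(
    genomes: list[tuple[str, str]],
    read_length: int,
    reads_per_sample: dict[str, int],
    seed: int = 0,
    strand: bool = True,
) -> dict[str, list[tuple[str, str]]]:
    """Uniform random substrings of the source genomes, random strand,
    per-sample counts exactly as requested (deliberately unequal, so the
    equal-depth subsampler has work to do)."""
    if read_length < 60:
        raise ValueError("read_length must be >= 60")
    if not genomes:
        raise ValueError("no source genomes")
    short = [gid for gid, s in genomes if len(s) < read_length]
    if short:
        raise ValueError(f"read_length exceeds genome length for: {short}")
    rng = np.random.default_rng(child_seed(seed, 3))
    out: dict[str, list[tuple[str, str]]] = {}
    for sid in sorted(reads_per_sample):
        n = reads_per_sample[sid]
        recs = []
        for i in range(n):
            gid, gseq = genomes[rng.integers(len(genomes))]
            start = int(rng.integers(len(gseq) - read_length + 1))
            read = gseq[start : start + read_length]
            if strand and rng.random() < 0.5:
                read = reverse_complement(read)
                tag = "-"
            else:
                tag = "+"
            recs.append((f"{sid}_r{i}|{gid}:{start}{tag}", read))
        out[sid] = recs
    return out


# ---------------------------------------------------------------------------
# Codon evolution (Goldman-Yang-style, uniform codon frequencies, kappa = 2)
# ---------------------------------------------------------------------------

def _standard_code() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    code = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        code[stop] = "*"
    return code


CODON_TABLE = _standard_code()
SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


@dataclass(frozen=True)
class CodonPairSimSpec:
    n_codons: int = 300
    omega: float = 1.0
    branch_length: float = 0.3  # expected substitutions per codon
    kappa: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_codons < 30:
            raise ValueError("n_codons must be >= 30")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.branch_length < 0:
            raise ValueError("branch_length must be >= 0")


def _codon_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """Rate matrix over the 61 sense codons: single-nucleotide changes only,
    kappa for transitions, omega for nonsynonymous changes; scaled so the
    expected substitution rate per codon is 1 under uniform frequencies."""
    n = len(SENSE_CODONS)
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    Q = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nt in "ACGT":
                if nt == c1[pos]:
                    continue
                c2 = c1[:pos] + nt + c1[pos + 1 :]
                j = idx.get(c2)
                if j is None:  # stop codon: inaccessible
                    continue
                rate = kappa if _is_transition(c1[pos], nt) else 1.0
                if CODON_TABLE[c1] != CODON_TABLE[c2]:
                    rate *= omega
                Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))
    if mean_rate > 0:
        Q /= mean_rate
    return Q


def simulate_codon_pair(spec: CodonPairSimSpec) -> tuple[str, str]:
    """Evolve one coding sequence from another under a codon substitution
    process whose nonsynonymous/synonymous rate ratio is spec.omega."""
    spec.validate()
    from scipy.linalg import expm

    rng = np.random.default_rng(child_seed(spec.seed, 4))
    anc_idx = rng.integers(len(SENSE_CODONS), size=spec.n_codons)
    if spec.branch_length == 0:
        seq = "".join(SENSE_CODONS[i] for i in anc_idx)
        return seq, seq
    Q = _codon_rate_matrix(spec.omega, spec.kappa)
    P = expm(Q * spec.branch_length)
    P = np.clip(P, 0, None)
    P /= P.sum(axis=1, keepdims=True)
    der_idx = [int(rng.choice(len(SENSE_CODONS), p=P[i])) for i in anc_idx]
    return (
        "".join(SENSE_CODONS[i] for i in anc_idx),
        "".join(SENSE_CODONS[i] for i in der_idx),
    )


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly random synonymous codons."""
    by_aa: dict[str, list[str]] = {}
    for c in SENSE_CODONS:
        by_aa.setdefault(CODON_TABLE[c], []).append(c)
    out = []
    for aa in protein:
        codons = by_aa.get(aa)
        if codons is None:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


# ---------------------------------------------------------------------------
# Random trees with independent path-sum truth
# ---------------------------------------------------------------------------

@dataclass
class TreeSim:
    newick: str
    taxa: list[str]
    distances: np.ndarray  # truth patristic matrix, same order as taxa


def simulate_tree(n_taxa: int, seed: int = 0, mean_branch: float = 0.1) -> TreeSim:
    """Random bifurcating topology by sequential random joins; exponential
    branch lengths.  The truth matrix is computed by breadth-first path
    summation over the node graph, independently of any newick parser."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(child_seed(seed, 5))
    taxa = [f"t{i}" for i in range(n_taxa)]

    # nodes: 0..n_taxa-1 leaves; edges accumulated as (u, v, length)
    next_node = n_taxa
    active = list(range(n_taxa))
    edges: list[tuple[int, int, float]] = []
    children: dict[int, list[tuple[int, float]]] = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        bl_a = float(rng.exponential(mean_branch) + 1e-3)
        bl_b = float(rng.exponential(mean_branch) + 1e-3)
        parent = next_node
        next_node += 1
        edges += [(parent, a, bl_a), (parent, b, bl_b)]
        children[parent] = [(a, bl_a), (b, bl_b)]
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [parent]
    root = active[0]

    # Independent truth: BFS path sums on the undirected edge graph.
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((n_taxa, n_taxa))
    for leaf in range(n_taxa):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other in range(n_taxa):
            D[leaf, other] = dist[other]
    np.fill_diagonal(D, 0.0)

    def to_newick(node: int) -> str:
        if node < n_taxa:
            return taxa[node]
        parts = [f"{to_newick(c)}:{bl:.10f}" for c, bl in children[node]]
        return "(" + ",".join(parts) + ")"

    return TreeSim(newick=to_newick(root) + ";", taxa=taxa, distances=D)
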