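"""Minimal profile hidden Markov models for protein family search.

A profile is built from a multiple alignment: columns with at least 50%
residue occupancy become match states, flanked by insert and delete states
in the usual plan7-like topology (M->M/I/D, I->I/M, D->D/M).  Sequences are
scored in bits with a *local* Viterbi pass: the model may attach to any
match state and detach from any match state at zero cost, and unaligned
flanking residues emit at null frequency, contributing exactly 0 bits.
This mirrors the default local behaviour of hmmsearch while staying small
enough to verify against exhaustive path enumeration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")

__all__ = [
    "AMINO_ACIDS",
    "MultipleAlignment",
    "ProfileModel",
    "SequenceHit",
    "build_profile",
    "score_sequence",
    "viterbi_match_path",
    "search",
    "read_fasta",
    "write_fasta",
    "read_aligned_fasta",
    "write_profile",
    "read_profile",
    "write_hits_tsv",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but degenerate."""


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped protein rows with identifiers."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have the same length")
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("all alignment rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def subset(self, indices: Sequence[int]) -> "MultipleAlignment":
        return MultipleAlignment(
            ids=tuple(self.ids[i] for i in indices),
            rows=tuple(self.rows[i] for i in indices),
        )

    def ungapped(self, i: int) -> str:
        return "".join(c for c in self.rows[i] if c not in GAP_CHARS)


@dataclass
class ProfileModel:
    """Position-specific emission/transition model with a bit-score threshold.

    ``match_emissions`` is (K, 20); ``insert_emissions`` is (K-1, 20) for the
    insert states between consecutive match states; transition vectors have
    length K-1 and are indexed by the source match/insert/delete position.
    """

    gene_id: str
    subgroup_id: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_ii: np.ndarray
    t_im: np.ndarray
    t_dd: np.ndarray
    t_dm: np.ndarray
    null_emissions: np.ndarray
    threshold: float | None = None
    match_columns: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in self.match_emissions.argmax(axis=1))

    def match_score_matrix(self) -> np.ndarray:
        """Per-match-state log2-odds emission scores against the null."""
        cached = getattr(self, "_msm", None)
        if cached is None:
            cached = np.log2(self.match_emissions / self.null_emissions)
            object.__setattr__(self, "_msm", cached)
        return cached

    def insert_score_matrix(self) -> np.ndarray:
        cached = getattr(self, "_ism", None)
        if cached is None:
            if self.n_match < 2:
                cached = np.zeros((0, 20))
            else:
                cached = np.log2(self.insert_emissions / self.null_emissions)
            object.__setattr__(self, "_ism", cached)
        return cached

    def log_transitions(self) -> dict[str, np.ndarray]:
        cached = getattr(self, "_ltr", None)
        if cached is None:
            with np.errstate(divide="ignore"):
                cached = {
                    n: np.log2(getattr(self, n))
                    for n in ("t_mm", "t_mi", "t_md", "t_ii", "t_im", "t_dd", "t_dm")
                }
            object.__setattr__(self, "_ltr", cached)
        return cached

    def validate(self) -> None:
        for name in ("match_emissions", "insert_emissions", "null_emissions"):
            v = getattr(self, name)
            if v.size and (v <= 0).any():
                raise ValueError(f"{name} must be strictly positive")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if self.insert_emissions.size and not np.allclose(
            self.insert_emissions.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("insert emission rows must sum to 1")
        if not np.isclose(self.null_emissions.sum(), 1.0, atol=1e-9):
            raise ValueError("null emissions must sum to 1")
        if self.threshold is not None and not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite when set")


@dataclass(frozen=True)
class SequenceHit:
    sequence_id: str
    gene_id: str
    subgroup_id: str
    bit_score: float
    passed: bool


# ---------------------------------------------------------------------------
# FASTA I/O (thin Biopython wrappers so callers stay format-agnostic)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    with open(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_aligned_fasta(path: str | Path) -> MultipleAlignment:
    recs = read_fasta(path)
    if not recs:
        raise ValueError(f"empty alignment file: {path}")
    return MultipleAlignment(
        ids=tuple(r[0] for r in recs), rows=tuple(r[1].upper() for r in recs)
    )


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def build_profile(
    alignment: MultipleAlignment,
    pseudocount_weight: float = 1.0,
    gene_id: str = "gene",
    subgroup_id: str = "sg0",
) -> ProfileModel:
    """Estimate a profile from a multiple alignment.

    Columns with >= 50% residue occupancy become match states.  Emissions are
    pseudocounted column frequencies; transitions are pseudocounted counts of
    the observed per-row state paths; the null model is the alignment-wide
    residue frequency.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    if alignment.n_rows < 2:
        raise ValueError("alignment must have at least 2 rows")

    n_rows, n_cols = alignment.n_rows, alignment.n_cols
    cols = [[row[c] for row in alignment.rows] for c in range(n_cols)]
    occupancy = [sum(ch not in GAP_CHARS for ch in col) / n_rows for col in cols]
    match_cols = [c for c in range(n_cols) if occupancy[c] >= 0.5]
    if not match_cols:
        raise DegenerateInputError("alignment has no match column (all columns >50% gaps)")
    K = len(match_cols)

    # Null model: overall residue frequency (pseudocounted for positivity).
    null = np.full(20, pseudocount_weight)
    for row in alignment.rows:
        for ch in row:
            j = AA_INDEX.get(ch)
            if j is not None:
                null[j] += 1.0
    null /= null.sum()

    match_em = np.full((K, 20), pseudocount_weight)
    for k, c in enumerate(match_cols):
        for ch in cols[c]:
            j = AA_INDEX.get(ch)
            if j is not None:
                match_em[k, j] += 1.0
    match_em /= match_em.sum(axis=1, keepdims=True)

    # Insert emissions: residues in non-match columns between match columns
    # k and k+1 feed insert state I_k.
    insert_em = np.full((max(K - 1, 0), 20), pseudocount_weight)
    for k in range(K - 1):
        for c in range(match_cols[k] + 1, match_cols[k + 1]):
            for ch in cols[c]:
                j = AA_INDEX.get(ch)
                if j is not None:
                    insert_em[k, j] += 1.0
    if insert_em.size:
        insert_em /= insert_em.sum(axis=1, keepdims=True)

    # Transition counts from observed state paths between consecutive match
    # columns.  Per row and inter-match region k: state at match col k
    # (M or D), n_ins inserted residues, state at match col k+1.
    c_mm = np.full(max(K - 1, 0), pseudocount_weight)
    c_mi = np.full(max(K - 1, 0), pseudocount_weight)
    c_md = np.full(max(K - 1, 0), pseudocount_weight)
    c_ii = np.full(max(K - 1, 0), pseudocount_weight)
    c_im = np.full(max(K - 1, 0), pseudocount_weight)
    c_dd = np.full(max(K - 1, 0), pseudocount_weight)
    c_dm = np.full(max(K - 1, 0), pseudocount_weight)
    for row in alignment.rows:
        for k in range(K - 1):
            src_match = row[match_cols[k]] not in GAP_CHARS
            dst_match = row[match_cols[k + 1]] not in GAP_CHARS
            n_ins = sum(
                row[c] not in GAP_CHARS
                for c in range(match_cols[k] + 1, match_cols[k + 1])
            )
            if n_ins > 0:
                # D->I is not in the topology; attribute inserts to M source.
                c_mi[k] += 1.0
                c_ii[k] += n_ins - 1
                c_im[k] += 1.0
            elif src_match and dst_match:
                c_mm[k] += 1.0
            elif src_match and not dst_match:
                c_md[k] += 1.0
            elif not src_match and dst_match:
                c_dm[k] += 1.0
            else:
                c_dd[k] += 1.0

    m_tot = c_mm + c_mi + c_md
    i_tot = c_ii + c_im
    d_tot = c_dd + c_dm
    prof = ProfileModel(
        gene_id=gene_id,
        subgroup_id=subgroup_id,
        match_emissions=match_em,
        insert_emissions=insert_em,
        t_mm=c_mm / m_tot,
        t_mi=c_mi / m_tot,
        t_md=c_md / m_tot,
        t_ii=c_ii / i_tot,
        t_im=c_im / i_tot,
        t_dd=c_dd / d_tot,
        t_dm=c_dm / d_tot,
        null_emissions=null,
        match_columns=tuple(match_cols),
    )
    prof.validate()
    return prof


# ---------------------------------------------------------------------------
# Viterbi scoring
# ---------------------------------------------------------------------------

def _emission_scores(seq: str, score_matrix: np.ndarray) -> np.ndarray:
    """(K, L) matrix of per-state emission scores; unknown residues score 0."""
    idx = np.fromiter(
        (AA_INDEX.get(ch, 20) for ch in seq), dtype=np.intp, count=len(seq)
    )
    padded = np.concatenate(
        [score_matrix, np.zeros((score_matrix.shape[0], 1))], axis=1
    )
    return padded[:, idx]


def _viterbi(
    seq: str,
    match_scores: np.ndarray,
    insert_scores: np.ndarray,
    profile: ProfileModel,
    traceback: bool = False,
):
    """Local Viterbi in bits.

    Entry to any match state and exit from any match state are free; flanking
    residues are implicit null emissions (0 bits).  Returns the best score,
    and with ``traceback`` also the per-match-state residue assignment of the
    best path ('-' for match states outside the local alignment or deleted).
    """
    K = profile.n_match
    L = len(seq)
    if L == 0:
        raise DegenerateInputError("cannot score an empty sequence")

    with np.errstate(divide="ignore"):
        l_mm = np.log2(profile.t_mm)
        l_mi = np.log2(profile.t_mi)
        l_md = np.log2(profile.t_md)
        l_ii = np.log2(profile.t_ii)
        l_im = np.log2(profile.t_im)
        l_dd = np.log2(profile.t_dd)
        l_dm = np.log2(profile.t_dm)

    em = _emission_scores(seq, match_scores)  # (K, L)
    ei = _emission_scores(seq, insert_scores) if K > 1 else np.zeros((0, L))

    NEG = -np.inf
    VM = np.full((K, L), NEG)
    VI = np.full((max(K - 1, 0), L), NEG)
    VD = np.full((K, L + 1), NEG)  # VD[k, i]: delete state k after consuming i residues
    if traceback:
        ptr_m = np.zeros((K, L), dtype=np.int8)  # 0=begin 1=M 2=I 3=D
        ptr_i = np.zeros((max(K - 1, 0), L), dtype=np.int8)  # 1=M 2=I
        ptr_d = np.zeros((K, L + 1), dtype=np.int8)  # 1=M 3=D

    for i in range(L):
        for k in range(K):
            # Match state k emitting residue i.
            best, arg = 0.0, 0  # free local entry
            if k > 0 and i > 0:
                cand = VM[k - 1, i - 1] + l_mm[k - 1]
                if cand > best:
                    best, arg = cand, 1
                cand = VI[k - 1, i - 1] + l_im[k - 1]
                if cand > best:
                    best, arg = cand, 2
            if k > 0:
                cand = VD[k - 1, i] + l_dm[k - 1]
                if cand > best:
                    best, arg = cand, 3
            VM[k, i] = em[k, i] + best
            if traceback:
                ptr_m[k, i] = arg
        for k in range(K - 1):
            if i > 0:
                a = VM[k, i - 1] + l_mi[k]
                b = VI[k, i - 1] + l_ii[k]
                if a >= b:
                    VI[k, i] = ei[k, i] + a
                    if traceback:
                        ptr_i[k, i] = 1
                else:
                    VI[k, i] = ei[k, i] + b
                    if traceback:
                        ptr_i[k, i] = 2
        for k in range(1, K):
            a = VM[k - 1, i] + l_md[k - 1]
            b = VD[k - 1, i + 1] + l_dd[k - 1]
            if a >= b:
                VD[k, i + 1] = a
                if traceback:
                    ptr_d[k, i + 1] = 1
            else:
                VD[k, i + 1] = b
                if traceback:
                    ptr_d[k, i + 1] = 3

    flat = int(VM.argmax())
    k_end, i_end = divmod(flat, L)
    score = float(VM[k_end, i_end])

    if not traceback:
        return score

    # Trace the best path back to its free entry point.  For M/I states the
    # index i is the emitted residue; for D states it is residues consumed.
    assign = ["-"] * K
    state, k, i = "M", k_end, i_end
    while True:
        if state == "M":
            assign[k] = seq[i]
            p = ptr_m[k, i]
            if p == 0:
                break
            if p == 1:
                state, k, i = "M", k - 1, i - 1
            elif p == 2:
                state, k, i = "I", k - 1, i - 1
            else:
                state, k, i = "D", k - 1, i
        elif state == "I":
            p = ptr_i[k, i]
            state, i = ("M", i - 1) if p == 1 else ("I", i - 1)
        else:  # delete
            p = ptr_d[k, i]
            if p == 1:
                state, k, i = "M", k - 1, i - 1
            else:
                state, k, i = "D", k - 1, i
    return score, "".join(assign)


def _viterbi_score_fast(
    seq: str,
    match_scores: np.ndarray,
    insert_scores: np.ndarray,
    profile: ProfileModel,
) -> float:
    """Column-vectorized local Viterbi (score only); same recurrence as
    :func:`_viterbi`, with the in-column delete chain done as a prefix scan."""
    K = profile.n_match
    L = len(seq)
    NEG = -np.inf
    lt = profile.log_transitions()
    l_mm, l_mi, l_md = lt["t_mm"], lt["t_mi"], lt["t_md"]
    l_ii, l_im = lt["t_ii"], lt["t_im"]
    l_dd, l_dm = lt["t_dd"], lt["t_dm"]
    em = _emission_scores(seq, match_scores)
    ei = _emission_scores(seq, insert_scores) if K > 1 else np.zeros((0, L))

    # cumulative delete-chain costs: C[k] = sum(l_dd[:k])
    C = np.concatenate(([0.0], np.cumsum(l_dd))) if K > 1 else np.zeros(1)

    vm_prev = np.full(K, NEG)
    vi_prev = np.full(max(K - 1, 0), NEG)
    vd_col = np.full(K, NEG)  # VD[k] with i residues consumed
    best = NEG
    for i in range(L):
        cand = np.zeros(K)  # free local entry
        if K > 1:
            np.maximum(cand[1:], vm_prev[:-1] + l_mm, out=cand[1:])
            np.maximum(cand[1:], vi_prev + l_im, out=cand[1:])
            np.maximum(cand[1:], vd_col[:-1] + l_dm, out=cand[1:])
        vm = em[:, i] + cand
        if K > 1:
            vi = ei[:, i] + np.maximum(vm_prev[:-1] + l_mi, vi_prev + l_ii)
            A = np.full(K, NEG)
            A[1:] = vm[:-1] + l_md
            vd_col = C + np.maximum.accumulate(A - C)
        else:
            vi = vi_prev
        m = vm.max()
        if m > best:
            best = m
        vm_prev = vm
        vi_prev = vi
    return float(best)


def score_sequence(
    profile: ProfileModel,
    sequence: str,
    match_scores: np.ndarray | None = None,
) -> float:
    """Bit score of the best local alignment of ``sequence`` to ``profile``.

    ``match_scores`` overrides the default log2(match/null) matrix; the
    HMM-ModE layer passes log2(match/FP) here.
    """
    if not sequence:
        raise DegenerateInputError("cannot score an empty sequence")
    return _viterbi_score_fast(
        sequence.upper(),
        profile.match_score_matrix() if match_scores is None else match_scores,
        profile.insert_score_matrix(),
        profile,
    )


def viterbi_match_path(
    profile: ProfileModel,
    sequence: str,
    match_scores: np.ndarray | None = None,
) -> tuple[float, str]:
    """Best score plus the residue assigned to each match state ('-' if none)."""
    ms = profile.match_score_matrix() if match_scores is None else match_scores
    return _viterbi(
        sequence.upper(), ms, profile.insert_score_matrix(), profile, traceback=True
    )


def search(
    profiles: Sequence[ProfileModel],
    sequences: Sequence[tuple[str, str]],
) -> list[SequenceHit]:
    """Scan sequences against calibrated profiles.

    One hit per (sequence, gene): the best-scoring subgroup wins; ``passed``
    compares against that subgroup's threshold.  Output is ordered by input
    sequence, then gene id.
    """
    for p in profiles:
        if p.threshold is None:
            raise ValueError(f"profile {p.gene_id}/{p.subgroup_id} has no threshold set")
    by_gene: dict[str, list[ProfileModel]] = {}
    for p in profiles:
        by_gene.setdefault(p.gene_id, []).append(p)
    hits: list[SequenceHit] = []
    for sid, seq in sequences:
        if not seq:
            continue
        for gene in sorted(by_gene):
            best: tuple[float, ProfileModel] | None = None
            for p in by_gene[gene]:
                s = score_sequence(p, seq)
                if best is None or s > best[0]:
                    best = (s, p)
            s, p = best
            hits.append(
                SequenceHit(
                    sequence_id=sid,
                    gene_id=gene,
                    subgroup_id=p.subgroup_id,
                    bit_score=s,
                    passed=s >= p.threshold,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Profile serialization: documented key-value text format, one file per profile
# ---------------------------------------------------------------------------

def _fmt_matrix(m: np.ndarray) -> str:
    return "\n".join(" ".join(f"{x:.6f}" for x in row) for row in np.atleast_2d(m))


def write_profile(profile: ProfileModel, path: str | Path, fp_emissions=None) -> None:
    lines = [
        f"gene\t{profile.gene_id}",
        f"subgroup\t{profile.subgroup_id}",
        f"n_match\t{profile.n_match}",
        f"threshold\t{'NA' if profile.threshold is None else f'{profile.threshold:.6f}'}",
        "null_emissions",
        " ".join(f"{x:.6f}" for x in profile.null_emissions),
        "match_emissions",
        _fmt_matrix(profile.match_emissions),
        "insert_emissions",
        _fmt_matrix(profile.insert_emissions) if profile.insert_emissions.size else "",
        "transitions",
    ]
    for name in ("t_mm", "t_mi", "t_md", "t_ii", "t_im", "t_dd", "t_dm"):
        v = getattr(profile, name)
        lines.append(name + "\t" + " ".join(f"{x:.6f}" for x in v))
    if fp_emissions is not None:
        lines.append("fp_emissions")
        lines.append(_fmt_matrix(fp_emissions))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path):
    """Read the key-value profile format; returns (ProfileModel, fp_emissions|None)."""
    text = Path(path).read_text().splitlines()
    kv = {}
    gene = subgroup = None
    n_match = 0
    threshold = None
    matrices: dict[str, list[list[float]]] = {}
    current = None
    for line in text:
        if not line.strip():
            continue
        if "\t" in line:
            key, val = line.split("\t", 1)
            if key == "gene":
                gene = val
                current = None
            elif key == "subgroup":
                subgroup = val
                current = None
            elif key == "n_match":
                n_match = int(val)
                current = None
            elif key == "threshold":
                threshold = None if val == "NA" else float(val)
                current = None
            elif key.startswith("t_"):
                kv[key] = np.array([float(x) for x in val.split()])
                current = None
            continue
        if re.fullmatch(r"[a-z_]+", line.strip()):
            current = line.strip()
            matrices.setdefault(current, [])
            continue
        if current is not None:
            matrices[current].append([float(x) for x in line.split()])

    def arr(name, default_shape):
        rows = matrices.get(name, [])
        if not rows:
            return np.zeros(default_shape)
        return np.array(rows)

    null = np.array(matrices["null_emissions"][0])
    match_em = arr("match_emissions", (n_match, 20))
    insert_em = arr("insert_emissions", (max(n_match - 1, 0), 20))
    if insert_em.ndim == 1:
        insert_em = insert_em.reshape(-1, 20)
    prof = ProfileModel(
        gene_id=gene,
        subgroup_id=subgroup,
        match_emissions=match_em,
        insert_emissions=insert_em,
        null_emissions=null,
        threshold=threshold,
        **{k: kv[k] for k in ("t_mm", "t_mi", "t_md", "t_ii", "t_im", "t_dd", "t_dm")},
    )
    fp = matrices.get("fp_emissions")
    return prof, (np.array(fp) if fp else None)


def write_hits_tsv(hits: Sequence[SequenceHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tgene\tsubgroup\tbit_score\tpassed\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.gene_id}\t{h.subgroup_id}\t"
                f"{h.bit_score:.4f}\t{int(h.passed)}\n"
            )
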