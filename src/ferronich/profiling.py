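"""From sequence collections to the samples x genes occurrence matrix.

Metagenome reads are translated in all six frames, fragments shorter than
the length cutoff are discarded, samples are subsampled to equal depth, and
each surviving sequence is scanned against the calibrated profiles.  Hit
counts per gene are tabulated into an occurrence matrix; gene columns with
no hits anywhere are dropped before the multivariate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .profile_hmm import ProfileModel, score_sequence
from .synthetic import CODON_TABLE, reverse_complement

__all__ = [
    "SampleCollection",
    "OccurrenceMatrix",
    "six_frame_translate",
    "subsample_equal_depth",
    "profile_sample",
    "assemble_matrix",
    "read_labels_tsv",
]


@dataclass
class SampleCollection:
    sample_id: str
    sequences: list[tuple[str, str]]
    kind: Literal["genome_proteins", "metagenome_reads"] = "genome_proteins"

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


def _translate_codons(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            aas.append("X")  # codons containing N are never stops
        else:
            aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas)


def six_frame_translate(
    record: tuple[str, str], min_len: int = 25
) -> list[tuple[str, str]]:
    """Translate a nucleotide record in all six frames, split at stop codons,
    and keep fragments of at least ``min_len`` residues.

    Fragment ids encode source, frame (+1..+3 / -1..-3), and the 0-based
    half-open nucleotide coordinates on the read's forward strand.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    rid, seq = record
    seq = seq.upper()
    L = len(seq)
    out: list[tuple[str, str]] = []
    for strand in (+1, -1):
        template = seq if strand == 1 else reverse_complement(seq)
        for off in range(3):
            aa = _translate_codons(template[off:])
            pos = 0
            for frag in aa.split("*"):
                if len(frag) >= min_len:
                    # coordinates on the template strand
                    t_start = off + pos * 3
                    t_end = t_start + len(frag) * 3
                    if strand == 1:
                        f_start, f_end = t_start, t_end
                        frame = off + 1
                    else:  # map back to the forward strand
                        f_start, f_end = L - t_end, L - t_start
                        frame = -(off + 1)
                    out.append((f"{rid}|frame{frame:+d}|{f_start}-{f_end}", frag))
                pos += len(frag) + 1
    return out


def subsample_equal_depth(
    samples: list[SampleCollection],
    depth: int | Literal["min"] = "min",
    seed: int = 0,
) -> list[SampleCollection]:
    """Uniform without-replacement subsampling to a common depth.

    Samples already at the target depth pass through unshuffled; sampled
    records keep their original relative order.
    """
    if not samples:
        return []
    sizes = {s.sample_id: len(s.sequences) for s in samples}
    target = min(sizes.values()) if depth == "min" else int(depth)
    too_small = [sid for sid, n in sizes.items() if n < target]
    if too_small:
        raise ValueError(
            f"requested depth {target} exceeds sample size for: {too_small}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        if len(s.sequences) == target:
            out.append(s)
            continue
        keep = np.sort(rng.choice(len(s.sequences), size=target, replace=False))
        out.append(
            SampleCollection(
                sample_id=s.sample_id,
                sequences=[s.sequences[i] for i in keep],
                kind=s.kind,
            )
        )
    return out


def profile_sample(
    profiles: Sequence[ProfileModel],
    sample: SampleCollection,
    min_len: int = 25,
) -> dict[str, int]:
    """Scan one sample; returns gene -> hit count.

    Metagenome reads are six-frame translated first.  A sequence (or read)
    contributes at most one count to a given gene: the best subgroup decides,
    and a read counts once even if several of its frames pass.
    """
    for p in profiles:
        if p.threshold is None:
            raise ValueError(
                f"profile {p.gene_id}/{p.subgroup_id} is uncalibrated (no threshold)"
            )
    by_gene: dict[str, list[ProfileModel]] = {}
    for p in profiles:
        by_gene.setdefault(p.gene_id, []).append(p)
    counts = {g: 0 for g in by_gene}

    for rid, seq in sample.sequences:
        if sample.kind == "metagenome_reads":
            frags = [f for _, f in six_frame_translate((rid, seq), min_len)]
        else:
            frags = [seq] if seq else []
        if not frags:
            continue
        for gene, profs in by_gene.items():
            # per-subgroup thresholds: a fragment passes if any subgroup
            # clears its own cutoff; the read counts at most once per gene
            if any(
                score_sequence(p, frag) >= p.threshold
                for frag in frags
                for p in profs
            ):
                counts[gene] += 1
    return counts


@dataclass
class OccurrenceMatrix:
    """Samples x genes hit-count matrix with optional group labels."""

    counts: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, labels: dict[str, str] | None = None):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df, labels=labels or {})


def assemble_matrix(
    per_sample_counts: dict[str, dict[str, int]],
    gene_catalogue: Sequence[str],
    labels: dict[str, str] | None = None,
) -> OccurrenceMatrix:
    """Tabulate per-sample gene counts over the catalogue order, dropping
    gene columns with zero total count."""
    samples = list(per_sample_counts)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    df = pd.DataFrame(0, index=samples, columns=list(gene_catalogue), dtype=int)
    for sid, gc in per_sample_counts.items():
        for gene, c in gc.items():
            if gene in df.columns:
                df.loc[sid, gene] = int(c)
    if (df.values < 0).any():
        raise ValueError("counts must be nonnegative")
    zero = [g for g in df.columns if df[g].sum() == 0]
    df = df.drop(columns=zero)
    return OccurrenceMatrix(counts=df, labels=labels or {}, dropped_genes=zero)


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
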