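"""Disulfide-loop peptide discovery: the C-X{12-18}-C motif scan.

Vertebrate natriuretic peptides expose a loop of ~15 residues closed by a
cysteine bridge. The scanner enumerates ALL cysteine pairs enclosing a loop
of the requested length range — exhaustively, so overlapping loops and loops
sharing a cysteine are all reported (a greedy regular expression would miss
them). Candidate loops can then be scored against reference peptides,
summarised as sequence logos, and checked for single-exon containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .align import make_aligner, pairwise_global, percent_identity
from .errors import ValidationError
from .io import GAP, Alignment, GeneModel, SequenceRecord

__all__ = [
    "LoopMatch",
    "SimilarityReport",
    "LogoMatrix",
    "scan_loops",
    "score_similarity",
    "build_logo",
    "check_single_exon",
    "host_identity_matrix",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class LoopMatch:
    """One candidate disulfide loop: two cysteines and the residues strictly
    between them (1-based indices in the host protein)."""

    protein_id: str
    cys1: int
    cys2: int
    loop_seq: str

    def __post_init__(self):
        if GAP in self.loop_seq:
            raise ValidationError("loop_seq contains gap characters")
        if self.cys2 - self.cys1 - 1 != len(self.loop_seq):
            raise ValidationError("loop_seq length inconsistent with cysteine indices")

    @property
    def loop_len(self) -> int:
        return len(self.loop_seq)


@dataclass(frozen=True)
class SimilarityReport:
    loop: LoopMatch
    reference_id: str
    raw_score: float
    normalized_score: float


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column amino-acid frequencies and information content (bits)."""

    frequencies: np.ndarray  # shape (n_columns, 20), rows sum to 1
    alphabet: str = AA20

    def __post_init__(self):
        if self.frequencies.ndim != 2 or self.frequencies.shape[1] != len(self.alphabet):
            raise ValidationError("frequency matrix must be n_columns x 20")
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("column frequencies must sum to 1")

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    @property
    def info_bits(self) -> np.ndarray:
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(f > 0, f * np.log2(f), 0.0).sum(axis=1)
        return np.log2(len(self.alphabet)) - ent

    def to_tsv(self) -> str:
        lines = ["column\t" + "\t".join(self.alphabet) + "\tinfo_bits"]
        info = self.info_bits
        for i in range(self.n_columns):
            freqs = "\t".join(f"{v:.6f}" for v in self.frequencies[i])
            lines.append(f"{i + 1}\t{freqs}\t{info[i]:.6f}")
        return "\n".join(lines) + "\n"


def scan_loops(record: SequenceRecord, min_len: int = 12, max_len: int = 18
               ) -> list[LoopMatch]:
    """Report every cysteine pair (i, j) with min_len <= j-i-1 <= max_len.

    Exhaustive over all pairs: overlapping loops and shared cysteines are
    allowed. Output sorted by (cys1, cys2).
    """
    if record.alphabet != "protein":
        raise ValidationError("scan_loops expects a protein sequence")
    if min_len > max_len or min_len < 1:
        raise ValidationError(f"bad loop bounds [{min_len}, {max_len}]")
    seq = record.residues
    cys_positions = [i + 1 for i, ch in enumerate(seq) if ch == "C"]
    matches = []
    for a_idx, i in enumerate(cys_positions):
        for j in cys_positions[a_idx + 1:]:
            loop_len = j - i - 1
            if loop_len > max_len:
                break
            if loop_len >= min_len:
                span = seq[i:j - 1]
                if GAP in span:  # gapped input: loop does not exist in the protein
                    continue
                matches.append(LoopMatch(protein_id=record.id, cys1=i, cys2=j,
                                         loop_seq=span))
    return matches


def score_similarity(loop: LoopMatch, references: list[SequenceRecord],
                     aligner=None) -> list[SimilarityReport]:
    """Global-alignment score of the loop against each reference peptide,
    normalised by the reference's self-alignment score; sorted descending."""
    if not references:
        raise ValidationError("no reference peptides supplied")
    aligner = aligner or make_aligner()
    reports = []
    for ref in references:
        ref_seq = ref.ungapped
        _, _, raw = pairwise_global(loop.loop_seq, ref_seq, aligner)
        _, _, self_score = pairwise_global(ref_seq, ref_seq, aligner)
        if self_score <= 0:
            raise ValidationError(f"reference {ref.id!r} has non-positive self-score")
        reports.append(SimilarityReport(loop=loop, reference_id=ref.id,
                                        raw_score=raw,
                                        normalized_score=raw / self_score))
    reports.sort(key=lambda r: (-r.normalized_score, r.reference_id))
    return reports


def build_logo(loops, pseudocount: float = 0.0) -> LogoMatrix:
    """Column frequency matrix of a set of equal-length loops (or an
    Alignment of loops). info_bits = log2(20) - Shannon entropy."""
    if isinstance(loops, Alignment):
        rows = [r.residues for r in loops.records]
    else:
        rows = [lp.loop_seq if isinstance(lp, LoopMatch) else str(lp) for lp in loops]
    if not rows:
        raise ValidationError("no loops supplied")
    n = len(rows[0])
    if any(len(r) != n for r in rows):
        raise ValidationError("unequal loop lengths: align them first")
    index = {aa: k for k, aa in enumerate(AA20)}
    counts = np.full((n, len(AA20)), float(pseudocount))
    for row in rows:
        for col, ch in enumerate(row.upper()):
            if ch in index:  # gaps and X carry no frequency mass
                counts[col, index[ch]] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValidationError("a column has no standard amino acids")
    return LogoMatrix(frequencies=counts / totals)


def check_single_exon(match: LoopMatch, model: GeneModel,
                      codon_offset: int = 0) -> bool:
    """True iff the genomic span of codons cys1..cys2 lies within one exon.

    Protein residue k maps to CDS nucleotides 3(k+codon_offset)-2 ..
    3(k+codon_offset); CDS coordinates map to the genome through the gene
    model's CDS intervals (reversed on the minus strand). A CDS length not
    divisible by 3 only drops the truncated final codon.
    """
    # genomic coordinate of every CDS nucleotide, in translation order
    genome_coords: list[int] = []
    for start, end in model.cds:
        genome_coords.extend(range(start, end + 1))
    if model.strand == "-":
        genome_coords.reverse()
    n_codons = len(genome_coords) // 3
    first, last = match.cys1 + codon_offset, match.cys2 + codon_offset
    if first < 1 or last > n_codons:
        raise ValidationError(
            f"codons {first}..{last} outside CDS of {n_codons} complete codons")
    nt_lo, nt_hi = 3 * first - 2, 3 * last
    span = genome_coords[nt_lo - 1:nt_hi]
    touched = set()
    for g in span:
        for idx, (es, ee) in enumerate(model.exons):
            if es <= g <= ee:
                touched.add(idx)
                break
    return len(touched) == 1


def host_identity_matrix(proteins: list[SequenceRecord], aligner=None) -> np.ndarray:
    """Symmetric matrix of global-alignment percent identity, diagonal 100."""
    if len(proteins) < 2:
        raise ValidationError("need at least two proteins")
    aligner = aligner or make_aligner()
    n = len(proteins)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(proteins[i].ungapped, proteins[j].ungapped, aligner)
            mat[i, j] = mat[j, i] = pid
    return mat
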