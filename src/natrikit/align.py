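"""Global pairwise and star alignment of protein sequences.

The externally produced MSA is the primary input path for the pipeline; this
module supplies a deterministic built-in fallback: BLOSUM62, affine gaps
(open 10, extend 0.5 — a gap of length L costs 10 + 0.5*(L-1)), end gaps
penalised. Pairwise alignments of each sequence against a common reference
are merged on reference coordinates into a star alignment.
"""

from __future__ import annotations

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ValidationError
from .io import GAP, Alignment, SequenceRecord

__all__ = ["make_aligner", "pairwise_global", "align_star", "percent_identity"]

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


def make_aligner(matrix: str = "BLOSUM62",
                 gap_open: float = GAP_OPEN,
                 gap_extend: float = GAP_EXTEND) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


def pairwise_global(a: str, b: str, aligner: PairwiseAligner | None = None
                    ) -> tuple[str, str, float]:
    """Globally align two protein strings; returns (gapped_a, gapped_b, score).

    The first optimal alignment in biopython's deterministic enumeration
    order is returned, so repeated calls are bit-reproducible.
    """
    if not a or not b:
        raise ValidationError("cannot align empty sequences")
    aligner = aligner or make_aligner()
    alignments = aligner.align(a, b)
    best = alignments[0]
    return str(best[0]), str(best[1]), alignments.score


def percent_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment columns * 100."""
    ga, gb, _ = pairwise_global(a, b, aligner)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
    return 100.0 * matches / len(ga)


def align_star(reference: SequenceRecord, others: list[SequenceRecord],
               aligner: PairwiseAligner | None = None) -> Alignment:
    """Star alignment: every sequence aligned pairwise against ``reference``
    and merged on reference coordinates.

    Insertions relative to the reference are merged by maximal expansion: the
    gap block opened before reference position p in the merged alignment is
    as long as the longest insertion any pairwise alignment placed there.
    """
    if not others:
        raise ValidationError("align_star needs at least one other sequence")
    if reference.alphabet != "protein" or any(o.alphabet != "protein" for o in others):
        raise ValidationError("align_star accepts protein sequences only")
    aligner = aligner or make_aligner()

    ref = reference.ungapped
    n = len(ref)
    # per pairwise alignment: insertion lengths before ref position i (0..n)
    pairwise = []
    max_insert = [0] * (n + 1)
    for other in others:
        ga, gb, _ = pairwise_global(ref, other.ungapped, aligner)
        inserts = [0] * (n + 1)  # inserts[i] = other residues between ref i-1 and i
        segments = [[] for _ in range(n + 1)]  # other residues in each slot
        matched = [""] * n  # other character aligned to each ref position
        ref_pos = 0
        for ca, cb in zip(ga, gb):
            if ca == GAP:
                inserts[ref_pos] += 1
                segments[ref_pos].append(cb)
            else:
                matched[ref_pos] = cb
                ref_pos += 1
        pairwise.append((other, segments, matched))
        for i in range(n + 1):
            max_insert[i] = max(max_insert[i], inserts[i])

    def build_row(segments, matched) -> str:
        out = []
        for i in range(n + 1):
            seg = "".join(segments[i])
            out.append(seg.ljust(max_insert[i], GAP))
            if i < n:
                out.append(matched[i] if matched[i] else GAP)
        return "".join(out)

    ref_row = build_row([[] for _ in range(n + 1)], list(ref))
    rows = [SequenceRecord(id=reference.id, residues=ref_row, alphabet="protein",
                           description=reference.description)]
    for other, segments, matched in pairwise:
        rows.append(SequenceRecord(id=other.id, residues=build_row(segments, matched),
                                   alphabet="protein", description=other.description))
    return Alignment(records=tuple(rows))
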