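"""Pairwise dN/dS selection screen (Nei–Gojobori 1986 counting method).

For each codon the number of synonymous (S) and nonsynonymous (N) sites is
the expected fraction of single-nucleotide changes that preserve the amino
acid, with changes to stop codons excluded from the denominator. Observed
differences between two codons are averaged over all orderings of the
single-nucleotide steps, excluding pathways that traverse a stop codon
(no sense-codon pair has all pathways blocked under the standard code).
Proportions are Jukes–Cantor corrected, d = -(3/4) ln(1 - (4/3) p), and
omega = dN/dS flags candidate positive selection when > 1.

This is a desk-scale screen, not a branch/site likelihood model; an export
to PHYLIP + Newick is provided so the codon-model analysis can be run in
external software on the same inputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .errors import SaturationError, ValidationError
from .io import SequenceRecord

__all__ = [
    "STOP_CODONS",
    "GENETIC_CODE",
    "CodonSequence",
    "DnDsResult",
    "codon_sites",
    "pathway_differences",
    "ng86_pair",
    "omega_screen",
    "screen_tsv",
    "write_phylip",
]

_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
GENETIC_CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


@dataclass(frozen=True)
class CodonSequence:
    """An in-frame coding sequence split into codons.

    Codons containing N or alignment gaps are retained here and excluded
    pairwise during comparison; internal stop codons are rejected.
    """

    id: str
    codons: tuple[str, ...]

    def __post_init__(self):
        for idx, codon in enumerate(self.codons):
            if len(codon) != 3:
                raise ValidationError(f"{self.id}: codon {idx + 1} is not a triplet")
            if codon in STOP_CODONS and idx < len(self.codons) - 1:
                raise ValidationError(f"{self.id}: internal stop codon at codon {idx + 1}")
            if not set(codon) <= set("ACGTN-"):
                raise ValidationError(f"{self.id}: bad characters in codon {codon!r}")

    @classmethod
    def from_string(cls, seq_id: str, nt: str) -> "CodonSequence":
        nt = nt.upper().replace(".", "-")
        if len(nt) % 3 != 0:
            raise ValidationError(f"{seq_id}: length {len(nt)} not divisible by 3")
        codons = tuple(nt[i:i + 3] for i in range(0, len(nt), 3))
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]  # trailing stop dropped
        return cls(id=seq_id, codons=codons)

    @classmethod
    def from_record(cls, record: SequenceRecord) -> "CodonSequence":
        if record.alphabet != "nucleotide":
            raise ValidationError(f"{record.id}: coding sequences must be nucleotide")
        return cls.from_string(record.id, record.residues)


@dataclass(frozen=True)
class DnDsResult:
    """NG86 site counts, difference counts, corrected distances and omega
    for one sequence pair."""

    id_a: str
    id_b: str
    n_codons: int  # codons actually compared (after pairwise exclusion)
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    dN: float
    dS: float

    @property
    def pN(self) -> float:
        return self.Nd / self.N_sites if self.N_sites else 0.0

    @property
    def pS(self) -> float:
        return self.Sd / self.S_sites if self.S_sites else 0.0

    @property
    def omega(self) -> float | None:
        """dN/dS, or None when dS = 0 (undefined ratio)."""
        if self.dS == 0.0:
            return None
        return self.dN / self.dS

    @property
    def candidate_positive(self) -> bool:
        return self.omega is not None and self.omega > 1.0


def _is_sense(codon: str) -> bool:
    return codon in GENETIC_CODE and codon not in STOP_CODONS


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(n, s): nonsynonymous and synonymous site counts of one sense codon.

    Per position, s gains the fraction of non-stop single-nucleotide changes
    that are synonymous; n = 3 - s.
    """
    if not _is_sense(codon):
        raise ValidationError(f"codon_sites requires a sense codon, got {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return 3.0 - s, s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nd, sd): nonsynonymous/synonymous step counts between two sense
    codons, averaged over all orderings of the single-nucleotide steps;
    pathways traversing a stop codon are excluded. nd + sd = k (the number
    of differing positions)."""
    for c in (codon_a, codon_b):
        if not _is_sense(c):
            raise ValidationError(f"pathway_differences requires sense codons, got {c!r}")
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diffs):
        current = codon_a
        nd = sd = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                valid = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            totals.append((nd, sd))
    if not totals:  # unreachable under the standard code; guard anyway
        raise ValidationError(f"all pathways {codon_a}->{codon_b} traverse stops")
    nd = sum(t[0] for t in totals) / len(totals)
    sd = sum(t[1] for t in totals) / len(totals)
    return nd, sd


def _jukes_cantor(p: float, label: str) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        raise SaturationError(f"{label} proportion {p:.4f} >= 3/4: distance undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(a: CodonSequence, b: CodonSequence) -> DnDsResult:
    """NG86 dN/dS for one pre-aligned codon pair.

    Codons containing N or gaps in either sequence are dropped pairwise;
    site counts are averaged between the two sequences.
    """
    if len(a.codons) != len(b.codons):
        raise ValidationError(
            f"{a.id} and {b.id} have different codon counts; align them first")
    n_a = s_a = n_b = s_b = nd = sd = 0.0
    n_compared = 0
    for ca, cb in zip(a.codons, b.codons):
        if not (_is_sense(ca) and _is_sense(cb)):
            continue  # pairwise exclusion of N/gap codons
        n_compared += 1
        na, sa = codon_sites(ca)
        nb, sb = codon_sites(cb)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        d_n, d_s = pathway_differences(ca, cb)
        nd += d_n
        sd += d_s
    if n_compared == 0:
        raise ValidationError(f"no comparable codons between {a.id} and {b.id}")
    N_sites = (n_a + n_b) / 2.0
    S_sites = (s_a + s_b) / 2.0
    pN = nd / N_sites if N_sites else 0.0
    pS = sd / S_sites if S_sites else 0.0
    return DnDsResult(
        id_a=a.id, id_b=b.id, n_codons=n_compared,
        N_sites=N_sites, S_sites=S_sites, Nd=nd, Sd=sd,
        dN=_jukes_cantor(pN, "nonsynonymous"),
        dS=_jukes_cantor(pS, "synonymous"),
    )


def omega_screen(seqs: list[CodonSequence],
                 grouping: dict[str, str] | None = None) -> dict:
    """All-pairs NG86 table; pairs with omega > 1 (and dS > 0) are flagged
    as candidate positive selection.

    With a ``grouping`` map (sequence id -> clade name), mean omega is also
    summarised within and between groups (pairs with undefined omega are
    left out of the means).
    """
    if len(seqs) < 2:
        raise ValidationError("omega_screen needs at least two sequences")
    results = [ng86_pair(a, b) for a, b in itertools.combinations(seqs, 2)]
    summary: dict = {
        "n_pairs": len(results),
        "n_flagged": sum(1 for r in results if r.candidate_positive),
    }
    if grouping is not None:
        within, between = [], []
        for r in results:
            if r.omega is None:
                continue
            ga, gb = grouping.get(r.id_a), grouping.get(r.id_b)
            (within if ga == gb and ga is not None else between).append(r.omega)
        summary["mean_omega_within"] = sum(within) / len(within) if within else None
        summary["mean_omega_between"] = sum(between) / len(between) if between else None
    return {"results": results, "summary": summary}


def screen_tsv(results: list[DnDsResult]) -> str:
    lines = ["id_a\tid_b\tn_codons\tN_sites\tS_sites\tNd\tSd\tpN\tpS\tdN\tdS\tomega\tflag"]
    for r in results:
        omega = "NA" if r.omega is None else f"{r.omega:.6f}"
        flag = "candidate_positive_selection" if r.candidate_positive else "."
        lines.append(
            f"{r.id_a}\t{r.id_b}\t{r.n_codons}\t{r.N_sites:.4f}\t{r.S_sites:.4f}\t"
            f"{r.Nd:.4f}\t{r.Sd:.4f}\t{r.pN:.6f}\t{r.pS:.6f}\t"
            f"{r.dN:.6f}\t{r.dS:.6f}\t{omega}\t{flag}")
    return "\n".join(lines) + "\n"


def write_phylip(seqs: list[CodonSequence], path=None) -> str:
    """Relaxed sequential PHYLIP of the codon alignment, for use with
    external codon-model software together with a Newick tree."""
    if not seqs:
        raise ValidationError("no sequences to write")
    length = len(seqs[0].codons) * 3
    lines = [f" {len(seqs)} {length}"]
    for s in seqs:
        if len(s.codons) * 3 != length:
            raise ValidationError("PHYLIP export requires equal-length sequences")
        lines.append(f"{s.id}  {''.join(s.codons)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
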