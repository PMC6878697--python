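"""Binding-pocket conservation scoring across ortholog alignments.

A pocket is an ordered set of residue positions on a reference receptor
(1-based in the ungapped reference sequence) together with the expected
amino acid at each position, typically taken from a ligand-bound complex
structure or the literature. The pocket is projected through a multiple
alignment onto each other species, and conservation is reported as the
count (and fraction) of pocket sites where the other sequence carries
exactly the expected residue.

Match criterion is strict letter identity: a gap or ``X`` at a pocket
column is a mismatch and never shrinks the denominator, so every species
is scored out of the same pocket total. An optional annex column flags
physico-chemically similar replacements (Grantham distance <= 100),
kept clearly separate from the identity counts.
"""

from __future__ import annotations

import csv
import io as _io
import itertools
import json
import math
from dataclasses import dataclass

from .errors import PocketDefinitionError, ValidationError
from .io import GAP, Alignment, SequenceRecord

__all__ = [
    "PocketDefinition",
    "PocketProjection",
    "SiteComparison",
    "ConservationRecord",
    "load_pocket",
    "load_pocket_config",
    "project_pocket",
    "score_conservation",
    "conservation_table",
    "conservation_table_tsv",
    "grantham_distance",
]


# --- Grantham (1974) amino-acid difference, computed from the published
#     composition/polarity/volume properties; mean over pairs scaled to 100.
_GRANTHAM_PROPS = {
    "S": (1.42, 9.2, 32.0), "R": (0.65, 10.5, 124.0), "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61.0), "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0), "G": (0.74, 9.0, 3.0), "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0), "Y": (0.20, 6.2, 136.0), "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0), "Q": (0.89, 10.5, 85.0), "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0), "D": (1.38, 13.0, 54.0), "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0), "W": (0.13, 5.4, 170.0),
}
_GRANTHAM_ALPHA, _GRANTHAM_BETA, _GRANTHAM_GAMMA = 1.833, 0.1018, 0.000399


def _grantham_table() -> dict[frozenset, float]:
    def raw(x, y):
        (c1, p1, v1), (c2, p2, v2) = _GRANTHAM_PROPS[x], _GRANTHAM_PROPS[y]
        return math.sqrt(_GRANTHAM_ALPHA * (c1 - c2) ** 2
                         + _GRANTHAM_BETA * (p1 - p2) ** 2
                         + _GRANTHAM_GAMMA * (v1 - v2) ** 2)

    pairs = list(itertools.combinations(_GRANTHAM_PROPS, 2))
    scale = 100.0 / (sum(raw(x, y) for x, y in pairs) / len(pairs))
    return {frozenset((x, y)): scale * raw(x, y) for x, y in pairs}


_GRANTHAM = _grantham_table()


def grantham_distance(a: str, b: str) -> float | None:
    """Grantham distance between two amino acids; None when either is not
    one of the 20 standard residues (gap, X)."""
    if a == b and a in _GRANTHAM_PROPS:
        return 0.0
    return _GRANTHAM.get(frozenset((a, b)))


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PocketDefinition:
    """Reference receptor's binding residues: (position, expected amino acid).

    Positions are 1-based in the ungapped reference sequence and strictly
    increasing; each expected residue is checked against the reference at
    load time.
    """

    receptor_id: str
    sites: tuple[tuple[int, str], ...]
    source: str = ""

    def __post_init__(self):
        if not self.sites:
            raise PocketDefinitionError("pocket has no sites")
        prev = 0
        for pos, aa in self.sites:
            if pos <= prev:
                raise PocketDefinitionError(
                    f"pocket positions must be strictly increasing (at {pos})")
            prev = pos
            if len(aa) != 1:
                raise PocketDefinitionError(f"expected_aa {aa!r} is not a single letter")

    @property
    def positions(self) -> list[int]:
        return [p for p, _ in self.sites]

    @property
    def total(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class PocketProjection:
    """Injective, order-preserving map pocket position -> alignment column
    (both 1-based)."""

    receptor_id: str
    columns: tuple[tuple[int, int], ...]  # (pocket position, alignment column)

    def column_of(self, position: int) -> int:
        for pos, col in self.columns:
            if pos == position:
                return col
        raise KeyError(position)


@dataclass(frozen=True)
class SiteComparison:
    position: int
    column: int
    ref_aa: str
    other_aa: str
    match: bool
    grantham: float | None  # None at gaps/X

    @property
    def similar(self) -> bool:
        """Physico-chemically similar under Grantham <= 100 (annex metric)."""
        return self.grantham is not None and self.grantham <= 100.0


@dataclass(frozen=True)
class ConservationRecord:
    """One table row: pocket residues of ``ref_id`` shared by ``other_id``."""

    ref_id: str
    other_id: str
    shared: int
    total: int
    per_site: tuple[SiteComparison, ...]

    def __post_init__(self):
        if not (0 <= self.shared <= self.total):
            raise ValidationError("shared outside [0, total]")
        if len(self.per_site) != self.total:
            raise ValidationError("per_site length != total")

    @property
    def fraction(self) -> float:
        return self.shared / self.total

    @property
    def n_similar(self) -> int:
        return sum(1 for s in self.per_site if s.similar)


def load_pocket(config_entry: dict, reference: SequenceRecord) -> PocketDefinition:
    """Validate one pocket config entry against its reference sequence.

    ``config_entry``: mapping with keys receptor_id, sites (list of
    [position, expected_aa]) and optional source. Raises
    :class:`PocketDefinitionError` naming the offending position when the
    expected residue disagrees with the reference.
    """
    receptor_id = config_entry["receptor_id"]
    if receptor_id != reference.id:
        raise PocketDefinitionError(
            f"pocket receptor_id {receptor_id!r} does not match reference {reference.id!r}")
    ref_seq = reference.ungapped
    sites = []
    for pos, aa in config_entry["sites"]:
        pos, aa = int(pos), str(aa).upper()
        if not 1 <= pos <= len(ref_seq):
            raise PocketDefinitionError(
                f"pocket position {pos} outside reference 1..{len(ref_seq)}")
        if ref_seq[pos - 1] != aa:
            raise PocketDefinitionError(
                f"pocket position {pos}: expected {aa} but reference has {ref_seq[pos - 1]}")
        sites.append((pos, aa))
    return PocketDefinition(receptor_id=receptor_id, sites=tuple(sites),
                            source=str(config_entry.get("source", "")))


def load_pocket_config(path_or_text, references: dict[str, SequenceRecord]
                       ) -> list[PocketDefinition]:
    """Load pocket definitions from JSON (list of entries) or TSV with
    columns receptor_id, position, expected_aa[, source]."""
    import os

    text = path_or_text
    if isinstance(path_or_text, (str, os.PathLike)) and os.path.exists(path_or_text):
        text = open(path_or_text).read()
    text = text.strip()
    entries: list[dict]
    if text.startswith("[") or text.startswith("{"):
        data = json.loads(text)
        entries = data if isinstance(data, list) else [data]
    else:
        grouped: dict[str, dict] = {}
        reader = csv.DictReader(_io.StringIO(text), delimiter="\t")
        for row in reader:
            entry = grouped.setdefault(
                row["receptor_id"],
                {"receptor_id": row["receptor_id"], "sites": [],
                 "source": row.get("source", "")})
            entry["sites"].append([int(row["position"]), row["expected_aa"]])
        entries = list(grouped.values())
    pockets = []
    for entry in entries:
        rid = entry["receptor_id"]
        if rid not in references:
            raise PocketDefinitionError(f"no reference sequence for receptor {rid!r}")
        pockets.append(load_pocket(entry, references[rid]))
    return pockets


def project_pocket(aln: Alignment, pocket: PocketDefinition) -> PocketProjection:
    """Map each pocket position p to the alignment column holding the p-th
    non-gap character of the reference row."""
    if pocket.receptor_id not in aln:
        raise ValidationError(f"reference {pocket.receptor_id!r} absent from alignment")
    ref_row = aln[pocket.receptor_id].residues
    # column (1-based) of the k-th non-gap reference character
    col_of_pos: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(ref_row, start=1):
        if ch != GAP:
            k += 1
            col_of_pos[k] = col
    columns = []
    for pos, aa in pocket.sites:
        if pos not in col_of_pos:
            raise ValidationError(
                f"pocket position {pos} beyond reference length {k} in alignment")
        col = col_of_pos[pos]
        if ref_row[col - 1] != aa:
            raise ValidationError(
                f"alignment reference disagrees with pocket at position {pos}: "
                f"{ref_row[col - 1]} != {aa}")
        columns.append((pos, col))
    return PocketProjection(receptor_id=pocket.receptor_id, columns=tuple(columns))


def score_conservation(aln: Alignment, pocket: PocketDefinition, other_id: str
                       ) -> ConservationRecord:
    """Count pocket sites where ``other_id`` carries exactly the expected
    residue. Gaps and X count as mismatches (fixed denominator)."""
    if other_id not in aln:
        raise ValidationError(f"record {other_id!r} absent from alignment")
    projection = project_pocket(aln, pocket)
    other_row = aln[other_id].residues
    per_site = []
    for (pos, aa), (_, col) in zip(pocket.sites, projection.columns):
        other_aa = other_row[col - 1]
        per_site.append(SiteComparison(
            position=pos, column=col, ref_aa=aa, other_aa=other_aa,
            match=(other_aa == aa), grantham=grantham_distance(aa, other_aa)))
    shared = sum(1 for s in per_site if s.match)
    return ConservationRecord(ref_id=pocket.receptor_id, other_id=other_id,
                              shared=shared, total=pocket.total,
                              per_site=tuple(per_site))


def conservation_table(aln: Alignment, pockets: list[PocketDefinition],
                       others: list[str]) -> list[ConservationRecord]:
    """One record per (pocket, other) pair, sorted by pocket then descending
    shared count; ties broken by other_id lexicographic order."""
    records = []
    for pocket in pockets:
        rows = [score_conservation(aln, pocket, other_id) for other_id in others]
        rows.sort(key=lambda r: (-r.shared, r.other_id))
        records.extend(rows)
    return records


def conservation_table_tsv(records: list[ConservationRecord]) -> tuple[str, str]:
    """Serialise records to (summary TSV, per-site long-format TSV)."""
    out = _io.StringIO()
    out.write("ref_id\tother_id\tshared\ttotal\tfraction\tn_similar_grantham100\n")
    for r in records:
        out.write(f"{r.ref_id}\t{r.other_id}\t{r.shared}\t{r.total}\t"
                  f"{r.fraction:.6f}\t{r.n_similar}\n")
    long = _io.StringIO()
    long.write("ref_id\tother_id\tposition\tcolumn\tref_aa\tother_aa\tmatch\tgrantham\n")
    for r in records:
        for s in r.per_site:
            g = "" if s.grantham is None else f"{s.grantham:.1f}"
            long.write(f"{r.ref_id}\t{r.other_id}\t{s.position}\t{s.column}\t"
                       f"{s.ref_aa}\t{s.other_aa}\t{int(s.match)}\t{g}\n")
    return out.getvalue(), long.getvalue()
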