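"""Readers/writers and validated containers for every external format the
pipeline touches: FASTA, aligned FASTA, GFF3, Newick and PDB (ATOM/HETATM).

Conventions
-----------
* All residue positions are 1-based inclusive in reports and interfaces.
* The gap symbol is ``-``; ``.`` is normalised to ``-`` on read.
* A trailing ``*`` (stop) on a protein sequence is stripped on read.
* Parsing failures raise :class:`~natrikit.errors.FormatError`; invariant
  violations raise :class:`~natrikit.errors.ValidationError` — never silent
  truncation.
"""

from __future__ import annotations

import io as _io
import math
import os
from dataclasses import dataclass, field

import dendropy
import gemmi
from Bio import SeqIO

from .errors import FormatError, ValidationError

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")
GAP = "-"

__all__ = [
    "SequenceRecord",
    "Alignment",
    "GeneModel",
    "Residue",
    "Atom",
    "StructureModel",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_gff3",
    "read_structure",
    "read_newick",
    "write_newick",
]


def _as_text(path_or_text) -> str:
    """Accept a path, a Path-like, or raw text (detected by markup/newlines)."""
    if isinstance(path_or_text, os.PathLike):
        return open(path_or_text).read()
    if isinstance(path_or_text, str):
        stripped = path_or_text.lstrip()
        looks_like_content = (
            "\n" in path_or_text
            or stripped.startswith(">")
            or stripped.startswith("(")
            or stripped.startswith("ATOM")
            or stripped.startswith("HETATM")
            or stripped.startswith("##gff")
        )
        if not looks_like_content and os.path.exists(path_or_text):
            return open(path_or_text).read()
        return path_or_text
    raise TypeError(f"expected path or text, got {type(path_or_text)!r}")


# ---------------------------------------------------------------------------
# Sequences


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with a unique id and a declared alphabet."""

    id: str
    residues: str
    alphabet: str = "protein"  # {"protein", "nucleotide"}
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"sequence id {self.id!r} empty or contains whitespace")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        if self.alphabet not in ("protein", "nucleotide"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        allowed = (PROTEIN_ALPHABET if self.alphabet == "protein" else NUCLEOTIDE_ALPHABET) | {GAP}
        bad = set(self.residues) - allowed
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} has characters {sorted(bad)} outside the "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def _infer_alphabet(residues: str) -> str:
    letters = set(residues) - {GAP}
    if letters <= NUCLEOTIDE_ALPHABET:
        return "nucleotide"
    if letters <= PROTEIN_ALPHABET:
        return "protein"
    raise FormatError(f"characters {sorted(letters - PROTEIN_ALPHABET)} fit neither alphabet")


def _normalise(seq: str, alphabet: str | None) -> tuple[str, str]:
    seq = seq.upper().replace(".", GAP)
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise FormatError("internal '*' stop symbol (only a trailing stop is accepted)")
    if alphabet is None:
        alphabet = _infer_alphabet(seq)
    return seq, alphabet


def read_fasta(path_or_text, alphabet: str | None = None) -> list[SequenceRecord]:
    """Parse FASTA text or a FASTA file into validated records.

    Ids are the first whitespace-delimited header token; wrapped lines are
    concatenated and upper-cased. The alphabet is inferred per record
    (nucleotide iff all characters are ACGTN) unless given explicitly.
    """
    text = _as_text(path_or_text)
    if not text.strip():
        raise FormatError("empty FASTA input")
    if not text.lstrip().startswith(">"):
        raise FormatError("FASTA input does not start with '>'")
    records = []
    seen = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq, alph = _normalise(str(rec.seq), alphabet)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=seq, alphabet=alph, description=desc))
    if not records:
        raise FormatError("no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path=None, width: int = 60) -> str:
    lines = []
    for rec in records:
        header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
        lines.append(header)
        for i in range(0, len(rec.residues), width):
            lines.append(rec.residues[i:i + width])
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


@dataclass(frozen=True)
class Alignment:
    """A validated multiple alignment: equal-length rows, unique ids."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        if not self.records:
            raise ValidationError("alignment has no records")
        n = len(self.records[0].residues)
        if n < 1:
            raise ValidationError("alignment has zero columns")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate ids in alignment")
        for rec in self.records:
            if len(rec.residues) != n:
                raise FormatError(
                    f"ragged alignment: {rec.id!r} has length {len(rec.residues)}, expected {n}"
                )
            if set(rec.residues) == {GAP}:
                raise ValidationError(f"record {rec.id!r} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    def __contains__(self, rec_id: str) -> bool:
        return any(r.id == rec_id for r in self.records)


def read_alignment(path_or_text, alphabet: str | None = None) -> Alignment:
    """Aligned FASTA -> :class:`Alignment`; ragged lengths are rejected."""
    records = read_fasta(path_or_text, alphabet=alphabet)
    return Alignment(records=tuple(records))


def write_alignment(aln: Alignment, path=None) -> str:
    return write_fasta(list(aln.records), path=path)


# ---------------------------------------------------------------------------
# Gene models (GFF3)


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS intervals of one gene, 1-based inclusive on the genomic axis."""

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        for name, ivals in (("exon", self.exons), ("CDS", self.cds)):
            prev_end = 0
            for start, end in ivals:
                if start < 1 or end < start:
                    raise ValidationError(f"bad {name} interval [{start},{end}]")
                if start <= prev_end:
                    raise ValidationError(f"{name} intervals overlap or are unsorted")
                prev_end = end
        # every CDS base must fall inside some exon
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValidationError(f"CDS [{cs},{ce}] not contained in any exon")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


def _gff3_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for part in col9.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path_or_text, gene_id: str) -> GeneModel:
    """Extract the exon/CDS structure of ``gene_id`` from GFF3 text.

    A feature belongs to the gene when its ID or Parent attribute chain
    mentions ``gene_id`` (direct Parent or a transcript whose Parent is the
    gene). Intervals are kept exactly as annotated (no merging).
    """
    text = _as_text(path_or_text)
    exons, cds, strands = [], [], set()
    # ids owned by the gene (the gene itself plus its transcripts)
    owned = {gene_id}
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"GFF3 line {lineno} has {len(cols)} columns, expected 9")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise FormatError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        rows.append((cols[2], start, end, cols[6], _gff3_attributes(cols[8])))
    for ftype, start, end, strand, attrs in rows:
        parents = set(attrs.get("Parent", "").split(",")) if "Parent" in attrs else set()
        if attrs.get("ID") and (parents & owned or attrs.get("gene_id") == gene_id):
            owned.add(attrs["ID"])
    for ftype, start, end, strand, attrs in rows:
        parents = set(attrs.get("Parent", "").split(",")) if "Parent" in attrs else set()
        belongs = bool(parents & owned) or attrs.get("ID") == gene_id or attrs.get("gene_id") == gene_id
        if not belongs:
            continue
        if ftype == "exon":
            exons.append((start, end))
            strands.add(strand)
        elif ftype == "CDS":
            cds.append((start, end))
            strands.add(strand)
    if not exons and not cds:
        raise FormatError(f"gene {gene_id!r} not found in GFF3 input")
    if len(strands) > 1:
        raise FormatError(f"gene {gene_id!r} has features on both strands")
    return GeneModel(
        gene_id=gene_id,
        strand=strands.pop() if strands else "+",
        exons=tuple(sorted(set(exons))),
        cds=tuple(sorted(set(cds))),
    )


# ---------------------------------------------------------------------------
# Structures (PDB ATOM/HETATM)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self):
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValidationError(f"non-finite coordinate in atom {self.name!r}")


@dataclass(frozen=True)
class Residue:
    number: int
    name: str
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValidationError(f"residue {self.name} {self.number} has no atoms")


@dataclass(frozen=True)
class StructureModel:
    """Chains of residues with Cartesian coordinates (Å)."""

    chains: dict[str, tuple[Residue, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for chain_id, residues in self.chains.items():
            numbers = [r.number for r in residues]
            if len(set(numbers)) != len(numbers):
                raise ValidationError(f"duplicate residue numbers in chain {chain_id!r}")


def read_structure(path_or_text) -> StructureModel:
    """Parse PDB ATOM/HETATM records (fixed-width, PDB 3.3 dialect).

    Alternate locations: only altLoc ``' '`` or ``'A'`` kept; waters (HOH)
    dropped. The first model of a multi-model file is used.
    """
    text = _as_text(path_or_text)
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise FormatError("no ATOM/HETATM records in PDB input")
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable PDB input: {exc}") from exc
    if len(structure) == 0:
        raise FormatError("PDB input contains no model")
    model = structure[0]
    chains: dict[str, tuple[Residue, ...]] = {}
    for chain in model:
        residues = []
        for res in chain:
            if res.name == "HOH":
                continue
            atoms = [
                Atom(name=at.name, element=at.element.name, x=at.pos.x, y=at.pos.y, z=at.pos.z)
                for at in res
                if at.altloc in ("\x00", "A", " ")
            ]
            if atoms:
                residues.append(Residue(number=res.seqid.num, name=res.name, atoms=tuple(atoms)))
        if residues:
            chains[chain.name] = tuple(residues)
    if not chains:
        raise FormatError("PDB input has no non-water residues")
    return StructureModel(chains=chains)


# ---------------------------------------------------------------------------
# Trees (Newick via dendropy)


def read_newick(path_or_text) -> dendropy.Tree:
    text = _as_text(path_or_text)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparseable Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in Newick input")
    if not labels:
        raise FormatError("Newick tree has no labelled leaves")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(f"negative branch length {edge.length}")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
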