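"""Seeded synthetic-data generators.

Each generator produces inputs with the statistical structure its pipeline
stage assumes — ortholog families with elevated pocket-site conservation,
proteomes with planted disulfide loops, codon pairs evolved at a controlled
dN/dS ratio, toy receptor–ligand complexes with planted contact pockets,
and gene trees at a controlled discordance from a species taxonomy — along
with the ground truth needed to check recovery. All outputs are
bit-reproducible given (params, seed) and parse cleanly through the
package's readers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ValidationError
from .io import SequenceRecord
from .motifs import AA20, LoopMatch
from .selection import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, CodonSequence

__all__ = [
    "FamilySimParams",
    "LoopPlantParams",
    "CodonSimParams",
    "ComplexSimParams",
    "TreeSimParams",
    "sim_ortholog_family",
    "sim_proteome",
    "sim_codon_pair",
    "sim_complex",
    "sim_trees",
]

_AA = np.array(list(AA20))
_NON_C = np.array([a for a in AA20 if a != "C"])


# ---------------------------------------------------------------------------
# Ortholog families with planted pocket conservation


@dataclass(frozen=True)
class FamilySimParams:
    n_species: int
    seq_len: int
    pocket_positions: tuple[int, ...]  # 1-based
    p_pocket: float
    p_bg: float
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.p_bg <= self.p_pocket <= 1.0:
            raise ValidationError("need 0 <= p_bg <= p_pocket <= 1")
        if not set(self.pocket_positions) <= set(range(1, self.seq_len + 1)):
            raise ValidationError("pocket positions outside 1..seq_len")
        if self.n_species < 1 or self.seq_len < 1:
            raise ValidationError("n_species and seq_len must be positive")


def sim_ortholog_family(params: FamilySimParams
                        ) -> tuple[SequenceRecord, list[SequenceRecord], list[dict]]:
    """Reference protein uniform over the 20 amino acids; each species copies
    it per site with probability p_pocket (pocket sites) or p_bg
    (background), otherwise substitutes a uniformly chosen different
    residue. The truth table records realised per-species pocket matches."""
    rng = np.random.default_rng(params.seed)
    ref = "".join(rng.choice(_AA, size=params.seq_len))
    pocket = set(params.pocket_positions)
    is_pocket = np.array([i + 1 in pocket for i in range(params.seq_len)])
    p_site = np.where(is_pocket, params.p_pocket, params.p_bg)
    reference = SequenceRecord(id="ref", residues=ref, alphabet="protein")
    others, truth = [], []
    for k in range(params.n_species):
        copy = rng.random(params.seq_len) < p_site
        chars = list(ref)
        for i in np.nonzero(~copy)[0]:
            alternatives = [a for a in AA20 if a != ref[i]]
            chars[i] = alternatives[rng.integers(len(alternatives))]
        seq = "".join(chars)
        sp = f"sp{k + 1}"
        others.append(SequenceRecord(id=sp, residues=seq, alphabet="protein"))
        truth.append({
            "species": sp,
            "pocket_matches": int(copy[is_pocket].sum()),
            "pocket_total": int(is_pocket.sum()),
            "background_matches": int(copy[~is_pocket].sum()),
            "background_total": int((~is_pocket).sum()),
        })
    return reference, others, truth


# ---------------------------------------------------------------------------
# Proteomes with planted disulfide loops


@dataclass(frozen=True)
class LoopPlantParams:
    n_proteins: int
    protein_len: int
    planted: tuple[tuple[int, int], ...]  # (loop_len, count)
    cysteine_background_rate: float = 0.0
    seed: int = 0
    min_spacing: int = 19  # background gap between planted loops

    def __post_init__(self):
        if self.n_proteins < 1 or self.protein_len < 1:
            raise ValidationError("n_proteins and protein_len must be positive")
        if any(l < 1 or c < 0 for l, c in self.planted):
            raise ValidationError("planted loop lengths must be >= 1")
        if not 0.0 <= self.cysteine_background_rate <= 1.0:
            raise ValidationError("cysteine_background_rate outside [0, 1]")


def _background(rng, length: int, c_rate: float) -> list[str]:
    chars = []
    for _ in range(length):
        if rng.random() < c_rate:
            chars.append("C")
        else:
            chars.append(str(rng.choice(_NON_C)))
    return chars


def sim_proteome(params: LoopPlantParams
                 ) -> tuple[list[SequenceRecord], list[LoopMatch]]:
    """Proteins with background cysteine rate ``cysteine_background_rate``
    and planted loops (C + non-C interior + C) at recorded, non-overlapping
    positions spaced so that planted cysteines of different loops cannot
    form additional in-range pairs."""
    rng = np.random.default_rng(params.seed)
    loops: list[int] = []
    for loop_len, count in params.planted:
        loops.extend([loop_len] * count)
    per_protein: list[list[int]] = [[] for _ in range(params.n_proteins)]
    for idx, loop_len in enumerate(loops):
        per_protein[idx % params.n_proteins].append(loop_len)

    records, truth = [], []
    for p_idx in range(params.n_proteins):
        my_loops = per_protein[p_idx]
        footprint = sum(l + 2 for l in my_loops)
        n_gaps = len(my_loops) + 1
        base_gap = params.min_spacing if len(my_loops) > 1 else 0
        slack = params.protein_len - footprint - base_gap * (len(my_loops) - 1)
        if my_loops and slack < 0:
            raise ValidationError(
                f"protein {p_idx + 1}: planted loops do not fit protein_len")
        # random split of the slack across gaps
        if my_loops:
            cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
            gaps = np.diff(np.concatenate([[0], cuts, [slack]])).tolist()
            gaps = [g + (base_gap if 0 < i < n_gaps - 1 else 0)
                    for i, g in enumerate(gaps)]
        else:
            gaps = [params.protein_len]
        chars: list[str] = []
        pid = f"prot{p_idx + 1}"
        for i, loop_len in enumerate(my_loops):
            chars.extend(_background(rng, gaps[i], params.cysteine_background_rate))
            cys1 = len(chars) + 1
            interior = "".join(rng.choice(_NON_C, size=loop_len))
            chars.extend("C" + interior + "C")
            truth.append(LoopMatch(protein_id=pid, cys1=cys1,
                                   cys2=cys1 + loop_len + 1, loop_seq=interior))
        chars.extend(_background(rng, gaps[-1], params.cysteine_background_rate))
        records.append(SequenceRecord(id=pid, residues="".join(chars),
                                      alphabet="protein"))
    return records, truth


# ---------------------------------------------------------------------------
# Codon pairs under a controlled omega


@dataclass(frozen=True)
class CodonSimParams:
    n_codons: int
    omega: float
    events_per_site: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValidationError("omega must be positive")
        if self.n_codons < 1:
            raise ValidationError("n_codons must be >= 1")
        if self.events_per_site < 0:
            raise ValidationError("events_per_site must be >= 0")


def _evolve(codons: list[str], n_events: int, omega: float, rng) -> list[str]:
    codons = list(codons)
    n = len(codons)
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    for _ in range(n_events):
        idx = int(rng.integers(n))
        pos = int(rng.integers(3))
        current = codons[idx]
        others = [b for b in "ACGT" if b != current[pos]]
        new = current[:pos] + others[int(rng.integers(3))] + current[pos + 1:]
        if new in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[new] == GENETIC_CODE[current]
        accept_p = p_syn if synonymous else p_non
        if rng.random() < accept_p:
            codons[idx] = new
    return codons


def sim_codon_pair(params: CodonSimParams) -> tuple[CodonSequence, CodonSequence]:
    """Two sequences descended from a uniform-sense-codon ancestor; each
    lineage attempts events_per_site * n_codons substitutions (position and
    replacement nucleotide uniform), rejecting stops and accepting
    synonymous/nonsynonymous proposals with probabilities min(1, 1/omega)
    and min(1, omega) — a relative nonsyn/syn acceptance ratio of omega."""
    rng = np.random.default_rng(params.seed)
    ancestor = [SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
                for _ in range(params.n_codons)]
    n_events = int(round(params.events_per_site * params.n_codons))
    a = _evolve(ancestor, n_events, params.omega, rng)
    b = _evolve(ancestor, n_events, params.omega, rng)
    return (CodonSequence(id="lineage_a", codons=tuple(a)),
            CodonSequence(id="lineage_b", codons=tuple(b)))


# ---------------------------------------------------------------------------
# Toy receptor-ligand complexes


@dataclass(frozen=True)
class ComplexSimParams:
    n_receptor_residues: int
    pocket_positions: tuple[int, ...]
    in_pocket: bool
    jitter_A: float = 0.0
    seed: int = 0
    grid_spacing_A: float = 10.0

    def __post_init__(self):
        if not set(self.pocket_positions) <= set(
                range(1, self.n_receptor_residues + 1)):
            raise ValidationError("pocket positions outside residue range")
        if self.jitter_A < 0:
            raise ValidationError("jitter_A must be >= 0")
        if not self.pocket_positions:
            raise ValidationError("pocket_positions must be non-empty")


def _pdb_atom(serial: int, name: str, resname: str, chain: str, resnum: int,
              xyz, element: str, hetatm: bool = False) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    return (f"{record}{serial:5d}  {name:<3}{resname:>4} {chain}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
            f"{element:>2}")


def sim_complex(params: ComplexSimParams) -> tuple[str, dict]:
    """PDB text of a toy complex: receptor residues as single pseudo-atoms
    on a cubic grid (chain A), ligand atoms (chain B) placed 3 Å from
    pocket residues (in-pocket) or 3 Å from non-pocket residues at least
    ``14 + jitter_A`` Å away from every pocket residue (off-pocket), plus
    Gaussian jitter of norm <= jitter_A. Returns (pdb_text, truth dict)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_receptor_residues
    side = int(np.ceil(n ** (1 / 3)))
    coords = []
    for i in range(n):
        coords.append((params.grid_spacing_A * (i % side),
                       params.grid_spacing_A * ((i // side) % side),
                       params.grid_spacing_A * (i // (side * side))))
    coords = np.asarray(coords, dtype=float)
    pocket_idx = np.array([p - 1 for p in params.pocket_positions])
    pocket_xyz = coords[pocket_idx]

    if params.in_pocket:
        anchors = pocket_xyz
    else:
        non_pocket = [i for i in range(n) if i + 1 not in set(params.pocket_positions)]
        far = [i for i in non_pocket
               if np.linalg.norm(coords[i] - pocket_xyz, axis=1).min()
               >= 14.0 + params.jitter_A]
        if not far:
            raise ValidationError(
                "infeasible geometry: no non-pocket residue far enough from the pocket")
        take = far[:max(3, min(len(far), len(pocket_idx)))]
        anchors = coords[take]

    lig_atoms = []
    for anchor in anchors:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        jitter = rng.normal(scale=params.jitter_A / 3.0, size=3) if params.jitter_A else 0.0
        if params.jitter_A:
            norm = np.linalg.norm(jitter)
            if norm > params.jitter_A:
                jitter = jitter / norm * params.jitter_A
        lig_atoms.append(anchor + 3.0 * direction + jitter)

    lines = []
    serial = 1
    for i, xyz in enumerate(coords, start=1):
        lines.append(_pdb_atom(serial, "CA", "ALA", "A", i, xyz, "C"))
        serial += 1
    for j, xyz in enumerate(lig_atoms, start=1):
        lines.append(_pdb_atom(serial, "C1", "LIG", "B", j, xyz, "C", hetatm=True))
        serial += 1
    lines.append("END")
    truth = {"in_pocket": params.in_pocket,
             "pocket_positions": sorted(params.pocket_positions)}
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# Species/gene tree pairs at controlled discordance


@dataclass(frozen=True)
class TreeSimParams:
    groups: dict[str, str] = field(default_factory=dict)  # leaf -> group
    target_discordance: int = 0  # number of leaf-pair label swaps
    seed: int = 0

    def __post_init__(self):
        if len(self.groups) < 4:
            raise ValidationError("need at least 4 leaves")
        if self.target_discordance < 0:
            raise ValidationError("target_discordance must be >= 0")

    @property
    def n_leaves(self) -> int:
        return len(self.groups)


def _caterpillar(labels: list[str]) -> str:
    if len(labels) == 1:
        return f"{labels[0]}:1"
    inner = f"({labels[0]}:1,{labels[1]}:1):1"
    for label in labels[2:]:
        inner = f"({inner},{label}:1):1"
    return inner


def sim_trees(params: TreeSimParams) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Species tree congruent with the taxonomy (each group monophyletic);
    gene tree = species tree with ``target_discordance`` seeded random
    leaf-label swaps."""
    rng = np.random.default_rng(params.seed)
    by_group: dict[str, list[str]] = {}
    for leaf in sorted(params.groups):
        by_group.setdefault(params.groups[leaf], []).append(leaf)
    for name, members in by_group.items():
        if len(members) < 2:
            warnings.warn(f"group {name!r} has < 2 leaves and cannot be "
                          f"evaluated for monophyly", stacklevel=2)
    subtrees = [_caterpillar(members) for _, members in sorted(by_group.items())]
    if len(subtrees) == 1:
        newick = f"({subtrees[0]});"
    else:
        inner = subtrees[0]
        for sub in subtrees[1:]:
            inner = f"({inner},{sub}):1"
        newick = inner[:inner.rfind(":")] + ";"
    taxa = dendropy.TaxonNamespace()
    species = dendropy.Tree.get(data=newick, schema="newick",
                                taxon_namespace=taxa, preserve_underscores=True)
    gene = dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=taxa, preserve_underscores=True)
    species.is_rooted = gene.is_rooted = False
    leaves = list(gene.leaf_node_iter())
    for _ in range(params.target_discordance):
        i, j = rng.choice(len(leaves), size=2, replace=False)
        leaves[i].taxon, leaves[j].taxon = leaves[j].taxon, leaves[i].taxon
    return species, gene
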