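# Methods

natrikit implements the desk-scale computational core of a receptor–ligand
coevolution analysis: given a reference receptor whose ligand-binding pocket
is known at residue resolution, it asks how conserved that pocket is across
orthologs, whether candidate disulfide-loop ligands exist in other proteomes,
whether the receptor's coding sequence shows signs of positive selection,
how congruent receptor gene trees are with the species taxonomy, what the
ancestral pocket looked like, and whether docked ligand poses occupy the
reference pocket. This note records the models, parameter choices, numerical
conventions and limitations; nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pocket conservation

A pocket is an ordered list of sites `(position, expected_aa)` on the
*ungapped* reference sequence (1-based), supplied by the user (typically
from a ligand-bound complex structure or literature). Positions are
projected through a multiple alignment by mapping position *p* to the
column holding the *p*-th non-gap reference character; the projection is
checked to be injective, order-preserving and consistent with the declared
expected residues, and any disagreement is a hard error naming the site.

Conservation for another aligned sequence is the count of pocket columns
carrying exactly the expected residue. The criterion is strict letter
identity: a gap or `X` is a mismatch and never shrinks the denominator, so
every species is scored out of the same pocket total and fractions are
comparable across rows. Totals always derive from the supplied pocket
definition — the package never assumes a particular pocket size.
Physico-chemical similarity (Grantham distance ≤ 100) is reported as a
clearly separated annex column, not folded into the identity count. The
Grantham matrix is computed from the published composition/polarity/volume
properties with the mean-pair distance scaled to 100; this reproduces the
canonical table to ±1 unit of its printed rounding.

## Disulfide-loop discovery

The ligand motif is `C-X{min..max}-C` with default bounds 12–18, read as
*exclusive* of the cysteines (a literal reading of "surrounded by"); both
bounds are configurable because the reference vertebrate peptides have 15
residues between their cysteines. The scanner enumerates **all** cysteine
index pairs `(i, j)` with `min ≤ j−i−1 ≤ max`, so overlapping loops and
loops sharing a cysteine are all reported — a greedy regular expression
would silently miss them.

Candidate loops are scored against user-supplied reference peptides by
global alignment (see *Alignment* below), normalised by the reference's
self-alignment score so that 1.0 means "identical to the reference" and
the score is invariant to rescaling the scoring system. Loop sets are
summarised as a position frequency matrix over the 20 amino acids with
per-column information content `log2(20) − H` in bits (no small-sample
correction; pseudocount configurable, default 0).

The single-exon check maps protein residue *k* to CDS nucleotides
`3k−2..3k` (an optional integer codon offset accommodates proteins whose
N-terminus is trimmed relative to the CDS), walks the gene model's CDS
intervals in translation order (reversed on the minus strand), and returns
true iff the genomic span of the two cysteine codons and everything
between them intersects exactly one annotated exon. A CDS length not
divisible by 3 drops only the truncated final codon.

## Alignment

Externally computed alignments (aligned FASTA) are the primary input path.
The built-in fallback is global pairwise alignment with BLOSUM62 and affine
gaps — open 10, extend 0.5, end gaps penalised; a gap of length L costs
10 + 0.5·(L−1) — merged on reference coordinates into a star alignment
where insertions are expanded to the longest insertion any pairwise
alignment placed at that reference slot. The first optimal alignment in
the underlying library's deterministic enumeration order is always taken,
so outputs are bit-reproducible; alternative optimal gap placements exist
in general, which is why oracle tests compare scores, not gap positions.
Pairwise identity is matches / alignment columns × 100.

## NG86 selection screen

The screen is the Nei–Gojobori (1986) counting method with Jukes–Cantor
correction. Per sense codon, position *i* contributes to the synonymous
site count the fraction of its three single-nucleotide changes that
preserve the amino acid, with changes to stop codons excluded from the
denominator (stop-excluded renormalisation); n = 3 − s. Observed
differences between two codons are averaged over all k! orderings of the
k ≤ 3 single-nucleotide steps, excluding orderings that pass through a
stop codon — under the standard code no sense pair has all orderings
blocked, so nd + sd = k always. Site counts are averaged between the two
sequences; codons containing `N` or alignment gaps in either sequence are
dropped pairwise. Distances are d = −(3/4)·ln(1 − (4/3)·p), a saturation
error is raised at p ≥ 3/4, and ω = dN/dS is flagged *undefined* (not 0 or
∞) when dS = 0. Pairs with ω > 1 and dS > 0 are flagged as candidate
positive selection.

This is a screen, not a branch/site likelihood analysis: it has no
transition/transversion bias, no codon-frequency model, and no
branch-specific rates. For users who want the likelihood analysis, the
package exports the codon alignment as relaxed PHYLIP plus a Newick tree
suitable for external codon-model software.

## Trees, congruence, ancestral states

The in-repo builder is Saitou–Nei neighbor-joining on p-distances
(pairwise gap deletion; optional Poisson correction −ln(1−p)). Tie-breaks
take the lowest index pair among Q-criterion minima; negative branch
lengths are clamped to zero with the deficit transferred to the sibling so
the joined pair's distance is preserved. On additive matrices NJ is exact,
which the tests exploit by regenerating matrices from random trees.
Externally built ML trees are imported as Newick and flow through the same
downstream analyses.

Congruence is measured as (i) the Robinson–Foulds distance — the symmetric
difference of non-trivial unrooted bipartitions (maximum 2(n−3)) — and
(ii) per-group monophyly: a group is monophyletic iff some edge splits
exactly that group from the rest.

Ancestral sequences use unweighted per-column parsimony. For binary nodes
this is the textbook Fitch intersection/union pass; multifurcating nodes
use Hartigan's counting generalisation (keep the states attained by the
maximum number of children, add `n_children − max_count` changes), which
remains exactly minimal. The top-down pass takes the parent's state when
admissible, otherwise the alphabetically smallest admissible state, and
ties at the root resolve alphabetically — so reconstructions are
bit-reproducible. The score is invariant under re-rooting; internal nodes
are labelled `anc1, anc2, ...` in preorder.

## Pose classification

A receptor residue is in contact with the ligand when any of its heavy
atoms (hydrogens and deuteriums ignored) lies within a cutoff (default
5.0 Å, a conventional heavy-atom contact distance) of any ligand heavy
atom. A pose is `same_pocket` when the Jaccard overlap between contact
residue numbers and the reference pocket's residue numbers reaches a
threshold, default 0.3. There is no canonical numeric criterion for "same
binding pocket", so both knobs are exposed on the CLI; contact sets are
monotone in the cutoff and invariant under rigid-body motion of the whole
complex, and both properties are tested.

## Synthetic data: what it emulates, and what it does not

All generators take an explicit seed and are bit-reproducible; every
output parses through the package's own readers.

* **Ortholog families** — a uniform-random reference protein; each species
  copies it per site with probability `p_pocket` at pocket sites and
  `p_bg` elsewhere, substituting a uniformly different residue otherwise.
  This gives pocket sites elevated identity over background with exact
  per-species truth. It does not emulate indels, rate variation among
  background sites, or phylogenetic correlation between species.
* **Proteomes with planted loops** — background residues with a
  configurable cysteine rate, planted loops written as `C + non-C interior
  + C` at recorded positions, spaced ≥ 19 background residues apart so
  cysteines of different planted loops cannot form extra in-range pairs.
  Real proteomes have clustered cysteines and compositional bias that this
  does not model.
* **Codon pairs** — a uniform sense-codon ancestor; each lineage attempts
  `events_per_site × n_codons` substitutions (uniform position and
  replacement nucleotide), rejecting stops, accepting synonymous proposals
  with probability min(1, 1/ω) and nonsynonymous with min(1, ω), i.e. a
  relative nonsyn/syn acceptance ratio of ω. The default
  `events_per_site = 0.5` per lineage yields ≈ 0.3 substitutions/site of
  pair divergence at ω = 1 — enough signal for a stable NG86 estimate and
  comfortably below the p = 3/4 saturation bound. This is an
  acceptance-ratio scheme, not a full Markov codon model: it has no
  transition/transversion bias and no codon-frequency stationarity, which
  is precisely the regime in which NG86's assumptions hold, so calibration
  passing here does not demonstrate robustness to those biases on real
  data.
* **Toy complexes** — one pseudo-atom per receptor residue on a 10 Å cubic
  grid; in-pocket ligand atoms placed 3 Å from each pocket residue,
  off-pocket atoms 3 Å from non-pocket residues at least 14 Å (+ jitter)
  from every pocket residue, so planted labels are geometrically
  unambiguous at the 5 Å cutoff. Real complexes have full side chains,
  packing and borderline contacts that this deliberately avoids.
* **Tree pairs** — a species tree with each taxonomy group as a
  monophyletic caterpillar clade, and a gene tree derived from it by a
  given number of random leaf-label swaps. Swaps are a blunt discordance
  dial: RF distance grows with swap count only in expectation (tested by
  rank correlation), not deterministically.

## Sizes and determinism

Default test and acceptance workloads are sized for interactive runs on a
single core: 100-replicate oracle sweeps for projection/scanning, the full
61×61 sense-codon pathway enumeration, 200-replicate selection
calibrations at 300 codons, 50-instance tree/parsimony/contact oracle
sweeps, and a 10-pose docking split. The complete suite runs in a few
seconds; `scripts/acceptance.py` recomputes everything from scratch in
under ten. Every random draw flows from an explicit seed, and the pipeline
manifest records config, input checksums and per-stage row counts so a
rerun with the same seed reproduces all non-timestamp output bytes.

## Known limitations

* NG86 is a counting method; ω estimates are biased near saturation and
  the screen deliberately reports saturation as an error rather than a
  number. No branch- or site-level inference is attempted.
* Parsimony ancestral states ignore branch lengths and substitution
  biases; they substitute for probabilistic reconstruction, not replicate
  it.
* NJ on non-additive (noisy) distances has no optimality guarantee; the
  package treats externally built ML trees as first-class inputs.
* The pocket analysis is purely sequence-based: residues with similar
  physico-chemistry, altered backbone geometry or compensatory changes are
  outside its vocabulary beyond the Grantham annex column.
* The same-pocket call depends on the chosen cutoff and Jaccard threshold;
  with partial overlaps near the threshold the label is sensitive to both.
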