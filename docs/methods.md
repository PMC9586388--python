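# Methods

## Digestion model

Trypsin is modelled by the rule *cut after K or R unless the next residue is
P*; the C-terminus is never a cleavage site. Peptides with k missed
cleavages are concatenations of k+1 consecutive fully-cleaved fragments.
Defaults: `max_missed = 2`, length window `[min_len, max_len] = [7, 50]`
amino acids, both bounds inclusive; 5, 6 and 9 are common alternative lower
bounds (5 is an extreme choice that inflates shared short peptides, 9 is the
HUPO HPP requirement), and the package exposes `min_len` everywhere so
length sweeps are one loop. The missed-cleavage count of a peptide is the
number of internal positions satisfying the rule, so a K directly before P
inside a peptide contributes zero. Identical sequences arising at several
positions within one protein collapse to a single map entry (the biadjacency
is binary), retaining the smallest k. No N-terminal methionine clipping and
no semi-tryptic peptides are generated. Non-standard residues (B, J, O, U,
X, Z) are ordinary characters, and I/L are not merged: all matching is
literal sequence identity, which is sufficient because no masses are ever
computed.

## Graph construction

The peptide → protein-accession map is the uncollapsed biadjacency.
Collapsing proceeds proteins-first: accessions with identical peptide sets
merge into a protein node, then peptides with identical protein-node support
merge into a peptide node. One pass of each suffices: peptide grouping is
computed on the final protein nodes, and two protein nodes with different
peptide sets necessarily keep different peptide-node neighborhoods, so a
verification pass can find nothing to merge (this fixed point is asserted by
property tests, not re-derived at run time). Components and all outputs are
deterministically ordered (components by descending protein-node count, then
descending peptide-node count, then smallest member accession; nodes by
smallest member), so repeated runs produce byte-identical tables.

## Isomorphism classes

Type-preserving isomorphism is decided via canonical forms: each component
is converted to an igraph graph with two vertex colors (protein/peptide) and
canonically labeled with BLISS; the key serializes the canonical edge list
plus the color vector. Folding the node type into colors implements the
"same structure *and* same node types" requirement in a single step. Member
multiplicities (how many accessions or sequences a node groups) are ignored
for isomorphism. A hand-written exhaustive permutation search over protein-
and peptide-node bijections (≤ 12 nodes) acts as an independent oracle; the
test suite checks key-equality ⇔ brute-force-isomorphic over structured and
random corpora, including the M-vs-W pair that uncolored isomorphism would
conflate. Class ranking is by descending count with ties broken by ascending
size signature then key — the ranking of equal-count classes is a package
convention, as no canonical one exists.

## Quantitative level

Preprocessing of an intensity table: decoy-only rows dropped, intensities of
modification variants of one sequence summed per sample (missing treated as
zero unless all variants are missing), zeros converted to missing, sequences
outside the digestion length window removed. Quantified sequences are mapped
to proteins by substring containment against the full database (the way
search engines assign peptides), independent of the digest; a 5-mer prefix
index prunes candidates but cannot change the result. Replicates of a state
are averaged when at least `min_valid` (default 2, generalizing the
triplicate rule "two or more missing → missing") values are observed; the
peptide ratio of a state pair is the ratio of these means — aggregation
before ratio, on raw intensities, not logs — and is missing if either mean
is. Comparisons are all unordered state pairs with the earlier-sorted state
in the numerator; the direction convention is recorded in the output
metadata. Per comparison, only peptides with a valid ratio enter the graph;
the component sets of all comparisons are pooled as a multiset (identical
components from different comparisons count separately) and classified
jointly.

## Synthetic data generator

Proteins are concatenations of globally unique tryptic *blocks*: strings
over the 15-letter alphabet excluding K, R (cleavage sites) and P (the rule
exception), terminated by K or R, with lengths uniform in `block_len`
(default 7–12, inside the default length window). A digest at zero missed
cleavages therefore returns exactly the planted blocks, making the expected
graph of every motif analytic: smallest → (1 protein, 1 peptide) node,
M → (2, 3), N → (2, 2), W → (3, 2); random motifs plant a random connected
incidence whose expected component is the incidence itself. Global block
uniqueness guarantees planted components never merge. Isoforms are a parent
copy with one block deleted (accession `<parent>-2`), so their peptides are
by construction unique or isoform-unique, never shared across base
accessions.

Default study conditions, chosen once as a realistic label-free spike-in
style design: 200 components with motif mix smallest 0.45 / M 0.20 / N 0.10
/ W 0.05 / random 0.20 (the single-protein graph dominating with the M shape
second, as in database-level digests of mammalian proteomes); five states ×
three replicates; per-peptide detection probability 0.7 and per-replicate
missingness 0.1 (DDA-like sparsity — many theoretical peptides are never
quantified); intensities log-normal with μ = 16, σ = 2 on the natural-log
scale (≈ 10⁷ median, LFQ-like). Random streams are split per purpose
(sequence generation / detection / missingness / intensity) from one seed,
so changing e.g. the intensity model does not perturb which peptides exist.

What the generator does *not* emulate: homology-driven sharing structure of
real proteomes (sharing is planted, not evolved), peptide detectability as a
function of sequence, intensity response to concentration, retention time,
chimeric spectra. Passing tests therefore demonstrate correctness of the
graph machinery and of the pipeline's bookkeeping under known ground truth,
not fidelity to any particular organism's proteome.

## Numerical and degenerate-input choices

Means and ratios are plain float64 arithmetic; no tolerances are needed
except 1e-9 when asserting histogram normalization. Empty component lists
summarize to all-zero summaries with (0, 0, 0) largest-graph triples; an
empty peptide map yields no components; a database entry whose digest is
empty is reported as excluded rather than erroring. Decoy handling defaults
to the `DECOY_` prefix convention (configurable, since no universal
convention exists); databases are assumed decoy-free by default and skipped
decoys are listed as excluded accessions.

## Two uniqueness notions

Everywhere in the graph metrics, uniqueness is node-level: a peptide node is
unique when adjacent to one protein node (which may group several
indistinguishable accessions). Only the isoform cross-tabulation switches to
accession level — unique (one accession), isoform-unique (several
accessions, all isoforms of one base accession), shared (≥ 2 base
accessions) — because that is the natural resolution for asking what
including isoforms does to peptide uniqueness. Both notions are implemented
and named distinctly.

## Problem sizes

The test suite and the acceptance script run on synthetic databases of
25–300 planted components (up to 2,000 for the Monte-Carlo survival check),
sizes at which every pipeline stage completes in seconds while still
exercising pooling over all ten pairwise comparisons of a five-state
design. Reproducing published full-proteome tables would require the exact
pinned UniProt releases and PRIDE quantitative tables, which are external
downloads; the pipeline accepts such inputs unchanged through the same
`RunConfig` interface.

## Known limitations

- Quantified-peptide mapping is exact substring matching; search engines
  additionally consider mass tolerances and modifications, which can assign
  peptides this mapping will not.
- The brute-force isomorphism oracle is factorial and capped at 12 nodes by
  design; it exists for validation, not production use.
- GraphML export writes one file per class representative; exporting every
  component of a full proteome digest would be impractical and is not
  attempted.
- The CLI's `graphs` and `classify` subcommands are aliases of `summarize`
  (all three artifacts come from one run; splitting them would recompute
  the pipeline for no benefit).
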