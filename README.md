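# pepgraph

Bipartite peptide–protein graphs for bottom-up proteomics.

In bottom-up proteomics proteins are digested (typically with trypsin) into
peptides, and only the peptides are measured. Many peptide sequences occur in
more than one database protein, so inferring and quantifying proteins from
peptides is ambiguous. The relationship is naturally a bipartite graph *G*
with protein nodes *N₁(G)*, peptide nodes *N₂(G)* and an edge whenever the
peptide belongs to the protein. `pepgraph` builds these graphs — from an in
silico tryptic digestion of a FASTA database, or from a measured peptide
intensity table — and characterizes them: protein ambiguity groups, connected
components, node-type-preserving isomorphism classes, and the aggregate
metrics that tell you how hard protein inference and quantification will be
for a given data set. It is aimed at computational proteomics researchers who
develop or evaluate protein inference/quantification methods.

## The model

Starting from the binary biadjacency matrix (peptides × proteins):

1. **Collapse** proteins with identical peptide sets into one protein node
   (a protein group), then peptides belonging to exactly the same protein
   nodes into one peptide node. A peptide node is **unique** if it touches
   one protein node, **shared** otherwise.
2. **Decompose** into connected components — independent units for
   inference/quantification.
3. **Classify** components into isomorphism classes, where the bijection
   must preserve the node type: an M-shaped graph (two proteins, each with a
   unique peptide, joined by a shared one) and a W-shaped graph (three
   proteins connected through two shared peptides, no unique peptide) are
   *not* isomorphic even though they are as uncolored graphs.
   Canonicalization is BLISS canonical labeling with node types as colors.
4. **Summarize**: node/edge/graph/class counts, largest graphs, unique vs
   shared percentages, protein nodes without any unique peptide (the hard
   case), node-count histograms with a pooled 10+ bin, and — when comparing
   a canonical-only against a with-isoforms database — the cross-tabulation
   of unique / isoform-unique / shared peptides.

On the quantitative level, graphs are built per pairwise comparison of
experimental states from the peptides with a valid intensity ratio
(replicates averaged when at least `min_valid` are observed; ratio defined
only when both state means exist), and the per-comparison components are
pooled and analyzed jointly.

A synthetic-data generator plants components of known motifs (smallest, M,
N, W, random) from globally unique tryptic sequence blocks, so every stage
is testable with analytic ground truth, and simulates the measurement
process (per-peptide detection, log-normal intensities, per-replicate
dropout).

## Worked example

Three proteins; A and B share the peptide `VVVVK`, C stands alone:

```python
from pepgraph import *

records = [
    ProteinRecord("A", "AAAAKVVVVK"),
    ProteinRecord("B", "CCCCKVVVVK"),
    ProteinRecord("C", "DDDDKEEEEK"),
]
pmap = digest_database(records, DigestConfig(min_len=5, max_missed=0))
comps = components_from_map(pmap)
for c in comps:
    print(c.size_signature(), [sorted(n.accessions) for n in c.protein_nodes])
print(summarize(comps, classify_components(comps), pmap).to_dict())
```

prints

```
(2, 3, 2, 1, 4) [['A'], ['B']]
(1, 1, 1, 0, 1) [['C']]
{'protein_accessions': 3, 'protein_nodes': 3, 'peptide_sequences': 5,
 'peptide_nodes': 4, 'edges': 5, 'graphs': 2, 'graphs_one_protein': 1,
 'isomorphism_classes': 2, 'largest_graph': (2, 3, 4),
 'second_largest_graph': (1, 1, 1)}
```

The first component is the M shape — signature (2 protein nodes, 3 peptide
nodes, 2 unique, 1 shared, 4 edges): easy to infer (both proteins have a
unique peptide) but ambiguous to quantify (the shared `VVVVK` intensity is a
mixture). The second is the smallest possible graph, one protein with one
unique peptide node — the easy case.

The same analyses run from the shell:

```sh
pepgraph simulate --seed 3 --n-components 200 --out-dir sim/
pepgraph summarize sim/database.fasta --out-dir run/ --min-len 7
pepgraph quant --config run.yaml --out-dir quant_run/
```

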