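# Methods

This note records the definitions the package implements, the choices made
where the underlying method leaves details open, and what the synthetic
benchmark does and does not establish.

## Chain model

A chain is one RNA polymer chain from a PDB or mmCIF file: its full polymer
sequence (A/C/G/U, with unmappable or modified residues recorded as N) plus
one *representative atom* per resolved residue. Every distance in the
pipeline uses that single atom, chosen per residue by the priority
C3′ → C1′ → P → first atom present; C3′ is a backbone atom present in
essentially all deposited nucleotides. Multi-model structures use model 1;
alternate locations take the first conformer. Hybrid polymer chains
(mixed RNA/DNA) are excluded entirely, as are protein and DNA chains.

For mmCIF input the sequence comes from the canonical one-letter entity
sequence (modified nucleotides are already mapped to their parent base) and
coordinates are indexed by `label_seq_id`, so residues missing from the
model keep their place in the sequence. For PDB-format input the sequence
comes from SEQRES and residue numbers are taken as 1-based sequence
positions — the convention this package's own writer uses; mmCIF is the
recommended dialect for arbitrary external files.

Inclusion filters: chains shorter than 20 nt are dropped everywhere;
in update mode, chains missing more than 95% of their residue coordinates
are additionally dropped. "Length" here is the polymer length (the
deposited entity length), not the count of resolved residues.

## Sequence stage

Pairs are length-eligible when the longer chain is at most 2× the shorter.
Eligible pairs are globally aligned (Needleman–Wunsch). The scoring is not
prescribed by the redundancy definition, so standard nucleotide defaults
are used and exposed in the configuration: match +1, mismatch −1, linear
gap −2. Tie-breaking is deterministic (per column from the alignment's
end: match/mismatch preferred over a gap, then a gap in the first
sequence), so alignments are reproducible across runs and platforms.

**Sequence identity** = identically matched aligned nucleotides / length of
the shorter chain. Identical *matched* pairs are counted, not aligned
columns — otherwise two same-length unrelated sequences would score 100%.
N/X characters align like any base but never count as identical. The
denominator is the full polymer length; whether unresolved residues should
be excluded is genuinely open, and the polymer length is the conservative
reading (it can only lower identity).

## Structural stage

Rigid superposition is the Kabsch algorithm (SVD closed form, proper
rotation enforced, so mirror solutions are never returned).

*Docking route* (pairs with identity = 1.0): residues are paired by
sequence position, restricted to positions resolved in both chains; one
global superposition is computed and the reported RMSD is the **arithmetic
mean of per-residue distances** ("average RMSD"). Pairs with fewer than 3
common resolved positions are incomparable and contribute no edge.

*Surrogate aligner* (identity < 1.0): the seed pairing comes from the
sequence alignment (coordinate-bearing pairs only); then iterate
{superpose on current inliers → recompute all pair distances → inliers =
pairs closer than 4 Å} until the inlier set is stable, at most 20
iterations. RMSD is the root-mean-square over the final inliers and
`n_aligned` their count. If the inlier set ever drops below 3 the pair is
incomparable. This is a deliberately simple, fully documented stand-in for
an external global RNA 3D aligner; an external binary can be plugged in via
`external_aligner_cmd` (invoked with two single-chain PDB files, output
parsed for RMSD and aligned-residue count). The surrogate makes no claim
to reproduce any particular external tool's RMSD values — with an anchored
stack-based aligner the numbers on real divergent pairs will differ.

Derived measures, from an alignment result of chains A and B:

* **SAR** = `n_aligned` / coordinate-bearing residue count of the shorter
  chain (shorter by polymer length, ties by smaller coordinate count);
  in update mode the denominator is the *new* chain's coordinate count,
  since the question asked is "is the new chain covered by this
  representative". Capped at 1.
* **PSI** = 100 × `n_aligned` / shorter chain's polymer length. Polymer
  length (not coordinate count) is the chosen denominator; this is flagged
  as a sensitivity point, and the coordinate count variant is exactly SAR.

All standard-mode comparisons run on canonically ordered chain pairs
(lexicographic by uid), which makes every measure symmetric by
construction.

## Clustering

Within one organism, Redundant Groups are the connected components of the
identity graph (edges: eligible pairs with identity ≥ 80%): "assigned to
the same group" is read as transitive closure, mirroring the transitivity
the cluster stage states explicitly. Every in-group pair is then compared
structurally (no pruning) and the redundancy graph gets an edge where
identity ≥ 80%, RMSD < 4 Å (strict) and SAR ≥ 80% (inclusive). Redundant
Clusters are its connected components. The "others" and "synthetic
construct" pseudo-organisms are clustered exactly like real organisms.

Cluster ids are 1-based, assigned in deterministic order (organism name,
then smallest member uid), so the output is invariant to input order. A
pairwise-similarity cache (TSV) lets re-runs skip computed pairs; a warm
cache reproduces the dataset byte for byte.

## Representative selection

Per cluster, each member's (r, n, b, d) is normalized: n₀ = n/max n,
b₀ = b/max b, d₀ = d/max d within the cluster (max 0 → 0 for everyone,
which cannot change the ranking); r₀ = 1 − r/max r, so the best (lowest)
resolution scores highest. Members without a numeric resolution (e.g.
solution NMR) get r₀ = 0 — the worst value; only numeric resolutions are
normalized, and the method tie-break already privileges X-ray. The score
is the weighted sum with defaults (0.4, 0.25, 0.25, 0.1), which sum to 1
by construction (validated).

Score ties: experimental method (X-ray diffraction, then cryo-EM, then
NMR, then others — only "X-ray first" is prescribed; the rest of the
ranking is this package's choice and is configurable), then longer polymer
length, then latest release date, then the lexicographically smallest uid.
The final fallback makes selection total and deterministic.

Base-pair counts (b) are expected from an annotation file produced by a
real base-pair annotation tool. Without one, a crude built-in heuristic is
used (complementary bases whose representative atoms lie 15–20 Å apart,
greedily paired, each residue at most once) — explicitly a stand-in so the
quality score remains total, not a claim of annotation correctness.

## Incremental update

New chains (after the update-mode filters) are compared only against the
previous version's cluster representatives, same organism only when
organism division is on. A representative is *similar* when all three
thresholds hold (SAR with the new chain as denominator). Among similar
representatives the match maximizes similarity; "maximum similarity" is
not further specified, so the package orders lexicographically by lowest
RMSD, then highest SAR, then highest identity — structure is the binding
criterion — and this is configurable territory documented here rather than
a tunable. Matched chains join their representative's cluster (degrees are
recomputed over the enlarged cluster and the representative re-selected);
untouched clusters are copied verbatim; unmatched new chains run through
the full pipeline as a fresh pool with new ids. Prior clusters are never
split or re-merged — consistency with a from-scratch rebuild is the
periodic rebuild's job, not the updater's. Chains absent from the input
(withdrawn depositions) are dropped, removing their clusters when emptied.

## Cross-organism merge

Representatives of all cluster pairs are compared (length eligibility
applies); clusters whose representatives satisfy all three thresholds are
pooled transitively. Each pooled set is then *fully* re-compared pairwise
and re-clustered by connected components — rep-vs-rep links alone could
chain non-redundant chains together. Since all prior intra-organism edges
are re-established, existing clusters never split, and the merged cluster
count can only stay equal or shrink. Ids are reassigned from 1; a merged
cluster's organism field holds the semicolon-joined organism set.

## Dataset comparison

Comparisons are restricted to chains present in both datasets. For each
cluster of A the *compatible* cluster of B shares the most common chains
(ties to the smallest id; the tie rule is this package's choice). Average
cluster RMSD/PSI are means over all unordered common-member pairs;
single-common-chain clusters are Null. RMSD-diff = avg(A) − avg(B) and
PSI-diff likewise; negative RMSD-diff and positive PSI-diff favour A; Null
propagates. Overall similarity = percent of common chains lying inside
their cluster's compatible cluster; 100% for self-comparison, by
construction. Dataset-level averages are means over clusters with ≥ 2
common members (singletons have no pairs to average).

## Synthetic benchmark

The generator plants ground truth rather than imitating real RNA: chains
live on a parametric helical backbone with constant 5.9 Å spacing between
consecutive representative atoms (the typical P–P distance of an A-form
helix). Redundant families are seeded perturbations of one parent — 0.3 Å
coordinate noise and 3% point mutations by default, comfortably inside the
redundancy thresholds, the regime real re-depositions of one molecule
occupy — plus truncations and coordinate drops to exercise
polymer-length ≠ coordinate-count paths. Structurally divergent chains get
independent backbones or ≥ 8 Å scrambling, far outside the 4 Å cutoff.

What a green benchmark establishes: the pipeline's plumbing — parsing,
alignment, superposition, graph construction, representative selection,
update/merge bookkeeping — is correct on inputs whose answer is known, and
is deterministic. What it does not establish: behaviour on real deposited
coordinates (full atomic detail, modified residues in coordinates,
crystallographic artefacts, genuinely ambiguous borderline pairs near the
80%/4 Å thresholds), nor equivalence with any external structural aligner.
The environment this package was developed in has no network access to the
PDB, so the documented real-entry examples are exercised through labelled
synthetic stand-ins (see `tests/conftest.py`) that reproduce the documented
facts about those entries; pointing the same tests at the real mmCIF files
requires no code changes.

## Numerical and degenerate-input choices

* RMSD threshold is strict (< 4 Å), identity and SAR thresholds inclusive
  (≥ 0.80); boundary cases are tested explicitly.
* Superposition requires ≥ 3 points; degenerate (collinear) inputs still
  yield a proper rotation.
* Quality scores are compared after rounding to 12 decimals so that float
  noise cannot shuffle tie-breaks.
* Empty datasets, header-only TSVs, singleton clusters and zero-new-chain
  updates are all defined no-ops, not errors.
* Seeds: all generator randomness flows through explicit integer seeds;
  the pipeline itself is deterministic.

## Known limitations

* The surrogate aligner is sequence-seeded; two conformations of one
  molecule whose sequence alignment is uninformative (e.g. heavy N runs)
  may be declared incomparable rather than aligned structure-first.
* One representative atom per residue means base orientation never enters
  any distance; two backbones threading the same path with different base
  geometry would be called redundant.
* The base-pair heuristic is geometric and crude; supply real annotations
  for meaningful b-weighting in representative selection.
* PDB-format input assumes residue numbers index the SEQRES sequence;
  renumbered author chains should be supplied as mmCIF.
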