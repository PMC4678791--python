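# Methods

## Composition vectors

A genome enters the analysis as the multiset of its annotated protein
sequences. For a peptide length K, every length-K window of every protein
is counted; windows never span protein boundaries, and any window touching
a non-canonical symbol (anything outside the 20 standard amino acids:
`X B Z J U O *` and gap characters) is discarded while the rest of the
protein still counts. This keeps draft and permanently-draft annotations
usable — only the ambiguous windows are lost.

Let `f(w)` be a window count divided by the total window count *at that
length* (so `f` sums to 1 separately at K, K−1 and K−2). The neutral
background for `w = a1…aK` is the (K−2)-th order Markov prediction

```
q(w) = f(a1…a(K−1)) · f(a2…aK) / f(a2…a(K−1))
```

and the vector component is `a(w) = (f(w) − q(w)) / q(w)`.

Numerical conventions, fixed deliberately:

* **Frequencies, not raw counts, in the Markov ratio.** The count and
  frequency forms differ by the near-unity factor
  `N_{K−1}² / (N_K · N_{K−2})`; the frequency form is self-normalising and
  is the one implemented.
* **`q = 0 ⇒ a = 0`** (neither dropped nor infinite): a peptide whose
  background cannot be predicted carries no selection signal.
* **Unobserved peptides are absent** from the sparse vector even when
  `q > 0`. An explicit `a = −1` entry for every predicted-but-unseen
  peptide is a defensible alternative; absence was chosen because it keeps
  vector size bounded by the proteome and the cosine dominated by observed
  signal. The choice matters only in the extreme sparse regime (tiny
  proteomes at large K).
* A genome with zero countable windows at K, K−1 or K−2 is rejected as
  degenerate, by name.

All three count tables for one genome are built in one traversal, and all
K values of a run share the table pass. Vectors can be cached on disk as
JSON keyed by (proteome content hash, K), so re-runs with a different K
subset reuse work.

## Dissimilarity

`C(u,v)` is the cosine of the two sparse vectors, accumulated over the
intersection of their supports with compensated summation (`math.fsum`)
and clamped to [−1, 1] before `D = (1 − C)/2` — the clamp only absorbs
last-ulp excursions. Matrix entries are therefore reproducible
bit-for-bit for a fixed input order, which is what makes whole-project
byte-determinism possible downstream. Pairs are computed once (upper
triangle in id order) and mirrored, so symmetry is exact as stored.
Matrices are exchanged in the square PHYLIP dialect with 17 significant
digits, which round-trips IEEE doubles exactly.

## Tree inference

Saitou–Nei neighbor joining, chosen as the standard agglomeration for
distance matrices of this kind. Two contracts are added on top of the
textbook algorithm:

* **Deterministic tie-break.** When several pairs minimise the
  Q-criterion exactly, the pair whose cluster keys (smallest genome id in
  each cluster) sort lexicographically first is joined. Equal-distance
  inputs thus give one reproducible topology rather than an
  implementation-dependent one.
* **Lengths are diagnostic only.** Negative branch-length estimates are
  retained internally, never clamped; the product of the method is the
  branching order, and Newick output suppresses lengths unless asked.

Rooting is by a designated outgroup: the outgroup must form one side of
an edge (otherwise the error says so rather than forcing a root), and the
root is placed at that edge's midpoint. The outgroup can be hidden from
display counts after rooting.

Robinson–Foulds distances are computed from normalised non-trivial
bipartition sets; the test suite cross-checks them against dendropy's
implementation, and neighbor joining itself against scikit-bio's, keeping
implementation and oracle separate.

## Taxonomy congruence

The nine-rank lineage dialect (`<D>…<T>`, `Unclassified` for gaps) is
parsed tag-delimited, so taxon names may contain spaces. Genomes present
as FASTA but missing from the lineage file get an all-`Unclassified`
lineage instead of an error. Taxon buckets are keyed by the full lineage
prefix down to the rank under study, so homonymous names under different
parents never merge; a genome counts in `m` of `{n + m}` iff any of its
nine ranks is `Unclassified`.

Monophyly of a member set is decided on the rooted tree: the maximal
clades containing only members always partition the set; one cluster
means monophyletic, several mean convergent (`Name{k/n}` each), and
single-member taxa are reported as a separate `singleton` status so
summaries are not inflated by trivial cases. Without an outgroup a
bipartition mode provisionally roots the tree on a non-member pendant
edge, making the verdict a statement about unrooted splits only.

Collapsing replaces a node by one labelled `<R>Name{n + m}` node when all
its genomes share a named taxon at some rank `i ≤ max_rank` **and** no
genome still carries a named deeper rank (up to `max_rank`) that could
refine the view; the label uses the deepest such shared rank. The second
condition is what makes `max_rank` meaningful: without it, any tree whose
domains are monophyletic would collapse to domain nodes at every setting.
Sharing only `Unclassified` never licenses a collapse, but incomplete
genomes inside a named taxon's clade are absorbed into its `m` count.
Collapse conserves genomes — the summed `{n + m}` counts over collapsed
leaves always equal the project's genome total, asserted everywhere.
Note that collapse is clade-based: on an outgroup-free (seed-rooted) tree
a taxon straddling the display root appears as two nodes even though the
bipartition-mode report calls it monophyletic; with an outgroup the two
views agree.

Lineage modification is a pure overlay: ranks named in the modification
file overwrite, unmentioned ranks persist, genome ids are conserved, and
re-reporting after a modification changes only the touched taxa.

## Synthetic data

The simulator draws a root proteome (default 200 proteins × 300 residues,
residues i.i.d. from an average globular-protein composition) and evolves
it along a guide tree by independent per-site substitution, each edge
carrying its own probability (capped at 0.75); a substituted site takes
one of the 19 other residues uniformly. No indels, duplications, gene
gain/loss or rate heterogeneity are modelled: the CV statistic is
window-based, and per-site substitution is the minimal process that
degrades shared K-peptides at a controlled rate. Passing tests therefore
demonstrate correctness of the machinery and recoverability of clean
divergence signal — not robustness to the gene-content variation and
transfer that motivate whole-genome methods on real data.

The emitted lineage table names, at rank index i, the depth-i ancestor
clade of each leaf (keyed by the clade's smallest leaf id; ranks below
the leaf's depth become per-genome singletons, sTrain is the genome id).
Taxa at every rank are thus exactly clades of the true tree, giving an
end-to-end oracle: a correct pipeline must report 100 % of named taxa
monophyletic whenever it recovers the true topology. A perturbation
helper reassigns chosen genomes to wrong taxa (copying a donor's prefix)
and returns the move list, so convergence detection is testable by
construction.

## Problem sizes and determinism

Test and acceptance runs use an 8-leaf balanced guide tree with
substitution probability 0.05 per edge, 20 seeded replicates at K = 5 and
6 (the prokaryote sweet spot), plus 200 random additive matrices (n ≤ 16)
for neighbor joining and 500 random tree/assignment pairs (n ≤ 12) for
monophyly — sizes at which the independent oracles are exhaustive and a
full run stays at minutes scale. The 90 % topology-recovery bound on the
simulated study is a frozen regression threshold measured at first
implementation (observed: 20/20 at both K), not an external claim.
Everything is deterministic given the seed: fixed iteration orders,
compensated summation and the NJ tie-break make two runs of one seeded
project byte-identical, which the suite asserts file by file.
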