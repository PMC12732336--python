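# Methods

## The Gene Space model

A coding sequence is tokenized at one of three levels: single nucleotides,
in-frame codons, or adjacent codon pairs.  Only the 61 sense codons are
admissible at the codon levels; any token containing a stop codon
(TAA/TAG/TGA) or an ambiguity code is excluded from counting.  A gene's
coordinates are its token counts divided by its total token count, so every
gene lies on the (n−1)-simplex with n = 4, 61 or 3721 vertices.  Axis order
is lexicographic over token strings; any fixed order is geometrically
equivalent, and fixing it makes embeddings bit-reproducible.

Codon pairs are counted with a sliding window over adjacent in-frame codons
advancing one codon per step, so a gene of L codons yields L−1 candidate
pairs; a `pair_mode="disjoint"` option counts non-overlapping pairs
instead.  Both conventions produce the same coincidence structure on short
repeated sequences; sliding is the default because the pair level exists to
capture correlations between *adjacent* codons, and the sliding count uses
every adjacency.  When a codon is skipped under the validation policy, its
position is retained as a gap sentinel so that only genuinely adjacent
codons are ever paired.

Geometry is exact Euclidean geometry on the simplex: the barycenter (all
coordinates 1/n) represents equal token usage; any two distinct vertices
are √2 apart; the center-to-vertex distance — the largest distance from
the center attainable in the simplex — is √((n−1)/n), which is 0.8660 at
n = 4, 0.9918 at n = 61, and ≈ 1 at n = 3721.  Normalized center distances
divide by this quantity so vertices map to exactly 1; the value measures
inequality of token usage within a gene.

## Species separation

Two organisms' gene clouds are separated with a support vector machine with
linear kernel (soft margin C = 1, solver tolerance 1e−6), so the decision
boundary is a hyperplane in the token-frequency space.  Accuracy uses a
split-half swap protocol: each organism's genes are split into two disjoint
halves (odd counts put the extra gene in the first half), a model is
trained on the first halves, the pooled second halves are scored as the
fraction of genes assigned to their true organism, the halves are swapped,
and the two values are averaged.  Accuracy is pooled over both organisms'
test genes by default (a `balanced` flag gives the macro average); genes
falling exactly on the decision boundary are scored incorrect for either
class, a conservative tie rule.  One seed drives both organisms' splits and
is recorded in the result.

## Genome Subspaces

The subspace of one organism is the half-space delimited by a linear
one-class SVM boundary fitted to its gene cloud.  The parameter ν
upper-bounds the fraction of training genes left outside; the default
ν = 0.1 targets a subspace holding at least 90% of the training set, and
empirically the achieved outside fraction tracks ν to within ~1% at
n ≥ 500 genes.  Coordinates enter the fit unscaled and uncentered: the
simplex coordinates are the space of interest, and rescaling them would
change the geometry being delineated.

Membership is decision(x) = w·x − ρ ≥ 0, evaluated within the solver
tolerance (1e−6, recorded in the model), so boundary points count as
inside; without the tolerance a degenerate cloud of identical training
points would classify its own training point as outside due to solver
round-off.

**Vertex-count volume.**  The true volume of a half-simplex in 60 or 3720
dimensions is computationally out of reach, so subspace size is proxied by
the number of simplex vertices inside the region, out of n.  This is a
finite exact enumeration: for a vertex the decision value reduces to
wᵢ − ρ, so the count is computed in one vectorized pass and is
bit-reproducible.  Vertex token identities are retained for Venn
intersections across organisms and for amino-acid summaries (standard
genetic code; codon pairs contribute both constituent codons' amino acids).

**Overfitting ratio.**  The gene set is split in half; a subspace is fitted
on one half; the training loss is the fitted half's own outside-fraction
and the validation loss the held-out half's; the halves are swapped and the
two validation/training ratios averaged.  A ratio near 1 indicates the
boundary generalizes.  If a training loss is exactly 0 the ratio for that
split is reported as validation_loss/ν and flagged — this preserves the
"≈1 means no overfitting" reading without dividing by zero.  Losses are
fractions, not counts; the ratio is invariant to that choice for equal
split sizes.

**Volume-vs-fraction curves and vertex invariance.**  To probe how evenly
genes fill the subspace, the boundary is refitted with ν = 1 − f for a
sweep of target gene fractions f, recording the achieved inside fraction
and vertex volume; ν is the only mass-control knob in the method, so the
sweep is implemented as a ν sweep.  Vertex invariance is the share of
vertices whose inside/outside status is identical across all fits in the
sweep; values near 1 mean the vertex composition of the subspace is robust
to the chosen fraction.

## Synthetic CDS generator

A synthetic organism is a first-order Markov chain over the 61 sense
codons:

* **codon marginals** drawn from a symmetric Dirichlet with concentration
  `skew` (default 0.3 — a realistically biased unicellular genome; small
  values concentrate usage on few codons, large values approach uniform);
* **transition matrix** T = (1 − c)·(rows = marginals) + c·R with mixing
  weight `correlation` c (default 0.3) and R a random row-stochastic
  matrix whose rows are drawn from Dirichlet(marginals × 50), so each row's
  mean is the marginal vector and the chain's stationary distribution stays
  near the marginals even at high correlation;
* **gene lengths** log-normal in codons with median 300 and σ = 0.5,
  truncated to [30, 3000] — a realistic CDS length spread for unicellular
  genomes with mean gene length around 300 codons.

Divergence between organisms multiplies the marginals by
exp(divergence · N(0,1)) per codon and renormalizes; the transition matrix
is rebuilt around the new marginals with the same correlation.  The
total-variation distance between old and new marginals grows stochastically
with the divergence knob.  Stop codons never occur in the gene body by
construction; an optional terminal TAA exercises the terminal-stop
stripping of the validation policy.

What the generator does *not* emulate: amino-acid-sequence constraints,
GC gradients along genes, expression-level strata, horizontal transfer, or
any higher-order codon structure.  Passing tests on synthetic data
therefore demonstrate the correctness and calibration of the machinery
(embedding, protocols, geometry), not biological claims about real
genomes; real-FASTA ingestion is supported for the latter.

## Numerical choices and problem sizes

* Solver tolerance 1e−6 for both the two-class and one-class fits,
  recorded in model metadata.
* Default validation policy: require length divisible by 3, strip terminal
  stop, skip (rather than reject on) internal stops and ambiguity codes,
  require ≥ 10 countable tokens per gene.  The annotated frame is always
  used; no ORF re-detection, no reverse-complementing.
* Genes with zero countable tokens at a level are dropped from that level's
  matrix with a logged warning.
* Calibration and trend checks in the test suite use 400–2000 genes per
  organism with fixed seeds — enough for the ν-property to hold within
  ~1%, chance-level separation within ±0.05, and overfitting ratios within
  [0.8, 1.25] across seeds, while keeping the suite fast on one CPU.

## Known limitations

* The vertex-count volume is a coarse proxy at the nucleotide and codon
  levels (4 and 61 vertices): sweeps of the gene fraction may not change
  the count at all there; the codon-pair level (3721 vertices) resolves
  such changes.
* The one-class region is an unbounded half-space, not a bounded envelope;
  a diverged organism's cloud can fall entirely on the inside of another
  organism's half-space, so validation loss against a specific divergent
  profile is directional only on average over profiles.
* Tokens longer than six nucleotides are out of scope: the dimensionality
  (e.g. 226,980 for 9-mers) exceeds any genome's gene count and the models
  would overfit catastrophically.
* The split-half protocol leaves codon-pair models trained on fewer genes
  than dimensions; the reported overfitting ratio quantifies exactly this.
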