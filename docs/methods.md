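# Methods

## Model overview

`mnbdr` treats drug repositioning as a comparison of disease and drug
perturbations in a shared *module* feature space.  The assumptions, in
order of appearance in the pipeline:

* **Modules are functional units.** Dense clusters in a high-confidence
  PPI network act together; perturbation of any part of a module is
  evidence about the whole unit.
* **Cross-talk carries disease information.** Modules joined by
  significantly many inter-module interactions influence one another, so
  a module's relevance to a disease should borrow strength from its
  network neighbors.
* **A good drug hits the disease's important modules, and hits them
  hardest.** The indicator S rewards drugs whose own module ranking
  places the disease's top modules near the same positions with large
  perturbation values.  These are perturbation-*overlap* semantics; the
  direction of the drug's effect (reversal vs. mimicry) is deliberately
  not modeled.

## Procedure and parameters

### Input filtering

PPI edges are kept at STRING combined score ≥ 770 (inclusive), the
conventional high-confidence cut.  Gene identifiers are opaque strings;
no ID mapping is attempted — callers harmonize identifier spaces across
the network, disease, and drug inputs.  Disease fold-changes are
`log2((mean_case + c) / (mean_control + c))` with pseudocount `c = 1` by
default; groups smaller than 3 samples trigger a warning.  Drug vectors
(perturbation z-scores) feed the same downstream transform unchanged:
"fold-change" is read generically as signed perturbation.  A pluggable
sample-filter predicate (default: pass-all) is the hook for upstream
signal-strength filtering of drug signatures.

### Module detection (MCODE-style)

Vertex weight = `k · d`, where the highest k-core of the closed
neighborhood of the vertex has core number `k` and edge density `d`;
vertices of degree < 2 (degree cutoff) weigh 0.  Seeds are processed in
decreasing weight order (ties: lexicographic vertex id); growth admits an
unassigned neighbor when its weight ≥ 0.8 × seed weight
(node score cutoff 0.2), recursively; the haircut trims the grown cluster
to its 2-core; clusters below 5 members are discarded; fluff is not
implemented.  Every vertex belongs to at most one module, and output is
invariant to edge ordering.

One behavioral consequence worth knowing: when two equally dense clusters
are joined by even a single edge, both sides of the edge carry equal
weight, so growth crosses the junction and the clusters merge into one
module.  This is inherent to weight-threshold growth, and it is why the
end-to-end benchmark (below) feeds the scoring stages the planted module
definitions rather than re-detected ones.  A ModuleSet produced by any
external tool can likewise be supplied via GMT, bypassing detection.

### Cross-talk permutation test

For modules A and B, the observed count of PPI edges with one endpoint in
each set is compared to `n_perm = 1000` draws of two *disjoint*,
node-uniform random sets of sizes |A| and |B| from all nodes of the
filtered network.  The one-sided p-value uses the +1 pseudo-count
convention, `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so it is never 0; a
flag recovers the bare ratio.  The null is degree-blind by design —
degree-preserving rewiring nulls are out of scope.  Edges of the module
network are the pairs with p < 0.01, uncorrected (a Benjamini–Hochberg
option exists in spirit via the exposed per-pair p-values); modules with
no significant partner stay as isolated nodes.  Per-pair seeds are
derived by hashing the run seed with the sorted module names, so results
are independent of iteration order and reproducible.

### Importance and propagation

Module importance uses the two-branch range statistic (`Fmax − Fmin` when
the module's scores straddle zero, else the largest absolute score).
Genes missing from a score vector are ignored; an entirely unmeasured
module scores 0, keeping the vector aligned with the module order for
propagation.  The boundary cases `Fmax = 0` or `Fmin = 0` fall into the
max-absolute branch (the straddle condition is strict).

Disease vectors are refined by `P_k = λ W P_{k−1} + (1−λ) P_0` with
`λ = 0.85`, W the column-normalized unweighted adjacency of the module
network (isolated modules get uniform teleport columns, the standard
dangling-node repair), `P_0` the raw importances L1-normalized so mass
conservation and the stopping rule (L1 change < 1e-9, ≤ 1000 iterations)
are scale-free.  Normalizing `P_0` does not affect anything downstream:
only the ranking is consumed, and ranking is scale-invariant.  Drug
vectors are *not* propagated — the drug side uses raw importances.

### Drug scoring

`S = Σ_{i=1..n} V(i) / (|P(i) − i| + 1)` over the disease's top-n
modules, where positions P(·) come from ranking *all* modules by the
drug's importance (descending, ties lexicographic).  The scoring function
defaults to `n = 15`; the benchmark harness instead derives
`n = ⌈10 % of the module count⌉` (minimum 2), which is the proportion
behind the reference choice of 15 on a 116-module network.  On the
12-module synthetic network, using all modules would let the noise tail
of the sum swamp the alignment signal.

### Baselines

* KS connectivity (CMap): signed two-list enrichment, `KS_up − KS_down`,
  range [−2, 2]; disease signatures default to the top 100 up and 100
  down genes.
* Zhang score: sum of signature sign × drug signed rank over signature
  genes, normalized by the maximal attainable sum, range [−1, 1].
* XSum: drug profile truncated to its top/bottom `extreme_k = 100` genes
  by value; score = Σ values over up-tags − Σ over down-tags.
* Module-only variant: the full pipeline with propagation replaced by the
  identity.

### Evaluation

Per-disease ROC AUC is the Mann–Whitney probability (ties ½); AUC0.1 is
the *unnormalized* trapezoidal area of the ROC restricted to FPR ≤ 0.1
with linear interpolation at the boundary (maximum 0.1, chance 0.005).
Cross-disease averages are unweighted; diseases lacking a positive (or
negative) candidate are excluded with a warning.  The permutation null
reassigns each disease's positives uniformly among its candidates,
preserving counts.  Both the empirical p (+1 pseudo-count, floored at
1/(n_perm+1)) and a Gaussian tail probability from the null's mean and
standard deviation are reported: extreme significance (p ≪ 1/n_perm) is
expressible only parametrically, and surfacing both makes that explicit.

## Synthetic benchmark: what it emulates, and what it does not

`simulate_ppi` plants `n_modules = 12` disjoint 8-cliques, wires
`n_crosstalk_pairs = 6` disjoint module pairs with
Bernoulli(0.3) bipartite edges, and adds an Erdős–Rényi background
(`p = 0.005`) over 600 background genes.  Background noise edges span
background–background and background–module pairs only: inter-module
connectivity is governed solely by the cross-talk probability, so the
planted-module and planted-cross-talk ground truths stay unambiguous
(with noise edges allowed between equal-weight cliques, any
weight-threshold grower chains cliques together and recovery is
ill-defined).  The cross-talk probability 0.3 (expected ~19 of 64
possible edges) keeps planted cross-talks far from the significance
boundary, in the spirit of a fully-connected planted pair.

`simulate_benchmark` drives each of 10 diseases by one cross-talk pair
(recycled round-robin; diseases sharing a pair share true drugs).  Driver
genes draw `±δ + N(0, σ)` with an enforced half-and-half sign mix per
module (so the straddle branch of the importance statistic is always
exercised); other genes draw `N(0, σ)`; defaults `δ = 2.5`, `σ = 0.8`.
Of 60 drugs, 6 per used pair are true drugs perturbing exactly that pair;
remaining decoys alternate between perturbing a random *non*-cross-talk
module pair and pure noise.  Signs are drawn independently per condition,
so a true drug agrees with its disease at the module level but not at the
signed gene level — which is what separates module-space methods from
gene-signature matching on this benchmark.

Limitations of the emulation: uniform clique modules (real modules vary
in size and density, which is precisely what keeps real MCODE clusters
from merging across cross-talks); no scale-free degree structure; no
LINCS-style moderated-z statistics, dose/cell-line structure, or
batch effects; positives are noiseless labels.  Passing here shows the
machinery is correct and the method behaves as designed under its own
assumptions — not that it attains any particular performance on real
STRING/TCGA/LINCS data.

A property observed under these conditions: the full method and the
module-only variant produce nearly identical benchmark AUC (≈ 0.99, vs
≈ 0.5 for gene-signature KS), because at this signal-to-noise the raw
importance ranking already places the driver pair on top and propagation
rarely changes the top of the list.  Propagation's contribution shows up
at the margins (it protects a driver pair whose raw ranking is disturbed
by noise, and demotes singleton noise modules whose cross-talk partner is
quiet); its correctness is verified directly against the closed-form
linear solve rather than through benchmark deltas.

## Numerical choices and degenerate inputs

* Ties are broken lexicographically everywhere a ranking is consumed
  (module seeds, module rankings, drug rankings), making every output
  bit-reproducible for a given seed.
* All randomness flows through explicit integer seeds;
  per-module-pair seeds are SHA-256-derived, so adding or removing pairs
  never perturbs other pairs' p-values.
* Empty-graph reads warn rather than fail; an all-zero disease prior is
  an error (there is nothing to propagate); a disease whose candidates
  are single-class is excluded from evaluation with a warning.
* Propagation convergence: L1 tolerance 1e-9, cap 1000 iterations; with
  λ ≤ 0.95 the iteration contracts at rate λ and converges in ≤ ~400
  iterations even at tolerance 1e-12.

## Known limitations

* Directionality is not modeled: a drug that *mimics* the disease
  perturbation scores as well as one that reverses it, faithfully to the
  overlap semantics of S.
* The degree-blind permutation null overstates cross-talk significance
  between high-degree modules on degree-heterogeneous networks.
* Multiple testing across module pairs is uncorrected (raw p < 0.01).
* Equal-density clusters joined by any edge merge during detection (see
  above).
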