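# Methods

## Model

The package segments a genome into hidden accessibility states from binned
single-cell (or pseudo-bulk) ATAC-seq counts. The observation for bin *i*
is the vector *x<sub>i</sub>* of fragment counts across *C* tracks (cells
or cell-cluster pseudo-bulks). Each hidden state *s* carries a positive
concentration vector α<sub>s</sub> over tracks, and the emission
probability is the Dirichlet-multinomial pmf conditioned on the bin total
*n<sub>i</sub>* = Σ<sub>c</sub> x<sub>ic</sub>:

P(x | α<sub>s</sub>) = C(n; x) · Γ(A)/Γ(n+A) · Π<sub>c</sub> Γ(x<sub>c</sub>+α<sub>sc</sub>)/Γ(α<sub>sc</sub>),  A = Σ<sub>c</sub> α<sub>sc</sub>.

Conditioning on *n* deliberately makes sequencing depth a nuisance
parameter: states are distinguished by *how a bin's fragments are
allocated across cells*, not by how many fragments it has. The
concentration total *A* controls within-state overdispersion (small *A* =
bursty, cell-exclusive accessibility; large *A* = near-multinomial).

Bins form a hidden Markov chain along each chromosome. Chromosomes are
independent sequences sharing parameters and re-initialized from the
initial distribution; transitions never span chromosome boundaries. Bins
with zero total count are modelled rather than skipped — the
Dirichlet-multinomial pmf of the empty count vector is 1 under every
state, so such bins carry no emission information and inherit their state
from neighbouring context through the transition matrix.

## Fitting

Parameters are estimated by Baum-Welch (EM):

- **E-step.** A scaled (numerically stable) forward-backward pass per
  chromosome yields per-bin posteriors, expected transition counts and the
  log-likelihood. Emission log-likelihoods are computed sparse-aware: the
  per-track gamma terms vanish at zero counts, so only stored nonzeros are
  touched.
- **M-step.** Transition rows and the initial distribution come from
  expected counts. Each α<sub>s</sub> is updated by Minka's fixed-point
  iteration on the posterior-weighted counts (10 inner iterations,
  entries floored at 1e-6); each inner step is a bound-maximization step,
  so the EM objective never decreases. A moment-matching alternative
  (`alpha_update="moments"`) matches the weighted mean allocation and a
  method-of-moments concentration total; because plain moment matching is
  not an ascent step, the candidate is rejected whenever it scores worse
  than the current α on that state's weighted likelihood, which restores
  generalized-EM monotonicity.
- **Convergence.** EM stops after the requested iteration cap (the caps
  used for the two analysis modes, 300 and 100, are upper bounds) or when
  the log-likelihood improves by less than 1e-6·|loglik| in one step. An
  earlier, looser tolerance of 1e-4·|loglik| was found to stop fits tens
  of nats short of convergence on realistic problem sizes and was
  tightened accordingly.
- **Viterbi ties** are broken toward the lowest state index,
  deterministically.
- **Degenerate states** (expected occupancy numerically zero) are
  reinitialized from a perturbed global profile with a warning.

### Initialization and restarts

EM on this model has strong merge/split local optima: a fit may split one
broad state in two and merge a rare state into the background at a
log-likelihood thousands of nats below the best basin. Restarts therefore
cycle through three complementary seeding schemes, and the fit with the
best final log-likelihood wins:

1. **global** — concentration vectors are the global track profile with
   mild Gamma(5, 0.2) multiplicative noise (good default, conservative);
2. **anchored** — every state is anchored on the smoothed (±1 bin) local
   profile of a data bin, chosen k-means++-style: the first anchor is
   sampled from outlier-weighted bins (bins whose per-fragment likelihood
   under a single global state falls furthest below the median), and the
   remaining anchors greedily maximize cosine dissimilarity to the anchors
   already chosen. This reliably seeds rare allocation patterns that
   cover ~1% of the genome;
3. **sharp** — global profile with Exponential(1) multiplicative noise,
   giving widely dispersed starting profiles that split broad states.

Transitions always start near-uniform with a sticky diagonal (0.9), and
restart seeds are derived deterministically from the user seed (the first
restart uses the seed itself, so a single-restart fit is reproducible as a
plain fit).

## Pipeline conventions

- **Coordinates** are BED-style, 0-based half-open, throughout; fragment
  midpoints use floor((start+end)/2); strand is ignored.
- **Counting**: fragments are assigned to the single bin containing their
  midpoint; per-(bin, barcode) entries may be capped (default 4 for the
  per-cell matrix). The cap is applied after summing duplicate fragment
  records per bin and barcode. Barcode quality filtering (default
  [1000, 30000] fragments) always uses the *uncapped* per-barcode totals,
  which are carried alongside the matrix.
- **Feature identification (fi)**: states whose Viterbi calls cover at
  most 1.5% of the genome (inclusive) are foreground; bins called with a
  foreground state at posterior ≥ 0.9 (inclusive) are kept and bookended
  same-state bins merged, the merged interval taking the maximum member
  posterior. "Accessible in cell j" means count > 0 (configurable); the
  cell-state association is log(a<sub>ij</sub>/b<sub>i</sub>) in natural
  log, with a<sub>ij</sub> = 0 reported as NaN rather than −∞ so heatmaps
  stay renderable.
- **Program identification (pi)**: 500 bp pseudo-bulk tracks, 30 states,
  100 iterations, 7 restarts by default; no count cap is applied to
  pseudo-bulk tracks. Reads-in-(cluster, state) are tabulated over
  Viterbi-called bins by default (reproducible from the state-call BED
  plus the matrix alone); `use_expected=True` weights bins by posterior
  probabilities instead.
- **Enrichment statistics**: the hypergeometric test is upper-tail,
  inclusive of the observed count; the binomial composition test is
  two-sided exact (sum of outcome probabilities not exceeding the observed
  point probability); Benjamini–Hochberg FDR is reported alongside raw
  p-values, raw remaining primary. TSS windows are ±10 kb, clipped at
  chromosome ends; bins count as inside a window when their midpoint is.
  The entropy computation follows the stated order exactly: add the
  pseudocount, depth-normalize each cluster column, renormalize each
  region row to a probability vector (the final renormalization is implied
  by the entropy formula requiring a probability vector), then
  SE = −Σ p log₂ p in bits.
- **Region classification against a chromatin-state annotation**: the
  observed state coverage of a region is normalized by the state's total
  coverage over the region set; the expected share is the genome-wide
  state probability times the region length normalized by the region
  set's total covered length, mirroring the observed-side normalization.
  The score is the log ratio of the two shares, the label the argmax,
  ties going to the lowest state index (flagged); zero-coverage regions
  are labelled "background".

## Synthetic data

The generator draws data from the model's own generative assumptions so
that every pipeline stage can be tested against exact ground truth:

- a state path per chromosome from a sticky Markov chain
  T<sub>ij</sub> = s<sub>i</sub>δ<sub>ij</sub> + (1−s<sub>i</sub>)f<sub>j</sub>,
  with f solved so the stationary distribution equals the requested state
  frequencies;
- per bin, a Poisson fragment total with state-dependent mean, allocated
  to cells by a Dirichlet-multinomial whose concentration encodes which
  cell clusters the state is accessible in;
- fragments of fixed 150 bp length with midpoints uniform in the bin
  (only midpoints matter downstream).

Default conditions: a 2 Mb genome (2 × 1 Mb chromosomes) at 1 kb bins
(2,000 bins), 200 cells in 4 equal clusters, three states — a
regulatory-like state (10% of bins, accessible in two clusters, 90
fragments/bin across cells), a broad state open in all cells and a broad
state open in the other two clusters (45% each, 30 fragments/bin).
Within-state overdispersion is moderate (α = 3 per accessible cell, 0.02
per inaccessible cell): states are defined as distinct cross-cell
allocation profiles, and dispersion so extreme that a background state can
imitate cell-exclusive bins would contradict the model's own premise and
make state identity unidentifiable for any method.

For experiments that plant a rare state at a stated genome fraction, the
`planted` path mode carves foreground segments totalling exactly
round(freq·B) bins into a Markov background path; the default `markov`
mode leaves the realized fraction binomially variable, which is the
honest general setting but conflates path-sampling noise with recovery
performance when a fraction is part of the experimental condition.

Gene-set annotation is simulated by placing each set gene's TSS within
±10 kb of a bin of its target state (at a configurable placement rate,
decoys uniform), and a chromatin-state BED is derived by mapping
accessibility states to labels.

**What the generator does not emulate:** real fragment-size mixtures,
Tn5 sequence bias, barcode collisions or chemistry artifacts, copy-number
variation, batch effects, and the empirical sparsity patterns of any
particular dataset. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the model's assumptions, not
performance guarantees on real tissue data.

## Problem sizes used in tests

Unit tests run on a 300-bin/60-cell simulation; the recovery benchmark
uses the default 2,000-bin/200-cell conditions; foreground-recovery and
program-recovery checks use 1,000-bin/100-cell and 800-bin/120-cell
simulations over 20 seeds with reduced schedules (60/40 iterations, 7/3
restarts). These sizes were chosen so that the full suite and the
acceptance script each complete on a single CPU in minutes while leaving
every scored quantity estimable with comfortable statistical margins.

## Known limitations

- The number of states is fixed by the user; no model selection is
  provided.
- Emission families other than the Dirichlet-multinomial (Poisson,
  negative binomial) are out of scope, as are variational inference and
  GPU acceleration.
- Downstream dimensionality reduction, clustering, batch correction and
  differential accessibility are intentionally outside the package; the
  exported region BED is their input. The differential-accessibility
  selection constants referenced alongside the fi regions (minimum log2
  fold change 1, adjusted p ≤ 10%, top 500 regions per cluster) are
  documented here but the DE fit itself is not implemented.
- `fit()` is single-threaded; per-chromosome E-steps are independent and
  could be parallelized without changing results.
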