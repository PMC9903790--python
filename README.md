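# scregseg

Genome segmentation of single-cell ATAC-seq accessibility with a
Dirichlet-multinomial hidden Markov model.

Single-cell ATAC-seq measures chromatin accessibility per cell barcode as
sparse fragment counts over the genome. This package addresses two tasks
that arise before and after cell clustering:

- **Feature identification (fi).** Segment genome-wide 1 kb tiles of the
  cells × bins count matrix into hidden states; states whose calls cover
  at most 1.5% of the genome are rare, informative "foreground" states,
  and their high-confidence regions (posterior ≥ 0.9, bookended bins
  merged) are the features for downstream dimensionality reduction —
  without needing predefined peaks or cluster labels.
- **Program identification (pi).** Segment 500 bp cluster pseudo-bulk
  tracks into states that act as regulatory programs shared across or
  specific to cell types, summarized by the state-cluster association
  log(P<sub>cs</sub>/P<sub>b</sub>).

It is aimed at computational genomics researchers working with sci-ATAC
or 10x scATAC fragment files.

## Model

Bin *i* emits its count vector *x<sub>i</sub>* over tracks (cells or
clusters) from a Dirichlet-multinomial conditioned on the bin total
*n<sub>i</sub>*:

```
P(x | α_s) = C(n; x) · Γ(A_s)/Γ(n+A_s) · Π_c Γ(x_c+α_sc)/Γ(α_sc),   A_s = Σ_c α_sc
```

so states are distinct cross-cell allocation profiles and depth is a
nuisance. States follow a Markov chain along each chromosome. Fitting is
Baum-Welch with a Minka fixed-point α update and multiple random restarts
(best log-likelihood kept); decoding uses Viterbi for state calls and
forward-backward for per-bin posteriors d<sub>ij</sub>. Downstream
statistics include the stationary-distribution enrichment score
((o<sub>i</sub>−e<sub>i</sub>)²/e<sub>i</sub>² for o<sub>i</sub>>e<sub>i</sub>,
with e<sub>i</sub> = N·p<sub>i</sub>), nearest-TSS hypergeometric gene-set
enrichment, gene-body marker scores, Shannon-entropy cell-type
specificity, exact binomial cell-composition tests, and classification of
regions against a histone-PTM chromatin-state annotation. See
`docs/methods.md` for the full account.

## Worked example

```python
import scregseg as sg

# simulate a small dataset with known ground truth (2,000 x 1 kb bins,
# 200 cells in 4 clusters, one rare regulatory-like state)
cfg = sg.SimConfig(seed=1)
frags, chrom_sizes, labels, truth = sg.simulate_dataset(cfg)

bins = sg.make_bins(chrom_sizes, cfg.binsize)
cm = sg.count_matrix(frags, bins, cap=4)

model = sg.DirichletMultinomialHMM(cm, n_states=3)
res = model.fit(n_iter=100, n_restarts=5, seed=2)
print(res.summary())
```

which prints (abridged):

```
Dirichlet-multinomial HMM results
================================================
n_bins:              2000
n_tracks:            200
n_states:            3
log-likelihood:      -157983.2294
EM iterations:       29
restarts:            5
restart llf spread:  5812.9727

 state  stationary_prob  genome_fraction  mean_call_posterior  concentration_total
     0           0.3047           0.3205               1.0000             587.6780
     1           0.0910           0.0915               1.0000             387.4065
     2           0.6043           0.5880               1.0000             310.6593
```

The fitted states recover the planted structure exactly (state-path
adjusted Rand index 1.0 on this seed): state 1 is the rare
regulatory-like state (9.2% of bins in this realization), and the ~5,800
nat spread between restart log-likelihoods shows why multiple seeded
restarts matter. Decoding and foreground extraction then follow the fi
recipe:

```python
seg = res.decode()                                   # Viterbi + posteriors
fg = sg.select_foreground_states(seg, max_fraction=0.015)
regions = sg.extract_regions(seg, fg, min_posterior=0.9)
regions.to_bed("foreground.bed")

assoc = sg.cell_state_association(seg, cm)           # log(a_ij / b_i)
```

For program identification, collapse cells to cluster pseudo-bulks and
refit:

```python
cluster_cm = sg.collapse_by_group(sg.count_matrix(frags, bins), labels)
pires, piseg = sg.run_pi(cluster_cm, n_states=3, n_iter=40, n_restarts=3, seed=7)
print(sg.state_cluster_association(piseg, cluster_cm).logratio.round(2))
```

```
         cluster0  cluster1  cluster2  cluster3
state_0      0.32      0.32     -0.24     -0.25
state_1      0.99      0.99     -4.40     -4.53
state_2     -3.98     -3.95      0.45      0.45
```

A state's association row has large positive entries exactly for the
clusters in which its regions are accessible: here state 1 (the
regulatory-like state, open in clusters 0 and 1) scores ~1.0 for those
two clusters and is strongly depleted elsewhere.

The same pipeline is available from the shell:

```bash
scregseg simulate --seed 7 -o sim/
scregseg fragments-to-counts --fragments sim/fragments.tsv \
    --chromsizes sim/chrom.sizes --binsize 1000 --cap 4 \
    --min-frags 0 --max-frags 1000000 -o counts
scregseg fit --counts counts --n-states 3 --n-iter 100 --restarts 5 --seed 2 -o model.json
scregseg fi --model model.json --counts counts -o regions.bed
```

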