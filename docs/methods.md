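# Methods

`acetknn` predicts, from a single amino-acid sequence plus its database
annotations, whether a protein is acetylated anywhere — a whole-protein
binary call, not a per-site one. This note documents the model, its
parameters, the synthetic data used for validation, and the design
decisions that were genuinely open.

## The predictor

A protein `P = P1 P2 ... PL` (L ≥ 30 canonical residues) is mapped to a
numeric vector from three kinds of information, then classified by a
random forest after Relief feature selection.

### Type-1 pseudo amino acid composition (PseAAC)

The sequence-intrinsic block. With correlation depth λ and damping weight
w, the encoding is

    p_u = f_u / (1 + w Σ_j θ_j)          u = 1..20
    p_{20+j} = w θ_j / (1 + w Σ_j θ_j)   j = 1..λ

where `f_u` are residue frequencies and each tier correlation
`θ_j = mean_i Θ(R_i, R_{i+j})` averages the squared differences of three
standardized physicochemical properties (hydrophobicity, hydrophilicity,
side-chain mass) between residues j apart. Defaults: λ = 5 (25
components), w = 0.05. The vector is non-negative and sums to 1.
Because Θ is symmetric in its arguments, the encoding is exactly invariant
under sequence reversal; order sensitivity shows up under any other
reordering of the residues.

### Grey-model PSSM summary (80 features)

Evolutionary conservation comes from a PSI-BLAST position-specific scoring
matrix (L×20 log-odds; the package parses `-out_ascii_pssm` files but
never runs PSI-BLAST). Each of the 20 residue columns is rescaled through
the logistic map `1/(1+e^-x)` — the grey model assumes a positive series,
log-odds are signed — and fitted with the classic GM(1,1) construction:
accumulate `x1 = cumsum(x0)`, form background values
`z1(k) = (x1(k)+x1(k-1))/2`, and solve `x0(k) + a·z1(k) = b` by least
squares. The column is summarized by the quadruple (a, b, mean, SD), so
20 columns × 4 = 80 features. If all background values coincide (constant
zero column) the fit degenerates and (a, b) = (0, mean) is used.

The exact decomposition of the 80 into per-column statistics is a design
choice: two grey coefficients per column alone would give 40, so the two
order-free moments complete the budget while keeping every value
PSSM-derived. A min–max rescale is available as an alternative to the
logistic map (`gray_rescale="minmax"`).

### Annotation KNN scores

The core idea. Eight keyword vocabularies are recognized: GO, Pfam,
Smart, PROSITE, SUPFAM, InterPro, PRINTS (the functional-domain
annotations) and SL (subcellular localization). The distance between two
proteins under vocabulary j mixes set dissimilarity and sequence
similarity:

    Dist_j(p, q) = w1 · (1 − |A_p ∩ A_q| / |A_p ∪ A_q|) + w2 · d_PseAAC(p, q)

The KNN score at neighborhood size k is the fraction of acetylated
proteins among the k nearest labeled reference proteins; sweeping k over
the 50-point grid 0.1%, 0.4%, ..., 14.8% of the reference size (step
0.3%) gives a 50-vector per vocabulary. A ninth pseudo-vocabulary, PAAC,
uses the PseAAC Euclidean distance alone. The default model matrix is
the 7 functional-domain blocks plus the 25 PseAAC components — 375
columns; the full configurable pool (gray-PSSM + PseAAC + 9 KNN blocks)
is 555.

Numerical conventions, chosen for determinism and neutrality:

* **w1 = w2 = 0.5** after normalizing the Euclidean term per query by its
  maximum over the reference corpus, which puts both terms on a [0, 1]
  scale. The normalization is monotone per query, so neighbor rankings —
  the only thing the scores depend on — are unaffected. The standalone
  `fuzzy_distance` function returns the raw unnormalized mix.
* **k = max(1, round(f·N))** with half-up rounding; the floor of 1
  prevents empty neighborhoods at the 0.1% grid point on small corpora.
* **Ties** among equidistant neighbors break by lexicographic record id,
  making every score bit-reproducible.
* **Two empty annotation sets** count as maximally dissimilar (set term
  1): absence of annotation is no evidence of similarity. Logged at debug
  level for auditability.
* **Self-exclusion** is mandatory in training mode (a record in its own
  reference is otherwise its own nearest neighbor, leaking its label) and
  off at prediction time, when the query is unseen.

### Relief selection and the forest

Relief (original formulation: deterministic full sweep, one nearest hit
and one nearest miss per instance, Euclidean distance over
range-normalized features) assigns each feature a weight in [−1, 1];
constant features are forced to 0 and excluded from distances.
`n_neighbors > 1` switches to ReliefF-style averaging, and a sampled mode
(`m`, seeded) reproduces the classic randomized variant. Selection is
top-n (default n = 156, the published operating point of this feature
family) or by weight threshold; either way a per-block ledger reports how
many features survived from each block.

The engine is a random forest: 500 trees, √p features per split, fixed
seed, probability output thresholded at 0.5. All hyperparameters are
exposed.

### Evaluation protocol

Stratified 5-fold cross-validation. Within each fold, the KNN reference
corpus, the Relief weights and the forest are all fitted on the training
records only; per-fold selection was chosen over a single global Relief
pass because the latter leaks test labels into feature choice. Metrics:
Acc, Mcc, Sn, Sp, Pre, F-measure, G-mean from the closed forms (0/0 → 0
by convention, logged), plus ROC/AUC by descending-threshold sweep
(equal to the tie-corrected Mann–Whitney statistic). Fold means ± SD and
the pooled-score ROC are both reported. For a large unbalanced corpus,
`evaluate_balanced_datasets` splits the negative pool into three disjoint
subsets of the positive-set size (e.g. 2175 → 725/725/725), evaluates
each balanced dataset, and reports per-dataset means plus their average —
fold-level and dataset-level averages are distinct and both available.

## Synthetic data

The generator emulates the statistical structure the method assumes,
without any biological realism claims:

* sequences i.i.d. over approximate proteome residue frequencies, lengths
  uniform in 30–500 (default corpus 725 positive / 2175 negative);
* per-vocabulary keyword sets of Poisson(5) size drawn from a 200-keyword
  vocabulary split into an enriched half and a background half: positives
  draw each keyword from the enriched half with probability `enrichment`,
  negatives always draw background;
* PSSMs: integer log-odds ~ round(N(0, 2)) clipped to ±9, with a
  `pssm_signal` shift added to five fixed columns in positives.

Presets: `null` (enrichment 0, shift 0 — a negative control), `weak`
(0.4, 1), `strong` (0.8, 2 — the default validation condition). The same
seed yields byte-identical FASTA/TSV/PSSM output.

What the generator does **not** emulate: GO DAG structure and
between-vocabulary correlation, homology between sequences (inputs are
assumed redundancy-reduced), realistic PSSM column covariance, and any
relation between sequence content and annotations. Passing tests
therefore demonstrate that the pipeline recovers class signal of the
assumed form and stays at chance without it — not field performance on
curated proteome data.

## Validation problem sizes

The bundled checks run at desk scale: the negative-control
cross-validation band uses twenty 60+60 corpora (pooled n = 2400, 99%
binomial band ±2.6% around 0.5); strong-signal detection uses three
100+100 corpora (observed pooled AUC ≈ 0.98); Relief recovery uses
n = 300 with 20 informative features shifted by 1 SD against 80 noise
features; the score-gap shape checks average twenty 40+40 corpora.

## Known limitations

* Absolute published accuracies for this feature family depend on a
  specific curated protein extract and its PSI-BLAST profiles; they are
  not reproducible from synthetic data and are not a target here.
* With few annotated neighbors the KNN scores are coarse (k = 1 at the
  smallest grid fractions), so small-corpus score profiles are noisy.
* Proteins without any annotation fall back to the maximal-dissimilarity
  convention in every set term and are effectively scored by PseAAC
  distance alone; a per-record warning is emitted at prediction time.
* Relief weights on strongly correlated blocks (adjacent grid points are
  highly correlated) spread credit across the block; the per-block ledger
  is the honest summary of what survived.
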