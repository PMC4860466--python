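# Methods

This note records the model, the choices made where the design was genuinely
open, what the synthetic data generator does and does not emulate, and the
problem sizes used by the shipped experiments.

## Architecture and training

Three rectangular 30 x 40 SOMs (no wraparound; grid distance is Euclidean on
(row, col)) represent semantics (68-d rater-proportion feature vectors),
phonology (81-d slot vectors), and orthography (297-d slot vectors).  Node
weights initialize uniformly in [0, 1] per coordinate from a per-replicate
seed.  The best matching unit (BMU) is the Euclidean argmin with ties broken
toward the lowest row-major index.  Updates use a truncated Gaussian kernel:
nodes within grid distance <= r of the BMU move by
`lr * exp(-d^2 / (2 sigma^2))` toward the input, with `sigma = r` (1 when
r = 0).  The learning rate decreases linearly from 0.2 to 0.1 over the anneal
window and stays at 0.1 afterwards.

The neighborhood radius starts at 15 and self-adjusts: quantization error
(QE; mean input-space distance from each stimulus to its BMU's weights) is
recorded once per epoch over the whole stimulus set, and at every 5th epoch
(with at least 10 epochs of history) the radius drops by 1 when the mean QE
of the last five epochs lies within 25% of the mean of the five before —
i.e. when learning has plateaued at the current resolution.  The training
radius floor is 1.  The separate floor of 3 used for orthographic activation
spreading applies only at test time, in the production module.

Training is three-phase (full scale 500 epochs): epochs 0–50 the semantic
and phonological maps self-organize independently; from epoch 50 the
orthographic map joins and Hebbian learning begins — semantic->phonological
pathways per language, scaled by each name's empirical agreement proportion
N, plus lateral links between co-activated cross-language name BMUs; from
epoch 100 the semantic->orthographic and phonological<->orthographic
(one-to-one per word) pathways join.  Stimulus order is reshuffled every
epoch from the replicate RNG.  Scaled-down runs keep the same proportions:
`TrainingConfig.scaled(E)` places the boundaries at 0.1 E and 0.2 E and
anneals the learning rate over the first 0.2 E epochs, mirroring the
coincidence of anneal end and reading start at full scale.

### Hebbian details

The increment is `dw_kl = beta * alpha_k * alpha_l * N` with beta = 0.2.
The activation fields alpha are truncated Gaussian bumps centered on the
stimulus object's semantic BMU and on the name's word-form BMU, with each
map's current radius (the source never states what alpha is beyond "the
activation levels of corresponding nodes"; the bump is the natural SOM
choice).  Multiplicative normalization rescales any *outgoing* weight vector
whose maximum exceeds 1 — the standard Willshaw-style reading of
per-vector normalization.

Inside the trainer, one epoch's Hebbian increments are accumulated as a
single batched outer product (a BLAS matrix product over the stacked bump
fields) with the cap applied at the end of the epoch.  The increments are
mathematically identical to per-stimulus updates; only the cap cadence
differs, and the cap is a ceiling rather than a competitive rule, so the
batched form preserves the learning dynamics while making desk-scale
ensembles practical.

Lateral connections are stored sparsely between word-BMU node pairs of
different languages (only activated names ever participate).  Their
activation levels during learning are the names' empirical agreement
proportions for the current object, consistent with the role of non-target
name agreement in the production decomposition.  Both directions grow
symmetrically; self-connections are never created.

## Production

Naming an object builds the semantic bump at its BMU and reads activation at
each target-language word's phonological BMU as the sum of three
non-negative routes (each route is a pathway propagation
`alpha_l = clip(sum_k alpha_k w_kl, 0, 1)`):

1. **semantic**: through the target language's semantic->phonological matrix;
2. **lateral**: through the *other* language's matrix, restricted to nodes
   labeled (at test only) with the non-target language, then across the
   sparse lateral links;
3. **orthographic**: through the semantic->orthographic matrix, spread over
   the orthographic neighborhood (a node's spread activation is the sum of
   its activated neighbors within radius max(3, current radius), excluding
   itself), then back through the orthography->phonology matrix.

The total is the simulated name agreement; route additivity is exact by
construction.  The dominant set contains the argmax name plus any name
scoring strictly more than 80% of the maximum.  If two words collide on one
BMU the tie is reported and broken by the larger summed associative
in-weight.  Accuracy is the percentage of objects whose simulated dominant
set intersects the empirical dominant set (same 80% rule on the norms);
objects without norms in the comparison group are excluded and objects the
model cannot name count as misses.

Because pathway weights are capped at 1 individually while bump fields
activate many nodes, propagated activations saturate at the clip for
well-learned names; dominance and the convergence statistics are driven by
the graded activations of competitor names.

## Encoders

Both word-form templates are filled by one rule: parse the form into maximal
consonant/vowel runs; a run occupies the C- or V-block of the current group,
left-justified; a consonant run that follows a vowel run opens the next
group.  This is anchored to the published example layout of *bidon*
(`b--i--/d--o--/n-----/...`), whose final consonant opens group 3.  Unfilled
slots are exactly zero, so the number of nonzero slot blocks equals the
word's length.  Multi-word names are encoded as a single concatenated form
(the source does not specify their treatment).

Phoneme coordinates follow the generic three-dimensional articulatory coding
(consonant/vowel flag, place/backness, manner/height) scaled into [0.1, 1]
so a filled slot is never the all-zero padding pattern; the packaged table
covers the Dutch and French IPA inventories and is config-replaceable, since
the published model defers to an external pattern generator whose exact
values are not printed.  Letter vectors are black-pixel proportions over a
3 x 3 partition of a 90 x 90 glyph (900 pixels per cell); the packaged table
was produced by rasterizing DejaVu Sans glyphs through
`letter_vector_from_glyph`, with the rows for *b* and *d* pinned to the
published reference vectors.  The vowel-letter set for the orthographic
template defaults to {a, e, i, o, u, y, è, é, î} and is configurable.

## Synthetic naming norms

The generator emulates the three-table structure of bilingual naming norms:
73 objects x 68 features, name inventories of 42 and 39 (three frequent
category names per language plus low-frequency names), 25 participants per
group, and 1–9 distinct names per object under the defaults.

Latent binary prototypes define language A's categories; language B's
prototypes are the same vectors with a `divergence` fraction of features
flipped (default 0.3), misaligning the two languages' category boundaries.
Each object starts at its prototype, is pulled toward a second category by a
per-object graded-membership draw (uniform in [0, `boundary_mix`], default
0.5), then passes through per-feature flip noise and a simulated 12-rater
panel.  The graded pull exists because naming norms are full of boundary
exemplars — low-agreement objects attracting several names — and half the
analysis battery (outliers, boundary complexity, boundary-dependent centers)
is about exactly those; with `boundary_mix = 0` the generator reduces to
pure prototype-plus-noise objects.  Naming probabilities are a softmax over
negative Euclidean prototype distances at temperature `kappa` (default 0.1,
concentrating agreement on the nearest category), distributed over the
category's dominant name (75% share) and a small object-specific set of
low-frequency names; responses are multinomial draws.  The bilingual group's
category probabilities are a fixed 50/50 mixture of the A- and B-derived
probabilities — deliberately *not* an output of the network model, so the
statistics module can be validated against known ground truth while the
model's own bilingual output remains the object of the experiments.

What the generator does **not** emulate: participant-level individual
differences, developmental trajectories, real featural structure of
household containers, real Dutch/French word forms, or empirically calibrated
agreement distributions (the only published anchors are the 1–9 name range
and two example splits).  Passing the qualitative experiments therefore shows
that the mechanisms produce the convergence pattern under controlled
conditions, not that the model quantitatively reproduces human norms.

## Analysis battery

Similarity profiles are the n(n-1)/2 pairwise Pearson correlations between
object name distributions, in row-major upper-triangle order; undefined
entries (constant rows) are recorded as missing, excluded pairwise, and
counted.  Group comparisons Fisher-transform the profile correlations
(z = arctanh r) and use `Z = (z1 - z2)/sqrt(1/(n1-3) + 1/(n2-3))` with the
retained pair counts as n.  Typicality reverses the naming pathway through
the transpose of the semantic->phonological matrix (the links are learned
bidirectionally).  Category centers weight object BMU coordinates by the
name's typicality activation over all objects: the boundary-dependent center
is the weighted mean, the boundary-independent one the per-coordinate lower
weighted median.  Members are objects whose forward-naming argmax is the
category name; outliers lie closer to another listed category's
boundary-dependent center.  The stepwise discriminant analysis uses
F-to-enter p <= 0.05 and F-to-remove p >= 0.10 (the defaults of the classic
stepwise implementations), with a secondary stop when a candidate would
change the canonical correlation by less than 0.01; Wilks' lambda is
det(W)/det(T) with a recorded ridge if the SSCP matrices are singular, and
final significance uses the exact two-group F transform.

## Problem sizes and numerical choices

The shipped convergence experiment trains 5 replicates x {bilingual,
monolingual-A, monolingual-B, no-lateral} for 200 epochs (phases 20/40) on
the default 73-object dataset — the package's desk-scale protocol, chosen so
a full run completes in minutes while leaving every phase of the full
protocol represented; the full-scale study conditions (20 replicates, 500
epochs) are a constructor argument away.  Replicate seeds derive from the
experiment seed; every random draw flows through `numpy.random.default_rng`.
State archives store arrays losslessly and are SHA-256 checksummed;
reloading reproduces naming outputs bit-identically (sparse lateral sums use
a fixed key order for this reason).

## Known limitations

* Activation saturation (see Production) compresses differences among
  well-learned dominant names; analyses relying on graded dominant-name
  activation inherit this.
* The lateral matrix keys nodes, not words; as BMUs drift during training,
  stale node pairs persist with small weights.  They decay in influence
  because propagation reads activation at current BMUs.
* The stepwise selection, like all stepwise procedures, capitalizes on
  chance with many candidate features; it is used comparatively (bilingual
  vs. monolingual counts), never inferentially.
* Monolingual "groups" are independent single-language models fed the same
  semantic vectors; cross-language monolingual correlations therefore
  compare two separate networks, which is the intended baseline.
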