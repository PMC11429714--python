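# Methods

This note records the statistical model behind `kinlink`, the
conventions chosen where the field's practice is not unique, the
synthetic data model used for validation, and known limitations.

## Windows and coordinates

A phosphosite is keyed by (protein, acceptor residue, 1-based position),
PhosphoSitePlus-style (e.g. `PPP1R12A_T696`). Its sequence window spans
positions −5…+4 around the acceptor: a 10-character string with the
acceptor at index 5. This length covers every position used by the
consensus motifs handled here (−5, −4, −3, −2, 0, +4). Windows that run
off a protein terminus are padded with `_`; padded positions contribute
exactly 0 to every PSSM score and never satisfy a consensus position.

## Consensus motifs

* ROCK: a basic residue (R/K) at −2 (βXpS/T) or −3 (βXXpS/T) with an
  S/T acceptor. A tyrosine acceptor returns no match by contract.
* AMPK: strict mode requires hydrophobic (M/L/I/F/V) at −5, basic
  (R/K/H) at both −4 and −3, and hydrophobic at +4
  (φββXXpS/TXXXφ). Relaxed mode accepts the common variants —
  hydrophobic at −5 *or* +4, and basic at −3. Strict is the default;
  both are exposed because reported AMPK substrates frequently deviate
  from the full consensus at one flank.

## PSSM scoring and percentiles

A kinase model is a log-odds matrix over (position, residue) plus an
S/T acceptor preference. The raw score of a window is the sum of
log-odds over non-padded flanking positions plus the log acceptor
preference — the standard additive-log-odds (product-of-odds) PSSM
convention. Raw scores are mapped to empirical percentiles (0–100)
against a background sample with the midpoint rule for ties
(`100·(#below + #equal/2)/n`), which makes percentile a monotone
function of the raw score. The default background is *dataset-internal*:
each kinase's scores against all quantified windows of the comparison.
An external reference sample can be attached per model instead
(`KinaseMotifModel.set_background`). Each site then retains its
`top_kinase_percentile_count` (default 25) kinases, read as "the 25
kinases with the highest percentile ranks", with boundary ties broken
by raw score and then kinase name so results are deterministic.

## Differential regulation

Sites are called up/down when |log2FC| ≥ `log2fc_min` (1.5) and
adjusted p ≤ `adjp_max` (0.05), boundaries inclusive. The signed
regulation score is `w · log2FC` with `w = minmax(−log10 p_adj)` taken
across all quantified sites of the comparison. Using −log10 p (rather
than p itself) makes the most significant site carry weight 1 and the
least significant weight 0; normalizing raw p would weight
non-significant sites most, contradicting the score's downstream use.
The transform is switchable (`p_weight_transform`: `neglog10`, `raw`,
`one_minus`). Min-max of a constant vector is defined as all zeros.
Adjusted p of exactly 0 is clamped to the smallest positive float with
a warning before the log.

## Kinase-motif enrichment and relative activity

For each kinase × direction within a comparison, the 2×2 table counts
top-k membership among the direction's called sites (foreground)
versus all other quantified sites of the same comparison (background);
foreground and background are disjoint by construction. The p-value is
the one-sided Fisher exact (hypergeometric upper tail of ≥ observed
foreground hits); the log2 frequency factor is the ratio of foreground
to background hit rates, with 0.5 added to all four cells only when
some cell is zero (Haldane-style continuity). BH runs over one family
per comparison: all kinases × both directions, excluding untestable
(empty-foreground) directions. The relative kinase activity picks each
kinase's more significant direction (ties: larger |frequency factor|,
then up before down), weights its frequency factor by
`minmax(−log10 p_adj)` across the comparison's kinases, and signs the
result positive for up and negative for down; the frequency factor's
own sign is preserved within the direction. Because the weight is ≤ 1,
|activity| never exceeds the largest |frequency factor|.

## Interaction, pathway and network scores

For a kinase–phosphosite link: `KLS = percentile/100 · |activity|`
(percentile rescaled to 0–1 so both factors share scale), plus 0.5 per
curated evidence level (in vitro, in vivo; site-level records override
protein-level ones) plus `n/(n+1)` for `n` interaction references
(matched at the protein-pair level). The final interaction score is
the augmented KLS times the site's signed regulation score, so it
carries the regulation's sign. Differential sites keep their top
`top_interactions_per_site` (3) kinases ranked by |final score| (ties:
higher augmented KLS, then name); filtering precedes all aggregation.
Kinase–substrate scores are signed sums over the substrate's retained
sites. The pathway interaction score is (sum of member-protein score
sums) × (fraction of detected members with ≥ 1 score); the fraction is
0–1 by default, with a ×100 percent scale as a pure rescaling option.
Networks are bipartite kinase→substrate graphs (edge weight = pair
score, direction attribute = sign; substrate nodes carry the Chronos
score and an `essential` flag), exported as GraphML or SIF.

## ORA and dependency partitioning

Overrepresentation is the one-tailed hypergeometric test of a gene
set's foreground hits given its background representation, with
enrichment ratio = foreground proportion / background proportion. Sets
with fewer than `min_background` (3) members in the background are
skipped and excluded from the BH family (reported as absent, not as
p = 1). Genes are essential iff Chronos ≤ −0.5 (boundary essential);
the regulated-phosphoprotein foreground — selectable as up-only,
down-only, co-regulated (≥ 1 up and ≥ 1 down site in the same
comparison) or any — is partitioned into essential and non-essential
parts, each tested against the background of all detected
phosphoproteins with BH within the partition. Foreground genes without
a dependency score are dropped from both partitions with a log entry.

## Flux and isotopologue arithmetic

Stress-test metrics are differences of specific rate measurements; a
measurement belongs to an injection's segment if it falls strictly
between that injection and the next. Non-mitochondrial respiration
(the post-rotenone/antimycin minimum) and maximal respiration (the
post-FCCP maximum minus non-mito) follow the vendor-standard readings,
recorded here as assumptions since the terms are used without
definition in most methods write-ups. The glycolysis formula is
implemented as `max(post-glucose, pre-oligomycin) − last(pre-glucose)`
— the subtraction is the only dimensionally meaningful reading — and
the glycolytic reserve is capacity − glycolysis, which may be negative
(no clamping). Isotopologue fractional abundance divides each mass
shift's peak area by the metabolite's total; total-intensity
normalization divides each sample row by its sum, so it is idempotent
and invariant to positive rescaling of a sample.

## Synthetic data model

The generator emulates, at desk scale, the inputs of an acute
two-drug phosphoproteomics experiment:

* **Kinase library** — each kinase gets a near-uniform log-odds matrix
  (Normal(0, 0.1)) with 1–3 strongly preferred (position, residue)
  pairs (log-odds ≥ 2). The first model carries the literal AMPK
  consensus preferences, the second the ROCK preferences, so the
  consensus matchers and the PSSM route can be cross-checked on the
  same planted kinases.
* **Phosphoproteome** — default 2000 sites on 400 proteins, one
  comparison, 5% of sites regulated, planted effect size 3 (mean
  |log2FC|) over a null SD of 0.3. Planted substrates of up-active
  kinases draw log2FC ~ Normal(+3, 0.3) and windows from the owning
  kinase's PSSM (per-position categorical with probabilities ∝
  exp(log-odds)); null sites draw log2FC ~ Normal(0, 0.3) and uniform
  windows with S/T acceptors. Raw p-values are the two-sided normal
  tails of log2FC/SD — exactly uniform under the null and consistent
  with the fold change on planted sites — and adjusted p-values come
  from the pipeline's own BH step. These sizes make the default suite
  and the acceptance script run in seconds while leaving the planted
  signal strong and the null calibrated.
* **Annotations** — 60% of planted kinase–substrate pairs receive
  in vitro/in vivo evidence flags and 50% receive geometric (support
  ≥ 1) reference counts; one planted pathway per active kinase
  contains that kinase's substrate proteins; the first up-active
  kinase's substrate proteins are designated essential with Chronos
  drawn below −0.6 (margin under the −0.5 cutoff), all other genes
  Normal(0, 0.3); 20 decoy gene sets of 10–30 random proteins.

What passing recovery tests shows — and does not. The generator's null
windows are uniform over residues, its planted windows are drawn from
the same PSSMs used for scoring, and fold changes are homoscedastic
Gaussians; real TMT data have compositional residue biases, missing
values, peptide-to-site roll-up, and moderated test statistics, none
of which are modeled. Recovery here therefore validates the *inference
machinery* (that the scores rank truly active kinases first and the
tests are calibrated), not the biological error rates to expect on
real spectra.

## Numerical choices and degenerate inputs

* Empty 2×2 table: the one-sided p is 1 by definition (P(X ≥ 0)).
* BH is delegated to `statsmodels` (`fdr_bh`); tests verify it against
  an independently hand-stepped implementation.
* Exact tails are delegated to `scipy.stats.hypergeom`; tests verify
  them against explicit enumeration of the support for every table
  with total ≤ 30 and seeded samples up to 60.
* Evidence and reference increments are stored as exact constants
  (0.5 per level; n/(n+1)), not as floating-point differences, so the
  documented decomposition `augmented − base ∈ {0, 0.5, 1} ⊕ [0, 1)`
  holds exactly.
* All tie-breaks (top-k kinases, top-3 interactions, direction choice)
  are total orders ending in lexicographic kinase name, so every output
  is deterministic given the config seed.

## Known limitations

* The percentile background convention (dataset-internal) differs from
  a fixed external reference set; with a real kinase library, attach
  the reference background per model for comparable percentiles.
* The enrichment background (all quantified non-foreground sites of
  the same comparison, shared across directions) is one of several
  defensible choices; it is configurable at the API level.
* Gene-set term clustering/pruning (as done by web ORA services) is
  out of scope; only the hypergeometric statistic is implemented.
* No spectral processing: the pipeline starts from quantified,
  localized phosphosite tables, and no glycolytic-index metric is
  computed (no standard formula exists).
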