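# kinlink

Kinase–substrate inference from differential phosphoproteomics, with the
bioenergetic arithmetic that typically accompanies such studies.

## What it is for

Acute drug perturbations — for example combining an OXPHOS (complex I)
inhibitor with a ROCK inhibitor in lung cancer cells — rewire cell
signaling within hours. TMT phosphoproteomics measures the result as a
table of phosphosites with per-comparison log2 fold changes and
BH-adjusted p-values, but the quantity of biological interest is which
*kinases* changed activity and which substrates they drive. `kinlink`
implements that inference chain as a tested, reusable library:

1. **Differential calling.** A site is regulated when |log2FC| ≥ 1.5 and
   adjusted p ≤ 0.05 (both inclusive, both configurable). Its signed
   *regulation score* is `minmax(−log10 p_adj) · log2FC`, normalized per
   treatment comparison.
2. **Motif scoring.** Each phosphosite's −5…+4 sequence window is scored
   against a library of kinase position-specific scoring matrices
   (additive log-odds plus a log S/T acceptor preference), converted to
   an empirical percentile against the dataset's own windows, and each
   site keeps its top 25 kinases by percentile. Consensus matchers for
   the ROCK (β at −2 or −3; β = R/K) and AMPK (φ at −5/+4, β at −4/−3;
   φ = M/L/I/F/V, β = R/K/H) motifs are included.
3. **Kinase-motif enrichment.** Per kinase and direction, a one-sided
   Fisher exact test compares top-25 membership among regulated sites
   against all other quantified sites; BH correction runs per
   comparison. The signed *relative kinase activity* is
   `minmax(−log10 p_adj) · log2(frequency factor)` of the most
   significant direction (positive up, negative down).
4. **Interaction scoring.** The kinase library score for a
   kinase–phosphosite link is `KLS = percentile · |activity|`, augmented
   by +0.5 per curated evidence level (in vitro / in vivo,
   PhosphoSitePlus-style) and by `n/(n+1)` for `n` interaction
   references (BioGRID-style). The *final interaction score* is the
   augmented KLS times the site's signed regulation score; each
   differential site keeps its top 3 kinases, scores are summed per
   kinase–substrate pair, and a *pathway interaction score* multiplies
   the member-protein score sum by the fraction of members scored.
5. **Overrepresentation and dependency.** One-tailed hypergeometric ORA
   with BH and a minimum background of 3, run separately on essential
   (Chronos ≤ −0.5) and non-essential regulated phosphoproteins against
   the all-detected-phosphoprotein background.
6. **Flux and tracer arithmetic.** Mitochondrial and glycolysis
   stress-test metrics (basal, ATP-linked, proton leak, maximal, spare,
   glycolysis, glycolytic capacity/reserve) from OCR/ECAR traces with
   injection annotations, isotopologue fractional abundance, and
   total-intensity normalization.

A real 303-kinase PSSM library and curated databases can be supplied as
TSV inputs; none are bundled. Instead, the `synthetic` module generates
every input with *planted* ground truth — active kinases, motif-true
substrates, essential genes — so the whole chain is validated by
recovery.

## Worked example

```sh
kinlink --seed 5 --outdir demo run-all
```

simulates a 2000-site phosphoproteome on 400 proteins with two planted
up-active kinases (`AMPK_SYN`, `ROCK_SYN`) and one down-active
(`KIN000`), then runs the full pipeline. `demo/run_summary.json` reports:

```json
"combination_vs_control": {
  "n_sites": 2000, "n_up": 67, "n_down": 33,
  "top_kinases_by_activity": ["AMPK_SYN", "ROCK_SYN", "KIN021", "KIN000", "KIN017"],
  "n_network_edges": 274
}
```

Both planted up-active kinases head the activity ranking; the head of
`demo/activities_combination_vs_control.tsv` shows why:

```
kinase    direction  fg_hits/fg  bg_hits/bg  freq_factor  adj_p     activity
AMPK_SYN  up         57/67       964/1933    0.771        3.2e-07   0.771
ROCK_SYN  up         51/67       959/1933    0.618        5.7e-04   0.308
KIN021    down       23/33       963/1967    0.510        0.33     -0.037
```

`AMPK_SYN`'s motif appears in the top-25 sets of 85% of up-regulated
sites versus 50% of background sites; its frequency factor
(log2 of that ratio) times a normalized significance of 1 gives its
activity. Decoy kinases sit near zero. The scored network
(`network_*.graphml`, 274 kinase→substrate edges weighted by the summed
final interaction scores, substrates flagged essential at
Chronos ≤ −0.5) and per-pathway interaction scores are written
alongside.

Individual stages are available as `simulate`, `enrich`,
`score-network`, `ora` and `flux` subcommands, or directly from Python:

```python
import kinlink as kl
cfg = kl.RunConfig(seed=5)
library = kl.generate_kinase_library(50, seed=5)
truth = kl.default_truth()
sites, truth = kl.generate_phosphoproteome(truth, library, cfg, seed=6)
inference = kl.run_kinase_inference(sites, library, cfg)[truth.comparison]
print(inference.activities.nlargest(3, "activity"))
```

## Layout

| module                    | contents                                            |
|---------------------------|-----------------------------------------------------|
| `kinlink.config`          | `RunConfig`: thresholds, filter sizes, seed         |
| `kinlink.io`              | TSV/GMT/PSSM/trace readers, GraphML/SIF export      |
| `kinlink.synthetic`       | planted-truth generators for every input            |
| `kinlink.motifs`          | consensus matchers, PSSM scoring, percentiles       |
| `kinlink.differential`    | differential calls, regulation scores               |
| `kinlink.enrichment`      | Fisher tests, BH, frequency factors, activities     |
| `kinlink.netscore`        | KLS, evidence augmentation, filters, networks       |
| `kinlink.pathways`        | hypergeometric ORA, dependency partitioning         |
| `kinlink.flux`            | stress-test metrics, isotopologue normalization     |
| `kinlink.pipeline` / `cli`| orchestration and the `kinlink` executable          |

See `docs/methods.md` for the statistical conventions, the synthetic
data model, and the design decisions behind them.
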