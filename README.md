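# crosswell

Quantify **well-to-well cross-contamination** in plate-based microbiome
experiments.

Negative controls in 16S amplicon studies are usually assumed to capture
*external* contamination — DNA from kits, reagents, and consumables.  But
when samples are extracted in 96-well plates, material also moves
physically **between wells**, so blanks and low-biomass samples pick up
reads from their high-biomass neighbors.  Contaminant-removal tools that
subtract everything found in blanks will then remove the most abundant
*genuine* taxa in the study.

`crosswell` implements the analysis used to measure this effect with a
checkerboard validation design: known bacterial isolates placed at high
biomass ("sources", ~1e7 cells) among low-biomass "sink" wells (~1e5
cells, one isolate) and no-template blanks (NTCs).  Because every well's
intended content is known, every read can be attributed:

* **expected** — reads of the isolate placed in that well;
* **well-to-well (W2W)** — reads of a panel isolate that belongs in a
  *different* well (an sOTU tag is assigned to an isolate only on a 100%
  exact match over the 150-bp tag; dataset singletons are removed; no
  rarefaction);
* **background** — reads matching no panel isolate (the reagent
  "contaminome").

From the per-sample partition the package derives the field's standard
summaries: W2W **prevalence** (% of samples with ≥1 W2W read), W2W
**composition** (mean/median/max of the W2W read fraction, in %),
richness inflation and the W2W share of richness, the **distance-decay**
of contamination events (Euclidean distance in well units from the source
well), **barcode leakage** between co-sequenced plates, and the
sensitivity of replicate **beta-diversity** (Bray-Curtis
`Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)` vs binary Jaccard `1−|A∩B|/|A∪B|`) to rare
contaminant tags.

A first-class **simulator** generates whole plate experiments with known
per-read ground truth — distance-decaying transfer kernel, shared
heavy-tailed background pool, PCR/sequencing noise, replicate PCR plates,
and index leakage — so the entire pipeline is validated end-to-end at
desk scale.

## Worked example

Simulate one robot-extracted plate under default conditions and summarize
contamination per sample type:

```python
from crosswell.simulate import SimParams, simulate_extraction_plate
from crosswell.classify import classify_sotus
from crosswell.quantify import (records_from_metadata, partition_table,
                                partitions_frame, summarize_groups)

params = SimParams(seed=7)
sim = simulate_extraction_plate(params)
cls = classify_sotus(sim.table, sim.panel)
records = records_from_metadata(sim.metadata)
parts = partition_table(sim.table, cls, records)
print(summarize_groups(partitions_frame(parts), ["sample_type"]).round(2).to_string())
```

```
             n_samples  prevalence_pct  mean_richness  w2w_pct_of_richness  w2w_mean_pct  w2w_median_pct  w2w_max_pct  background_mean_pct  background_median_pct  background_max_pct
sample_type
NTC                 48           100.0          88.52                18.10         83.39           85.37        94.05                16.61                  14.63               66.37
sink                24           100.0          50.50                24.66          1.90            2.01         3.53                 0.50                   0.52                0.72
source              24           100.0           5.67                57.08          0.02            0.02         0.04                 0.01                   0.00                0.02
```

Reading this: every simulated blank contains W2W reads (prevalence 100%),
and W2W contamination dominates blank composition (median 85% of an NTC's
reads come from neighboring wells), while the same transfer is a ~2%
effect in low-biomass sink wells and negligible (0.02%) in high-biomass
source wells — contamination impact scales inversely with input biomass.
Richness is inflated far above the single expected sOTU per well, by
background tags and W2W contaminants together.

The same analysis runs from the shell on TSV/BIOM + FASTA + CSV inputs:

```bash
crosswell simulate --out sim/ --seed 7
crosswell quantify --table sim/table.tsv --metadata sim/metadata.tsv \
                   --refs sim/refs.fasta --out report/
crosswell spatial  --table sim/table.tsv --metadata sim/metadata.tsv \
                   --refs sim/refs.fasta --layout sim/layout.csv --out report/
crosswell all --out run/ --seed 7     # simulate + full report bundle
```

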