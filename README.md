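# granulekit

Quantitative analysis of Argonaute partitioning into germ granules and
of the small-RNA repertoires those granules shape — for researchers
studying *C. elegans* germline condensates (P granules, Z granules) and
small-RNA pathways, and more generally anyone quantifying protein
enrichment in biomolecular condensates from fluorescence images or
calling IP-enriched genes from small-RNA sequencing.

The package implements five analysis stages, each paired with a
synthetic-data generator that plants known ground truth, so every
stage is testable offline:

1. **Granule partition quantification** (`granulekit.imaging`).
   Granules are segmented from a marker channel with a
   Laplacian-of-Gaussian band-pass followed by Otsu thresholding, and
   the partition coefficient of a query protein is measured per
   confocal plane as

   *R(z)* = mean *I*<sub>query</sub>(granule, *z*) / mean *I*<sub>query</sub>(cytoplasm, *z*),

   summarized as mean ± SD over planes. A ring-SD metric (SD of
   intensity along a perinuclear band) scores punctate vs. diffuse
   localization, and ROI-based dense/dilute ratios quantify in vitro
   condensate partitioning (six 2.47 × 2.47 µm ROIs inside and outside
   condensates, with a bright-aggregate exclusion rule).
2. **Small-RNA target calling** (`granulekit.targets`). A gene is an
   Argonaute target when, in **every** biological replicate,
   IP ≥ 5 RPM and (IP + ε)/(input + ε) ≥ 2 (RPM = reads per million
   mapped; ε a small pseudocount guarding zero-input genes). Target
   sets are compared with exact Venn algebra, and positional targeting
   signatures are summarized as metagene profiles: each target gene is
   rescaled to 100 length bins and the mean coverage (RPM) per bin is
   averaged over targets.
3. **Gene-set enrichment** (`granulekit.enrichment`). Fisher's exact
   test (two-sided) on the 2×2 overlap table within an explicit
   universe, effect size log₂(observed/expected), Benjamini–Hochberg
   FDR across a matrix of comparisons.
4. **FG-dipeptide bias scanning** (`granulekit.dipeptides`). G-rich
   low-complexity segments are found by a binomial low-probability
   window scan (all windows of 15–500 residues), then scored for FG/GF
   dipeptide enrichment with a binomial upper tail against a background
   dipeptide frequency at a 0.005 probability threshold — the
   computation behind surveys of FG repeats in Vasa-family helicases.
5. **Workflow orchestration** (`granulekit.workflow` and the
   `granulekit` CLI): YAML-configured, seeded, byte-reproducible runs
   with a checksummed output manifest.

## Worked example

```python
import numpy as np
from granulekit.simulate import GranuleImageSpec, generate_granule_image
from granulekit.imaging import (segment_granules, make_cytoplasm_mask,
                                granule_cytoplasm_ratio)

spec = GranuleImageSpec(query_enrichment_ratio=3.1)   # planted truth
stack, truth = generate_granule_image(spec, seed=7)
seg = segment_granules(stack, "marker")
granules = seg.mask & (truth.nucleus_masks == 0)
cyto = make_cytoplasm_mask(np.ones_like(granules), truth.nucleus_masks, granules)
res = granule_cytoplasm_ratio(stack, "query", granules, cyto)
print(f"granule/cytoplasm ratio: {res.mean_ratio:.2f} +/- {res.sd_ratio:.2f} "
      f"over {res.n_planes_used} planes (true 3.1)")
```

prints

```
granule/cytoplasm ratio: 2.99 +/- 0.03 over 10 planes (true 3.1)
```

i.e. the planted 3.1-fold granule enrichment of the query protein is
recovered within a few percent from segmentation-derived masks; only
the 10 planes that actually intersect granules enter the summary.
The same session, continued for target calling and enrichment:

```python
from granulekit.simulate import SrnaExperimentSpec, generate_srna_experiment
from granulekit.targets import call_targets, compare_target_sets
from granulekit.enrichment import fisher_enrichment

exp, _, _ = generate_srna_experiment(SrnaExperimentSpec(), seed=1,
                                     with_coverage=False)
wt, _ = call_targets(exp, "WT")          # >= 5 RPM and >= 2-fold, all replicates
mut, _ = call_targets(exp, "mutant")
venn = compare_target_sets(wt, mut)
print(f"targets: WT {venn.sizes['a_total']}, mutant {venn.sizes['b_total']}, "
      f"shared {venn.sizes['shared']}")

universe = {f"g{i}" for i in range(20)}
r = fisher_enrichment({f"g{i}" for i in range(5)},
                      {f"g{i}" for i in range(1, 9)}, universe)
print(f"overlap {r.n_overlap}, expected {r.expected_overlap:.1f}, "
      f"log2 enrichment {r.log2_enrichment:.2f}, p = {r.p_value:.3f}")
```

```
targets: WT 497, mutant 499, shared 496
overlap 4, expected 2.0, log2 enrichment 1.00, p = 0.109
```

Here 497 of the 500 planted targets are called in each condition and
the Fisher cell reports a 2-fold overlap excess (log₂ = 1) that is not
significant in a 20-gene universe.

A full demo pipeline runs from a YAML config:

```sh
granulekit run config.yaml --outdir out/
```

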