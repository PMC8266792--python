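# clscreen

Quantification of pooled-overexpression **chronological lifespan (CLS)**
screens in budding yeast.

In such a screen, thousands of strains — a common host carrying single
galactose-inducible ORF plasmids — starve together in one flask. The pool is
sampled weekly, viable cells are recovered on plates, and the cloned ORFs are
PCR-amplified and sequenced, yielding per-strain read counts for every
(environment, replicate flask, timepoint) sample. A strain that outlives the
pool average rises in frequency among alive cells; the trend of its frequency
over starvation time is its *relative CLS*. `clscreen` turns those counts into
slopes, strain classes, overlap statistics and ranked enrichment results, and
ships a fully parameterized simulator of the whole design so every stage can
be exercised with known ground truth.

## The model

For strain *i* in environment *e* (H = water, G = water + galactose),
replicate *r* and day *t*, the read count gives a frequency
*p* = count / sample total, which is variance-stabilized with the angular
transform (in degrees):

    θ = (180/π) · arcsin(√p),     θ(0) = 0°, θ(0.5) = 45°, θ(1) = 90°

Each replicate series is summarized by the ordinary-least-squares slope of θ
against *t* (degrees/day). The **average slope** per environment is the mean
of the four replicate slopes; the **combined slope** is the mean of all eight.
Strains whose read total in an environment is below 160 are discarded there
(amplification failure). On the filtered set:

- **L** (long-lived): average slope > 0 in both H and G;
- **S** (short-lived): the *n*_S most negative combined slopes among strains
  negative in both environments;
- **M** (medium): the *n*_M smallest |combined slope| among the rest.

The overlap of the well-amplified H and G sets is compared with the
hypergeometric expectation *n*_H·*n*_G/*N* for independent draws — the
signature of repeatable, strain-intrinsic amplification dropout.

For functional analysis, strains are ranked by slope and each annotation term
is scored with the **minimum hypergeometric (mHG)** statistic: the minimum,
over all list prefixes, of the hypergeometric upper-tail probability of the
member count in that prefix. Its exact p-value (over uniform permutations of
the membership vector) is computed by a lattice dynamic program — no cutoff
has to be chosen in advance.

Companion modules normalize phenotype assays on the L/M/S cohorts (ATP per
cell; ROS as median net fluorescence over mean cell size after
autofluorescence subtraction; propidium-iodide dead fractions; rank-based
pairwise group tests) and measure transcriptome fold-change concordance
between two test strains against a common control (CPM normalization, log₂
fold changes, fourfold/sixteenfold flags, Pearson/Spearman concordance).

## Worked example

```python
import numpy as np
from clscreen import (SimConfig, simulate_screen, call_amplified,
                      compute_frequencies, fit_strain_slopes, classify_strains,
                      overlap_stats, rank_strains, enrich, TermAnnotation)

cfg = SimConfig(n_strains=200, read_depth=20_000, seed=7)
tensor, truth = simulate_screen(cfg)
calls = call_amplified(tensor)                      # 160-read rule
slopes = fit_strain_slopes(compute_frequencies(tensor))
ov = overlap_stats(calls, slopes)
print(f"well-amplified: {ov.nH} in H, {ov.nG} in G of {ov.N}; "
      f"overlap {ov.observed_overlap} (expected {ov.expected_overlap:.2f} "
      f"under independence)")
labels = classify_strains(slopes, calls, n_S=5, n_M=3)
print("labels:", labels.labels.value_counts().to_dict())

ranking = rank_strains(slopes, calls, "H", "best-first")
d = truth.death_rate.mean(axis=1)
slow = set(np.array(truth.strains)[np.argsort(d)[:20]]) & set(ranking)
res = enrich(ranking, TermAnnotation({"slow-dying": slow}))[0]
print(f"mHG for planted term: stat={res.mhg:.3g} at cutoff {res.cutoff} "
      f"(b={res.b_at_cutoff}/{res.B}), exact p={res.pvalue:.3g}")
```

prints

```
well-amplified: 48 in H, 48 in G of 200; overlap 28 (expected 11.52 under independence)
labels: {'unclassified': 11, 'L': 9, 'S': 5, 'M': 3}
mHG for planted term: stat=0.00514 at cutoff 14 (b=4/4), exact p=0.00864
```

Read: at this sequencing depth only 48 of 200 strains amplify well in each
environment, but the same strains fail in both — the observed overlap (28) is
far above the independence expectation (11.52), reproducing the screen's
repeatable-dropout signature. Among dual-passing strains, 9 rise in frequency
in both environments (long-lived), and a term planted on the slowest-dying
strains is recovered at the top of the slope ranking with an exact mHG
p-value of 0.009.

The same pipeline is available from a shell:

```sh
clscreen simulate --config config.yaml --seed 7 --out sim/
clscreen quantify --counts sim/counts.tsv --threshold 160 --out quant/
clscreen enrich --counts sim/counts.tsv --env H --annotation terms.tsv --out enr.tsv
```

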