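# pterodiv

**Diversity dynamics of Late Cretaceous pterosaurs** — a tested Python
pipeline for the standard palaeodiversity workflow: time-calibrate a
cladogram against stratigraphic ranges, build taxic and ghost-inclusive
phylogenetic diversity curves, quantify functional diversity per time bin
in a shared morphospace, test sampling with rarefaction, and audit
published cladogram statistics with a mixed discrete/continuous parsimony
scorer. A synthetic-data generator reproduces the statistical structure of
the study inputs so the whole pipeline runs — and is tested — with no
external data.

## Who this is for

Palaeobiologists asking whether an apparent diversity decline before a
mass extinction is real or a sampling artifact. The motivating case is the
end-Cretaceous: does pterosaur diversity dwindle toward the K-Pg boundary,
or does the record merely thin out (the Signor-Lipps Effect)?

## The methods, briefly

* **Time calibration** (minimal scaling): post-order,
  `age(leaf) = fad`, `age(node) = max(age(child) + min_branch)` with
  `min_branch = 0` for counting (minimum divergence dates) or 1 Ma for
  plotting. Any gap between a divergence and the first fossil on an edge
  is a **ghost lineage**.
* **Diversity curves** in 1-Ma bins (half-open, older edge inclusive):
  taxic = ranges intersecting the bin (range-through); phylogenetic =
  lineage extents (divergence → last appearance), so
  phylogenetic ≥ taxic bin-wise, with equality once no younger relatives
  can imply ghosts.
* **Functional morphospace**: Gower dissimilarity
  `d(i,j) = Σ w δ / Σ w` over mixed categorical/ordered/continuous
  characters with missing data (pairwise deletion, ranges pooled across
  bins), embedded by **PCoA** (`B = −½ J D² J`, negative eigenvalues
  dropped). Disparity per bin = **sum of ranges** (spread) and **product
  of ranges** (volume proxy) over the retained axes.
* **Rarefaction**: subsample each bin without replacement (5,000
  replicates by default) on the full-data ordination scores; report the
  mean and 95% percentile band per level.
* **Parsimony**: exact tree length for unordered (0/1 cost), ordered
  (`|a − b|`), and unit-rescaled continuous characters; ensemble
  `CI = Σm/Σs` and `RI = (Σg − Σs)/(Σg − Σm)`; random-addition + SPR
  search with optional parsimony ratchet, audited against exhaustive
  enumeration.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate a 24-taxon assemblage spanning the Santonian–Maastrichtian, then
run the full pipeline:

```sh
pterodiv simulate --n-taxa 24 --seed 7 --out-dir synth
pterodiv calibrate --tree synth/tree.nwk --occ synth/occ.csv \
    --min-branch 1 --out timetree.nwk --ghosts ghosts.csv
pterodiv diversity --tree synth/tree.nwk --occ synth/occ.csv --out curve.csv
pterodiv morphospace --traits synth/traits.csv --schema synth/schema.yaml \
    --out disparity.csv --scores scores.csv
pterodiv rarefy --traits synth/traits.csv --schema synth/schema.yaml \
    --group Maastrichtian --metric sum --reps 5000 --seed 42 --out raref.csv
```

which logs

```
INFO pterodiv: calibrated 24 leaves; root age 96.213 Ma
INFO pterodiv: wrote 46 ghost segments
INFO pterodiv: wrote 23 bins
INFO pterodiv: ordination: 10 axes; axis 1 carries 30.3% of variance
INFO pterodiv: rarefied 'Maastrichtian' over 8 levels x 5000 reps
```

and writes, in `disparity.csv`, the per-bin disparity in one shared
morphospace:

```
group,n_taxa,axes_used,sum_of_ranges,product_of_ranges
Santonian-Campanian,15,10,3.8545576650261992,1.4194121124921072e-05
Maastrichtian,8,10,3.820593940837318,5.191515910376765e-06
```

Read: despite having half the taxa (8 vs 15) and a bin less than half as
long (6.1 vs 14.2 Ma, so time-averaging favours the older bin), the
simulated Maastrichtian sample spreads across almost the same total range
of function space (3.82 vs 3.85). The rarefaction table shows the sum of
ranges still climbing at the full sample size — sampling is nowhere near
saturation:

```
group,metric,level,mean,lower,upper
Maastrichtian,sum,2,1.5835116686443333,0.9545217062774012,2.1189187056887064
...
Maastrichtian,sum,8,3.820593940837318,3.820593940837318,3.820593940837318
```

(the band collapses at the full group size, where only one subset exists).

The same objects are available as a library:

```python
from pterodiv import (read_newick, read_occurrences, calibrate_tree,
                      gower_distance, pcoa, sum_of_ranges)
```

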