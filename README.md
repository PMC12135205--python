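# pfish

Analysis toolkit for **optical pooled CRISPR screening with imaging spatial
transcriptomics**: CRISPR guide RNAs are amplified in situ and read out like
MERFISH barcodes over sequential rounds of multi-channel fluorescence
imaging, alongside a spatial transcriptome measured in the same cells.
Because every perturbed cell keeps its spatial context, the assay supports
effect readouts that droplet-based Perturb-seq cannot: density-dependent
effects, effects transmitted from a perturbed cell to its unperturbed
contact neighbors, and pairing with live functional imaging (e.g. calcium
responses).

The package covers the complete computational chain, plus a simulator that
generates every input with known ground truth:

| stage | module |
|---|---|
| error-correcting barcode codebooks | `pfish.codebook` |
| bit-image decoding into guide spots | `pfish.decode` |
| segmentation, neighbor graphs, count/design tables | `pfish.cells` |
| perturbation-effect inference | `pfish.effects` |
| calcium phenotyping + guide enrichment | `pfish.calcium` |
| MERFISH gene-panel selection | `pfish.panel` |
| synthetic imaging runs / screens / calcium movies | `pfish.simulate` |

## The core quantities

**Barcodes.** Each guide is a binary codeword of length
`n_rounds × n_channels` with Hamming weight 4 and pairwise Hamming
distance ≥ 4, so any single dropped or spurious bit is correctable
(reads of weight 3, 4 or 5 decode; two-error reads are ambiguous and
discarded). Codewords that light up only in one color, or fully light one
round, are excluded as optical-artifact-prone. *Blank* barcodes — valid
codewords assigned to no guide — calibrate the decoder: with `R` real and
`B` blank barcodes, a decoded table of `n` spots of which `n_b` match
blanks has misidentification rate

```
rate = (n_b / B) / ((n − n_b) / R)
```

**Effects.** The effect of perturbation *p* on gene *g* is a natural-log
fold change,

```
LFC[p, g] = ln( mean expression of g in cells carrying p / mean in control cells )
```

with a pseudocount ε = 0.01 on both means. Significance comes from
permuting the cell → perturbation assignment (10,000 label permutations
shared across genes), a two-sided add-one p-value, Benjamini–Hochberg
adjustment pooled over the whole matrix, and a q < 0.1 call threshold.
Density-stratified effects run this pipeline separately in cells with ≤ 2
contact neighbors ("low density") and ≥ 3 ("high density"), each against
controls of the same stratum; intercellular effects compare control cells
with ≥ 1 neighbor carrying *p* against control cells with no perturbed
neighbor at all.

## Worked example

Generate the production-style codebook (74 guides + 4 blanks over 5
rounds × 3 colors), simulate a noisy field of view, and decode it:

```python
import numpy as np
from pfish.codebook import ColorLayout, generate_codebook
from pfish.simulate import ImagingSimConfig, simulate_imaging_run
from pfish.decode import decode_field, estimate_error_rate

layout = ColorLayout(n_rounds=5, n_channels=3)
cb = generate_codebook(layout, n_targets=74, n_blanks=4, seed=7)

cfg = ImagingSimConfig(shape=(768, 768), n_spots=400,
                       p_dropout=0.05, p_flip=0.04, seed=3)
run = simulate_imaging_run(cb, cfg)
spots = decode_field(run.bit_stacks, run.backgrounds, cb)
```

which prints (via the surrounding report statements):

```
codebook: 78 entries, 74 real guides, 4 blanks
candidates: 400, matched: 330, blank matches: 0
blank-normalized error rate: 0.00%
identity recall vs ground truth: 0.815
```

330 of 400 candidates survive error correction at these per-bit error
rates, none lands on a blank barcode (blank hits are ≲ 0.2 % of decodes
at realistic noise, so a few hundred spots usually show none), and 81.5 %
of planted spots are recovered with the correct identity.

Then simulate a small screen with two planted effects and infer them:

```python
from pfish.simulate import ScreenSimConfig, simulate_screen
from pfish.effects import run_intrinsic

effects = np.zeros((3, 12))
effects[0, 0] = np.log(2)     # pert_01 doubles gene_001
effects[1, 3] = -0.9          # pert_02 knocks gene_004 down
sim = simulate_screen(ScreenSimConfig(
    n_perturbations=3, cells_per_perturbation=150, n_control_cells=300,
    n_genes=12, baseline_mean=10.0, effects=effects, seed=0))
table = run_intrinsic(sim.counts, sim.design, n_perm=10000, seed=1)
print(table.to_long().query("q < 0.1"))
```

```
perturbation     gene     lfc      p      q      mode  n_cells
     pert_01 gene_001  0.7071 0.0001 0.0018 intrinsic      150
     pert_02 gene_004 -1.0373 0.0001 0.0018 intrinsic      150
```

Exactly the two planted effects are called (out of 36 tests), with LFCs
within sampling error of the planted ln 2 = 0.693 and −0.9.

A `pfish` command-line interface wraps the same steps
(`pfish codebook`, `pfish simulate imaging|screen|calcium`, `pfish decode`,
`pfish segment`, `pfish counts`, `pfish effects`, `pfish calcium`,
`pfish panel`); run `pfish --help`.

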