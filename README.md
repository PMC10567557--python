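# peginsert

Toolkit for measuring and predicting **prime-editing insertion
efficiency**. Prime editors write short DNA sequences into a genomic site
using a pegRNA whose 3' extension carries a primer binding site (PBS) and
a reverse-transcriptase template (RTT) encoding the insert plus a homology
arm (HA). How well a given sequence inserts varies over orders of
magnitude and depends on its length, nucleotide composition, secondary
structure, and the cell's mismatch-repair (MMR) status.

`peginsert` is aimed at people who run pooled prime-insertion screens or
design insertion reagents. It provides:

- a canonical **pegRNA data model** (written-strand inserts; the extension
  assembles as `revcomp(insert + HA) + PBS`);
- **structure features**: ViennaRNA MFE folding with length-controlled
  z-scores (MFE standardized against 1,000 random same-length inserts in
  the same context), spacer-pairing counts and scaffold-loop disruption;
- a **screen pipeline**: exact flank-anchored read counting for target and
  pegRNA amplicons, an outcome classifier (library insertion, unedited,
  SNV-only, scaffold integration, mutated insertion, duplication,
  nick-proximal and other deletions), per-position SNV profiling, and the
  efficiency statistic `(target frequency) / (pegRNA frequency)` with
  read filtering, length-bin and z-score normalization;
- the **MMR length-dependence model** `ratio(L) = a·exp(−b·L) + 1` fit to
  knockout/wild-type fold changes;
- a **gradient-boosted predictor** (XGBoost, ten features, grouped
  train/test splits by insert sequence, exact additive attribution);
- **design utilities**: codon-variant enumeration/ranking with a poly-A
  terminator filter, and padding of short inserts to the favourable
  15–21 nt range;
- a **synthetic-screen generator** that encodes the known effect sizes
  (+2.2% per %C, 4.8-fold poly-A penalty, MMR fold change a=25, b=0.58)
  so every stage is testable end to end without external data.

## Worked example

Simulate a 100-insert screen at 500× coverage, run the read pipeline, and
compare recovered efficiencies with the generator's ground truth:

```python
import numpy as np
from peginsert.core import ScreenContext, TargetSite
from peginsert.simulate import GeneratorParams, simulate_library, simulate_screen
from peginsert.screen import (match_target_reads, match_pegrna_reads,
    pegrna_plasmid_flanks, compute_efficiencies)

rng = np.random.default_rng(7)
bases = np.array(list("ACGT"))
site = TargetSite("demo", "".join(rng.choice(bases, 30)), "".join(rng.choice(bases, 70)))
ctx = ScreenContext("demo", "HEK293T-like", mmr_proficient=False)

library = simulate_library(100, seed=1)
params = GeneratorParams(coverage=500, n_background=100)
target_reads, pegrna_reads, truth = simulate_screen(
    library, site, ctx, params, seed=1, emit="reads")

target = match_target_reads(target_reads, site, library)
up, down = pegrna_plasmid_flanks(site)
pegrna = match_pegrna_reads(pegrna_reads, library, up, down)
eff = compute_efficiencies(target, pegrna)

merged = eff.merge(truth, on="insert_id")
r = np.corrcoef(merged["efficiency"], merged["true_efficiency"])[0, 1]
print(f"recovered {len(eff)} efficiencies; Pearson R vs truth = {r:.3f}")
print(merged[["insert_id", "length", "efficiency", "true_efficiency"]].head(3).to_string(index=False))
```

which prints:

```
recovered 96 efficiencies; Pearson R vs truth = 0.966
insert_id  length  efficiency  true_efficiency
 ins00000      12    0.023508         3.035901
 ins00001      30    0.055479         3.922002
 ins00002       6    0.053763         6.056735
```

96 of 100 inserts survive the ≥20-pegRNA-read filter. `efficiency` is the
frequency ratio (target reads over pegRNA reads, both as fractions), while
`true_efficiency` is the generator's percent rate: the ratio recovers the
percent scale divided by 100, and the two correlate at R = 0.96 at this
coverage. Downstream, efficiencies are length-bin-normalized and z-scored
per screen before model training.

The same workflow is available from the shell:

```bash
peginsert simulate --n 500 --coverage 1000 --seed 1 --out sim/
peginsert screen --target-fastq sim/target.fastq --pegrna-fastq sim/pegrna.fastq \
    --library sim/library.tsv --site sim/site.json --out screen/
peginsert efficiencies --counts screen/counts.tsv --library sim/library.tsv --out eff.tsv
```

plus `features`, `train`, `predict`, `mmr-fit`, and `design codons` /
`design pad` subcommands.

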