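# mockrep

Replicate-reproducibility analysis for mock-community COI metabarcoding —
and the multinomial sequencing simulator that generates such datasets.

## The problem

When one amplicon library is sequenced twice, the two runs never return
exactly the same OTU table. How much of that disagreement is *technical*
(index-specific PCR bias among tagged primers) and how much is *random
sampling* (a sequencing run reads only a tiny multinomial draw from the
library)? The distinction decides how to treat rare OTUs: if their
flickering presence–absence is pure sampling noise, removing them cleans up
incidence-based β-diversity without hiding any primer artefact.

`mockrep` implements the analysis used to answer this with a mock community
of 34 equimolar marine invertebrates amplified with 7 indexed COI primer
pairs and sequenced on 2 MiSeq runs (14 replicate communities):

- **tables** (`mockrep.table`) — OTU-by-sample contingency tables (TSV /
  BIOM-JSON 1.0, either orientation) with sample (primer, run) and OTU
  (target flag, taxonomy) metadata;
- **read QC** (`mockrep.readqc`) — paired-read merging (≤5 mismatches, no
  gaps), expected-error ≤ 1 filtering (EE = Σ 10^(−Q/10)), dual-index
  demultiplexing with a tag-jump guard, homopolymer/ambiguity screens, a
  stop-codon screen under the invertebrate mitochondrial code (table 5),
  dereplication, abundance-ranked preclustering (Hamming ≤ 3), singleton
  removal — with a read-conservation ledger;
- **diversity** (`mockrep.diversity`) — Jaccard and Bray–Curtis
  dissimilarities, hypergeometric rarefaction, dataset-wide rare-OTU
  filters and the threshold sweep, detection-frequency and rank-abundance
  summaries;
- **replicate design** (`mockrep.design`) — the four overlapping replicate
  pair classes (within/between primer × within/between run) and Welch's
  *t*;
- **multivariate** (`mockrep.multivariate`) — PERMANOVA (sequential sums of
  squares from the Gower-centred squared-dissimilarity matrix, free label
  permutations, pseudo-*F*, *R*², (c+1)/(m+1) *p*), classical PCoA with
  abundance-weighted OTU scores, UPGMA with deterministic tie-breaking, and
  jackknife branch support from rarefied re-clustering — all computed
  directly from the distance matrix;
- **simulator** (`mockrep.simulate`) — the generative model: equimolar
  target pool × lognormal amplification bias, Zipf rare tail (0.3% of
  reads), one fixed library per indexed primer (θ_{i,p} ∝ a_i·ε_{i,p}),
  and runs as independent multinomial(N, θ) draws from the *same* library —
  so within-primer, between-run variation is random sampling by
  construction. Also emits paired FASTQ (indices + degenerate primers +
  in-frame templates) for end-to-end tests.

## Worked example

```python
import pandas as pd
import mockrep as m

table, truth = m.simulate_table(m.MockModel(seed=1))   # 14 samples x 120 OTUs
rarefied = m.rarefy(table, int(table.sample_totals().min()), seed=2)

design = m.ReplicateDesign.from_table(rarefied)
dm = m.pairwise_distances(rarefied, "bray_curtis")
for s in m.summarize_by_class(dm, design):
    print(s.pair_class.value, round(s.min, 3), round(s.max, 3))

factors = pd.DataFrame({"run": rarefied.sample_meta["run"].astype(str),
                        "primer": rarefied.sample_meta["primer_index"].astype(str)},
                       index=rarefied.sample_meta.index)
print(m.permanova(dm, factors, n_perm=9999, seed=3).to_dataframe().round(4))
```

prints (seed 1):

```
within_primer 0.008 0.015
between_primer 0.053 0.102
within_run 0.053 0.1
between_run 0.008 0.102
   Source  Df     SS  F Model     R2      P
      run   1 0.0001   0.9747 0.0017 0.4482
   primer   6 0.0344  93.9580 0.9878 0.0001
Residuals   6 0.0004      NaN 0.0105    NaN
    Total  13 0.0348      NaN 1.0000    NaN
```

Within-primer Bray–Curtis (two runs of the same library: sampling only)
stays ≤ 0.02 while between-primer pairs reach ~0.10, and the primer factor
explains ~99% of abundance-based variance. Run the same PERMANOVA on
Jaccard and the primer factor collapses to noise level (*R*² ≈ 0.48,
*p* ≈ 0.53): index bias distorts read *counts*, while presence–absence
disagreement is random sampling of the rare tail. The
`examples/` scripts walk through each capability (simulation, replicate
dissimilarity, threshold sweep, PERMANOVA/PCoA, UPGMA + jackknife, FASTQ
QC) and print what the numbers mean.

A thin CLI wraps the same library calls:

```bash
mockrep simulate --seed 1 --out-dir simulated
mockrep report --seed 1 --out-dir report --paper-mode
mockrep qc r1.fastq r2.fastq --out-dir qc_out
mockrep analyze --config run.yaml
```

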