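# retrocall

Junction-amplicon analysis of retrotransposon mobilisation in pluripotent
stem cells: insertion calling, de novo filtering, target-primed reverse
transcription (TPRT) hallmark annotation, detection-sensitivity modelling
and a gene-position permutation test — together with a synthetic-data
generator that plants insertions with known structure so the whole pipeline
is testable offline.

## The problem

Retrotransposon capture sequencing enriches genomic DNA for the 5′ and 3′
junctions of recent LINE-1 (L1), *Alu*, SVA and LTR insertions and sequences
across them. Calling *de novo* insertions in human induced pluripotent stem
cells (hiPSCs) and embryonic stem cells (hESCs) from such libraries raises
four linked questions that this package answers computationally:

1. **Which junction-read pileups are insertions?** Reads are collapsed to
   unique amplicons (distinct alignment start per junction side, family and
   sample), single-linkage clustered, and reported only when a cluster holds
   **≥ 2 unique amplicons separated by ≥ 5 nt** — duplicates never count.
2. **Which calls are de novo in pluripotent cells?** A four-filter cascade:
   not (i) in a known non-reference insertion catalog, (ii) in the parental
   cells, (iii) in an earlier hESC passage, (iv) in multiple cell lines.
3. **Is an insertion a genuine TPRT product?** The annotator reports the
   target site duplication (TSD), the match of the integration site to the
   L1 endonuclease motif 5′-TTTT/AA-3′, the poly-A tail, 5′ truncation,
   twin-priming inversions (with spacer), microcomplementarity, untemplated
   5′ nucleotides, and endonuclease-independent signatures.
4. **What did we miss, and what is the rate?** Bernoulli subsampling of the
   library over a depth grid measures per-family detection as a function of
   variant allele fraction (VAF). With per-family weights *w_f* and
   detection fractions *d_f*, the overall false-negative rate is

   ```
   FN = 1 − Σ_f w_f d_f / Σ_f w_f,          FN(v) = 1 − d(v) · (1 − FN)
   ```

   and the per-line de novo rate is the Horvitz–Thompson-style sum
   Σ_i 1/p̄_i over observed insertions, where p̄_i is insertion *i*'s mean
   normalized detection probability over the VAF grid above a 5% floor;
   the per-cell rate scales this by the mean observed VAF.

A permutation test (positions drawn uniformly over the intragenic genome,
p = k/N on the mean TSS percentile) quantifies the 5′ bias of intragenic
insertions.

## Worked example

```python
from retrocall import sensitivity as sens

model = sens.FNModel(baseline_detection=sens.BASELINE_DETECTION_HIPSC,
                     weights=sens.FAMILY_WEIGHTS_HIPSC)
print(model.summary())
print(f"FN at 50% VAF: {100*model.fn_at(sens.DETECTION_AT_50_HIPSC):.1f}%")
print(f"FN at  5% VAF: {100*model.fn_at(sens.DETECTION_AT_5_HIPSC):.1f}%")
```

prints

```
False-negative model
  baseline FN: 7.9%
  L1: weight 214, baseline detection 88.5%
  Alu: weight 1411, baseline detection 92.8%
  SVA: weight 53, baseline detection 88.3%
  LTR: weight 14, baseline detection 89.8%
FN at 50% VAF: 30.5%
FN at  5% VAF: 94.4%
```

i.e. with the study-reported per-family insertion counts and detection
fractions, 7.9% of germline insertions are missed outright, and a de novo
insertion carried by 50% (5%) of cells is missed 30.5% (94.4%) of the time.

A simulated reprogramming cohort runs through the whole pipeline in a few
seconds:

```python
import pandas as pd
from retrocall.simulate import SimConfig, simulate_cohort
from retrocall.calling import run_caller
from retrocall.denovo import annotate_de_novo

cohort = simulate_cohort(SimConfig(genome_length=500_000, n_genes=0,
                                   seed=13, depth=25, duplicate_rate=0.1))
calls = []
for sample, reads in cohort.reads.items():
    c = run_caller(reads, library=cohort.library)
    c["call_id"] = sample + ":" + c["call_id"]
    calls.append(c)
calls = pd.concat(calls, ignore_index=True)
verdicts = annotate_de_novo(calls, cohort.catalog, cohort.design)
print(f"calls: {len(calls)} across {calls['sample'].nunique()} samples")
print(f"de novo: {int(verdicts['de_novo'].sum())} of {len(verdicts)} "
      "pluripotent-sample calls")
```

prints

```
calls: 103 across 6 samples
de novo: 12 of 87 pluripotent-sample calls
```

and the 12 de novo verdicts coincide exactly with the cohort's planted
pluripotent-private insertions (each line carries its private events in
every passage; the hESC line acquires them in the later passage only).

## Command line

```sh
retrocall run-all --outdir out --seed 7         # demo pipeline end to end
retrocall call --reads out/reads_iPS-A_p30.tsv --window 200 \
    --min-unique 2 --min-sep 5 --catalog out/catalog.bed
retrocall bias --insertions ins.bed --genes out/genes.bed \
    --permutations 1000000 --seed 11
```

Every survey constant (2 unique amplicons, 5 nt separation, 10 samplings
per depth, 5% VAF floor, 10⁶ permutations) is a flag with that default.
Outputs are plain TSV/BED/FASTA/JSON with provenance headers; `run-all`
writes a manifest with per-stage checksums so identical seeds give
identical outputs.

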