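# crcprograms

Single-cell transcriptional program discovery and validation for
patient-derived colorectal cancer (CRC) models.

Patient-derived CRC spheroids contain functionally distinct tumor-cell
subpopulations — stem-like, transit-amplifying (TA)-like, Paneth-like and
terminally differentiated (Tdiff)-like cells — whose expression programs
overlap with cell states such as cell cycle, oxidative phosphorylation
(OXPHOS) and hypoxia/glycolysis. This package implements the complete
analysis chain used to discover and validate such programs from single-cell
RNA-seq of multi-patient spheroid cohorts, and to connect them to patient
outcome and to functional stem-cell assays. It is aimed at computational
biologists who want a tested, scriptable version of this workflow.

## What it computes

**Preprocessing** (`crcprograms.preprocess`). Cells pass QC with
&gt;100,000 reads, &gt;1000 detected genes and &lt;15% mitochondrial reads;
the top 5% of libraries by reads are dropped within each patient.
Expression is

&nbsp;&nbsp;&nbsp;&nbsp;*E*<sub>i,j</sub> = log₂(CPM<sub>i,j</sub>/10 + 1),

genes are kept when the aggregate *Ea* = log₂(mean<sub>cells</sub>(*E*) + 1)
reaches a cutoff (default 3.5), and inter-patient shifts are removed by
per-patient mean-centering, *Er*<sub>i,j</sub> = *E*<sub>i,j</sub> −
mean[*E*<sub>i,1…n</sub>]. Cultures are gated on an LGR5 score (total LGR5
transcripts / cell number, strictly > 1).

**Program inference** (`crcprograms.factorize`, `crcprograms.scoring`).
Non-negative matrix factorization of the clipped centered matrix
(*X* ≈ *W·H*, default *k* = 25, best of 10 seeded restarts) yields gene
loadings and cell scores. Factors whose score distributions are dominated
by single patients are excluded by pairwise histogram-intersection overlap
(< 50% in ≥ 5 patients). Each retained factor becomes a signature of its
top 200 loading genes; cells are scored as the mean expression over
signature genes minus the mean over expression-bin-matched random control
genes; correlated signatures merge into meta-signatures (complete linkage
on 1 − *r*, cut at *r* = 0.6). A program is *active* in a cell when its
corrected score exceeds the cohort mean by more than one SD, and each cell
is assigned the argmax of its active type programs. Cell-state differences
between types are tested by two-tailed Mann–Whitney.

**Bulk validation** (`crcprograms.bulk`). Bulk cohorts are scored by mean
signature expression and stratified into six clusters (cl1–cl6) by five
sequential complete-linkage binary splits on the signatures defining each
cluster; groups are compared by Kaplan–Meier/log-rank and by
likelihood-ratio comparison of nested Cox models.

**Limiting dilution** (`crcprograms.dilution`). Spheroid-forming and
tumor-initiating cell frequencies are estimated from dose/response tables
under the single-hit Poisson model, P(well negative) = exp(−*f·d*), by
maximum likelihood with likelihood-ratio 95% confidence intervals, plus
between-condition likelihood-ratio tests and bulk-normalized ratios.

**Synthetic cohorts** (`crcprograms.simulate`). Seeded generators produce
multi-patient count matrices with planted type/state programs, patient
offsets and negative-binomial noise; bulk cohorts with cluster-dependent
survival; and dilution assays — so the whole chain is testable end to end
without any external data.

## Worked example

```python
import crcprograms as c

sim = c.default_spheroid_config(seed=1)          # 8 patients x 200 cells
pipe = c.synthetic_pipeline_config(seed=1, k=10)
res = c.evaluate_program_recovery(sim, pipe)
print(res["recovery"]["jaccard"].round(3).to_dict())
print("accuracy:", round(res["assignment_accuracy"], 3))
```

prints

```
{'stem': 0.906, 'TA': 0.893, 'Paneth': 0.868, 'Tdiff': 0.932,
 'cell_cycle': 0.775, 'OXPHOS': 0.893, 'hypoxia_glycolysis': 0.972}
accuracy: 0.885
```

— every planted program is recovered by a retained meta-signature
(top-gene Jaccard 0.78–0.97) and 88.5% of cells are re-assigned to their
true type. TA-assigned cells score higher than Tdiff-assigned cells on the
OXPHOS program and lower on hypoxia/glycolysis, reproducing the
proliferative/metabolic split between those compartments.

From the shell, a limiting-dilution table is analyzed with:

```bash
$ crcprograms ldassay estimate --table assay.tsv
frequency 0.00823014 (1/121.5), 95% CI [0.00493695, 0.0129297]
```

i.e. one active (sphere-forming) cell per ~122 seeded cells.

## Layout

- `src/crcprograms/` — `simulate`, `preprocess`, `factorize`, `scoring`,
  `bulk`, `dilution`, `io`, `config`, `pipeline`, `tables`, `cli`
- `docs/methods.md` — model assumptions, parameter choices, limitations
- `tests/` — unit, property and end-to-end tests (pytest)
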