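# iopgenes

Prioritization funnel and differential gene–gene correlation analysis for
intraocular-pressure (IOP)–associated genes.

Genome-wide association studies have linked more than 150 genes to IOP,
the only modifiable risk factor for primary open-angle glaucoma (POAG).
Only a handful can be followed up functionally. This package implements,
as a tested and reusable pipeline, two analyses that triage such a
candidate list:

- **Evidence funnel** (`iopgenes.prioritization`): layered filters over
  tabular evidence — differential expression in glaucomatous trabecular
  meshwork (TM) tissue (|FC| ≥ 1.5) and Schlemm's canal (SC) cells, high
  expression in healthy outflow cells/tissue (FPKM ≥ 10), microarray
  detection above background (DABG ≤ 0.05), SNP location in regulatory
  regions, eQTL support, cyclic-stretch response (|FC| > 2, p < 0.05),
  and scRNA-Seq cluster specificity — combined by non-redundant set
  algebra and a per-gene evidence tally.
- **Differential correlation** (`iopgenes.diffcorr`): for every unordered
  gene pair, within-group Pearson correlations r₁, r₂ are compared with
  the Fisher z test for two independent correlations,

  z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)),

  followed by Benjamini–Hochberg adjustment over all pairs; pairs at
  FDR ≤ 0.1 form a network (`iopgenes.network`) exportable to
  Cytoscape SIF/GraphML, with degree/hub statistics.

Supporting modules: `tables_io` (TSV schemas and packaged transcriptions
of the published evidence tables), `synthetic` (two-group multivariate
normal expression with planted correlation structure, plus randomized
evidence tables with known ground truth), and `assays` (pg/mL ↔ nM
conversion, ΔΔCt relative expression, mean ± SD summaries).

## Worked example

Run the funnel over the packaged evidence tables:

```sh
python analysis/01_prioritize_funnel.py
```

```
funnel counts: {'de_tm': 10, 'de_sc': 17, 'de_sc_up': 8, 'de_sc_down': 9,
 'de_union': 24, 'de_shared': 3, 'high_expr_cells': 15,
 'tm_tissue_confirmed': 4, 'snps_histone': 15, 'snps_enhancer_promoter': 8,
 'snps_with_eqtl': 10, 'stretch_de': 4}
shared TM/SC DE genes: ['ANTXR1', 'LTBP2', 'MAFB']
TM-tissue-confirmed genes: ['ANKH', 'EFEMP1', 'PTPN1', 'TES']
top of evidence tally: [('TES', 6), ('ANKH', 5), ('ANTXR1', 5), ('COL8A2', 5), ('EFEMP1', 5)]
```

Reading: 10 candidate genes are differentially expressed in glaucomatous
TM tissue and 17 in glaucomatous SC cells (8 up, 9 down), 24 non-redundant
genes in total of which 3 appear in both comparisons; 15 of the 24 are
highly expressed in healthy TM/SC cells; 4 are both significantly detected
and highly expressed in TM tissue; all 15 annotated SNPs sit in histone-
modification regions, 8 in enhancer/promoter regions, and 10 SNP/gene
pairs have significant eQTL. The testin gene *TES* passes the most filters
(score 6) and strictly tops the evidence tally.

The simulation-backed differential correlation run (no expression matrix
for the original tissue comparison is publicly available, so study-scale
conditions — 157 focus + 480 background genes, 13 vs 14 samples — are
simulated with planted differentially correlated pairs):

```sh
python analysis/03_diffcorr_simulation.py && python analysis/04_network.py
```

```
tested 202566 pairs over 637 genes
22 significant pairs (FDR <= 0.1) over 44 genes, 32 focus genes
recovered 16/20 planted pairs
44 nodes, 22 edges
```

`analysis/02_estradiol_units.py` checks the aqueous-humor estradiol
table's unit consistency (e.g. 59.70 pg/mL → 0.22 nM at 272.38 g/mol),
and `analysis/05_calibration.py` measures the test's type-I error and
power at the study's group sizes. An end-to-end run is one command:

```sh
iopgenes pipeline --n-genes 40 --seed 5 --out-dir run/
```

See `docs/methods.md` for the model, assumptions, and known limitations.

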