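# toxsar

Fingerprint-based compound grouping and the analysis mathematics of four
in vitro (geno)toxicity assays, built around a nine-member β-nitrostyrene
derivative panel:

- **chem** — compound-table parsing; Crippen LogP, Ertl TPSA, Lipinski
  rule-of-five and Ghose heavy-atom drug-likeness checks.
- **fingerprints** — an independent implementation of the 881-bit
  PubChem/CACTVS substructure-key fingerprint, plus MACCS-166, a
  radius-2 circular (1024-bit) and a linear-path (2048-bit) kind;
  Tanimoto similarity, panel similarity matrices, lead-referenced
  ranking and a SMARTS-rule selection report.
- **cytotox** — LDH percent-cytotoxicity and WST-1 percent-viability
  normalization with technical/biological replicate handling.
- **comet** — per-slide tail-intensity summaries (mean, median,
  responder fraction) and condition-level aggregation; the arithmetic
  mean is the default summary because bimodal TI distributions let the
  median sit on the undamaged mode.
- **mla** — the full OECD TG 490 microwell calculation chain: suspension
  growth, Poisson zero-class cloning efficiencies, RTG, mutation
  frequency with small/large colony split, the Global Evaluation Factor
  (126×10⁻⁶) relevance call and the guideline validity report.
- **foci** — γH2A.X (intensity threshold) and pH3-S10 (intensity +
  area window) nucleus classification with minimum-count flags.
- **stats** — one-way ANOVA with Dunnett many-to-one comparisons;
  adjusted p-values from the multivariate-t reference evaluated by
  seeded Monte-Carlo integration.
- **synth** — seeded generators producing each assay's input tables
  with known ground truth, used by the recovery-style tests.

## CLI

One entry point with one subcommand per module; every run writes CSV
outputs plus a `manifest.json` (version, options, input checksums):

```sh
toxsar descriptors src/toxsar/data/panel.csv --out out/
toxsar similarity  src/toxsar/data/panel.csv --kind pubchem881 --out out/
toxsar panel       src/toxsar/data/panel.csv --ref-id 1 --out out/
toxsar simulate mla --seed 7 --out sim/
toxsar mla sim/mla.csv --vehicle vehicle --out out/
toxsar stats values.csv --control vehicle --out out/
```

`toxsar simulate <plate|comet|mla|foci>` emits tables in exactly the
schema the matching analysis subcommand reads, plus a ground-truth
sidecar JSON.

## Notes

- The PubChem fingerprint ring section uses the SSSR ring set; ring
  choice in bridged polycyclic systems is toolkit-dependent, which can
  shift ring-count bits there (irrelevant for the packaged panel).
- SMILES are used as written — the charged nitro form is not normalized,
  since descriptor fragment classes differ between charged and neutral
  representations.
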