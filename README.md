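# memtarget

In-silico screening of **metastasis-associated membrane proteins** as
immunotherapy targets in solid tumors, modelled on laryngeal squamous cell
carcinoma (LSCC) cohorts with lymph-node (LN) metastasis annotation.

Cell-surface proteins are the most tractable class of immunotherapy
targets, but a good target must satisfy three conditions at once: it must
be abundant in the tumor relative to normal tissue, it must track the
malignant phenotype of interest (here, LN metastasis), and it must be
largely absent from healthy organs so that targeting it spares them.
`memtarget` implements that screen end to end for a cohort with an LN+
(metastatic) and an LN− (non-metastatic) tumor group plus adjacent-normal
samples:

1. **Differential expression** — per-protein pooled-variance two-sample
   *t*-test on log2 abundances (optional empirical-Bayes moderated *t*),
   calling a protein differential at raw *p* < 0.05 and |log2 FC| > 0.585
   (1.5-fold; 1.0 for transcriptome features, i.e. 2-fold).
2. **Membrane filtering** — differential proteins are restricted to those
   annotated to the plasma membrane (GO cellular-component terms collapsed
   into an eight-compartment vocabulary).
3. **Target prioritization** — each candidate *g* receives three components
   scaled to [0, 1]:

   * c_expr(g) = max(log2 FC tumor/normal, 0) / max over candidates,
   * c_sig(g)  = −log10 p(LN+ vs LN−) / max over candidates,
   * c_off(g)  = 1 if the protein is undetected in every healthy tissue,
     else clamp(−log10(max tissue abundance in AU / 10), 0, 1),

   and the final score is the capped Euclidean magnitude

   score(g) = min( sqrt(c_expr² + c_sig² + c_off²), √3 ≈ 1.732 ).

   A perfect target — maximal tumor enrichment, maximal metastasis
   significance, no off-tumor expression — scores exactly √3.
4. **Cohort gates** — Kaplan–Meier curves with the log-rank test and
   univariate Cox proportional-hazards regression (Breslow ties,
   Newton–Raphson with step-halving) establish that LN status carries
   prognostic signal; per-gene 2×2 chi-square tests associate mutation
   status with LN metastasis.

A seeded synthetic-cohort generator (`memtarget.simulate`) produces
proteome + transcriptome matrices, clinical and survival tables, MAF-lite
mutations, compartment annotations and a healthy-tissue abundance profile
with *planted* membrane targets and decoys, so the whole pipeline is
testable without any data download; the generator's truth ledger backs the
recovery and calibration tests.

## Worked example

```python
from memtarget import SimulationConfig, simulate_cohort, TargetScreen

cohort = simulate_cohort(SimulationConfig(seed=7))
results = TargetScreen(
    cohort.proteome, cohort.clinical, cohort.annotation, cohort.offtumor,
    transcriptome=cohort.transcriptome, mutations=cohort.mutations,
).fit()
print(results.summary())
```

prints

```
Membrane-target screen
==========================================================
samples: 24 LN+ tumors, 23 LN- tumors, 20 adjacent normals
features tested: 1000

differential (LN+ vs LN-, proteome): 42 up, 25 down
differential (LN+ vs LN-, transcriptome): 17 up, 0 down
membrane candidates (up): 26

survival gates (LN+ vs LN-):
  PFS log-rank chi2 =  3.347, p = 0.06734; Cox HR =  1.81 (p = 0.07078)
  OS  log-rank chi2 =  0.986, p = 0.32070; Cox HR =  1.45 (p = 0.32343)

mutation association, most significant: GENE0004 (p = 5.081e-06), GENE0003 (p = 0.000396), GENE0002 (p = 0.005741)

top-ranked targets:
 rank feature_id  c_expr  c_sig  c_off  score
    1   MEMT0001   0.735  1.000  1.000  1.594
    2   MEMT0006   0.879  0.772  1.000  1.539
    3   MEMT0015   0.885  0.559  1.000  1.448
    ...
```

Of the 26 membrane candidates, the planted targets (`MEMT…`, silent in
healthy tissue, hence c_off = 1) fill the top ranks, while the decoy
membrane proteins (broad healthy-tissue expression, c_off = 0) fall below
them — exactly the separation the off-tumor component is designed to
enforce.  The survival block shows the LN+ group progressing faster
(hazard ratio ≈ 1.8 for PFS), and the mutation block recovers the genes
simulated with mutation enrichment in the LN− group.

The same screen runs from the shell:

```bash
memtarget simulate --outdir cohort --seed 7
cat > screen.yaml <<EOF
inputs:
  proteome: cohort/proteome.tsv
  clinical: cohort/clinical.csv
  annotation: cohort/annotation.tsv
  offtumor: cohort/offtumor.tsv
EOF
memtarget run --config screen.yaml --outdir run1
```

`run1/` then contains every stage TSV, `ranked_targets.tsv`,
`summary.txt`, the resolved configuration and a manifest with stage row
counts; re-running on the same inputs is byte-identical.

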