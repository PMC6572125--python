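# phosphopipe

Downstream analysis of multiplexed (TMT) quantitative phosphoproteomics for
molecular-subtype studies, modeled on a bladder-carcinoma cell-line panel:
one non-neoplastic control line plus tumor lines classified as *luminal*,
*basal* or *non-type*, labeled in a 10-plex with two technical replicates.
Starting from a phosphopeptide quantitation table (site assignments with
localization probabilities and per-channel reporter intensities), the
pipeline

1. **quantifies** every peptide as within-replicate log2 ratios against the
   control channel, after discarding peptides with any site localization
   probability ≤ 0.75 or any unquantified channel, and calls hyper-/hypo-
   phosphorylation at a 2-fold cutoff;
2. **extracts a differential signature** between the non-type and the
   luminal/basal samples with a pooled-variance two-sample *t*-test
   (signature: raw p ≤ 0.05; BH q reported alongside), and clusters rows
   and columns hierarchically (row z-scores, 1 − Pearson distance, average
   linkage);
3. **scores EMT phenotype** per sample as the difference of the two
   one-sided two-sample Kolmogorov–Smirnov statistics between the
   mesenchymal- and epithelial-gene-set expression ECDFs,
   `score = max(ECDF_Epi − ECDF_Mes) − max(ECDF_Mes − ECDF_Epi) ∈ [−1, +1]`
   (positive = mesenchymal-like);
4. **infers kinase activity** (KSEA) from annotated substrate sites:
   `z = (m̄_s − m̄_p)·√m / δ`, where m̄_s is the mean log2 fold-change of a
   kinase's m matched substrate sites and m̄_p, δ are the mean and SD of all
   site fold-changes; kinases are reportable at p < 0.05 with m ≥ 5;
5. **discovers phosphorylation motifs** around the signature sites
   (±7-residue windows) by greedy iterative fixing of the most binomially
   over-represented residue/position pair (p < 10⁻³; minimum occurrence 20
   for serine-centered, 10 for threonine-centered runs) against a
   whole-proteome background.

A synthetic-data generator (`phosphopipe.synth`) emulates the full study —
planted differential peptides, planted active kinases, a planted sequence
motif and planted epithelial/mesenchymal expression polarity — so every
stage is testable against ground truth without any external download.

## Worked example

```python
import phosphopipe as pp
from phosphopipe.synth import default_gene_set_pair, simulate_expression, STUDY_POLARITY

design = pp.study_design()                       # 7 samples x 2 replicates
proteome = pp.simulate_proteome(300, (150, 250), seed=7)
expt = pp.simulate_phospho_experiment(design, proteome, 2000, seed=7)

kept = pp.filter_quantified_complete(pp.filter_localization(expt.records))
qm = pp.compute_ratios(kept, design)
print(f"{len(kept)} of {len(expt.records)} peptides survive the filters")

res = pp.differential_test(qm, design)
print(f"signature: {int(res.in_signature.sum())} peptides (p <= 0.05)")

fcs = pp.site_fold_changes(qm, kept, design)
kres = pp.ksea(fcs, expt.kinase_substrates)
print(kres.head(4)[["kinase", "m", "z", "p", "reportable"]].to_string(index=False))

sets = default_gene_set_pair()
expr = simulate_expression(design.samples, sets, STUDY_POLARITY, seed=7)
for r in pp.emt_score_all(expr, sets)[:3]:
    print(f"{r.sample:10s} EMT score {r.score:+.2f} ({r.label})")
```

prints

```
1774 of 2000 peptides survive the filters
signature: 298 peptides (p <= 0.05)
 kinase  m        z            p  reportable
KINA003 10 8.494269 1.991819e-17        True
KINA002 10 7.950770 1.853559e-15        True
KINA001  8 7.137753 9.486920e-13        True
KINN008  8 0.522788 6.011220e-01       False
UMUC3      EMT score +0.87 (mesenchymal-like)
J82        EMT score +0.67 (mesenchymal-like)
T24        EMT score +0.53 (mesenchymal-like)
```

The 226 dropped peptides are those with a localization probability ≤ 0.75
or a missing channel; the signature holds the ~200 planted differential
peptides plus the expected ~5% false positives; the three planted kinases
(`KINA*`) dominate the z ranking while the null kinases (`KINN*`) sit near
z = 0; and the three non-type lines score mesenchymal-like, as planted.

## Command line

```bash
phosphopipe simulate --config config.yaml --datadir data/   # synthetic dataset + truth.json
phosphopipe run-all  --config config.yaml                   # quant -> differential -> emt -> ksea -> motifs
phosphopipe quantify / differential / emt / ksea / motifs   # single stages
```

`run-all` writes the quant matrix, dysregulation calls, site tallies, the
differential table and signature, Newick dendrograms, EMT scores, the KSEA
table, motif reports and a `summary.json` of surviving-row counts; reruns
on unchanged inputs are byte-identical.

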