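# herbfp

Chromatographic fingerprinting, chemometrics and single-marker
quantification (QAMS) for herbal quality evaluation, built around a
synthetic HPLC-ELSD panel generator so every stage is testable offline.

The package reimplements, from their defining formulas, the full quality
evaluation workflow for Allii Macrostemonis Bulbus (AMB): common-peak
fingerprint construction with marker-anchored retention-time correction and
congruence-coefficient similarity; PCA, hierarchical clustering and OPLS-DA
with VIP scores and label-permutation validation; and quantification by
both the external standard method (ESM) and the quantitative analysis of
multi-components by single marker (QAMS) via relative correction factors
(RCFs), including durability and method-validation statistics
(LOD/LOQ/RSD/recovery).  Since no raw chromatograms are deposited anywhere,
a first-class simulator emulates an 18-batch, three-group, 30-constituent
panel with configurable group fold-changes, retention drift and area noise.

## Modules

| module | contents |
| --- | --- |
| `herbfp.synthetic` | `ConstituentSpec`, `Chromatogram`, `PanelConfig`; Gaussian/EMG trace simulation, calibration series, multi-batch panels with ground truth |
| `herbfp.peaks` | peak detection (Savitzky–Golay + morphological baseline), noise estimation, LOD/LOQ at S/N 3 and 10 |
| `herbfp.fingerprint` | piecewise-linear retention correction, greedy common-peak matching (±0.1 min window), averaged reference fingerprint, cosine similarity |
| `herbfp.chemometrics` | scaling, SVD PCA with 7-fold Q², Ward HCA with silhouette-selected k, OPLS-DA, VIP, permutation test |
| `herbfp.quant` | calibration fitting, ESM, RCF = (A_s/C_s)/(A_i/C_i), relative-retention-time peak localization, QAMS, RD, durability study, RSD/recovery |
| `herbfp.workflow` | config-driven pipeline, report tables, run manifest, CLI |
| `herbfp.defaults` | built-in calibration lines, expected relative retention times, and the published 18-batch ESM/QAMS determination table |

## CLI

```bash
herbfp simulate --seed 1 --outdir out/panel          # synthetic chromatograms + manifest
herbfp run --seed 1 --outdir out/run                 # full pipeline report bundle
herbfp run --config config.yaml --outdir out/run     # or from a YAML config
herbfp chemo --from-dir out/run --seed 1             # re-run chemometrics from cached tables
herbfp qams  --from-dir out/run --seed 1             # re-run QAMS from cached tables
```

Exit code 2 signals a validation error (bad config/inputs).  The report
bundle contains the similarity, validation, RCF/durability and ESM/QAMS/RD
tables, PCA/OPLS-DA scores, VIP values, the permutation record, a Newick
dendrogram, and a `manifest.json` from which every table is recomputable.
The global `--seed` is expanded into per-stage seeds by fixed offsets
(panel +0, calibration +101, permutations +202, durability +303) so stages
can be rerun independently yet reproducibly.  Figures are optional
(`make_figures: true` in the config; headless-safe).

## Conventions worth knowing

- ELSD response is linear (`area = slope·C + intercept`, floored at 0) to
  match the published calibration fits; a classical power-law mode exists
  but is off by default.
- The printed RCF formula in the source literature is dimensionally
  inconsistent; the standard form `(A_s·C_i)/(A_i·C_s)` is implemented and
  reproduces the published factors within 2–3 %.
- S/N is baseline-corrected height over noise SD; LOQ/LOD = 10/3 exactly.
- OPLS-DA uses one predictive component, 7-fold round-robin CV, and VIP
  satisfying `mean(VIP²) = 1`.
- Contents are reported in µg/g with 2.00 g sample mass and 2 mL extract
  volume, so concentration and content coincide numerically.
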