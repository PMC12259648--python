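# ablineage

Antibody lineage analysis for a Phl p 5-specific human antibody clonotype:
IMGT numbering and germline-allele comparison, unmutated-common-ancestor
(UCA) inference from V(D)J junction analysis, reversion-variant and
site-directed-mutagenesis primer design, and quantitative biophysics —
1:1 Langmuir SPR kinetics, nanoDSF-style melting temperatures, Taylor
dispersion hydrodynamic radii, and exact Mann–Whitney group comparison.

## The problem

Antibody 212579 is a human IgG1 that binds the major timothy grass pollen
allergen Phl p 5 with sub-nanomolar affinity, despite carrying only six
amino-acid substitutions (three per chain) relative to the unmutated state
of its germline genes (IGHV3-48\*03 / IGHD3-10\*01 or IGHD3-16\*02 /
IGHJ6\*02; IGKV3-20\*01 / IGKJ5\*01). Dissecting how much of its affinity,
thermostability and hydrodynamic behaviour is germline-encoded requires:

1. reconstructing the lineage's UCA — aligning the rearranged genes to
   germline V/(D)/J alleles, labelling every junction base as templated or
   non-templated (N), reverting templated positions to germline and, by
   the standard UCA assumption, leaving non-templated bases untouched;
2. enumerating the reversion/allele-swap variant panel and the overlapping
   complementary mutagenesis primers that build it; and
3. fitting the characterization data: sensorgrams to the 1:1 Langmuir
   model (KD = kd/ka), melt curves to a first-derivative Tm, taylorgrams
   to a Gaussian dispersion profile
   (D = r_c² t_R / 24σ², R_h = k_B T / 6πηD), with an exact Mann–Whitney
   U test for the residue-40 hydrodynamic-radius comparison.

Every input the pipeline consumes can be generated synthetically with a
fixed seed (germline fixture sets, V(D)J rearrangements with trimming,
N-additions and somatic hypermutation, instrument traces matching the
study designs), so all stages are testable without downloads. The package
also ships the published measurement tables of the 212579 panel so that
derived quantities (KD arithmetic, fold changes, Tm shifts, group
statistics) are recomputed rather than quoted.

## Worked example

```python
from ablineage.report import build_report

rep = build_report()          # published panel tables by default
kin = rep["kinetics"]
print(kin.loc[["212579", "UCA", "E38_H_S"],
              ["ka_1e5", "kd_1e-4", "KD_nM", "KD_from_rates_nM",
               "KD_fold_vs_parental"]])
```

```
         ka_1e5  kd_1e-4  KD_nM  KD_from_rates_nM  KD_fold_vs_parental
variant
212579      4.4      1.4   0.32             0.318                    1
UCA         0.6      5.1    8.5               8.5                   27
E38_H_S     2.8     27.3    9.9              9.75                   31
```

The UCA binds 27-fold weaker than the matured antibody but is still in the
low-nM range; swapping the allele-unique E38 of the heavy chain to the
serine found in the other IGHV3-48 alleles costs ~20-fold in dissociation
rate (`kd_fold_vs_parental` = 20 for the E38_H_S row). The
`KD_from_rates_nM` column recomputes kd/ka for every row and flags entries
whose printed KD is internally inconsistent.

```python
c = rep["rh25_residue40_comparison"]
print(c["n40_mean_sd_nm"], c["t40_mean_sd_nm"],
      c["mann_whitney_U"], round(c["exact_two_sided_p"], 4))
```

```
(6.16, 0.13) (6.46, 0.15) 33.0 0.0101
```

Variants retaining the germline asparagine at heavy position 40 are more
compact (6.16 ± 0.13 nm at 25 °C) than those carrying the somatic T40
(6.46 ± 0.15 nm); the exact two-sided Mann–Whitney p over all 792
labelings is 8/792 ≈ 0.0101.

A command-line interface wraps the same stages:

```bash
ablineage simulate --seed 1 --out scenario/
ablineage infer-uca --germline scenario/germline.fasta \
    --input scenario/rearrangements.fasta --out scenario/uca/
ablineage fit-spr  --input scenario/instruments/sensorgrams.csv --out spr.json
ablineage fit-dsf  --input scenario/instruments/melt_curves.csv --out tm.json
ablineage report   --out report.json
```

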