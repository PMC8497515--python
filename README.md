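# codigest

Decision support for anaerobic co-digestion of animal manures: theoretical
biomethane potential (BMP) from ultimate analysis, PICRUSt-style functional
prediction from 16S feature tables, class-discriminative pathway screening,
and a rule-based co-digestion advisor — with a synthetic-data module so the
whole pipeline is testable without external downloads.

## Who this is for

Biogas process engineers and microbiome researchers who want to combine the
two standard lines of evidence for choosing co-digestion substrates:

1. **Substrate chemistry.** From total solids (TS), volatile solids (VS) and
   the elemental composition (C, H, N, S, O of dry matter), three classical
   models predict the methane yield per gram of volatile solids:

   * Buswell–Boyle stoichiometry: the empirical formula C_aH_bO_cN_dS_e is
     digested as
     `C_aH_bO_cN_dS_e + w H2O -> m CH4 + c CO2 + d NH3 + e H2S` with
     `m = a/2 + b/8 - c/4 - 3d/8 - e/4`, and
     `BMP_B = 22,400 mL/mol x m per g TS / (VS/TS)`;
   * COD equivalence (Forgacs): `BMP_F = 350 mL CH4 per g O2 x ThOD`, with
     the theoretical oxygen demand
     `ThOD = 32 (C/12 + H/4 - O/32 - 3N/56) / (VS/TS)` g O2/g VS;
   * Calorific (Dulong): `HHV = 337 C% + 1419 (H% - O%/8) + 93 S% + 23.26 N%`
     kJ/kg, and `BMP_D = HHV / 37.78 MJ m^-3`.

2. **Community function.** A 16S OTU table is corrected for 16S copy number,
   multiplied through a per-genome KO copy-count reference
   (`M[s,k] = sum_o abundance[s,o] x copies[o,k]`), aggregated to KEGG
   pathway levels, and screened for class-discriminative pathways with a
   tie-corrected Kruskal–Wallis test (exact permutation p-values for designs
   up to 12 samples) plus a deterministic effect score
   (log10 of the largest pairwise class-mean difference on the per-million
   scale; significant when p < 0.05 and score >= 2.0). Pairwise class
   contrasts use Welch's unequal-variance t-test on mean percentage
   proportions with 95% confidence intervals, the statistic behind extended
   error-bar plots.

The advisor merges both: substrates are ranked by BMP, significant
pathway enrichments relevant to anaerobic digestion (hydrolysis,
acidogenesis/acetogenesis, growth support) are tallied per substrate from a
packaged, editable annotation, and emphasis weights
`w_i ∝ BMP_i (1 + tally_i / max(1, Σ tally))` are reported together with the
additive mixture BMP and pathogen alerts from a genus-role table.

## Worked example

```python
from codigest import characterize, reference_ultimate_analyses

for name, ua in reference_ultimate_analyses().items():
    r = characterize(ua)
    print(f"{name:6s} ThOD={r.thod:.2f} HHV={r.hhv:.1f} "
          f"BMP_F={r.bmp_f:.1f} BMP_B={r.bmp_b:.1f} BMP_D={r.bmp_d:.1f}")
```

```
cow    ThOD=0.41 HHV=4607.4 BMP_F=144.2 BMP_B=143.8 BMP_D=122.0
pig    ThOD=0.63 HHV=6324.9 BMP_F=222.1 BMP_B=221.6 BMP_D=167.4
horse  ThOD=0.72 HHV=7403.5 BMP_F=251.3 BMP_B=250.9 BMP_D=196.0
```

ThOD is in g O2 per g VS, HHV in MJ per tonne TS, and the BMPs in
mL CH4 per g VS; the potentials rise from cow to pig to horse under all
three models. Screening the bundled synthetic microbiome and feeding the
result to the advisor:

```python
from codigest import make_reference_fixture, lefse_screen, flag_ad_relevant, recommend

fx = make_reference_fixture(seed=0)
results = lefse_screen(fx.microbiome)
for r in results:
    if r.significant:
        print(f"{r.feature_id}: effect={r.effect_size:.2f} "
              f"p={r.p_value:.4f} class={r.assigned_class}")

tally = flag_ad_relevant(results)
plan = recommend({n: characterize(ua) for n, ua in fx.substrates.items()},
                 tally.counts)
print(plan.ranking, {k: round(v, 3) for k, v in plan.weights.items()})
```

```
Phosphotransferase system (PTS): effect=4.01 p=0.0036 class=horse
Starch and sucrose metabolism: effect=3.97 p=0.0036 class=horse
Amino acid and nucleotide sugar metabolism: effect=3.89 p=0.0036 class=horse
Fructose and mannose metabolism: effect=3.88 p=0.0036 class=horse
Riboflavin metabolism: effect=3.75 p=0.0107 class=horse
['horse', 'pig', 'cow'] {'cow': 0.166, 'horse': 0.579, 'pig': 0.256}
```

The four pathways planted as horse-enriched in the synthetic community are
recovered with exact-permutation p-values of 6/1680 and effect scores well
above 2; the advisor puts the largest feed emphasis on horse manure, which
has both the highest mono-digestion BMP and the enriched
hydrolysis/acidogenesis pathways.

The same stages are available from the shell:

```bash
codigest simulate --seed 2 --out-dir demo/
codigest characterize --substrates demo/substrates.csv --out demo/bmp.tsv
codigest predict --otu demo/otu.tsv --gene-content demo/gene_content.tsv \
    --hierarchy demo/hierarchy.tsv --level 3 --out demo/pathways.tsv
codigest compare --table demo/pathways.tsv --metadata demo/metadata.tsv \
    --method lefse --out demo/differential.tsv
codigest advise --bmp demo/bmp.tsv --differential demo/differential.tsv \
    --out demo/plan.json
```

or as one pipeline run with a manifest of input/output hashes:
`codigest run --config run.yaml`.

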