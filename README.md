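# hybridzone

Geographic cline analysis of mito-nuclear discordance across a
secondary-contact zone, built as a tested, reusable pipeline over synthetic
data with known truth.

## The problem

When two long-diverged lineages meet again, hybrid zones form, and markers
with different inheritance modes can introgress at different rates. In
female-heterogametic taxa (birds: females ZW), Haldane's rule predicts
reduced fertility of hybrid females — and with it restricted movement of the
maternally inherited mitochondrial genome relative to biparental nuclear
markers. The observable signature is a **narrower mtDNA cline than nuclear
cline** across the contact zone. The motivating system is the contact
between coastal and interior scrub-jay lineages in the western Great Basin:
a 13-population transect, restriction-typed mtDNA haplotypes, 13
microsatellite loci summarised as admixture Q-scores, and a reported mtDNA
cline width of ~131 km against a nuclear width of ~331 km.

This package implements every stage of that analysis and a synthetic-data
generator that plants the same structure, so the whole chain is testable
end to end without any data download:

| stage | module |
|---|---|
| synthetic secondary-contact zones (truth known) | `hybridzone.simulate` |
| in-silico restriction typing (2 bands = coastal, 1 = interior) | `hybridzone.rflp` |
| Hardy–Weinberg / linkage exact tests, locus retention | `hybridzone.qc` |
| Bayesian admixture Q-scores, successive K=2 splitting | `hybridzone.admixture` |
| cline models, MH fitting, AICc selection, 2-LL intervals | `hybridzone.clines` |
| neutral-diffusion time since contact | `hybridzone.dating` |
| PCA + trait-on-ancestry regression | `hybridzone.phenotype` |
| file dialects and the end-to-end pipeline | `hybridzone.io`, `hybridzone.pipeline` |

## The model at the core

Site frequencies `p(x)` along transect position `x` follow a sigmoid cline
with optional exponential tails:

```
f(x)  = 1 / (1 + exp(-4 (x - c) / w))                      (centre c, width w)
left tail, x < c - δL:   f(c - δL) · exp(θL (x - c + δL)),
                         θL = (4 τL / w) / (1 + exp(-4 δL / w))
p(x)  = p_min + (p_max - p_min) · f(x)
```

Fifteen models (five tail configurations × three `p_min`/`p_max` scaling
sets) plus a no-cline null are fitted by Metropolis–Hastings under flat
priors and ranked by AICc; each parameter gets a two-log-likelihood support
interval (all samples within 2 log-units of the maximum), and two datasets'
widths differ significantly when each point estimate falls outside the
other's interval. Cline width then converts to time since contact under
neutral diffusion, `w = 2.51 σ √t`, with sex-appropriate dispersal σ.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic zone (truth: mtDNA width 131 km, nuclear width 331 km, both
centred at 300 km; 13 sites × 20 individuals; divergence 0.8):

```bash
python analysis/01_simulate_zone.py    # genotypes, sites, amplicons, truth
python analysis/02_type_mtdna.py       # digest -> coastal/interior per site
python analysis/03_genotype_qc.py      # HWE scan, Bonferroni, locus retention
python analysis/04_admixture.py        # K=2 Q-scores, per-site means
python analysis/05_fit_clines.py       # model selection, widths, comparison
python analysis/06_date_contact.py     # neutral-diffusion date ranges
python analysis/07_phenotype.py        # trait ~ Q at three spatial extents
```

Output of the cline stage (script 05) on the default zone:

```
mtdna:   preferred model ('fixed_none', 'none'), w = 137 km (2-LL 103-185),
         c = 295 km (2-LL 276-314); null dAICc = 267.0
nuclear: preferred model ('fixed_none', 'none'), w = 259 km (2-LL 206-329),
         c = 305 km (2-LL 280-331); null dAICc = 191.8
mtDNA cline narrower: True
reciprocal 2-LL CI exclusion (significant width difference): True
```

Reading: both markers are decisively clinal (the null model loses by
hundreds of AICc units), the centres agree, and the mtDNA width estimate
(137 km, truth 131) falls below the nuclear interval while the nuclear
estimate (259 km, truth 331 — attenuated by the finite transect) falls above
the mtDNA interval: the planted mito-nuclear discordance is recovered as
significant. Script 06 then converts widths to contact dates, and also
reproduces the published year ranges from the reported widths under the
`paper_match` inversion:

```
reported mtdna width 131 km (paper-match inversion) -> 690-7,600 years
reported nuclear width 331 km (paper-match inversion) -> 12,000-440,000 years
```

Script 07 recovers the phenotype contrast: plumage scores regress strongly
on Q inside the core zone (R² ≈ 0.60–0.65, p < 0.001) while morphometrics
are non-significant.

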