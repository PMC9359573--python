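# culexkdr

Dual-probe RT-qPCR genotyping of the *kdr* L1014F pyrethroid-resistance
mutation in *Culex* mosquitoes, with the population and association
statistics a vector-control surveillance program needs on top of the raw
genotype calls.

## The problem and who this is for

Pyrethroid adulticides are a mainstay of *Culex* (West Nile virus vector)
control. The L1014F substitution in the voltage-gated sodium channel
(*Vgsc*) confers knockdown resistance (*kdr*): genotypes LL (susceptible),
LF, and FF (resistant) segregate in field populations, and their frequencies
tell an abatement district whether spraying will work. A TaqMan allelic-
discrimination RT-qPCR assay reads this SNP from the same RNA extracts
agencies already prepare for arbovirus testing: a FAM-labelled probe matches
the wild-type TTA codon and a HEX-labelled probe the mutant TTT codon, and
the two probes compete on the cDNA template.

This package implements that workflow end to end for analysts at public
health and vector-control agencies: in-silico evaluation of the assay oligos
against *Vgsc* cDNA templates, genotype calling from plate exports,
resistance statistics, trap-site geography, and a seeded synthetic-data
generator so every stage is testable without instrument data.

## The statistics at the core

**Genotyping statistic.** For each specimen

    ΔCT = CT_TTT − CT_TTA

with an absent CT replaced by 40 (the final cycle). Early wild-type probe
(large positive ΔCT) ⇒ LL; the mirror case ⇒ FF; both probes together
(ΔCT ≈ 0) ⇒ LF. Calls come from 1-D k-means with k = 3 (cluster order maps
FF < LF < LL) or from fixed per-species ΔCT decision bands; specimens with
no product by cycle 30 are excluded.

**Resistance-allele frequency** from genotype counts (N_LL, N_LF, N_FF),
N = their sum:

    F(FF,LF) = (2·N_FF + N_LF) / 2N,   SE = sqrt(F(1−F) / 2N)

**Association models.** Genotype ordered LL < LF < FF is regressed on
species / region / land use with the proportional-odds cumulative-logit
model

    logit P(Y ≤ j) = β0j − β₁·Species − β₂·Region − β₃·LandUse

fit by Newton–Raphson; exp(β) is the odds ratio of carrying a more resistant
genotype, with Wald 95% CIs and standard-normal p-values. Genotype-by-
knockdown tables from CDC bottle bioassays are tested with a Fisher exact
test on r×c tables (full enumeration, seeded Monte-Carlo fallback), and
knockdown time courses are summarised by OLS knockdown-vs-time lines,
slope-equality ANCOVA, 45-min resistance ratios, and the CDC 90%-at-120-min
classification.

## Worked example

Allele frequency and species odds ratio from a genotype count table (here
the package's bundled survey counts: 208/226/310 LL/LF/FF for *Cx. pipiens*,
401/57/49 for *Cx. tarsalis*):

```python
>>> from culexkdr import stats, tables
>>> est = stats.allele_frequency(*tables.SPECIES_COUNTS["Cx. pipiens"])
>>> round(est.f, 4), round(est.se, 4), est.n_individuals
(0.5685, 0.0128, 744)
>>> fit = stats.fit_proportional_odds_counts(
...     {k: tables.SPECIES_COUNTS[k] for k in ("Cx. tarsalis", "Cx. pipiens")},
...     reference="Cx. tarsalis")
>>> round(fit.odds_ratios["Cx. pipiens"], 2)
8.99
```

So 56.85% of *Cx. pipiens* chromosomes carry the resistance allele, and that
species has 8.99-fold odds of a more resistant genotype than *Cx. tarsalis*.

In-silico assay evaluation from the shell (bundled synthetic templates embed
the real primer/probe sites with the deposited templates' geometry):

```text
$ kdrcall assay-eval
# using bundled synthetic templates
tarsalis_syn      product=373bp  fwd_mm=0  rev_mm=0  probe_mm TTA=0 TTT=1  genotype=LL
erythrothorax_syn product=373bp  fwd_mm=0  rev_mm=0  probe_mm TTA=0 TTT=1  genotype=LL
pipiens_syn       product=373bp  fwd_mm=0  rev_mm=0  probe_mm TTA=2 TTT=3  genotype=LL
```

The sequencing primer pair produces the expected 373-bp product on every
template; the divergent template carries two probe mismatches but perfect
primer sites, and the 1014 codon reads as wild-type (LL) on all three.

## The analysis

Numbered drivers under `analysis/` run the full study workflow on synthetic
data and write their tables under `results/`:

1. `01_simulate_cohort.py` — 1377-specimen survey cohort + qPCR plate
2. `02_call_genotypes.py` — QC, ΔCT, per-species clustering, accuracy vs truth
3. `03_assay_insilico.py` — oligo evaluation across templates
4. `04_bioassay.py` — knockdown kinetics, resistance ratios, Fisher tests
5. `05_population_stats.py` — allele frequencies and odds ratios, published
   counts and simulated cohort side by side

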