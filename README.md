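# spermlimit

Sperm-limited negative-feedback modeling of *C. elegans* egg laying, with
per-strain parameter estimation and the quantitative-genetic analyses that
go with it: covariate QTL scans of recombinant inbred line (RIL) panels,
drop-one ANOVA epistasis calls, and the model-derived *sign-epistasis zone*.

## The problem

A hermaphrodite makes a fixed pool of self-sperm (a few hundred) before its
germline switches permanently to oogenesis, so lifetime self-fecundity is
sperm-limited. Sperm secrete the hormone MSP, which drives oocyte maturation
and ovulation in a dose-dependent way — a negative feedback: every
fertilization consumes a sperm, lowering MSP and slowing subsequent
ovulation. The macroscale model is

```
E' = k_f · O · S        (fertilized eggs)
O' = k_o − E'           (mature oocytes)
S' = −E'                (remaining sperm)
```

with initial condition (S, O, E)(0) = (S₀, 0, 0), where k_o is the oocyte
generation rate (oocytes·animal⁻¹·h⁻¹), k_f the fertilization rate constant
((sperm·h)⁻¹) and S₀ the self-sperm pool. Two conservation relations follow:
E + S = S₀ and O + E = k_o·t.

The consequence this package is built around: an *age-independent* genetic
difference in k_o produces an *age-dependent* effect on the observable
egg-laying rate. The faster genotype lays more eggs early, exhausts its
sperm sooner, and lays fewer eggs late — the effect size crosses zero once.
Between two loci that both act on k_o, the crossing time of the modifier
locus depends on the focal-locus background, opening a time window (the
sign-epistasis zone) in which the modifier helps in one background and
hurts in the other.

## What's here

| module | contents |
| --- | --- |
| `spermlimit.model` | numeric (Dormand–Prince) and overflow-safe closed-form solutions, egg rate, window eggs, effect sizes, sperm trajectory, mating (sperm top-up) scenario |
| `spermlimit.fitting` | per-strain (k_o, S₀) Levenberg–Marquardt fits from windowed egg counts, shared-k_f panel fits, identifiability diagnostics |
| `spermlimit.panel` | synthetic biparental selfed-RIL panels (Haldane recombination), planted QTL architectures on k_o/S₀, Poisson egg-count assays |
| `spermlimit.qtl` | vectorized marker-regression LOD scans (single / additive / interactive covariate), permutation thresholds, Bayes credible intervals |
| `spermlimit.epistasis` | genotype partitions, drop-one ANOVA with BH FDR control, direction-of-effect epistasis classification, sign-epistasis zone |
| `spermlimit.cli` | `spermlimit simulate|fit|scan|epistasis|report|all --config cfg.yaml` |
| `analysis/` | numbered drivers running the full study-scale analysis |

## Worked example

```sh
python analysis/01_simulate.py --seed 0 --out results/run
python analysis/02_fit.py      --seed 0 --out results/run
python analysis/03_scan.py     --seed 0 --out results/run
python analysis/04_epistasis.py --seed 0 --out results/run
python analysis/05_sign_zone.py --out results/run
```

simulates a 94-strain × 192-marker panel with three planted QTLs (focal
k_o −5.2 on II, modifier k_o −1.0 on X, S₀ +40 on V; Poisson counts from
five 6-hour windows of six animals), then fits, scans and tests it. With
seed 0 the run prints, among other lines:

```
fitted 94 strains (94 converged); k_o range [4.63, 12.72], S_0 range [238, 332]
median recovery error: k_o 3.5%, S_0 3.0%
k_o scan:
  lod_single: threshold 2.93 (1000 perms), significant chromosomes ['II']
  lod_addcov: threshold 2.92 (1000 perms), significant chromosomes ['X']
s_0 scan:
  lod_single: threshold 2.91 (1000 perms), significant chromosomes ['V']
 * cX_m16 @ 45 h: F=20.7 q=7.42e-08 -> negative epistasis (var explained 23.0%)
model sign-epistasis zone: [37.0, 58.9] h post-L4
```

Reading it: the fits recover the planted parameters to a few percent; the
k_o scan finds the focal locus genome-wide significantly on II and — once
the focal genotype is an additive covariate — the small modifier on X; the
S₀ scan finds only the sperm-count locus on V. The modifier is classified
as *negative epistasis* precisely at the 42–48 h time point, which falls
inside the model's predicted sign-epistasis zone of 37–59 h; at earlier and
later windows its effect is additive, pointing the same way in both focal
backgrounds.

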