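# phylodemo

Statistical phylogeography by simulate-and-score hypothesis testing.

`phylodemo` is for population geneticists who want to ask which of
several *a priori* demographic histories best explains the sequence
diversity observed in a structured sample — the classic question for
South American seasonally-dry-forest trees, whose disjunct modern
ranges may be relicts of a widespread glacial distribution. The package
simulates each candidate history under a backward-time structured
coalescent, evolves sequence alignments on the simulated genealogies,
and scores the observed summary statistics against the simulated
distributions.

Four built-in hypotheses describe a 17-deme system traced to a horizon
at the Last Glacial Maximum (21 kyr BP; 1,400 generations at 15
years/generation): **PLAH** (glacial expansion in place across a
connected arc), **PPPH** (glacial range shift into a single source
region), **BOTH** (arc expansion plus shift), and **RETRACTION**
(glacial range contraction). Deme sizes follow N(τ) = N0·e^{gτ} with
g = ln(N1/N0)/t; every lineage outside the source deme migrates into it
with probability 0.01 per generation.

Scoring follows the simulation-calibrated framework: for each scenario,
`n_sim` replicates of pooled-sample haplotype diversity
h = n(1 − Σp²)/(n − 1) and nucleotide diversity π give

* a two-tailed probability P = min(1, 2·#{sim > obs}/n_sim),
* an empirical log-likelihood ln L = ln(bin height at obs / modal bin
  height),
* AIC = −2 ln L + 2K (K = 2), with ΔAIC, normalized Akaike weights,
  and a ΔAIC < 2 plausibility flag.

Also included: Nei diversity statistics and Excoffier AMOVA φST with
permutation tests; Mantel-test isolation by distance on linearized
φ/(1−φ) versus log10 geodesic distance; climate-stability and
range-centroid analyses on suitability rasters; quantile-regression
clines of diversity; and a synthetic-data generator that reproduces the
shape of a 17-population, two-partition (cpDNA 1,742 bp HKY+Γ; ITS
518 bp TIM1+Γ) study so the whole pipeline is testable end to end.

## Worked example

Generate a synthetic study whose true history is PPPH, then ask the
engine to identify it:

```python
from phylodemo import *
from phylodemo.synth import default_template, generate_dataset
from phylodemo.model_selection import PartitionConfig, run_model_comparison

tpl = default_template("PPPH", master_seed=42)
bundle = generate_dataset(tpl)
aln = bundle.alignments["cpDNA"]
h = haplotype_diversity(haplotype_counts(aln))
pi = nucleotide_diversity(aln)
# observed pooled h = 0.886, pi = 0.00368, S = 72

cp = tpl.partitions[0]
part = PartitionConfig(name="cpDNA", model=cp.model, length=cp.length,
                       mu=cp.mu, samples=tpl.sample_config())
scens = [build_hypothesis_scenario(n)
         for n in ("PLAH", "PPPH", "BOTH", "RETRACTION")]
res = run_model_comparison({"cpDNA": {"h": h, "pi": pi}},
                           scens, [part], n_sim=500, master_seed=42)
print(res.table[res.table.statistic == "pi"])
```

```
  scenario     P    lnL    AIC  dAIC  AICw  plausible
      PLAH 1.000   -inf    inf   inf 0.000      False
      PPPH 0.028 -3.651 11.301 4.293 0.105      False
      BOTH 1.000 -1.504  7.008 0.000 0.895       True
RETRACTION 1.000   -inf    inf   inf 0.000      False
```

On π alone this draw sits between PPPH's and BOTH's distributions
(PLAH and RETRACTION simulate π far above the observed value and score
−inf, i.e. zero support). Combining the evidence from both statistics
(summing ln L over h and π) settles it:

```python
res.best_combined("cpDNA")   # -> 'PPPH'
```

A `P` of 1.000 means the observed value sits at or below the simulated
median (the two-tailed formula is capped at 1): failure to reject. The
same workflow is available from the shell:

```sh
phylodemo synth --seed 42 --out data/
phylodemo stats --fasta data/cpDNA.fasta --popmap data/popmap.tsv --seed 1
phylodemo compare --config run.yaml --nsim 2000 --seed 7
phylodemo spatial --phist phist.tsv --coords data/coordinates.tsv \
    --rasters data/suitability_21ka.asc --rasters data/suitability_present.asc
```

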