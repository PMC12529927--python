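# seedless

Tools for analyzing microRNA target sites that act through the guide
**3′ region** — with or without pairing to the seed.

MicroRNAs loaded into Argonaute (AGO) normally recognize targets through
perfect Watson–Crick pairing to the seed (guide nucleotides 2–7, giving the
canonical 6mer/7mer-A1/7mer-m8/8mer site classes). Some miRNAs, however,
bind and repress through *3′-only sites*: ≥10 nt of contiguous
complementarity to the guide 3′ region (nucleotide 9 onwards) with little
or no seed pairing. `seedless` implements the quantitative pipeline for
studying this targeting mode:

- **Site grammar** (`site_grammar`): canonical classes, 3′ registers
  (`mX_Y` = pairing to guide positions X–Y), compound sites with their
  offset (target bridge length minus guide-coordinate distance; a site is
  written `m13_20|+2|m2_7`), and single-best-site read assignment.
- **Relative K<sub>d</sub> from AGO-RBNS** (`rbns_kd`): maximum-likelihood
  inference of per-site dissociation constants relative to the no-site
  background from bind-n-seq enrichment profiles,
  p<sub>ij</sub> = a<sub>i</sub>/(a<sub>i</sub>+κ<sub>j</sub>) with
  multinomial read counts, plus bootstrap CIs and flanking-nucleotide
  stratification.
- **Multiplicative compound-site model** (`compound_model`):
  −log₁₀(K<sub>d</sub>) = A<sub>3′</sub>·B<sub>seed</sub>·C<sub>offset</sub>,
  fit by least squares in log space.
- **Binding kinetics and energetics** (`binding_kinetics`): fractional
  saturation fits θ = [AGO–miR]/([AGO–miR]+K<sub>d</sub>), pseudo-first-order
  association AR(t) = AR<sub>eq</sub>(1−e^(−k·A·t)), k<sub>off</sub> =
  K<sub>d</sub>·k<sub>on</sub>, and ΔG° = RT ln K<sub>d</sub> versus
  nearest-neighbor predictions for the equivalent duplex in solution.
- **Chemical-probing quantification** (`probing_quant`): per-position
  relative reactivity (S−Q)/(N−Q) from gel-lane band intensities.
- **Reporter-assay modelling** (`mpra_model`): the 8,820-variant reporter
  design arithmetic, CPM fold-changes, the occupancy-repression model
  (fold-repression = 1 + b·N with N = a/(a+κ)), and slicing-site detection
  from zero- versus positive-offset variant pairs.
- **3′-UTR survey** (`targetome_survey`): genome-style scans for canonical,
  3′-only, and 3′+microseed sites with chance-rate arithmetic
  (a 10-nt site is 4⁶/4¹⁰ = 1/256 as frequent as a 6-nt site).
- **Expression response** (`expression_response`): leave-one-out log₂
  fold-changes from logTPM matrices, UTR-length-matched control cohorts,
  and one-sided Kolmogorov–Smirnov repression tests.
- **Synthetic data** (`synthetic_data`): seeded generators for every input
  above with serialized ground truth, so each estimator is testable by
  parameter recovery.

## Worked example

```python
import numpy as np
from seedless import (MirnaGuide, assign_site, compute_offset, gen_rbns_pools,
                      RbnsCountTable, fit_relative_kd, FitOptions,
                      fit_saturation, BindingCurve, gen_binding_data)

guide = MirnaGuide("miR-155", "UUAAUGCUAAUCGUGAUAGGGGU")

# classify one target RNA
read = "CCAAGCUAUCACGAUUAGGUAGCAUUAAGCC"
site = assign_site(read, guide)
print(f"read classified as: {site.name} at {site.target_span}")
print("offset of m13_20 + 8-nt bridge + m2_7:", compute_offset(7, 13, 8))

# recover relative Kd values from synthetic bind-n-seq pools
kappa = {"8mer": 0.003, "7mer-m8": 0.02, "6mer": 0.1}
a = [1.0, 0.1, 0.01]                      # free-AGO dilution series
pools, truth = gen_rbns_pools(guide, kappa, a, depth=50_000, seed=7)
table = RbnsCountTable.from_reads(pools, guide, site_list=list(kappa))
fit = fit_relative_kd(table, FitOptions(dilutions=a))
for s in kappa:
    print(f"{s:9s} true {kappa[s]:<6g} fitted {fit.kappa[s]:.4f}")

# fit a noisy saturation binding curve
df, _ = gen_binding_data("saturation", {"kd": 70e-12,
        "concentrations": list(np.geomspace(5e-12, 10e-9, 8))},
        noise_sd=0.03, replicates=3, seed=1)
sat = fit_saturation(BindingCurve.from_frame(df), seed=1)
print(f"Kd = {sat.kd*1e12:.0f} pM "
      f"(95% CI {sat.ci95[0]*1e12:.0f}-{sat.ci95[1]*1e12:.0f} pM)")
```

Output:

```
read classified as: m9_19|+3|m1_8 at (6, 28)
offset of m13_20 + 8-nt bridge + m2_7: 2
8mer      true 0.003  fitted 0.0032
7mer-m8   true 0.02   fitted 0.0203
6mer      true 0.1    fitted 0.0954
Kd = 71 pM (95% CI 68-74 pM)
```

The example read carries a compound site — an 11-nt 3′-complementary
segment (guide positions 9–19) bridged at offset +3 to a full seed match —
and the relative-K<sub>d</sub> fit recovers the simulated affinities of
the canonical classes from 50,000-read pools. The fitted
κ values are dissociation constants relative to the no-site background
(smaller = tighter binding: here the 8mer binds ~300-fold better than
background).

A CLI mirrors the main stages:

```bash
seedless classify --guide guide.fa --reads reads.txt --preset rbns --out sites.tsv
seedless rbns-fit --guide guide.fa --input input.txt --bound b1.txt,b2.txt --out-prefix kd
seedless survey --utrs utrs.fa --guides guides.fa --out-prefix survey
seedless simulate rbns --guide guide.fa --out-prefix sim --seed 7
```

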