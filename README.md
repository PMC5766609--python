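# dopedlib

Computational toolkit for **doped ("soft-randomized") phage-display peptide
library campaigns** aimed at dual-receptor agonists — the use case being
glucagon-backbone peptides selected alternately on glucagon-receptor (GCGR)
and GLP-1-receptor (GLP1R) expressing cells to find balanced co-agonists.
It is written for the computational side of such a campaign: library
designers sizing a doped library, oligo designers choosing trimer codon
blocks, and screeners calling mutations and classifying EC50 tables.

## What it computes

**Library statistics** (`dopedlib.design`). A doped library randomizes
*m* positions of a parent peptide; each keeps the wild-type residue with
probability *p*<sub>wt</sub> and otherwise takes one of *a* alternatives
uniformly. The mutation count per clone is Binomial(*m*, 1 − *p*<sub>wt</sub>),
so for class *k*:

- fraction  f_k = C(m,k) (1−p_wt)^k p_wt^(m−k)
- diversity D_k = C(m,k) a^k  (exact integers)
- Poisson coverage c_k = 1 − exp(−n_k / D_k) with n_k = N f_k expected clones
- unique clones U_k = D_k c_k, average duplication r_k = n_k / U_k

**Oligo design** (`dopedlib.oligo`). Each randomized position is an exact
trimer-codon mixture (wild-type codon at weight *p*<sub>wt</sub>, the 18
non-Cys alternatives sharing the rest). The probability that a random
library member contains an unwanted NcoI (CCATGG) or NotI (GCGGCCGC) site
is computed *exactly* by propagating a state distribution through an
Aho–Corasick automaton over the recognition sequences, and a deterministic
coordinate-descent optimizer swaps synonymous codons (at randomized and
constant positions alike) to minimize it. Primer-extension duplex assembly
and NcoI/NotI digestion checks round out the cloning path.

**Selection simulation** (`dopedlib.simulate`). A seeded generative model:
clones sampled from the doped distribution, latent log10 EC50 pairs
assigned additively per cached (position, residue) mutation effect, and
alternating depletion/capture/wash/amplification rounds against the two
receptors (scheme 1 starts on GCGR, scheme 2 on GLP1R).

**Screen analysis & pharmacology** (`dopedlib.screen`, `dopedlib.pharm`).
Mutation calling against the glucagon backbone (with −2/−1 N-terminal
extension labels), sub-library window assignment, positivity/hit
summaries, GCGR/GLP1R EC50 ratios, potency tiers (≤ 30 pM, ≤ 80 pM on
both receptors), the balanced-co-agonist window (ratio in [0.5, 1.5]),
DPP-IV liability detection, the D-Ser2 + Lys10(γEγEC16) engineering
transformations, and a 4-parameter-logistic dose-response fit.

A transcribed 35-peptide two-receptor activity table and the
engineered-analogue comparison table ship as packaged fixtures
(`dopedlib.io.load_phage_peptides`, `load_engineered_peptides`).

## Worked example

```python
from dopedlib import DopedDesign, GLUCAGON, build_design_table

design = DopedDesign(parent=GLUCAGON,
                     randomized_positions=tuple(range(1, 10)),
                     p_wt=0.45, n_alternatives=18, library_size=60_000_000)
print(build_design_table(design).to_text())
```

```
k       fraction  cumulative  physical_clones  diversity  coverage  unique_clones  avg_duplicates
0 (wt)     0.08%       0.08%         4.54e+04       1.00   100.00%           1.00        45400.84
     1     0.83%       0.91%         4.99e+05     162.00   100.00%         162.00         3082.77
     2     4.07%       4.98%         2.44e+06   1.17e+04   100.00%       1.17e+04          209.32
     3    11.60%      16.58%         6.96e+06   4.90e+05   100.00%       4.90e+05           14.21
     4    21.28%      37.86%         1.28e+07   1.32e+07    61.91%       8.19e+06            1.56
     5    26.00%      63.86%         1.56e+07   2.38e+08     6.34%       1.51e+07            1.03
     6    21.19%      85.05%         1.27e+07   2.86e+09     0.44%       1.27e+07             <<1
     7    11.10%      96.15%         6.66e+06   2.20e+10     0.03%       6.66e+06             <<1
     8     3.39%      99.54%         2.03e+06   9.92e+10     0.00%       2.03e+06             <<1
     9     0.46%     100.00%         2.76e+05   1.98e+11     0.00%       2.76e+05             <<1
  Sum:      100%                     6.00e+07                            4.55e+07
```

Reading: at 6×10⁷ physical clones, classes 0–3 (≈ 17% of clones, every
variant with up to three mutations) are fully covered; the 4-mutation class
is 62% covered; beyond that the theoretical diversity dwarfs the library.
A 6×10⁷-clone library holds ≈ 4.6×10⁷ distinct variants.

Classifying the packaged activity table:

```python
from dopedlib.io import load_phage_peptides
from dopedlib.pharm import summarize_activity

records, _ = load_phage_peptides()
print(summarize_activity(records))
```

```
{'n': 35, 'tiers': {'co-agonist-balanced': 11, 'co-agonist-biased(GCGR)': 10,
 'co-agonist-biased(GLP1R)': 6, 'inactive': 2, 'single-agonist(GCGR)': 5,
 'single-agonist(GLP1R)': 1}, 'both_le_0.03nM': 7, 'both_le_0.08nM': 18,
 'undefined_ratio': 6, 'balanced_gcgr_over_glp1r': 11,
 'balanced_glp1r_over_gcgr': 8}
```

Reading: 18 of the 35 peptides are potent co-agonists (EC50 ≤ 0.080 nM on
both receptors), 7 pass the stricter 0.030 nM cut from the printed means,
11 sit in the balanced window 0.5 ≤ GCGR/GLP1R ≤ 1.5, and 6 rows have an
undefined ratio because one side is censored ("> bound").

The same pipelines are exposed on the command line:

```bash
dopedlib design-stats --config design.yaml
dopedlib design-oligos --sites NcoI,NotI --max-site-prob 0.0013
dopedlib simulate-selection --scheme 1 --rounds 4 --seed 1 --out-prefix run
dopedlib call-mutations --clones clones.fasta
dopedlib classify-activity --table activity.csv
```

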