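# diffcoex

Differential gene-coexpression network analysis for two-group
(disease vs normal) expression studies.

Coexpression networks connect genes whose expression profiles rise and fall
together across samples; contrasting the disease and normal networks exposes
functional links that are impaired or invoked by disease even when no single
gene is differentially expressed. `diffcoex` implements that comparison as a
reusable, tested pipeline, motivated by the apoptosis/autophagy crosstalk
question in chronic myelogenous leukemia (CML): which coexpression links
among the core apoptosis, autophagy, cell-cycle and PI3K/AKT genes exist only
in healthy cells, and which regulators (miRNAs, transcription factors) might
coordinate them.

## The method

For genes *i*, *j* and a sample group *g*, the **coexpression level** is the
absolute Pearson correlation

&nbsp;&nbsp;&nbsp;&nbsp;*C<sub>g</sub>(i, j) = |cor(x<sub>i</sub>, x<sub>j</sub>)|* ∈ [0, 1],

computed over the group's samples only; the absolute value scores strong
inhibitory (negative) relationships as highly as activating ones. With
*C<sub>d</sub>* (disease) and *C<sub>n</sub>* (normal) in hand for all
*G(G−1)/2* pairs, a single **disease-associated threshold** *C\** is chosen
by the two-sample Kolmogorov–Smirnov criterion on the *inverted* empirical
CDFs *F<sub>g</sub>(C) = Prob(C<sub>g</sub> ≥ C)* (inverted because interest
lies in strong coexpression):

&nbsp;&nbsp;&nbsp;&nbsp;*D = max<sub>C</sub> |F<sub>d</sub>(C) − F<sub>n</sub>(C)|*, &nbsp; *C\** = the achieving threshold.

At *C\** every pair dichotomizes into strong (*C ≥ C\**) and weak classes;
an uncorrected Pearson chi-square on the 2×2 strong/weak × disease/normal
table verifies the association. Strong pairs are then partitioned into
**common**, **normal-specific** and **disease-specific** networks, given
edge thicknesses by a linear [1, 6] rescaling of the coexpression levels,
and exported as Pajek `.net` files. Optionally, regulator→target annotation
tables yield **miRNA regulatory signatures** (MRS), **TF regulatory
signatures** (TRS) — a regulator plus the strong pairs whose both genes it
targets, kept when it covers ≥ 4 pairs, merged when signatures share genes —
and their pairwise intersection, the **composite regulatory signature**
(CRS).

A multivariate-normal simulator with planted per-group correlation blocks
generates two-group matrices mirroring the motivating study design (20-gene
panel, 16 disease + 8 normal samples), so the whole pipeline is testable
without any data download.

## Worked example

Library use, statsmodels-style:

```python
from diffcoex import DifferentialCoexpression, make_study_fixture

dataset, planted = make_study_fixture(seed=1)   # 20 genes, 16+8 samples
results = DifferentialCoexpression(dataset).fit()
print(results.summary())
```

Or from the shell:

```sh
diffcoex simulate --seed 1 --out-matrix expr.tsv --out-groups groups.tsv
diffcoex threshold --expression expr.tsv --groups groups.tsv --out-dir thr
```

which prints

```
Differential coexpression threshold
-----------------------------------
optimal threshold C*      : 0.5311
KS deviation D            : 0.8579
KS p-value (asymptotic)   : 3.721e-61
contingency (strong/weak x disease/normal):
  strong      8   171
  weak      182    19
chi-square (1 d.f., uncorrected): 280.6142
chi-square p-value        : 5.517e-63
```

Read: at the KS-optimal threshold *C\** = 0.5311 the two coexpression
distributions deviate by *D* = 0.8579 — 171 of the 190 gene pairs are
strongly coexpressed in the normal group against only 8 in the disease group,
reflecting the simulated design in which most planted links exist only in
the normal samples (the direction the motivating study reported in CML: many
more strong links in healthy cells). The chi-square confirms the strong/weak
dichotomy is group-associated. `diffcoex network ... --out-dir net` then
writes `common.net`, `normal_specific.net` and `disease_specific.net`
(Pajek) plus a full edge list, and

```sh
diffcoex signatures --expression expr.tsv --groups groups.tsv \
    --annotations examples/synthetic_annotations.tsv --out-dir sig
```

enumerates MRS/TRS/CRS signatures over the normal-specific network using the
shipped synthetic annotation fixture. `diffcoex run --config cfg.yaml`
executes everything end-to-end with a run log; reruns are byte-identical.

Real data enter through `read_expression` (tab-delimited gene × sample
matrix + two-column sample→group file; GEO series-matrix comment lines are
skipped) and `select_panel` (probe→gene collapse by `max_mean` or `mean`,
absent panel symbols reported).

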