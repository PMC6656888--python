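# Methods

## Model and procedure

`herbnet` treats a multicomponent drug as a bipartite relation between
its chemical compounds and predicted protein targets, each edge weighted
by an external predictor's confidence score *S* ≥ 0. Gene sets describe
which targets participate in disease-relevant effector processes
(secretion, motility, cytokine signalling and the like). The analysis
assumes:

- prediction scores are comparable across compounds and targets, so one
  global threshold is meaningful (edges are kept iff *S* strictly
  exceeds it; default 40);
- a pathway is relevant to the drug to the extent that its *targeted*
  members attract many distinct compounds (RCN) with strong best scores
  (BS). Members with no interacting compound carry no evidence and are
  excluded from the per-pathway denominator *n* — a target with zero
  compounds has neither a compound count nor a maximal score to
  contribute;
- protein abundance is proportional to summed peptide intensity divided
  by the number of observable (theoretical fully tryptic, 6–30 aa)
  peptides — the iBAQ assumption — and total protein load per sample is
  comparable after dividing by the per-sample iBAQ total.

### Pathway relevance

RCN(P_j) = (Σᵢ C_Tᵢ)/n and BS(P_j) = (Σᵢ max S_Tᵢ)/n over the n targeted
members, each min–max adjusted across the m scored pathways. The two
adjusted columns are combined as

    aggregate = w · adj_RCN + (1 − w) · adj_BS,   w ∈ [0, 1], default 0.5.

The combination rule is genuinely open — no principled weighting exists
without calibration data — so the symmetric mean is the default and *w*
is exposed for sensitivity analysis. Ranks descend by aggregate with
deterministic tie-breaking (raw BS, then raw RCN, then pathway id), so
output files are byte-reproducible.

Degenerate min–max (all pathways equal in a column) maps every value to
0.5: an all-equal column carries no discriminating information and
mid-scale avoids asserting either extreme. With a single pathway both
columns are degenerate and the aggregate is 0.5 by construction.

An optional validation report compares predicted interactions against an
independent high-confidence reference set: precision, recall, and a
one-sided hypergeometric p for the overlap against random draws from a
caller-stated universe of compound–target pairs.

### In-silico digestion and iBAQ

Digestion cleaves after every K or R; with the Keil rule (default on)
the bond before proline is left intact. The rule is a flag because
trypsin specificity is sometimes stated without the proline exception.
Zero missed cleavages; length bounds 6 and 30 inclusive; ambiguity codes
(X, B, Z, U) count toward fragment length and never act as cleavage
sites. Counting is positional: a fragment sequence occurring twice
counts twice. Proteins with count 0 have undefined iBAQ and are excluded
(logged, and reported in the `IBAQTable.excluded` slot).

### Differential statistics

Welch's two-sample t-test per protein on normalised iBAQ, two-sided,
with BH FDR within the contrast; the selection flag defaults to raw
p < 0.05 with BH always reported alongside. The test choice is a
documented default, not a claim about any particular historical analysis;
a one-way ANOVA across all arms is available as an omnibus alternative.
Numerical edge cases: a protein with zero variance and equal means in
both groups gets p = 1 (no evidence of change); zero variance with
unequal means gets the smallest positive double. Fold changes are
log₂(mean_B/mean_A) after replacing zeros with half the smallest nonzero
normalised value in the whole matrix — imputation affects the fold
change only, never the test, keeping log₂FC finite without distorting
inference.

### Candidate discovery

The conjunctive rule — up in model vs control (p < α, log₂FC > 0), down
under the highest dose vs model (p < α, log₂FC < 0), and strictly
decreasing group means along model → low → medium → high — is a
reconstruction of "dose-dependent reduction" as a selection criterion.
Strict monotonicity is scored as Spearman ρ of group mean against dose
rank with ρ = −1 required; a one-sided Jonckheere–Terpstra trend test
(normal approximation, no tie correction — the data are continuous) is
available via `monotone="jt"` for noisier settings where strict ordering
of four noisy means is too brittle. A positive-control drug arm belongs
in the design but not on the ladder.

### Enrichment

One-sided hypergeometric over-representation per gene set with BH across
sets; k/K/N/n are reported so any figure can be recomputed by hand. A
many-to-many target↔accession mapping collapses isoform accessions to
gene-level targets before counting (a gene is selected if any of its
accessions is).

## Synthetic data: what it emulates and what it does not

The generators emulate the *shape* of a herbal-formula study at reduced
scale: 50 compounds / 80 targets / 12 effector pathways (the real
setting has hundreds of compounds and ~561 thresholded targets), and a
proteome of 300 proteins over six arms (control, disease model, three
doses, positive control) with six samples per arm. Reduced sizes keep
the full pipeline under a minute; recovery behaviour at this scale is
qualitative, not a power analysis for the full-scale study.

Planted signals:

- the relevant pathway's member targets each gain 5 extra distinct
  compounds with scores drawn from 60–100 (background: 1 + Poisson(2)
  compounds per target, scores uniform 20–100, so the 40 threshold
  bites);
- candidate proteins follow a disease/dose profile of group multipliers
  1.0 / 2.0 / 1.8 / 1.4 / 1.0 / 1.2 (control, model, low, medium, high,
  positive): doubled in disease, then 0.9×, 0.7×, 0.5× of the model
  level with increasing dose, partial normalisation under the positive
  control;
- baseline abundances are log-normal (log₁₀ mean 6.5, sd 0.6, a
  plausible label-free dynamic range) with multiplicative log-normal
  noise at CV 10%.

Deliberately not modelled: missing values / dropout structure, peptide-
level variation, shared peptides between proteins, intensity-dependent
variance, batch effects, and real amino-acid composition (sequences are
i.i.d. with K+R at ~11%). Passing tests therefore show that the
*computations* are correct and that planted effects of the stated size
are recoverable under well-behaved noise — not that the pipeline is
robust to real-data pathologies.

All generators are pure functions of (parameters, seed); substreams are
derived per generator (`default_rng([stream_tag, seed])`) so the network
and proteome draws are independent and regeneration is bit-identical.

## Pipeline and determinism

`herbnet run` executes the eight stages from one YAML config with
unknown-key rejection, writes every intermediate artifact with a
version/config-hash header comment, and a manifest with per-stage row
counts and wall-clock. The config hash excludes the output directory, so
runs into different locations from the same analysis config are
byte-identical. A failing stage aborts the run (exit code 3 from the
CLI) leaving its partial outputs with a `.partial` suffix.

## Known limitations

- RCN/BS have no null model; ranks are relative, with no significance
  attached (by design — relevance p-values would need a calibrated
  background).
- The hypergeometric validation of predictions requires the caller to
  state the pair universe; precision/recall depend on reference
  completeness.
- Welch on n = 6 per group relies on approximate normality of
  normalised iBAQ; heavy-tailed real data would favour the
  Jonckheere–Terpstra path or rank tests.
- Identifier namespaces are opaque strings end to end; cross-namespace
  joins happen only through the explicit mapping table.
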