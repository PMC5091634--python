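# Methods

## Scope and data model

The package evaluates p53 immunohistochemistry (IHC) as a classifier of
*TP53* mutation status. The unit of analysis is a cohort table: one row per
case with a case identifier, histotype (HGSOC or EC), a *TP53* variant in
HGVS protein or coding notation (or the sentinel `NDM` for no detectable
mutation), and one observed staining column per assay method
(`pattern_m1`–`pattern_m4`, values OE/CA/WT/CY/unscored). Sequencing is
treated as the reference standard; IHC is the index test. Wet-lab concerns —
staining chemistry, tissue-microarray construction, sequencing and variant
calling — are out of scope: the pipeline starts from called variants and
scored patterns.

## Variant parsing and reference coordinates

All positions are 1-based closed intervals on the canonical 393-aa p53
protein (major *TP53* transcript, 1182-nt CDS across coding exons 2–11).
The domain intervals, thresholds and exon boundaries ship as a packaged JSON
fixture; there is no network lookup and no isoform selection. Which
transcript a report's codon numbering follows is an assumption, not an
inference: inputs numbered against another isoform are not re-numbered, by
design.

The protein-level parser accepts the dialects that co-occur in clinical
reports — one- and three-letter amino-acid codes, `X`/`*`/`Ter` for stop,
`p.` prefix optional and case-insensitive, an optional trailing digit on
deletions (`p.I255del1`), frameshifts with or without the shifted stop
(`p.K382fs`, `p.K382Nfs*40`) — and normalises to one-letter codes with `*`
for stop. Parsing is total over this dialect: anything else raises an error
naming the offending token, and codons outside [1, 393] raise a range error.
The coding-level parser maps intronic-offset positions within ±2 nt of an
anchor (the splice window) to `splicing`; the anchor is range-checked against
the CDS but deliberately not validated against the exon table, because
clinical splice notations are not always anchored at the canonical boundary
nucleotide. Exonic coding positions translate to codons as `ceil(pos/3)`;
nucleotide-level ref/alt are not translated to amino acids (no base sequence
is packaged), which is sufficient because classification depends only on
variant kind and codon.

## Classification

Mutation types are `nonsynonymous`, `stopgain`, `indel` (with an
inframe/frameshift qualifier), `splicing`, `synonymous`, `none`. Functional
class is a pure function of type: GOF ← nonsynonymous; LOF ← stopgain, indel
or splicing; NDM ← synonymous or none. A case with several variants is
classified by a fixed disruption priority (stopgain > frameshift > splicing >
in-frame indel > nonsynonymous > synonymous), recording a multi-hit flag —
deterministic and conservative toward LOF. In-frame indels stay LOF even
though they are predicted to stain OE: the class scheme and the staining
prediction are deliberately decoupled, and the "putative GOF" reading of
OE-staining in-frame indels is surfaced only through the predictor's rule
trace, never as a class change.

## Staining prediction rules

For truncating variants the premature termination codon (PTC) drives the
prediction:

| PTC position | product | predicted pattern | confidence |
|---|---|---|---|
| < 213 | degraded by nonsense-mediated decay | CA | high |
| 213–244 | unruled window | CA (majority truncating outcome) | ambiguous |
| ≥ 245 | expressed truncation of PTC−1 aa | CY if length ∈ [292, 306], else WT | low |

Expressed truncations in 292–306 aa lose the nuclear localization signal
(aa 316–325) and accumulate in the cytoplasm; longer NLS-lacking truncations
(lengths 307–315) default to WT because observed data offer no discriminating
rule there. Missense → OE (high); in-frame indel → OE (low); splicing → CA
(low; the majority observed outcome for splice mutations, with the
uncertainty surfaced rather than a refusal to predict); synonymous/none → WT
(high). Epitope retention (DO-7, aa 19–26) is computed and carried in the
product for completeness; for N-terminally intact truncations it is always
true.

**Frameshift stop proxy.** The true shifted stop codon of a frameshift
depends on the downstream nucleotide sequence. The predictor uses the
frameshift start codon as the PTC estimate — a lower bound usually within a
few codons of the true shifted stop — and marks every expressed frameshift
product `low` confidence. This choice trades a small length bias for a fully
self-contained package.

**Ambiguity never convicts.** Discordance triage treats predictions of
`ambiguous` confidence as non-discordant by construction, so the unruled
213–244 window cannot generate spurious review work.

A note on a tension in the source data: the narrative rule "stopgains with WT
staining occur after codon 245" coexists with a contingency table containing
zero stopgain/WT cells (the WT-staining truncations there are indels and
splicing). The predictor follows the table: expressed truncations outside
the CY window predict WT at low confidence, and stopgain monotonicity (an
earlier stop never converts a CA prediction into an expressed pattern) holds
by an exhaustive sweep over codons 1–393.

## Concordance evaluation

Binary mode: predicted *abnormal* iff pattern ∈ {OE, CA, CY}; truth
*deleterious* iff class ≠ NDM. Ternary mode: OE→GOF, CA→LOF, WT→NDM;
cytoplasmic cases are excluded (CY maps to no single class) and tallied.
Unscored cases are excluded from both modes and tallied. Included + excluded
always equals the cohort size.

Sensitivity, specificity and balanced accuracy = (Se+Sp)/2 follow the
standard definitions, one-vs-rest per class in ternary mode; overall accuracy
is the concordant fraction of included cases with an exact (Clopper–Pearson)
95% binomial interval, the convention of the caret-style classification
toolkits this analysis mirrors. A zero denominator yields `None` plus a
warning — degenerate cohorts must be visible, never silently zero.
Comparisons against printed two-decimal values use Python's half-even
rounding. Cohen's κ is the unweighted coefficient computed from the raters'
contingency table, κ = (p₀ − p_e)/(1 − p_e); the scikit-learn implementation
serves as an independent cross-check in the test suite only.

The `ConcordanceModel`/`ConcordanceResults` pair packages these functions in
a statsmodels-style interface: the model holds the classified cohort and the
evaluation settings, `fit()` tabulates and estimates, and the results object
carries the confusion matrix, the metrics with their interval, the exclusion
tally, and a printable `summary()`.

## Discordance and revisions

Discordant cases are those whose observed pattern contradicts their
sequencing class (mode-specific: the binary and ternary discordance lists are
distinct reports, since e.g. a CA-staining GOF case is binary-concordant but
ternary-discordant). CY and unscored cases go to a separate advisory list.
Revisions are external data — records of full-section restains or
re-sequencing — supplied as CSV/JSON, never inferred. Application copies the
cohort, verifies each record's `old_value` against the current state (stale
records and re-application fail loudly; nothing is ever double-applied),
recomputes derived classifications, and emits an audit log. Row count is
conserved by construction.

## Synthetic cohort generator

The generator emulates the study conditions: 171 HGSOC + 80 EC; deleterious
mutation prevalence 169/171 (HGSOC) and 7/80 (EC); class mix given mutation
112:57 (HGSOC) and 5:2 (EC); LOF type split 24:17:17
(indel:stopgain:splicing) with 2/24 of indels in-frame; substitution hotspots
p.R175H/p.Y220C/p.R273H at weights 9/6/5 among 115 substitutions and p.R196X
at 4 among 17 stopgains, the remainder uniform over the DNA-binding domain
(codons 102–292); method-1 staining conditionals P(pattern | mutation type)
taken from the post-revision contingency proportions; and a 2% non-assessable
(unscored) rate, a realistic tissue-microarray core dropout where no exact
figure is stated. Methods 2–4 have no numeric anchor and default to
perturbed copies of method 1 with progressively inflated WT→CA and OE→WT
confusion (5/5, 10/8 and 15/12 percent), qualitatively emulating
weaker-staining assays; these are free parameters. All draws flow from one
integer seed through a single `numpy` generator, so cohorts are byte-identical
under a fixed seed.

The rater-pair generator copies the method-1 patterns and perturbs each label
independently at a given rate, with confusions concentrated between CA and WT
(the patterns observers actually disagree about; OE and CY drift to WT). At a
6% disagreement rate on ~148 scored cases it yields κ ≈ 0.89.

What the generator does **not** emulate: within-case correlation of the four
assays beyond their shared mutation type, allelic fraction and sequencing
depth, antigen-degradation artefacts, and real hotspot fine structure outside
the four named sites. Tests passing on synthetic cohorts therefore validate
the pipeline's bookkeeping and statistics, not the biological accuracy of any
particular assay.

## Packaged fixture

The real per-case study table is not public. The packaged fixture expands
the published post-revision method-1 contingency table (249 assessable
cases) into one synthetic row per cell count, with variant notations chosen
to be mechanistically typical of each cell (NMD-territory truncations in the
CA cells, the recurrent p.R306X in the CY cell, p.I255del in the OE/indel
cell, published hotspots among the missense cases, and one synonymous change
among the 76 NDM-class cases). Histotypes are a synthetic reconstruction —
EC = 5 GOF + 2 LOF + 73 NDM — reproducing the published per-histotype counts
of deleterious EC mutations (7), WT-staining LOF HGSOC (7) and cytoplasmic
HGSOC (4); the published 251-case demographics and the 249-case contingency
table cannot be reconciled row-for-row from printed data alone, so cohort
fractions use the design denominators 171 and 80.

## Problem sizes and numerical choices

Fixture-based computations run on 249 rows in well under a second. The
property suite uses 1,000 random cohorts of 4–60 cases for per-case-loop
oracle equivalence, a ten-fold cohort (2,510 cases) for generator parameter
recovery within two binomial standard errors, and 20 seeds for κ
calibration — sizes chosen to make the statistical checks sharp while the
whole suite stays fast. Probability rows must sum to 1 within 1e−9.
Goodness-of-fit unit checks use a per-type chi-square rather than stacked
per-cell intervals to keep the family-wise false-alarm rate controlled at a
fixed seed.

## Known limitations

* Frameshift product lengths are lower-bound proxies (see above).
* Coding-level substitutions are not translated to amino-acid changes;
  a coding notation for a nonsense substitution (e.g. `c.637C>T`) is
  classified as a generic substitution unless supplied at protein level.
* The predictor models the DO-7-based assay only; method 2–4 differences
  exist solely in the generator's conditionals.
* No RNA-level splice-isoform modelling: splice variants get the majority
  outcome (CA) at low confidence, although neighbouring splice mutations are
  known to produce different patterns.
* Pre-revision per-method performance, the 23-case discordance list and the
  observed κ = 0.88 depend on non-public per-case data and are therefore
  covered by property-based checks, not numeric reproduction.
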