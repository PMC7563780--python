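# Methods

## Scope and data model

The package operates entirely at gene level: a somatic alteration is either
a small variant (SNV/INDEL with a protein change and a trusted driver flag)
or a whole-gene copy-number event (amplification or deletion). No genomic
coordinates, allele fractions or read-level evidence are stored; driver
status is an input annotation, not something the package derives. A cohort
joins three tables — clinical, small variants, CNVs — against a panel
definition (gene universe, target size in Mb, known-tumor-gene subset,
genome size in Mb), with referential integrity enforced at load time.

## Adjusted TMB

Targeted panels are designed to capture known tumor suppressors and
oncogenes, so their variant yield per megabase is biased upward relative to
the genome. The adjusted burden therefore splits a sample's coding variants
into the known-tumor-gene pool, normalised by the genome size, and the
remainder, normalised by the panel target size:

```
TMB = (n_somatic − n_tumorgene) / target_size_Mb + n_tumorgene / genome_size_Mb
```

Both addends are exposed on the per-sample result so the normalisation can
be audited and, if a different reading of the correction is preferred,
swapped in one place. Choices worth knowing:

* `n_somatic` counts **all** coding SNVs/INDELs, synonymous included; CNVs
  never contribute.
* The tumor-gene term counts **variants** in known tumor genes, not genes —
  symmetric with the first term's variant count.
* Defaults: `target_size_mb = 1.3` (typical for a few-hundred-gene panel),
  `genome_size_mb = 3101.79` (GRCh37 total); both configurable per cohort
  directory (`config.yaml`).
* TMB is exact in computation; rounding (2 decimals) happens only at
  presentation.

Consequences used as test invariants: adding a non-tumor-gene variant
raises TMB by exactly `1/target_size_mb` and a tumor-gene variant by exactly
`1/genome_size_mb`; with an empty tumor-gene set the formula reduces to the
naive `n_somatic / target_size_mb`.

## Genomic subtype classification

Driver small variants in BRAF, the RAS family (NRAS, HRAS, KRAS) and NF1
define the classes; everything else is triple wild-type (TWT). Co-mutated
patients are resolved with the fixed precedence **BRAF > RAS > NF1** — the
convention of the large melanoma sequencing programmes — which is also the
unique tie-break under which the reference cohort's class counts
(23 + 21 + 2 + 36 = 82) reconcile with its per-gene mutation counts.
Copy-number events never change the class, and non-driver variants are
ignored. Each label carries its evidence (the qualifying gene/protein-change
pairs); TWT iff the evidence is empty.

## Exact tests

Both cohort statistics are implemented from first principles so they can be
validated against enumeration:

* **Fisher's exact test**: hypergeometric tail for the one-sided
  (over-representation) p; the two-sided p sums all margin-fixed tables no
  more probable than the observed one (the definition R's `fisher.test`
  uses). A relative tolerance of 1e-7 on the probability comparison guards
  against float noise at the boundary. Unit and property tests compare both
  tails against a brute-force enumeration that computes table probabilities
  through the row-margin product formula, and against
  `scipy.stats.fisher_exact`.
* **Mann–Whitney U**: for groups of ≤ 12 each, the exact two-sided p is
  computed from the full permutation distribution of the rank sum over all
  C(n, n1) group assignments, built by dynamic programming over doubled
  (integer) midranks — numerically identical to enumerating every
  labelling, which the tests do at small n. Ties are handled by midranks;
  the permutation distribution of the rank sum is symmetric about
  n1(n+1)/2 even with ties (the midrank multiset is invariant under rank
  reflection), so the two-sided p is P(|T − E| ≥ |t_obs − E|). Larger
  groups fall back to scipy's tie-corrected normal approximation with
  continuity correction.

## Enrichment analysis

One test per (gene, subtype): altered/unaltered within the subtype versus
the rest of the cohort, where "altered" means any driver alteration (small
variant or CNV — subtype-defining lesions span both, e.g. GNAQ mutations
and MYC amplifications in uveal melanoma). The reported `significant` flag
uses the raw one-sided p at alpha (default 0.05); sidedness and the absence
of multiplicity correction mirror how such panels are conventionally
screened, and a two-sided p plus a Benjamini–Hochberg column are emitted so
stricter readings need no recomputation. Output ordering is deterministic:
(group, p, gene).

## Resistance predictor

A rule is `(gene_set, combination_k, require_pretreatment)`: it fires when
at least `combination_k` distinct genes of the set carry a driver
alteration, OR (if enabled) when the patient was pretreated with BRAF/MEK
inhibitors before ICI. `combination_k = 1` is plain union semantics; the
"any combination of changes in EGFR/PTEN/TP53/CDKN2A" variant is
`combination_k = 2`, the reading under which all of its published
performance numbers are arithmetically consistent. Only ICI-treated
patients enter the 2×2 (progressors a, c vs disease-control b, d);
sensitivity a/(a+c), specificity d/(b+d), relative risk
[a/(a+b)] / [c/(c+d)] with an explicit undefined flag when a stratum is
empty or no rule-negative patient progressed. Fisher p is two-sided by
default with the one-sided tail reported alongside. Rates are exact;
presentation rounding is decimal half-up (percentages to 1 decimal, RR to
2).

## Reference cohort

The original patient-level tables were never published, but the reported
counts pin the joint structure tightly enough to reconstruct an 82-patient
cohort on which **every** published count holds simultaneously: subtype
sizes 42/14/9/8/9; 75 ICI-treated splitting 45 PD / 12 SD / 18 PR; driver
counts BRAF 23, NRAS 20 (2 overlapping BRAF), HRAS 1, KRAS 2, NF1 5 (3
overlapping BRAF/NRAS), hence classes 23/21/2/36; MYC amplified in all 8
uveal patients and 12 others; the four predictor tables (19,4,26,26),
(28,6,17,24), (33,10,12,20), (9,0,36,30); per-gene PD vs SD+PR frequencies
for EGFR (6/45 vs 0/30), TP53 (6/45 vs 1/30), PTEN (11/45 vs 3/30); and
BRAF/MEKi pretreatment in 16/18 BRAF-mutant progressors vs 2/4 disease
controls. The overlap arithmetic forces most of the joint structure (e.g.
gene-positive ∩ pretreated progressors = 19 + 16 − 28 = 7); where several
assignments remained admissible — which individual patients carry the
CDKN2A-only alterations, the EGFR/PTEN/TP53 overlap pattern among the 19
gene-positive progressors (two PTEN+EGFR and two PTEN+TP53 doubles), the
placement of flavor CNVs (KIT/PDGFRA/CDK4/RICTOR in acral, CCND2/CHEK2 in
mucosal) — one assignment was chosen and pinned. Passenger variant counts
per subtype were set so the per-subtype adjusted-TMB medians land near the
reported ones; they are deliberately not exact targets. The assignment is
committed as package data; the in-code constructor that produced it is kept
and a test asserts byte-identity, while `verify_fixture` re-checks every
pinned count on load. Any change to a count is a breaking change.

Known internal inconsistencies of the source counts, resolved as follows:
the cohort-level ICI denominator is 75 (45+12+18), not the 76 printed in
one summary table; the full rule's PPV is 28/34 = 82.4% (consistent with
RR 1.99), not the printed 84.4%; the genes-only rule's 4 rule-positive
disease controls are the unique integer consistent with RR 1.65; PTEN's
progressor frequency is 11/45 = 24.4% (printed once as 24.5%).

## Stochastic simulator

`simulate_cohort` draws cohorts of any size with the cohort-level structure
the analysis assumes: subtype from the observed proportions; per-subtype
Bernoulli driver alterations at the reference cohort's frequencies (GNAQ and
GNA11 drawn mutually exclusively in uveal patients); BRAF/MEKi pretreatment
Bernoulli(18/23) given a BRAF driver; ICI treatment Bernoulli(75/82); and
RECIST response from a two-point conditional model,
P(PD | rule-positive) = 28/34 and P(PD | rule-negative) = 17/41 with
non-progressors split SD:PR = 12:18. Burden is realised as data, not as
labels: a per-subtype log-normal TMB draw (median-parameterised, sigma 0.8 —
a spread consistent with the reported IQRs) is converted to a count of
passenger variants on non-tumor panel genes, and passenger CNV counts top up
to a negative-binomial total (dispersion 3) whose mean is solved numerically
so the distribution's median matches the configured per-subtype median
(8/12.5/33/8/16). All draws come from one seeded generator; identical seeds
give byte-identical serialized cohorts.

What the simulator does **not** emulate — and hence what passing recovery
tests do not show about real data: sequence context and signatures, allele
fractions, FFPE artifacts, gene–gene correlation beyond the GNAQ/GNA11
exclusivity, subtype-dependent therapy assignment, and exact reported
IQRs/ranges. Recovery tests run at n = 10,000, where binomial 3-SE bands
are tight enough to catch implementation drift yet wide enough not to flag
sampling noise; TMB medians are checked to 5% (the count grid imposed by a
1.3 Mb panel quantises achievable medians to steps of 1/1.3 ≈ 0.77).

## Numerical and degenerate-input choices

* Enrichment requires ≥ 2 subtypes; a single-subtype cohort is an error,
  an empty comparison group in burden tests is skipped with a warning, an
  empty reference group is an error.
* Burden summaries of single-patient groups report degenerate IQR/range
  (the value itself).
* A rule firing for every patient yields specificity 0 and an explicitly
  flagged undefined relative risk, never a silent NaN.
* Pipeline outputs are byte-deterministic: rows sorted on stable keys,
  JSON with sorted keys, fixed float formatting.

## Problem sizes

The test suite exercises exhaustive Fisher enumeration for all tables with
total ≤ 16 plus a stratified sample up to 30, Mann–Whitney enumeration up
to 6+6 observations against the DP implementation, 100 replicates of the
82-patient simulation for the directional mucosal-CNV check, and one shared
10,000-patient cohort for parameter recovery.
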