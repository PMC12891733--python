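# Methods

`tcrvax` implements the statistical core of an immunomonitoring workflow
for pooled mutant-KRAS (mKRAS) peptide vaccine studies: six vaccine
antigens (KRAS G12V, G12A, G12R, G12C, G12D, G13D), serial IFNγ ELISPOT of
peripheral blood, and bulk TCRβ sequencing of 7-day peptide expansion
cultures. This note records the models, the parameters that matter, the
numerical conventions, and the design choices made where the design was
genuinely open.

## Clonotype identity and repertoire model

A clonotype is the pair (TRBV gene/allele label, CDR3β amino-acid
sequence). Identity is exact string equality after normalization: labels
are upper-cased and the separators `-`/`*` are unified to `.` (so the
Adaptive export `TCRBV28-01*01` equals `TCRBV28.01.01`), but alleles are
never collapsed to gene level — public-clonotype claims in this pipeline
are allele-resolved. CDR3 sequences are whatever string the input
provides (junction or trimmed CDR3; the two are not distinguished);
records containing stop (`*`) or other non-amino-acid characters, and
out-of-frame records when `productive_only=True` (the default), are
excluded before aggregation.

A repertoire is a map clonotype → read count for one subject × condition
(baseline PBMC, vehicle-only culture, irrelevant control peptide culture,
one of six antigen cultures, or tumor tissue). Clonotype frequencies
p_i = count_i / total_reads play the role of species frequencies in the
clonality summary.

## Repertoire clonality

The clonality readout is `1 − H/ln(n)` where `H = −Σ p_i ln p_i` and `n`
is the number of unique clonotypes: 0 for a perfectly even repertoire,
approaching 1 at maximal clonality. Note the naming caveat: "Shannon
equitability" conventionally denotes the evenness `H/ln(n)` itself; this
package implements the *complement* because that is the form used as the
expansion readout in this setting, and the docstring says so. The
statistic is undefined at n = 1 (ln 1 = 0) and raises. When all counts
are exactly equal the function returns exactly 0.0 rather than the
one-ulp float residue of `1 − H/ln n`.

## Expansion calling

For each subject × antigen culture, every clonotype observed in that
culture is tested against a reference culture (clonotypes seen only in
the reference cannot be "expanded" and are not part of the testing
family):

* **OR** — the ratio of raw read counts, condition over reference
  (`+inf` when the clonotype is absent from the reference; no
  pseudocount). This is deliberately a count ratio, not a
  contingency-table odds ratio.
* **p** — one-sided Fisher exact test for frequency enrichment in the
  condition, i.e. the exact hypergeometric upper tail of the 2×2 table
  of (clonotype reads, other reads) × (condition, reference).
* **q** — Benjamini–Yekutieli step-up adjustment, valid under arbitrary
  dependence, with the family defined as all clonotypes tested in that
  one subject × condition (each expansion culture is one
  multiple-testing family).

A clonotype is called expanded when `q ≤ 0.05`, `OR ≥ 5` and its
condition frequency is `≥ 0.1 %`; all thresholds are inclusive and
configurable. The frequency cutoff can be disabled (`apply_freq_cutoff=
False`), the relaxed OR-only mode used when chasing low-frequency CD8
clonotypes. The frequency cutoff is evaluated before baseline filtering,
as a property of the expansion culture itself.

The reference condition is `vehicle_only` by default with
`control_peptide` selectable; reports record which was used. The q
threshold of 0.05 mirrors the global two-sided significance level used
elsewhere in the workflow and is exposed in the configuration.

Downstream classification: calls are unioned per clonotype across
antigens; a clonotype meeting the criteria for ≥ 2 mKRAS peptides is
**cross-reactive**; a clonotype present in the subject's unstimulated
baseline repertoire (count ≥ 1) is flagged and removed from the
mKRAS-specific catalogue (pre-existing clones are unlikely to be
vaccine-induced); a clonotype expanded in ≥ 2 subjects (exact identity)
is **public**. Tumor overlap counts catalogue clonotypes present in a
tumor-tissue repertoire, with a per-antigen breakdown.

## High-similarity (HS) CDR3 matching

Default metric: optimal string alignment (OSA) — unit-cost
substitutions, insertions, deletions and adjacent transpositions; plain
Levenshtein and Hamming are selectable. Input is normalized to upper
case. Two deliberately different rules coexist:

* `hs_matches` (external-cohort screening, default `max_dist=2`)
  compares CDR3 strings only, because external CDR3 calls often lack
  reliable V annotation;
* `hs_public_pairs` (near-identical public pairs, default `max_dist=1`)
  additionally requires the identical TRBV allele.

A length-difference pre-filter (`||a|−|b|| > max_dist`) prunes pairs
without changing results (it is a lower bound of both OSA and
Levenshtein).

## ELISPOT responder cascade

Replicate wells are averaged (mean of 3). Each antigen is normalized to
the control-peptide stimulation at the same timepoint — by default the
difference of SFU (antigen − control); a pseudocounted ratio
`(antigen+1)/(control+1)` is selectable (`scale="fold"`), since the
source descriptions mix both phrasings. The pseudocount (default 1 SFU)
guards empty control wells. Fold-change versus the week-0 baseline is
computed per timepoint and the maximum taken within an inclusive 17-week
window (primary-endpoint convention); `window_weeks=inf` gives the
any-time variant. Per subject, two modes are summarized: the pooled
average over the six antigens (excluded antigens are omitted with a
warning, never imputed) and the response to the subject's tumor KRAS
mutation.

**Responder rule.** A subject is a responder when the pre-to-post change
exceeds `k × SD` where the SD is the standard deviation of baseline
values *across patients* (per mode) and `k = 2.77`. The constant is
`z(0.975)·√2` rounded to two decimals: the difference of two equally
variable measurements has standard deviation √2·σ, so `|Δ| > 2.77σ` is
the two-sided α = 0.05 criterion. The directional responder call
(`Δ > 2.77σ`) therefore has a one-sided null rate of 0.025;
`significant_two_sided` exposes the |Δ| event whose null rate is 0.05.
The comparison is strict (a change of exactly 2.77 SD is not a
response). Per-antigen positivity counts (0–6) use per-antigen baseline
SDs with the same rule.

A caveat the package inherits from the design it implements: the 2.77·SD
criterion is exact for a single pre/post pair. Taking the maximum over
several post-vaccine timepoints scans multiple comparisons and is
anticonservative under the null; the calibration simulations therefore
use a single post-vaccine timepoint, which is the regime in which the
nominal rate is meaningful.

Multiplex cytokine readings flagged out-of-range are clamped to the
standard-curve limits (`OOR<` → lower limit, `OOR>` → upper limit).

## Outcome stratification

Subjects are split at the q-th percentile (default 25th) of an
immune-response score using numpy's linear-interpolation percentile;
ties at the threshold go to the low group (the source convention is
unknown; this one is fixed and documented). Survival is summarized with
the Kaplan–Meier product-limit estimator (median = earliest time with
S(t) ≤ 0.5, "not reached" when S never gets there) and compared with
the two-group log-rank test; both are delegated to `lifelines` behind
this module's interface and cross-checked in the tests against hand
product-limit and observed-minus-expected computations. Cox hazard-ratio
fits are deliberately not wrapped — any survival package fits them
directly.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is
validated. Per subject, a pool of `n_clonotypes = 20 000` clonotypes
(random CDR3s of length 10–18 with `CASS…F` framing, TRBV alleles from a
fixed list) receives background frequencies from a symmetric Dirichlet
with concentration 0.1 — a heavy-tailed background whose largest clones
reach roughly 0.1–1 %, enough to exercise the frequency cutoff without
claiming biological realism. Reads are multinomial at `depth = 100 000`.

All conditions of a subject share one base-frequency vector, so
spike-free condition/reference pairs are exchangeable and the Fisher
cascade can be calibration-tested. Spiked clones (20 per antigen) are
given a target culture frequency drawn uniformly from [0.2 %, 0.4 %] and
a base frequency of target/`spike_fold` (fold 20), so they sit near the
detection thresholds the study prescribes. A fifth of spikes pick up one
or two extra antigens, biased toward the G12C/G12A/G12V set (with G12R
next), mirroring the commonly shared cross-reactivity pattern. A few
clonotypes are planted identically in two subjects with a shared antigen
(public truth). Baseline repertoires omit all spiked clones except a
designated overlap set (drawn from mono-reactive, non-public spikes so
the cross-reactive and public truth survive the baseline filter
unchanged). Tumor repertoires contain the background plus a planted
subset of specific clones at 0.5 % — all other spikes are zeroed there,
making the planted overlap count exactly recoverable. All truth sets are
intersected with the clones actually emitted, so truth is always a
subset of the observable data.

ELISPOT panels draw negative-binomial counts (mean 25 SFU, dispersion 20
→ variance ≈ 56) in triplicate over a week grid; responders receive a
shift of `responder_effect_sd_units = 6` × the theoretical cross-subject
SD of the pooled baseline value on every antigen, scaled by a
peak-and-decay profile (0 at week 0, full effect weeks 8–16, decaying to
10 % by week 52). The pooled baseline SD accounts for the control well
being shared across the six antigens: Var = Var_NB/n_rep · (1/6 + 1).
Survival data are exponential event times with independent exponential
censoring.

Every generator is a pure function of (configuration, seed) via
`numpy.random.default_rng` seed sequences; identical seeds reproduce
outputs byte-for-byte.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: V(D)J recombination statistics and germline
CDR3 sharing, HLA-dependent antigen responses, culture-to-culture
variability of expansion efficiency, PCR/template sampling bias, or
clonotype frequencies correlated between subjects. Recovery results on
this generator demonstrate that the statistical cascade is implemented
correctly and is well-calibrated, not that real cultures reach these
effect sizes.

## Numerical conventions

* Fisher p-values are exact hypergeometric tails (scipy); the test suite
  verifies them against exact integer-arithmetic enumeration for all
  2×2 tables with depths ≤ 50 (max |Δ| < 1e−12).
* BY adjustment delegates to statsmodels and is verified against the
  direct step-up formula.
* Report tables are deterministically ordered (descending count, then
  (CDR3, V) ties; sorted subjects) and floats serialized at 12
  significant digits, making whole report directories byte-reproducible.
* Degenerate inputs raise rather than guess: single-clonotype
  repertoires (clonality undefined), both-zero count pairs (OR
  undefined), zero baseline SD (degenerate threshold), empty specific
  sets (undefined overlap fraction), empty survival groups.

## Validation problem sizes

The packaged checks run at these sizes, chosen to make every result
statistically meaningful at desk scale: truth recovery on 10 cohorts of
12 subjects × 20 000 clonotypes at depth 10⁵; null calibration on 2 000
simulated subjects (ELISPOT) and ~20 000 null clonotype tests
(expansion); oracle sweeps over 1.75 million Fisher tables, 200 random
p-vectors and 10 000 random CDR3 pairs; and a byte-exact regression of
the 3-subject toy study against frozen reports.

## Known limitations

* The expansion OR is a plain count ratio and is reported as `+inf` for
  reference-absent clonotypes; rank-based summaries of OR should handle
  the infinity explicitly.
* Whether "2 amino-acid differences" in HS matching should count indels
  and transpositions like substitutions is convention; OSA (the default
  of the commonly used string-distance tooling) is assumed, and the
  metric is configurable.
* The responder rule presumes approximately normal, equally variable
  pre/post measurements; with heavy-tailed SFU distributions the
  empirical two-sided rate can drift from 0.05 (the negative-binomial
  simulations stay within binomial tolerance).
* Baseline filtering removes genuinely vaccine-boosted clones that
  pre-existed at baseline; the generator reproduces this by design, and
  truth accounting excludes baseline-present clones from the expected
  specific catalogue.
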