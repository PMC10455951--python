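# Methods

This note records the models, conventions and open design choices behind
`hlatarget`, in the spirit of a statistical-methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and data model

The package consumes the *tables* a search engine, binding predictor and
topology predictor emit — it does not search spectra, predict binding
affinity from sequence (beyond a transparent PSSM surrogate for testing),
or predict membrane topology. Retention time is minutes everywhere;
modifications are `pos|Name` pairs (1-based); decoy status falls back to a
`DECOY_` accession prefix when tables carry no explicit flag; canonical
tab-separated dialects are defined per format, with foreign column names
mapped in via a `dialect` argument.

## Target-decoy q-values

Proprietary search-engine FDR machinery (e.g. fused decoy searches) is
unpublished, so the ladder uses the standard estimator: at threshold t,
FDR(t) = #decoys(score ≥ t) / max(1, #targets(score ≥ t)); the q-value of
a PSM is the minimum FDR over thresholds that would accept it. Ties share
the FDR of the full tie group; q is non-increasing in score, invariant to
monotone score transforms, and clipped to 1. The 5% cutoff applies at PSM
level by default (peptide-level aggregation is a caller decision); the
paper-style ladder order is FDR → decoy → RT-calibrant → blank → modified
→ length 8–12 → deduplicate. The retained *set* is order-invariant (each
step is a row predicate); only per-step counts depend on order, and they
always sum to the input size.

## Motif analysis

Motifs are summarised as position frequency matrices with optional
pseudocount smoothing, `(count + c) / (n + 20c)`. Repertoire-vs-reference
comparison reports the percentage-point difference per (position, residue)
cell and a two-sided exact binomial test of the observed count against the
reference frequency, Bonferroni-corrected across all L×20 cells (the
logo-difference tool used in the field does not publish its exact internal
statistics; the binomial formulation is a transparent equivalent, with
configurable alpha). A cell is called an anchor when it is both
significant and enriched; depleted cells at anchor positions are
significant but not enriched, which is how the planted-motif recovery
check can demand *exactly* the planted cells.

Rank binning: SB for percent rank ≤ 0.5, WB for 0.5 < rank ≤ 2.0, NB
otherwise. The two published threshold phrasings overlap at 0.5; the
boundary goes to SB, matching the predictor convention that "strong"
means rank ≤ 0.5. Restriction of pan-class-I peptides takes the allele
with the minimum rank over the genotype (ties broken lexicographically,
making the call order-invariant), accepting both SB and WB by default;
an SB-only mode is a flag, since published workflows differ on this.

## Fragment masses and spectral validation

b/y ions are computed from a 20-entry monoisotopic residue-mass table
(proton 1.00727646688 Da, water 18.0105646863 Da); a peptide of length L
has exactly 2(L−1) singly charged fragments, with charge-2 ions available
as (m + H⁺)/2. Matching takes, per theoretical fragment, the nearest peak
within ±0.02 Da (the fragment tolerance of the original searches), zero
when none; correlation is Pearson's R over that fragment-indexed vector
pair, which is robust to noise peaks because unmatched intensities
contribute zeros on a shared basis. Constant vectors raise a distinct
`ZeroVarianceError` rather than returning a sentinel.

The default pass rule is R ≥ 0.9 alone. The ±3 min retention-time window
is implemented but off by default: the bundled 12-peptide reference panel
itself contains confirmed peptides whose printed RT differences are 3.1
and 3.8 min, so a strictly binding window is inconsistent with the
published decisions (8/12 would pass instead of 11/12); both rules are
exposed and neither intent is guessed.

## LFQ differential expression

Preprocessing log2-transforms and keeps proteins with at least three
valid values in some group (groups smaller than three warn and defer to
the other groups). Imputation is per-sample downshifted-normal: missing
cells in sample s draw from N(m_s − 1.8·sd_s, (0.3·sd_s)²) with m_s, sd_s
from that sample's observed values — the de-facto defaults for this
imputation style, exposed in `ImputationParams`; observed cells are never
altered and the draw is seed-reproducible. Testing is a two-sided Student
t-test (equal variance, matching the desktop tool convention; Welch via
flag) with Benjamini–Hochberg adjustment; the published significance
threshold for this step is ambiguous ("0.01% FDR" appears alongside a
search-level FDR statement), so the threshold is a plain config knob with
BH 0.05 as default. Zero-variance/equal-mean rows get p = 1. Z-scoring
uses sample SD (n−1) everywhere, with constant rows mapping to zeros.

### Known limitation: 3-vs-3 power after BH

At the planted-effect scale used in the recovery check (|log2FC| = 2,
within-group SD 0.5, 3 vs 3, 100 of 2,000 proteins), a Student t-test has
df = 4 and noncentrality ≈ 4.9: raw power is ~0.95 at p ≤ 0.05 but only
~0.3 at p ≤ 0.0025, and BH across 2,000 proteins with ≤100 true positives
needs roughly p ≲ k·0.05/2000 ≈ 0.002, so the step-up procedure
self-consistently rejects almost nothing (simulated sensitivity 1–3%).
Downshifted imputation does not rescue this: dropout strikes individual
cells, so mixed observed/imputed groups gain variance rather than
separation. The acceptance suite states the ≥0.8 sensitivity bound and
honestly fails it; the FDR (≤0.1) and global-null (≈0 calls) properties
do hold and pass. Designs with more replicates or moderated-variance
tests would be needed for high sensitivity at this effect size.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed).

* **Motif repertoires** — anchor positions receive a stated total
  probability split equally over the listed residues (e.g. P2 {L,M} at
  0.9 → 0.45 each), non-anchor positions are uniform. The A3-like preset
  places basic anchors at P1 and P9, following the study design this
  package mirrors (the canonical allotype anchor is P2/P9; the preset is
  overridable). Non-9-mer sampling keeps internal anchors in place and
  maps the C-terminal anchor to the new terminus. The default length
  distribution {9: 0.65, 10: 0.2, 11: 0.1, 8: 0.03, 12: 0.02} matches the
  canonical class I shape (~63–70% nonamers).
* **PSM contamination** — decoys are composition-preserving shuffles with
  `DECOY_` accessions; scores are Gaussian, true (60 ± 10) stochastically
  above decoy (40 ± 10), overlapping enough that the FDR step is
  non-trivial; eleven invented RT-calibrant sequences stand in for a
  commercial spike-in kit; blank-only peptides appear in both a sample
  and the emitted blank list; modified duplicates copy a true PSM with
  one added oxidation.
* **Spectrum pairs** — fragment base intensities are log-normal (σ = 1)
  once per pair, perturbed per spectrum by multiplicative log-normal
  noise of the stated CV, plus uniform random noise peaks; at CV = 0 with
  no noise peaks the two spectra are identical and mirror R is exactly 1,
  degrading smoothly with CV. No chromatographic peak shapes, isotope
  envelopes or multiply charged fragments are simulated.
* **LFQ experiments** — baseline log2 abundances N(24, 2.5), within-group
  SD 0.5, exactly round(frac_de·n) proteins shifted by the stated log2
  effect in group 1; dropout probability is logistic and *decreasing* in
  log2 intensity (midpoint 21, steepness 1.5 → ~15% missing overall, a
  moderate MNAR regime), which is what justifies downshifted imputation.
* **Annotation fixtures** — each database takes the stated fraction of
  the universe plus distractors outside it, at the declared peptide- or
  protein-level kind.
* **TM stand-in** — a Kyte–Doolittle window counter labelled as a trivial
  surrogate; it generates fixtures only.

Because these generators are idealised (independent Gaussian noise, no
chimeric spectra, no shared peptides between proteins, no batch effects),
green tests demonstrate correctness of the *computations*, not
performance guarantees on real instrument data.

## Numerical and reporting conventions

Hypergeometric enrichment uses the exact right tail P(X ≥ x); the
adjustment is plain Bonferroni by default with Holm step-down as an
option (the cited network tool's "step down" correction is Holm;
plain Bonferroni is kept as the more transparent default since no
term-level numbers are being matched). Exclusive set intersections cover
all 2^k − 1 combinations and sum to the union size; k ≤ 12. Surfaceome
ranking averages log intensity across lines (a reference-line mode was
considered and rejected for symmetry), breaks ties lexicographically, and
takes "detected in a line" as present in ≥1 replicate (configurable).
Epitope-database joins match bare sequences, not (peptide, allele) pairs.

Problem sizes in the default test and acceptance runs (200–1,000
randomized tables, 200 spectrum pairs, 2,000-peptide repertoires, 10 LFQ
replicates of 2,000 × 6) were chosen so every stochastic check has
comfortable statistical margin while the whole suite stays interactive.

The end-to-end runner stamps every artifact with the seed and a hash of
the merged configuration and is byte-deterministic given both.
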