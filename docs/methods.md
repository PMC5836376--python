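# Methods

This note documents the statistical procedures, the numerical conventions
they rely on, what the synthetic-data generator does and does not emulate,
and the design choices made where the design was genuinely open.

## Input model and filtering

The pipeline consumes peptide-level label-free quantification tables: one
row per peptide sequence, one raw-intensity column per MS run. Rows
flagged as decoy ("reverse") or contaminant are removed at load time;
sequences outside 8–25 residues are dropped (HLA class I search-space
bounds); duplicate sequences are merged by summing intensities per sample.
A raw intensity of 0 is treated as "not detected" and stored as missing —
label-free intensity scales are arbitrary, and a true zero is not
distinguishable from dropout.

Coordinates are 1-based inclusive throughout. A peptide shared between
proteins is attributed to the first protein of its `Proteins` list (a
razor-protein-like rule). This choice is not forced by the science — no
standard exists for attributing shared ligands — but it makes the
nested-set analysis deterministic; `multiplicity` records how many times
a peptide occurs within its leading protein so ambiguous placements are
visible.

## Preprocessing

**Log2 transform.** Applied to positive intensities only; missingness is
preserved.

**Width normalization.** Per sample, with quartiles q1 < q2 < q3 of the
observed log2 intensities: x ↦ (x−q2)/(q3−q2) if x > q2, (x−q2)/(q2−q1)
if x < q2, 0 at the median. This centres every sample at 0 and equalizes
the spread of both tails separately, which is robust to the asymmetric
intensity distributions typical of ligandomes. Quartiles use linear
interpolation between order statistics (the "type-7" rule, numpy's
default); no convention is canonical here, so one is fixed for
bit-reproducibility. Degenerate samples (q3 = q2 or q2 = q1, or fewer
than 4 observed values) are rejected with the sample named.

One numerical caveat: re-computing quartiles of the transformed values
reproduces (−1, 0, 1) *exactly* only when the quartile indices are
integral (n ≡ 1 mod 4 observed values). Otherwise the interpolated
median straddles the kink of the piecewise-linear map and deviates by a
term of the order of the central inter-order-statistic gap — a property
of interpolated quantiles, not an implementation error. q1 and q3 are
exact for any n because their interpolation segments lie within one
linear piece.

**Imputation.** Missing cells are drawn from
Normal(mean_s − downshift·sd_s, (width_fraction·sd_s)²) per sample, with
width_fraction = 0.2 and downshift = 1.8 by default. The 20% width is the
field's standard for label-free dropout imputation; the downshift encodes
that dropout is abundance-dependent (missing-not-at-random), placing
imputed values in the lower tail. Setting downshift = 0 centres the
imputation on the observed mean, the most conservative reading when only
the imputation width is specified. Imputation is per sample (not global),
never overwrites an observed value, and is deterministic given the seed.

## Differential presentation

The moderated statistic is d = (x̄₂ − x̄₁)/(se + S0) with the
pooled-variance standard error and S0 ≥ 0 (default 1 at the peptide
level; 0.2 is the usual protein-level choice). S0 = 0 recovers the
classical pooled t exactly (tested against an independent closed form to
1e−9).

The null distribution comes from group-label permutations preserving
group sizes. For a 4 + 4 design there are only C(8,4) = 70 distinct
relabelings, so they are enumerated exhaustively (the default cap is 250,
matching common practice); enumeration also makes the q-values invariant
to sample column order. The q-value estimator is deliberately simple and
documented rather than cloned from any tool: for peptide i,

    q_i = median over permutations of #{ |d_null| ≥ |d_i| } / #{ |d_obs| ≥ |d_i| }

capped at 1 and made monotone non-increasing in |d| by a running maximum
from the top. Ties count as exceedances (conservative). Under global-null
simulations the fraction of peptides called at FDR 0.01 stays well below
0.02 (acceptance suite). No additional multiple-testing layer is applied
on top of this permutation FDR. Volcano classes follow the invariant:
`up` ⇔ q ≤ FDR and log2fc > 0; `down` symmetric; `ns` otherwise.

The one-sample test used for nested-pair shifts is the textbook
t = x̄/(s/√n) with a one-sided (greater) alternative against zero change;
stars are * p < 0.1, ** p < 0.05, *** p < 0.01. Zero-variance groups are
reported as "no shift" without a p-value rather than an infinite t.

## Cleavage classes, lengths, hydrophobicity, alleles, enrichment

The C-terminal residue partitions peptides into tryptic-like ({K, R}),
chymotryptic-like ({A, F, I, L, M, V, Y}) and other (the remaining 11
residues). "Other" peptides are excluded from tryptic/chymotryptic
contrasts but always reported.

Length distributions are computed on the peptides detected uniquely in
one condition (set difference of detection), overall and stratified by
cleavage class. Hydrophobicity defaults to the Kyte–Doolittle mean
(GRAVY); the scale is pluggable by name or as an explicit residue→value
mapping, since published "hydrophobicity score" definitions vary.

Allele assignment consumes an external prediction table (e.g. NetMHC
%rank). A peptide is assigned iff exactly one allele is below the rank
threshold (default 2%); otherwise it is a multi-binder, a non-binder, or
unpredicted — statuses partition the set.

Positional enrichment compares residue frequencies per position between
two same-length peptide sets with a two-proportion pooled-variance z
test, switching to the exact Fisher test whenever any 2×2 cell is below
5. Fisher was chosen for the small-count branch (rather than a one-set
binomial against the other's frequencies) because it keeps the procedure
exactly anti-symmetric: swapping experiment and reference flips
enriched↔depleted with identical p-values. Enrichment runs at a single
length (default 9) because cross-length positional alignment is
undefined; other lengths are run separately.

## Nested sets

Nested pairs are detected on protein coordinates of the leading protein:
two mapped peptides form a pair iff they share the start XOR the end and
differ in length by 1–5 residues. Equal starts mean a C-terminal
extension, equal ends an N-terminal one; pairs differing at both termini
are not nested pairs under this definition (internal bulges are out of
scope). Chains are allowed — a core may pair with several extensions —
because no deduplication rule is canonical. Detection is verified against
a brute-force all-pairs oracle on random fixtures.

The per-pair statistic is Δ = log2FC(long) − log2FC(short) on
normalized/imputed log2 intensities: the printed form
log2((treated_long − ctrl_long)/(treated_short − ctrl_short)) is
dimensionally ambiguous when the inner terms are already log-scale means,
and the difference-of-fold-changes reading is the one under which "zero
change" is a meaningful null. The literal linear-intensity-difference
reading is implemented as `mode="raw_diff"` for sensitivity analysis (it
is undefined whenever a difference is non-positive). Δ is antisymmetric
under swapping the group labels.

C-side pairs are grouped by the cleavage-class transition of short → long
C-terminal residues (T→T, C→C, C→T, T→C; classes outside the two sets are
labelled O and fall outside the four canonical groups). Each side and
each transition group with ≥ 2 pairs is tested with the one-sided
one-sample t against zero. Cleavage-context windows take P1 as the long
peptide's C-terminal residue, P2..P5 the four preceding residues, and
P1'..P5' the five downstream protein residues, with '-' beyond protein
boundaries; the frequency matrices exclude gaps per position.

## QC

Pairwise Pearson correlations default to pairwise-complete observed cells
(≥ 3 shared observations, else undefined) so imputation cannot inflate r;
a post-imputation mode exists for parity with matrix-completion-style
workflows. Replicate overlap reports the fraction of a group's detected
peptides seen in exactly k of n replicates. Spike-in statistics sum
heavy/light areas over charge states, take log2(heavy/light) per
replicate, and report mean, SD and CV% across replicates; the CV is
computed on the log2 ratio (the base must be fixed somewhere; log2
matches every other quantity in the pipeline), is 0 when the SD is 0, and
is undefined around a zero mean with nonzero SD.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume:

* a random proteome (uniform residue background by default; 200 proteins
  of length 400 by default);
* two allele caricatures — tryptic-like (C-term K/R, position-2 anchor
  L/V/T) and chymotryptic-like (position-2 P anchor, C-term L/F/A) —
  with anchor and C-terminal residues written into the protein before
  peptides are cut, so every peptide is an exact substring at its stated
  coordinates;
* an HLA-I length distribution over 8–14 with mode 9 (45% 9-mers);
* a nested fraction (default 0.07, the magnitude reported for real
  class I ligandomes) of cores receiving a long partner extended 1–5
  residues into real protein context on one side, with the long C-side
  C-terminus drawn from the same allele model;
* intensities: per-peptide base abundance ~ Normal(25, 2) log2 units,
  per-cell replicate noise Normal(0, 0.25), and treatment effects of
  +1.0 log2 for chymotryptic-like peptides and +0.5 extra for long
  nested partners — the qualitative effect structure of an
  immunoproteasome-inducing stimulus;
* logistic missing-not-at-random dropout, P(missing) =
  expit((midpoint − abundance)/slope) with midpoint 20 and slope 1,
  giving a few percent of low-abundance dropout at the default
  abundance scale. Real dropout structure is not quantified anywhere;
  these are free knobs, not estimates.

Peptide windows are allocated disjointly within proteins. This keeps
generation O(n), guarantees coordinate validity, and means the planted
pairs are provably the only nested pairs — convenient for truth-based
tests, but it also means the generator does not produce the dense
overlapping peptide ladders, shared-protein correlations, interference
or batch structure of real data. Passing the recovery tests therefore
shows the estimators are correct under the generative model, not that
real ligandomes meet that model. A single seed drives a hierarchical RNG
(separate streams for proteome, peptide placement, intensities and
missingness), so each stage is independently reproducible.

## Analysis scale and normalization in the recovery checks

Parameter-recovery checks (and the acceptance script) run the chain
log2 → MNAR imputation → test, reading effects in log2 units. Width
normalization is deliberately not applied there: it equalizes per-run
intensity scales, which simulated samples share by construction, and its
median-centring assumes most features are unchanged — with half the
ligandome truly shifted it would re-centre each treated sample and bias
both class means toward zero by construction. On real data, where run-
to-run loading differences dominate and the changed fraction is smaller,
normalization is the pipeline default (`preprocess.normalize: true`).

Problem sizes used by the default test suite and the acceptance script —
4,000-peptide recovery runs, 2,000-peptide null calibrations over 10
seeds, 20-seed nested-null batches at 800 peptides — were chosen so that
sampling error is several times smaller than the recovery tolerances
while the whole suite runs in seconds.

## Determinism and outputs

Every stochastic step takes an explicit seed; the pipeline writes stage
TSVs plus `report.json` deterministically (sorted keys, fixed float
formats), so identical config + seed reproduces the bundle byte for
byte. `manifest.json` carries wall-clock stage timings and input digests
and is the only non-deterministic file.

## Known limitations

* Identification-level FDR, match-between-runs and spectrum processing
  are upstream concerns; the pipeline starts from a peptide table.
* Only two-group unpaired designs are supported; no paired or
  multi-group testing, and no empirical-Bayes variance moderation.
* The q-value estimator is behaviorally, not bit-for-bit, comparable to
  other SAM-style implementations; published tools do not document their
  exact S0-curve constructions.
* Binding prediction, motif deconvolution and logo rendering are
  external; the package only consumes/emits their tabular interfaces.
* Class II ligandomes would need a different length model (12–19 with
  mean ~15) and no C-terminal cleavage reading; only the length switch
  would carry over.
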