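# Methods

This note documents the models, conventions, and numerical choices behind
`icecore`, and what the synthetic studies do and do not establish.

## R-OTU decontamination

**Model.** Low-biomass libraries are treated as mixtures of genuine template
and a contaminant pool that enters every library (reagents, air, instruments)
at roughly similar absolute amounts. Background controls sample that pool
with little genuine template, so scaling each library's composition by its
qPCR-measured 16S copy load turns relative abundances into comparable
"absolute" abundances. The per-OTU ratio of mean absolute abundance in
controls to that in real samples (R-OTU) is then near the control:sample load
ratio divided by the carryover fraction for contaminants, and near the
cross-talk fraction times the load ratio for genuine taxa — separated by
orders of magnitude under realistic loads.

**Conventions.**
- The denominator mean pools *all* ice samples (one ratio per OTU). A
  per-sample mode (`per_sample=True`, max over samples) is available but is
  more conservative and not the default.
- 0/0 → 0 (an OTU absent everywhere is retained: absence is not evidence of
  contamination); positive/0 → +inf (a control-only OTU is a contaminant by
  definition).
- The threshold test is strict (`R > 0.01`), so an OTU exactly at the
  threshold is retained.
- Removal default is whole-OTU deletion plus renormalization. Because
  "proportional removal" can also be read subtractively, a `subtract` mode is
  provided: the control-implied proportion (mean control absolute abundance /
  sample load) is subtracted per OTU, floored at 0, then renormalized.
  Deletion is the default because it is the unambiguous reading of the
  threshold rule.

**dsDNA copy-number utility.** `copies/μl = (c × 1e-9 g/μl per μg/ml) /
(L × 660 g/mol / N_A)` with the conventional 660 g/mol per base pair. For
commercial lambda DNA this uses the full 48,502 bp genome length, which
reproduces the catalog value of 1.88×10⁹ copies/μl at 100 μg/ml; shorthand
statements of a "4.8 kb" lambda genome are inconsistent with that
concentration by exactly a factor of ten in length.

## Community statistics

- **Rarefaction** is single-draw subsampling without replacement
  (multivariate hypergeometric via numpy's seeded `Generator`), so the
  expected retained count of an OTU at proportion *p* and depth *d* is *pd*.
  Depth is a parameter because different analyses legitimately use different
  depths (e.g. 12,000 for the decontamination-evaluation samples, 24,000 for
  cross-core comparisons).
- **Weighted UniFrac** uses the branch-length-normalized variant so distances
  lie in [0, 1]; the normalization term Σ l_b (p_A+p_B) equals the
  leaf-depth-weighted form of the classical definition. The normalized
  variant need not satisfy the triangle inequality; violations are logged,
  never raised. Implementation is scikit-bio's, verified in tests against a
  per-branch enumeration oracle to 1e-12.
- **PCoA** is classical metric scaling. Explained percentages divide by the
  sum of *positive* eigenvalues only; negative eigenvalues (possible for
  non-Euclidean distances) are reported on the result object rather than
  corrected, since downstream use is visual ordination.
- **ANOSIM** uses mid-ranks for ties and the +1 permutation correction, so
  p is never 0 and the smallest attainable p is 1/(n_perm+1). Default 999
  permutations. **Mantel** is two-tailed on Pearson r of the off-diagonal
  entries with the same correction.

## Synthetic amplicon studies

Defaults describe the emulated design: 8 ice samples and 4 background
controls (named for a cold-room air control, a sterile artificial ice core,
an extraction blank, and a sequencing blank), 120 genuine and 30 contaminant
OTUs, libraries of 24,000 reads drawn multinomially, log-normal(μ=0, σ=2)
abundance profiles, ice qPCR loads log-uniform in 1e6–1e7 copies versus
control loads in 1e4–1e5 (a ~1:100 ratio), 1% contaminant carryover into ice
libraries, and 2% sample-to-blank cross-talk.

Under this construction, planted contaminants sit at
R ≈ load-ratio / carryover ≈ 1 and genuine taxa at
R ≈ cross-talk × load-ratio ≈ 2e-4, so the 0.01 threshold is the correct
discriminator *by design*. When no contaminants are simulated, a blank's
template is only the cross-talk carryover, so its copy load is scaled by the
cross-talk fraction — without this, a clean blank would paradoxically carry a
full contaminated-blank load of genuine-taxon template and every OTU would
sit at the threshold.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomy-assignment error, compositional correlation between taxa, PCR
amplification bias, or well-to-well index hopping. Passing recovery tests
therefore demonstrates the statistic's behavior under its own model
assumptions, not performance on arbitrary real data.

## Synthetic viromes

Viral genomes are i.i.d. uniform over {A,C,G,T} (10–25 kb by default).
Near-duplicates are substitution-only mutated copies over a specified shared
prefix fraction, with a random tail — so pairwise identity and shared
fraction are exact by construction and give a clean oracle for the
clustering thresholds. Hosts (30 kb) alternately receive a planted
homologous region of their linked virus (2.5 kb at 85% identity) or a CRISPR
array of ≥4 identical repeats (30 bp) whose spacers (30–40 bp) are copied
verbatim from the linked virus. Coverage depths are log-normal; library
sizes default to 2 Gb. Real viral genomes have skewed composition, repeats,
and indel divergence, none of which are modeled.

## vOTU clustering and the alignment engine

Clustering is greedy, longest-first (ties broken by lexicographic id):
each contig joins the earliest cluster whose representative shares ≥95%
identity across ≥80% of the shorter sequence; otherwise it founds a cluster.
This matches the longest-contig-as-seed convention and equals transitive
closure on instances whose pairwise relations are mutually consistent (the
planted-duplicate case), which the tests verify against a brute-force
single-linkage oracle.

The "80% of their lengths" denominator is the **shorter** sequence; the
alternatives (longer, or each separately) are stricter and not used.

The aligner seeds on shared unique 15-mers, groups seeds by diagonal,
rescored each candidate diagonal exactly as a maximum-scoring ungapped
segment (match +1, mismatch −2), and sums the best non-overlapping segments;
both strands are searched. This handles substitution-dominated divergence
near the species threshold but not indel-rich alignments — acceptable
because the 95% cutoff regime is substitution-dominated, and the tests
cross-check identity against an exact edit-distance DP oracle (edlib) on
1-kb instances to within 0.01. Two random 10-kb sequences share ~0.1
expected unique 15-mers, so unrelated pairs report near-zero aligned
fraction.

vOTU rarefaction counts a vOTU as detected at ≥1 assigned read by default
(`min_reads` configurable); curves report mean ± sd over seeded
subsamples without replacement.

Lifestyle folds are floor-truncated to one decimal, the rule that uniquely
reproduces 3.2 / 8.4 / 14.1 from 42.4% against 13 / 5 / 3% references (a
1e-9 guard absorbs float representation error before flooring).

## Host linkage

- **Similarity**: HSPs failing bit ≥50 or E ≤1e-3 are discarded; surviving
  HSPs' host-coordinate intervals are merged (so "span" means total aligned
  genomic span, allowing discontiguous HSPs to sum), and identity is
  alignment-length-weighted. Host coordinates are chosen over vOTU
  coordinates for the span because the 2-kb requirement reads most naturally
  as genomic span.
- **Composition (d2\*)**: word counts at k=6 are centered by the expectation
  under an i.i.d. mononucleotide null fitted per sequence; the cross term is
  scaled by the geometric mean of both expectations and each norm uses its
  own variance scaling. Words impossible under a sequence's base composition
  contribute nothing. Counting is forward-strand by default
  (`strand_symmetric=True` appends the reverse complement with an `N`
  junction guard). The "possibility ≥80%" acceptance rule is operationalized
  as genus consensus among the 30 lowest-dissimilarity hosts — an
  interpretation, made configurable (`top_n`, `min_consensus_pct`). With
  fewer than 30 hosts the consensus is over all hosts; a single-genus host
  database trivially yields 100% consensus.
- **CRISPR**: the miner finds exact direct repeats (23–47 bp) separated by
  distinct spacers (26–50 bp), requiring >2 repeats. Exact repeats only —
  fuzzy repeat matching is out of scope, which is acceptable for planted
  arrays and conservative on real genomes. Spacer-to-vOTU matching is exact
  substring search on both strands (zero mismatches by default; a
  substitution-tolerant scan is available behind `max_mismatch`).

Predictions are reported at host-genome level and rolled up to genus through
the supplied taxonomy map; genus-level agreement counts method pairs
predicting a shared genus for the same vOTU.

## Problem sizes and runtime

Test and acceptance workloads are sized for a single CPU: 50 simulated
studies for decontamination recovery, 200 null datasets of 12 samples with
199 permutations each for the type-I error checks (199 makes the
+1-corrected p-value lattice hit the 0.05 level exactly under uniformity),
1-kb instances for the DP-alignment cross-checks, and 200-bp pairs for the
4⁶-word d2* enumeration oracle. The full suite runs in well under a minute.

## Known limitations

- The aligner's ungapped diagonal model underestimates identity for
  indel-divergent pairs; for borderline real-data clustering decisions an
  external ANI tool should corroborate.
- The d2* implementation holds 4^k counts densely; practical up to k≈8.
- The CRISPR miner requires exact repeat copies and will miss degenerate
  arrays that dedicated miners recover.
- The subtractive decontamination mode assumes the control-implied
  proportion is additive on the absolute scale, which is a first-order
  approximation.
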