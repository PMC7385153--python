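# Methods

`hrdpipe` re-implements, as a tested pipeline over synthetic cohorts, an
analysis for identifying homologous-recombination-deficient (HRD) breast
tumors: mutational-signature extraction and refitting, genomic-scar HRD
scoring with top-decile classification, a recombination proficiency score
(RPS), a germline truncating-variant filter cascade over a DDR gene
panel, promoter-silencing calls, and the group-comparison statistics that
tie these layers together. This note records the models, the defaults,
and the design decisions taken where reasonable alternatives existed.

## Mutation catalogs

Somatic SNVs are reduced to the 96 trinucleotide categories (six
pyrimidine substitutions x 16 flanking-base pairs, COSMIC ordering).
Purine-reference records are reverse-complemented, base and flanks, so
the two strand descriptions of one event always land in the same
category; this symmetry is property-tested. Coordinates are 1-based
inclusive (MAF convention) at every external interface. Records are
first reduced to calls supported by at least two variant callers
(`min_callers`, default 2), non-SNV records are dropped with a logged
count, and samples at or above 5,800 SNVs are excluded as hypermutants
(`max_snv`; the boundary is inclusive).

## De-novo signature extraction

Each restart factorizes the sample x 96 count matrix by
Kullback-Leibler NMF (multiplicative updates; the KL objective is the
Poisson log-likelihood appropriate for counts) augmented with an
automatic-relevance prior: each component carries an exponential (L1)
relevance scale, re-estimated every sweep, whose posterior shrinks
components the data do not need. Plain KL-NMF with post-hoc
activity-share pruning was evaluated first and rejected: on clean
four-signature synthetic data it retains all `k_max` components in every
restart (surplus components duplicate real signatures or absorb
multinomial noise above any sensible share threshold), so a
component-count vote never concentrates. The ARD variant drives surplus
components to zero during fitting; a final 1%-of-activity share prune
(`prune_share`) removes numerically dead components.

Extraction runs `n_restarts` (default 50) randomly initialized fits from
`k_max` = 10. The surviving component count of each restart votes for
the cohort's signature number; the modal count must win at least
`quorum` = 60% of restarts, otherwise extraction fails loudly with the
vote table. Consensus profiles are the centroids of the winning
restarts' profiles after cosine matching (Hungarian assignment to the
first winner), renormalized. Consensus exposures are an NNLS refit of
the catalog onto the consensus profiles.

A signature whose largest single-sample contribution is at least
`singleton_threshold` = 0.5 of its total activity is flagged as a
singleton; the pipeline excludes the dominant sample and re-runs
extraction (up to `max_singleton_rounds` = 3), mirroring the procedure
of removing an ultra-mutant tumor that manufactures its own signature.

Extraction is exactly reproducible from its seed. It is invariant to
sample ordering only up to the restart noise of the consensus (the
random initializations do not permute with the samples), which tests
bound at cosine >= 0.98.

## Reference refitting and naming

Refitting solves, per sample, non-negative least squares of the
96-frequency vector on a fixed reference signature matrix; normalized
contributions below `floor` = 0.06 are zeroed and the rest renormalized
(the floor suppresses the small spurious loadings NNLS spreads over
correlated references; it is configurable and all recovery tests that
measure raw NNLS accuracy run with floor 0). The per-sample
reconstruction cosine is reported; adding components can never lower it
below the best single reference, which is asserted as a property.

The bundled reference is **synthetic**: the published 30-signature
reference matrix is not redistributable here, so `hrdpipe.reference`
deterministically constructs 30 probability profiles whose key members
mimic the qualitative structure of the processes they are named for
(CpG C>T for id 1, TpC-focused APOBEC pair for ids 2/13 with a shared
minor substitution fraction, a near-flat HRD-like profile for id 3, a
mismatch-repair flavour for id 6, a POLE flavour for id 10); the rest
are sparse random profiles from a fixed seed. Naming promotes a match
to its conventional alias only at cosine >= 0.8, and reports the two
APOBEC ids jointly when they are the two best matches. Nothing
quantitative in the package depends on the real reference values: every
accuracy statement is against the generator's own truth profiles.

## Genomic scars and the HRD score

From allele-specific copy-number segments (major/minor integer copy
numbers, 1-based inclusive coordinates), three components are counted
per sample with the standard published definitions, made explicit here
because the segment inputs carry no conventions of their own:

* **LOH** — minor_cn = 0, length > 15 Mb, not spanning a whole
  chromosome;
* **TAI** — major_cn != minor_cn, length > 11 Mb, touching a chromosome
  end, not crossing the centromere (crossing = extending strictly beyond
  both centromere boundaries);
* **LST** — after per-arm smoothing (segments < 3 Mb removed, adjacent
  same-state segments merged across gaps <= 3 Mb), breakpoints between
  adjacent segments each >= 10 Mb in different states with gap <= 3 Mb.
  Arms are split at the centromere midpoint.

All four length parameters are configuration keys. The HRD score is the
plain sum LOH + TAI + LST. No ploidy-dependent correction is applied to
LST; raw breakpoint counts are reported, and externally published scores
(which may differ in that respect) are therefore carried with a
`source=imported` flag and never mixed silently with computed scores —
supplying both for one sample is an error unless they agree.

Classification is by the cohort's own top decile by default
(`hrd_rule=top_quantile`, q = 0.10): the realized threshold is the
smallest score at which the at-or-above fraction does not exceed q, and
tie groups are never split — a tie group too large to fit in the decile
is left out entirely. A fixed inclusive cutoff (default 57, the scale of
the published pan-cancer scores) is available for imported scores.

**RPS** = -(RIF1 + PARPBP + RAD51 + XRCC5) on FPKM; **RPS-beta** applies
the published regression weights (0.2171423, 0.1946173, 0.2783017,
0.3099387), which sum to 1 so that unit inputs give exactly -1. Both
are linear and non-positive on non-negative expression.

## Germline filter cascade

Candidate germline variants (expected upstream provenance: a paired
tumor/normal VarScan2 run in somatic mode with `--min-coverage 30
--min-var-freq 0.08`, annotated by ANNOVAR; neither tool is re-executed)
pass through conjunctive rules: quality (depth >= 10, supporting reads
>= 5, VAF >= 0.08 — the VAF floor is a strict `<` exclusion — and not
labelled somatic), homopolymer context (a single-base run of >= 5 bp
within 3 bp of the site; both parameters are explicit stand-ins for
"near homopolymer regions" and configurable), mapping-quality difference
(|mean ref MAPQ − mean alt MAPQ| >= 30 fails, inclusive), read-end
position (median variant position in the terminal 10% of the read),
population frequency (AF >= 1% fails, inclusive; a missing AF passes —
the rule removes known-common variants only), functional region (only
exonic and splicing survive), truncation (ClinVar hotspot, nonsense,
frameshift indel, or splice site), and the 11-gene DDR panel (ATM, BAP1,
BRCA1, BRCA2, BRIP1, CDK12, CHEK2, NBN, PALB2, POLQ, RAD51C;
configurable). "Supporting reads" is read as the count of variant-
supporting reads. Context evidence may arrive precomputed (flags) or
raw (flank sequence, median read position); missing optional evidence
passes with a warning. Every rule is evaluated for every variant, so
the trace is complete and the survivor set provably independent of rule
order; tests assert equality with the intersection of per-rule survivor
sets and monotonicity under threshold relaxation.

## Epigenetic silencing

A gene is hypermethylated in a sample when its summarized promoter beta
is >= 0.75 (inclusive) and silenced when additionally expressed below
1 FPKM (strict); silencing implies hypermethylation by construction.
Promoter probes are summarized by the mean by default: the 0.75
threshold is only meaningful on the [0, 1] beta scale, whereas a
sum over probes exceeds 1 for multi-probe promoters. Sum mode is
provided for compatibility with summed-level conventions and flagged in
the output; promoter membership is an input annotation, not computed.

## Statistics

Two-group comparisons use the two-sided Wilcoxon rank-sum test: exact by
full enumeration of group splits (midranks, hence tie-aware) when both
groups have at most 8 observations, tie-corrected normal approximation
otherwise. Three or more groups use one-vs-rest rank-sum tests; note
that a strongly shifted group also displaces the "rest" of the other
labels, so the interpretable quantity is the ordering of the per-label
p-values. Multiplicity is controlled by Benjamini-Hochberg step-up
adjustment (tested against a brute-force restatement).

Differential expression between two sample groups computes per-gene fold
change as the ratio of group mean FPKMs (genes with a zero mean in
either group are excluded with a logged count — their log fold change is
not finite), a rank-sum p-value, BH adjustment across tested genes, and
selects genes with |log2 FC| > 1.5 and adjusted p < 0.05 (both strict,
both configurable; the strict `<` on the adjusted p is used where
stated thresholds conflict between `<` and `<=`).

The IFN-γ signature is the per-sample mean of IDO1, CXCL10, CXCL9,
HLA-DRA, STAT1 and IFNG on the log2(FPKM+1) scale by default (raw FPKM
optional); missing genes are dropped with a warning.

Outlier removal uses Tukey fences with linear-interpolation quantiles
(configurable choice; the fence rule itself does not fix a quantile
estimator): values strictly outside [Q1 − 1.5 IQR, Q3 + 1.5 IQR] are
removed. The burden-activity relationship restricts to samples with
signature activity >= 0.5, removes burden outliers by the Tukey rule,
and fits ordinary least squares of burden on activity, reporting R²,
the F-test p-value, and the coefficients.

## ROC analysis

Scores predict the positive class at or above a threshold (higher =
more HRD-like). Thresholds are the unique scores plus sentinels; the
curve is integrated by the trapezoidal rule walking from the strictest
threshold to the laxest, which handles tied false-positive rates
correctly and reproduces the Mann-Whitney identity exactly on tie-free
data. The operating cutoff maximizes sensitivity + specificity; exact
ties break toward the lowest threshold (favouring sensitivity in a
screening setting) and are logged.

## Synthetic cohorts and what they do (not) show

The generator emits every input table with known ground truth:

* **Mutations.** Per-sample signature weights are drawn from a Dirichlet
  centred on the sample's group mixture (concentration 1.5; groups are
  BRCA1-mutant, BRCA2-mutant, HRD-without-BRCA, and non-HRD), context
  counts are multinomial over the mixed profiles with 500-2,000
  mutations per sample, and each mutation is placed on the pyrimidine
  strand at a reference position matching its context. Positions are
  confined to a 300 kb mutation-accessible window at the start of each
  chromosome; the emitted FASTA covers that window, so catalogs are
  exactly recomputable from MAF + FASTA. Single-caller decoy calls
  (5% of load) exercise the consensus filter and are excluded from the
  truth tallies.
* **Segments.** The synthetic genome has three chromosomes of 150-230 Mb
  with stated centromeres. Qualifying segments are laid out so the three
  counters return exactly the requested per-sample counts: telomeric
  12 Mb imbalanced segments for TAI, interstitial 16 Mb minor-zero
  segments for LOH, and alternating-state chains of 10.5 Mb segments for
  LST, always separated by 4 Mb (> the LST gap) so placements cannot
  interact; non-qualifying decoys (short LOH, interstitial imbalance,
  sub-threshold transitions, sub-smoothing blips) are added when room
  remains. Deterministic mode places exactly the configured counts or
  fails; stochastic mode draws counts Poisson and truncates to capacity,
  recording realized counts in the ledger. Default group means (e.g.
  BRCA1-mutant 9/4/7, non-HRD 2/1/2) are scaled to this genome, not to a
  full human genome — absolute HRD scores here are not on the published
  pan-cancer scale, which is why classification is quantile-based.
* **Expression, methylation, germline.** FPKM is log-normal (sigma = 1.0
  on log2) around per-gene baselines with per-group log2 shifts (HRD-like
  groups overexpress BARD1/BRIP1 and the RPS genes; BRCA1-mutant tumors
  get keratins and a stronger interferon programme; BRCA2-mutant tumors
  get a hormone programme). Silencing events jointly set beta in
  [0.78, 0.95] and FPKM < 1 for BRCA1 or RAD51C in ~3% of samples, with
  hypermethylated-but-expressed decoys. Germline candidates comprise one
  clean truncating BRCA1/BRCA2 variant per BRCA-mutant sample, one
  sole-violator per cascade rule, and an off-panel decoy.

The generator reproduces the *data contracts* and planted effect
structure, not the biology: no clonality, replication timing, LD,
realistic copy-number landscapes, or correlated noise. Passing tests
demonstrate that the algorithms recover what the generator planted under
its noise model, not performance on real tumors.

## Numerical and degenerate-input conventions

Zero-mutation samples refit to zero exposure rows (flagged). Zero
profile vectors are rejected in cosine computations. Exposure argmax
ties resolve to the lexicographically first signature name, logged; an
all-zero row is "unassigned". Catalog/exposure/score tables are written
with `%.6g` floats and sorted JSON keys so identical runs are
byte-identical; germline candidate tables round-trip floats exactly.
NMF convergence is declared when the KL objective changes by < 1e-7
(relative) across a 50-iteration window, capped at 2,000 iterations.

## Problem sizes used by the test suite and acceptance script

Cohorts of 200 samples (500-2,000 mutations each) for exposure recovery
and consensus extraction (50 restarts); 1,000 random segment tables for
the scar-counter oracle; 500 replicates for ROC binormal calibration and
250-500 for DEG calibration; full end-to-end runs at n = 200 with a
byte-identical rerun check. These sizes make the whole suite complete in
a few minutes on one CPU while keeping every stochastic criterion's
sampling error well inside its asserted tolerance.

## Known limitations

* The signature reference is a synthetic stand-in; matches to it name
  processes by convention only.
* LST counts are not ploidy-corrected; imported pan-cancer scores may be.
* One-vs-rest p-values are not independent across labels.
* The exact rank-sum enumeration is O(C(n1+n2, n1)) and is capped at
  groups of 8; larger groups use the tie-corrected normal approximation.
* The generator's capacity-truncation in stochastic scar mode slightly
  deflates the upper tail of scar counts relative to a Poisson model.
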