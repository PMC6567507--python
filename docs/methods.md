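# Methods

This package re-implements, as a tested pipeline over synthetic data, an
interlaced small-RNA + degradome analysis of a heat-stress experiment in a
polyploid crop: miRNA/isomiR ascertainment from hairpin-precursor evidence,
star-sequence prediction, negative-binomial differential expression across
a 2 treatment x 3 timepoint x 4 replicate design, and degradome (PARE)
validation of miRNA-guided cleavage sites. Every stage is exercised
end-to-end on generated data with planted ground truth, so recovery,
specificity and calibration are measurable rather than asserted.

## The synthetic dataset

The generator is first-class code, not a fixture. It emulates the
statistical structure the analysis assumes; defaults (all configurable in
one YAML file) are:

- **Design**: 24 libraries — control and heat treatments sampled at 0, 1
  and 4 days after treatment (DAT), 4 biological replicates per cell.
- **Precursors**: 50 hairpins of the form flank + arm + loop + arm + flank
  (~80 nt; mature length 20–22 nt, loop 8 nt, flanks 15 nt). The star
  strand is the complement of the mature offset so both 3' ends overhang
  the duplex by exactly 2 nt; one stem pair is converted to a G:U wobble.
  Construction is rejection-sampled until the built-in folder recovers the
  planted duplex anchors, so duplex geometry is guaranteed on the
  generator's own output. Each precursor carries 1–3 isomiRs with 1–3 nt
  5'/3' end shifts, kept inside the 18–24 nt size window.
- **Genome**: precursors and 50 decoy loci (dinucleotide-shuffled copies of
  precursors — same composition, no planted complementarity) interleaved
  with ~1.5 kb random spacers over 3 chromosomes, random strands (~150 kb
  total). Decoys are the negative controls for discovery specificity.
- **Expression**: per-precursor abundance log-uniform in 100–30,000 RPM,
  scaled so planted reads are 70% of each library; the remaining 30% are
  random genomic fragments, 18–30 nt with a 24-nt mode. isomiR proportions
  are drawn once per precursor from a Dirichlet(8, 1, ..., 1) and held
  fixed across libraries; the star's abundance ratio is log-normal around
  0.2. Counts are negative binomial via gamma-Poisson with variance
  mu + phi mu^2, phi = 0.1 (typical sRNA-seq overdispersion).
- **Heat response**: 30% of precursors get a planted log2 fold change
  (|lfc| >= 1, exponential tail) applied to all their variants, scaled by
  a recovery profile over timepoints (1.0, 0.5, 0.25 at 0/1/4 DAT), so the
  effect is strongest immediately after the stress and decays — the
  heat-0-vs-4-DAT contrast is non-null while control-0-vs-4 is null.
- **Reads**: insert + a fixed 3' adapter (the documented TruSeq small-RNA
  adapter), truncated to 50-cycle machine reads, constant quality. No
  sequencing-error or PCR-duplicate model (a stated non-goal): tag
  collapsing and exact mapping therefore behave noiselessly, which is what
  the downstream contracts assume.
- **Degradome**: 12 target transcripts (~500 nt CDS) embed the perfect
  reverse complement of one planted mature miRNA each; 6 decoy transcripts
  embed a dinucleotide-shuffled site. Signal reads are 20-mers whose 5'
  end sits exactly at the position paired to miRNA position 10 (NB mean
  50); background 5' ends sit at uniform positions with exponentially
  distributed per-position weight, totalling ~50% of reads, lengths 18–22
  so the 19–21 nt size selection is exercised.

Sizes were chosen so the full pipeline runs in about a minute on one core
while keeping every statistical property measurable (e.g. at depth 2x10^5
the 10-RPM filter corresponds to 2 reads, so the background genuinely
stresses the biogenesis gates). What passing tests show is that the
*methods* are correct and calibrated on data satisfying their assumptions;
they do not show robustness to sequencing error, incomplete genomes or
expression structure the generator does not model.

## Folding model

Hairpin evidence uses a Nussinov-style dynamic program over nested
structures: allowed pairs G:C (-3), A:U (-2), G:U (-1 kcal/mol), minimum
hairpin loop 3 nt, minimizing total energy, with a deterministic traceback
(prefer pairing position i with its smallest optimal partner). Energies are
integers internally, so optimality comparisons are exact; the DP is checked
against exhaustive enumeration of all nested structures for short
sequences. This model was chosen over full Turner nearest-neighbour rules
to keep the module dependency-free and oracle-testable; the retention
threshold (energy per nucleotide < -0.2 kcal/mol/nt) matches the scale of
Turner-model energies on plant precursors and is configurable. An adapter
to an external RNAfold-compatible folder is provided and interchangeable;
absolute-energy compatibility is not claimed, and the acceptance checks are
discrimination (planted hairpins pass, shuffled decoys fail), not energy
values.

A candidate passes the hairpin test when (a) energy per nucleotide is
strictly below the threshold and (b) the structure has exactly one terminal
loop on the path carrying the candidate mature span: at least half the span
paired, all its pairs subtending one common terminal loop, and the widest
pair touching the span enclosing only that loop. Multi-loop (cloverleaf)
structures fail regardless of energy.

## Discovery

Distinct tags are collapsed per library and kept when they reach 10
reads-per-million in at least one library; the RPM denominator is the
retained (post size-selection) read total. Mapping is exact and full-length
on both strands through an 18-mer seed index; a tag may map to many loci
and the placement count is reported (`multi_locus_count`).

Candidate precursor loci come in two modes, because deriving loci is
upstream of the sequencing evidence: *annotation mode* folds supplied
BED/GFF3 intervals (the default when loci are available, as in the
synthetic runs, mirroring analyses that map tags onto a pre-computed locus
set); *de novo mode* folds windows of increasing flank size (30/60/100/150
nt, symmetric and one-sided) around tag clusters, retaining the
lowest-energy-per-nt window that passes the hairpin test, with one
refinement pass that trims a window to the widest pair subtending the
anchor tag and refolds (flanking sequence otherwise obscures some stems).

Ascertainment applies, per tag, the biogenesis criteria of plant miRNA
annotation practice: the tag must place inside a retained candidate on the
locus strand, must not straddle the terminal loop, and must pair as a
*mature-style duplex* — at least half its bases paired, partners compact
(within span length + 4) and entirely on the opposite arm, including one
near-uninterrupted helix of >= 14 stacked pairs (about two helical turns).
The stack requirement is what separates genuine arms from chance stems:
shuffled-decoy structures pair plentifully under the simplified energy
model but fragment into short helices. Without it a few percent of decoy
loci are ascertained; with it, decoy ascertainment is zero across seeds
while planted recovery stays above 95%.

Star prediction projects through the pair table: star 5' = partner(m3 - 2),
star 3' = partner(m5) + 2, scanning up to 3 nt inward when an anchor is
unpaired and carrying the offset into the projection. Star support is
evidence-grading, not a filter (mature miRNAs are reported without it):
`star_evidence` is set only when the geometry shows exact 2-nt 3' overhangs
on both ends *and* the predicted star is either itself sequenced or present
in the user catalog.

Families come from the best ungapped catalog match (<= 2 mismatches,
length difference <= 2, ties to the lexicographically smallest family;
otherwise "novel"); names follow the family–precursorIndex.variant-arm
pattern with precursors numbered by genomic order and variants by
descending abundance, so naming is a pure function of the input.

## Differential expression

A from-first-principles count-GLM stack in the edgeR tradition, simpler
than edgeR's machinery by design; its contract is calibration and recovery,
not bit-compatibility:

- **TMM**: reference = library whose upper-quartile CPM is closest to the
  mean; genes zero in either library excluded; M trimmed 30% per tail, A 5%
  per tail; factor = 2^(precision-weighted mean M) with delta-method
  weights; factors rescaled to geometric mean 1.
- **Dispersion**: common phi maximizes the summed Cox–Reid adjusted profile
  likelihood (log-likelihood minus half the log-determinant of the expected
  information) over a 30-point log grid on [1e-4, 10]; tagwise phi_g
  maximize APL_g + w x mean-APL with w = prior_df / residual df (prior_df
  default 10), which shrinks single-tag estimates toward the common value.
- **GLM**: one-way cell-means fits (6 cells) with log link and offsets =
  log(library size x TMM factor), Fisher scoring per cell (a 1-D Newton
  step, vectorized across tags). Contrasts merge two cells in the reduced
  model: heat vs control at each DAT, plus 0 vs 4 DAT within each
  treatment. LR = 2(ll_full - ll_reduced) against chi-square(1); log2FC
  from the fitted cell coefficients. All-zero rows report p = 1 and
  log2FC = 0; non-converged rows (not observed in practice) report NA and
  are excluded from the FDR denominator.
- **FDR**: Benjamini–Hochberg step-up, property-tested against the
  brute-force definition.
- **Summaries**: classical (Torgerson) MDS of library log2(RPM+1) profiles;
  agglomerative complete-linkage clustering under the Chebyshev (maximum)
  distance with deterministic lexicographic tie-breaking; heat maps use
  log2(RPM+1) (the +1 offset is this package's choice).

Null simulations (phi = 0.1, 24 libraries, no planted effect) give
uniform p-values (KS < 0.1 at 2000 tags) and essentially no FDR < 0.05
calls; planted 4-fold changes are detected for >= 90% of tags at 4
replicates, with log2FC recovered to a few tenths.

## Degradome validation

Degradome tags (19–21 nt after size selection) are mapped sense-strand,
exact and full-length, onto coding sequences; each placement adds the tag
count to the 5'-end profile at its start (multi-mapping tags count at every
placement — simpler and conservative for peak calling). Target scoring is
the classical plant-targeting penalty scheme on the ungapped antisense
alignment: match 0, G:U 0.5, mismatch 1, penalties doubled at miRNA
positions 2–13; candidate sites score <= 6 (configurable). The cleavage
site is the transcript base paired to miRNA position 10. Peaks are
categorized 0 (unique maximum), 1 (tied maximum), 2 (above the median of
nonzero positions), 3 (otherwise), 4 (single read).

Significance is an empirical null: dinucleotide-preserving shuffles of the
miRNA (Altschul–Erikson) re-run through the identical search; p =
(1 + #shuffles achieving a site with score <= observed and category <=
observed) / (n_shuffles + 1), 1000 shuffles by default, 100 in tests and
the synthetic runs. This self-contained null was chosen because it is
calibratable at desk scale; it is not the p-value of any external tool.
Retention requires p < 0.05 and raw cleavage-site abundance > 4 (both
strict; "abundance" is raw reads at the site). t-plot tables (position,
abundance, cleavage flag) and figures are emitted per retained hit.

## Numerical and determinism choices

- Folding energies are integer kcal/mol, so DP ties are exact; traceback
  tie-breaking is fixed. numba JIT accelerates the O(n^3) DP with a pure
  Python fallback.
- All randomness flows from one seed through named SeedSequence streams;
  per-library streams make read generation order-independent.
- Tables are written with a fixed float format and sorted, deterministic
  row orders; identical config + seed produces byte-identical outputs.
- Tag order is descending total count with lexicographic ties; cluster and
  candidate processing follow genomic order.
- Degenerate inputs: empty libraries raise (RPM undefined); all-zero count
  rows get conventional DE output; profiles without reads cannot be
  categorized; miRNAs with fewer than 3 distinct dinucleotides cannot be
  shuffled and raise.

## Known limitations

- The simplified pair-energy model scores random RNA generously (interior
  loops are free), so absolute energies are not comparable to Turner-model
  folders; discrimination relies on the structural gates above.
- De novo locus discovery recovers ~90% of planted duplexes (folding in
  arbitrary flanking context occasionally hides a stem); annotation mode
  recovers > 95% and is the default when loci are supplied.
- Ungapped target alignment only (no bulged targets); genome-wide (non-CDS)
  degradome mapping, phased-siRNA loci and interaction-network queries are
  out of scope.
- The generator does not model sequencing error, PCR duplication,
  chloroplast/structural RNA contamination (an exact-match exclusion list
  hook exists, empty by default) or isomiR proportions varying across
  conditions.
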