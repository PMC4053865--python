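# Methods

This note documents the models, parameters and numerical choices behind
`bacmap`, in the spirit of a methods supplement. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Band space and Sulston scoring (`bacmap.fingerprints`)

HICF sizes labeled restriction fragments of 50–500 bp in four fluorescent
channels. For scoring, each raw size is multiplied by a scale factor
(default 30) and shifted by `channel_index x 15,000` so the four channels
occupy disjoint intervals of one unified axis of span 60,000. Two bands
match when they differ by at most the tolerance (default 12 units); the
number of distinguishable band slots is therefore
`D = (500-50) x 4 x 30 / (2 x 12) = 2,250`.

The Sulston score is the upper binomial tail over the smaller clone's
band count, with the exact (not linearized) single-band chance-match
probability `p = 1 - (1 - 1/D)^{n_hi}`. It is evaluated in log space
(log-sum-exp over `gammaln` terms; the bulk path uses the regularized
incomplete beta and falls back to the exact summation below double
underflow, clamped at 1e-320). Which of the two band counts enters the
tail is not dictated by the formula's provenance; the smaller count is
used, which is the conservative choice (larger tail) and makes the score
symmetric.

Band matching is a greedy two-pointer sweep over the sorted lists. For
points on a line with a fixed tolerance this greedy matching attains the
maximum cardinality; the test suite verifies it against a brute-force
bipartite matcher.

With these defaults, two average (~105-band) fingerprints sharing >30% of
their bands score below 1e-15 — the correspondence the network cutoff is
built on — while 10^5 random null pairs essentially never do (tested).

## 2. Synthetic chromosome generator (`bacmap.synthetic`)

The generator emulates a flow-sorted wheat chromosome arm at 1:10 scale
by default (31.4 Mb for a 314 Mb arm) and is the source of ground truth
for every downstream test. Coordinates are kb, 0-based, half-open, with
the centromere at 0.

**Restriction sites.** Each enzyme's sites follow an inhomogeneous Poisson
process whose rate interpolates linearly from a centromeric to a telomeric
value. Defaults (sites per 100 kb, centromere → telomere): HindIII
50.1 → 42.8; HaeIII 422.1 → 349.3; BamHI 27.2 → 20.4; XhoI 25.5 → 18.9;
EcoRI and XbaI flat at 25 (no gradient is reported for them, and flat
rates are the neutral choice).

**Fingerprint model.** The four labeled channels are BamHI, EcoRI, XbaI
and XhoI, with HaeIII as the frequent secondary cutter. A sized fragment
runs from a labeled site to the next cut site of any fingerprinting
enzyme (or the clone end) and is retained when its length falls in the
50–500 bp calling window. This reproduces the observed direction and
magnitude of the band-count gradient (more bands per clone near the
centromere, ratio ≈ 1.16 between the arm's extreme fifths) because the
labeled-enzyme site density, not the fragment-length distribution,
dominates the band count. Band-position jitter (Gaussian, default sd 2
band units against tolerance 12) and band dropout (default 5%) are
applied after unification. The jitter and dropout defaults are a
deliberate mid-level noise: strong enough that borderline overlaps
(~30% shared) are unreliable and the adaptive assembly machinery is
genuinely exercised, weak enough that the ~50%-overlap regime stays
clean.

**Gene space.** Genes (default 380 = 1:10 of an approximately 3,800-gene
arm) sit on a linear density gradient. The configurable
`density_ratio_tel_cen = 2.36` is defined as the ratio of *mean density in
the telomeric fifth to the centromeric fifth* (the measurable regional
contrast); the endpoint ratio of the linear profile is derived from it
(R ≈ 3.05). 76% of genes belong to islands of 2–3 members placed within
one mean insert (113 kb) of their island anchor (offsets centered, so
islands do not bias the gradient); the remainder are singletons from the
same gradient.

**Clone library.** The partial digest walks past a geometric number of
uncut HindIII sites, giving an exponential-like pre-selection insert
length; size selection keeps 100–200 kb. Because sampling that law by
rejection would discard >99.9% of draws, the implementation samples the
size-selected length directly from the truncated exponential whose scale
is calibrated (Brent root-finding) so the post-selection mean equals the
configured 113 kb, then snaps the right end to the next HindIII site.
Clone counts are fixed fractions: `round(n x purity)` target clones
(default purity 0.81), `round(n x contamination_rate)` chimeras (default
2%, two target intervals at least ten inserts apart), the remainder
decoys. Decoys are cloned from an independent equal-length chromosome
generated with a distinct seed stream, giving them realistic but unlinked
fingerprints. Default `n_clones = 4,941` yields 14.4 arm equivalents
(4,941 x 113 kb x 0.81 / 31.4 Mb), the coverage regime of the real
library at 1:10 scale. A caveat of the single-decoy-chromosome design:
unlike a real sorted-fraction background (scattered genome-wide), decoys
at 3–4x coverage assemble into contigs of their own, so raw
coverage-versus-arm summaries exceed 1; truth-based scores separate the
sources.

**References and synteny.** Three reference gene orders share the truth
order for syntenic genes. A gene is non-syntenic overall with probability
linear in position, calibrated so the centromeric and telomeric
deletion-bin means are 0.42 and 0.58; overall-syntenic genes are retained
per reference with probabilities (0.92, 0.74, 0.72), reproducing the
primary reference's higher synteny share. Non-syntenic genes are
relocated to a random reference position or dropped (50/50). Reference
coordinates contract by a linear expansion gradient whose
telomeric-bin/centromeric-bin contrast is configurable (default 2x). One
inversion spanning 15% of the syntenic genes is planted in the distal
region of the primary reference (the reference-lineage case a zipper
corrects); with `shared_inversion=True` the same physical window is
reversed in all three references, emulating an inversion in the query
lineage — the detectable case for colinearity-break analysis.

**Determinism.** Every operation draws from
`default_rng(SeedSequence([seed, stream]))` with a fixed stream id per
stage, so identical configurations are bit-reproducible and stages can be
re-run independently.

## 3. Assembly (`bacmap.assembly`)

The overlap network contains every clone pair scoring at or below the
network cutoff (1e-15). For large inputs an inverted-index prefilter over
two half-offset coarse band grids (bin width = 2 x tolerance) selects
candidate pairs by co-occupancy count; any two bands within tolerance
share a coarse bin in at least one grid, so the summed count upper-bounds
the true matched count. The per-pair candidate threshold is the minimal
significant match count for the pair's band counts minus a safety margin
of 4 (absorbing duplicate-band collapse within a bin); pairs below it
cannot be significant. The prefilter is verified against the exact
all-pairs path on a full noisy library.

Questionable material is annotated, never deleted:

* **Q-overlap** — parallel support (common network neighbours of the two
  ends) below 2. "Multiple parallel connections" is read as at least two,
  the weakest reading; configurable.
* **Q-clone** — fingerprint below `min_bands` (default 30); promiscuous
  (more than 500 overlaps stronger than 1e-50); or *branch-inducing*: the
  clone's trusted neighbourhood splits into two or more mutually
  non-overlapping groups. The last rule is the network signature of a
  chimera (its two halves' neighbours share no overlap) and is applied
  before any ordering; at default scale it recovers essentially all
  planted chimeras with no false positives on pure clones. It matters
  because chimeric shortcut edges otherwise destroy the spectral geometry
  of the clone order.

Contig assembly takes connected components of the trusted subnetwork,
orders each by **spectral seriation** (Fiedler vector of the shared-band-
weighted Laplacian; dense eigendecomposition up to 400 clones,
shift-invert Lanczos with a deterministic start vector above), and checks
**linearity as the consecutive-ones property**: every clone's closed
neighbourhood must occupy a contiguous rank run. Non-linear components
are repaired by flagging rank-split branch clones (at most 5% of a
component per pass — a mass of apparent branch points means the order
itself is unreliable), by exhaustive single-clone-removal search in
components of at most 40 clones, or re-clustered at the stricter cutoffs
1e-25 → 1e-30 → 1e-33; a component still non-linear at maximum stringency
is kept as a `branched` contig rather than dropped. With realistic clone-
length variation the strict consecutive-ones test fails even noise-free
(a long clone can reach past a short one's horizon), so large contigs
typically finish `branched` at high stringency — mirroring the original
strategy of assembling at 1e-15 through 1e-33 — while their clone order
remains essentially exact (|Spearman rho| ≥ 0.98 noisy, ~1.0 noise-free).

Start coordinates accumulate unshared-band counts between rank
neighbours, scaled by kb-per-band = mean insert / mean band count.
Fragments truncated at clone ends are sized in one clone of an
overlapping pair but not the other, adding ~2 spuriously unshared bands
per adjacency (about one in-range truncated fragment per clone end);
this constant is subtracted, bringing noise-free length estimates within
~6% of truth. Ties everywhere break by (score, shared bands, clone id),
and each contig's orientation is canonicalized, so assembly is invariant
to clone input order.

## 4. MTP and scaffolding (`bacmap.scaffolding`)

The MTP is the hop-count-shortest chain from the first- to last-ranked
clone over overlaps at the MTP cutoff (default 1e-25, the middle of the
30–50%-overlap regime; ties broken by total significance). Unspannable
contigs yield partial chains with explicit gaps. Contig-ending clones are
those overlapping the terminal MTP clone but no interior one.

Junctions between contig ends are scored at the relaxed 1e-15 cutoff
using all parked Q material: direct end-clone overlaps, or a single
bridging clone contributing the weaker of its two links (the
conservative, weakest-link reading). Clones flagged branch-inducing are
excluded from bridging — reusing a suspected chimera to join contigs is
exactly the false-join trap. Per end, the strongest parallel-confirmed
candidate wins; an unconfirmed candidate is accepted only when it beats
the next best by at least 5 orders of magnitude, else the end stays
unmerged (ambiguous). A junction is realized when both of its ends choose
it; merging is greedy by ascending score with cycle rejection, fixes
relative orientations, and serializes its evidence (clone pair or bridge,
score, validation class, connection count) so every merge is auditable.
Scaffold length sums contig lengths minus the estimated junction overlap,
or plus one mean insert for bridge joins.

N50/L50/N90/L90 follow the standard definition (length and 1-based index
where the descending cumulative length first reaches 50%/90% of the
total), verified against a brute-force oracle.

## 5. Anchoring (`bacmap.anchoring`)

The zipper backbone is the primary reference's syntenic gene order; genes
missing from it but syntenic in both other references are zipped in at
the rank interpolated from those references' coordinates; a known
primary-lineage inversion interval is reversed back. Zipper entries
record only *syntenic* homolog positions — a relocated copy is not a
colinear anchor.

Scaffolds are placed at the **median** zipper index of their markers
(robust to isolated non-syntenic markers), oriented by the Spearman
correlation between within-scaffold marker coordinates and zipper index
(recorded as unknown below |rho| = 0.5 or with fewer than 3 informative
markers rather than guessed), and binned by marker majority with ties
flagged. Markers hitting clones in more than one scaffold are excluded
and logged. Anchoring is invariant under global zipper reversal
(orientations flip, order reverses; tested).

Colinearity breaks: per reference, the homolog positions of the
query-ordered syntenic genes define steps; a step is discordant when its
sign opposes the reference's global orientation. Discordant steps mark
the query-adjacent pairs they span; maximal runs of pairs discordant in
at least two references and spanning at least three genes are breaks
(single-reference runs are reported separately, sub-threshold spans as
singletons). This definition recovers a reversed block's boundary genes
exactly and classifies a single relocated gene as a singleton, because a
lone relocation produces exactly one discordant step (two spanned genes).

Deletion bins: the six cytological fractions (33/22/11/10/7/17% of the
arm) define the synthetic bin bounds; established bins I–V merge the two
satellite bins into bin IV. The bin-to-zipper-interval mapping is taken
from truth gene positions, standing in for the EST-based mapping a real
arm provides. The real study's homology-search thresholds (BLAST
e-values, BES identity rules) have no synthetic counterpart: homology is
a generator label here.

Scaling: `L_W = (1/coverage_fraction) x (L_arm / L_ref) x L_segment`;
per-bin expansion divides a bin's anchored scaffold length by the span of
its zipper interval in the chosen reference.

## 6. Pool deconvolution (`bacmap.pools`)

The design pools clones along plates, rows (A–P) and columns (1–24); the
full 17-plate layout gives 57 pools. Signals are log-intensities from a
two-component Gaussian model (background mean 8, sd 0.5; signal mean 11,
sd 0.8 on a log2-like scale typical of two-color arrays), with
independent per-cell false positives (default 0.0019, the rate at which
the closed-form chance of ≥2 positive pools among 57 is ≈0.006) and false
negatives (default 0.02). The positivity threshold defaults to the
background mode plus 3 robust SDs (median/MAD of the lower half).

A candidate clone must have **all three** of its pools positive: with
densely re-arrayed plates, two positive pools constrain only two
coordinates and cannot single out a well, so probes that lose a pool to a
false negative stay unresolved rather than being guessed. Exactly one
consistent clone is `unambiguous`; several, all mutually overlapping in
the assembly network, are `multi_consistent`; anything else (including
combinatorial ghost addresses from multi-clone probes) is unresolved.
Candidates are ranked by the summed signal-vs-background log-likelihood
ratio over their three pools, and the maximum-likelihood candidate must
itself be pool-consistent. The resulting behavior — roughly a third to a
half of probed genes resolved, with near-perfect accuracy on resolved
calls (both computed by the test suite) — reflects a deliberate design
bias toward precision over yield, the trade-off pooled screens make when
unresolved probes can be recovered later by PCR on the pools.

The chance-call probability is closed-form,
`P = 1 - (1-f)^K - K f (1-f)^{K-1}`, verified against Monte-Carlo.

## 7. Gene-space statistics (`bacmap.genespace`)

The interval test filters contigs above 1 Mb, apportions the 1,000
intervals across them by largest remainder (equal-length pieces within a
contig, exactly N overall), bins genes, and compares the integer observed
0/1/2+ occupancies with the closed forms by chi-square (2 df). Observed
counts here are integers by construction; fractional interval
bookkeeping is not emulated. A vanishing expected class contributes
nothing when its observed count is zero. Uniform-placement calibration
(class frequencies within 3 SE, ~5% rejection at alpha 0.05) is part of
the test suite.

Gene islands are connected components (≥2 genes) of the gene graph whose
edges join genes on the same clone or on clones overlapping at the
assembly network cutoff (1e-15); detection is independent of input
order. Note an intrinsic property of this distance-based definition: at
the default synthetic gene density (~12 genes/Mb against a ~113 kb clone
length) chance co-location alone merges most singleton genes into
islands, so the detected fraction substantially exceeds the planted
island fraction; conversely, measuring on the deconvolved unique-address
subset breaks islands by subsampling and under-recovers. The detected
fraction is therefore reported as what it is — a property of the gene
spacing process under this definition — rather than an estimator of the
planted parameter.

Restriction profiles accept per-enzyme site maps or a DNA sequence (all
six supported recognition sites are palindromic, so single-strand motif
counting suffices); `emit_fasta` realizes a site map as a concrete
sequence with spurious motif occurrences destroyed, up to collisions
between sites of different enzymes closer than one motif length.

## 8. Pipeline and formats (`bacmap.pipeline`, `bacmap.io`, `bacmap.cli`)

Stages (`simulate → assemble → mtp → scaffold → pools → anchor →
genespace`) communicate through serialized artifacts (band files, TSV
tables, AGP, JSON reports) in the output directory, so each can be rerun
alone; a missing input fails with the stage name. The resolved
configuration is serialized next to the outputs; unknown YAML keys are
rejected. Band files round-trip byte-identically in the native dialect
and interoperate with the FPC `.sizes` layout.

## 9. Problem sizes and limitations

Default test and acceptance runs use the 1:10-scale arm (4,941 clones);
unit tests use a 3 Mb arm at the same coverage, chosen so the whole suite
exercises every stage at full statistical structure in about two minutes.
Known limitations: decoy contamination forms one coherent chromosome
rather than a scattered background (see §2); the synthetic bin model uses
clean boundaries without the satellite/Nor mapping ambiguity of a real
arm; homology is a generator label, not an alignment; FPC's consensus-
band map is out of scope (only summary metrics are computed for
comparison tables); and passing recovery tests on this generator shows
the machinery is correct under its stated statistical structure, not that
real wheat data lacks further pathologies (repeat-driven band sharing,
plate effects, partial digestion biases).
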