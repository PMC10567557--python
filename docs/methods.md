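# Methods

`peginsert` models and measures the efficiency with which short DNA
sequences (1–69 nt) are written into a genomic site by prime editing. This
note documents the model, the processing conventions, the synthetic-screen
generator, and the numerical choices a maintainer would want to know.

## The pegRNA data model and orientation

A pegRNA is a Cas9 guide with a 3' extension consisting of a
reverse-transcriptase template (RTT) followed by a primer binding site
(PBS). The PBS anneals to the nicked genomic strand; the RT copies the
template so that the insert, then a homology arm (HA) matching the genome
downstream of the nick, are appended to the nicked strand as a 3' flap.

Every insert is stored as its *written* sequence — 5'→3' on the edited
genomic strand — and pegRNA-side sequences are always derived as reverse
complements, never stored. Because the RT copies the insert first, the
extension assembles as

    extension (5'→3') = revcomp(insert + HA) + PBS

i.e. `revcomp(HA)` sits next to the scaffold and `revcomp(insert)` next to
the PBS. The nick is a zero-width boundary; offsets (e.g. a "+9" variant)
are 1-based downstream of it. Default geometry is a 13-nt PBS and a 34-nt
HA.

## Structure features

Secondary structure is scored by minimum-free-energy folding (ViennaRNA,
37 °C, standard RNA nearest-neighbour parameters; the parameter set is a
pinned property of the environment and MFE values can drift ~0.5 kcal/mol
between parameter releases). Because MFE scales with length, the model
feature is a **z-score**: the observed MFE standardized against 1,000
uniform-random inserts of the same length folded in the same fixed context
(insert alone, insert+HA = the RTT, the full extension, or
insert+scaffold). Negative z means stronger-than-average structure.
Backgrounds are seeded and cached per (length, context), which makes
whole-library scoring cheap. A degenerate background (sd 0, e.g. a 1-nt
insert alone) reports z = 0 with a flag.

Two discrete structure features describe interactions with the guide
itself:

- **Spacer pairing** (0–3): on a two-strand co-fold of (spacer + first
  scaffold G) with (revcomp of the first 3 written insert nt + PBS), the
  number of insert-side nucleotides paired into the spacer strand. The
  two-strand construct avoids artifactual linker pairings. Extended
  pairing into the protospacer can sequester the spacer and lower editing.
- **Scaffold loop disruption**: the full scaffold is folded together with
  the pegRNA-side insert; a stem-loop is called disrupted when ≥3 of its
  bases pair with insert bases. The default loop intervals are the three
  hairpins of the 86-nt improved scaffold's own MFE structure
  (repeat:anti-repeat duplex = loop 1 at 1–40; the two 3' hairpins at
  59–70 and 71–86). The ≥3-base threshold exists because single-base
  contacts into transiently unpaired regions occur for most random
  inserts and carry no signal; with it, ~7% of random 20-mers disrupt
  loop 1 while designed complements always do. Loop coordinates and the
  threshold are configuration.

## The ten-feature model

The gradient-boosted regressor (XGBoost) uses: insert length; %C, %A, %T
of the written insert (%G implicit, to avoid collinearity); RTT structure
z; MMR proficiency of the cell line; spacer pairing count; complementarity
of the first insert nucleotide with the +1 nick-site base; the maximum
adenine run (≥4 A on the written strand is ≥4 T on the U6 cassette — a
Pol-III terminator that truncates pegRNA transcription); and loop-1
intactness. Hyperparameters: 100 trees, learning rate 0.1, depth 4,
minimum loss reduction 0.1, L1 1e-5, L2 0.1, full column subsample.

Targets are insertion efficiencies z-scored within each screen and
replicate, so the model predicts *relative* efficiency; a screen's mean
and sd invert predictions back to percent rates (floored at 0). Splitting
is grouped by insert sequence — every measurement of an insert, across all
sites and lines, lands on one side — so held-out performance reflects
unseen sequences. The z-scoring inside screens uses the population sd
(each group is a whole screen, not a sample). Attribution uses exact
tree-path additive contributions (the TreeExplainer algorithm as shipped
inside XGBoost); contributions plus bias sum exactly to the prediction.

A 53-feature extended set (melting temperature via the SantaLucia
nearest-neighbour model at default salt, alternative folding contexts,
dinucleotide fractions and further cheap descriptors) is available for
feature-set comparisons; its exact roster beyond the named features is a
versioned package choice (`EXTENDED_MANIFEST`).

## Screen processing

Counting is exact, ungapped string matching of each insert flanked by
fixed anchors — 10 nt of target-site sequence per side for the target
amplicon, 15 nt of pegRNA plasmid sequence for the pegRNA amplicon — with
zero mismatches, so only insertions at the nick are counted. Insertion
efficiency = (target-amplicon frequency) / (pegRNA-amplicon frequency).
Inserts with fewer than 20 pegRNA reads in *any* replicate are dropped
from all replicates (the filter applies to the pegRNA amplicon only).
These ratios underestimate absolute rates (uninfected cells and unmatched
pegRNA reads are not corrected for); all downstream analysis is relative.

Outcome classification operates on reads trimmed to a fixed window from
10 nt upstream of the PBS to 60 nt downstream of the nick (83 nt for an
indel-free read with a 13-nt PBS), through a sequential decision tree:
exact library insertion → N-containing reads dropped → exact reference
(unedited) → reference length (substitutions only) → scaffold integration
(≥5 scaffold nucleotides, GCACC, directly after the RT template product)
→ mutated insertion (optimal-string-alignment distance ≤3 to a library
insert >10 nt; short inserts are excluded because near-misses saturate) →
duplication (≥2 HA copies) → deletion overlapping the nick ±10 nt → other
deletion → other. The "unedited" branch requires the exact reference
window rather than only the intact 20-nt nick context: with a
substring-level check, deletions distal to the nick would be absorbed
into "unedited" and the other-deletion class would be unreachable.
Deletion intervals come from longest prefix/suffix matching against the
reference; reads mixing deletions with substitutions fall to "other".

Per-position substitution rates are tallied over indel-free reads only; a
known non-reference allele (e.g. a +9 SNP present on one chromosome copy)
is excluded from mutation calls and its frequency reported separately.

Normalizations: length-relative rates divide by the median of same-length
inserts (<10 nt) or of the length bin (10–14, 15–19, 20–24, 25–29, 30–39,
40–49, 50–59, 60–69); two library sets measured in separate screens are
merged by scaling the second by the ratio of shared-insert means and
averaging the shared inserts.

## The MMR exponential model

Mismatch repair excises short (<~13 nt) heteroduplex insertions, so losing
MMR boosts short inserts most. After scaling the two genotypes to equal
means on >13-nt inserts (removing the screen batch factor), per-insert
KO/WT fold changes are fit by nonlinear least squares on the ratio scale:

    ratio(L) = a · exp(−b·L) + 1,   a > 0, b > 0

initialized at a = max(ratio) − 1, b = 0.5, bounded a ∈ (0, 1e3],
b ∈ (0, 5]. The fold change at L = 1 is a·e^(−b) + 1; the per-nt decay of
the MMR benefit is 1 − e^(−b); variance explained is 1 − SS_res/SS_tot on
the ratio scale. Fitting in ratio space (not log-ratio) is the default; a
caller can fit log-ratios by transforming inputs.

## The synthetic-screen generator

The generator is the test bed for every stage. Ground-truth log percent
efficiency of a design is

    log rate = μ + f(L) + β_C·(%C − 25) + β_z·z_RTT
               − log(4.8)·[max A-run ≥ 4] − log(a·e^(−bL) + 1)·[MMR+]

with defaults: baseline μ = log 3 (a few percent, typical of a
mid-efficiency screen); a piecewise-linear length curve f with a boost at
3–4 nt (×2.8), a plateau at 15–21 nt (×1.45) and decay beyond 30 nt
(reaching ×1/6 at 69 nt); β_C = log 1.022 (+2.2% relative rate per
percentage point of cytosine); β_z = −0.18 (≈ +20% per sd of structure
strength); a 4.8-fold expression penalty for Pol-III terminator runs; and
MMR parameters a = 25, b = 0.58 (fold change ≈15 at 1 nt, ≈44% decay per
nt). Replicate noise is multiplicative lognormal (default sd 0.5 on the
log scale; replicate scatter on the rate scale is heavy-tailed). Screens
are sampled with lognormal plasmid abundances (sd 0.5), multinomial
pegRNA-amplicon counts over abundance, and target-amplicon reads as a
mixture of unedited reads, correct insertions (∝ abundance × efficiency)
and spiked indel categories; reads are emitted as exact flank-anchored
strings (FASTQ with constant qualities — quality is never consumed).

What the generator does *not* emulate: sequencing errors and PCR bias,
target-site-specific activity differences, spacer-pairing or
loop-disruption effects on efficiency (those features carry no signal in
synthetic data), and correlated replicate structure. Passing tests
therefore demonstrate that the pipeline and model recover the encoded
effect structure under realistic counting and measurement noise — not
that real screens contain only these effects.

## Problem sizes and numerical choices

The validation suite uses the generator at the scale the effects were
characterized: 3,000 inserts across two repair contexts for predictor
recovery (held-out grouped split, Pearson R ≥ 0.8 with attribution signs
matching the generator), 2,000 inserts × 20 noise seeds for MMR parameter
recovery (a within ±20%, b within ±15% in ≥90% of seeds, with lognormal
sd 0.3 on the fold changes), 1,000 inserts per length for z-score
self-normalization (|mean z| < 0.1), and exact-count oracles for the read
pipeline. Background folding uses 1,000 samples (resampling error on z
≲0.15); structure backgrounds are cached per length and context. All
randomness flows from explicit seeds; tree training is single-threaded
and bit-reproducible, and a fixed seed reproduces byte-identical CLI
outputs.

## Known limitations

- Target-site effects are represented only through the HA-dependent
  folding context; no guide-activity score is modelled.
- The MMR model is phenomenological; it does not simulate repair
  intermediates.
- Exact loop boundaries on the scaffold and the composition of the
  extended feature set beyond the named features are package choices,
  exposed as configuration.
- Counting requires pre-merged reads and exact anchors; no gapped
  alignment or quality filtering is performed.
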