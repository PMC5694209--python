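# Methods

This note documents the models, parameters and design choices behind
`mtfscan`, and what its synthetic benchmarks do and do not demonstrate.

## Problem

A membrane-bound transcription factor (MTF) is a TF carrying at least one
transmembrane (TM) helix; it is held dormant at a membrane and activated by
proteolytic release or by an alternative splice isoform lacking the TM
segment. Identifying MTFs genome-wide reduces to calling TM helices on TF
protein sequences with high confidence, which no single predictor does
reliably — predictors built on hidden Markov models, neural networks and
hydrophobicity profiles disagree substantially on borderline proteins. The
pipeline therefore combines predictors in two branches and unions the calls.

## Built-in hydropathy predictor

**Profile.** Each residue *p* gets a trapezoid-weighted window average of a
hydropathy scale: weight 1.0 across an 11-residue core, decaying linearly to
1/6 across 5-residue wedges on each side (full window 21). At sequence ends
the window is truncated and renormalized by the weights actually applied, so
short sequences are still scored; a single residue scores its raw scale
value. Two scales ship as plain-text resources: **GES**
(Goldman–Engelman–Steitz transfer free energies, kcal/mol, hydrophobic
positive; the default) and **KD** (Kyte–Doolittle). The unknown residue X
scores 0 on both.

**Segment calling.** Candidate segments are maximal profile runs ≥ the lower
cutoff (0.6 GES units); runs separated by a gap shorter than `min_loop_len`
(2) are merged; surviving runs shorter than `min_helix_len` are dropped. A
kept run whose peak reaches the upper cutoff (1.0) is graded *certain*,
otherwise *putative*. The cutoffs 1.0/0.6 and the 11+2×5 window follow the
classic hydrophobicity-profile convention for this predictor class.

`min_helix_len` applies to the *profile run*, not the physical helix, and
defaults to **9**. With a 21-residue window, smoothing erodes each end of
the above-cutoff run by roughly the wedge width when the flanks are
hydrophilic — and by more when they are strongly charged (Arg/Asp-rich
flanks can erode a 19-residue helix's run to 10 positions). A run of 9 thus
corresponds to a physical helix of roughly 15–17+ residues, the accepted
minimum for a membrane-crossing helix. Setting the floor at the helix scale
(17) would silently reject real-length helices with charged flanks.

**Orientation.** The positive-inside rule: both alternating loop labelings
(first loop inside vs outside) are scored by counting K+R in the loops
labeled `i`, considering at most `loop_charge_window` (15) loop residues
adjacent to each membrane span; the larger inside count wins, ties going to
first-loop-inside. Charged residues far from any span are deliberately
ignored — the rule's empirical support concerns membrane-proximal charge.

## External predictors and the two-branch decision

Third-party predictors enter as parsed reports only (TMHMM long format,
TMHMM plp posterior tracks, or a generic `id<TAB>{i,M,o}-string` format);
no binary is executed. Non-alternating loop labels in foreign topology
strings are accepted as written but flagged.

**Agreement.** Two predictions agree iff they have the same span count,
corresponding spans overlap by ≥ `min_overlap` (5) residues (capped by the
shorter span's length, preserving reflexivity for degenerate spans), and —
when both have spans — the same N-terminal loop state. Span-free predictions
agree regardless of loop label: different tools emit all-`i` vs all-`o` for
soluble proteins, and orientation of a non-existent membrane topology is
meaningless; requiring it would artificially split the soluble consensus
class.

**Consensus.** Predictions are visited in a fixed priority order (HMMTOP,
PHOBIUS, S-TMHMM, TOPPRED, SCAMPI, MEMSAT, then the built-in predictor,
then anything else alphabetically); each joins the first existing class
whose *founder* it agrees with, else founds a class. Greedy clustering
against founders makes non-transitive agreement deterministic. The largest
class wins; ties resolve to the earlier-founded (higher-priority) class.
The winner may be soluble.

**TMHMM branch.** A TMHMM helix survives iff its per-residue membrane
posterior summary is strictly > 0.90. The summary statistic is the **mean**
over the span by default (`min` available via config): the mean is less
brittle to a single low-confidence edge residue while still demanding
uniformly strong support. Without a posterior track, helices pass
unfiltered with a logged warning.

**Merge.** A protein is an MTF iff either branch calls ≥ 1 span (set
union). When both fire, the consensus spans are reported; provenance
records every branch that fired.

## Span location classes

A span is N-terminal if its midpoint m ≤ n_frac·L, C-terminal if
m > (1−c_frac)·L, else central; n_frac = c_frac = 1/3 by default. The
boundaries are design choices — no standard numeric definition of
"N-terminal region" exists — so the fractions are configurable and recorded
in every report header. Boundary midpoints resolve toward the terminal
classes (≤ for N, > for C), stated explicitly for reproducibility; the
half-open boundaries make mirror symmetry exact except within one residue
of a zone edge. Percentages round half-up (not banker's) at one decimal,
matching how printed count ratios in this literature round. For
two-span proteins the patterns NN, CC and NC are tabulated and everything
else is reported as an explicit "others" bucket rather than dropped.

## Alternative-splicing screen

A locus is ALS-activatable when some variant isoform (a) has zero predicted
TM spans and (b) retains the reference's TF domain. Condition (b) is
operationalized as ≥ 90 % of domain positions aligned to identical residues
in a global alignment (match 2, mismatch −1, gap run of length k scoring
−5 − k). Domain intervals are caller-supplied; domain detection is out of
scope. The reference isoform is the one with predicted TM spans — the
longest if several, ties to the smallest id. Gaps and mismatches both count
as uncovered, so partial domain loss fails the screen. Alignment uses
biopython's pairwise aligner; among co-optimal alignments the first in its
deterministic enumeration order is taken, which can only move gap placement,
not the score. An intact nuclear-localization signal is *not* required —
only the domain condition is implemented.

## Synthetic fixtures

The generator emulates the computational shape of a TF-proteome screen:

- planted proteins: hydrophilic background (S,T,N,Q,D,E,K,R,G,P uniform)
  with contiguous hydrophobic blocks (L,I,V,F,A,M) of 19–23 residues
  centered in requested zones; multi-span proteins use distinct zones;
- decoys: hydrophilic background *adversarially resampled* until the whole
  default-parameter profile sits strictly below the lower cutoff, making
  the expected false-positive count exactly zero and turning specificity
  into a sharp assertion;
- isoform sets: a 300-residue reference (soluble-decoy background + one
  21-residue block at 181–201, domain interval 40–99) and a variant with
  the TM block and/or half the domain excised exactly.

Everything is seeded (numpy `default_rng`); seeds are recorded in FASTA
headers and identical seeds produce byte-identical files.

What passing these benchmarks shows: the profile arithmetic, segment
calling, consensus algebra, branch merge, classification, alignment
coverage and orchestration are correct, and the planted-helix recovery of
the built-in predictor is ≥ 95 % with zero decoy false positives at the
default parameters. What it does not show: performance on real proteomes,
where helices have heterogeneous composition, flanking regions are not
uniformly hydrophilic, and predictors disagree in structured ways. Real
TF-family biology (NAC/bZIP domain motifs) is not imitated.

## Problem sizes and numerical choices

The benchmark suite uses 500 planted + 500 decoy proteins for recovery, a
3 × 100-protein genome fixture for the end-to-end scan, 50 loci for the ALS
screen and 200 random sequences for the profile-oracle comparison — sizes
at which every property is sharp while the whole suite runs in seconds.
Profile equality against the brute-force oracle is asserted at 1e−9
(float accumulation order differs between implementations). Degenerate
inputs: empty FASTA yields an empty report and exit code 0; empty span
lists are valid predictions ("soluble"); empty MTF sets yield empty
summary tables, while percentage functions require ≥ 1 record because
their denominators would otherwise be undefined.

## Known limitations

- The built-in predictor is a single-scale hydropathy method; it has no
  notion of signal peptides (PHOBIUS-style discrimination must come in via
  adapters) and will call any sufficiently long hydrophobic stretch.
- Orientation is a two-way choice by loop charge; re-entrant and
  interfacial helices are out of scope.
- The consensus is span-count strict: predictors disagreeing on count never
  cluster, even if all their spans overlap.
- TMHMM "probability score" is interpreted as the mean per-span posterior;
  if the intended semantics was a different report field, the threshold
  comparison still applies unchanged via the `min` statistic or by
  supplying pre-filtered reports.
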