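# Methods

## Mass model

A linear peptide's neutral mass is the sum of its residue masses plus one
water; [M+H]⁺ adds one proton (1.00728 Da); the m/z of a multiply
protonated species is (neutral + z·proton)/z. Residue monoisotopic and
average masses are taken from pyteomics' standard amino-acid compositions
and exposed through a single `ResidueMassTable`; internal precision is the
full floating-point value, and rounding to the one decimal customary in
fragment tables is purely a formatting step.

Modifications are `ModificationSpec`s carrying a mass delta and a
site-eligibility rule:

| modification | Δmono (Da) | site rule |
|---|---|---|
| pyroglutamate | −17.0265 | N-terminal Gln only (not Glu) |
| hydroxylation | +15.9949 | Pro immediately followed by Gly |
| disulfide | −2.0157 per bond | ⌊nCys/2⌋ bonds maximum |
| carbamidomethyl | +57.0215 | per cysteine, **opt-in** |

Cysteines are free thiols by default: AFP preparations here are not
alkylated, and the fragment masses of Cys-containing peptides reproduce
only under that assumption. The hydroxylation site rule is the
collagen-like X-P-G constraint, implemented as "P immediately followed by
G" (equivalent for internal prolines; a peptide-terminal Pro whose
follower is unknown is treated as ineligible). Intact protein masses use
the average scale with a disulfide correction defaulting to all cysteines
paired — bond counts are predicted from Cys counts, not pairing topology.

b-ion rung *n* is the first *n* residue masses plus a proton; an
N-terminal pyroglutamate shifts every rung, hydroxylations shift rungs at
and after their site (sites filled leftmost-first). The final rung equals
[M+H]⁺ − water, which the tests use as an identity.

## Fold grammar and segmentation

Segmentation parses a mature sequence against the PPII bundle grammar:
maximal chains of consecutive, in-frame tripeptides whose first residue is
in the anchor alphabet (default {G}; a relaxed mode admits {G, A} since
real alignments show occasional non-Gly anchors). Chains are collected in
all three frame offsets and overlaps resolved greedily by coverage —
longest chain first, ties to the lowest start index — so each region
reports the frame that explains most of it. Chains of 5+ repeats are
split greedily left-to-right into helices of at most 4 repeats; a trailing
remainder of 1–2 repeats is dropped into the adjacent loop. Helices under
the default bounds are therefore always 9 or 12 residues. Gaps between
consecutive helices are loops, flagged canonical when 3–6 residues long;
sequence outside the first/last helix is reported as terminal tails rather
than loops (the literature does not classify them). Helices, loops and
tails partition the input exactly — a tested invariant.

Faces: consecutive helices alternate between the two layers of the
bundle. The layer whose pooled X₂ residues are richer in {A, S, T, V} is
labelled the ice-binding surface; on an exact tie the even-ordinal layer
is chosen, the convention reported for nine-helix AFPs. Which layer
starts the IBS varies between proteins, so composition decides and the
convention is only a tie-break.

AFP-likeness combines the two diagnostics used for these proteins —
glycine mole fraction and the fraction of residues inside anchored
tripeptide runs. Default thresholds (Gly ≥ 0.20, coverage ≥ 0.50) are
deliberately permissive screening values, both configurable; published
compositions of purified PPII AFPs sit far above them.

## Digestion and matching

Trypsin cleaves after Lys/Arg except before Pro. Zero-missed-cleavage
peptides tile the protein; up to *m* missed cleavages concatenate up to
*m*+1 consecutive tiles (default *m* = 1 for matching). Lys-Pro and
Arg-Pro bonds survive digestion but can break non-enzymatically in the
spectrometer source, so for every internal K|P / R|P junction both
flanking products are enumerated and marked non-tryptic. PTM hypothesis
enumeration crosses every combination of 0..min(max, n_sites)
hydroxylations over eligible sites with pyroglutamate on/off when the
peptide starts with Gln.

Fragment peaks are treated as singly protonated monoisotopic masses and
matched at an absolute tolerance (default 0.3 Da — fragment tables print
one decimal). A match is attributed to **every** isoform containing the
peptide as an exact substring, not only the digest it came from, because
near-identical isoforms share most fragments. Intact MALDI labels come
from linear-mode spectra of whole proteins, so they are compared as
average masses at a relative tolerance (default 0.2%), at which the
proton mass is negligible; each protein contributes its disulfide-corrected
base mass plus successive +16 Da hydroxylation satellites.

## Identity and grouping

Global identity uses a hand-written Needleman–Wunsch (match +1, mismatch
0, linear gap −1) with a deterministic traceback: match/mismatch over a
gap in the second sequence over a gap in the first. Percent identity is
100 × matches / alignment length, gap columns included in the
denominator. Because the tie-break selects one co-optimal alignment, the
inputs are sorted before aligning, which makes the operation symmetric by
construction. Published isoform identities come from unstated alignment
tools and parameters, so exact reproduction of particular percentages is
not claimed — the operation is documented and self-consistent instead.
The same scoring applies unchanged to nucleotide sequences. Grouping is
single-linkage at a percent-identity threshold (default 80); raising the
threshold can only refine the partition.

## Synthetic data

The generator emulates the study material — AFP families and their mass
observations — from the fold grammar: 6–13 helices (drawn uniformly when
unspecified) of 3–4 tripeptides, loops of 3–6 residues, an optional
19–24-residue signal peptide, and optional cysteines placed in loops
(where they appear in real bundles). X₁ is drawn glycine-heavy and X₂
from an Ala-rich alphabet on the IBS layer (chosen per protein with a
fair coin between the odd and even layer) or a polar/charged alphabet on
the other; weights were set once so mature glycine fractions land at
roughly 0.3–0.45, qualitatively matching purified AFP compositions — they
are descriptive defaults, not fitted values. Loops exclude glycine, which
makes helix boundaries unambiguous, and carry the Lys/Arg that make the
proteins digestible plus occasional Pro; a loop-final Pro ahead of a
helix anchor creates an X-P-G hydroxylation site, the only place the
grammar admits one.

Simulated MALDI lists contain each protein's average base mass plus a
ladder of +16 Da satellites up to a per-site binomial draw at the
hydroxylation rate (default 1/6 — on the order of one modified motif in
six); simulated fragment lists contain the [M+H]⁺ of every
zero-missed-cleavage peptide and in-source product with per-site
hydroxylation and (for N-terminal Gln) pyroglutamate draws. Gaussian mass
noise (default σ = 0.05 Da, a one-decimal instrument; σ = 0 for exact
round-trips) is additive. Family generation applies per-residue point
substitutions at a stated rate, with helix anchor positions protected by
default to emulate core conservation; the substitution alphabet excludes
Gly and Lys/Arg so mutation changes neither the repeat grammar nor the
digest map.

All randomness flows through one `numpy.random.default_rng(seed)` per
call — identical seeds give identical outputs on any platform.

What the generator does **not** emulate: intensity structure and peak
shape of real spectra, chemical noise and contaminant peaks, isotope
envelopes, charge states beyond 1+, indels between isoforms, and
non-grammatical sequence (e.g. His-rich AFPs of other folds). Passing
round-trip tests therefore demonstrates internal consistency of the
pipeline under the fold grammar, not performance on raw instrument data.

## Numerical and design choices

- Coordinates are 0-based half-open internally and in JSON; human-facing
  tables are 1-based inclusive.
- Fragment matching reports every candidate within tolerance rather than
  only the best, leaving disambiguation to the caller; recovery tests
  rank by |Δ|, then fewer modifications, then position. Note that Gly-Gly
  and Asn are exactly isobaric, as are Ser and hydroxylated Ala-sites —
  repetitive glycine-rich sequences make occasional exact collisions
  unavoidable at any tolerance.
- Shrinking the matching tolerance can only remove matches (tested
  monotonicity).
- Outputs are written atomically (temp file + rename); a failed run never
  leaves partial files. Same config + seed gives byte-identical JSON.
- Degenerate inputs: sequences shorter than one minimal helix yield a
  zero-helix model flagged non-PPII; fewer than two helices leave faces
  unassigned; empty peak lists and header-only CSVs are valid and empty.

## Problem sizes used in the test suite

Round-trip suites run 100 generated proteins for segmentation/face and
PTM recovery and 200 for digestion conservation, each a few hundred
residues — small enough to run in seconds while exercising every helix
count the grammar allows. The segmentation criterion expects ≥ 90/100
helix-count and ≥ 95/100 face recoveries and ≥ 95% PTM multiplicity
recovery at zero noise; the implementation currently achieves 100% on
all three, with the slack left for grammar edge cases, not tuned to the
observed rate.

## Known limitations

- Fragment termini beyond tryptic + K|P/R|P in-source products (e.g. the
  composite C-terminal ladders seen for very large fragments) are matched
  only via substring attribution, not reconstructed.
- Disulfide pairing topology, 3-D coordinates, docking and energetics are
  out of scope; so are signal-peptide prediction (cleavage sites are
  consumed as annotations), isotope envelopes, FDR estimation and de novo
  sequencing.
- Percent identity from other alignment tools will differ near indels;
  comparisons across tools should use the documented scoring.
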