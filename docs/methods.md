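# Methods

`mirest` re-implements, as a tested and reusable pipeline, the classic
homology-based ("comparative genomics") protocol for discovering plant
microRNAs in EST collections, together with the accompanying
target-prediction and conservation analyses.  This note records the
models, the operational choices made where the protocol is
under-specified, and what the synthetic benchmarks do and do not show.

## The discovery funnel

Known plant mature miRNAs are used as queries against an EST collection;
candidate loci must then survive a cascade of filters:

1. **Homology** — an EST window matches a reference mature with at most
   4 mismatches (substitutions plus gap columns) on either strand.
2. **Redundancy removal** — one representative ("single tone") EST per
   reference family.
3. **Coding filter** — ESTs that look protein-coding are removed.
4. **Hairpin structure** — the excised precursor folds into a stem-loop
   with minimum free energy ≤ −18 kcal/mol (or no worse than the
   reference hairpin), with at least 16 Watson–Crick/G:U pairs between
   the mature and the opposite arm (miRNA\*), the mature lying in the
   stem, and no large loop interrupting it.

### Alignment-free homology scan

BLASTn is deliberately replaced by an exact mismatch-bounded scan: the
acceptance quantity in this protocol is the mismatch count, not a BLAST
score, so an exhaustive Hamming scan over both strands (numpy sliding
windows) is both simpler and strictly more sensitive.  When indels are
allowed (the reference tables contain gapped matures), a banded
edit-distance search (edlib, infix mode) is used and gap columns are
charged against the same 0–4 budget; terminal overhangs are free.
Ties break to the leftmost window, then the + strand.

The "single tone" criterion is operationalized as ≥ 95 % containment
identity between hit-spanning regions (hit ± 100 nt); within a group the
longest EST wins, ties going to the smallest accession.  The protocol's
BLASTX-versus-nr coding check is replaced by a local six-frame ORF scan:
a record whose longest ORF (AUG → stop, open-ended at fragment edges)
reaches 100 codons is called coding.  Both thresholds are configurable;
the ORF heuristic is a documented proxy, not a similarity search.

## RNA folding

Secondary structures are predicted by our own Zuker-style dynamic
program over a simplified nearest-neighbour model:

- stacking free energies for the six canonical pair types
  (`data/stack_energies.tsv`, Turner-class values in kcal/mol);
- hairpin, bulge and internal-loop initiation penalties by size
  (`data/loop_energies.tsv`), with logarithmic extrapolation beyond
  size 30 and an internal-loop asymmetry penalty (0.6 kcal/mol per
  unit, capped at 3.0);
- a linear multibranch score (3.4 init + 0.4 per branch);
- minimum hairpin loop of 3 nt; G:U allowed everywhere; dangling ends
  and coaxial stacking omitted.

Energies are handled as integer centi-kcal/mol, which makes ties exact;
tie-breaking is minimum energy, then the larger pair count, then a fixed
traceback order.  The open chain is always admissible, so reported
energies are never positive.  An exhaustive enumerator over all nested
structures (≤ 18 nt) scores candidates with the *same* loop
decomposition and serves as the independent oracle: the DP equals the
enumeration minimum on hundreds of random sequences in the test suite.

Interior-loop search in the DP is capped at total size 30 (the standard
speed heuristic); the kernel is numba-compiled and handles windows up to
500 nt.

**What is not reproduced:** MFOLD 3.6 absolute energies.  The published
precursor MFEs depend on MFOLD's exact tables and are carried as
descriptive fixture data; the −18 kcal/mol screening threshold remains
meaningful because it is a configurable parameter of the same physical
quantity.

### Precursor excision and mature placement

Around each homology hit, candidate windows extend the hit by 0–250 nt
per side in 25-nt steps (defaults; the bundled pipelines use 50–75 nt
since their planted precursors are compact).  The window whose fold
maximizes the mature:star pair count, subject to the mature sitting in a
stem, wins; ties go to the shortest window.

Mature:star pairs are counted as the longest strictly-decreasing run of
partner positions across the mature — in a nested structure, pairs into a
single opposite arm are exactly such a run, so stray pairs into flanking
sequence or other branches are excluded.  The arm is 5′/3′ according to
whether the star lies downstream/upstream, "loop" when partners fall on
both sides, "split" when the mature pairs with nothing.  The largest run
of unpaired mature positions is reported as the loop/bulge proxy
(default tolerance 6 nt).

## Validation criteria

Each flag is evaluated independently: `mfe_ok`, `pairs_ok` (≥ 16),
`in_stem`, `mismatch_ok` (≤ 4), `noncoding_ok`; a candidate is accepted
iff all hold.  When the absolute MFE or pairing thresholds fail but the
candidate is no worse than its reference hairpin, the flag is granted
and `relaxation_used` records it — this is how the protocol retains
weak-but-conserved hairpins (e.g. a −10.6 kcal/mol precursor).  The
Methods value of 16 pairs is used rather than the 17 quoted later in
the source narrative; both are reachable via configuration.

Characterization reports distribution bins and scalar statistics.
Mature-level statistics run over rows; precursor-level statistics
(length, MFE) run over distinct precursor records, because a clustered
precursor contributes two matures but one hairpin — this is what makes
the reference precursor-length mean come out at 159 nt.  Parity means
are rounded half-up; GC% is truncated to 2 decimals, the convention the
printed tables evidently use.  A precursor with ≥ 2 non-overlapping
accepted matures is a polycistronic cluster; for fixture rows without
coordinates, co-resident matures are distinct iff their (sequence, arm)
pairs differ, which correctly calls the single vun-mir4414 cluster and
refuses the two families that share one EST region.

## Target prediction

Sites are scanned in the ungapped antiparallel register (miRNA position
*i* from the 5′ end against site position *L−i+1*).  A window passes at
≥ 75 % paired coverage (WC + G:U) and a penalty score ≤ 3.0 (mismatch 1,
G:U 0.5, gap 2) — the penalty is our stand-in for the expectation score
of server-side tools whose internals are not public.  The duplex is then
scored by summing the folding stack table over consecutive pairs, with
internal-loop penalties for mismatch interruptions; target structure is
ignored (hybridization-energy-only, as in RNAhybrid-class tools).

Acceptance requires hybrid energy ≤ −20 kcal/mol, a stringent seed —
all-WC pairing across miRNA positions 2–7 and/or 8–13 (G:U counts as
paired elsewhere but not inside the seed, configurable) — and ≥ 3
supporting pairs in the 3′ supplementary region (positions 17+).  For
matures shorter than 19 nt the supplementary requirement scales down to
the number of positions the molecule actually has beyond 16.

Functional categories come from first-match keyword rules over the nine
labels of the reference target table; unknown descriptions fall back to
"Hypothetical protein".

## Conservation and phylogeny

Matures are aligned by deterministic center-star progressive alignment
(center = minimal summed edit distance; "once a gap, always a gap"),
which is fully adequate for ≤ 26-nt near-identical sequences and
replaces ClustalW.  A position frequency matrix over {A,C,G,U,gap} with
per-column information content (2 − Shannon entropy of the gap-
renormalized base frequencies) substitutes for a rendered logo.  Trees
are built with textbook Saitou–Nei neighbor joining on p-distances
(gap columns excluded pairwise); ties in the Q criterion break to the
smallest node pair, negative branch lengths are clamped to zero with the
raw value recorded, and the output is an unrooted trifurcating newick
(branch lengths droppable for a cladogram).  NJ recovers additive
matrices exactly, which the tests verify against randomly generated
trees and against an independent implementation.

## Synthetic data

The generator emulates the study's inputs at desk scale: EST corpora
(uniform 300–900 nt, configurable GC bias; the reference set's 18–86 %
GC range motivates testing both extremes) with planted homologs at 0–4
mismatches on either strand, duplicate ESTs for dedup testing, coding
decoys with planted ORFs (backgrounds are rejection-sampled to stay
below the ORF threshold so the coding truth is exact), hairpin
precursors (mature + loop + mutated reverse complement, star mutations
placed as one contiguous non-pairing block so the planted pair count is
respected by the MFE fold), and transcriptomes with seed-perfect,
seed-broken and energy-failing target sites, all verified at
construction time.  A special pair-limited precursor places a central
C-run in an otherwise G-free environment, bounding the mature:star
pairing *by construction* rather than by the folding engine's choice.
Every feature is recorded in a JSON truth manifest; the same seed yields
byte-identical corpora.

What the synthetic benchmarks do **not** show: recovery of the published
discovery counts (46 miRNAs / 45 families from 187,487 ESTs), which
depend on the real dbEST release and reference set, nor MFOLD-exact
energies.  Those quantities are covered by the packaged reference-table
fixtures and by property tests, not by regression.

## Known fixture discrepancies (flagged, not reconciled)

- vun-mir2622's printed GC% (42.85) is inconsistent with its own printed
  22-nt mature (45.45 recomputed); the fixture stores the recomputed
  value and `validate_fixtures` reports the erratum.
- The narrative's function tallies (36 transcription factors, 15
  transporters) differ from the printed labels (35/16); Metabolism (37)
  and stress (15) agree.
- The narrative's mean precursor MFE (−40) does not recompute from the
  printed column (−41.49 over 45 precursors).
- The narrative credits "miR1882" with targeting pectin methylesterase;
  the target table lists vun-mir8182 for that target (probable typo).

## Problem sizes used by the test suite

Folding oracle: 500 random sequences ≤ 18 nt.  Screening: 20 seeded
corpora of 10 ESTs × 250–450 nt × 3 references, each checked against a
brute-force window oracle, plus 20 seeded hairpin constructs per flag.
Targets: 10 seeded transcriptomes with 5 planted sites each.  NJ: 25
random 4–8 taxon additive trees.  These sizes exercise every code path
while keeping the default suite fast; all are scaled up trivially via
the same APIs.
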