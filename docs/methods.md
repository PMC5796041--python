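# Methods

## The design problem

The package generates artificial protein sequences whose *predicted*
per-residue disorder probability is smooth and close to a user-chosen target
`Dt ∈ {0.55, 0.60, …, 0.95}`. Two statistics of a scored span drive every
decision: the mean score `D̄o` and the range `ΔDo = Do_max − Do_min`
(a smoothness measure). A sequence is acceptable when `ΔDo ≤ 0.15` and
`|Dt − D̄o| ≤ 0.025`, both bounds inclusive.

## The reference disorder scorer

Published disorder predictors of the pairwise-energy family are distributed as
binaries whose internal parameters are not printed; the original design
service used one as a black box. This package therefore defines a scorer
*contract* — deterministic `sequence → one score in [0, 1] per residue` — and
ships a documented reference implementation:

1. **Energy.** For residue `i`, the estimated energy is the mean of
   `E[a_i, a_j]` over all neighbors `j` with sequential separation
   `2 ≤ |i − j| ≤ 100` (the "long disorder" regime; termini simply have fewer
   neighbors). The symmetric matrix is the negated product of shifted
   TOP-IDP propensities, `E[a, b] = −(t_a − t_W)(t_b − t_W)`, where `t` is the
   TOP-IDP disorder propensity scale and W (the most order-promoting residue)
   anchors the shift at zero. Pairs of disorder-promoting residues therefore
   get the lowest energies, and substituting any residue by a more
   disorder-promoting one can only lower energies everywhere — making the
   mean score provably monotone in the marginal propensities.
2. **Transform.** `s = 1 / (1 + exp(slope · (e − midpoint)))`, strictly
   decreasing in the energy, with `midpoint = −0.70`, `slope = 5.0` (below).
3. **Smoothing.** A centered 21-residue mean, truncated and renormalized at
   the termini.

The implementation uses per-letter prefix sums (O(20·n) per sequence); a
brute-force per-window recomputation serves as the test oracle.

**Calibration.** The two free transform constants were fixed once, by
simulation of the block-mean distribution, against two qualitative
requirements the method cannot work without:

- *Grid reachability*: random 18-alphabet blocks must populate every family
  from 0.55 to 0.95. At the chosen constants the per-family acceptance
  probability ranges from ≈ 9 % (0.55) through ≈ 12 % (0.70) to ≈ 2 % (0.95),
  so a full 9 × 50 library needs a few thousand proposals (≈ 1 s).
- *Compositional contrast*: concatenating blocks of different composition
  must be visible in the smoothed profile, because the whole rationale of
  repeat-initialization is that an exact tandem repeat gives the flattest
  profile. A first candidate (midpoint −0.40, slope 2.5) satisfied
  reachability but was too flat — concatenated and repeated starts were
  equally acceptable, inverting the method's motivating ordering. Steepening
  the logistic to slope 5.0 (midpoint re-centered at −0.70) restores it:
  ≈ 96 % of repeat-initialized versus ≈ 84 % of concatenation-initialized
  starting sequences pass the dual gate, and discarded-sequence counts rise
  with length and with falling `Dt`.

No claim of numerical compatibility with any published predictor is made;
only these qualitative behaviors (window of 21, long-range regime, W most
order-promoting, repeat-flatness) are reproduced. An external predictor can
be substituted by passing a callable wherever a `ScorerModel` is accepted.

## Building-block library

Blocks are 10-mers drawn i.i.d. uniformly (with replacement) from the
18-letter alphabet. Each is evaluated as the central block of a 7× tandem
repeat of itself — three full blocks of flanking context on each side, so the
21-residue smoothing window never touches a terminus of the construct. A
block is rejected if its central `ΔDo > 0.15`; otherwise it is filed under the
nearest grid `Dt`. Filing additionally requires `|Dt_nearest − D̄o| ≤ 0.025`
(means equidistant between two grid points go to the lower one): without this
bound a smooth block with, say, mean 0.40 would poison the 0.55 family and the
family label would no longer guarantee the sequence-level mean criterion.
Families fill independently to 50; surplus accepted blocks are discarded;
duplicates within a family are permitted. A global proposal cap (default 10⁶)
guarantees termination under a pathological scorer.

With the reference scorer the block-level `ΔDo` filter rejects almost nothing
(smoothing a period-10 repeat over 21 residues bounds the central range by
roughly the raw-score range divided by 21); family scarcity — strongest at the
grid extremes — comes from the mean-residual bound. The published threshold
sweep showed heavy low-`Dt` rejection whose magnitudes depend on the original
predictor's internals; here only the orderings (acceptance monotone in the
threshold; low `Dt` hardest) are meaningful, and only they are asserted.

## Sequence assembly

For requested length `l` (50–200) and target `Dt`:

1. round `l` up to `l_r`, a multiple of 10; set `i = l_r/10`, `j = i − 1`;
2. draw one family block, shuffle its residues once, tandem-repeat it
   `i` times;
3. repeat `j` times: draw another family block, shuffle it, insert it between
   positions `L/2` and `L/2 + 1` (1-based), delete five residues from each
   end, re-score the **entire** sequence, and accept iff the dual gate holds.
   After 200 rejected candidates for one insertion, discard the whole
   sequence and restart from step 2 (counted as one discarded sequence;
   a configurable restart cap, default 50, turns a hopeless request into an
   error rather than a hang — the deterministic analogue of the original
   service's 5-minute timeout);
4. trim `l_r − l` residues one at a time from the extremity whose score
   deviates more from `Dt`, reading deviations from the frozen profile of the
   accepted `l_r`-length sequence (ties trim the N-terminus). The dual
   criterion is guaranteed at `l_r`; after trimming it is re-computed and
   logged but not re-enforced, matching the stated step order of the original
   procedure.

Shuffling and central insertion exist to break tandem repetitiveness, which
at the DNA level promotes recombination and deletion in vivo; designs of
length 100 draw their nine insertions from ≥ 3 distinct blocks in practice.
Batches derive per-design RNG streams from the master seed with a
counter-based spawn scheme, and every design's provenance (initial and
inserted blocks, post-shuffle permutations, rejection counts, discarded-
sequence count) replays to the identical sequence without an RNG.

Output names follow `{l}-{achieved mean, 2 decimals}_{rank}`, ranks in
generation order (whether the original service ranked by score proximity is
not documented; generation order is used here). An optional flag appends a
single W for A280 quantification, off by default, since that was a manual
post-design step in the published use case.

## Characterization formulas

Logarithms in the two mass laws are base 10 — required to reproduce the
printed 18.2 Å at 12,620 Da; natural logarithms do not. Reported radii round
to one decimal in Å. Molecular masses use average (not monoisotopic) residue
masses plus one water, as appropriate for SEC/SDS-PAGE work, via Biopython's
standard table. The folded-protein and calibration-standard laws cross near
14.7 kDa; the disordered power law exceeds the folded law across the entire
50–200-residue design range, which is the expansion SEC exploits.

## What the tests establish — and what they do not

The synthetic world here is the generator itself: uniform 18-alphabet blocks
scored by the reference scorer. Green tests establish that the *procedure* is
implemented faithfully (thresholds boundary-inclusive, caps exact,
determinism, provenance replay, oracle-identical scoring) and that its
qualitative operating characteristics hold (threshold monotonicity,
repeat > concatenation initialization, discarded counts non-decreasing in
`l_r`, hardest at low `Dt`). They do not establish agreement with any
particular predictor's absolute scores, nor anything about wet-lab behavior
(expression, SEC, CD, binding) of designed sequences.

Numerical conventions: 0-based half-open spans internally, 1-based in
user-facing text; acceptance comparisons use plain `<=` at float resolution;
equidistant family assignment prefers the lower `Dt`; trim ties prefer the
N-terminus. Benchmark replicate counts in the test suite are scaled to
single-CPU minutes (50 requests per condition for the length trend, ≥ 200
replicates per strategy for the initialization comparison).

## Known limitations

- The reference scorer is a stand-in honoring a contract, not a validated
  disorder predictor; absolute score values have no biophysical calibration.
- Low-`Dt`, long requests can exhaust the restart cap (the published service
  showed the same failure mode and offered no explanation either).
- No composition, charge, hydropathy or repeat-content constraints beyond
  W/C exclusion and shuffling; no DNA back-translation or codon optimization.
- The library permits duplicate blocks within a family by chance.
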