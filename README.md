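# idpdesign

Generate artificial intrinsically disordered protein (IDP) sequences of a
chosen length and predicted disorder probability, entirely in silico and
independent of any pre-existing protein.

Intrinsically disordered proteins lack a stable fold under physiological
conditions; designing one from scratch means producing an amino-acid string
whose *predicted* per-residue disorder probability is uniformly high and close
to a chosen target. `idpdesign` does this by rejection sampling over a library
of short peptide "building blocks":

- A pluggable **disorder scorer** assigns each residue a score `Do ∈ [0, 1]`
  (scores above 0.5 read as disordered). The bundled reference scorer
  estimates per-residue pairwise interaction energies from the composition of
  sequential neighbors at separation 2–100, maps them through a decreasing
  logistic, and smooths with a centered 21-residue window. Any external
  predictor can be plugged in as a plain `sequence -> scores` callable.
- A **building-block library** of nine families (target disorder
  `Dt = 0.55 … 0.95`, step 0.05), 50 blocks each, is built by drawing random
  10-mers over an 18-letter alphabet (no W, no C), scoring each inside a 7×
  tandem repeat of itself, and keeping blocks whose central score range
  `ΔDo = Do_max − Do_min ≤ 0.15`, filed under the nearest `Dt` (residual
  ≤ 0.025).
- The **designer** assembles a sequence of rounded length `l_r` (requested
  length `l` rounded up to a multiple of 10) from `i = l_r/10` tandem copies of
  one shuffled family block, then performs `j = i − 1` central insertions of
  further shuffled family blocks (trimming five residues from both ends each
  time). After every insertion the whole sequence must satisfy the dual gate
  `ΔDo ≤ 0.15` **and** `|Dt − D̄o| ≤ 0.025`; after 200 rejected candidates for
  one insertion the whole sequence is discarded and assembly restarts.
  Finally the sequence is trimmed to exactly `l` residues from the extremity
  whose score deviates most from `Dt`.
- **Characterization** utilities evaluate the standard power laws
  `log Rs = 0.369·log MM − 0.254` (SEC calibration standards),
  `log Rs^NF = 0.357·log MM − 0.204` (natively folded) and
  `Rs^IDP = 2.49·N^0.509` (disordered), plus the mean residue ellipticity
  `[MRE] = 3300·m·ΔA/(l·c·n)` for circular dichroism data.

Requests are bounded as in the original service: lengths 50–200, one to ten
sequences per query, `Dt` on the nine-point grid. Everything is deterministic
under a fixed master seed, and each design carries a full provenance record
(blocks used, shuffles, rejection counts) that replays to the same sequence
without an RNG.

## Worked example

```sh
$ idpdesign build-library --seed 1 --out library.fasta
library complete: 450 blocks in 9 families -> library.fasta

$ idpdesign design -l 100 -d 0.60 -n 2 --seed 7 --library library.fasta \
      --out designed.fasta --provenance designed.jsonl
100-0.61_1	mean=0.6073	delta=0.1152	discarded=0
100-0.60_2	mean=0.5992	delta=0.1280	discarded=7
wrote 2 sequence(s) to designed.fasta (seed 7)
```

Each line is one design: its name (`{length}-{achieved mean score to 2
decimals}_{rank}`), the mean and range of its per-residue disorder scores, and
how many whole sequences were discarded (200-rejection aborts) before this one
was accepted. The second design needed 7 restarts — low-`Dt` requests are the
hardest, a behavior the benchmark harness (`idpdesign sweep`) quantifies.

```sh
$ idpdesign characterize designed.fasta
      name  n_residues  mass_da  rs_folded_A  rs_idp_A
100-0.61_1         100 11797.27         17.8      26.0
100-0.60_2         100 11918.16         17.8      26.0
```

For each sequence: residue count, average molecular mass (Da), and the
expected Stokes radius (Å) if it were natively folded versus disordered — the
~8 Å gap is the hydrodynamic expansion by which size-exclusion chromatography
distinguishes an IDP from a folded protein of the same mass.

The same functionality is available as a library
(`from idpdesign import build_library, design_batch, stokes_idp, ...`); see
`docs/methods.md` for the model details and design choices.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the package itself, the expected Stokes radius of a
12,620 Da natively folded protein and of a 123-residue IDP (both in Å, one
decimal), and the number of distinct residue types observed across 1,000
freshly proposed building blocks under the given seed, writing the three
values as JSON.
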