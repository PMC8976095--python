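# Methods

## The sensing problem

A toehold switch couples reporter translation to the presence of a specific
trigger RNA. The switch mRNA carries, 5'→3': a 35-nt *sensing region* that
is the reverse complement of a window on the target gene, a loop containing
the ribosome binding site, and a descending stem that re-pairs part of the
sensing region around an unpaired AUG bulge before running into a 21-nt
linker and the reporter frame. In the OFF state the RBS and AUG sit inside
the hairpin; a trigger strand invading through the 12-nt single-stranded
toehold opens the stem and frees them. For species identification the
toolkit designs such sensors against the three standard plant barcode loci
(MatK, RbcL, TrnL-UAA) and only calls a species when sensors for **all
three markers** are predicted (or measured) ON — the conjunction rule that
makes barcode identification robust to single-locus homoplasy.

## Switch architecture and constraints

Defaults (all configurable via `SwitchArchitecture` / YAML):

| parameter | default | meaning |
|---|---|---|
| sensing_len | 35 nt | trigger binding site width |
| toehold_len | 12 nt | single-stranded invasion handle |
| pre/post-start stem | 9 + 11 bp | stem re-paired before/after the AUG bulge |
| loop_seq | `AACAGAGGAGA` | contains the RBS motif `AGGAGA` |
| linker_seq | 21 nt | flexible linker, length ≡ 0 mod 3 |
| GC bounds / homopolymer | [0.2, 0.8] / 6 | soft filters (hard with `--strict`) |

The loop and linker are package defaults in the style of the published
series-B switch lineage, not measured data. Candidates whose descending
stem or linker junction places a stop codon (UAA/UAG/UGA) in frame with the
AUG are discarded outright — such a switch could never translate its
reporter. Only the plus strand is scanned: barcode amplicons have a defined
orientation.

Scoring combines three components, each in [0, 1], with weights
0.4 / 0.3 / 0.3 (exposed in `ScoreWeights` and reported with every
candidate): hairpin fidelity (fraction of designed stem pairs recovered in
the MFE fold of the full switch), toehold accessibility (fraction of window
positions unpaired in the MFE fold of the source transcript), and
activation (sensor–trigger hybridization gain −ΔΔG°, scaled by 30
kcal/mol and clipped). There is no published ground truth for these
weights; they encode the qualitative priorities of the field (a switch must
fold as designed, its site must be reachable, and binding must be strongly
favorable) and are deliberately configuration, not constants.

## Folding engine

Energy model: a structure's free energy is the sum of a per-pair formation
term and a stacking term for every pair whose inner neighbour is also
paired. The shipped `turner-stack-v1` model uses Turner/Xia-style
Watson-Crick stack energies with rounded wobble entries (see
`data/stack_params.yaml`; mirror symmetry is enforced by the loader,
positive entries are clipped to 0) and zero per-pair terms; a `unit-pair`
model (−1 kcal/mol per pair, no stacking) backs the enumeration oracles.
No dangles, coaxial stacks, loop-length penalties or pseudoknots; hairpin
loops must enclose ≥ 3 bases; G·U is allowed. R = 0.0019872 kcal/(mol·K),
T = 310.15 K, so RT = 0.6163 kcal/mol.

Numerics: energies are handled as integer centi-kcal, and co-optimal
structures are resolved by minimizing the triple (energy, number of pairs,
sorted pair list) lexicographically. Because lexicographic order on
(energy, pairs) is a group order under addition, the DP over combined
integer keys is exact, every sub-interval of an optimal decomposition is
forced to its own optimum, and a greedy traceback (pair the leftmost
position with the smallest partner whenever a tuple-optimal continuation
exists) provably returns the same canonical structure the brute-force
enumerator selects. The test suite checks this equivalence on 500+ random
sequences up to 12 nt under both models.

Two-strand complexes concatenate sensor and trigger with a 3-position
spacer that is barred from pairing; pairs spanning the strand break are
exempt from the hairpin-loop minimum. ΔΔG° = ΔG°(complex) − ΔG°(monomers)
is never positive. The bound fraction is a concentration-free two-state
logistic `f = 1/(1 + exp(ΔΔG°/RT))` (0.5 exactly at ΔΔG° = 0); an optional
concentration-aware mode `f = Kc/(1 + Kc)` with `K = exp(−ΔΔG°/RT)` serves
the 2 µM trigger condition of cell-free assays. The two-state form is a
stand-in: ensemble definitions and tube concentrations behind published
"fraction bound" numbers vary, so the choice is documented rather than
hidden.

## Specificity classification

Pairs are banded on the complex free energy: `strong` below −103 kcal/mol
(strict <), `nonfunctional` above −90 (strict >), `indeterminate` between.
These defaults mirror the fold-change boundaries they were derived from
(ON/OFF > 60 below the strong cutoff, no function above the weak one, ratio
10 as the empirical ON call) — but any folding engine assigns its own
absolute energies, and the absolute energy of a 90 + 120 nt complex carries
a sensor-specific offset from monomer self-structure. The thresholds are
therefore configuration, and `calibrate_thresholds` refits them from
labeled pairs (the widest separating band when labels are separable, the
purity-maximizing cut otherwise). The acceptance script calibrates **per
sensor**, labeling exact binding sites strong and variants with ≥ 3
mismatches nonfunctional from generator ground truth.

Indeterminate pairs default to the bound-fraction vote (ON when
f ≥ 0.5). In the conjunction call a species is positive only when every
required marker has at least one ON sensor; a missing marker is an error,
never a silent OFF.

Variant windows are extracted at the same coordinates by default (barcode
loci are homologous and effectively aligned); `best-match` mode scans all
windows exhaustively for unaligned inputs.

## Plate quantification

Calibration is an ordinary least-squares line of standard concentration on
blank-subtracted reading (MEFL = slope·(a.u. − blank) + intercept); r² is
reported, non-positive slopes and constant readings are rejected.
Whole-cell signals are divided by OD600 first (points below OD 0.01 are
masked, not errored — early-inoculation readings are noise, not data).
The endpoint is the latest sample at or before t_end (floor convention,
deterministic across readers); the default t_end of 150 min reflects a
quasi-steady state of cell-free reactions by 2 h 30 min, while the in vivo
summary time is a required user choice. Fold change is the ratio of
replicate-mean endpoints (not the mean of ratios); per-arm SDs are reported
without propagation into a ratio CI. Rank correlation between conditions
uses Spearman's rho with an exhaustive permutation p-value for n ≤ 8 and
the large-sample approximation above (9!+ enumerations buy no accuracy
worth their cost).

## Synthetic data

`synth_gene_family` draws a uniform root per marker and mutates each
non-reference species i.i.d. per site (uniform over the three alternative
bases, no indels), recording the exact mutation mask — so window mismatch
counts are ground truth, not estimates. Planted matches pin designated
windows back to the root (pinning beats mutation, with a warning).
`synth_plate_kinetics` produces `baseline + A(1 − e^{−t/τ})` traces with
τ = saturation_time/3, ON amplitude = true ratio × OFF amplitude, and
multiplicative Gaussian noise; optional logistic OD600 for in vivo mode.
Defaults (3 replicates, 10% noise CV, 5-min sampling over 8 h, 120-min
saturation) emulate the measurement designs of cell-free biosensor assays.

What passing tests on these generators do **not** show: real barcode loci
evolve with indels and rate heterogeneity, real triggers have biased
composition and long-range structure, and real TXTL kinetics saturate by
resource exhaustion, not by a clean exponential. The generators validate
the pipeline's bookkeeping and statistics, not the biology.

## Problem sizes and determinism

The shipped validation uses genes of 120–300 nt, panels of 3–12 species,
design scans at steps 5–25, 500 oracle folds ≤ 12 nt, 50 planted panels and
100 kinetics datasets — sizes chosen so the whole suite runs in well under
a minute while every code path is exercised; all randomness flows through
explicit integer seeds, and reruns are byte-identical.

## Known limitations

- Absolute ΔG°′ values are engine-specific; only calibrated comparisons
  within one engine are meaningful.
- No partition function: the bound fraction is two-state, not ensemble.
- The composite design score is a documented heuristic, not a validated
  efficacy predictor; wet-lab screening remains necessary.
- Indels between species break coordinate-mode window extraction; use
  `best-match` or pre-align.
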