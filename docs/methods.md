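# Methods

## Model and assumptions

The pipeline identifies phase-I metabolites of a parent drug from
centroided MS^E peak lists. Its premises are those of accurate-mass
small-molecule work in positive electrospray:

* every ion is a singly charged cation — [M+H]⁺, [M+Na]⁺ or [M+K]⁺;
* a metabolite differs from the parent by a composition delta, not by a
  rearranged skeleton, so candidate formulas are reachable by composing a
  small set of biotransformation rules;
* collision-induced dissociation proceeds by ejection of small neutrals
  (water, formic acid, acetic acid, CO, ethylene), so a high-energy
  fragment is validated when some multiset of registered losses connects
  it to the protonated molecule;
* isomers (same formula, different structure) are indistinguishable by
  mass and are separated only chromatographically.

Adduct m/z is `M + m(cation atom) − m(e⁻)`; subtracting the electron mass
matters at the 0.5 mDa level and is required to reproduce printed errors
of the reference observations to 0.1 mDa. Atomic masses are embedded
constants (H 1.007825, C 12, N 14.003074, O 15.994915, Na 22.989770,
K 38.963707; electron 0.000549 Da) so results do not depend on an external
isotope table; a test cross-checks them against pyteomics.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| precursor tolerance | ±2 | mDa | accuracy window of the Q-TOF workflow modelled |
| fragment tolerance | ±0.5 | Da | published fragment series are unit-resolution |
| retention alignment | ±0.1 | min | isomer spacing in the 16-min gradient |
| fragment cap | 10 | ions | most-intense fragments considered per match |
| loss-search depth | 4 | losses | longest published ladder (3 waters + 1 acid) |
| rule caps | +O ≤ 2, −O ≤ 1, +H2 ≤ 1 | — | span of observed classes; configurable |
| enumeration depth | 3 | steps | covers every observed class |

Rule caps and the step limit are configuration defaults describing what
was observed, not claims about chemistry; both are loadable from YAML.

## Tie-breaks and degenerate inputs

* **Precursor matching** keeps one best match per peak — smallest |error|
  at 0.1 mDa granularity, then fewest transformations, then lexicographic
  class label, then adduct order H < Na < K — and retains every
  within-tolerance alternative as diagnostics. This matters because the
  candidate space is mass-degenerate: DHA and DHA-O + O share C15H24O5,
  and de-ART + O shares C15H22O5 with the parent. Recovery scoring
  therefore asks whether the true class is *among* a match's assignments,
  which is the strongest claim mass alone supports.
* **Loss-path search** prefers minimal multiset cardinality, then no ±H2
  over +H2 over −H2, then the lexicographically smallest label sequence.
  At 0.5 Da several multisets can tie: CO (27.995) and C2H4 (28.031) are
  indistinguishable, and a 2-loss + H2 path can displace a 3-water ladder.
  The search is verified against an exhaustive enumeration oracle; only
  the cumulative mass, not the narrative order of losses, is testable.
* **Empty fragment lists** yield coverage "not evaluable" (None), distinct
  from coverage 0; infeasible rule branches (element count would go
  negative) are pruned, not errors; inconsistent fixture rows are graded
  pass/warn/fail (≤0.05 / ≤0.3 mDa printed-vs-recomputed gap) and reported
  verbatim.
* With per-rule caps honoured, enumeration at depth 3 yields 11 candidate
  classes; the 9 observed ones plus {−O,+O,+O} and {+H2,+O,+O}, which are
  formula-degenerate with observed classes or unobserved and never win a
  tie-break.

## Synthetic data: what it emulates and what it does not

No raw spectra exist for the study conditions modelled, so the generator
emulates the *structure* of the acquisition. Defaults are the study
conditions: the 39-metabolite panel carries the published classes,
adducts, retention times and per-system membership (so the planted Venn is
23/32/16); σ = 0.5 mDa Gaussian m/z error (a quarter of the tolerance
window, typical of a calibrated Q-TOF); 20 expected decoy peaks per sample
uniform over m/z 50–1000; 30 matrix peaks shared verbatim with the paired
blank; 0.02 min retention jitter; log-uniform intensities. Decoys and
matrix peaks are rejection-sampled to stay ≥ 5 mDa from every candidate
ion so they are genuine negatives. A single seed drives all randomness;
identical specs are byte-reproducible.

Not emulated: chromatographic peak shape, isotope envelopes, ion
suppression, mass-dependent error, correlated fragment intensities, and
in-source fragmentation. Passing recovery tests therefore show the
*logic* (subtraction, matching, annotation, comparison) is correct under
a calibrated-instrument error model — not that real-matrix data of
arbitrary quality would be recovered as cleanly.

One structural limitation is inherited from the panel itself: it contains
two same-class metabolites, one per system, co-eluting at 2.2 min. A
truth-blind cross-system join by (class, |ΔRt| ≤ 0.1 min) necessarily
pairs them, so the pipeline's common count on this panel is 17 where the
planted truth distinguishes them (16). On panels whose distinct
metabolites are separated beyond the Rt tolerance, pipeline Venn counts
equal the truth exactly (this is tested). Resolving such co-elutions
needs fragment- or structure-level evidence outside the scope of
formula-level identification.

## Numerical choices

Reported mDa errors round half away from zero to one decimal (sign
preserved). m/z is written with 4 decimals, retention times with 3.
Matching precomputes the candidate × adduct ladder once per run; the loss
search is iterative-deepening DFS with mass pruning, exact for the
default registry and depth. The fixture validator compares printed errors
against unrounded recomputed ones, so legitimate 0.05 mDa rounding slack
does not flag a row.

## Known limitations

* Only +1 cations, positive mode; no isotope-pattern scoring.
* Class labels are formula-level; site of metabolism and stereochemistry
  are out of scope.
* Phase-II conjugates are absent from the default rules (none occur in
  the modelled system) but can be added via the rule config.
* The packaged reference table reproduces its source verbatim; 8 of its
  55 printed observations are internally inconsistent (formula or m/z
  typos) and are surfaced by `validate_fixture` rather than corrected.
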