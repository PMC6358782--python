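"""Explain the reference-standard fragment series by neutral losses.

For each authentic standard (artemisinin, deoxyartemisinin,
dihydroartemisinin) the published high-energy fragment ions are explained
as multisets of neutral losses (H2O, HCOOH, CH3COOH, CO, C2H4) from the
protonated molecule, optionally with one +-H2 rearrangement. Coverage 1.0
means every fragment in the series is accounted for.
"""

from artmet import annotate_spectrum, enumerate_candidates, ion_mz
from artmet.peaks import Peak, PrecursorMatch
from artmet.references import REFERENCE_COMPOUNDS

candidates = {c.label: c for c in enumerate_candidates("C15H22O5")}
for name in ("ART", "de-ART", "DHA"):
    ref = REFERENCE_COMPOUNDS[name]
    cand = candidates[name]
    theo = ion_mz(cand.formula, "M+H")
    match = PrecursorMatch(Peak(theo, 1.0, 1.0, "low"), cand, "M+H", theo, 0.0)
    ann = annotate_spectrum(match, list(ref.fragments))
    print(f"{name} ({cand.formula}), [M+H]+ = {theo:.4f}, "
          f"coverage = {ann.coverage:.2f}")
    for a in ann.assignments:
        h2 = {0: "", 1: " +H2", -1: " -H2"}[a.h2]
        path = " + ".join(a.losses) or "(precursor)"
        print(f"  m/z {a.observed_mz:>5.0f}  <- loss of {path}{h2}"
              f"  (theo {a.theoretical_mz:.4f})")
    print()
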