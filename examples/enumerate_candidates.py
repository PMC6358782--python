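"""Enumerate candidate phase-I metabolites of artemisinin.

Composes the default biotransformation rules (hydroxylation +O up to twice,
deoxygenation -O once, carbonyl reduction +H2 once) on C15H22O5 and prints
each candidate class with its formula and theoretical adduct m/z — the
search space against which observed precursor ions are matched.
"""

from artmet import enumerate_candidates, ion_mz

candidates = enumerate_candidates("C15H22O5", max_steps=3)
print(f"{len(candidates)} candidate classes (path multisets):\n")
print(f"{'class':<14} {'formula':<10} {'steps':>5} {'[M+H]+':>10} {'[M+Na]+':>10} {'[M+K]+':>10}")
for cand in candidates:
    mzs = [ion_mz(cand.formula, a) for a in ("M+H", "M+Na", "M+K")]
    print(
        f"{cand.label:<14} {str(cand.formula):<10} {cand.n_steps:>5} "
        + " ".join(f"{mz:>10.4f}" for mz in mzs)
    )
print(
    "\nNote: DHA and DHA-O + O share C15H24O5 — isomeric classes are kept"
    "\ndistinct by path, since only retention time can separate them."
)
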