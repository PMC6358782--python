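"""Match printed observed precursor m/z values to candidate metabolites.

Takes the per-system observed m/z values from the packaged summary table,
treats each as a low-energy peak, and matches it against the enumerated
candidate adduct ladder within +-2 mDa. Where a formula is mass-degenerate
(e.g. de-ART + O vs the parent itself) all within-tolerance alternatives
are kept as diagnostics.
"""

from artmet import enumerate_candidates, load_reference_table, match_precursors
from artmet.peaks import Peak

candidates = enumerate_candidates("C15H22O5")
records = load_reference_table()

print(f"{'id':<4} {'printed class':<12} {'obs m/z':>9} {'best match':<12} "
      f"{'adduct':<6} {'err(mDa)':>8}  alternatives")
shown = 0
for record in records:
    obs = record.in_vivo or record.in_vitro
    matches = match_precursors([Peak(obs.mz, record.rt_min, 1.0)], candidates)
    if not matches:
        continue  # rows whose printed m/z carries a typo find no candidate
    m = matches[0]
    alts = ", ".join(l for l in m.labels if l != m.candidate.label) or "-"
    print(f"{record.metabolite_id:<4} {record.component:<12} {obs.mz:>9.4f} "
          f"{m.candidate.label:<12} {m.adduct:<6} {m.reported_error_mda:>8.1f}  {alts}")
    shown += 1
print(f"\n{shown}/39 rows matched; a best match is the smallest-|error|, "
      "fewest-transformation assignment.")
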