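"""Blank subtraction and accurate-mass precursor matching."""

import numpy as np
import pytest

from artmet.biotransform import CandidateMetabolite
from artmet.chem import ion_mz, mass_error_mda, parse_formula, reported_mda
from artmet.peaks import (
    Peak,
    PeakTable,
    match_precursors,
    subtract_blank,
)


def table(peaks, system="in_vivo", sample_id="s"):
    return PeakTable(sample_id, system, tuple(peaks))


class TestSubtractBlank:
    def test_within_both_windows_removed(self):
        sample = table([Peak(321.1301, 2.8, 10.0)])
        blank = table([Peak(321.1303, 2.81, 5.0)], system="blank")
        assert len(subtract_blank(sample, blank, 2.0, 0.1)) == 0

    def test_outside_mz_window_retained(self):
        sample = table([Peak(321.1301, 2.8, 10.0)])
        blank = table([Peak(321.1350, 2.8, 5.0)], system="blank")
        assert len(subtract_blank(sample, blank, 2.0, 0.1)) == 1

    def test_empty_blank_is_identity(self):
        sample = table([Peak(321.1301, 2.8, 10.0), Peak(100.0, 1.0, 1.0)])
        blank = table([], system="blank")
        assert subtract_blank(sample, blank).peaks == sample.peaks

    def test_self_subtraction_is_empty(self):
        peaks = [Peak(200.0 + i, 1.0 + i, 10.0) for i in range(5)]
        sample = table(peaks)
        blank = table(peaks, system="blank", sample_id="b")
        assert len(subtract_blank(sample, blank)) == 0

    def test_idempotent(self):
        sample = table([Peak(200.0, 1.0, 1.0), Peak(321.1301, 2.8, 10.0)])
        blank = table([Peak(200.0, 1.0, 1.0)], system="blank")
        once = subtract_blank(sample, blank)
        twice = subtract_blank(once, blank)
        assert once.peaks == twice.peaks

    def test_constructed_signal_plus_blank_recovers_signal(self):
        rng = np.random.default_rng(7)
        signal = [Peak(float(m), float(r), 10.0) for m, r in
                  zip(rng.uniform(100, 400, 10), rng.uniform(1, 10, 10))]
        matrix = [Peak(float(m) + 50.0, float(r), 5.0) for m, r in
                  zip(rng.uniform(500, 900, 10), rng.uniform(1, 10, 10))]
        sample = table(signal + matrix)
        blank = table(matrix, system="blank")
        assert set(subtract_blank(sample, blank).peaks) == set(signal)

    def test_channel_mismatch_not_removed(self):
        sample = table([Peak(200.0, 1.0, 1.0, "high")])
        blank = table([Peak(200.0, 1.0, 1.0, "low")], system="blank")
        assert len(subtract_blank(sample, blank)) == 1

    def test_swapped_arguments_rejected(self):
        sample = table([Peak(200.0, 1.0, 1.0)])
        with pytest.raises(ValueError, match="blank"):
            subtract_blank(sample, sample)


class TestMatchPrecursors:
    def test_monohydroxylated_sodium_adduct(self, candidates):
        match, = match_precursors([Peak(321.1301, 2.8, 10.0)], candidates)
        assert match.candidate.label == "ART + O"
        assert match.adduct == "M+Na"
        assert reported_mda(match.error_mda) == -0.8

    def test_far_peak_unmatched(self, candidates):
        assert match_precursors([Peak(400.0, 2.8, 10.0)], candidates) == []

    def test_empty_candidates_empty_result(self):
        assert match_precursors([Peak(321.1301, 2.8, 10.0)], []) == []

    def test_tolerance_must_be_positive(self, candidates):
        with pytest.raises(ValueError):
            match_precursors([Peak(321.1301, 2.8, 10.0)], candidates, tol_mda=0)

    def test_isomer_tie_goes_to_fewer_transformations(self, candidates):
        # DHA (1 step) and DHA-O + O (3 steps) share C15H24O5 exactly.
        theo = ion_mz(parse_formula("C15H24O5"), "M+Na")
        match, = match_precursors([Peak(theo, 5.8, 10.0)], candidates)
        assert match.candidate.label == "DHA"
        assert "DHA-O + O" in match.labels

    def test_remaining_tie_goes_to_lexicographic_label(self):
        parent = parse_formula("C15H22O5")
        f = parse_formula("C15H22O6")
        a = CandidateMetabolite(parent, ("+O",), f, "BBB")
        b = CandidateMetabolite(parent, ("+O",), f, "AAA")
        theo = ion_mz(f, "M+H")
        match, = match_precursors([Peak(theo, 1.0, 1.0)], [a, b])
        assert match.candidate.label == "AAA"

    def test_best_match_agrees_with_brute_force(self, candidates):
        """Exhaustive policy evaluation over the whole candidate ladder."""
        rng = np.random.default_rng(11)
        ladder = [
            (c, a, ion_mz(c.formula, a))
            for c in candidates
            for a in ("M+H", "M+Na", "M+K")
        ]
        adduct_rank = {"M+H": 0, "M+Na": 1, "M+K": 2}
        for _ in range(50):
            cand, adduct, theo = ladder[rng.integers(len(ladder))]
            mz = theo + rng.uniform(-2e-3, 2e-3)
            match, = match_precursors([Peak(float(mz), 1.0, 1.0)], candidates)
            best = min(
                (
                    (c, a, t)
                    for c, a, t in ladder
                    if abs(mass_error_mda(mz, t)) <= 2.0
                ),
                key=lambda item: (
                    reported_mda(abs(mass_error_mda(mz, item[2]))),
                    item[0].n_steps,
                    item[0].label,
                    adduct_rank[item[1]],
                ),
            )
            assert (match.candidate.label, match.adduct) == (best[0].label, best[1])

    def test_tolerance_monotone(self, candidates):
        rng = np.random.default_rng(3)
        peaks = [
            Peak(float(m), 1.0, 1.0)
            for m in rng.uniform(280, 340, 200)
        ]
        tight = {m.peak for m in match_precursors(peaks, candidates, tol_mda=1.0)}
        loose = {m.peak for m in match_precursors(peaks, candidates, tol_mda=2.0)}
        assert tight <= loose

    def test_high_energy_peaks_ignored(self, candidates):
        theo = ion_mz(parse_formula("C15H22O6"), "M+Na")
        assert match_precursors([Peak(theo, 2.8, 10.0, "high")], candidates) == []

    def test_fixture_rows_recovered(self, records, candidates):
        """Every self-consistent printed observation is recovered: its class
        and adduct appear among the within-tolerance assignments."""
        checked = 0
        for record in records:
            theo = ion_mz(record.formula, record.adduct.label)
            for system in ("in_vivo", "in_vitro"):
                obs = record.observation(system)
                if obs is None or abs(mass_error_mda(obs.mz, theo)) > 2.0:
                    continue  # skip rows with printed-formula/m-z typos
                matches = match_precursors(
                    [Peak(obs.mz, record.rt_min, 1.0)], candidates
                )
                assert matches, (record.metabolite_id, system)
                pairs = {
                    (alt.candidate.label, alt.adduct)
                    for alt in matches[0].alternatives
                }
                assert (record.component, record.adduct.label) in pairs
                checked += 1
        # 47 of the 55 printed observations are consistent with their
        # printed formula + adduct; the other 8 carry known typos
        assert checked == 47
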