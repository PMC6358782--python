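"""Neutral-loss explanation of high-energy fragments and coverage scoring."""

import numpy as np
import pytest

from artmet.chem import formula_mass, ion_mz, parse_formula
from artmet.fragments import (
    H2_MASS,
    annotate_spectrum,
    default_loss_registry,
    explain_fragment,
    explain_fragment_oracle,
    losses_from_config,
)
from artmet.peaks import Peak, PrecursorMatch
from artmet.references import REFERENCE_COMPOUNDS

ART_MH = ion_mz(parse_formula("C15H22O5"), "M+H")  # 283.1540


def make_match(candidates_by_label, label, adduct="M+H"):
    cand = candidates_by_label[label]
    theo = ion_mz(cand.formula, adduct)
    return PrecursorMatch(Peak(theo, 1.0, 1.0, "low"), cand, adduct, theo, 0.0)


class TestRegistry:
    def test_default_masses_equal_formula_mass(self):
        registry = default_loss_registry()
        assert set(registry) == {"H2O", "HCOOH", "CH3COOH", "CO", "C2H4"}
        for loss in registry.values():
            assert loss.mass == formula_mass(loss.formula)

    @pytest.mark.parametrize(
        "label, mass",
        [("H2O", 18.0106), ("HCOOH", 46.0055), ("CH3COOH", 60.0211),
         ("CO", 27.9949), ("C2H4", 28.0313)],
    )
    def test_documented_masses(self, label, mass):
        assert default_loss_registry()[label].mass == pytest.approx(mass, abs=5e-5)

    def test_user_extensible(self):
        registry = losses_from_config({"losses": [{"label": "NH3", "formula": "NH3"}]})
        assert registry["NH3"].mass == pytest.approx(17.0265, abs=5e-5)


class TestExplainFragment:
    @pytest.mark.parametrize(
        "fragment, losses, h2",
        [
            (265, ("H2O",), 0),
            (247, ("H2O", "H2O"), 0),
            (237, ("HCOOH",), 0),
            (205, ("CH3COOH", "H2O"), 0),
        ],
    )
    def test_artemisinin_ladder(self, fragment, losses, h2):
        out = explain_fragment(ART_MH, fragment)
        assert out is not None
        assert (out.losses, out.h2) == (losses, h2)

    def test_triple_water_without_rearrangement(self):
        # with +-H2 allowed a shorter 2x28 Da multiset also fits m/z 229;
        # disabling the rearrangement isolates the successive-water ladder
        out = explain_fragment(ART_MH, 229, allow_h2=False)
        assert (out.losses, out.h2) == (("H2O", "H2O", "H2O"), 0)

    def test_hydrogen_adjustment(self):
        # water loss plus H2 addition, the rearrangement seen for reduced species
        out = explain_fragment(301.1646, 285, allow_h2=True)
        assert out is not None
        assert out.losses == ("H2O",) and out.h2 == 1

    def test_h2_disabled(self):
        assert explain_fragment(301.1646, 285, allow_h2=False) is None

    def test_identity_is_empty_path(self):
        out = explain_fragment(ART_MH, ART_MH)
        assert out is not None and out.losses == () and out.h2 == 0

    def test_no_explanation_is_none(self):
        assert explain_fragment(100.0, 99.9, tol=0.01) is None

    def test_mass_bookkeeping(self):
        out = explain_fragment(ART_MH, 205)
        registry = default_loss_registry()
        total = sum(registry[l].mass for l in out.losses)
        assert out.theoretical_mz + total - out.h2 * H2_MASS == pytest.approx(
            ART_MH, abs=1e-9
        )


class TestOracle:
    def test_double_water(self):
        assert (("H2O", "H2O"), 0) in explain_fragment_oracle(ART_MH, 247)

    def test_deep_combination(self):
        # 283.1540 - (H2O + HCOOH + C2H4) = 191.1066
        assert (("C2H4", "H2O", "HCOOH"), 0) in explain_fragment_oracle(ART_MH, 191)

    def test_empty_when_unreachable(self):
        assert explain_fragment_oracle(100.0, 99.9, tol=0.01) == set()

    def test_depth_capped(self):
        with pytest.raises(ValueError):
            explain_fragment_oracle(ART_MH, 191, max_depth=6)

    def test_search_agrees_with_oracle_on_random_instances(self):
        """explain_fragment is non-None iff the exhaustive enumeration finds
        a path, and its answer is a member of the oracle set of minimal size."""
        rng = np.random.default_rng(42)
        n_explained = 0
        for _ in range(200):
            precursor = float(rng.uniform(150, 500))
            fragment = precursor - float(rng.uniform(0, 150))
            got = explain_fragment(precursor, fragment)
            oracle = explain_fragment_oracle(precursor, fragment)
            if not oracle:
                assert got is None
                continue
            n_explained += 1
            assert got is not None
            assert (got.losses, got.h2) in oracle
            assert len(got.losses) == min(len(p) for p, _ in oracle)
        assert n_explained > 20  # the random box hits real ladders often enough

    def test_depth_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            precursor = float(rng.uniform(150, 500))
            fragment = precursor - float(rng.uniform(0, 130))
            shallow = explain_fragment(precursor, fragment, max_depth=3)
            if shallow is not None:
                assert explain_fragment(precursor, fragment, max_depth=4) is not None


class TestAnnotateSpectrum:
    @pytest.mark.parametrize("name", ["ART", "de-ART", "DHA"])
    def test_reference_coverage_complete(self, candidates_by_label, name):
        ref = REFERENCE_COMPOUNDS[name]
        match = make_match(candidates_by_label, name if name != "ART" else "ART")
        ann = annotate_spectrum(match, list(ref.fragments))
        assert ann.coverage == 1.0
        assert ann.considered == len(ref.fragments)

    def test_deart_239_is_a_28da_loss(self, candidates_by_label):
        """m/z 239 from protonated de-ART is one 28 Da loss; CO and C2H4 are
        indistinguishable at unit resolution, and the published CO route is
        in the exhaustive solution set."""
        match = make_match(candidates_by_label, "de-ART")
        ann = annotate_spectrum(match, [239])
        assignment, = ann.assignments
        assert len(assignment.losses) == 1
        assert assignment.losses[0] in ("CO", "C2H4")
        oracle = explain_fragment_oracle(match.theoretical_mz, 239)
        assert (("CO",), 0) in oracle

    def test_unreachable_fragments_zero_coverage(self, candidates_by_label):
        match = make_match(candidates_by_label, "ART")
        ann = annotate_spectrum(match, [30.0, 35.0])
        assert ann.coverage == 0.0

    def test_empty_fragment_list_not_evaluable(self, candidates_by_label):
        match = make_match(candidates_by_label, "ART")
        ann = annotate_spectrum(match, [])
        assert ann.coverage is None and ann.considered == 0

    def test_cap_limits_considered(self, candidates_by_label):
        match = make_match(candidates_by_label, "ART")
        fragments = [Peak(265.0, 1.0, float(i + 1), "high") for i in range(15)]
        ann = annotate_spectrum(match, fragments, max_fragments=10)
        assert ann.considered == 10

    def test_intensity_ranking_before_cap(self, candidates_by_label):
        match = make_match(candidates_by_label, "ART")
        weak_unexplainable = [Peak(40.0 + i, 1.0, 1.0, "high") for i in range(10)]
        strong_explained = [Peak(265.1434, 1.0, 1e6, "high")]
        ann = annotate_spectrum(match, weak_unexplainable + strong_explained,
                                max_fragments=1)
        assert ann.coverage == 1.0

    def test_sodiated_precursor_uses_protonated_ladder(self, candidates_by_label):
        # fragment series continues from [M+H]+ even for an [M+Na]+ precursor
        match = make_match(candidates_by_label, "ART", adduct="M+Na")
        ann = annotate_spectrum(match, [265, 247])
        assert ann.coverage == 1.0
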