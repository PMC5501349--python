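"""Candidate enumeration, fragment matching, and the localization filter."""
from __future__ import annotations

import numpy as np
import pytest

from middledown.model import (
    CH2,
    H3_TAIL,
    LabelScheme,
    Spectrum,
    TailSequence,
    ion_ladder,
    make_proteoform,
    proteoform_mass,
)
from middledown.search import (
    ACCEPTED,
    REJECTED_AMBIGUOUS,
    CandidateCapError,
    SearchConfig,
    enumerate_candidates,
    isoscale_filter,
    match_fragments,
    score_psm,
    search_spectrum,
    site_determining_ions,
    PSM,
)

from conftest import brute_force_candidates

NO_SILAC = LabelScheme(sequence_channel_enabled=False)


def noiseless_spectrum(p, scheme=LabelScheme(), sid="s1", intensity=100.0):
    peaks = [(i.neutral_mass, intensity) for i in ion_ladder(p, scheme)]
    return Spectrum(
        id=sid,
        precursor_neutral_mass=proteoform_mass(p, scheme),
        precursor_charge=8,
        peaks=peaks,
    )


class TestEnumeration:
    def test_unmodified_tail_always_a_candidate(self, h3_tail, h3_config):
        m = proteoform_mass(make_proteoform(h3_tail), h3_config.scheme)
        cands = enumerate_candidates(m, h3_config, h3_tail)
        assert ("", "light") in {(c.notation, c.channel) for c in cands}

    def test_single_k_site_dimethyl_unique(self, toy_tail):
        cfg = SearchConfig(
            precursor_tol=0.01, modifiable_sites=(4,), scheme=NO_SILAC
        )
        m = proteoform_mass(make_proteoform(toy_tail), cfg.scheme) + 2 * CH2
        cands = enumerate_candidates(m, cfg, toy_tail)
        assert [(c.notation, c.channel) for c in cands] == [("K4me2", "light")]

    def test_two_k_sites_give_three_isobaric_placements(self, two_k_tail):
        cfg = SearchConfig(precursor_tol=0.01, scheme=NO_SILAC)
        m = proteoform_mass(make_proteoform(two_k_tail), cfg.scheme) + 2 * CH2
        cands = enumerate_candidates(m, cfg, two_k_tail)
        assert {c.notation for c in cands} == {"K1me2", "K4me2", "K1me1K4me1"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_toy_tails(self, seed):
        """Composition-first enumeration equals exhaustive enumeration."""
        rng = np.random.default_rng(seed)
        tail = TailSequence(name=f"toy{seed}", residues="AKSGRKTA"[: 6 + seed])
        cfg = SearchConfig(scheme=NO_SILAC, max_mods=4)
        base = proteoform_mass(make_proteoform(tail), cfg.scheme)
        for _ in range(60):
            m = base + rng.uniform(-5.0, 130.0)
            got = {(c.notation, c.channel) for c in enumerate_candidates(m, cfg, tail)}
            assert got == brute_force_candidates(m, cfg, tail)

    def test_enumeration_deterministic_order(self, h3_tail, h3_config):
        m = proteoform_mass(make_proteoform(h3_tail, "K9me2"), h3_config.scheme)
        a = enumerate_candidates(m, h3_config, h3_tail)
        b = enumerate_candidates(m, h3_config, h3_tail)
        assert [c.notation for c in a] == [c.notation for c in b]
        assert [len(c.mods) for c in a] == sorted(len(c.mods) for c in a)

    def test_cap_raises_instead_of_truncating(self, h3_tail):
        cfg = SearchConfig(
            modifiable_sites=(4, 8, 9, 14, 18, 23, 26, 27, 36),
            scheme=NO_SILAC,
            max_candidates=50,
        )
        m = proteoform_mass(make_proteoform(h3_tail), cfg.scheme) + 6 * CH2
        with pytest.raises(CandidateCapError, match="tighten"):
            enumerate_candidates(m, cfg, h3_tail)

    def test_nonpositive_precursor_rejected(self, toy_tail):
        with pytest.raises(ValueError):
            enumerate_candidates(-5.0, SearchConfig(), toy_tail)


class TestMatching:
    def test_noiseless_spectrum_matches_all_ions_at_zero_error(self, h3_tail):
        p = make_proteoform(h3_tail, "K9me2K14ac")
        s = noiseless_spectrum(p)
        matched = match_fragments(s, p, 0.01)
        assert len(matched) == 2 * (len(h3_tail) - 1)
        assert all(abs(m.error_ppm) < 1e-9 for m in matched)

    def test_empty_spectrum_matches_nothing(self, h3_tail):
        p = make_proteoform(h3_tail)
        s = Spectrum(id="e", precursor_neutral_mass=proteoform_mass(p), peaks=[])
        assert match_fragments(s, p, 0.01) == []

    def test_wrong_placement_misses_region_ions(self, h3_tail):
        """A K9me2 spectrum matched against K14me2 loses c9..c13 (and the
        mirror z ions): those fragments sit 2xCH2 off."""
        true = make_proteoform(h3_tail, "K9me2")
        wrong = make_proteoform(h3_tail, "K14me2")
        s = noiseless_spectrum(true)
        matched = {(m.ion.series, m.ion.index) for m in match_fragments(s, wrong, 0.01)}
        n = len(h3_tail)
        for i in range(9, 14):
            assert ("c", i) not in matched
            assert ("z", n - i) not in matched
        assert ("c", 8) in matched and ("c", 14) in matched

    def test_score_range_and_examples(self, h3_tail):
        p = make_proteoform(h3_tail, "K27me3")
        s = noiseless_spectrum(p)
        full = match_fragments(s, p, 0.01)
        assert score_psm(full, p, s) == pytest.approx(1.0)
        assert score_psm([], p, s) == 0.0
        # half the ions carrying half the total intensity -> 0.5
        half = full[: len(full) // 2]
        half_s = Spectrum(
            id="h",
            precursor_neutral_mass=s.precursor_neutral_mass,
            peaks=s.peaks,
        )
        frac = sum(m.peak_intensity for m in half) / s.total_intensity
        expected = 0.5 * (len(half) / len(full) + frac)
        assert score_psm(half, p, half_s) == pytest.approx(expected)
        assert expected == pytest.approx(0.5, abs=1e-9)


class TestSiteDeterminingIons:
    def test_no_rivals_every_ion_qualifies(self, h3_tail):
        p = make_proteoform(h3_tail, "K9me2")
        sdi = site_determining_ions(p, [])
        assert len(sdi[p.mods[0]]) == 2 * (len(h3_tail) - 1)

    def test_pairwise_rival_gives_c9_to_c13(self, h3_tail):
        p = make_proteoform(h3_tail, "K9me2")
        r = make_proteoform(h3_tail, "K14me2")
        sdi = site_determining_ions(p, [r])
        got = {(i.series, i.index) for i in sdi[p.mods[0]]}
        n = len(h3_tail)
        expected = {("c", i) for i in range(9, 14)} | {("z", n - i) for i in range(9, 14)}
        assert got == expected

    def test_intersection_for_rivals_relocating_same_mod(self, h3_tail):
        """Rivals moving K9me2 to K14 or K18: the intersection is the
        c9..c13 stretch that differs from both (checked by brute force
        over the three ladders)."""
        p = make_proteoform(h3_tail, "K9me2")
        r1 = make_proteoform(h3_tail, "K14me2")
        r2 = make_proteoform(h3_tail, "K18me2")
        sdi = site_determining_ions(p, [r1, r2])[p.mods[0]]
        lads = {
            q.notation: {(i.series, i.index): i.neutral_mass for i in ion_ladder(q)}
            for q in (p, r1, r2)
        }
        brute = {
            key
            for key, m in lads["K9me2"].items()
            if abs(m - lads["K14me2"][key]) > 1e-4
            and abs(m - lads["K18me2"][key]) > 1e-4
        }
        assert {(i.series, i.index) for i in sdi} == brute
        union = site_determining_ions(p, [r1, r2], how="union")[p.mods[0]]
        assert {(i.series, i.index) for i in sdi} <= {
            (i.series, i.index) for i in union
        }


class TestIsoscaleFilter:
    def _psm(self, p, s, tol=0.01):
        matched = match_fragments(s, p, tol)
        return PSM("s1", p, matched, score_psm(matched, p, s))

    def test_noiseless_modified_form_accepted(self, h3_tail, h3_config):
        p = make_proteoform(h3_tail, "K9me2")
        s = noiseless_spectrum(p, h3_config.scheme)
        rivals = [make_proteoform(h3_tail, "K14me2"), make_proteoform(h3_tail, "K18me2")]
        psm = isoscale_filter(self._psm(p, s), rivals, h3_config)
        assert psm.status == ACCEPTED
        assert all(psm.localization[m] for m in p.mods)

    def test_deleting_discriminating_region_flips_to_ambiguous(self, h3_tail, h3_config):
        p = make_proteoform(h3_tail, "K9me2")
        rival = make_proteoform(h3_tail, "K14me2")
        full = noiseless_spectrum(p, h3_config.scheme)
        n = len(h3_tail)
        drop = {("c", i) for i in range(9, 14)} | {("z", n - i) for i in range(9, 14)}
        keep = [
            (i.neutral_mass, 100.0)
            for i in ion_ladder(p, h3_config.scheme)
            if (i.series, i.index) not in drop
        ]
        s = Spectrum(
            id="d", precursor_neutral_mass=full.precursor_neutral_mass, peaks=keep
        )
        psm = isoscale_filter(self._psm(p, s), [rival], h3_config)
        assert psm.status == REJECTED_AMBIGUOUS

    def test_unmodified_accepts_on_any_match(self, h3_tail, h3_config):
        p = make_proteoform(h3_tail)
        s = noiseless_spectrum(p, h3_config.scheme)
        psm = isoscale_filter(self._psm(p, s), [], h3_config)
        assert psm.status == ACCEPTED

    def test_no_matches_rejected_on_score(self, h3_tail, h3_config):
        p = make_proteoform(h3_tail, "K9me2")
        s = Spectrum(id="x", precursor_neutral_mass=proteoform_mass(p), peaks=[])
        psm = isoscale_filter(self._psm(p, s), [], h3_config)
        assert psm.status == "rejected_score"

    def test_me3_and_ac_never_share_a_discriminating_peak(self, h3_tail, h3_config):
        """0.01 Da matching keeps the 0.0364 Da trimethyl/acetyl gap apart:
        the acetyl candidate never claims the trimethyl's site ions."""
        p = make_proteoform(h3_tail, "K9me3")
        rival = make_proteoform(h3_tail, "K9ac")
        s = noiseless_spectrum(p, h3_config.scheme)
        own = match_fragments(s, p, 0.01)
        riv = match_fragments(s, rival, 0.01)
        own_keys = {(m.ion.series, m.ion.index, m.peak_index) for m in own}
        riv_keys = {(m.ion.series, m.ion.index, m.peak_index) for m in riv}
        sdi = site_determining_ions(p, [rival])[p.mods[0]]
        for i in sdi:
            hit_own = any(k[:2] == (i.series, i.index) for k in own_keys)
            hit_riv = any(k[:2] == (i.series, i.index) for k in riv_keys)
            assert hit_own and not hit_riv


class TestSearchSpectrum:
    def test_true_form_top_ranked_and_accepted(self, h3_tail, h3_config):
        p = make_proteoform(h3_tail, "K14acK27me2:2")
        s = noiseless_spectrum(p, h3_config.scheme)
        res = search_spectrum(s, h3_config, h3_tail)
        assert res.psm.proteoform.notation == "K14acK27me2:2"
        assert res.psm.status == ACCEPTED

    def test_mixed_isobaric_spectrum_yields_cohort(self, h3_tail, h3_config):
        a = make_proteoform(h3_tail, "K9me2")
        b = make_proteoform(h3_tail, "K14me2")
        peaks: dict[float, float] = {}
        for p, w in ((a, 300.0), (b, 100.0)):
            for i in ion_ladder(p, h3_config.scheme):
                k = round(i.neutral_mass, 6)
                peaks[k] = peaks.get(k, 0.0) + w
        s = Spectrum(
            id="mix",
            precursor_neutral_mass=proteoform_mass(a, h3_config.scheme),
            peaks=sorted(peaks.items()),
        )
        res = search_spectrum(s, h3_config, h3_tail)
        assert res.psm.proteoform.notation == "K9me2"
        assert res.psm.status == ACCEPTED
        assert [c.proteoform.notation for c in res.cohort] == ["K14me2"]
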