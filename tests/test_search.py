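"""Crosslink search: digestion, candidate enumeration, MS1/MS2 matching,
site localization, UV dependence and reliability tiering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlmap.chemistry import (
    ChemistryError,
    crosslink_mass,
    mz as to_mz,
    parse_peptide,
    peptide_mass,
)
from xlmap.search import (
    CrosslinkMatch,
    DigestSpec,
    Ms1Feature,
    Ms2Spectrum,
    TierRubric,
    cleavage_sites,
    digest,
    enumerate_candidates,
    fragment_ions,
    localize_sites,
    match_ms1,
    score_ms2,
    tier_matches,
    uv_dependence,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(sequence, spec):
    """Oracle: enumerate every substring whose boundaries are termini or
    cleavage sites and whose internal missed-cleavage count is legal."""
    cut_after = set(cleavage_sites(sequence))  # 0-based "cut after i"
    starts = {0} | {i + 1 for i in cut_after}
    ends = {len(sequence)} | {i + 1 for i in cut_after}
    out = set()
    for s, e in itertools.product(starts, ends):
        if e <= s:
            continue
        missed = sum(1 for i in cut_after if s <= i < e - 1)
        if missed > spec.max_missed_cleavages:
            continue
        if spec.min_length <= e - s <= spec.max_length:
            out.add((s + 1, sequence[s:e]))
    return out


class TestDigest:
    def test_proline_suppresses_cleavage(self):
        peps = digest("SPTKPKGR", DigestSpec(max_missed_cleavages=0))
        assert {p.sequence for p in peps} == {"SPTKPK", "GR"}

    def test_missed_cleavage_products(self):
        peps = digest(
            "LDGQTPHEDRNRQTEIFTHFMTNSAK", DigestSpec(max_missed_cleavages=1)
        )
        seqs = {p.sequence for p in peps}
        assert {"LDGQTPHEDR", "NR", "LDGQTPHEDRNR", "QTEIFTHFMTNSAK"} <= seqs

    def test_empty_sequence(self):
        assert digest("") == []

    def test_illegal_character_rejected(self):
        with pytest.raises(ChemistryError):
            digest("GRJK")

    def test_parent_coordinates(self):
        peps = digest("SPTKPKGR", DigestSpec(max_missed_cleavages=0), parent="p")
        by_seq = {p.sequence: p for p in peps}
        assert (by_seq["SPTKPK"].start, by_seq["SPTKPK"].end) == (1, 6)
        assert (by_seq["GR"].start, by_seq["GR"].end) == (7, 8)

    @settings(deadline=None, max_examples=80)
    @given(
        seq=st.text(alphabet=AMINO_ACIDS, min_size=0, max_size=60),
        missed=st.integers(0, 3),
        min_len=st.integers(1, 3),
        max_len=st.integers(8, 40),
    )
    def test_equals_brute_force_enumeration(self, seq, missed, min_len, max_len):
        spec = DigestSpec(missed, min_len, max_len)
        got = {(p.start, p.sequence) for p in digest(seq, spec, parent="p")}
        assert got == brute_force_digest(seq, spec)


class TestEnumerateCandidates:
    def test_counting(self):
        bait = [parse_peptide("BGR")]
        prey = [parse_peptide(s) for s in ("GR", "SPTKPK", "LDGQTPHEDR")]
        assert len(enumerate_candidates(bait, prey, max_ox=0)) == 3

    def test_met_oxidation_variants(self):
        cands = enumerate_candidates(
            [parse_peptide("BGR")], [parse_peptide("QTEIFTHFMTNSAK")], max_ox=1
        )
        masses = sorted(c.mass for c in cands)
        assert len(masses) == 2
        assert masses[1] - masses[0] == pytest.approx(15.9949, abs=1e-4)

    def test_bait_without_photo_residue_excluded(self):
        cands = enumerate_candidates(
            [parse_peptide("GR"), parse_peptide("BGR")], [parse_peptide("SPTKPK")], 0
        )
        assert all(c.alpha.sequence == "BGR" for c in cands)

    def test_empty_bait_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates([], [parse_peptide("GR")])


class TestMatchMs1:
    def test_published_pair_matches_inside_window(self):
        cand = crosslink_mass(parse_peptide("LDGQTPBEDRNR"), parse_peptide("SPTKPK"))
        hits = match_ms1([Ms1Feature(mass=2207.0968)], [cand], 10.0)
        assert len(hits) == 1
        assert abs(hits[0][2]) < 10

    def test_distant_mass_does_not_match(self):
        cand = crosslink_mass(parse_peptide("LDGQTPBEDRNR"), parse_peptide("SPTKPK"))
        assert match_ms1([Ms1Feature(mass=2300.0)], [cand], 10.0) == []

    def test_equals_brute_force_all_pairs(self):
        rng = np.random.default_rng(7)
        cands = [
            crosslink_mass(parse_peptide("BGR"), parse_peptide("GR"))
            for _ in range(200)
        ]
        # spread candidate masses by faking distinct species masses
        cands = [
            type(c)(c.alpha, c.beta, float(m))
            for c, m in zip(cands, rng.uniform(500, 3500, 200))
        ]
        feats = [Ms1Feature(mass=float(m)) for m in rng.uniform(500, 3500, 50)]
        got = {
            (id(f), id(c))
            for f, c, _ in match_ms1(feats, cands, 50.0)
        }
        expected = {
            (id(f), id(c))
            for f in feats
            for c in cands
            if abs((f.neutral - c.mass) / c.mass * 1e6) <= 50.0
        }
        assert got == expected

    def test_window_widening_is_monotone(self):
        rng = np.random.default_rng(11)
        cands = [
            type(c)(c.alpha, c.beta, float(m))
            for c, m in zip(
                [crosslink_mass(parse_peptide("BGR"), parse_peptide("GR"))] * 50,
                rng.uniform(500, 1500, 50),
            )
        ]
        feats = [Ms1Feature(mass=float(m)) for m in rng.uniform(500, 1500, 20)]
        narrow = {(id(f), id(c)) for f, c, _ in match_ms1(feats, cands, 10.0)}
        wide = {(id(f), id(c)) for f, c, _ in match_ms1(feats, cands, 40.0)}
        assert narrow <= wide

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            match_ms1([], [], 0.0)


def make_xl(alpha="BGR", beta="SPTKPK"):
    # distinct C-terminal residues on the two chains: peptides that end in
    # the same residue share y1 (and b_{n-1} + partner) masses exactly,
    # which is a real ambiguity but not what these tests probe
    return crosslink_mass(parse_peptide(alpha), parse_peptide(beta))


def ladder_spectrum(xl, beta_site, charge=3, keep=None, shift_ppm=0.0):
    """Spectrum holding the complete (or filtered) z=1 fragment ladder."""
    frags = fragment_ions(xl, "alpha", xl.alpha.photo_sites()[0]) + fragment_ions(
        xl, "beta", beta_site
    )
    if keep is not None:
        frags = [f for f in frags if keep(f)]
    mzs = np.sort([to_mz(f.neutral, 1) * (1 + shift_ppm * 1e-6) for f in frags])
    return Ms2Spectrum(
        precursor_mz=to_mz(xl.mass, charge),
        precursor_charge=charge,
        peaks_mz=mzs,
        peaks_intensity=np.ones_like(mzs),
    )


class TestFragmentIons:
    def test_fragment_count(self):
        xl = make_xl()
        frags = fragment_ions(xl, "beta", 2)
        assert len(frags) == 2 * (len("SPTKPK") - 1)

    def test_y1_of_arg_terminal_peptide(self):
        xl = make_xl(beta="GR")
        y1 = [f for f in fragment_ions(xl, "beta", 1) if f.kind == "y"][0]
        assert to_mz(y1.neutral, 1) == pytest.approx(175.1190, abs=1e-3)

    def test_link_spanning_fragments_carry_partner_mass(self):
        xl = make_xl()
        alpha_mass = peptide_mass(xl.alpha)
        with_link = {
            (f.kind, f.index): f.neutral for f in fragment_ions(xl, "beta", 1)
        }
        without = {
            (f.kind, f.index): f.neutral
            for f in fragment_ions(xl, "beta", len(xl.beta.sequence))
        }
        n = len(xl.beta.sequence)
        for i in range(1, n):
            # site-1 hypothesis: every b ion spans the link, no y ion does;
            # site-n hypothesis: the reverse — so b shifts by +mass(alpha)
            # and y by -mass(alpha) between the two hypotheses
            assert with_link[("b", i)] - without[("b", i)] == pytest.approx(
                alpha_mass, abs=1e-9
            )
            assert with_link[("y", i)] - without[("y", i)] == pytest.approx(
                -alpha_mass, abs=1e-9
            )


class TestScoreMs2:
    def test_complete_ladder_fully_matched(self):
        xl = make_xl()
        report = score_ms2(ladder_spectrum(xl, beta_site=3), xl)
        assert report.alpha_matched == report.alpha_total
        assert report.beta_matched == report.beta_total
        assert report.intensity_explained == pytest.approx(1.0)

    def test_shifted_spectrum_matches_nothing(self):
        xl = make_xl()
        report = score_ms2(ladder_spectrum(xl, 3, shift_ppm=50.0), xl, window_ppm=15.0)
        assert report.total_matched == 0

    def test_planted_fraction_recovered(self):
        xl = make_xl()
        rng = np.random.default_rng(5)
        frags = fragment_ions(xl, "alpha", 1) + fragment_ions(xl, "beta", 3)
        kept = [f for f in frags if rng.random() < 0.6]
        mzs = np.sort([to_mz(f.neutral, 1) for f in kept])
        spectrum = Ms2Spectrum(to_mz(xl.mass, 3), 3, mzs, np.ones_like(mzs))
        report = score_ms2(spectrum, xl)
        n_alpha = len({(f.kind, f.index) for f in kept if f.chain == "alpha"})
        assert report.alpha_matched == n_alpha
        assert report.beta_matched >= len(
            {(f.kind, f.index) for f in kept if f.chain == "beta"}
        )

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            score_ms2(
                Ms2Spectrum(1000.0, 3, np.array([]), np.array([])), make_xl()
            )


class TestLocalization:
    def test_complete_ladder_gives_single_site(self):
        xl = make_xl()
        report = score_ms2(ladder_spectrum(xl, beta_site=3), xl)
        _, beta = localize_sites(report)
        assert beta == (3, 3)

    def test_no_discriminating_ions_gives_full_interval(self):
        xl = make_xl()
        # only alpha-chain fragments present: nothing pins the beta site
        report = score_ms2(
            ladder_spectrum(xl, 3, keep=lambda f: f.chain == "alpha"), xl
        )
        _, beta = localize_sites(report)
        assert beta == (1, len(xl.beta.sequence))

    @pytest.mark.parametrize("gap", [(2, 4), (1, 3), (4, 6)])
    def test_missing_ladder_region_gives_interval(self, gap):
        """Removing the ions that discriminate sites j..k leaves exactly the
        interval j..k ambiguous (brute-force enumeration over hypotheses)."""
        lo, hi = gap
        xl = make_xl()
        true_site = lo
        n = len(xl.beta.sequence)

        def discriminates(f):
            # a beta b_i ion separates sites <= i from sites > i
            if f.chain != "beta":
                return True
            i = f.index if f.kind == "b" else n - f.index
            return not (lo <= i < hi)

        report = score_ms2(
            ladder_spectrum(xl, true_site, keep=discriminates), xl
        )
        _, beta = localize_sites(report)
        assert beta == (lo, hi)


class TestUvDependence:
    def test_absent_without_uv_is_flagged(self):
        xl = make_xl()
        plus = [Ms1Feature(mass=xl.mass, intensity=1e6, condition="+UV")]
        ratio, flagged = uv_dependence(plus, [], xl)
        assert ratio == pytest.approx(100.0)  # floor = 1% of +UV signal
        assert flagged

    def test_equal_signal_not_flagged(self):
        xl = make_xl()
        plus = [Ms1Feature(mass=xl.mass, intensity=5e5, condition="+UV")]
        minus = [Ms1Feature(mass=xl.mass, intensity=5e5, condition="-UV")]
        ratio, flagged = uv_dependence(plus, minus, xl)
        assert ratio == pytest.approx(1.0)
        assert not flagged

    def test_planted_enrichment_flagged(self):
        xl = make_xl()
        rng = np.random.default_rng(3)
        plus = [
            Ms1Feature(mass=xl.mass * (1 + rng.normal(0, 3) * 1e-6),
                       intensity=2e6, condition="+UV")
        ]
        minus = [
            Ms1Feature(mass=xl.mass * (1 + rng.normal(0, 3) * 1e-6),
                       intensity=1e5, condition="-UV")
        ]
        ratio, flagged = uv_dependence(plus, minus, xl)
        assert ratio == pytest.approx(20.0)
        assert flagged

    def test_species_absent_everywhere_rejected(self):
        with pytest.raises(ValueError):
            uv_dependence(
                [Ms1Feature(mass=999.0, intensity=1.0)], [], make_xl()
            )


class TestTiering:
    def _match(self, alpha_n, beta_n, uv, ppm):
        xl = make_xl()
        report = score_ms2(ladder_spectrum(xl, 3), xl)
        report.alpha_matched = alpha_n
        report.beta_matched = beta_n
        return CrosslinkMatch(
            xl=xl, ms1_ppm=ppm, report=report, uv_dependent=uv
        )

    @pytest.mark.parametrize(
        "alpha_n,beta_n,uv,ppm,expected",
        [
            (5, 5, True, 2.0, "high"),
            (5, 5, True, 8.0, "medium"),   # MS1 error too large for high
            (5, 5, False, 2.0, "medium"),  # not UV-dependent
            (5, 1, True, 2.0, "medium"),   # one-chain evidence
            (1, 2, True, 2.0, "low"),
        ],
    )
    def test_rubric(self, alpha_n, beta_n, uv, ppm, expected):
        (tiered,) = tier_matches([self._match(alpha_n, beta_n, uv, ppm)])
        assert tiered.tier == expected

    def test_rubric_thresholds_configurable(self):
        (tiered,) = tier_matches(
            [self._match(2, 2, True, 2.0)], TierRubric(min_fragments=2)
        )
        assert tiered.tier == "high"
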