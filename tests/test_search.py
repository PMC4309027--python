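import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoid import chem
from phosphoid.peptide_db import DigestConfig, Protein, build_composite, build_decoy
from phosphoid.search import (
    SearchParams,
    SiteConfig,
    enumerate_site_configs,
    generate_theoretical,
    peak_score,
    precursor_candidates,
    score_match,
    search_spectrum,
)
from phosphoid.spectra import Peak, Spectrum

peptide_seq = st.text(alphabet=sorted(chem.STANDARD_AA), min_size=2, max_size=20)


class TestPrecursorCandidates:
    def test_ppm_window(self, bundled_db):
        params = SearchParams(precursor_tol=7.0, precursor_unit="ppm")
        entry = bundled_db.entries[len(bundled_db.entries) // 2]
        spec = Spectrum("s", entry.neutral_mass + chem.PROTON, 2, [Peak(100, 1)])
        hits = precursor_candidates(bundled_db, spec, params)
        assert entry in hits
        delta = 7.0 * entry.neutral_mass / 1e6
        for e in hits:
            assert abs(e.neutral_mass - entry.neutral_mass) <= delta + 1e-12

    def test_da_boundary_inclusive(self):
        targets = [Protein("P1", "GGGGG")]
        db = build_composite(targets, [], DigestConfig(min_length=1))
        mass = db.entries[0].neutral_mass
        params = SearchParams(precursor_tol=0.5, precursor_unit="Da")
        spec = Spectrum("s", mass + 0.5 + chem.PROTON, 1, [Peak(100, 1)])
        assert precursor_candidates(db, spec, params) == db.entries

    def test_empty_db(self):
        db = build_composite([], [], DigestConfig())
        spec = Spectrum("s", 1000.0, 2, [Peak(100, 1)])
        assert precursor_candidates(db, spec, SearchParams()) == []


class TestSiteConfigs:
    def test_two_of_four_serines(self):
        configs = enumerate_site_configs("FSAASSASK", 2)
        assert [c.modified_sequence for c in configs] == [
            "FsAAsSASK", "FsAASsASK", "FsAASSAsK",
            "FSAAssASK", "FSAAsSAsK", "FSAASsAsK",
        ]

    def test_single_serine(self):
        configs = enumerate_site_configs("SCPEDCK", 1)
        assert [c.modified_sequence for c in configs] == ["sCPEDCK"]

    def test_zero_phospho(self):
        configs = enumerate_site_configs("FSAASSASK", 0)
        assert len(configs) == 1
        assert configs[0].modified_sequence == "FSAASSASK"

    def test_too_many_sites_error(self):
        with pytest.raises(ValueError):
            enumerate_site_configs("SCPEDCK", 2)

    @settings(max_examples=80, deadline=None)
    @given(peptide_seq, st.integers(min_value=0, max_value=8))
    def test_count_matches_exhaustive_subsets(self, seq, n):
        sites = [i for i, aa in enumerate(seq) if aa in "ST"]
        if len(sites) > 8 or n > len(sites):
            return
        configs = enumerate_site_configs(seq, n)
        expected = {tuple(c) for c in combinations(sites, n)}
        assert {c.phospho_positions for c in configs} == expected
        assert len(configs) == math.comb(len(sites), n)


class TestTheoreticalSpectrum:
    def test_ak_b1_y1(self):
        theo = generate_theoretical(SiteConfig("AK", ()))
        by = {(f.series, f.index): f.mz for f in theo.fragments if f.loss == ""}
        assert by[("b", 1)] == pytest.approx(72.0444, abs=1e-4)
        assert by[("y", 1)] == pytest.approx(147.1128, abs=1e-4)

    @settings(max_examples=60, deadline=None)
    @given(peptide_seq)
    def test_by_complementarity(self, seq):
        # b_i + y_{n-i} = (M+H) + proton at 1+
        theo = generate_theoretical(SiteConfig(seq, ()))
        mh = chem.peptide_mass(seq) + chem.PROTON
        by = {(f.series, f.index): f.mz for f in theo.fragments if f.loss == ""}
        for i in range(1, len(seq)):
            assert by[("b", i)] + by[("y", len(seq) - i)] == pytest.approx(
                mh + chem.PROTON, abs=1e-6
            )

    def test_phospho_shifts_all_b_ions(self):
        plain = generate_theoretical(SiteConfig("SCPEDCK", ()))
        phos = generate_theoretical(SiteConfig("SCPEDCK", (0,)))
        b0 = {f.index: f.mz for f in plain.fragments if f.series == "b" and f.loss == ""}
        b1 = {f.index: f.mz for f in phos.fragments if f.series == "b" and f.loss == ""}
        for i in b0:
            assert b1[i] - b0[i] == pytest.approx(chem.PHOSPHO, abs=1e-4)

    def test_h3po4_loss_only_on_phospho_fragments(self):
        theo = generate_theoretical(SiteConfig("SAAAK", (0,)))
        y_losses = {
            f.index for f in theo.fragments if f.series == "y" and f.loss == "H3PO4"
        }
        assert y_losses == set()  # no y fragment contains the N-terminal phospho-S
        b_losses = {
            f.index for f in theo.fragments if f.series == "b" and f.loss == "H3PO4"
        }
        assert b_losses == {1, 2, 3, 4}

    def test_loss_gating_water_ammonia(self):
        theo = generate_theoretical(SiteConfig("GGK", ()))
        # no S/T/E/D anywhere: no water losses; K present: ammonia on all
        assert not any(f.loss == "H2O" for f in theo.fragments)
        y_nh3 = {f.index for f in theo.fragments if f.series == "y" and f.loss == "NH3"}
        assert y_nh3 == {1, 2}
        b_nh3 = {f.index for f in theo.fragments if f.series == "b" and f.loss == "NH3"}
        assert b_nh3 == set()  # b fragments GG, G contain no R/K/N/Q

    def test_all_mz_positive_and_indices_in_range(self):
        theo = generate_theoretical(SiteConfig("FSAASSASK", (1, 4)))
        n = len("FSAASSASK")
        for f in theo.fragments:
            assert f.mz > 0
            assert 1 <= f.index <= n - 1


class TestPeakScore:
    def test_zero(self):
        assert peak_score(0.0) == 0.0

    def test_unit_intensity(self):
        assert peak_score(1.0) == pytest.approx(0.462117, abs=1e-6)

    def test_asymptote(self):
        assert peak_score(100.0) == pytest.approx(1.0, abs=1e-40)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            peak_score(-1.0)

    @given(st.floats(min_value=0, max_value=100))
    def test_range(self, intensity):
        # mathematically < 1; float arithmetic saturates to 1.0 near I ~ 37
        assert 0.0 <= peak_score(intensity) <= 1.0


def brute_force_score(spectrum, theoretical, tol):
    """Independent double-loop oracle with one match per experimental peak."""
    score, matched = 0.0, 0
    for p in spectrum.peaks:
        if any(abs(p.mz - f.mz) <= tol for f in theoretical.fragments):
            score += 2.0 / (1.0 + math.exp(-p.intensity)) - 1.0
            matched += 1
    return score, matched


class TestScoreMatch:
    def test_no_match(self):
        theo = generate_theoretical(SiteConfig("AK", ()))
        spec = Spectrum("s", 500.0, 2, [Peak(400.0, 100.0)])
        score, m, pairs = score_match(spec, theo)
        assert score == 0.0 and m == 0 and pairs == []

    def test_two_intense_matches(self):
        theo = generate_theoretical(SiteConfig("AK", ()))
        by = {(f.series, f.index): f.mz for f in theo.fragments if f.loss == ""}
        spec = Spectrum(
            "s", 500.0, 2,
            [Peak(by[("b", 1)], 100.0), Peak(by[("y", 1)], 100.0)],
        )
        score, m, _ = score_match(spec, theo)
        assert m == 2
        assert score == pytest.approx(2.0, abs=1e-40)

    @settings(max_examples=100, deadline=None)
    @given(
        peptide_seq,
        st.lists(
            st.tuples(
                st.floats(min_value=50, max_value=2000, allow_nan=False),
                st.floats(min_value=0, max_value=100, allow_nan=False),
            ),
            min_size=1,
            max_size=60,
        ),
    )
    def test_matches_brute_force_oracle(self, seq, peak_data):
        theo = generate_theoretical(SiteConfig(seq, ()))
        spec = Spectrum("s", 1000.0, 2, [Peak(mz, i) for mz, i in peak_data])
        params = SearchParams(fragment_tol=0.8)
        score, m, _ = score_match(spec, theo, params)
        exp_score, exp_m = brute_force_score(spec, theo, 0.8)
        assert m == exp_m
        assert score == pytest.approx(exp_score, abs=1e-9)

    def test_score_bounded_by_matched_count(self, rng):
        theo = generate_theoretical(SiteConfig("FSAASSASK", (1,)))
        for _ in range(20):
            peaks = [
                Peak(float(rng.uniform(50, 1500)), float(rng.uniform(0, 100)))
                for _ in range(30)
            ]
            spec = Spectrum("s", 1000.0, 2, peaks)
            score, m, _ = score_match(spec, theo)
            assert 0.0 <= score <= m


def planted_spectrum(modseq, z=2, intensity=90.0):
    seq = modseq.upper()
    positions = tuple(i for i, c in enumerate(modseq) if c.islower())
    config = SiteConfig(seq, positions)
    theo = generate_theoretical(config)
    peaks = [
        Peak(f.mz, intensity) for f in theo.fragments if f.loss == ""
    ]
    neutral = chem.peptide_mass(seq, len(positions))
    precursor_mz = chem.mz_from_neutral(neutral, z)
    peaks.append(Peak(precursor_mz - chem.PHOSPHORIC_ACID / z, 100.0))
    peaks.sort(key=lambda p: p.mz)
    return Spectrum("planted", neutral + chem.PROTON, z, peaks), config


@pytest.fixture(scope="module")
def scpedck_db():
    targets = [Protein("P1", "SCPEDCKAAAGGR")]
    return build_composite(
        targets, build_decoy(targets), DigestConfig(min_length=5)
    )


class TestSearchSpectrum:
    def test_planted_phosphopeptide_rank_one(self, scpedck_db):
        spec, config = planted_spectrum("sCPEDCK")
        target, decoy = search_spectrum(spec, scpedck_db)
        assert target
        assert target[0].modified_sequence == "sCPEDCK"

    def test_no_candidates_gives_empty_lists(self, scpedck_db):
        spec = Spectrum("s", 50000.0, 2, [Peak(100.0, 50.0)])
        assert search_spectrum(spec, scpedck_db) == ([], [])

    def test_lists_partition_by_decoy_flag(self, bundled_db):
        spec, _ = planted_spectrum("sCPEDCK")
        target, decoy = search_spectrum(spec, bundled_db)
        assert all(not h.is_decoy for h in target)
        assert all(h.is_decoy for h in decoy)

    def test_true_isomer_never_outscored_on_clean_spectra(self):
        # site-determining fragments match only the true configuration
        for modseq in ("FsAASSASK", "FSAASsASK", "sCPEDCK", "TAsGSSVTSLDGTR"):
            spec, config = planted_spectrum(modseq)
            scores = {}
            for iso in enumerate_site_configs(config.sequence, config.n_phospho):
                theo = generate_theoretical(iso)
                s, _, _ = score_match(spec, theo)
                scores[iso.modified_sequence] = s
            best = scores[modseq]
            assert best == max(scores.values())

    def test_deterministic_ordering(self, bundled_db):
        spec, _ = planted_spectrum("sCPEDCK")
        a = search_spectrum(spec, bundled_db)
        b = search_spectrum(spec, bundled_db)
        assert [h.modified_sequence for h in a[0]] == [
            h.modified_sequence for h in b[0]
        ]
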