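import numpy as np
import pytest

from topdemux.core_io import PrSM
from topdemux.demultiplex import (
    MULTIPLEXED,
    SINGLE,
    classify_spectrum,
    detect_error_prone,
    feature_map,
    filter_fdr,
    group_proteoforms,
    nnmfm,
    precursor_intensity,
    run_pipeline,
    select_primary,
    shared_match_ratio,
    two_round_search,
)
from topdemux.search_engine import theoretical_prefix_masses

from conftest import exact_by_ions, make_precursor, make_spectrum


def prsm(accession="P1", x=10, y=0, z=0, evalue=1e-6, mass=4500.0, sid="s1",
         is_decoy=False, masses=None):
    if masses is None:
        masses = frozenset(float(i) * 7.0 + 100.0 for i in range(x))
    return PrSM(
        spectrum_id=sid,
        precursor_rank=z,
        accession=accession,
        proteoform_mass=mass,
        shift_count=y,
        shift_da=100.0 if y else 0.0,
        matched_masses=frozenset(masses),
        nnmfm=len(masses) - y * 5 - z * 4,
        evalue=evalue,
        is_decoy=is_decoy,
    )


class TestPrecursorIntensity:
    def test_filtered_sum(self):
        peaks = [(900.1, 500.0), (900.9, 300.0), (1101.2, 200.0)]
        assert precursor_intensity(peaks, 899.5, 902.5) == 800.0

    def test_empty_overlap(self):
        assert precursor_intensity([(900.1, 500.0)], 950.0, 960.0) == 0.0

    def test_window_covering_all(self):
        peaks = [(900.1, 500.0), (900.9, 300.0), (1101.2, 200.0)]
        assert precursor_intensity(peaks, 0.0, 2000.0) == 1000.0


class TestClassification:
    def _spec(self, i1, i2=None):
        precs = [make_precursor(4000.0, intensity=i1, rank=1, feature_id=1)]
        if i2 is not None:
            precs.append(make_precursor(5000.0, intensity=i2, rank=2, feature_id=2))
        return make_spectrum([500.0], precs)

    def test_ratio_at_alpha_is_multiplexed(self):
        # inclusive boundary: 250/1000 = 0.25 >= 0.2; and exactly 0.20
        assert classify_spectrum(self._spec(1000, 250), 0.2) == MULTIPLEXED
        assert classify_spectrum(self._spec(1000, 200), 0.2) == MULTIPLEXED

    def test_ratio_below_alpha_is_single(self):
        assert classify_spectrum(self._spec(1000, 199), 0.2) == SINGLE

    def test_one_precursor_is_single(self):
        assert classify_spectrum(self._spec(1000), 0.2) == SINGLE

    def test_zero_intensity_is_single(self):
        assert classify_spectrum(self._spec(0.0, 0.0), 0.2) == SINGLE


class TestErrorProneDetection:
    def test_shared_ratio_formula(self):
        m1 = frozenset(range(12))
        m2 = frozenset(range(5, 15))  # |m2|=10, overlap 7
        assert shared_match_ratio(m1, m2) == pytest.approx(0.7)
        assert shared_match_ratio(m1, m1) == 1.0
        assert shared_match_ratio(m1, frozenset(range(100, 105))) == 0.0

    def test_empty_set_gives_zero(self):
        assert shared_match_ratio(frozenset(), frozenset([1.0])) == 0.0

    def test_same_protein_is_error_prone(self):
        a = prsm("P1", masses=frozenset([1.0]))
        b = prsm("P1", masses=frozenset([9.0]))
        assert detect_error_prone(a, b, 0.7)

    def test_shared_ratio_boundary_inclusive(self):
        common = [float(i) for i in range(7)]
        a = prsm("P1", masses=frozenset(common + [10.0, 11.0, 12.0]))
        b = prsm("P2", masses=frozenset(common + [20.0, 21.0, 22.0]))
        assert detect_error_prone(a, b, 0.7)  # 7/10 = 0.70 exactly
        b69 = prsm("P2", masses=frozenset(common[:-1] + [20.0, 21.0, 22.0, 23.0]))
        assert not detect_error_prone(a, b69, 0.7)  # 6/10


class TestNNMFM:
    @pytest.mark.parametrize(
        "x,y,z,expected", [(20, 1, 1, 11), (20, 0, 0, 20), (3, 1, 1, -6)]
    )
    def test_formula_with_default_penalties(self, x, y, z, expected):
        assert nnmfm(x, y, z, 5, 4) == expected


def _two_protein_world():
    """Two distinct proteins whose masses differ by <200 Da so the shifted
    mis-assignment channel is open."""
    rng = np.random.default_rng(8)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    while True:
        sa = "".join(rng.choice(aas, size=40))
        sb = "".join(rng.choice(aas, size=40))
        ma = theoretical_prefix_masses(sa).proteoform_mass
        mb = theoretical_prefix_masses(sb).proteoform_mass
        if 10.0 < ma - mb < 190.0:
            from topdemux.core_io import Protein

            return [Protein("PA", sa), Protein("PB", sb)]


class TestSelectPrimary:
    def test_only_one_pfps_identified(self, cfg):
        db = _two_protein_world()
        fa = theoretical_prefix_masses(db[0].sequence)
        frags = sorted(exact_by_ions(db[0].sequence).tolist())
        p1 = make_precursor(fa.proteoform_mass, intensity=1000, rank=1, feature_id=1)
        p2 = make_precursor(fa.proteoform_mass + 3000, intensity=500, rank=2, feature_id=2)
        spec = make_spectrum(frags, [p1, p2])
        sel = select_primary(spec, db, cfg)
        assert sel.primary_rank == 0
        assert sel.prsm1.accession == "PA"
        assert sel.prsm2 is None

    def test_error_prone_resolved_by_nnmfm(self, cfg):
        # fragments overwhelmingly from PB; F1 carries PA-compatible mass, so
        # PFPS1 matches PB only through a shift while PFPS2 matches PB cleanly
        db = _two_protein_world()
        fa = theoretical_prefix_masses(db[0].sequence)
        fb = theoretical_prefix_masses(db[1].sequence)
        frags = sorted(exact_by_ions(db[1].sequence).tolist())
        p1 = make_precursor(fa.proteoform_mass, intensity=1000, rank=1, feature_id=1)
        p2 = make_precursor(fb.proteoform_mass, intensity=500, rank=2, feature_id=2)
        spec = make_spectrum(frags, [p1, p2])
        sel = select_primary(spec, db, cfg)
        assert sel.error_prone  # both PrSMs hit PB
        assert sel.prsm1.accession == "PB" and sel.prsm2.accession == "PB"
        assert sel.primary_rank == 1  # clean zero-shift match wins on NNMFM

    def test_nnmfm_tie_prefers_f1(self, cfg):
        # neither PFPS identified: F1 by fallback
        db = _two_protein_world()
        p1 = make_precursor(9999.0, intensity=1000, rank=1, feature_id=1)
        p2 = make_precursor(9899.0, intensity=500, rank=2, feature_id=2)
        spec = make_spectrum([300.0, 400.0], [p1, p2])
        sel = select_primary(spec, db, cfg)
        assert sel.primary_rank == 0
        assert sel.prsm1 is None and sel.prsm2 is None


class TestTwoRoundSearch:
    def test_subtract_then_identify_second(self, cfg, small_proteome):
        pa, pb = small_proteome[0], small_proteome[1]
        fa = theoretical_prefix_masses(pa.sequence)
        fb = theoretical_prefix_masses(pb.sequence)
        frags_a = exact_by_ions(pa.sequence)[:15]
        frags_b = exact_by_ions(pb.sequence)[:10]
        spec = make_spectrum(
            np.concatenate([frags_a, frags_b]),
            [
                make_precursor(fa.proteoform_mass, intensity=1000, rank=1, feature_id=1),
                make_precursor(fb.proteoform_mass, intensity=500, rank=2, feature_id=2),
            ],
        )
        result = two_round_search(spec, small_proteome, cfg, primary_rank=0)
        assert result.round1.accession == pa.accession
        assert result.round1.matched_count == 15
        assert result.round2.accession == pb.accession
        assert result.round2.matched_count == 10
        # subtraction soundness
        assert not result.round1.matched_masses & result.round2.matched_masses

    def test_same_protein_keeps_lower_evalue(self, cfg, small_proteome):
        # both rounds hit the same protein: round 1 via unshifted prefixes,
        # round 2 via shifted suffixes on the remaining masses
        pa = small_proteome[3]
        fa = theoretical_prefix_masses(pa.sequence)
        prefixes = fa.prefix_masses[:10]
        shifted_suffixes = (fa.proteoform_mass + 100.0) - fa.prefix_masses[-10:]
        spec = make_spectrum(
            np.concatenate([prefixes, shifted_suffixes]),
            [
                make_precursor(fa.proteoform_mass, intensity=1000, rank=1, feature_id=1),
                make_precursor(fa.proteoform_mass + 100.0, intensity=500, rank=2, feature_id=2),
            ],
        )
        result = two_round_search(spec, small_proteome, cfg, primary_rank=0)
        kept = result.prsms
        assert len(kept) == 1
        assert kept[0].accession == pa.accession

    def test_round2_runs_on_full_list_when_round1_empty(self, cfg, small_proteome):
        pb = small_proteome[1]
        fb = theoretical_prefix_masses(pb.sequence)
        frags = exact_by_ions(pb.sequence)[:12]
        spec = make_spectrum(
            frags,
            [
                make_precursor(99999.0, intensity=1000, rank=1, feature_id=1),
                make_precursor(fb.proteoform_mass, intensity=500, rank=2, feature_id=2),
            ],
        )
        result = two_round_search(spec, small_proteome, cfg, primary_rank=0)
        assert result.round1 is None
        assert result.round2.accession == pb.accession
        assert result.round2.matched_count == 12


class TestFdrFilter:
    def test_clean_targets_kept(self):
        rows = [
            prsm("T1", evalue=1e-9, sid="a"),
            prsm("T2", evalue=1e-8, sid="b"),
            prsm("T3", evalue=1e-7, sid="c"),
            prsm("D1", evalue=1e-2, sid="d", is_decoy=True),
        ]
        kept = filter_fdr(rows, 0.01)
        assert sorted(p.accession for p in kept) == ["T1", "T2", "T3"]

    def test_alternating_targets_decoys_all_rejected(self):
        # decoy leads each pair, so every prefix FDR is >= 0.5
        rows = []
        for i in range(10):
            rows.append(
                prsm(f"D{i}", evalue=10.0 ** (-9 + i) / 2, sid=f"d{i}", is_decoy=True)
            )
            rows.append(prsm(f"T{i}", evalue=10.0 ** (-9 + i), sid=f"t{i}"))
        assert filter_fdr(rows, 0.01) == []

    def test_vacuous_cutoff_keeps_all_targets(self):
        rows = [
            prsm("T1", evalue=1e-3, sid="a"),
            prsm("D1", evalue=1e-5, sid="b", is_decoy=True),
        ]
        kept = filter_fdr(rows, 1.0)
        assert [p.accession for p in kept] == ["T1"]

    def test_empty_input(self):
        assert filter_fdr([], 0.01) == []


class TestGrouping:
    def test_same_protein_within_mass_tol(self, cfg):
        a = prsm("P1", mass=10000.0, sid="s1")
        b = prsm("P1", mass=10001.1, sid="s2")
        groups = group_proteoforms([a, b], {}, cfg)
        assert len(groups) == 1

    def test_same_protein_beyond_tol_split(self, cfg):
        a = prsm("P1", mass=10000.0, sid="s1")
        b = prsm("P1", mass=10001.3, sid="s2")
        fmap = {("s1", 0): 1, ("s2", 0): 2}
        assert len(group_proteoforms([a, b], fmap, cfg)) == 2

    def test_same_feature_links_different_proteins(self, cfg):
        a = prsm("P1", mass=10000.0, sid="s1")
        b = prsm("P2", mass=12000.0, sid="s2")
        fmap = {("s1", 0): 7, ("s2", 0): 7}
        assert len(group_proteoforms([a, b], fmap, cfg)) == 1

    def test_boundary_1p19_groups_1p20_does_not(self, cfg):
        a = prsm("P1", mass=10000.0, sid="s1")
        close = prsm("P1", mass=10001.19, sid="s2")
        apart = prsm("P1", mass=10001.20, sid="s3")
        fmap = {("s1", 0): 1, ("s2", 0): 2, ("s3", 0): 3}
        assert len(group_proteoforms([a, close], fmap, cfg)) == 1
        assert len(group_proteoforms([a, apart], fmap, cfg)) == 2

    def test_best_evalue_is_group_minimum(self, cfg):
        a = prsm("P1", mass=10000.0, sid="s1", evalue=1e-4)
        b = prsm("P1", mass=10000.5, sid="s2", evalue=1e-9)
        g = group_proteoforms([a, b], {}, cfg)[0]
        assert g.best_evalue == pytest.approx(1e-9)


class TestRunPipeline:
    def test_empty_database_yields_empty_tables(self, cfg):
        spec = make_spectrum([500.0], [make_precursor(4000.0)])
        result = run_pipeline([spec], [], cfg)
        assert result.prsms == [] and result.groups == []

    def test_single_spectra_reduce_to_one_round(self, cfg, target_decoy_db, small_proteome):
        pa = small_proteome[0]
        fa = theoretical_prefix_masses(pa.sequence)
        spec = make_spectrum(
            exact_by_ions(pa.sequence)[:12],
            [make_precursor(fa.proteoform_mass, intensity=1000)],
        )
        full = run_pipeline([spec], target_decoy_db, cfg)
        naive = run_pipeline(
            [spec], target_decoy_db, cfg, primary_selection=False, second_round=False
        )
        assert [p.accession for p in full.prsms] == [p.accession for p in naive.prsms]
        assert len(full.prsms) == 1

    def test_fragment_intensities_do_not_affect_matching(self, cfg, target_decoy_db, small_proteome):
        pa = small_proteome[0]
        fa = theoretical_prefix_masses(pa.sequence)
        masses = tuple(sorted(exact_by_ions(pa.sequence)[:12].tolist()))
        prec = make_precursor(fa.proteoform_mass, intensity=1000)
        s1 = make_spectrum(masses, [prec])
        s2 = s1.__class__(
            spectrum_id=s1.spectrum_id,
            iso_lo=s1.iso_lo,
            iso_hi=s1.iso_hi,
            precursors=s1.precursors,
            frag_masses=s1.frag_masses,
            frag_intensities=tuple(2 * v for v in s1.frag_intensities),
        )
        r1 = run_pipeline([s1], target_decoy_db, cfg)
        r2 = run_pipeline([s2], target_decoy_db, cfg)
        assert [p.matched_masses for p in r1.prsms] == [p.matched_masses for p in r2.prsms]

    def test_output_prsms_satisfy_stored_invariants(self, cfg, target_decoy_db, small_proteome):
        pa, pb = small_proteome[4], small_proteome[5]
        fa = theoretical_prefix_masses(pa.sequence)
        fb = theoretical_prefix_masses(pb.sequence)
        spec = make_spectrum(
            np.concatenate(
                [exact_by_ions(pa.sequence)[:14], exact_by_ions(pb.sequence)[:9]]
            ),
            [
                make_precursor(fa.proteoform_mass, intensity=1000, rank=1, feature_id=1),
                make_precursor(fb.proteoform_mass, intensity=600, rank=2, feature_id=2),
            ],
        )
        result = run_pipeline([spec], target_decoy_db, cfg)
        assert len(result.prsms) == 2
        for p in result.prsms:
            assert p.matched_masses <= set(spec.frag_masses)
            assert p.nnmfm == pytest.approx(
                p.matched_count - p.shift_count * cfg.delta - p.precursor_rank * cfg.gamma
            )

    def test_feature_map_covers_all_precursors(self, small_proteome):
        pa = small_proteome[0]
        fa = theoretical_prefix_masses(pa.sequence)
        spec = make_spectrum(
            [500.0],
            [
                make_precursor(fa.proteoform_mass, intensity=1000, rank=1, feature_id=11),
                make_precursor(fa.proteoform_mass + 50, intensity=500, rank=2, feature_id=22),
            ],
        )
        fmap = feature_map([spec])
        assert fmap == {("S1", 0): 11, ("S1", 1): 22}
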