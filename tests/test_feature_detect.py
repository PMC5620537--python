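"""MS1 envelope/feature detection, MS/MS linkage, unassigned mining."""

import numpy as np
import pytest

from mzcanvas.averagine import isotope_distribution
from mzcanvas.constants import ISOTOPE_SPACING, PROTON
from mzcanvas.feature_detect import (DetectorParams, detect_envelopes,
                                     detect_features, link_ms2,
                                     unassigned_features)
from mzcanvas.model import Spectrum
from mzcanvas.results_store import PSMRecord, ResultsDB
from mzcanvas.spectra_io import read_run, write_mzml
from mzcanvas.synth import (NoiseModel, SyntheticPeptideSpec, demo_specs,
                            make_run)
from mzcanvas.pepcalc import Peptide


def _ms1(mzs, intens, scan_id=1, rt=1.0):
    return Spectrum(scan_id=scan_id, ms_level=1, rt=rt,
                    mz=np.array(mzs, float), intensity=np.array(intens, float))


def _envelope_peaks(mono_mz, charge, neutral, depth=3, amp=1000.0):
    fracs = isotope_distribution(neutral, depth)
    mzs = [mono_mz + k * ISOTOPE_SPACING / charge for k in range(depth)]
    return mzs, [amp * f for f in fracs]


class TestDetectEnvelopes:
    def test_z2_cluster_recovered(self):
        mono = 500.000
        neutral = (mono - PROTON) * 2
        mzs, ints = _envelope_peaks(mono, 2, neutral)
        envs = detect_envelopes(_ms1(mzs, ints))
        assert len(envs) == 1
        assert envs[0].charge == 2
        assert envs[0].mono_mz == pytest.approx(mono, abs=1e-6)
        assert envs[0].score >= 0.9

    def test_isolated_singletons_yield_nothing(self):
        envs = detect_envelopes(_ms1([400.0, 900.0], [100.0, 80.0]))
        assert envs == []

    def test_overlapping_z1_z2_both_recovered(self):
        m1, i1 = _envelope_peaks(600.30, 1, 600.30 - PROTON, amp=800.0)
        m2, i2 = _envelope_peaks(600.75, 2, (600.75 - PROTON) * 2, amp=1000.0)
        order = np.argsort(m1 + m2)
        all_mz = np.array(m1 + m2)[order]
        all_in = np.array(i1 + i2)[order]
        envs = detect_envelopes(_ms1(all_mz, all_in))
        assert sorted(e.charge for e in envs) == [1, 2]
        by_z = {e.charge: e for e in envs}
        assert by_z[1].mono_mz == pytest.approx(600.30, abs=1e-6)
        assert by_z[2].mono_mz == pytest.approx(600.75, abs=1e-6)

    def test_peak_disjointness(self, noisy_run_dir):
        path, _, _ = noisy_run_dir
        for scan in read_run(path).scans(ms_level=1):
            seen = set()
            for env in detect_envelopes(scan):
                overlap = seen & set(env.peak_indices)
                assert not overlap
                seen |= set(env.peak_indices)

    def test_profile_rejected(self):
        s = _ms1([500.0, 500.5], [1.0, 2.0])
        s.centroided = False
        with pytest.raises(Exception):
            detect_envelopes(s)


class TestDetectFeatures:
    def _match(self, feature, row, ppm=5.0):
        return (feature.charge == row.charge
                and abs(feature.mono_mz - row.mono_mz) / row.mono_mz
                <= ppm * 1e-6
                and abs(feature.apex_rt - row.apex_rt) < 0.3)

    def test_zero_noise_exact_recovery(self, clean_run, clean_truth):
        feats = detect_features(clean_run)
        assert len(feats) == len(clean_truth) == 10
        for _, row in clean_truth.iterrows():
            assert sum(self._match(f, row) for f in feats) == 1

    def test_snr10_recall_precision(self, noisy_run_dir):
        path, _, truth = noisy_run_dir
        feats = detect_features(read_run(path))
        tp = sum(any(self._match(f, row) for _, row in truth.iterrows())
                 for f in feats)
        assert tp / len(truth) >= 0.95      # recall
        assert tp / len(feats) >= 0.95      # precision

    def test_min_scans_threshold(self, tmp_path):
        # one-scan blip must not become a feature at min_scans=3
        spec = SyntheticPeptideSpec(Peptide("AEFVEVTK"), charge=2,
                                    apex_rt=0.4, sigma=0.01, include_ms2=False)
        path = str(tmp_path / "blip.mzML")
        make_run([spec], gradient=(1.0, 0.2), seed=0, out_path=path)
        run = read_run(path)
        present = [s.scan_id for s in run.scans(1) if s.n_peaks > 0]
        assert len(present) == 1
        assert detect_features(run, DetectorParams(min_scans=3)) == []

    def test_gap_spanning(self, clean_run_dir, tmp_path):
        """A 1-scan dropout is bridged at max_gap=1, split at max_gap=0."""
        _, spectra, truth = clean_run_dir
        row = truth.iloc[0]
        member = [int(x) for x in row.ms1_scan_ids.split(";")]
        drop = member[len(member) // 2]
        edited = []
        for s in spectra:
            if s.scan_id == drop:
                lo, hi = row.mono_mz - 0.1, row.mono_mz + 3.0
                keep = (s.mz < lo) | (s.mz > hi)
                s = s.with_peaks(s.mz[keep], s.intensity[keep])
            edited.append(s)
        path = str(tmp_path / "gap.mzML")
        write_mzml(edited, path)
        run = read_run(path)
        bridged = [f for f in detect_features(run, DetectorParams(max_gap=1))
                   if self._match(f, row)]
        assert len(bridged) == 1
        assert bridged[0].n_scans == len(member) - 1
        split = [f for f in detect_features(run, DetectorParams(max_gap=0))
                 if f.charge == row.charge
                 and abs(f.mono_mz - row.mono_mz) / row.mono_mz <= 5e-6]
        assert len(split) == 2

    def test_area_matches_trapezoid_of_generator_trace(self, clean_run,
                                                       clean_truth):
        feats = detect_features(clean_run)
        for _, row in clean_truth.iterrows():
            f = next(f for f in feats if self._match(f, row))
            rts, monos = [], []
            for sid in (int(x) for x in row.ms1_scan_ids.split(";")):
                s = clean_run.get_scan(sid)
                rts.append(s.rt)
                j = np.argmin(np.abs(s.mz - row.mono_mz))
                monos.append(s.intensity[j])
            brute = np.trapezoid(monos, rts)
            assert f.area == pytest.approx(brute, rel=0.01)


class TestLinkMS2:
    def test_generator_ms2_linked_to_its_feature(self, clean_run, clean_truth):
        feats = link_ms2(detect_features(clean_run), clean_run)
        for _, row in clean_truth.iterrows():
            want = {int(x) for x in row.ms2_scan_ids.split(";") if x}
            f = next(f for f in feats
                     if abs(f.mono_mz - row.mono_mz) / row.mono_mz <= 5e-6)
            assert set(f.ms2_scan_ids) == want

    def test_far_rt_not_linked(self, clean_run):
        feats = detect_features(clean_run)
        ms2 = clean_run.scans(ms_level=2)[0]
        target = next(f for f in feats
                      if abs(f.mono_mz - ms2.precursor_mz) < 0.01)
        # fake scan at an rt far outside every feature
        far = Spectrum(scan_id=9999, ms_level=2, rt=99.0, mz=ms2.mz,
                       intensity=ms2.intensity, precursor_mz=ms2.precursor_mz,
                       precursor_charge=ms2.precursor_charge)
        run2 = read_run(clean_run.source_path)
        run2.add(far)
        feats = link_ms2(detect_features(run2), run2)
        target = next(f for f in feats
                      if abs(f.mono_mz - ms2.precursor_mz) < 0.01)
        assert 9999 not in target.ms2_scan_ids

    def test_plus_one_isotope_precursor_links(self, clean_run_dir, tmp_path):
        """MS2 selecting the +1 isotope still links to the feature."""
        path, spectra, truth = clean_run_dir
        row = truth.iloc[2]
        iso1 = row.mono_mz + ISOTOPE_SPACING / row.charge
        extra = Spectrum(scan_id=5000, ms_level=2, rt=row.apex_rt + 1e-3,
                         mz=np.array([200.0]), intensity=np.array([1.0]),
                         precursor_mz=iso1, precursor_charge=int(row.charge))
        p2 = str(tmp_path / "iso.mzML")
        write_mzml(list(spectra) + [extra], p2)
        run = read_run(p2)
        feats = link_ms2(detect_features(run), run)
        # brute force over all (feature, scan) pairs for the expected owner
        owner = [f for f in feats if 5000 in f.ms2_scan_ids]
        assert len(owner) == 1
        assert abs(owner[0].mono_mz - row.mono_mz) / row.mono_mz <= 5e-6


class TestUnassigned:
    def _linked(self, run):
        return link_ms2(detect_features(run), run)

    def test_empty_db_returns_all(self, clean_run):
        feats = self._linked(clean_run)
        assert len(unassigned_features(feats, ResultsDB())) == len(feats)

    def test_full_db_returns_none(self, clean_run):
        feats = self._linked(clean_run)
        db = ResultsDB()
        db.add_records([PSMRecord(run="clean", scan_id=sid, peptide="PEPTIDEK",
                                  charge=2)
                        for f in feats for sid in f.ms2_scan_ids])
        assert unassigned_features(feats, db) == []

    def test_partial_db_set_difference(self, clean_run, clean_truth):
        feats = self._linked(clean_run)
        assigned_rows = clean_truth.iloc[:3]
        scans = [int(x) for r in assigned_rows.ms2_scan_ids
                 for x in r.split(";") if x]
        db = ResultsDB()
        db.add_records([PSMRecord(run="clean", scan_id=s, peptide="AEFVEVTK",
                                  charge=2) for s in scans])
        unas = unassigned_features(feats, db)
        assert len(unas) == 7
        assert all(not (set(f.ms2_scan_ids) & set(scans)) for f in unas)
        areas = [f.area for f in unas]
        assert areas == sorted(areas, reverse=True)
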