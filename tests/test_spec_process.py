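"""Spectral pre-processing: de-isotoping, charge reduction, filtering,
pipelines with provenance records, and re-search export."""

import numpy as np
import pytest

from mzcanvas.averagine import isotope_distribution
from mzcanvas.constants import ISOTOPE_SPACING, PROTON
from mzcanvas.errors import DataError
from mzcanvas.model import Spectrum
from mzcanvas.pepcalc import Peptide, fragment_ions
from mzcanvas.spec_process import (PipelineError, ProcessingStep,
                                   apply_pipeline, charge_reduce, deisotope,
                                   export_for_research, filter_ions,
                                   parse_pipeline_config, parse_record_digest,
                                   register_step, replay, spectrum_digest)
from mzcanvas.synth import make_msms


def _ms2(mzs, intens, charges=None):
    return Spectrum(scan_id=7, ms_level=2, rt=2.0, mz=np.array(mzs, float),
                    intensity=np.array(intens, float), precursor_mz=600.0,
                    precursor_charge=2,
                    peak_charges=None if charges is None
                    else np.array(charges, int))


class TestDeisotope:
    def test_z2_envelope_collapsed_with_summed_intensity(self):
        mzs = [500.000, 500.000 + ISOTOPE_SPACING / 2,
               500.000 + 2 * ISOTOPE_SPACING / 2]
        s = _ms2(mzs, [100.0, 60.0, 20.0])
        out = deisotope(s)
        assert out.n_peaks == 1
        assert out.mz[0] == pytest.approx(500.000, abs=1e-9)
        assert out.intensity[0] == pytest.approx(180.0)
        assert out.peak_charges[0] == 2

    def test_identity_on_envelope_free_spectrum(self):
        s = _ms2([300.0, 450.0, 800.0], [5.0, 7.0, 3.0])
        out = deisotope(s)
        np.testing.assert_array_equal(out.mz, s.mz)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_idempotent_and_never_grows(self, rng):
        s = make_msms(Peptide("DAFLGSFLYEYSR"), 2, fragment_charges=(1, 2),
                      fragment_isotopes=3, seed=5)
        once = deisotope(s)
        twice = deisotope(once)
        assert once.n_peaks <= s.n_peaks
        np.testing.assert_array_equal(once.mz, twice.mz)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_tic_conserved_for_envelope_only_spectrum(self):
        fr = isotope_distribution(1200.0, 4)
        mzs, ints = [], []
        for base, z in ((400.0, 1), (700.0, 2)):
            for k, f in enumerate(fr):
                mzs.append(base + k * ISOTOPE_SPACING / z)
                ints.append(1000 * f)
        order = np.argsort(mzs)
        s = _ms2(np.array(mzs)[order], np.array(ints)[order])
        out = deisotope(s)
        assert out.intensity.sum() == pytest.approx(s.intensity.sum(),
                                                    rel=1e-12)


class TestChargeReduce:
    def test_z2_peak_lands_at_singly_charged_mz(self):
        s = _ms2([500.0], [10.0], charges=[2])
        out = charge_reduce(s)
        assert out.mz[0] == pytest.approx(2 * 500.0 - PROTON, abs=1e-9)
        assert out.peak_charges[0] == 1

    def test_identity_on_singly_charged(self):
        s = _ms2([300.0, 400.0], [1.0, 2.0], charges=[1, 1])
        out = charge_reduce(s)
        np.testing.assert_array_equal(out.mz, s.mz)

    def test_neutral_mass_conserved_per_peak(self, rng):
        mzs = np.sort(rng.uniform(200, 900, 100))
        charges = rng.integers(1, 5, 100)
        s = _ms2(mzs, np.ones(100), charges=charges)
        out = charge_reduce(s, merge_tol=1e-12)
        before = np.sort(mzs * charges - charges * PROTON)
        after = np.sort(out.mz * out.peak_charges
                        - out.peak_charges * PROTON)
        # merged collisions sum intensity but every surviving neutral mass
        # must come from the input set
        for nm in after:
            assert np.min(np.abs(before - nm)) < 1e-9

    def test_without_annotations_is_noop(self):
        s = _ms2([500.0], [10.0])
        assert charge_reduce(s) is s

    def test_collision_merge(self):
        # z=2 at 500.0 reduces to 998.992724, colliding with existing z=1 peak
        target = 2 * 500.0 - PROTON
        s = _ms2([500.0, target], [10.0, 5.0], charges=[2, 1])
        out = charge_reduce(s, merge_tol=0.01)
        assert out.n_peaks == 1
        assert out.intensity[0] == pytest.approx(15.0)


class TestFilterIons:
    def test_empty_exclusion_is_identity(self):
        s = _ms2([100.0, 200.0], [1.0, 2.0])
        out = filter_ions(s, [], 0.01)
        np.testing.assert_array_equal(out.mz, s.mz)

    def test_full_exclusion_empties_spectrum(self):
        s = _ms2([100.0, 200.0], [1.0, 2.0])
        assert filter_ions(s, [100.0, 200.0], 0.01).n_peaks == 0

    def test_window_survivors_match_brute_force(self, rng):
        mzs = np.sort(rng.uniform(100, 1000, 10))
        s = _ms2(mzs, np.arange(1.0, 11.0))
        excl = [float(mzs[2]), float(mzs[5]), float(mzs[8])]
        out = filter_ions(s, excl, 0.001)
        brute = [m for m in mzs if all(abs(m - e) > 0.001 for e in excl)]
        np.testing.assert_allclose(out.mz, brute)
        assert out.n_peaks == 7


class TestPipeline:
    def _steps(self, excl):
        return [ProcessingStep("filter_ions",
                               {"exclusion_mzs": excl, "tol": 0.02}),
                ProcessingStep("deisotope", {}),
                ProcessingStep("charge_reduce", {})]

    def test_empty_pipeline_is_identity(self):
        s = _ms2([100.0], [1.0])
        out, rec = apply_pipeline(s, [])
        assert out is s or np.array_equal(out.mz, s.mz)
        assert rec.steps == []
        assert rec.input_digest == rec.output_digest

    def test_composition_equals_manual_application(self):
        contams = [(136.0623, 5e4), (185.1280, 6e4), (301.2220, 4e4)]
        s = make_msms(Peptide("LVNELTEFAK"), 2, fragment_charges=(1, 2),
                      fragment_isotopes=3, extra_peaks=contams, seed=3)
        excl = [c[0] for c in contams]
        piped, rec = apply_pipeline(s, self._steps(excl))
        manual = charge_reduce(deisotope(filter_ions(s, excl, 0.02)))
        np.testing.assert_array_equal(piped.mz, manual.mz)
        np.testing.assert_array_equal(piped.intensity, manual.intensity)
        assert rec.output_digest == spectrum_digest(manual)

    def test_replay_reproduces_record(self):
        s = make_msms(Peptide("QTALVELLK"), 2, fragment_isotopes=3, seed=9)
        out, rec = apply_pipeline(s, self._steps([400.0]))
        replayed = replay(rec, s)
        np.testing.assert_array_equal(replayed.mz, out.mz)
        with pytest.raises(DataError):
            replay(rec, _ms2([100.0], [1.0]))

    def test_unknown_step_rejected(self):
        with pytest.raises(DataError, match="unknown processing step"):
            apply_pipeline(_ms2([100.0], [1.0]),
                           [ProcessingStep("transmogrify", {})])

    def test_failing_step_flags_partial_record(self):
        def boom(spectrum, **params):
            raise RuntimeError("kaput")

        register_step("boom", boom)
        s = _ms2([100.0], [1.0])
        with pytest.raises(PipelineError) as err:
            apply_pipeline(s, [ProcessingStep("filter_ions",
                                              {"exclusion_mzs": [1.0],
                                               "tol": 0.01}),
                               ProcessingStep("boom", {})])
        rec = err.value.record
        assert rec.partial
        assert [st.name for st in rec.steps] == ["filter_ions"]

    def test_user_registered_step_runs_in_pipeline(self):
        def halve(spectrum, factor=2.0):
            return spectrum.with_peaks(spectrum.mz,
                                       spectrum.intensity / factor)

        register_step("halve", halve)
        s = _ms2([100.0, 200.0], [4.0, 8.0])
        out, rec = apply_pipeline(s, [ProcessingStep("halve",
                                                     {"factor": 4.0})])
        np.testing.assert_allclose(out.intensity, [1.0, 2.0])
        assert rec.steps[0].params == {"factor": 4.0}

    def test_config_parsing(self):
        steps = parse_pipeline_config(
            "# clean-up\nfilter_ions exclusion_mzs=136.0623,185.128 tol=0.02\n"
            "deisotope\ncharge_reduce merge_tol=0.005\n")
        assert [s.name for s in steps] == ["filter_ions", "deisotope",
                                           "charge_reduce"]
        assert steps[0].params["exclusion_mzs"] == [136.0623, 185.128]
        assert steps[2].params["merge_tol"] == 0.005


class TestExport:
    def test_digest_titles_and_determinism(self, tmp_path):
        spectra = [make_msms(Peptide(seq), 2, fragment_isotopes=3, seed=k,
                             scan_id=k + 1)
                   for k, seq in enumerate(["AEFVEVTK", "YLYEIARR"])]
        steps = [ProcessingStep("deisotope", {})]
        processed = [apply_pipeline(s, steps) for s in spectra]
        p1, p2 = str(tmp_path / "a.mgf"), str(tmp_path / "b.mgf")
        export_for_research(processed, p1, run_name="clean")
        export_for_research(processed, p2, run_name="clean")
        assert open(p1, "rb").read() == open(p2, "rb").read()  # byte-identical
        text = open(p1).read()
        assert text.count("BEGIN IONS") == 2
        records = {rec.digest: rec for _, rec in processed}
        titles = [ln for ln in text.splitlines() if ln.startswith("TITLE=")]
        for title in titles:
            digest = parse_record_digest(title)
            assert digest in records  # digests resolve to stored records

    def test_precursor_fields_unchanged_by_processing(self, tmp_path):
        s = make_msms(Peptide("AEFVEVTK"), 2, fragment_isotopes=3, seed=1)
        out, rec = apply_pipeline(s, [ProcessingStep("deisotope", {})])
        assert out.precursor_mz == s.precursor_mz
        assert out.precursor_charge == s.precursor_charge
        assert out.activation == s.activation
        assert not np.array_equal(out.mz, s.mz)  # only peak content differs
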