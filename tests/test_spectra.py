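"""Spectrum axis arithmetic, doublet detection, and spectrum algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsplit import (
    QuadrupolarDoublet,
    SplittingSet,
    build_axis,
    detect_doublets,
    identify_residual_doublet,
    splitting_shift,
    sum_spectra,
    synthesize_spectrum,
)
from qsplit.errors import (
    AmbiguityError,
    FragmentMismatchError,
    IncompatibleAxesError,
    InvalidParameterError,
    OutOfRangeError,
)
from qsplit.fixtures import make_doublet_spectrum

from conftest import FIVE_SPLITTINGS


class TestAxis:
    @pytest.mark.parametrize(
        "n_points, width, expected_spacing",
        [
            (32768, 43_100.0, 1.3153076171875),  # the instrument's 1.32 Hz/point
            (2, 100.0, 50.0),
            (1000, 1000.0, 1.0),
        ],
    )
    def test_spacing(self, n_points, width, expected_spacing):
        axis = build_axis(n_points, width)
        assert axis.spacing == pytest.approx(expected_spacing, rel=1e-12)

    def test_instrument_axis_rounds_to_printed_resolution(self):
        assert round(build_axis(32768, 43_100.0).spacing, 2) == 1.32

    def test_frequencies_symmetric_about_center(self):
        for center in (0.0, 150.0):
            f = build_axis(256, 1000.0, center=center).frequencies()
            np.testing.assert_allclose(f + f[::-1], 2 * center, atol=1e-9)

    @pytest.mark.parametrize("n_points, width", [(1, 100.0), (0, 100.0), (64, 0.0), (64, -5.0)])
    def test_invalid_parameters_rejected(self, n_points, width):
        with pytest.raises(InvalidParameterError):
            build_axis(n_points, width)


class TestSynthesize:
    def test_single_doublet_peaks_at_programmed_positions(self):
        axis = build_axis(4096, 10_000.0)
        spec = synthesize_spectrum([QuadrupolarDoublet(splitting=1000.0)], axis)
        freqs = axis.frequencies()
        top2 = freqs[np.argsort(spec.intensity)[-2:]]
        np.testing.assert_allclose(sorted(np.abs(top2)), 500.0, atol=axis.spacing)
        # symmetric line pair: equal maxima
        i_left = np.argmin(np.abs(freqs + 500.0))
        i_right = np.argmin(np.abs(freqs - 500.0))
        assert spec.intensity[i_left] == pytest.approx(spec.intensity[i_right], rel=1e-6)

    def test_empty_doublet_list_gives_zero_spectrum(self):
        spec = synthesize_spectrum([], build_axis(128, 1000.0))
        assert np.all(spec.intensity == 0.0)

    def test_component_outside_axis_raises(self):
        with pytest.raises(OutOfRangeError):
            synthesize_spectrum([QuadrupolarDoublet(splitting=2000.0)], build_axis(128, 1000.0))

    def test_noise_is_seed_reproducible(self):
        axis = build_axis(512, 5000.0)
        a = synthesize_spectrum([QuadrupolarDoublet(1000.0)], axis, noise_sd=0.1, seed=7)
        b = synthesize_spectrum([QuadrupolarDoublet(1000.0)], axis, noise_sd=0.1, seed=7)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestDetect:
    def test_noiseless_round_trip_within_one_spacing(self):
        spec, _ = make_doublet_spectrum([1000.0], axis=build_axis(8192, 20_000.0))
        found = detect_doublets(spec)
        assert len(found) == 1
        assert found.doublets[0].splitting == pytest.approx(1000.0, abs=spec.axis.spacing)
        assert not found.unpaired

    def test_two_doublet_spectrum_recovered(self):
        # a fragment in two average orientations shows two splittings
        spec, _ = make_doublet_spectrum([8000.0, 21_000.0])
        found = detect_doublets(spec)
        got = sorted(d.splitting for d in found.doublets)
        np.testing.assert_allclose(got, [8000.0, 21_000.0], atol=2 * spec.axis.spacing)

    def test_doublets_ordered_outermost_first(self, five_doublet_spectrum):
        spec, _ = five_doublet_spectrum
        found = detect_doublets(spec)
        splittings = [d.splitting for d in found.doublets]
        assert splittings == sorted(splittings, reverse=True)

    def test_lone_peak_is_reported_unpaired(self):
        axis = build_axis(4096, 10_000.0)
        freqs = axis.frequencies()
        intensity = np.exp(-0.5 * ((freqs - 300.0) / 30.0) ** 2)
        from qsplit import Spectrum

        found = detect_doublets(Spectrum(axis, intensity))
        assert len(found.doublets) == 0
        assert len(found.unpaired) == 1
        assert found.unpaired[0][0] == pytest.approx(300.0, abs=axis.spacing)

    def test_flat_spectrum_yields_empty_result(self):
        from qsplit import Spectrum

        axis = build_axis(256, 1000.0)
        found = detect_doublets(Spectrum(axis, np.zeros(256)))
        assert len(found) == 0 and not found.unpaired

    def test_min_snr_must_exceed_one(self, five_doublet_spectrum):
        with pytest.raises(InvalidParameterError):
            detect_doublets(five_doublet_spectrum[0], min_snr=0.5)


class TestSumAndResidual:
    def test_sum_of_one_is_identity(self):
        spec, _ = make_doublet_spectrum([5000.0])
        total = sum_spectra([spec])
        np.testing.assert_array_equal(total.intensity, spec.intensity)

    def test_spectrum_plus_negation_is_zero(self):
        from qsplit import Spectrum

        spec, _ = make_doublet_spectrum([5000.0])
        neg = Spectrum(spec.axis, -spec.intensity)
        assert np.all(sum_spectra([spec, neg]).intensity == 0.0)

    def test_axis_mismatch_rejected(self):
        a, _ = make_doublet_spectrum([5000.0], axis=build_axis(1024, 20_000.0))
        b, _ = make_doublet_spectrum([5000.0], axis=build_axis(2048, 20_000.0))
        with pytest.raises(IncompatibleAxesError):
            sum_spectra([a, b])

    def test_sum_of_four_singles_shows_four_doublets(self):
        singles = [make_doublet_spectrum([s], seed=i)[0] for i, s in enumerate(FIVE_SPLITTINGS[:4])]
        found = detect_doublets(sum_spectra(singles))
        got = sorted(d.splitting for d in found.doublets)
        np.testing.assert_allclose(got, sorted(FIVE_SPLITTINGS[:4]),
                                   atol=2 * singles[0].axis.spacing)

    def test_residual_doublet_is_the_held_out_one(self):
        # sum of four singly labelled spectra vs. the fully labelled spectrum:
        # the unmatched pair belongs to the unlabelled fragment
        singles = [make_doublet_spectrum([s], seed=i)[0] for i, s in enumerate(FIVE_SPLITTINGS[1:])]
        full, _ = make_doublet_spectrum(FIVE_SPLITTINGS, seed=9)
        residual = identify_residual_doublet(sum_spectra(singles), full)
        assert residual.splitting == pytest.approx(FIVE_SPLITTINGS[0], abs=10.0)

    def test_identical_spectra_raise_zero_unmatched(self):
        spec, _ = make_doublet_spectrum(FIVE_SPLITTINGS[:3])
        with pytest.raises(AmbiguityError):
            identify_residual_doublet(spec, spec)

    def test_two_extra_doublets_raise_with_candidates(self):
        base, _ = make_doublet_spectrum(FIVE_SPLITTINGS[:3])
        full, _ = make_doublet_spectrum(FIVE_SPLITTINGS)
        with pytest.raises(AmbiguityError) as err:
            identify_residual_doublet(base, full)
        assert len(err.value.candidates) == 2


class TestSplittingShift:
    def test_identical_sets_give_zeros(self):
        s = SplittingSet({"C2": (25_000.0,), "C3": (21_000.0, 18_000.0)})
        assert all(v == (0.0,) * len(v) for v in splitting_shift(s, s).values())

    def test_elementwise_difference(self):
        ref = SplittingSet({"C2": (25_000.0,)})
        per = SplittingSet({"C2": (24_000.0,)})
        assert splitting_shift(ref, per) == {"C2": (-1000.0,)}

    def test_programmed_uniform_shift_recovered(self):
        values = {f"C{i}": (10_000.0 + 1500.0 * i,) for i in range(5)}
        ref = SplittingSet(values)
        per = SplittingSet({k: (v[0] - 500.0,) for k, v in values.items()})
        shifts = splitting_shift(ref, per)
        assert all(s == (-500.0,) for s in shifts.values())

    def test_label_and_count_mismatches_rejected(self):
        ref = SplittingSet({"C2": (25_000.0,)})
        with pytest.raises(FragmentMismatchError):
            splitting_shift(ref, SplittingSet({"C3": (25_000.0,)}))
        with pytest.raises(FragmentMismatchError):
            splitting_shift(ref, SplittingSet({"C2": (25_000.0, 1000.0)}))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        vals=st.lists(st.floats(1.0, 50_000.0), min_size=1, max_size=4),
        delta=st.floats(-1000.0, 1000.0),
    )
    def test_shift_is_antisymmetric(self, vals, delta):
        ref = SplittingSet({f"F{i}": (v,) for i, v in enumerate(vals)})
        per = SplittingSet({f"F{i}": (max(v + delta, 0.0),) for i, v in enumerate(vals)})
        fwd = splitting_shift(ref, per)
        rev = splitting_shift(per, ref)
        for k in fwd:
            assert fwd[k][0] == pytest.approx(-rev[k][0], abs=1e-9)


class TestSplittingSetInvariants:
    def test_at_most_two_per_fragment(self):
        with pytest.raises(InvalidParameterError):
            SplittingSet({"L4": (1.0, 2.0, 3.0)})

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            SplittingSet({"L4": (-1.0,)})

    def test_provenance_restricted(self):
        with pytest.raises(InvalidParameterError):
            SplittingSet({"L4": (1.0,)}, provenance="guessed")
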