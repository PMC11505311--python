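"""The 15 mode features, each checked against a loop-level definition oracle."""

import math

import numpy as np
import pytest

from ecgbispec.bispectrum import BispectrumMatrix, bispectrum_direct
from ecgbispec.features import (
    FEATURE_NAMES,
    LOG_EPS,
    approximate_entropy,
    bispectral_features,
    entropy_features,
    extract_all,
    fuzzy_entropy,
    lempel_ziv,
    lz76_phrase_count,
    permutation_entropy,
    psd_peak_burg,
    sample_entropy,
)

FS = 1000.0


# ---------------------------------------------------------------------------
# loop-level oracles (definitions written out directly, no vectorization)


def bispectral_oracle(w, fs, nfft, cutoff_hz=120.0, beta=0.95):
    n = w.shape[0]
    res = fs / nfft
    fcut = int(round(cutoff_hz / res))
    total = sum(w[i, j] for i in range(n) for j in range(n))
    out = {}
    out["bispec_brightness"] = (
        sum(w[i, j] for i in range(fcut, n) for j in range(fcut, n)) / total
    )
    logs = [math.log(max(w[i, j], LOG_EPS)) for i in range(n) for j in range(n)]
    out["bispec_flatness"] = math.exp(sum(logs) / (n * n)) / (total / (n * n))
    rolloff_bin = 0.0
    found = False
    for F in range(n):
        s = sum(w[i, j] for i in range(F + 1) for j in range(F + 1))
        if s <= beta * total:
            rolloff_bin, found = F, True
    out["bispec_rolloff"] = rolloff_bin * res if found else 0.0
    ent = 0.0
    for i in range(n):
        for j in range(n):
            p = w[i, j] / total
            if p > 0:
                ent -= p * math.log(p)
    out["bispec_entropy"] = ent
    tot2 = sum(w[i, j] ** 2 for i in range(n) for j in range(n))
    ent2 = 0.0
    for i in range(n):
        for j in range(n):
            q = w[i, j] ** 2 / tot2
            if q > 0:
                ent2 -= q * math.log(q)
    out["bispec_sq_entropy"] = ent2
    out["sum_log_amp"] = sum(logs)
    dlogs = [math.log(max(w[k, k], LOG_EPS)) for k in range(n)]
    out["sum_log_diag"] = sum(dlogs)
    m1 = sum(k * dlogs[k] for k in range(n))
    out["diag_moment1"] = m1
    out["diag_moment2"] = sum((k - m1) ** 2 * dlogs[k] for k in range(n))
    return out


def apen_oracle(x, m, r):
    n = len(x)

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            count = 0
            for tj in templates:
                if max(abs(a - b) for a, b in zip(ti, tj)) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m, r):
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + t] - x[j + t]) for t in range(m)) <= r:
                b += 1
            if max(abs(x[i + t] - x[j + t]) for t in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return 0.0  # undefined; the implementation's degenerate convention
    return -math.log(a / b)


def fuzzyen_oracle(x, m, r, nf=2.0):
    n = len(x)

    def phi(mm):
        templates = []
        for i in range(n - m):
            t = x[i : i + mm]
            mu = sum(t) / mm
            templates.append([v - mu for v in t])
        total = 0.0
        for i, ti in enumerate(templates):
            for j, tj in enumerate(templates):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(ti, tj))
                total += math.exp(-((d / r) ** nf))
        return total / (len(templates) * (len(templates) - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def permen_oracle(x, order, delay):
    patterns = {}
    n = len(x) - (order - 1) * delay
    for i in range(n):
        window = [x[i + k * delay] for k in range(order)]
        pat = tuple(sorted(range(order), key=lambda k: (window[k], k)))
        patterns[pat] = patterns.get(pat, 0) + 1
    total = sum(patterns.values())
    h = -sum(c / total * math.log(c / total) for c in patterns.values())
    return h / math.log(math.factorial(order))


class TestBispectralFeatures:
    def test_point_mass_at_origin(self):
        w = np.zeros((9, 9))
        w[0, 0] = 5.0
        B = BispectrumMatrix(values=w.astype(complex), nfft=16, fs=FS)
        f = bispectral_features(B)
        assert f["bispec_brightness"] == 0.0
        assert f["bispec_entropy"] == 0.0
        assert f["bispec_rolloff"] == 0.0

    def test_uniform_matrix(self):
        w = np.full((9, 9), 2.0)
        B = BispectrumMatrix(values=w.astype(complex), nfft=16, fs=FS)
        f = bispectral_features(B)
        assert f["bispec_flatness"] == pytest.approx(1.0)
        assert f["bispec_entropy"] == pytest.approx(math.log(81))

    def test_point_mass_above_cutoff_brightness_one(self):
        # fs=1000, nfft=16 -> 62.5 Hz/bin; cutoff 120 Hz -> bin 2
        w = np.zeros((9, 9))
        w[5, 5] = 1.0  # 312.5 Hz on both axes
        B = BispectrumMatrix(values=w.astype(complex), nfft=16, fs=FS)
        assert bispectral_features(B)["bispec_brightness"] == 1.0

    def test_all_zero_matrix_degenerate(self):
        B = BispectrumMatrix(values=np.zeros((9, 9), complex), nfft=16, fs=FS)
        f = bispectral_features(B)
        assert f["bispec_brightness"] == 0.0
        assert f["bispec_flatness"] == 0.0
        assert f["bispec_entropy"] == 0.0

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(100):
            w = rng.uniform(0, 3.0, size=(8, 8))
            w[rng.uniform(size=(8, 8)) < 0.2] = 0.0  # include exact zeros
            w = (w + w.T) / 2
            B = BispectrumMatrix(values=w.astype(complex), nfft=14, fs=FS)
            got = bispectral_features(B)
            want = bispectral_oracle(w, FS, 14)
            for key, val in want.items():
                assert got[key] == pytest.approx(val, rel=1e-9, abs=1e-9), key


class TestPsdPeakBurg:
    def test_ar_coefficients_match_reference_burg(self, rng):
        """Lattice recursion agrees with the statsmodels Burg coefficients."""
        from statsmodels.regression.linear_model import burg as sm_burg

        from ecgbispec.features import burg_ar

        x = rng.standard_normal(120)
        x -= x.mean()
        rho, _ = burg_ar(x, 10)
        rho_ref, _ = sm_burg(x, order=10, demean=False)
        np.testing.assert_allclose(rho, rho_ref, atol=1e-12)

    def test_peak_frequency_of_tone(self):
        t = np.arange(601) / FS
        _, freq = psd_peak_burg(np.sin(2 * np.pi * 40 * t), fs=FS)
        assert freq == pytest.approx(40.0, abs=2.0)

    def test_white_noise_peak_location_varies(self):
        locs = set()
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(601)
            locs.add(round(psd_peak_burg(x, fs=FS)[1]))
        assert len(locs) > 5  # no fixed bin across realizations

    def test_power_scales_quadratically(self, rng):
        x = rng.standard_normal(601)
        p1, _ = psd_peak_burg(x, fs=FS)
        p2, _ = psd_peak_burg(2.0 * x, fs=FS)
        assert p2 / p1 == pytest.approx(4.0, rel=0.01)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            psd_peak_burg(np.zeros(16), order=16)


class TestEntropies:
    def test_constant_signal(self):
        f = entropy_features(np.ones(50))
        assert f["apen"] == 0.0
        assert f["permen"] == 0.0
        assert f["sampen"] == 0.0

    def test_alternating_sequence_permutation_entropy(self):
        x = np.array([0.0, 1.0] * 25)
        assert permutation_entropy(x, order=3) == pytest.approx(
            math.log(2) / math.log(6), abs=1e-12
        )

    def test_random_sequences_match_oracles(self, rng):
        for _ in range(3):
            x = rng.standard_normal(60)
            r = 0.2 * float(np.std(x))
            assert approximate_entropy(x, 2, r) == pytest.approx(
                apen_oracle(list(x), 2, r), abs=1e-9
            )
            assert sample_entropy(x, 2, r) == pytest.approx(
                sampen_oracle(list(x), 2, r), abs=1e-9
            )
            assert fuzzy_entropy(x, 2, r) == pytest.approx(
                fuzzyen_oracle(list(x), 2, r), abs=1e-9
            )
            assert permutation_entropy(x, 3, 1) == pytest.approx(
                permen_oracle(list(x), 3, 1), abs=1e-9
            )

    def test_noise_less_regular_than_sinusoid(self, rng):
        n = 400
        t = np.arange(n) / FS
        sine = np.sin(2 * np.pi * 5 * t)
        noise = rng.standard_normal(n)
        noise *= np.std(sine) / np.std(noise)
        assert sample_entropy(noise, 2) > sample_entropy(sine, 2)

    def test_zero_tolerance_rejected(self, rng):
        with pytest.raises(ValueError):
            entropy_features(rng.standard_normal(60), r=0.0)


class TestLempelZiv:
    def test_constant_signal_single_phrase(self):
        _, c = lempel_ziv(np.ones(64))
        assert c == 1

    def test_hand_parsed_example(self):
        # 0001101001000101 parses as 0 | 001 | 10 | 100 | 1000 | then the
        # tail "101", which is reproducible from the history (positions
        # 4..6) and therefore uncounted: 5 completed phrases
        bits = np.array([0, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 1])
        assert lz76_phrase_count(bits) == 5

    def test_random_string_normalized_near_one(self, rng):
        x = rng.standard_normal(10_000)
        norm, _ = lempel_ziv(x)
        assert 0.8 <= norm <= 1.2


class TestExtractAll:
    @pytest.fixture(scope="class")
    def beat_and_modes(self):
        from ecgbispec.decompose import vmd
        from ecgbispec.preprocess import extract_beats
        from ecgbispec.synth import SynthConfig, generate_record

        rec = generate_record(SynthConfig(seed=4), "A", 0)
        beat = extract_beats(rec, leads=["II"])["II"][0]
        return beat, vmd(beat.samples, K=10, fs=FS)

    def test_five_modes_times_15_features_all_finite(self, beat_and_modes):
        beat, ms = beat_and_modes
        fvs = extract_all(beat, ms)
        assert len(fvs) == 5
        for fv in fvs:
            assert set(fv.values) == set(FEATURE_NAMES)
            assert np.all(np.isfinite(fv.as_array()))

    def test_deterministic(self, beat_and_modes):
        beat, ms = beat_and_modes
        a = extract_all(beat, ms)
        b = extract_all(beat, ms)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.as_array(), fb.as_array())

    def test_scale_invariant_features_and_log_shift(self, beat_and_modes):
        from ecgbispec.decompose import ModeSet

        beat, ms = beat_and_modes
        scaled = ModeSet(
            method=ms.method,
            modes=[10.0 * m for m in ms.modes],
            center_freqs=ms.center_freqs,
        )
        base = extract_all(beat, ms)
        big = extract_all(beat, scaled)
        # flatness is excluded here: its geometric mean floors the exact
        # zeros outside the bispectral triangle at LOG_EPS, which does not
        # scale with the signal; on strictly positive matrices it is
        # scale-invariant (checked below)
        invariant = [
            "bispec_brightness", "bispec_rolloff",
            "bispec_entropy", "bispec_sq_entropy", "permen", "lzc",
        ]
        for fb, fs_ in zip(base, big):
            for name in invariant:
                assert fs_.values[name] == pytest.approx(
                    fb.values[name], rel=1e-6, abs=1e-6
                ), name

    def test_sum_log_amp_shift_under_cubic_scaling(self, rng):
        # when every cell sits above the log floor, scaling the source by s
        # scales amplitudes by s^3 and shifts sum_log_amp by n_cells * 3 ln s
        w = rng.uniform(1.0, 5.0, size=(9, 9))
        w = (w + w.T) / 2
        b1 = BispectrumMatrix(values=w.astype(complex), nfft=16, fs=FS)
        b2 = BispectrumMatrix(values=(1000.0 * w).astype(complex), nfft=16, fs=FS)
        f1 = bispectral_features(b1)
        f2 = bispectral_features(b2)
        shift = f2["sum_log_amp"] - f1["sum_log_amp"]
        assert shift == pytest.approx(81 * 3.0 * math.log(10.0), rel=1e-9)
        assert f2["bispec_flatness"] == pytest.approx(f1["bispec_flatness"], rel=1e-9)
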