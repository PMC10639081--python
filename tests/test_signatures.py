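import numpy as np
import pandas as pd
import pytest

from conftest import nnls_projected_gradient
from isomutsig import (
    SBS96_LABELS,
    SignatureMatrix,
    SignatureNMF,
    SignatureRefitter,
    Spectrum,
    UndefinedSpectrumError,
    ValidationError,
    assemble_reference_set,
    cosine,
    difference_spectrum,
    nmf_extract,
    refit,
    refit_strict,
    select_mmrd,
    two_component_fit,
)


def random_signature_frame(rng, n_sigs, names=None, concentration=1.0):
    w = rng.gamma(concentration, 1.0, size=(96, n_sigs))
    w /= w.sum(axis=0)
    names = names or [f"S{i}" for i in range(n_sigs)]
    return pd.DataFrame(w, index=SBS96_LABELS, columns=names)


class TestRefit:
    def test_single_signature_spectrum_recovered_exactly(self):
        rng = np.random.default_rng(0)
        sigs = SignatureMatrix(random_signature_frame(rng, 5))
        spec = Spectrum(SBS96_LABELS, 100 * sigs.values[:, 2])
        fit = refit(spec, sigs)
        expected = np.zeros(5); expected[2] = 100
        assert np.allclose(fit.exposures, expected, atol=1e-9)
        assert fit.reconstruction_cosine == pytest.approx(1.0)

    def test_zero_spectrum_zero_exposures(self):
        rng = np.random.default_rng(1)
        sigs = SignatureMatrix(random_signature_frame(rng, 3))
        fit = refit(Spectrum(SBS96_LABELS, np.zeros(96)), sigs)
        assert np.all(fit.exposures == 0)

    def test_orthogonal_support_mixture_vs_projected_gradient(self):
        a = np.zeros(96); a[:48] = 1 / 48
        b = np.zeros(96); b[48:] = 1 / 48
        frame = pd.DataFrame({"A": a, "B": b}, index=SBS96_LABELS)
        sigs = SignatureMatrix(frame)
        spec = Spectrum(SBS96_LABELS, 70 * a + 30 * b)
        fit = refit(spec, sigs)
        oracle = nnls_projected_gradient(spec.values, sigs.values)
        assert np.allclose(fit.exposures, [70, 30], atol=1e-6)
        assert np.allclose(fit.exposures, oracle, atol=1e-4)

    def test_optimality_against_random_candidates(self):
        rng = np.random.default_rng(3)
        sigs = SignatureMatrix(random_signature_frame(rng, 4))
        y = rng.random(96) * 10
        fit = refit(Spectrum(SBS96_LABELS, y), sigs)
        best = np.linalg.norm(y - sigs.values @ fit.exposures)
        for _ in range(200):
            cand = rng.random(4) * 20
            assert best <= np.linalg.norm(y - sigs.values @ cand) + 1e-9

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        sigs = SignatureMatrix(random_signature_frame(rng, 2))
        with pytest.raises(ValidationError):
            refit(np.ones(83), sigs)


class TestRefitStrict:
    def test_decoys_removed_exposure_intact(self):
        rng = np.random.default_rng(5)
        frame = random_signature_frame(rng, 11, names=["true"] + [f"decoy{i}" for i in range(10)])
        sigs = SignatureMatrix(frame)
        spec = Spectrum(SBS96_LABELS, 500 * frame["true"].to_numpy())
        fit = refit_strict(spec, sigs, max_delta=0.004)
        assert set(fit.removed) == {f"decoy{i}" for i in range(10)}
        assert fit.exposure_of("true") == pytest.approx(500, abs=1e-6)

    def test_max_delta_zero_reduces_to_plain_refit(self):
        rng = np.random.default_rng(6)
        sigs = SignatureMatrix(random_signature_frame(rng, 6))
        y = Spectrum(SBS96_LABELS, rng.random(96) * 50)
        plain = refit(y, sigs)
        strict = refit_strict(y, sigs, max_delta=0.0)
        assert np.allclose(plain.exposures, strict.exposures, atol=1e-9)

    def test_max_delta_one_keeps_at_most_one(self):
        rng = np.random.default_rng(7)
        sigs = SignatureMatrix(random_signature_frame(rng, 6))
        y = Spectrum(SBS96_LABELS, rng.random(96) * 50)
        fit = refit_strict(y, sigs, max_delta=1.0)
        assert (fit.exposures > 0).sum() <= 1

    def test_agrees_with_exhaustive_subset_search(self):
        """On a single-signature spectrum with decoys, the greedy pruning
        lands on the same surviving set as an exhaustive search over all
        subsets for the smallest set reaching the full-set cosine."""
        from itertools import combinations
        from scipy.optimize import nnls as sp_nnls

        rng = np.random.default_rng(8)
        frame = random_signature_frame(rng, 6, names=[f"S{i}" for i in range(6)])
        sigs = SignatureMatrix(frame)
        y = 300 * frame["S3"].to_numpy()
        fit = refit_strict(Spectrum(SBS96_LABELS, y), sigs, max_delta=0.004)
        survivors = {n for n, e in zip(fit.names, fit.exposures) if n not in fit.removed}

        def cos_of(subset):
            A = frame[list(subset)].to_numpy()
            e, _ = sp_nnls(A, y)
            r = A @ e
            return np.dot(y, r) / (np.linalg.norm(y) * np.linalg.norm(r) + 1e-300)

        best = None
        for k in range(1, 7):
            for sub in combinations(frame.columns, k):
                if cos_of(sub) >= 1 - 1e-9:
                    best = set(sub)
                    break
            if best:
                break
        assert survivors == best == {"S3"}

    def test_telescoping_cosine_bound(self):
        rng = np.random.default_rng(9)
        sigs = SignatureMatrix(random_signature_frame(rng, 8))
        y = Spectrum(SBS96_LABELS, (sigs.values @ rng.random(8)) * 100)
        full = refit(y, sigs)
        strict = refit_strict(y, sigs, max_delta=0.004)
        k = len(strict.removed)
        assert strict.reconstruction_cosine > full.reconstruction_cosine - k * 0.004 - 1e-12


class TestEstimatorInterface:
    def test_get_set_params_and_transform(self):
        rng = np.random.default_rng(10)
        frame = random_signature_frame(rng, 3)
        est = SignatureRefitter(signatures=frame, strict=True, max_delta=0.01)
        assert est.get_params()["max_delta"] == 0.01
        est.set_params(max_delta=0.004).fit()
        X = (frame.to_numpy() @ np.array([[50, 10, 0], [0, 0, 80]]).T).T
        expo = est.transform(X)
        assert expo.shape == (2, 3)
        assert expo[1][2] == pytest.approx(80, abs=1e-6)

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = SignatureRefitter(strict=True)
        assert clone(est).strict is True


class TestNMF:
    def test_identical_columns_rank_one(self):
        col = np.abs(np.random.default_rng(0).normal(size=96)) + 0.1
        catalog = pd.DataFrame(
            np.tile(col[:, None], 8), index=SBS96_LABELS,
            columns=[f"s{i}" for i in range(8)]
        )
        sigs, expo = nmf_extract(catalog, k=1, n_starts=5, rng_seed=0)
        assert cosine(sigs.iloc[:, 0].to_numpy(), col) >= 1 - 1e-6

    def test_planted_two_signature_recovery(self, synthetic_signatures):
        rng = np.random.default_rng(1)
        A = synthetic_signatures["syn_mmrd"].to_numpy()
        B = synthetic_signatures["syn_oxygen"].to_numpy()
        assert cosine(A, B) < 0.6
        cols = {}
        for i in range(20):
            w = rng.uniform(0.2, 0.8)
            mix = w * A + (1 - w) * B
            cols[f"s{i}"] = rng.multinomial(2000, mix / mix.sum())
        catalog = pd.DataFrame(cols, index=SBS96_LABELS)
        sigs, expo = nmf_extract(catalog, k=2, n_starts=10, rng_seed=2)
        got = sigs.to_numpy()
        sims = np.array([[cosine(got[:, i], t) for t in (A, B)] for i in range(2)])
        # each planted signature matched by a distinct extracted one
        assert max(sims[0, 0], sims[1, 0]) >= 0.95
        assert max(sims[0, 1], sims[1, 1]) >= 0.95
        assert np.argmax(sims[0]) != np.argmax(sims[1])

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 96))
        est = SignatureNMF(n_signatures=3, n_starts=3, random_state=0).fit(X)
        curve = est.objective_curve_
        assert np.all(np.diff(curve) <= 1e-9)

    def test_seeded_bit_reproducibility(self):
        rng = np.random.default_rng(3)
        X = rng.random((8, 96))
        a = SignatureNMF(n_signatures=2, n_starts=4, random_state=7).fit(X)
        b = SignatureNMF(n_signatures=2, n_starts=4, random_state=7).fit(X)
        assert np.array_equal(a.signatures_.to_numpy(), b.signatures_.to_numpy())
        assert np.array_equal(a.exposures_, b.exposures_)

    def test_comparable_to_sklearn_nmf(self):
        """Independent cross-check: reconstruction error is close to
        scikit-learn's NMF on the same catalog and rank."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(4)
        W = rng.random((12, 2)); H = rng.random((2, 96))
        X = W @ H + 0.01 * rng.random((12, 96))
        ours = SignatureNMF(n_signatures=2, n_starts=10, random_state=0).fit(X)
        ref = NMF(n_components=2, init="random", random_state=0, max_iter=2000).fit(X)
        ref_err = np.linalg.norm(X - ref.transform(X) @ ref.components_)
        assert ours.reconstruction_err_ <= ref_err * 1.05

    def test_rank_must_be_below_sample_count(self):
        with pytest.raises(ValidationError):
            SignatureNMF(n_signatures=5).fit(np.random.rand(5, 96))


class TestDifferenceSpectrum:
    def test_equal_rates_undefined(self):
        v = np.abs(np.random.default_rng(0).normal(size=96)) + 0.1
        a = Spectrum(SBS96_LABELS, v * 10)
        b = Spectrum(SBS96_LABELS, v * 5)
        with pytest.raises(UndefinedSpectrumError):
            difference_spectrum(a, b, norm_high=10, norm_low=5)

    def test_planted_added_component_recovered(self, synthetic_signatures):
        S1 = synthetic_signatures["syn_mmrd"].to_numpy()
        S2 = synthetic_signatures["syn_oxygen"].to_numpy()
        low = Spectrum(SBS96_LABELS, S1 * 50)
        high = Spectrum(SBS96_LABELS, S1 * 50 + S2 * 60)
        diff, floored = difference_spectrum(high, low, 1.0, 1.0)
        assert cosine(diff.values, S2) >= 0.999
        assert floored == 0

    def test_flooring_counted(self):
        a = np.zeros(96); a[0] = 10; a[1] = 1
        b = np.zeros(96); b[0] = 1; b[1] = 10
        d, floored = difference_spectrum(
            Spectrum(SBS96_LABELS, a), Spectrum(SBS96_LABELS, b), 1.0, 1.0
        )
        assert floored == 1
        assert d.values.sum() == pytest.approx(1.0)

    def test_per_doubling_normalization_applied(self):
        v = np.zeros(96); v[5] = 1
        w = np.zeros(96); w[7] = 1
        high = Spectrum(SBS96_LABELS, 200 * v + 100 * w)
        low = Spectrum(SBS96_LABELS, 100 * w)
        # high sample grew twice as long: per-doubling the w channel cancels
        d, _ = difference_spectrum(high, low, norm_high=2.0, norm_low=1.0)
        assert d.values[7] == 0
        assert d.values[5] == pytest.approx(1.0)


class TestTwoComponentFit:
    def test_pure_low_stratum(self, synthetic_signatures):
        low = Spectrum(SBS96_LABELS, synthetic_signatures["syn_mmrd"].to_numpy(), normalized=False)
        diff = Spectrum(SBS96_LABELS, synthetic_signatures["syn_oxygen"].to_numpy())
        strata = [Spectrum(SBS96_LABELS, 400 * low.values)]
        out = two_component_fit(strata, low, diff)
        assert out.loc[0, "exposure_low"] == pytest.approx(400, rel=1e-6)
        assert out.loc[0, "exposure_difference"] == pytest.approx(0, abs=1e-6)

    def test_monotone_planted_mixture(self, synthetic_signatures):
        low_v = synthetic_signatures["syn_mmrd"].to_numpy()
        diff_v = synthetic_signatures["syn_oxygen"].to_numpy()
        strata = [
            Spectrum(SBS96_LABELS, 300 * low_v + f * 300 * diff_v)
            for f in np.linspace(0, 1, 10)
        ]
        out = two_component_fit(
            strata,
            Spectrum(SBS96_LABELS, low_v),
            Spectrum(SBS96_LABELS, diff_v),
        )
        expo = out["exposure_difference"].to_numpy()
        assert np.all(np.diff(expo) > 0)

    def test_collinear_components_warn(self, synthetic_signatures):
        v = synthetic_signatures["syn_mmrd"].to_numpy()
        s = Spectrum(SBS96_LABELS, v)
        with pytest.warns(UserWarning, match="collinear"):
            two_component_fit([Spectrum(SBS96_LABELS, 10 * v)], s, s)


class TestReferenceSetAssembly:
    def test_identity(self):
        rng = np.random.default_rng(0)
        base = SignatureMatrix(random_signature_frame(rng, 4))
        out = assemble_reference_set(base)
        assert out.names == base.names

    def test_substitution_counts(self):
        rng = np.random.default_rng(1)
        base = SignatureMatrix(random_signature_frame(rng, 10, names=[f"SBS{i}" for i in range(10)]))
        add = SignatureMatrix(random_signature_frame(rng, 4, names=["MMRd-A", "SigD", "SigHD", "SigOX"]))
        out = assemble_reference_set(base, drop=[f"SBS{i}" for i in range(6)], add=add)
        assert len(out) == 10 - 6 + 4
        assert out.names[-4:] == ["MMRd-A", "SigD", "SigHD", "SigOX"]
        assert out.names[:4] == [f"SBS{i}" for i in range(6, 10)]

    def test_unknown_drop_name_rejected(self):
        rng = np.random.default_rng(2)
        base = SignatureMatrix(random_signature_frame(rng, 3))
        with pytest.raises(ValidationError):
            assemble_reference_set(base, drop=["nope"])

    def test_duplicate_name_after_merge_rejected(self):
        rng = np.random.default_rng(3)
        base = SignatureMatrix(random_signature_frame(rng, 3, names=["A", "B", "C"]))
        add = SignatureMatrix(random_signature_frame(rng, 1, names=["B"]))
        with pytest.raises(ValidationError):
            assemble_reference_set(base, add=add)


class TestMmrdSelection:
    def _fit(self, a, b):
        from isomutsig.signatures import SignatureFit

        return SignatureFit(["MMRd-A", "MMRd-B", "other"], np.array([a, b, 5.0]), 0.9)

    def test_above_threshold_selected(self):
        assert select_mmrd(self._fit(600, 500)) is True

    def test_exactly_at_threshold_not_selected(self):
        assert select_mmrd(self._fit(400, 600)) is False

    def test_zero_not_selected(self):
        assert select_mmrd(self._fit(0, 0)) is False

    def test_missing_signature_rejected(self):
        from isomutsig.signatures import SignatureFit

        fit = SignatureFit(["X"], np.array([2000.0]), 0.9)
        with pytest.raises(ValidationError):
            select_mmrd(fit)
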