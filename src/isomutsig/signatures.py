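"""Signature refitting, strict refitting, de novo NMF extraction and the
oxygen difference-spectrum analyses.

A mutational signature is a probability distribution over mutation
channels; *refitting* decomposes an observed spectrum into non-negative
exposures (mutation counts attributed to each signature) by non-negative
least squares.  *Strict* refitting additionally prunes signatures whose
removal barely changes the reconstruction, which suppresses spurious
small exposures.  De novo extraction factorizes a channels x samples
catalog into k signatures by multiplicative-update NMF.

The two central estimators follow scikit-learn conventions
(``fit``/``transform``, ``get_params``, trailing-underscore fitted
attributes) and compose with sklearn pipelines; the module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import UndefinedSpectrumError, ValidationError
from .spectra import Spectrum, cosine

__all__ = [
    "SignatureMatrix",
    "SignatureFit",
    "SignatureRefitter",
    "SignatureNMF",
    "refit",
    "refit_strict",
    "nmf_extract",
    "difference_spectrum",
    "two_component_fit",
    "assemble_reference_set",
    "select_mmrd",
]


class SignatureMatrix:
    """A channels x signatures matrix with unit column sums.

    Thin, validated wrapper around a pandas DataFrame whose index holds
    channel labels and whose columns hold signature names.
    """

    def __init__(self, frame: pd.DataFrame, renormalize: bool = False) -> None:
        values = frame.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValidationError("signature matrix entries must be non-negative")
        sums = values.sum(axis=0)
        if renormalize:
            if (sums == 0).any():
                raise ValidationError("cannot normalize an all-zero signature column")
            frame = frame / sums
        elif not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("signature columns must sum to 1 (+/- 1e-6)")
        if frame.columns.duplicated().any():
            raise ValidationError("duplicate signature names")
        self.frame = frame

    @property
    def channels(self) -> list[str]:
        return list(self.frame.index)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        return SignatureMatrix(self.frame[list(names)])

    def __len__(self) -> int:
        return self.frame.shape[1]


class SignatureFit:
    """Exposures of reference signatures to one spectrum."""

    def __init__(
        self,
        names: Sequence[str],
        exposures: np.ndarray,
        reconstruction_cosine: float,
        removed: Sequence[str] = (),
    ) -> None:
        self.names = list(names)
        self.exposures = np.asarray(exposures, dtype=float)
        if (self.exposures < -1e-12).any():
            raise ValidationError("exposures must be non-negative")
        self.exposures = np.clip(self.exposures, 0, None)
        self.reconstruction_cosine = float(reconstruction_cosine)
        self.removed = list(removed)

    def exposure_of(self, name: str) -> float:
        try:
            return float(self.exposures[self.names.index(name)])
        except ValueError as exc:
            raise ValidationError(f"signature {name!r} not in fit") from exc

    @property
    def relative(self) -> np.ndarray:
        total = self.exposures.sum()
        return self.exposures / total if total > 0 else self.exposures

    def to_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=self.names)


def _spectrum_vector(spectrum: Spectrum | np.ndarray | pd.Series, channels: list[str]) -> np.ndarray:
    if isinstance(spectrum, Spectrum):
        if list(spectrum.labels) != channels:
            raise ValidationError("spectrum channels do not match signature channels")
        return spectrum.values
    if isinstance(spectrum, pd.Series):
        if list(spectrum.index) != channels:
            raise ValidationError("spectrum channels do not match signature channels")
        return spectrum.to_numpy(dtype=float)
    v = np.asarray(spectrum, dtype=float)
    if v.shape != (len(channels),):
        raise ValidationError("spectrum length does not match signature channels")
    return v


def _nnls_fit(y: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares; returns exposures and reconstruction
    cosine (0 when either vector is all zero)."""
    e, _ = nnls(A, y)
    recon = A @ e
    if np.linalg.norm(recon) == 0 or np.linalg.norm(y) == 0:
        return e, 0.0
    return e, float(np.dot(y, recon) / (np.linalg.norm(y) * np.linalg.norm(recon)))


class SignatureRefitter(BaseEstimator, TransformerMixin):
    """Non-negative least-squares refitting of spectra to known signatures.

    Parameters
    ----------
    signatures : SignatureMatrix or DataFrame
        Reference set; columns sum to 1.
    strict : bool, default False
        Greedily remove signatures whose removal decreases the
        reconstruction cosine by less than ``max_delta`` (one removal per
        iteration, smallest drop first, ties broken by signature order),
        then refit on the survivors.
    max_delta : float, default 0.004
        Per-iteration cosine-drop tolerance of the strict mode.

    After :meth:`fit`, ``signatures_`` holds the validated reference set.
    :meth:`transform` maps an (n_samples, n_channels) array of spectra to
    an (n_samples, n_signatures) exposure matrix; strict-mode removals are
    reported per sample in ``removed_`` after ``transform``.
    """

    def __init__(self, signatures=None, strict: bool = False, max_delta: float = 0.004):
        self.signatures = signatures
        self.strict = strict
        self.max_delta = max_delta

    def fit(self, X=None, y=None) -> "SignatureRefitter":
        sigs = self.signatures
        if sigs is None:
            raise ValidationError("signatures must be provided")
        if isinstance(sigs, pd.DataFrame):
            sigs = SignatureMatrix(sigs)
        if len(sigs) < 1:
            raise ValidationError("need at least one signature")
        self.signatures_ = sigs
        self.n_features_in_ = len(sigs.channels)
        return self

    def fit_one(self, spectrum: Spectrum | np.ndarray | pd.Series) -> SignatureFit:
        """Refit a single spectrum; returns the full :class:`SignatureFit`."""
        check_is_fitted(self, "signatures_")
        sigs = self.signatures_
        y = _spectrum_vector(spectrum, sigs.channels)
        A = sigs.values
        names = sigs.names
        if not self.strict:
            e, cos = _nnls_fit(y, A)
            return SignatureFit(names, e, cos)
        keep = list(range(len(names)))
        e, cos = _nnls_fit(y, A[:, keep])
        removed: list[str] = []
        while len(keep) > 1:
            best_idx, best_cos = None, -np.inf
            for j in range(len(keep)):
                sub = keep[:j] + keep[j + 1:]
                _, c = _nnls_fit(y, A[:, sub])
                if c > best_cos:  # ties keep the earliest (signature order)
                    best_idx, best_cos = j, c
            if cos - best_cos < self.max_delta:
                removed.append(names[keep.pop(best_idx)])
                e, cos = _nnls_fit(y, A[:, keep])
            else:
                break
        exposures = np.zeros(len(names))
        exposures[keep] = e
        return SignatureFit(names, exposures, cos, removed=removed)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "signatures_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        fits = [self.fit_one(x) for x in X]
        self.removed_ = [f.removed for f in fits]
        self.reconstruction_cosine_ = np.array([f.reconstruction_cosine for f in fits])
        return np.vstack([f.exposures for f in fits])


def refit(spectrum, sigs: SignatureMatrix | pd.DataFrame) -> SignatureFit:
    """Plain non-negative least-squares refit of one spectrum."""
    return SignatureRefitter(sigs).fit().fit_one(spectrum)


def refit_strict(spectrum, sigs, max_delta: float = 0.004) -> SignatureFit:
    """Strict refit: prune signatures whose removal costs < ``max_delta``
    reconstruction cosine per step, then refit the survivors."""
    return SignatureRefitter(sigs, strict=True, max_delta=max_delta).fit().fit_one(spectrum)


# ---------------------------------------------------------------------------
# de novo extraction
# ---------------------------------------------------------------------------


class SignatureNMF(BaseEstimator, TransformerMixin):
    """De novo signature extraction by multiplicative-update NMF.

    Factorizes a non-negative (n_samples, n_channels) catalog ``X`` into
    ``X ~ H W`` with ``W`` (k, n_channels) the signatures and ``H``
    (n_samples, k) the exposures, minimizing the Frobenius error.  The
    best of ``n_starts`` seeded random restarts is kept, signature rows
    are normalized to sum 1 and exposures rescaled, so exposures keep
    mutation-count units when the catalog holds counts.  Bit-reproducible
    for a fixed ``random_state``.

    Fitted attributes: ``signatures_`` (DataFrame, channels x k, unit
    column sums), ``exposures_`` (n_samples, k), ``reconstruction_err_``,
    ``objective_curve_`` (best restart's error per iteration).
    """

    def __init__(
        self,
        n_signatures: int = 2,
        n_starts: int = 200,
        max_iter: int = 2000,
        tol: float = 1e-6,
        random_state: int = 0,
        channel_labels: Sequence[str] | None = None,
    ):
        self.n_signatures = n_signatures
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.channel_labels = channel_labels

    def _mu_run(self, X: np.ndarray, rng: np.random.Generator):
        n, m = X.shape
        k = self.n_signatures
        eps = 1e-12
        H = rng.random((n, k)) + 0.1
        W = rng.random((k, m)) + 0.1
        prev = np.inf
        curve = []
        for _ in range(self.max_iter):
            H *= (X @ W.T) / np.maximum(H @ (W @ W.T), eps)
            W *= (H.T @ X) / np.maximum((H.T @ H) @ W, eps)
            err = float(np.linalg.norm(X - H @ W))
            curve.append(err)
            if prev - err < self.tol * max(prev, 1e-30):
                break
            prev = err
        return H, W, err, curve

    def fit(self, X, y=None) -> "SignatureNMF":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("catalog must be 2-D (samples x channels)")
        if (X < 0).any():
            raise ValidationError("catalog must be non-negative")
        n, m = X.shape
        if self.n_signatures >= n:
            raise ValidationError("rank must be smaller than the number of samples")
        if self.n_signatures > min(n, m):
            raise ValidationError("rank exceeds catalog dimensions")
        root = np.random.default_rng(self.random_state)
        seeds = root.integers(0, 2**31 - 1, size=self.n_starts)
        best = None
        for seed in seeds:
            H, W, err, curve = self._mu_run(X, np.random.default_rng(int(seed)))
            if best is None or err < best[2]:
                best = (H, W, err, curve)
        H, W, err, curve = best
        scale = W.sum(axis=1)  # normalize signatures, keep H in count units
        scale[scale == 0] = 1.0
        W = W / scale[:, None]
        H = H * scale[None, :]
        names = [f"Sig{i + 1}" for i in range(self.n_signatures)]
        labels = (
            list(self.channel_labels)
            if self.channel_labels is not None
            else [f"ch{i}" for i in range(m)]
        )
        self.signatures_ = pd.DataFrame(W.T, index=labels, columns=names)
        self.exposures_ = H
        self.reconstruction_err_ = err
        self.objective_curve_ = np.array(curve)
        self.n_features_in_ = m
        return self

    def transform(self, X) -> np.ndarray:
        """Exposures of new samples against the extracted signatures
        (non-negative least squares per sample)."""
        check_is_fitted(self, "signatures_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        A = self.signatures_.to_numpy()
        return np.vstack([_nnls_fit(x, A)[0] for x in X])

    def scree(self, X, ranks: Sequence[int], n_starts: int = 20) -> pd.Series:
        """Reconstruction error over candidate ranks, to support choosing
        the number of signatures (no automatic selection)."""
        errs = {}
        for k in ranks:
            est = SignatureNMF(
                n_signatures=k,
                n_starts=n_starts,
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=self.random_state,
                channel_labels=self.channel_labels,
            ).fit(X)
            errs[k] = est.reconstruction_err_
        return pd.Series(errs, name="frobenius_error")


def nmf_extract(
    catalog: np.ndarray | pd.DataFrame,
    k: int,
    n_starts: int = 200,
    rng_seed: int = 0,
    max_iter: int = 2000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Extract ``k`` de novo signatures from a channels x samples catalog.

    Returns (signatures DataFrame channels x k with unit column sums,
    exposures array k x samples in catalog units).
    """
    if isinstance(catalog, pd.DataFrame):
        labels = list(catalog.index)
        X = catalog.to_numpy(dtype=float).T
    else:
        labels = None
        X = np.asarray(catalog, dtype=float).T
    est = SignatureNMF(
        n_signatures=k,
        n_starts=n_starts,
        random_state=rng_seed,
        max_iter=max_iter,
        channel_labels=labels,
    ).fit(X)
    return est.signatures_, est.exposures_.T


# ---------------------------------------------------------------------------
# difference spectra and derived analyses
# ---------------------------------------------------------------------------


def difference_spectrum(
    high: Spectrum, low: Spectrum, norm_high: float, norm_low: float
) -> tuple[Spectrum, int]:
    """Per-channel positive part of ``high/norm_high - low/norm_low``,
    renormalized to sum 1.

    The norms are population doublings, so the subtraction acts on
    per-doubling mutation rates.  Returns ``(spectrum, n_floored)`` where
    ``n_floored`` counts channels clipped at zero (reported so the
    flooring is auditable).  An all-zero difference raises
    :class:`UndefinedSpectrumError`.
    """
    if list(high.labels) != list(low.labels):
        raise ValidationError("channel sets differ")
    if norm_high <= 0 or norm_low <= 0:
        raise ValidationError("normalization constants must be positive")
    d = high.values / norm_high - low.values / norm_low
    floored = int((d < 0).sum())
    d = np.clip(d, 0, None)
    if d.sum() == 0:
        raise UndefinedSpectrumError("difference spectrum is identically zero")
    return Spectrum(high.labels, d / d.sum(), normalized=True), floored


def two_component_fit(
    stratum_spectra: Sequence[Spectrum],
    comp_low: Spectrum,
    comp_diff: Spectrum,
) -> pd.DataFrame:
    """Decompose stratum spectra (e.g. replication-timing deciles) into a
    low-oxygen component and an oxygen difference component.

    Returns a DataFrame with one row per stratum: exposures of the two
    components and the reconstruction cosine.  Raises a warning when the
    components are (near-)collinear.
    """
    if list(comp_low.labels) != list(comp_diff.labels):
        raise ValidationError("component channel sets differ")
    if cosine(comp_low, comp_diff) > 1 - 1e-9:
        warnings.warn("two components are collinear; exposures are ill-conditioned",
                      stacklevel=2)
    frame = pd.DataFrame(
        np.column_stack([comp_low.values, comp_diff.values]),
        index=list(comp_low.labels),
        columns=["low", "difference"],
    )
    sigs = SignatureMatrix(frame, renormalize=True)
    rows = []
    for spec in stratum_spectra:
        f = refit(spec, sigs)
        rows.append(
            {
                "exposure_low": f.exposure_of("low"),
                "exposure_difference": f.exposure_of("difference"),
                "reconstruction_cosine": f.reconstruction_cosine,
            }
        )
    return pd.DataFrame(rows)


def assemble_reference_set(
    base: SignatureMatrix,
    drop: Sequence[str] = (),
    add: SignatureMatrix | None = None,
) -> SignatureMatrix:
    """Substitute signatures in a reference set: retained base signatures
    keep their original order, additions follow."""
    unknown = [n for n in drop if n not in base.names]
    if unknown:
        raise ValidationError(f"cannot drop unknown signatures {unknown}")
    kept = [n for n in base.names if n not in set(drop)]
    frame = base.frame[kept]
    if add is not None:
        if list(add.channels) != list(base.channels):
            raise ValidationError("added signatures have a different channel set")
        clash = set(kept) & set(add.names)
        if clash:
            raise ValidationError(f"duplicate signature names after merge: {sorted(clash)}")
        frame = pd.concat([frame, add.frame], axis=1)
    return SignatureMatrix(frame)


def select_mmrd(
    fit: SignatureFit, mmrd_names: Sequence[str] = ("MMRd-A", "MMRd-B"), threshold: float = 1000.0
) -> bool:
    """True iff the summed exposure of the MMRd signatures exceeds the
    threshold strictly (``> 1000`` mutations by default)."""
    total = sum(fit.exposure_of(n) for n in mmrd_names)
    return total > threshold
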