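"""wCCA electrooculogram-artifact removal.

Blinks generate large low-frequency potentials that volume-conduct from the
eyes over the whole scalp and dominate the VEOG sensor. The remover builds
two blocks from a trial — X = [six left-hemisphere channels; VEOG] and
Y = [six right-hemisphere channels; VEOG] — and runs canonical correlation
analysis (CCA) between them. Because the VEOG row is shared, the first
canonical pair (u1, v1) locks onto the ocular component common to both
hemispheres. u1 and v1 are wavelet-thresholded (db4, five levels, VisuShrink
universal threshold, zeroing the LARGE coefficients that carry the blink
transients) and the trial is rebuilt by inverting the canonical bases; the
per-channel correction is automatically proportional to each channel's
covariance with VEOG. The two midline channels (FZ, CZ), which have no
mirror partner, are cleaned with plain soft-threshold wavelet denoising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import linalg

from .montage import Montage, Trial


class DegenerateCovarianceError(ValueError):
    """A signal block is rank deficient; CCA directions are not identifiable."""


@dataclass
class CCAModel:
    """Canonical bases of a two-block CCA.

    A, B : square direction matrices; column i holds the weights a_i / b_i.
    rho : canonical correlations, descending, in [0, 1].
    x_means, y_means : per-row means removed before fitting (None if the
        caller centered the data itself).
    """

    A: np.ndarray
    B: np.ndarray
    rho: np.ndarray
    x_means: np.ndarray | None = None
    y_means: np.ndarray | None = None


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet decomposition and thresholding parameters.

    basis : wavelet family (default db4).
    levels : decomposition depth (default 5).
    threshold_rule : ``suppress_above`` zeroes coefficients whose magnitude
        EXCEEDS the universal threshold (removes large blink transients,
        keeps the small high-frequency EEG coefficients); ``classic_hard``
        zeroes below the threshold (standard denoising); ``soft`` shrinks
        toward zero by the threshold; ``none`` is the identity (diagnostics).
    threshold_scope : ``all`` thresholds the five detail subbands and the
        approximation (the approximation carries the low-frequency blink
        energy); ``details`` leaves the approximation untouched.
    mad : ``absolute`` uses median(|coeff|)/0.6745 as the noise-scale
        estimate; ``signed`` uses the literal signed median.
    """

    basis: str = "db4"
    levels: int = 5
    threshold_rule: str = "suppress_above"
    threshold_scope: str = "all"
    mad: str = "absolute"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_rule not in ("suppress_above", "classic_hard", "soft", "none"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_scope not in ("all", "details"):
            raise ValueError(f"unknown threshold scope {self.threshold_scope!r}")
        if self.mad not in ("absolute", "signed"):
            raise ValueError(f"unknown MAD convention {self.mad!r}")


@dataclass
class DenoiseReport:
    """Per-trial wCCA diagnostics."""

    rho1: float
    energy_removed: float
    veog_corr_pre: dict[str, float] = field(default_factory=dict)
    veog_corr_post: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------


def center_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove each row's mean; returns (centered matrix, means)."""
    m = np.asarray(m, dtype=float)
    if m.shape[-1] < 2:
        raise ValueError("need at least two samples per row to center")
    means = m.mean(axis=-1, keepdims=True)
    return m - means, means.ravel()


def _inv_sqrt_psd(c: np.ndarray, name: str) -> np.ndarray:
    """Symmetric inverse square root of a covariance; errors if rank deficient."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    if w[-1] <= 0 or w[0] < w[-1] * 1e-12:
        raise DegenerateCovarianceError(f"degenerate covariance in the {name} block")
    return (v / np.sqrt(w)) @ v.T


def cca_fit(xc: np.ndarray, yc: np.ndarray) -> CCAModel:
    """Fit CCA between two centered C x T blocks.

    Solves for direction matrices A, B maximizing corr(a_i' X, b_i' Y)
    subject to unit-variance constraints a_i' Cxx a_i = b_i' Cyy b_i = 1,
    via whitening of each block and an SVD of the whitened cross-covariance.
    The canonical variates are U = A' Xc, V = B' Yc with diagonal
    cross-correlation rho (descending).

    Sign convention: each pair (a_i, b_i) is flipped so that the covariance
    of u_i with the first row of the left block is non-negative (falls back
    to the sign of a_i's largest-magnitude weight when that covariance is
    numerically zero), making the decomposition deterministic.
    """
    xc = np.atleast_2d(np.asarray(xc, dtype=float))
    yc = np.atleast_2d(np.asarray(yc, dtype=float))
    t = xc.shape[1]
    if yc.shape[1] != t:
        raise ValueError("blocks must have the same number of samples")
    if t <= max(xc.shape[0], yc.shape[0]):
        raise ValueError("need more samples than channels for CCA")
    denom = t - 1
    cxx = xc @ xc.T / denom
    cyy = yc @ yc.T / denom
    cxy = xc @ yc.T / denom
    wx = _inv_sqrt_psd(cxx, "left")
    wy = _inv_sqrt_psd(cyy, "right")
    u, s, vt = np.linalg.svd(wx @ cxy @ wy)
    a = wx @ u
    b = wy @ vt.T
    rho = np.clip(s, 0.0, 1.0 + 1e-9)
    # deterministic sign: cov(u_i, x_1) >= 0
    ref = cxx[0] @ a  # covariance of each u_i with the first left-block row
    for i in range(a.shape[1]):
        sgn = np.sign(ref[i])
        if sgn == 0:
            j = int(np.argmax(np.abs(a[:, i])))
            sgn = np.sign(a[j, i]) or 1.0
        a[:, i] *= sgn
        b[:, i] *= sgn
    return CCAModel(A=a, B=b, rho=rho)


# ---------------------------------------------------------------------------
# Wavelet thresholding
# ---------------------------------------------------------------------------


def visu_threshold(subband: np.ndarray, n_j: int | None = None, mad: str = "absolute") -> float:
    """Universal (VisuShrink) threshold for one subband.

    k_j = sqrt(2 ln N_j) * median(|D_j|) / 0.6745, where N_j is the subband
    length and the median term estimates the noise standard deviation in the
    wavelet domain. ``mad="signed"`` uses the literal signed median instead
    of the median absolute value.
    """
    d = np.asarray(subband, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty subband")
    n = d.size if n_j is None else int(n_j)
    if n < 1:
        raise ValueError("subband length must be >= 1")
    med = np.median(np.abs(d)) if mad == "absolute" else np.median(d)
    return float(np.sqrt(2.0 * np.log(n)) * med / 0.6745)


def _apply_rule(coeffs: np.ndarray, k: float, rule: str) -> np.ndarray:
    if rule == "none":
        return coeffs
    if rule == "suppress_above":
        return np.where(np.abs(coeffs) > k, 0.0, coeffs)
    if rule == "classic_hard":
        return np.where(np.abs(coeffs) < k, 0.0, coeffs)
    if rule == "soft":
        return np.sign(coeffs) * np.maximum(np.abs(coeffs) - k, 0.0)
    raise ValueError(f"unknown threshold rule {rule!r}")


def wavelet_denoise(
    x: np.ndarray,
    spec: WaveletSpec = WaveletSpec(),
    return_report: bool = False,
):
    """Multilevel wavelet threshold denoising of a 1-D signal.

    Decomposes to ``spec.levels`` detail subbands plus one approximation
    (symmetric boundary extension), computes a VisuShrink threshold per
    subband, applies ``spec.threshold_rule``, and reconstructs to the input
    length. With ``return_report=True`` also returns the fraction of
    coefficient energy zeroed and the per-subband thresholds.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2**spec.levels:
        raise ValueError(f"signal of length {x.size} too short for {spec.levels} levels")
    coeffs = pywt.wavedec(x, spec.basis, level=spec.levels, mode="symmetric")
    total = sum(float(np.sum(c**2)) for c in coeffs)
    removed = 0.0
    out = []
    for j, c in enumerate(coeffs):
        is_approx = j == 0
        if is_approx and spec.threshold_scope == "details":
            out.append(c)
            continue
        k = visu_threshold(c, mad=spec.mad)
        c_new = _apply_rule(c, k, spec.threshold_rule)
        removed += float(np.sum(c**2) - np.sum(c_new**2))
        out.append(c_new)
    y = pywt.waverec(out, spec.basis, mode="symmetric")[: x.size]
    if return_report:
        frac = removed / total if total > 0 else 0.0
        return y, frac
    return y


# ---------------------------------------------------------------------------
# wCCA trial denoising
# ---------------------------------------------------------------------------


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def wcca_denoise(
    trial: Trial,
    montage: Montage,
    spec: WaveletSpec = WaveletSpec(),
) -> tuple[Trial, DenoiseReport]:
    """Remove ocular artifacts from the twelve symmetric channels of a trial.

    Builds the augmented blocks X = [left 6; VEOG], Y = [right 6; VEOG],
    centers them, fits CCA, wavelet-thresholds only the first canonical pair
    (u1, v1), reconstructs X_new = (A')^{-1} U_new (same for Y), re-adds the
    row means, and writes the first six rows back into the trial. Midline
    channels and VEOG are untouched (see :func:`wtd_central` for FZ/CZ).

    Returns the cleaned trial and a :class:`DenoiseReport` with the first
    canonical correlation, the zeroed energy fraction of u1/v1, and the
    pre/post correlation of each symmetric channel with VEOG.
    """
    li = montage.group_indices(montage.left_group)
    ri = montage.group_indices(montage.right_group)
    x = np.vstack([trial.data[li], trial.veog[None, :]])
    y = np.vstack([trial.data[ri], trial.veog[None, :]])
    xc, x_means = center_rows(x)
    yc, y_means = center_rows(y)
    model = cca_fit(xc, yc)
    for mat, name in ((model.A, "left"), (model.B, "right")):
        if np.linalg.cond(mat) > 1e10:
            raise DegenerateCovarianceError(f"non-invertible canonical basis ({name} block)")
    u = model.A.T @ xc
    v = model.B.T @ yc
    u_new = u.copy()
    v_new = v.copy()
    u_new[0], fu = wavelet_denoise(u[0], spec, return_report=True)
    v_new[0], fv = wavelet_denoise(v[0], spec, return_report=True)
    x_new = linalg.solve(model.A.T, u_new) + x_means[:, None]
    y_new = linalg.solve(model.B.T, v_new) + y_means[:, None]

    data = trial.data.copy()
    report = DenoiseReport(rho1=float(model.rho[0]), energy_removed=(fu + fv) / 2.0)
    for rows, idx, names in ((x_new, li, montage.left_group), (y_new, ri, montage.right_group)):
        for r, (i, name) in enumerate(zip(idx, names)):
            report.veog_corr_pre[name] = _corr(trial.data[i], trial.veog)
            data[i] = rows[r]
            report.veog_corr_post[name] = _corr(data[i], trial.veog)
    return trial.with_data(data), report


def wtd_central(
    trial: Trial,
    montage: Montage,
    spec: WaveletSpec = WaveletSpec(),
) -> Trial:
    """Soft-threshold wavelet denoising of the midline channels FZ and CZ.

    Other channels are returned bitwise unchanged; the wavelet basis/levels
    come from ``spec`` but the rule is forced to soft thresholding.
    """
    soft = replace(spec, threshold_rule="soft")
    data = trial.data.copy()
    for name in montage.central_group:
        i = montage.index(name)
        data[i] = wavelet_denoise(trial.data[i], soft)
    return trial.with_data(data)


class WCCADenoiser:
    """Stateless transformer applying wCCA (+ midline WTD) trial-wise.

    Shaped like an sklearn transformer so it slots into pipeline code:
    ``fit`` is a no-op, ``transform`` maps a list of :class:`Trial` to a
    list of cleaned trials.
    """

    def __init__(self, montage: Montage, spec: WaveletSpec = WaveletSpec(), central: bool = True):
        self.montage = montage
        self.spec = spec
        self.central = central

    def get_params(self, deep: bool = True) -> dict:
        return {"montage": self.montage, "spec": self.spec, "central": self.central}

    def set_params(self, **params) -> "WCCADenoiser":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "WCCADenoiser":
        return self

    def transform(self, X: list[Trial]) -> list[Trial]:
        out = []
        for trial in X:
            cleaned, _ = wcca_denoise(trial, self.montage, self.spec)
            if self.central:
                cleaned = wtd_central(cleaned, self.montage, self.spec)
            out.append(cleaned)
        return out


__all__ = [
    "CCAModel",
    "WaveletSpec",
    "DenoiseReport",
    "DegenerateCovarianceError",
    "center_rows",
    "cca_fit",
    "visu_threshold",
    "wavelet_denoise",
    "wcca_denoise",
    "wtd_central",
    "WCCADenoiser",
]
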