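"""Spherical-spline surface Laplacian (current source density) transform.

The scalp potential is interpolated with spherical splines and the surface
Laplacian of the interpolant is evaluated at the electrodes, attenuating
volume-conducted (spatially broad) activity and sharpening topography before
spectral analysis.  Two Legendre series define the transform, with spline
flexibility ``m`` and a diagonal smoothing constant ``lambda``:

    g(x) = 1/(4*pi) * sum_{n>=1} (2n+1) / (n (n+1))^m     * P_n(x)
    h(x) = 1/(4*pi) * sum_{n>=1} (2n+1) / (n (n+1))^(m-1) * P_n(x)

Spline coefficients ``c`` solve ``(G + lambda*I) c + c0 = v`` under the flat
spline constraint ``sum(c) = 0``; the CSD at each electrode is ``(H c) / r^2``
for head radius ``r``.  The whole map is linear, so it is precomputed once as
a dense matrix and applied per time sample.

The output carries units of potential per area (uV/cm^2 for inputs in uV and
radius in cm).  Downstream dB *differences* are invariant to this global
scale; only absolute dB levels depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

from .montage import Montage
from .preprocess import EpochSet

__all__ = ["CsdKernel", "build_kernel", "apply_laplacian", "spline_series"]


def spline_series(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Evaluate the spline Legendre series g (order ``m``) at cos(angle).

    ``sum_{n=1}^{n_terms} (2n+1)/(n(n+1))^m P_n(x) / (4 pi)``
    """
    n = np.arange(1, n_terms + 1)
    coefs = np.zeros(n_terms + 1)
    coefs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** m
    return npleg.legval(np.asarray(cosang, dtype=float), coefs) / (4 * np.pi)


@dataclass(frozen=True)
class CsdKernel:
    """Precomputed spherical-spline Laplacian for a fixed montage.

    Attributes
    ----------
    G, H
        Symmetric spline and Laplacian series matrices over electrode pairs.
    transform
        Dense ``(n, n)`` matrix mapping a potential map to CSD values.
    """

    montage: Montage
    G: np.ndarray
    H: np.ndarray
    transform: np.ndarray
    m: int
    n_terms: int
    lam: float
    head_radius_cm: float


def build_kernel(
    montage: Montage,
    m: int = 4,
    n_terms: int = 50,
    lam: float = 1e-5,
    head_radius_cm: float = 10.0,
) -> CsdKernel:
    """Build the CSD kernel for a montage.

    Defaults (m=4, 50 Legendre terms, lambda=1e-5, 10 cm radius) are the
    published defaults of the standard CSD implementation of this method.
    """
    if montage.n_channels < 8:
        raise ValueError("need at least 8 channels for a stable spherical spline")
    cosang = montage.cosine_distances()
    off = ~np.eye(montage.n_channels, dtype=bool)
    closest = cosang[off].max()
    if closest > 1 - 1e-9:
        i, j = np.unravel_index(
            np.argmax(np.where(off, cosang, -np.inf)), cosang.shape
        )
        raise ValueError(
            f"coincident electrode positions: {montage.labels[i]} / {montage.labels[j]}"
        )
    G = spline_series(cosang, m, n_terms)
    H = spline_series(cosang, m - 1, n_terms)

    n = montage.n_channels
    # Augmented system for the flat-spline constraint sum(c) = 0:
    # [[G + lam*I, 1], [1^T, 0]] @ [c, c0] = [v, 0]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    S = np.linalg.inv(A)[:n, :n]  # v -> c
    transform = (H @ S) / head_radius_cm**2
    return CsdKernel(
        montage=montage,
        G=G,
        H=H,
        transform=transform,
        m=m,
        n_terms=n_terms,
        lam=lam,
        head_radius_cm=head_radius_cm,
    )


def apply_laplacian(eset: EpochSet, kernel: CsdKernel) -> EpochSet:
    """Apply the surface Laplacian to every epoch (channels must match)."""
    if tuple(eset.channel_labels) != tuple(kernel.montage.labels):
        raise ValueError(
            "epoch channel order does not match the CSD kernel montage"
        )
    # (e, c, t): contract the channel axis with the dense transform.
    data = kernel.transform @ eset.epochs
    return EpochSet(
        epochs=data,
        epoch_meta=eset.epoch_meta.copy(),
        sampling_rate=eset.sampling_rate,
        window_length=eset.window_length,
        channel_labels=eset.channel_labels,
        units="uV/cm^2",
    )
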