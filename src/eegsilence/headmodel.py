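"""Electrode/source geometry, analytic forward model and covariance estimation.

The forward model is a current dipole in a homogeneous conducting sphere with
fixed radial orientation, one dipole per source location.  For a radial dipole
at eccentricity ``f = b/R`` and an electrode at angular distance ``gamma`` on
the sphere surface the potential has the closed form

    V ~ 2 (cos(gamma) - f) / g^3 + (1/f) (1/g - 1),
    g = sqrt(1 - 2 f cos(gamma) + f^2),

which is the summed Legendre series ``sum_n (2n+1) f^(n-1) P_n(cos gamma)``.
Rows of the gain matrix are average-referenced, matching scalp EEG referenced
to the common average.

The covariance side estimates a diagonal source-covariance model: with
column-normalized gains ``A~`` the scalp covariance is modelled as
``C_x ≈ A~ diag(s) A~^T + C_z`` and ``s`` is obtained by least squares over
the vectorized upper triangle, with negative entries clipped at zero.  The
noise covariance ``C_z`` is isotropic, sized from the smallest eigenvalues of
the scalp covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ElectrodeMontage",
    "SourceSpace",
    "Leadfield",
    "CovarianceModel",
    "average_reference",
    "build_spherical_leadfield",
    "normalize_leadfield",
    "estimate_covariances",
]


@dataclass
class ElectrodeMontage:
    """Scalp electrode set.

    Parameters
    ----------
    labels : list of str
        Unique channel names.
    positions : (n, 3) ndarray
        Head-centered coordinates in mm; x right, y anterior, z superior.
    reference : str
        Reference tag; only ``"average"`` is produced by this package.
    """

    labels: list
    positions: np.ndarray
    reference: str = "average"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions disagree in length")
        if len(self.labels) < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if not np.isfinite(self.positions).all():
            raise ValueError("electrode positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class SourceSpace:
    """Discrete cortical source grid with neighborhood structure.

    ``adjacency`` maps each source index to a frozen set of neighbor indices;
    it is symmetric and free of self-loops.  ``hemisphere`` holds 'L'/'R' per
    source, consistent with sign(x) up to half a grid step around the midline.
    ``parent`` optionally maps each high-resolution source to its
    low-resolution parent index.
    """

    positions: np.ndarray
    hemisphere: np.ndarray
    adjacency: dict
    spacing: float
    parcels: np.ndarray
    tier: str = "low"
    parent: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        self.parcels = np.asarray(self.parcels)
        p = len(self.positions)
        for q, nbs in self.adjacency.items():
            if q in nbs:
                raise ValueError(f"self-loop at source {q}")
            if not nbs:
                raise ValueError(f"source {q} has no neighbors")
            for v in nbs:
                if q not in self.adjacency[v]:
                    raise ValueError("adjacency is not symmetric")
        for q in range(p):
            x = self.positions[q, 0]
            h = self.hemisphere[q]
            if abs(x) >= self.spacing / 2 and h != ("R" if x > 0 else "L"):
                raise ValueError(f"hemisphere tag inconsistent with sign(x) at source {q}")

    @property
    def n_sources(self) -> int:
        return len(self.positions)

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        return np.where(self.hemisphere == hemi)[0]


@dataclass
class Leadfield:
    """Electrode-by-source gain matrix with its column-normalized copy."""

    A: np.ndarray
    A_norm: np.ndarray
    col_norms: np.ndarray
    montage: Optional[ElectrodeMontage] = None
    sources: Optional[SourceSpace] = None
    # cached quadratic-form kernels, filled lazily by estimate_covariances
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A.shape[1]

    def crosstalk_kernel(self) -> np.ndarray:
        """(A~^T A~)^2 elementwise; model[q] = kernel @ s_var."""
        if "K2" not in self._cache:
            AtA = self.A_norm.T @ self.A_norm
            self._cache["K2"] = AtA**2
        return self._cache["K2"]


@dataclass
class CovarianceModel:
    """Scalp covariance, isotropic noise covariance and fitted source variances."""

    C_x: np.ndarray
    C_z: np.ndarray
    s_var: np.ndarray
    selec: np.ndarray

    def __post_init__(self):
        if len(self.selec) == 0:
            raise ValueError("selec must be non-empty")
        if (self.s_var < 0).any():
            raise ValueError("source variances must be nonnegative")


def average_reference(X: np.ndarray) -> np.ndarray:
    """Re-reference to the common average: subtract the per-sample channel mean.

    Idempotent; raises for single-channel input where the reference is undefined.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("reference undefined: need at least 2 channels")
    if not np.isfinite(X).all():
        raise ValueError("non-finite samples")
    return X - X.mean(axis=0, keepdims=True)


def _radial_dipole_potential(elec: np.ndarray, src: np.ndarray, R: float) -> np.ndarray:
    b = np.linalg.norm(src, axis=1)
    f = b / R
    eh = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    sh = src / b[:, None]
    x = eh @ sh.T  # cos(gamma), (n, p)
    g = np.sqrt(1.0 - 2.0 * f[None, :] * x + f[None, :] ** 2)
    return 2.0 * (x - f[None, :]) / g**3 + (1.0 / f[None, :]) * (1.0 / g - 1.0)


def build_spherical_leadfield(
    montage: ElectrodeMontage,
    sources: SourceSpace,
    sphere_radius_mm: float,
) -> Leadfield:
    """Analytic forward matrix for radially oriented dipoles in a homogeneous sphere.

    Electrodes must lie on or near the sphere surface and away from the
    center; sources must lie strictly inside.  Rows are average-referenced,
    so every column sums to zero across electrodes.  Deterministic.
    """
    R = float(sphere_radius_mm)
    if R <= 0:
        raise ValueError("sphere radius must be positive")
    e_r = np.linalg.norm(montage.positions, axis=1)
    if (e_r < 1e-9).any():
        raise ValueError("electrode at sphere center")
    s_r = np.linalg.norm(sources.positions, axis=1)
    if (s_r >= R).any():
        bad = int(np.argmax(s_r >= R))
        raise ValueError(f"source {bad} on or outside the sphere (|r|={s_r[bad]:.1f} >= {R})")
    if (s_r < 1e-9).any():
        raise ValueError("radial orientation undefined for a dipole at the sphere center")
    A = _radial_dipole_potential(montage.positions, sources.positions, R)
    A = A - A.mean(axis=0, keepdims=True)
    return normalize_leadfield(A, montage=montage, sources=sources)


def normalize_leadfield(
    A: np.ndarray,
    montage: Optional[ElectrodeMontage] = None,
    sources: Optional[SourceSpace] = None,
) -> Leadfield:
    """Wrap a gain matrix with unit-l2-norm columns recorded alongside.

    ``A = A_norm @ diag(col_norms)`` holds exactly; a zero column raises with
    the offending source index.
    """
    if isinstance(A, Leadfield):
        A = A.A
    A = np.asarray(A, dtype=float)
    norms = np.linalg.norm(A, axis=0)
    if (norms == 0).any():
        bad = int(np.argmax(norms == 0))
        raise ValueError(f"zero gain column at source index {bad}")
    return Leadfield(A=A, A_norm=A / norms, col_norms=norms, montage=montage, sources=sources)


def _upper_triangle_normal_equations(An: np.ndarray, selec: np.ndarray):
    """Gram matrix and rhs-builder for the diagonal covariance fit.

    Fitting ``M ≈ sum_q s_q a_q a_q^T`` over the vectorized upper triangle of
    the ``selec`` submatrix gives normal equations ``G s = b`` with
    ``G[q,r] = ((a_q.a_r)^2 + sum_i a_q[i]^2 a_r[i]^2) / 2`` and
    ``b[q] = (a_q^T M a_q + sum_i a_q[i]^2 M[i,i]) / 2``.
    """
    As = An[selec]
    AtA = As.T @ As
    A2 = As**2
    G = 0.5 * (AtA**2 + A2.T @ A2)
    return G, A2


def _fit_diag_source_cov(
    M: np.ndarray,
    An: np.ndarray,
    selec: np.ndarray,
    ridge_rel: float = 1e-6,
    fixed_zero: Optional[np.ndarray] = None,
    cache: Optional[dict] = None,
) -> np.ndarray:
    """Least-squares diagonal source variances, negatives clipped at 0.

    ``fixed_zero`` constrains the listed sources to zero variance and refits
    the rest (used by the iterative localizer).
    """
    p = An.shape[1]
    key = ("G", tuple(selec.tolist()))
    if cache is not None and key in cache:
        G, A2 = cache[key]
    else:
        G, A2 = _upper_triangle_normal_equations(An, selec)
        if cache is not None:
            cache[key] = (G, A2)
    As = An[selec]
    Ms = M[np.ix_(selec, selec)]
    b = 0.5 * (np.einsum("iq,ij,jq->q", As, Ms, As, optimize=True)
               + A2.T @ np.diag(Ms))
    lam = ridge_rel * np.trace(G) / p
    s = np.zeros(p)
    if fixed_zero is not None and len(fixed_zero):
        keep = np.setdiff1d(np.arange(p), np.asarray(fixed_zero, dtype=int))
        Gk = G[np.ix_(keep, keep)] + lam * np.eye(len(keep))
        s[keep] = cho_solve(cho_factor(Gk), b[keep])
    else:
        ckey = ("chol", tuple(selec.tolist()), ridge_rel)
        if cache is not None and ckey in cache:
            c_and_lower = cache[ckey]
        else:
            c_and_lower = cho_factor(G + lam * np.eye(p))
            if cache is not None:
                cache[ckey] = c_and_lower
        s = cho_solve(c_and_lower, b)
    return np.clip(s, 0.0, None)


def estimate_covariances(
    X,
    lf: Leadfield,
    noise_frac: float = 0.25,
    selec: Optional[Sequence[int]] = None,
    ridge_rel: float = 1e-6,
) -> CovarianceModel:
    """Estimate scalp, noise and diagonal source covariances from a recording.

    Parameters
    ----------
    X : EEGRecording or (n, T) ndarray
        Average-referenced recording.
    lf : Leadfield
        Normalized leadfield for the same montage.
    noise_frac : float
        The noise variance is the mean of the smallest ``ceil(noise_frac*n)``
        eigenvalues of the scalp covariance; ``C_z = sigma^2 I``.
    selec : sequence of int, optional
        Electrode subset used for the source-variance fit (default: all).

    Notes
    -----
    Fewer than ``10 n`` samples triggers a warning: the scalp covariance is
    then poorly conditioned and the fitted source variances unstable.
    """
    data = X.X if hasattr(X, "X") else np.asarray(X, dtype=float)
    n, T = data.shape
    if n != lf.n_channels:
        raise ValueError(f"recording has {n} channels, leadfield {lf.n_channels}")
    if T < 10 * n:
        warnings.warn(f"only {T} samples for {n} channels; covariance estimate may be unstable")
    C_x = np.cov(data)
    C_x = 0.5 * (C_x + C_x.T)
    w = np.linalg.eigvalsh(C_x)
    if w[0] < -1e-8 * max(abs(w[-1]), 1.0):
        raise ValueError("scalp covariance is not positive semidefinite")
    n_noise = int(np.ceil(noise_frac * n))
    n_noise = max(1, min(n, n_noise))
    sigma2 = float(w[:n_noise].mean())
    if n_noise == n and np.allclose(w, w[0]):
        warnings.warn("all eigenvalues equal with noise_frac=1: C_z degenerates to C_x")
    C_z = sigma2 * np.eye(n)
    selec = np.arange(n) if selec is None else np.asarray(selec, dtype=int)
    s_var = _fit_diag_source_cov(C_x - C_z, lf.A_norm, selec,
                                 ridge_rel=ridge_rel, cache=lf._cache)
    return CovarianceModel(C_x=C_x, C_z=C_z, s_var=s_var, selec=selec)
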