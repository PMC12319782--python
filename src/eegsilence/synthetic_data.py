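"""Synthetic scalp EEG with planted ground truth.

The generator emulates the study conditions of a single-case diaschisis
experiment: five object-scrambling conditions (S256..S1) plus resting state,
five EEG bands, a high-density montage on a spherical head, a mirror-
symmetric two-hemisphere source shell, a contiguous low-power "lesion"
region, a per-parcel linear slope of band power across conditions, and a
band-specific (default Theta-only) slope reduction in the homotopic region
mirrored from the lesion.

Geometry.  The head is a sphere of radius 92 mm.  Electrodes sit on the
sphere surface on the cap z > -0.45 R as mirrored left/right pairs of a
deterministic Fibonacci spiral - high-density nets extend below the equator,
and symmetric coverage keeps the two hemispheres statistically exchangeable.
Sources sit on a shell at 0.85 R restricted to the same polar cap (the lower
part of the head sphere holds no cortex), built as one quasi-uniform
hemisphere mirrored through x = 0, so homotopic mapping is exact.

Parcels tile the shell into the study's vocabulary: posterior sources
(y < -0.15 r) form the visual territory, split into ventral (low z) and
dorsal; an anterior-superior sector is dlpfc; everything else is "other".

Signal model.  Sources are independent band-limited Gaussian processes
(white noise shaped by the spectral module's own filters - one filter
implementation throughout the package).  Under scrambling level i (ordinal
x_i in 1..5 from S256 to S1) a source's variance is

    var = base_var * (1 + alpha* * (x_i - 3) / 2),  floored at 0.05 base_var,

with alpha* the planted per-parcel, per-band slope coefficient scaled by
per-subject and per-band jitter factors.  Lesion sources keep 1% of base
variance in every condition; in a "case" subject the homotopic diaschisis
region's slope is replaced by a near-zero value in the planned band(s).
Sensor noise is band-limited white noise scaled to the target SNR.  The
emitted ground-truth record holds the exact ordinary-least-squares slope of
each source's planted power line, so every recovery metric is computable
without re-reading the scenario.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .headmodel import ElectrodeMontage, Leadfield, SourceSpace, build_spherical_leadfield
from .roi import LesionSpec
from .slopes import SCRAMBLING_ORDER
from .spectral import DEFAULT_BANDS, EEGRecording, bandpass

__all__ = [
    "HEAD_RADIUS_MM",
    "SOURCE_RADIUS_FRAC",
    "CAP_ZMIN_FRAC",
    "SyntheticScenario",
    "GroundTruth",
    "make_montage",
    "make_source_space",
    "simulate_scenario",
]

HEAD_RADIUS_MM = 92.0
SOURCE_RADIUS_FRAC = 0.85
CAP_ZMIN_FRAC = -0.45

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))

#: direction of the study's lesion centroid (right lateral fusiform area),
#: projected onto the source shell when planting the synthetic lesion
_LESION_DIRECTION = np.array([44.0, -46.0, -2.0])


def _cap_spiral(m: int, zmin: float) -> np.ndarray:
    """m quasi-uniform points on the unit-sphere cap z > zmin (Fibonacci)."""
    i = np.arange(m)
    c = 1.0 - (i + 0.5) / m * (1.0 - zmin)
    s = np.sqrt(1.0 - c**2)
    th = _GOLDEN * i
    return np.stack([s * np.cos(th), s * np.sin(th), c], axis=1)


def _half_mirror(count: int, zmin: float, radius: float) -> np.ndarray:
    """count points on the cap, as count/2 x>0 points plus their mirrors."""
    half = count // 2
    m = count
    while True:
        pts = _cap_spiral(m, zmin)
        keep = pts[pts[:, 0] > 0]
        if len(keep) == half:
            break
        m += 1 if len(keep) < half else -1
    right = radius * keep
    return np.vstack([right, right * np.array([-1.0, 1.0, 1.0])])


def make_montage(n: int = 128, seed: int = 0,
                 radius_mm: float = HEAD_RADIUS_MM,
                 zmin_frac: float = CAP_ZMIN_FRAC) -> ElectrodeMontage:
    """Deterministic quasi-uniform montage of mirrored electrode pairs.

    ``n`` electrodes on the head-sphere cap ``z > zmin_frac * R``; an odd
    count adds a vertex electrode.  ``seed`` is accepted for interface
    uniformity but the layout is fully deterministic.
    """
    if n < 16:
        raise ValueError("need at least 16 electrodes")
    pos = _half_mirror(n, zmin_frac, radius_mm)
    if n % 2 == 1:
        pos = np.vstack([pos, [0.0, 0.0, radius_mm]])
    labels = [f"E{i+1:03d}" for i in range(len(pos))]
    return ElectrodeMontage(labels=labels, positions=pos)


def _assign_parcels(pos: np.ndarray, r_src: float) -> np.ndarray:
    lab = np.full(len(pos), "other", dtype=object)
    x, y, z = pos.T
    visual = y < -0.15 * r_src
    ventral = visual & (z < 0.12 * r_src)
    dorsal = visual & ~ (z < 0.12 * r_src)
    dlpfc = (y > 0.45 * r_src) & (z > 0.15 * r_src)
    lab[ventral & (x > 0)] = "ventral_R"
    lab[ventral & (x < 0)] = "ventral_L"
    lab[dorsal & (x > 0)] = "dorsal_R"
    lab[dorsal & (x < 0)] = "dorsal_L"
    lab[dlpfc & (x > 0)] = "dlpfc_R"
    lab[dlpfc & (x < 0)] = "dlpfc_L"
    return lab.astype(str)


def make_source_space(p: int = 804, spacing_mm: Optional[float] = None, seed: int = 0,
                      radius_mm: float = SOURCE_RADIUS_FRAC * HEAD_RADIUS_MM,
                      zmin_frac: float = CAP_ZMIN_FRAC,
                      parent_space: Optional[SourceSpace] = None) -> SourceSpace:
    """Mirror-symmetric shell source grid inside the head sphere.

    ``p`` sources (p/2 per hemisphere) on a shell at ``radius_mm`` restricted
    to the cap ``z > zmin_frac * r``; adjacency links mutually proximal
    sources within 1.5x the grid step (the median nearest-neighbor distance
    unless ``spacing_mm`` is given).  Passing ``parent_space`` builds a
    high-resolution grid with each source mapped to its nearest parent.
    """
    if p < 50:
        raise ValueError("need at least 50 sources")
    pos = _half_mirror(p, zmin_frac, radius_mm)
    p_eff = len(pos)
    tree = cKDTree(pos)
    d, _ = tree.query(pos, k=2)
    spacing = float(spacing_mm) if spacing_mm is not None else float(np.median(d[:, 1]))
    if spacing <= 0 or spacing > radius_mm:
        raise ValueError(f"infeasible spacing {spacing} mm for p={p}")
    pairs = tree.query_pairs(1.5 * spacing)
    adjacency = {i: set() for i in range(p_eff)}
    for i, j in pairs:
        adjacency[i].add(j)
        adjacency[j].add(i)
    if any(not nbs for nbs in adjacency.values()):
        raise ValueError(f"infeasible spacing for p={p}: isolated sources")
    adjacency = {q: frozenset(nbs) for q, nbs in adjacency.items()}
    hemi = np.where(pos[:, 0] > 0, "R", "L")
    parcels = _assign_parcels(pos, radius_mm)
    parent = None
    tier = "low"
    if parent_space is not None:
        ptree = cKDTree(parent_space.positions)
        parent = ptree.query(pos)[1].astype(int)
        tier = "high"
    return SourceSpace(positions=pos, hemisphere=hemi, adjacency=adjacency,
                       spacing=spacing, parcels=parcels, tier=tier, parent=parent)


# ---------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic experiment.

    Defaults mirror the emulated acquisition: 128 electrodes, ~800 shell
    sources, 512 Hz sampling, 120 s of rest and 60 s per scrambling
    condition, 10 dB sensor SNR, a 100-source contiguous lesion with 1%
    residual variance, shape-sensitivity alpha* = 0.5 across the posterior
    visual territory in every band, and a Theta-only near-zero slope in the
    30 mm homotopic region mirrored from the lesion centroid.
    """

    seed: int
    n_electrodes: int = 128
    p_sources: int = 804
    fs: float = 512.0
    rest_duration_s: float = 120.0
    condition_duration_s: float = 60.0
    bands: Tuple[str, ...] = ("Full",)
    base_var: float = 100.0           # microvolt^2 per source
    snr_db: float = 10.0
    n_silent: int = 100
    lesion_var_frac: float = 0.01
    lesion_volume_mm3: float = 990.0
    slope_alpha: float = 0.5
    slope_plan: Optional[Dict[Tuple[str, str], float]] = None
    diaschisis_bands: Tuple[str, ...] = ("Theta",)
    diaschisis_alpha: float = 0.05
    diaschisis_radius_mm: float = 30.0
    subject_jitter_sd: float = 0.10
    band_jitter_sd: float = 0.05
    floor_frac: float = 0.05
    band_fs: Optional[Dict[str, float]] = None
    #: optional (3,) override for the silent-region center (mm); the lesion
    #: ROI geometry still follows lesion_spec
    silent_center: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("scenario seed is mandatory")
        self.seed = int(self.seed) & 0x7FFFFFFF

    # -- geometry ----------------------------------------------------------
    def build_geometry(self) -> Tuple[ElectrodeMontage, SourceSpace, Leadfield]:
        montage = make_montage(self.n_electrodes, seed=self.seed)
        sources = make_source_space(self.p_sources, seed=self.seed)
        lf = build_spherical_leadfield(montage, sources, HEAD_RADIUS_MM)
        return montage, sources, lf

    def lesion_spec(self, sources: SourceSpace) -> LesionSpec:
        """Lesion centroid: the right-ventral shell source nearest the
        study lesion direction, with the study lesion volume."""
        r_src = float(np.linalg.norm(sources.positions, axis=1).max())
        target = _LESION_DIRECTION / np.linalg.norm(_LESION_DIRECTION) * r_src
        right = sources.hemisphere_indices("R")
        q = right[np.argmin(np.linalg.norm(sources.positions[right] - target, axis=1))]
        return LesionSpec(centroid=sources.positions[q], volume_mm3=self.lesion_volume_mm3)

    def silent_indices(self, sources: SourceSpace) -> np.ndarray:
        """Planted contiguous silent set: n_silent right-hemisphere sources
        nearest the lesion centroid."""
        if self.silent_center is not None:
            center = np.asarray(self.silent_center, dtype=float).reshape(3)
        else:
            center = self.lesion_spec(sources).centroid
        right = sources.hemisphere_indices("R")
        d = np.linalg.norm(sources.positions[right] - center[None, :], axis=1)
        return np.sort(right[np.argsort(d)[: self.n_silent]])

    def diaschisis_indices(self, sources: SourceSpace) -> np.ndarray:
        """Homotopic diaschisis region: posterior sources within the planned
        radius of the mirrored lesion centroid."""
        lesion = self.lesion_spec(sources)
        mirror = lesion.centroid * np.array([-1.0, 1.0, 1.0])
        d = np.linalg.norm(sources.positions - mirror[None, :], axis=1)
        visual = np.isin(sources.parcels, ["ventral_L", "dorsal_L", "ventral_R", "dorsal_R"])
        return np.sort(np.where((d <= self.diaschisis_radius_mm) & visual)[0])

    # -- plans -------------------------------------------------------------
    def alpha_plan(self, sources: SourceSpace, band: str) -> np.ndarray:
        """Planted alpha* per source for one band, before jitter."""
        alpha = np.zeros(sources.n_sources)
        if self.slope_plan is not None:
            for (parcel, b), a in self.slope_plan.items():
                if b == band or b == "*":
                    alpha[sources.parcels == parcel] = a
        else:
            visual = np.isin(sources.parcels,
                             ["ventral_L", "ventral_R", "dorsal_L", "dorsal_R"])
            alpha[visual] = self.slope_alpha
        return alpha


@dataclass
class GroundTruth:
    """Everything needed to score recovery, frozen at simulation time."""

    subject: str
    role: str
    silent_indices: np.ndarray
    diaschisis_indices: np.ndarray
    lesion: LesionSpec
    #: band -> per-source exact OLS slope of the planted relative-power line
    slopes: Dict[str, np.ndarray]
    #: (condition, band) -> per-source planted variance
    variance_plan: Dict[Tuple[str, str], np.ndarray]
    seed: int


def _child_rng(seed: int, subject: str, *keys: int) -> np.random.Generator:
    tag = zlib.crc32(subject.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, tag, *keys]))


def _band_limited(rng: np.random.Generator, shape: Tuple[int, int],
                  fs: float, band: str) -> np.ndarray:
    """Unit-variance rows of band-limited Gaussian noise (package filters)."""
    raw = rng.standard_normal(shape)
    rec = EEGRecording(X=raw, fs=fs, condition="rest", band="broadband")
    out = bandpass(rec, band).X
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_scenario(
    sc: SyntheticScenario,
    lf: Leadfield,
    subject: str = "SM",
    role: str = "case",
    conditions: Optional[Sequence[str]] = None,
    bands: Optional[Sequence[str]] = None,
) -> Tuple[Dict[Tuple[str, str], EEGRecording], GroundTruth]:
    """Simulate one subject's recordings for every (condition, band).

    ``role='case'`` plants the lesion (silent region) and the homotopic
    diaschisis; ``role='control'`` plants neither.  Identical (scenario seed,
    subject) pairs give bit-identical recordings.
    """
    if role not in ("case", "control"):
        raise ValueError("role must be 'case' or 'control'")
    sources = lf.sources
    if sources is None or sources.n_sources != lf.n_sources:
        raise ValueError("leadfield does not match the scenario source space")
    conditions = tuple(conditions) if conditions else ("rest",) + SCRAMBLING_ORDER
    bands = tuple(bands) if bands else sc.bands
    p = sources.n_sources

    lesion = sc.lesion_spec(sources)
    silent = sc.silent_indices(sources) if role == "case" else np.array([], dtype=int)
    dias = sc.diaschisis_indices(sources) if role == "case" else np.array([], dtype=int)

    jrng = _child_rng(sc.seed, subject, 0)
    subj_factor = 1.0 + sc.subject_jitter_sd * jrng.standard_normal()
    band_factor = {b: 1.0 + sc.band_jitter_sd * jrng.standard_normal()
                   for b in DEFAULT_BANDS}

    x_ord = {cond: float(i + 1) for i, cond in enumerate(SCRAMBLING_ORDER)}

    variance_plan: Dict[Tuple[str, str], np.ndarray] = {}
    slopes: Dict[str, np.ndarray] = {}
    for band in bands:
        alpha = sc.alpha_plan(sources, band) * subj_factor * band_factor[band]
        if role == "case" and band in sc.diaschisis_bands and len(dias):
            alpha[dias] = sc.diaschisis_alpha
        var_by_cond = {}
        for cond in conditions:
            if cond == "rest":
                v = np.full(p, sc.base_var)
            else:
                v = sc.base_var * (1.0 + alpha * (x_ord[cond] - 3.0) / 2.0)
                v = np.maximum(v, sc.floor_frac * sc.base_var)
            if len(silent):
                v = v.copy()
                v[silent] *= sc.lesion_var_frac
            var_by_cond[cond] = v
            variance_plan[(cond, band)] = v
        # exact OLS slope of the planted relative-power line (vs rest)
        if all(c in var_by_cond for c in SCRAMBLING_ORDER) and "rest" in var_by_cond:
            xs = np.arange(1, 6, dtype=float)
            Y = np.stack([var_by_cond[c] / var_by_cond["rest"]
                          for c in SCRAMBLING_ORDER], axis=1)
            xc = xs - xs.mean()
            slopes[band] = (Y - Y.mean(axis=1, keepdims=True)) @ xc / float(xc @ xc)

    recordings: Dict[Tuple[str, str], EEGRecording] = {}
    band_list = list(DEFAULT_BANDS)
    for cond in conditions:
        dur = sc.rest_duration_s if cond == "rest" else sc.condition_duration_s
        for band in bands:
            fs_b = float((sc.band_fs or {}).get(band, sc.fs))
            T = int(round(dur * fs_b))
            rng = _child_rng(sc.seed, subject,
                             1 + conditions.index(cond), band_list.index(band))
            S = _band_limited(rng, (p, T), fs_b, band)
            S *= np.sqrt(variance_plan[(cond, band)])[:, None]
            X = lf.A @ S
            noise = _band_limited(rng, X.shape, fs_b, band)
            sig_power = float((X**2).mean())
            noise *= np.sqrt(sig_power / 10.0 ** (sc.snr_db / 10.0))
            X = X + noise
            X -= X.mean(axis=0, keepdims=True)
            recordings[(cond, band)] = EEGRecording(X=X, fs=fs_b, condition=cond,
                                                    band=band, subject=subject)

    truth = GroundTruth(subject=subject, role=role, silent_indices=silent,
                        diaschisis_indices=dias, lesion=lesion, slopes=slopes,
                        variance_plan=variance_plan, seed=sc.seed)
    return recordings, truth
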