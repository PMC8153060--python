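"""Synthetic single-hemisphere claustrum phantoms and subject cohorts.

The phantom emulates the anatomy the segmentation relies on, at 0.7 mm
isotropic resolution: a lateral-convex ellipsoidal putamen; a thin (1-2
voxel) lower-intensity gray-matter sheet 1.5-3.5 mm lateral to it (the
ground-truth claustrum, with occasional "puddle" widenings protruding
toward the insula); brighter white matter between and around it; an insular
gray-matter band further lateral; and a CSF band following the insular
surface. Gaussian noise is added per channel. Everything is deterministic
given the seed, and a left-hemisphere phantom is the exact mirror image of
the right-hemisphere one.

The cohort generator emulates the statistical substrate of the covariance
analysis: subject x region values drawn from a multivariate normal with a
planted correlation matrix, optionally scaled by a per-subject
multiplicative bias (the nuisance the z-scoring step removes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .covariance import RegionMeasureTable
from .errors import CovarianceError, PhantomError
from .metrics import DWIProtocol, _design_matrix
from .volumes import BinaryMask, ScalarVolume, write_mask, write_volume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue contrast and noise of a synthetic hemisphere.

    T1w tissue means (arbitrary units) default to CSF 30 < gray 70 <
    putamen 75 < white 110 with noise sd 5, so the gray/white separation is
    comparable to real T1w contrast: the clustering step is challenged but
    solvable. T2w means invert the contrast (CSF brightest). The claustrum
    sheet is 1-2 voxels thick at a smoothly varying lateral offset of
    1.5-3.5 mm from the putamen edge.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.7)
    hemisphere: str = "right"
    t1_means: dict = field(
        default_factory=lambda: {"csf": 30.0, "gray": 70.0, "putamen": 75.0, "white": 110.0}
    )
    t2_means: dict = field(
        default_factory=lambda: {"csf": 160.0, "gray": 90.0, "putamen": 85.0, "white": 60.0}
    )
    noise_sd: float = 5.0
    sheet_thickness_voxels: tuple[int, int] = (1, 2)
    lateral_offset_mm: tuple[float, float] = (1.5, 3.5)
    n_puddles: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise PhantomError(f"hemisphere must be 'left' or 'right': {self.hemisphere!r}")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if not (self.t1_means["csf"] < self.t1_means["gray"] < self.t1_means["white"]):
            raise PhantomError(
                "T1w contrast must order CSF < gray < white (the k-means premise)"
            )
        if min(self.sheet_thickness_voxels) < 0:
            raise PhantomError("sheet thickness must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class PhantomBundle:
    """A generated phantom: intensity channels, input masks, ground truth."""

    t1w: ScalarVolume
    t2w: ScalarVolume
    putamen: BinaryMask
    csf: BinaryMask
    insula: BinaryMask
    truth_claustrum: BinaryMask
    spec: PhantomSpec

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_volume(self.t1w, d / "t1w.nii.gz")
        write_volume(self.t2w, d / "t2w.nii.gz")
        write_mask(self.putamen, d / "putamen.nii.gz")
        write_mask(self.csf, d / "csf.nii.gz")
        write_mask(self.insula, d / "insula.nii.gz")
        write_mask(self.truth_claustrum, d / "truth_claustrum.nii.gz")
        self.spec.to_json(d / "spec.json")


def _smooth_field(rng: np.random.Generator, shape2d, sigma: float) -> np.ndarray:
    """Low-frequency random field in [0, 1], used to modulate geometry."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape2d), sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape2d)


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Build a deterministic phantom bundle from a spec.

    The geometry is constructed column-by-column from the putamen's lateral
    face so that the premise of the segmentation holds by construction: the
    truth sheet is an offset surface of that face, strictly between putamen
    and insula, with the CSF band following the insular surface. A left
    hemisphere is produced by building the right one and mirroring every
    grid across the midsagittal plane (exact, including noise).
    """
    if spec is None:
        spec = PhantomSpec()
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(spec.seed)

    # --- putamen: ellipsoid with a convex lateral face -------------------
    x0, y0, z0 = 0.38 * nx, ny / 2.0, nz / 2.0
    a, b, c = 0.10 * nx, 0.24 * ny, 0.20 * nz
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    putamen = (
        ((ii - x0) / a) ** 2 + ((jj - y0) / b) ** 2 + ((kk - z0) / c) ** 2
    ) <= 1.0

    # lateral-face map: most-lateral putamen index per (PA, IS) column
    has_col = putamen.any(axis=0)
    idx = np.arange(nx)[:, None, None]
    edge_x = np.max(np.where(putamen, idx, -1), axis=0)  # -1 where no putamen

    # --- ground-truth claustrum sheet ------------------------------------
    # offset surface of the lateral face, restricted to the interior of the
    # face (columns with enough putamen depth) so the sheet does not wrap
    # around the steep rim
    depth = putamen.sum(axis=0)
    sheet_cols = depth >= 3
    off_field = _smooth_field(rng, (ny, nz), sigma=8.0)
    lo_mm, hi_mm = spec.lateral_offset_mm
    off_vox = np.rint((lo_mm + off_field * (hi_mm - lo_mm)) / spec.spacing[0]).astype(int)
    off_vox = np.clip(off_vox, 1, None)
    t_lo, t_hi = spec.sheet_thickness_voxels
    thick_field = _smooth_field(rng, (ny, nz), sigma=6.0)
    thick = np.rint(t_lo + thick_field * (t_hi - t_lo)).astype(int)

    truth = np.zeros(spec.shape, dtype=bool)
    jj2, kk2 = np.nonzero(sheet_cols)
    for j, k in zip(jj2, kk2):
        start = edge_x[j, k] + off_vox[j, k]
        stop = min(start + thick[j, k], nx)
        truth[start:stop, j, k] = True

    # puddles: small lateral widenings of the sheet toward the insular gyri
    if spec.n_puddles > 0 and jj2.size > 0 and t_hi > 0:
        picks = rng.choice(jj2.size, size=min(spec.n_puddles, jj2.size), replace=False)
        for p in picks:
            jc, kc = jj2[p], kk2[p]
            for j in range(max(jc - 2, 0), min(jc + 3, ny)):
                for k in range(max(kc - 2, 0), min(kc + 3, nz)):
                    if sheet_cols[j, k] and (j - jc) ** 2 + (k - kc) ** 2 <= 4:
                        start = edge_x[j, k] + off_vox[j, k]
                        stop = min(start + thick[j, k] + 2, edge_x[j, k] + 7, nx)
                        truth[start:stop, j, k] = True

    # --- insular band and CSF band ---------------------------------------
    # extend the face map a few columns beyond the putamen so the bands
    # cover (and overhang) the whole ROI region
    face = np.where(has_col, edge_x, -(10 * nx))
    face_ext = ndimage.grey_dilation(face, size=(9, 9))
    band_cols = face_ext > 0
    if not band_cols.any() or int(face_ext[band_cols].max()) + 13 > nx:
        raise PhantomError(
            "geometry does not fit in the grid: the insular and CSF bands "
            f"(putamen face + 13 voxels) exceed the lateral extent ({nx} voxels)"
        )
    insula = np.zeros(spec.shape, dtype=bool)
    csf = np.zeros(spec.shape, dtype=bool)
    jj3, kk3 = np.nonzero(band_cols)
    for j, k in zip(jj3, kk3):
        e = face_ext[j, k]
        i0, i1 = min(e + 8, nx), min(e + 11, nx)
        insula[i0:i1, j, k] = True
        c0, c1 = min(e + 11, nx), min(e + 13, nx)
        csf[c0:c1, j, k] = True

    if truth.any() and (truth & (putamen | csf | insula)).any():
        raise PhantomError("geometry overlap: truth sheet intersects another tissue")

    # --- intensity channels ----------------------------------------------
    t1 = np.full(spec.shape, spec.t1_means["white"])
    t2 = np.full(spec.shape, spec.t2_means["white"])
    for tissue, mask in (("putamen", putamen), ("gray", truth | insula), ("csf", csf)):
        t1[mask] = spec.t1_means[tissue]
        t2[mask] = spec.t2_means[tissue]
    t1 = t1 + spec.noise_sd * rng.standard_normal(spec.shape)
    t2 = t2 + spec.noise_sd * rng.standard_normal(spec.shape)

    arrays = [t1, t2, putamen, csf, insula, truth]
    if spec.hemisphere == "left":
        arrays = [np.flip(arr, axis=0).copy() for arr in arrays]
    t1, t2, putamen, csf, insula, truth = arrays

    sp = spec.spacing
    return PhantomBundle(
        t1w=ScalarVolume(t1, sp),
        t2w=ScalarVolume(t2, sp),
        putamen=BinaryMask(putamen, sp),
        csf=BinaryMask(csf, sp),
        insula=BinaryMask(insula, sp),
        truth_claustrum=BinaryMask(truth, sp),
        spec=spec,
    )


def compose_bilateral(bundle: PhantomBundle) -> PhantomBundle:
    """Place a single-hemisphere phantom and its mirror on one double-width grid.

    The input hemisphere occupies its anatomical side (right hemisphere in
    the right half), the mirror the other, separated by background white
    matter — a bilateral stand-in for exercising hemisphere splitting.
    """
    nx, ny, nz = bundle.t1w.shape
    sp = bundle.t1w.spacing

    def widen(arr: np.ndarray, fill) -> np.ndarray:
        out = np.full((2 * nx, ny, nz), fill, dtype=arr.dtype)
        flipped = np.flip(arr, axis=0)
        if bundle.spec.hemisphere == "right":
            out[nx:], out[:nx] = arr, flipped
        else:
            out[:nx], out[nx:] = arr, flipped
        return out

    wm_t1 = bundle.spec.t1_means["white"]
    wm_t2 = bundle.spec.t2_means["white"]
    return PhantomBundle(
        t1w=ScalarVolume(widen(bundle.t1w.data, wm_t1), sp),
        t2w=ScalarVolume(widen(bundle.t2w.data, wm_t2), sp),
        putamen=BinaryMask(widen(bundle.putamen.data, False), sp),
        csf=BinaryMask(widen(bundle.csf.data, False), sp),
        insula=BinaryMask(widen(bundle.insula.data, False), sp),
        truth_claustrum=BinaryMask(widen(bundle.truth_claustrum.data, False), sp),
        spec=bundle.spec,
    )


def generate_dwi(
    md_per_tissue: dict[str, float],
    tissue_labels: np.ndarray,
    protocol: DWIProtocol,
    s0: float = 1000.0,
) -> np.ndarray:
    """Forward-simulate isotropic DWI signals S = S0 exp(-b * d) per tissue.

    ``tissue_labels`` is an integer grid; ``md_per_tissue`` maps label ->
    diffusivity in mm^2/s. Used to exercise the tensor fit end to end.
    """
    b = np.asarray(protocol.b_values, dtype=float)
    d = np.zeros(tissue_labels.shape, dtype=float)
    for label, md in md_per_tissue.items():
        d[tissue_labels == int(label)] = md
    return s0 * np.exp(-d[..., None] * b[None, None, None, :])


def generate_dwi_from_tensor(tensor6: np.ndarray, protocol: DWIProtocol, s0: float = 1000.0) -> np.ndarray:
    """Forward-simulate a 4-D signal grid from a per-voxel symmetric tensor.

    ``tensor6`` has shape (nx, ny, nz, 6) ordered (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz), matching the design matrix of the log-linear fit.
    """
    X = _design_matrix(protocol)  # (nvol, 7); columns 1..6 are -b g terms
    expo = tensor6 @ X[:, 1:].T  # (nx, ny, nz, nvol)
    return s0 * np.exp(expo)


@dataclass(frozen=True)
class CohortSpec:
    """Statistical design of a synthetic subject cohort.

    ``correlation`` is the planted cross-region correlation matrix
    (symmetric PSD, unit diagonal; identity if omitted). Each subject's row
    is optionally multiplied by a log-normal bias scalar with log-sd
    ``bias_sd`` — the global nuisance that per-subject z-scoring removes.
    """

    n_subjects: int
    region_labels: tuple[str, ...]
    correlation: np.ndarray | None = None
    bias_sd: float = 0.0
    mean: float = 10.0
    scale: float = 1.0
    seed: int = 0

    def corr_matrix(self) -> np.ndarray:
        p = len(self.region_labels)
        if self.correlation is None:
            return np.eye(p)
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (p, p):
            raise CovarianceError(f"correlation matrix must be {p}x{p}, got {corr.shape}")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise CovarianceError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise CovarianceError("correlation matrix is not positive semi-definite")
        return corr


def planted_correlation(
    region_labels: tuple[str, ...], pairs: dict[tuple[str, str], float]
) -> np.ndarray:
    """Identity correlation matrix with the given region pairs planted."""
    p = len(region_labels)
    corr = np.eye(p)
    index = {r: i for i, r in enumerate(region_labels)}
    for (r1, r2), rho in pairs.items():
        i, j = index[r1], index[r2]
        corr[i, j] = corr[j, i] = rho
    return corr


def generate_cohort(spec: CohortSpec) -> RegionMeasureTable:
    """Draw a subjects x regions table from the planted multivariate design."""
    if spec.n_subjects < 2:
        raise CovarianceError("need at least 2 subjects (correlations undefined below 3)")
    corr = spec.corr_matrix()
    rng = np.random.default_rng(spec.seed)
    # eigen factorization tolerates semi-definite matrices (Cholesky does not)
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((spec.n_subjects, len(spec.region_labels)))
    values = spec.mean + spec.scale * (z @ root.T)
    if spec.bias_sd > 0:
        bias = np.exp(spec.bias_sd * rng.standard_normal(spec.n_subjects))
        values = values * bias[:, None]
    df = pd.DataFrame(
        values,
        index=[f"sub-{i:04d}" for i in range(spec.n_subjects)],
        columns=list(spec.region_labels),
    )
    return RegionMeasureTable(df)
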