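"""Evaluation metric and structural measures.

Dice overlap for comparing segmentations, mask volume in mm^3, regional
means of scalar maps (T1w/T2w, MD), and mean diffusivity from a log-linear
diffusion-tensor fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyMaskError, ProtocolError
from .volumes import BinaryMask, ScalarVolume


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) of two voxel sets.

    Symmetric, 1.0 for identical non-empty masks, 0.0 for disjoint ones.
    Undefined (an error) when both masks are empty.
    """
    if not a.aligned_with(b):
        raise AlignmentError(f"masks are not aligned: {a.shape} vs {b.shape}")
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        raise EmptyMaskError("Dice is undefined for two empty masks")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def mask_volume(mask: BinaryMask) -> float:
    """Mask volume in mm^3: voxel count times the voxel volume.

    At the 0.7 mm isotropic resolution this toolkit targets, one voxel is
    0.343 mm^3.
    """
    return mask.count * float(np.prod(mask.spacing))


def region_mean(volume: ScalarVolume, mask: BinaryMask) -> float:
    """Mean of the finite voxel values under the mask.

    NaN voxels (e.g. T1w/T2w where T2w <= 0) are excluded; if any are
    dropped a warning reports how many. An error is raised when no finite
    voxel remains.
    """
    if not volume.aligned_with(mask):
        raise AlignmentError(f"volume {volume.shape} and mask {mask.shape} are not aligned")
    if mask.is_empty():
        raise EmptyMaskError("cannot take the mean over an empty mask")
    vals = volume.data[mask.data]
    finite = np.isfinite(vals)
    n_bad = int((~finite).sum())
    if n_bad == vals.size:
        raise EmptyMaskError("no finite voxels under the mask")
    if n_bad:
        warnings.warn(f"region_mean: excluded {n_bad} non-finite voxel(s)", stacklevel=2)
    return float(vals[finite].mean())


@dataclass(frozen=True)
class DWIProtocol:
    """Diffusion acquisition protocol: b-values (s/mm^2) and gradient directions.

    A tensor fit needs at least one b=0 volume and at least six
    diffusion-weighted volumes with non-collinear directions. Directions of
    weighted volumes must be unit vectors; b=0 volumes may carry a zero
    vector.
    """

    b_values: tuple[float, ...]
    directions: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.b_values) != len(self.directions):
            raise ProtocolError(
                f"{len(self.b_values)} b-values but {len(self.directions)} directions"
            )
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if not (b == 0).any():
            raise ProtocolError("protocol has no b=0 volume")
        weighted = b > 0
        norms = np.linalg.norm(g[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ProtocolError("gradient directions of weighted volumes must be unit vectors")

    @property
    def n_volumes(self) -> int:
        return len(self.b_values)

    @classmethod
    def from_fsl(cls, bval_path, bvec_path) -> "DWIProtocol":
        """Read the FSL text dialect: one row of b-values, three rows of components."""
        b = np.loadtxt(bval_path, ndmin=1).ravel()
        g = np.loadtxt(bvec_path, ndmin=2)
        if g.shape[0] == 3:
            g = g.T
        return cls(tuple(b.tolist()), tuple(map(tuple, g.tolist())))


def _design_matrix(protocol: DWIProtocol) -> np.ndarray:
    b = np.asarray(protocol.b_values, dtype=float)
    g = np.asarray(protocol.directions, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    # ln S = ln S0 - b g^T D g, D symmetric -> 6 unique elements
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def fit_md(
    dwi: np.ndarray,
    protocol: DWIProtocol,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ScalarVolume:
    """Mean diffusivity map from a log-linear least-squares tensor fit.

    Per voxel the model ln S = ln S0 - b g^T D g is solved in the least
    squares sense for the six unique tensor elements and ln S0; MD is
    trace(D)/3 in mm^2/s (with b in s/mm^2). Voxels with any non-positive or
    non-finite signal yield NaN. MD is expected to be non-negative in
    tissue; negative fitted values are reported as-is (and can be used for
    quality-control exclusion) rather than clamped.
    """
    dwi = np.asarray(dwi, dtype=np.float64)
    if dwi.ndim != 4:
        raise ProtocolError(f"expected a 4-D signal grid, got shape {dwi.shape}")
    if dwi.shape[3] != protocol.n_volumes:
        raise ProtocolError(
            f"signal has {dwi.shape[3]} volumes but protocol lists {protocol.n_volumes}"
        )
    if protocol.n_volumes < 7:
        raise ProtocolError("tensor fit needs at least 7 volumes (1 b=0 + 6 weighted)")
    X = _design_matrix(protocol)
    if np.linalg.matrix_rank(X) < 7:
        raise ProtocolError(
            "directions are collinear or insufficient: design matrix is rank-deficient"
        )
    pinv = np.linalg.pinv(X)
    flat = dwi.reshape(-1, protocol.n_volumes)
    usable = np.isfinite(flat).all(axis=1) & (flat > 0).all(axis=1)
    md = np.full(flat.shape[0], np.nan)
    if usable.any():
        coef = pinv @ np.log(flat[usable]).T  # (7, n_usable)
        md[usable] = (coef[1] + coef[2] + coef[3]) / 3.0
    return ScalarVolume(md.reshape(dwi.shape[:3]), spacing)


@dataclass(frozen=True)
class MeasureRecord:
    """One structural measurement of one region."""

    region: str
    hemisphere: str
    measure: str  # volume | t1w_t2w | md
    value: float
    units: str  # mm^3 | a.u. | mm^2/s

    def __post_init__(self) -> None:
        if self.measure == "volume" and self.value < 0:
            raise ValueError("volume cannot be negative")

    @property
    def flagged(self) -> bool:
        """True for physically suspect values (negative MD), a QC signal."""
        return self.measure == "md" and self.value < 0


def measures_to_csv(records: list[MeasureRecord], path) -> None:
    """Write measurement records as CSV (region,hemisphere,measure,value,units)."""
    pd.DataFrame(
        [
            {
                "region": r.region,
                "hemisphere": r.hemisphere,
                "measure": r.measure,
                "value": r.value,
                "units": r.units,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
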