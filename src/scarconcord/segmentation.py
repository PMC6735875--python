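"""Full-width-half-maximum (FWHM) scar segmentation of an LGE volume.

Late-gadolinium-enhanced (LGE) scar retains contrast and appears
hyper-intense. The FWHM rule normalises against the brightest myocardium:
the maximum signal intensity over the LV wall mask is computed and every
wall voxel whose intensity exceeds half of that maximum is labelled scar.
No denoising or pre-filtering is applied before taking the maximum; an
optional percentile clip is available for hyper-intense outliers but is
off by default.
"""
from __future__ import annotations

import numpy as np

from .volume import ImageVolume, LabelVolume, VolumeError


def fwhm_segment(volume: ImageVolume, wall: LabelVolume,
                 fwhm_frac: float = 0.5,
                 clip_percentile: float | None = None) -> LabelVolume:
    """Segment scar as wall voxels with intensity strictly above
    ``fwhm_frac`` times the maximum wall intensity.

    Parameters
    ----------
    volume : the LGE-like intensity image.
    wall : binary LV wall mask on the same grid.
    fwhm_frac : fraction of the wall maximum used as the cut; 0.5 is the
        classic full-width-half-maximum rule.
    clip_percentile : if given, the reference maximum is the wall-intensity
        percentile instead of the plain maximum (guards hyper-intense
        outliers). ``None`` (default) uses the plain maximum.
    """
    if not (0.0 < fwhm_frac <= 1.0):
        raise ValueError(f"fwhm_frac must be in (0, 1], got {fwhm_frac}")
    if wall.shape != volume.shape:
        raise VolumeError(f"wall shape {wall.shape} != volume shape {volume.shape}")
    in_wall = wall.data.astype(bool)
    if not in_wall.any():
        raise VolumeError("wall mask is empty: FWHM maximum undefined")
    wall_vals = volume.data[in_wall]
    if clip_percentile is None:
        ref_max = float(wall_vals.max())
    else:
        ref_max = float(np.percentile(wall_vals, clip_percentile))
    scar = np.zeros(volume.shape, dtype=np.uint8)
    scar[in_wall] = (wall_vals > fwhm_frac * ref_max).astype(np.uint8)
    return LabelVolume(scar, volume.affine)


def scar_point_cloud(scar: LabelVolume) -> np.ndarray:
    """World-mm centres of scar voxels, one point per labelled voxel.

    Voxel order is C order over indices, so output is deterministic.
    An empty mask yields an empty (0, 3) array.
    """
    idx = np.argwhere(scar.data > 0)
    if len(idx) == 0:
        return np.zeros((0, 3))
    return idx @ scar.affine[:3, :3].T + scar.affine[:3, 3]
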