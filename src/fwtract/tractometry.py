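"""Bundle-wise aggregation of scalar maps and lesion volumetrics.

Tract measures are unweighted means of a scalar map over the left and right
bundle masks, averaged bilaterally. The percent-change statistic compares a
conventional measure with its free-water-corrected counterpart. Lesion
volumetrics cover total white-matter-hyperintensity volume (normalized by
white-matter volume and log transformed) and the share of the bundle
crossed by the lesion mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["TractSummary", "WMHVolumetrics", "aggregate_tract", "percent_change", "wmh_volumetrics"]


@dataclasses.dataclass(frozen=True)
class TractSummary:
    """Side means of one scalar map over a bundle."""

    left_mean: float
    right_mean: float

    @property
    def bilateral_mean(self) -> float:
        return 0.5 * (self.left_mean + self.right_mean)


@dataclasses.dataclass(frozen=True)
class WMHVolumetrics:
    """Lesion volumetrics for one subject.

    total_wmh_ml : lesion volume in ml
    total_wmh_log : ln(lesion volume / white-matter volume + eps), with
        eps = one voxel's share of the white-matter volume so lesion-free
        subjects stay finite
    cingulum_wmh_pct : bundle-and-lesion intersection as % of bundle volume
    bundle_volume_pct_tiv : bundle volume as % of intracranial volume
    """

    total_wmh_ml: float
    total_wmh_log: float
    cingulum_wmh_pct: float
    bundle_volume_pct_tiv: float


def aggregate_tract(scalar_map: np.ndarray, left_mask: np.ndarray, right_mask: np.ndarray) -> TractSummary:
    """Unweighted in-mask means per side of a 3D scalar map.

    Raises if either mask is empty or off-grid, naming the side.
    """
    scalar_map = np.asarray(scalar_map, dtype=float)
    means = {}
    for side, mask in (("left", left_mask), ("right", right_mask)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != scalar_map.shape:
            raise ValueError(f"{side} mask is not on the map's grid")
        if not mask.any():
            raise ValueError(f"{side} bundle mask is empty")
        means[side] = float(scalar_map[mask].mean())
    return TractSummary(means["left"], means["right"])


def percent_change(conventional: float, corrected: float) -> float:
    """((corrected - conventional) / conventional) * 100."""
    if conventional == 0:
        raise ZeroDivisionError("percent change undefined for a zero conventional measure")
    return (corrected - conventional) / conventional * 100.0


def wmh_volumetrics(
    wmh_mask: np.ndarray,
    wm_mask: np.ndarray,
    bundle_mask: np.ndarray,
    icv_mask: np.ndarray,
    voxel_volume_ml: float,
) -> WMHVolumetrics:
    """Lesion volumetrics from binary masks sharing one grid."""
    wmh = np.asarray(wmh_mask, dtype=bool)
    wm = np.asarray(wm_mask, dtype=bool)
    bundle = np.asarray(bundle_mask, dtype=bool)
    icv = np.asarray(icv_mask, dtype=bool)
    if not (wmh.shape == wm.shape == bundle.shape == icv.shape):
        raise ValueError("masks must share one grid")
    n_wm = int(wm.sum())
    n_icv = int(icv.sum())
    if n_wm == 0:
        raise ValueError("white-matter mask is empty")
    if n_icv == 0:
        raise ValueError("intracranial mask is empty")
    n_wmh = int(wmh.sum())
    n_bundle = int(bundle.sum())
    if n_bundle == 0:
        raise ValueError("bundle mask is empty")

    total_ml = n_wmh * voxel_volume_ml
    eps = 1.0 / n_wm  # one voxel's share of the WM volume
    total_log = float(np.log(n_wmh / n_wm + eps))
    inter = int((bundle & wmh).sum())
    return WMHVolumetrics(
        total_wmh_ml=total_ml,
        total_wmh_log=total_log,
        cingulum_wmh_pct=100.0 * inter / n_bundle,
        bundle_volume_pct_tiv=100.0 * n_bundle / n_icv,
    )
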