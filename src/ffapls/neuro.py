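"""ROI phenotypes from voxel maps: fALFF, map standardization, ROI definition.

The three-modal ROI phenotype per subject and hemisphere is
  * FS    - face selectivity: mean faces-vs-objects contrast z over the ROI,
  * fALFF - mean (whole-brain standardized) fractional low-frequency
            amplitude over the ROI,
  * GMV   - modulated gray-matter volume summed over the ROI (voxel-volume
            scaled).
The ROI itself is the set of contiguous suprathreshold voxels of the
group-level contrast z-map inside an anatomical mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

MAP_KINDS = ("contrast_z", "falff", "gm_modulated")


@dataclass
class VoxelMaps:
    """Per-subject 3D maps of one kind on a shared grid.

    ``data`` is (subjects, i, j, k); ``mask`` a boolean anatomical mask on
    the same grid; ``voxel_size`` the edge lengths in mm.
    """

    subject_ids: list
    kind: str
    data: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        if self.kind not in MAP_KINDS:
            raise ValueError(f"map kind must be one of {MAP_KINDS}")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError("maps and mask must share the grid")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def to_nifti(self, path, subject_index: int = 0) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.data[subject_index].astype(np.float32), affine), str(path))


def compute_falff(
    timeseries: np.ndarray,
    sampling_interval: float,
    low_band: tuple[float, float] = (0.01, 0.08),
    total_band_upper: float = 0.25,
) -> float:
    """Fractional amplitude of low-frequency fluctuations.

    One-sided amplitude spectrum with DC excluded; the ratio of summed
    amplitudes in ``low_band`` over summed amplitudes in (0, total_band_upper].
    Returns NaN for a constant series (zero denominator).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 1 or len(ts) < 64:
        raise ValueError("need a 1-D series of at least 64 volumes")
    nyquist = 0.5 / sampling_interval
    if nyquist < total_band_upper:
        raise ValueError(
            f"Nyquist {nyquist:.3f} Hz below the total-band edge {total_band_upper} Hz"
        )
    amp = np.abs(np.fft.rfft(ts - ts.mean()))
    freqs = np.fft.rfftfreq(len(ts), d=sampling_interval)
    total = (freqs > 0) & (freqs <= total_band_upper)
    low = total & (freqs >= low_band[0]) & (freqs <= low_band[1])
    denom = amp[total].sum()
    if denom <= 0:
        return float("nan")
    return float(amp[low].sum() / denom)


def standardize_map(falff_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize in-mask voxels to mean 0, SD 1 (population SD).

    Out-of-mask voxels are zeroed.  Raises on fewer than 2 in-mask voxels or
    zero in-mask SD.
    """
    m = np.asarray(mask, dtype=bool)
    if m.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    vals = falff_map[m]
    sd = vals.std()
    if sd < 1e-14:
        raise ValueError("zero in-mask standard deviation")
    out = np.zeros_like(falff_map, dtype=float)
    out[m] = (vals - vals.mean()) / sd
    return out


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ROIDefinition:
    """Connected suprathreshold components, largest first.

    ``components`` is a list of (n_voxels, 3) integer index arrays in
    deterministic (size-desc, then lexicographic seed) order; ``voxels`` is
    the default ROI (the largest component, or the union if requested).
    """

    components: list[np.ndarray]
    voxels: np.ndarray
    threshold: float
    connectivity: int

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


def identify_roi(
    group_zmap: np.ndarray,
    anatomical_mask: np.ndarray,
    threshold: float = 2.58,
    connectivity: int = 26,
    roi: str = "largest",
) -> ROIDefinition:
    """Threshold + contiguity ROI definition.

    Suprathreshold (z > threshold) in-mask voxels are partitioned into
    connected components under 6/18/26-connectivity.  ``roi='largest'``
    returns the largest component as the ROI; ``roi='union'`` the union of
    all components.  No suprathreshold voxel yields an empty ROI.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive (one-tailed z)")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    supra = (group_zmap > threshold) & np.asarray(anatomical_mask, dtype=bool)
    labels, n = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    comps = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        comps.append(idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))])
    comps.sort(key=lambda c: (-len(c), tuple(c[0])))
    if not comps:
        voxels = np.empty((0, 3), dtype=int)
    elif roi == "largest":
        voxels = comps[0]
    elif roi == "union":
        voxels = np.vstack(comps)
    else:
        raise ValueError("roi must be 'largest' or 'union'")
    return ROIDefinition(components=comps, voxels=voxels,
                         threshold=threshold, connectivity=connectivity)


def _roi_values(data: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    return data[:, voxels[:, 0], voxels[:, 1], voxels[:, 2]]


def summarize_roi(
    contrast: VoxelMaps,
    falff: VoxelMaps,
    gm: VoxelMaps,
    voxels: np.ndarray,
    hemisphere: str = "right",
    standardize_falff: bool = True,
    total_brain_volume: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-subject ROI phenotype record (FS, fALFF, GMV) for one hemisphere.

    FS is the ROI mean of the contrast z-map, fALFF the ROI mean of the
    whole-brain-standardized fALFF map, GMV the ROI sum of modulated GM
    scaled by voxel volume.  If ``total_brain_volume`` is given, GMV is
    additionally residualized on it (control analysis) into ``gmv_resid``.
    """
    if len(voxels) == 0:
        raise ValueError("empty ROI")
    for vm in (falff, gm):
        if vm.data.shape != contrast.data.shape:
            raise ValueError("all modalities must share subjects and grid")
    mask = contrast.mask
    if not mask[voxels[:, 0], voxels[:, 1], voxels[:, 2]].all():
        raise ValueError("ROI extends outside the anatomical mask")
    fs = _roi_values(contrast.data, voxels).mean(axis=1)
    if standardize_falff:
        fmaps = np.stack([standardize_map(f, mask) for f in falff.data])
    else:
        fmaps = falff.data
    fa = _roi_values(fmaps, voxels).mean(axis=1)
    gmv = _roi_values(gm.data, voxels).sum(axis=1) * gm.voxel_volume
    out = pd.DataFrame(
        {"subject": contrast.subject_ids, "hemisphere": hemisphere,
         "fs": fs, "falff": fa, "gmv": gmv}
    ).set_index("subject")
    if (out["gmv"] < 0).any():
        raise ValueError("negative GMV; modulated GM maps must be nonnegative")
    if total_brain_volume is not None:
        tbv = np.asarray(total_brain_volume, dtype=float)
        X = np.column_stack([np.ones_like(tbv), tbv])
        beta, *_ = np.linalg.lstsq(X, out["gmv"].to_numpy(), rcond=None)
        out["gmv_resid"] = out["gmv"].to_numpy() - X @ beta
    return out


def split_half_measures(
    contrast: VoxelMaps,
    falff: VoxelMaps,
    gm: VoxelMaps,
    voxels: np.ndarray,
    seed: int | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Random equal (+/-1) split of ROI voxels; both halves summarized.

    Returns the two half-ROI phenotype tables and the voxel partition used
    (so the split is recorded and reproducible under a fixed seed).
    """
    if len(voxels) < 2:
        raise ValueError("need at least 2 ROI voxels to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(voxels))
    half = len(voxels) // 2
    v1, v2 = voxels[np.sort(perm[:half])], voxels[np.sort(perm[half:])]
    t1 = summarize_roi(contrast, falff, gm, v1, **kwargs)
    t2 = summarize_roi(contrast, falff, gm, v2, **kwargs)
    return t1, t2, (v1, v2)
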