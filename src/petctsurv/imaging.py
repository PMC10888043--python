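"""Volume I/O and intensity preprocessing for PET/CT survival modelling.

Volumes are carried as ``(z, y, x)`` arrays with millimetre spacing. The
intensity pipeline is deliberately simple: two-sided winsorization at
empirical quantiles (default 0.1% lower, 10% upper — i.e. clip at the 0.001
and 0.90 quantiles) to suppress noise spikes and spurious signal, followed by
an affine map to [0, 1]. Model inputs are square 2-D axial slices resampled
to a fixed side length.

PET is assumed already co-registered and resampled to the CT grid; masks must
share that grid. Registration, DICOM handling and SUV conversion are out of
scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np
from skimage.transform import resize

__all__ = [
    "ImageVolume",
    "PreprocessConfig",
    "ModelInput",
    "read_volume",
    "write_volume",
    "bandpass_normalize",
    "volume_to_input",
    "cache_inputs",
    "load_cached_inputs",
]

MODALITIES = ("PET", "CT")


@dataclass
class ImageVolume:
    """One modality's voxel grid.

    voxels : (z, y, x) float array in native intensity units
    spacing_mm : voxel spacing (z, y, x), all positive
    modality : "PET" or "CT"
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"non-3-D volume: ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("empty volume")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")


@dataclass
class PreprocessConfig:
    """Winsorization tails and model input size.

    lower_tail, upper_tail : fractions of mass clipped at the bottom / top of
        the intensity distribution (defaults 0.001 and 0.10)
    input_side : side length of the square model input
    """

    lower_tail: float = 0.001
    upper_tail: float = 0.10
    input_side: int = 224

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_tail < 1.0 - self.upper_tail <= 1.0):
            raise ValueError(
                f"need 0 <= lower_tail < 1 - upper_tail <= 1, got "
                f"({self.lower_tail}, {self.upper_tail})"
            )
        if self.input_side < 1:
            raise ValueError("input_side must be positive")


@dataclass
class ModelInput:
    plane: np.ndarray  # (input_side, input_side), values in [0, 1]
    modality: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.plane = np.asarray(self.plane, dtype=np.float64)
        if self.plane.ndim != 2 or self.plane.shape[0] != self.plane.shape[1]:
            raise ValueError(f"plane must be square 2-D, got {self.plane.shape}")
        if self.plane.min() < -1e-9 or self.plane.max() > 1 + 1e-9:
            raise ValueError("plane values outside [0, 1]")


def read_volume(path: str | os.PathLike, modality: str | None = None,
                subject_id: str = "") -> ImageVolume:
    """Read a NIfTI volume into canonical (z, y, x) order.

    NIfTI stores (x, y, z); axes are transposed on load. ``modality`` may be
    omitted if the filename contains a recognizable tag (``_pet``/``_ct``).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3-D image: ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if modality is None:
        stem = os.path.basename(str(path)).lower()
        for tag in MODALITIES:
            if tag.lower() in stem:
                modality = tag
                break
        else:
            raise ValueError("modality not given and not inferable from filename")
    return ImageVolume(
        voxels=np.transpose(data, (2, 1, 0)),
        spacing_mm=(zooms[2], zooms[1], zooms[0]),
        modality=modality,
        subject_id=subject_id or os.path.basename(str(path)).split(".")[0],
    )


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write an ImageVolume as NIfTI (inverse of :func:`read_volume`)."""
    data = np.transpose(vol.voxels, (2, 1, 0))
    affine = np.diag([vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0]))
    nib.save(img, str(path))


def bandpass_normalize(vol: ImageVolume, cfg: PreprocessConfig | None = None) -> ImageVolume:
    """Winsorize intensity tails, then map affinely to [0, 1].

    Values below the ``lower_tail`` quantile are raised to it; values above
    the ``1 - upper_tail`` quantile are lowered to it. The cut points use the
    'lower'/'higher' order-statistic conventions (rather than interpolated
    quantiles), which makes the whole operation exactly idempotent: applying
    it twice with the same configuration changes nothing. The clipped range
    is then rescaled so min = 0 and max = 1.
    """
    cfg = cfg or PreprocessConfig()
    x = vol.voxels
    if np.isnan(x).any():
        raise ValueError("NaN voxels; clean the volume before preprocessing")
    lo = np.quantile(x, cfg.lower_tail, method="lower")
    hi = np.quantile(x, 1.0 - cfg.upper_tail, method="higher")
    clipped = np.clip(x, lo, hi)
    span = clipped.max() - clipped.min()
    if span <= 0:
        raise ValueError("constant image: zero dynamic range after clipping")
    out = (clipped - clipped.min()) / span
    return ImageVolume(out, vol.spacing_mm, vol.modality, vol.subject_id)


def _central_square(plane: np.ndarray) -> np.ndarray:
    """Center-crop or zero-pad a 2-D array to square."""
    h, w = plane.shape
    side = max(h, w)
    padded = np.zeros((side, side), dtype=plane.dtype)
    oy, ox = (side - h) // 2, (side - w) // 2
    padded[oy:oy + h, ox:ox + w] = plane
    if h == w:
        return plane
    return padded


def volume_to_input(vol: ImageVolume, mask: ImageVolume | None = None,
                    cfg: PreprocessConfig | None = None) -> ModelInput:
    """Reduce a preprocessed 3-D volume to a fixed-size 2-D model input.

    Slice selection: the axial slice with the largest in-mask area when a
    mask is given, else the central axial slice. The slice is squared by
    center crop/pad, bilinearly resampled to ``input_side``, and clamped to
    [0, 1].
    """
    cfg = cfg or PreprocessConfig()
    if mask is not None:
        if mask.voxels.shape != vol.voxels.shape:
            raise ValueError("mask grid does not match volume grid")
        areas = (mask.voxels > 0).sum(axis=(1, 2))
        if areas.sum() == 0:
            raise ValueError("empty mask")
        z = int(np.argmax(areas))
    else:
        z = vol.voxels.shape[0] // 2
    plane = _central_square(vol.voxels[z])
    if plane.shape[0] != cfg.input_side:
        plane = resize(plane, (cfg.input_side, cfg.input_side), order=1,
                       mode="edge", anti_aliasing=False, preserve_range=True)
    plane = np.clip(plane, 0.0, 1.0)
    return ModelInput(plane=plane, modality=vol.modality, subject_id=vol.subject_id)


def cache_inputs(inputs: list[ModelInput], path: str | os.PathLike) -> None:
    """Cache processed model inputs as HDF5, dataset names <subject>/<modality>."""
    with h5py.File(path, "w") as f:
        for m in inputs:
            f.create_dataset(f"{m.subject_id}/{m.modality}", data=m.plane)


def load_cached_inputs(path: str | os.PathLike) -> list[ModelInput]:
    out: list[ModelInput] = []
    with h5py.File(path, "r") as f:
        for sid in f:
            for mod in f[sid]:
                out.append(ModelInput(plane=f[sid][mod][()], modality=mod,
                                      subject_id=sid))
    return out
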