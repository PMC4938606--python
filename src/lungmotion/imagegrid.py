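"""Voxel-grid containers, mask I/O, thresholding, morphology and overlap metrics.

Axis convention (fixed for the whole package, supine subject):
``x`` = left-right (LR), ``y`` = anterior-posterior (AP, +y anterior),
``z`` = cranial-caudal (CC, +z cranial).  All "most posterior/superior"
predicates elsewhere in the package are defined against these axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Two grids that must share shape/spacing/origin do not."""


@dataclass
class VoxelGrid:
    """A 3D scalar image with physical spacing and origin (mm).

    ``data[i, j, k]`` sits at physical position ``origin + (i, j, k) * spacing``
    with axis 0 = x (LR), axis 1 = y (AP, +anterior), axis 2 = z (CC, +cranial).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "VoxelGrid") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) physical coordinates of all voxel centers (C order)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class BinaryMask(VoxelGrid):
    """A VoxelGrid whose data is boolean foreground/background."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume()


@dataclass
class DynamicSequence:
    """An ordered series of T voxel grids on a common grid.

    Frame 1 (index 0) is full inspiration, frame T (index -1) full expiration.
    """

    frames: list = field(default_factory=list)
    frame_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a dynamic sequence needs T >= 2 frames")
        first = self.frames[0]
        for f in self.frames[1:]:
            first.require_same_grid(f)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> VoxelGrid:
        return self.frames[i]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> VoxelGrid:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return VoxelGrid(np.asarray(data), tuple(float(z) for z in zooms), tuple(float(o) for o in origin))


def _read_metaimage(path: Path) -> VoxelGrid:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D image")
    # SimpleITK arrays come back (z, y, x); transpose to our (x, y, z) layout.
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelGrid(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def read_volume(path) -> VoxelGrid:
    """Read a 3D intensity volume (NIfTI ``.nii/.nii.gz`` or MetaImage ``.mha/.mhd``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mha", ".mhd")):
        return _read_metaimage(path)
    return _read_nifti(path)


def read_mask(path) -> BinaryMask:
    """Read a binary mask; non-binary data is thresholded at 0.5 with a warning."""
    grid = read_volume(path)
    data = np.asarray(grid.data)
    values = np.unique(data)
    if not np.all(np.isin(values, (0, 1))):
        warnings.warn(f"{path}: data is not binary; thresholding at 0.5", stacklevel=2)
        data = data > 0.5
    return BinaryMask(data.astype(bool), grid.spacing, grid.origin)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as unsigned 8-bit NIfTI or MetaImage, by extension."""
    path = Path(path)
    data = mask.data.astype(np.uint8)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
        img.SetSpacing(mask.spacing)
        img.SetOrigin(mask.origin)
        sitk.WriteImage(img, str(path))
    else:
        import nibabel as nib

        affine = np.diag(list(mask.spacing) + [1.0])
        affine[:3, 3] = mask.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Thresholding and masking
# ---------------------------------------------------------------------------

def otsu_threshold(volume: VoxelGrid, nbins: int = 256) -> BinaryMask:
    """Foreground = voxels above the Otsu cut.

    The cut maximizes the between-class variance over an ``nbins``-bin
    histogram spanning [min, max]; ties break toward the lower threshold.
    """
    data = np.asarray(volume.data, dtype=float)
    if np.ptp(data) == 0:
        raise ValueError("constant volume: no Otsu threshold exists")
    from skimage.filters import threshold_otsu

    cut = threshold_otsu(data, nbins=nbins)
    return BinaryMask(data > cut, volume.spacing, volume.origin)


def build_body_mask(volume: VoxelGrid, exclude: Optional[BinaryMask] = None,
                    nbins: int = 256) -> BinaryMask:
    """Bright-tissue (body) mask: Otsu foreground minus an optional exclusion.

    The exclusion is typically a lung segmentation, so the returned mask
    covers the body but none of the air-filled regions used to estimate an
    intensity bias field.
    """
    mask = otsu_threshold(volume, nbins=nbins)
    if exclude is not None:
        volume.require_same_grid(exclude)
        out = mask.data & ~exclude.data
        if not out.any():
            warnings.warn("body mask is empty after exclusion", stacklevel=2)
        return BinaryMask(out, volume.spacing, volume.origin)
    return mask


BiasCorrector = Callable[[VoxelGrid, BinaryMask], VoxelGrid]


def iterative_bias_correction(
    volume: VoxelGrid,
    corrector: BiasCorrector,
    n_iter: int = 3,
    exclude: Optional[BinaryMask] = None,
    nbins: int = 256,
) -> tuple[VoxelGrid, BinaryMask]:
    """Drive a pluggable bias corrector with iteratively refined body masks.

    Each iteration thresholds the *current* corrected image to get a body
    mask (minus ``exclude``), then applies the corrector to the *original*
    image using that newest mask.  Three iterations are the default; the
    corrector contract is ``corrector(original_volume, mask) -> VoxelGrid``.

    Returns ``(corrected_volume, final_mask)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    current = volume
    mask: Optional[BinaryMask] = None
    for i in range(1, n_iter + 1):
        try:
            mask = build_body_mask(current, exclude=exclude, nbins=nbins)
        except ValueError as exc:
            raise ValueError(f"mask construction failed at iteration {i}: {exc}") from exc
        if mask.count == 0:
            raise ValueError(f"empty body mask at iteration {i}")
        try:
            current = corrector(volume, mask)
        except Exception as exc:  # noqa: BLE001 - annotate with iteration index
            raise RuntimeError(f"bias corrector failed at iteration {i}: {exc}") from exc
    assert mask is not None
    return current, mask


def polynomial_bias_corrector(order: int = 2) -> BiasCorrector:
    """A simple multiplicative-bias corrector: least-squares polynomial fit
    to log-intensities inside the mask, divided out everywhere.

    This is the package's lightweight reference corrector; an N4 backend
    (SimpleITK) can be plugged in through the same contract.
    """

    def correct(volume: VoxelGrid, mask: BinaryMask) -> VoxelGrid:
        data = np.asarray(volume.data, dtype=float)
        pos = data > 0
        fit_at = mask.data & pos
        if fit_at.sum() < 10:
            raise ValueError("too few positive voxels inside mask for bias fit")
        coords = np.indices(data.shape, dtype=float)
        coords = [(c - c.mean()) / max(c.std(), 1e-12) for c in coords]
        terms = [np.ones_like(data)]
        for px in range(order + 1):
            for py in range(order + 1 - px):
                for pz in range(order + 1 - px - py):
                    if px == py == pz == 0:
                        continue
                    terms.append(coords[0] ** px * coords[1] ** py * coords[2] ** pz)
        A = np.stack([t[fit_at] for t in terms], axis=1)
        b = np.log(data[fit_at])
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        log_bias = sum(c * t for c, t in zip(coef, terms))
        log_bias = log_bias - log_bias[fit_at].mean()  # preserve mean intensity
        corrected = np.where(pos, data / np.exp(log_bias), data)
        return VoxelGrid(corrected, volume.spacing, volume.origin)

    return correct


def n4_bias_corrector(
    spline_distance_mm: float = 100.0,
    fitting_levels: int = 2,
    max_iterations: int = 500,
) -> BiasCorrector:
    """N4 inhomogeneity-correction backend via SimpleITK (optional).

    Defaults follow the driver's intended MRI use: 100 mm initial control
    point spacing and two fitting levels of up to 500 iterations each.
    """

    def correct(volume: VoxelGrid, mask: BinaryMask) -> VoxelGrid:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(volume.data, float).transpose(2, 1, 0))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        msk = sitk.GetImageFromArray(mask.data.astype(np.uint8).transpose(2, 1, 0))
        msk.CopyInformation(img)
        n4 = sitk.N4BiasFieldCorrectionImageFilter()
        n4.SetMaximumNumberOfIterations([max_iterations] * fitting_levels)
        extent = max(s * n for s, n in zip(volume.spacing, volume.shape))
        n4.SetNumberOfControlPoints([max(4, int(np.ceil(extent / spline_distance_mm)) + 3)] * 3)
        out = n4.Execute(img, msk)
        return VoxelGrid(sitk.GetArrayFromImage(out).transpose(2, 1, 0), volume.spacing, volume.origin)

    return correct


# ---------------------------------------------------------------------------
# Morphology and overlap
# ---------------------------------------------------------------------------

def _ball_structuring_element(radius_mm: float, spacing: Sequence[float]) -> np.ndarray:
    r = np.asarray([int(np.floor(radius_mm / s)) for s in spacing])
    grids = np.indices(2 * r + 1).astype(float)
    for ax in range(3):
        grids[ax] = (grids[ax] - r[ax]) * spacing[ax]
    dist2 = (grids ** 2).sum(axis=0)
    return dist2 <= radius_mm ** 2 + 1e-9


def dilate_mask(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Morphological dilation with a physical-space ball of the given radius."""
    if radius_mm < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius_mm == 0:
        return BinaryMask(mask.data.copy(), mask.spacing, mask.origin)
    selem = _ball_structuring_element(radius_mm, mask.spacing)
    out = ndimage.binary_dilation(mask.data, structure=selem)
    return BinaryMask(out, mask.spacing, mask.origin)


def union_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    a.require_same_grid(b)
    return BinaryMask(a.data | b.data, a.spacing, a.origin)


def registration_mask(a: BinaryMask, b: BinaryMask, dilation_mm: float = 50.0) -> BinaryMask:
    """Union of first/last-frame lung masks, dilated (default 50 mm), used to
    restrict intensity-based registration to the lungs and their surroundings."""
    return dilate_mask(union_masks(a, b), dilation_mm)


def dice_overlap(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); both-empty convention = 1."""
    a.require_same_grid(b)
    na, nb = a.count, b.count
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
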