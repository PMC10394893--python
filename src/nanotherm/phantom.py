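"""Voxel phantoms of a tumor-bearing body with a nanoparticle volume-fraction map.

The phantom stands in for the imaging pipeline of an in-vivo study
(MRI -> manual segmentation -> surface meshes): a labelled, isotropic
voxel grid with codes for outside air, normal tissue, tumor and the
nanohybrid-loaded subregion, plus a per-voxel nanoparticle volume
fraction ``f_V``.  Coordinates are cell-centred, 0-based, axis order
(x, y, z); positions are in millimetres via ``origin + index * spacing``.

Three administration scenarios are generated:

* ``laser_only`` — f_V = 0 everywhere;
* ``IP``   — systemic (intraperitoneal) delivery: a small uniform f_V
  (default 5e-9) over the whole tumor;
* ``IT``   — direct intratumoral injection: a large f_V (default 1e-7)
  over a seeded, compact, irregular blob occupying a configurable
  fraction of the tumor, emulating the hypointense pool seen on
  T2-weighted MRI after injection.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "Label",
    "Phantom",
    "ProbeSet",
    "make_phantom",
    "import_masks",
    "surface_extract",
    "surface_area_mm2",
    "ellipsoid_area_thomsen",
    "export_stl",
    "default_probes",
    "F_V_IT",
    "F_V_IP",
]

log = logging.getLogger(__name__)

#: Nanohybrid volume fractions used in the treatment simulations
F_V_IT = 1.0e-7  # intratumoral injection
F_V_IP = 5.0e-9  # intraperitoneal (systemic) accumulation

SCENARIOS = ("laser_only", "IP", "IT")


class GeometryError(ValueError):
    pass


class Label(IntEnum):
    OUTSIDE = 0
    TISSUE = 1
    TUMOR = 2
    NANOHYBRID = 3  # nanohybrid-loaded tumor subregion


@dataclass
class Phantom:
    """Labelled voxel grid with nanoparticle volume-fraction map."""

    labels: np.ndarray  # int8, shape (nx, ny, nz)
    spacing_mm: float
    origin_mm: np.ndarray  # (3,) position of voxel (0,0,0) centre
    f_v: np.ndarray  # float64, same shape

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.f_v = np.asarray(self.f_v, dtype=np.float64)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.spacing_mm <= 0:
            raise GeometryError("spacing must be positive")
        if self.labels.shape != self.f_v.shape:
            raise GeometryError("labels and f_v must share a shape")
        if not np.isin(self.labels, [l.value for l in Label]).all():
            raise GeometryError("labels outside the fixed enumeration")
        if np.any(self.f_v[self.labels != Label.NANOHYBRID] != 0):
            raise GeometryError("f_V support must equal the nanohybrid label support")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels > Label.OUTSIDE

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels >= Label.TUMOR

    @property
    def nanohybrid_mask(self) -> np.ndarray:
        return self.labels == Label.NANOHYBRID

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points_mm) - self.origin_mm) / self.spacing_mm

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.atleast_2d(idx) * self.spacing_mm

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> dict:
        """Write labels and f_V as NIfTI volumes; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "labels": directory / "labels.nii.gz",
            "f_v": directory / "f_v.nii.gz",
        }
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), paths["labels"])
        nib.save(nib.Nifti1Image(self.f_v.astype(np.float64), self.affine), paths["f_v"])
        return paths

    @classmethod
    def load(cls, directory: str | Path) -> "Phantom":
        directory = Path(directory)
        lab_img = nib.load(directory / "labels.nii.gz")
        fv_img = nib.load(directory / "f_v.nii.gz")
        aff = lab_img.affine
        spacing = float(aff[0, 0])
        return cls(
            labels=np.asarray(lab_img.dataobj).astype(np.int8),
            spacing_mm=spacing,
            origin_mm=aff[:3, 3].copy(),
            f_v=np.asarray(fv_img.dataobj, dtype=np.float64),
        )


@dataclass(frozen=True)
class ProbeSet:
    """Named probe points in mm; ``c`` is the surface/validation point."""

    points_mm: dict

    def __getitem__(self, name: str) -> np.ndarray:
        return np.asarray(self.points_mm[name], dtype=float)

    def names(self):
        return list(self.points_mm)


def _ellipsoid_mask(shape, origin, spacing, center, semiaxes):
    idx = np.indices(shape, dtype=float)
    coords = [origin[i] + idx[i] * spacing for i in range(3)]
    s = sum(((coords[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return s <= 1.0


def make_phantom(
    body_semiaxes_mm=(10.0, 10.0, 14.0),
    tumor_center_mm=(0.0, 8.0, 0.0),
    tumor_semiaxes_mm=(4.0, 4.0, 4.0),
    scenario: str = "IT",
    spacing_mm: float = 0.5,
    seed: int = 0,
    shape=(64, 64, 64),
    body_center_mm=(0.0, 0.0, 0.0),
    blob_fraction: float = 0.3,
    blob_offset: float = 0.5,
    blob_axis: int = 1,
    blob_sign: int = 1,
    f_v_it: float = F_V_IT,
    f_v_ip: float = F_V_IP,
) -> Phantom:
    """Synthetic ellipsoid-body / ellipsoid-tumor phantom.

    The default geometry is a desk-scale stand-in for a mouse flank: a
    10 x 10 x 14 mm semi-axis body ellipsoid with a 4-mm-semiaxis subcutaneous
    tumor bulging from the +y surface.  For the IT scenario a compact
    irregular blob of ``blob_fraction`` of the tumor volume, flood-grown
    with seeded jitter from the injection point, carries ``f_v_it``.

    The injection point models the needle tip of a direct intratumoral
    injection performed through the skin over the tumor: it lies on the
    line from the tumor centroid to the beam-side apex (``blob_axis``,
    ``blob_sign``), a fraction ``blob_offset`` of the way up (0 = centre,
    1 = apex; default halfway).  The growth order is randomised by
    ``seed`` so the pool is irregular, but its anchor is anatomical, not
    random: the headline surface temperature would otherwise fluctuate
    strongly with the draw of the injection site.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    body_semiaxes = np.asarray(body_semiaxes_mm, float)
    tumor_semiaxes = np.asarray(tumor_semiaxes_mm, float)
    if np.any(body_semiaxes <= 0) or np.any(tumor_semiaxes <= 0):
        raise GeometryError("degenerate (non-positive) ellipsoid axes")
    if np.any(2 * tumor_semiaxes / spacing_mm < 8):
        raise GeometryError("spacing too coarse: tumor must span >= 8 voxels per axis")

    shape = tuple(int(n) for n in shape)
    origin = np.asarray(body_center_mm, float) - spacing_mm * (np.asarray(shape) - 1) / 2.0

    body = _ellipsoid_mask(shape, origin, spacing_mm, np.asarray(body_center_mm, float), body_semiaxes)
    tumor = _ellipsoid_mask(shape, origin, spacing_mm, np.asarray(tumor_center_mm, float), tumor_semiaxes)
    if not np.any(body & tumor):
        raise GeometryError("tumor ellipsoid does not intersect the body")

    labels = np.zeros(shape, dtype=np.int8)
    labels[body] = Label.TISSUE
    labels[tumor] = Label.TUMOR  # tumor treated as part of the body even where it bulges

    f_v = np.zeros(shape, dtype=np.float64)
    if scenario == "IP":
        labels[tumor] = Label.NANOHYBRID
        f_v[tumor] = f_v_ip
    elif scenario == "IT":
        start = _injection_point(tumor, blob_offset, blob_axis, blob_sign)
        blob = _grow_blob(tumor, blob_fraction, seed, start)
        labels[blob] = Label.NANOHYBRID
        f_v[blob] = f_v_it
    return Phantom(labels=labels, spacing_mm=spacing_mm, origin_mm=origin, f_v=f_v)


def _injection_point(tumor: np.ndarray, offset: float, axis: int, sign: int) -> tuple:
    """Needle-tip voxel on the centroid-to-apex line of the tumor."""
    if not 0.0 <= offset <= 1.0:
        raise ValueError("blob_offset must be in [0, 1]")
    cen = np.argwhere(tumor).mean(axis=0)
    line = np.round(cen).astype(int)
    sel = [int(line[a]) for a in range(3)]
    sel[axis] = slice(None)
    along = np.argwhere(tumor[tuple(sel)]).ravel()
    if along.size == 0:
        return tuple(line)
    apex = line.copy()
    apex[axis] = along.max() if sign > 0 else along.min()
    tip = np.round(cen + offset * (apex - cen)).astype(int)
    if not tumor[tuple(tip)]:  # numerical rounding pushed it out; fall back
        tip = line
    return tuple(tip)


def _grow_blob(tumor: np.ndarray, fraction: float, seed: int, start: tuple, jitter: float = 0.6) -> np.ndarray:
    """Seeded compact irregular subregion of the tumor.

    A 6-connected flood fill ordered by jittered distance from the start
    voxel grows until ``fraction`` of the tumor voxels is covered,
    emulating the irregular pool of injected nanofluid.
    """
    if not 0 < fraction <= 1:
        raise ValueError("blob fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_target = max(1, int(round(fraction * tumor.sum())))
    shape = tumor.shape
    blob = np.zeros(shape, dtype=bool)
    visited = np.zeros(shape, dtype=bool)
    heap = [(0.0, start)]
    visited[start] = True
    count = 0
    while heap and count < n_target:
        _, vox = heapq.heappop(heap)
        blob[vox] = True
        count += 1
        for ax in range(3):
            for d in (-1, 1):
                nb = list(vox)
                nb[ax] += d
                nb = tuple(nb)
                if not (0 <= nb[ax] < shape[ax]) or visited[nb] or not tumor[nb]:
                    continue
                visited[nb] = True
                r = np.linalg.norm(np.subtract(nb, start))
                heapq.heappush(heap, (r * (1.0 + jitter * rng.random()), nb))
    return blob


def import_masks(
    body_mask_path,
    tumor_mask_path,
    nanohybrid_mask_path=None,
    f_v_value: float = F_V_IT,
) -> Phantom:
    """Compose a phantom from binary NIfTI masks (precedence nanohybrid > tumor > body).

    Nanohybrid voxels outside the tumor mask are dropped with a warning,
    mirroring how a hypointense-volume segmentation is clipped to the
    tumor contour.
    """
    imgs = [nib.load(body_mask_path), nib.load(tumor_mask_path)]
    if nanohybrid_mask_path is not None:
        imgs.append(nib.load(nanohybrid_mask_path))
    shape0, aff0 = imgs[0].shape, imgs[0].affine
    for img in imgs[1:]:
        if img.shape != shape0 or not np.allclose(img.affine, aff0):
            raise GeometryError("masks must share shape and affine")
    arrays = []
    for img in imgs:
        arr = np.asarray(img.dataobj)
        vals = np.unique(arr)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("masks must be binary (0/1)")
        arrays.append(arr.astype(bool))
    body, tumor = arrays[0], arrays[1]
    labels = np.zeros(shape0, dtype=np.int8)
    labels[body] = Label.TISSUE
    labels[tumor] = Label.TUMOR
    f_v = np.zeros(shape0, dtype=np.float64)
    if len(arrays) == 3:
        nano = arrays[2]
        outside = nano & ~tumor
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} nanohybrid voxels outside the tumor mask were dropped"
            )
            log.warning("dropped %d nanohybrid voxels outside the tumor", int(outside.sum()))
        nano = nano & tumor
        labels[nano] = Label.NANOHYBRID
        f_v[nano] = f_v_value
    spacing = float(aff0[0, 0])
    return Phantom(labels=labels, spacing_mm=spacing, origin_mm=aff0[:3, 3].copy(), f_v=f_v)


def surface_extract(phantom: Phantom):
    """6-connected boundary voxels of the body with unit outward normals.

    Returns ``(indices, normals)``: ``indices`` is (N, 3) int voxel
    indices, ``normals`` (N, 3) unit vectors (the normalised sum of the
    exposed-face directions; for a voxel whose exposed faces cancel, the
    first exposed direction is used).
    """
    body = phantom.body_mask
    if not body.any():
        raise GeometryError("empty body")
    normals_sum = np.zeros(body.shape + (3,), dtype=float)
    exposed_any = np.zeros(body.shape, dtype=bool)
    first_dir = np.zeros(body.shape + (3,), dtype=float)
    for ax in range(3):
        for d in (-1, 1):
            nb_outside = ~np.roll(body, -d, axis=ax)
            # rolling past the array edge counts as outside
            edge = [slice(None)] * 3
            edge[ax] = -1 if d == 1 else 0
            nb_outside[tuple(edge)] = True
            exposed = body & nb_outside
            vec = np.zeros(3)
            vec[ax] = d
            normals_sum[exposed] += vec
            newly = exposed & ~exposed_any
            first_dir[newly] = vec
            exposed_any |= exposed
    idx = np.argwhere(exposed_any)
    n = normals_sum[exposed_any]
    norm = np.linalg.norm(n, axis=1)
    zero = norm == 0
    n[zero] = first_dir[exposed_any][zero]
    norm[zero] = 1.0
    return idx, n / norm[:, None]


def surface_area_mm2(phantom: Phantom, mask: np.ndarray | None = None, sigma_vox: float = 1.0) -> float:
    """Surface area of a label mask via marching cubes on a smoothed field."""
    mask = phantom.body_mask if mask is None else mask
    if not mask.any():
        raise GeometryError("empty mask")
    fld = ndimage.gaussian_filter(mask.astype(float), sigma_vox, mode="constant")
    verts, faces, _, _ = measure.marching_cubes(
        fld, level=0.5, spacing=(phantom.spacing_mm,) * 3
    )
    return float(measure.mesh_surface_area(verts, faces))


def ellipsoid_area_thomsen(a: float, b: float, c: float, p: float = 1.6075) -> float:
    """Thomsen's approximation of the ellipsoid surface area (error < 1.1%)."""
    return 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def export_stl(phantom: Phantom, path, mask: np.ndarray | None = None, sigma_vox: float = 1.0):
    """Export a label isosurface as STL for visual inspection."""
    import trimesh

    mask = phantom.body_mask if mask is None else mask
    fld = ndimage.gaussian_filter(mask.astype(float), sigma_vox, mode="constant")
    verts, faces, _, _ = measure.marching_cubes(fld, level=0.5, spacing=(phantom.spacing_mm,) * 3)
    verts = verts + phantom.origin_mm
    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(path)


def default_probes(phantom: Phantom, beam_axis: int = 1, beam_dir: int = -1) -> ProbeSet:
    """Default probe triple: c = body-surface apex on the beam ray through
    the tumor centroid, b = tumor centroid, a = lateral tumor margin."""
    tumor = phantom.tumor_mask
    if not tumor.any():
        tumor = phantom.body_mask
    centroid_vox = np.argwhere(tumor).mean(axis=0)
    b_mm = phantom.voxel_to_mm(centroid_vox)[0]

    # march along the beam axis from the incoming side to the first body voxel
    body = phantom.body_mask
    line_idx = np.round(centroid_vox).astype(int)
    n_ax = phantom.shape[beam_axis]
    order = range(n_ax - 1, -1, -1) if beam_dir < 0 else range(n_ax)
    c_vox = None
    for i in order:
        probe = line_idx.copy()
        probe[beam_axis] = i
        if body[tuple(probe)]:
            c_vox = probe
            break
    if c_vox is None:
        raise GeometryError("beam ray through tumor centroid misses the body")
    c_mm = phantom.voxel_to_mm(c_vox)[0]

    # lateral margin: last tumor voxel along +x from the centroid
    a_vox = line_idx.copy()
    lateral_ax = 0 if beam_axis != 0 else 2
    i = int(round(centroid_vox[lateral_ax]))
    while True:
        nxt = a_vox.copy()
        nxt[lateral_ax] = i + 1
        if i + 1 >= phantom.shape[lateral_ax] or not tumor[tuple(nxt)]:
            break
        i += 1
        a_vox = nxt
    a_mm = phantom.voxel_to_mm(a_vox)[0]
    return ProbeSet({"a": a_mm, "b": b_mm, "c": c_mm})
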