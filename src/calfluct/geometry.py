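"""Voxelized synapse-environment geometry and morphometrics.

This module represents a cube of neuropil as a 3D grid of compartment
labels (extracellular space, astrocyte, presynaptic bouton, postsynaptic
spine, dendritic shaft, other neuropil) at anisotropic voxel pitch, and
computes the geometric quantities the downstream simulation depends on:

* the fixation-shrinkage correction that relabels a thin shell of every
  cellular segment as extracellular space (ECS),
* compartment volume fractions,
* the astrocytic surface area, volume, and surface/volume ratio (SVR),
* astrocytic coverage of the pre- and postsynaptic membranes, and
* the five-criterion filter that selects "classical" single excitatory
  spine synapses for simulation.

Conventions
-----------
Surfaces are defined by face adjacency (6-connectivity).  Faces on the
boundary of the sample cube are *not* counted as surface: the process is
assumed to continue outside the sampled volume.  SVR is defined
physically as exposed face area divided by segment volume, using the
anisotropic face areas, which yields 1/µm directly and is independent of
voxel pitch for resolved structures.

Voxel indices are 0-based; the physical position of voxel ``(0, 0, 0)``
spans ``origin_nm + [0, pitch)`` on each axis (half-open extents).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ROLES",
    "LabelVolume",
    "SynapseRecord",
    "MorphometricsRecord",
    "apply_ecs_correction",
    "compartment_fractions",
    "astro_surface_area_volume",
    "surface_face_masks",
    "synaptic_coverage",
    "select_synapses",
    "morphometrics",
    "morphometrics_table",
    "load_vast_export",
]

#: Recognised compartment roles.
ROLES = ("ecs", "astro", "bouton", "spine", "dendrite", "other")

#: Default voxel pitch in nm (in-plane x/y, section thickness z).
DEFAULT_PITCH_NM = (6.0, 6.0, 30.0)

#: Default grid dimensions of a sampled synapse environment.
DEFAULT_SHAPE = (201, 201, 41)


class EmptySegmentError(ValueError):
    """Raised when an operation requires a compartment that has no voxels."""


@dataclass
class LabelVolume:
    """A 3D compartment-labelled voxel grid with anisotropic physical pitch.

    Parameters
    ----------
    labels
        Integer array of shape ``(nx, ny, nz)``; one compartment id per voxel.
    pitch_nm
        Voxel pitch ``(dx, dy, dz)`` in nm.  Default 6 x 6 x 30 nm.
    label_map
        Mapping of compartment id to role.  Roles must be drawn from
        :data:`ROLES`; an ECS id must exist.  Several ids may share the
        role ``"other"`` (distinct neuropil segments).
    origin_nm
        Physical coordinate of the corner of voxel ``(0, 0, 0)``.
    """

    labels: np.ndarray
    pitch_nm: tuple[float, float, float] = DEFAULT_PITCH_NM
    label_map: dict[int, str] = field(default_factory=lambda: {0: "ecs", 1: "astro"})
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be a 3D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.pitch_nm = tuple(float(p) for p in self.pitch_nm)
        if any(p <= 0 for p in self.pitch_nm):
            raise ValueError(f"pitch components must be positive, got {self.pitch_nm}")
        self.label_map = {int(k): str(v) for k, v in self.label_map.items()}
        bad_roles = set(self.label_map.values()) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles in label_map: {sorted(bad_roles)}")
        if "ecs" not in self.label_map.values():
            raise ValueError("label_map must contain an ECS id")
        used = set(np.unique(self.labels).tolist())
        unmapped = used - set(self.label_map)
        if unmapped:
            raise ValueError(f"labels contain ids missing from label_map: {sorted(unmapped)}")
        self.origin_nm = tuple(float(o) for o in self.origin_nm)

    # -- basic properties -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_nm3(self) -> float:
        dx, dy, dz = self.pitch_nm
        return dx * dy * dz

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical size of the sample cube along each axis."""
        return tuple(n * p for n, p in zip(self.shape, self.pitch_nm))

    @property
    def ecs_id(self) -> int:
        return min(i for i, r in self.label_map.items() if r == "ecs")

    def ids_for_role(self, role: str) -> list[int]:
        return [i for i, r in self.label_map.items() if r == role]

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of all voxels whose label maps to *role*."""
        ids = self.ids_for_role(role)
        if not ids:
            return np.zeros(self.shape, dtype=bool)
        if len(ids) == 1:
            return self.labels == ids[0]
        return np.isin(self.labels, ids)

    def role_fraction(self, role: str) -> float:
        return float(self.mask(role).sum()) / self.labels.size

    def position_to_index(self, points_nm: np.ndarray) -> np.ndarray:
        """Map physical positions (nm) to voxel indices (may be out of range)."""
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        rel = (pts - np.asarray(self.origin_nm)) / np.asarray(self.pitch_nm)
        return np.floor(rel).astype(np.int64)

    def contains(self, points_nm: np.ndarray) -> np.ndarray:
        """Whether physical positions fall inside the sample cube."""
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        lo = np.asarray(self.origin_nm)
        hi = lo + np.asarray(self.extent_nm)
        return np.all((pts >= lo) & (pts < hi), axis=1)

    # -- IO ---------------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("labels", data=self.labels, compression="gzip")
            d.attrs["pitch_nm"] = self.pitch_nm
            d.attrs["origin_nm"] = self.origin_nm
            d.attrs["label_map"] = json.dumps(self.label_map)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "LabelVolume":
        import h5py

        with h5py.File(path, "r") as f:
            d = f["labels"]
            return cls(
                labels=d[()],
                pitch_nm=tuple(d.attrs["pitch_nm"]),
                origin_nm=tuple(d.attrs["origin_nm"]),
                label_map={int(k): v for k, v in json.loads(d.attrs["label_map"]).items()},
            )

    def to_tiff(self, path: str | Path) -> None:
        """Write as multipage TIFF (z pages) plus a JSON metadata sidecar."""
        import tifffile

        path = Path(path)
        # pages along z: transpose to (nz, nx, ny)
        tifffile.imwrite(path, np.ascontiguousarray(self.labels.transpose(2, 0, 1)))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "pitch_nm": self.pitch_nm,
                    "origin_nm": self.origin_nm,
                    "label_map": self.label_map,
                }
            )
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "LabelVolume":
        import tifffile

        path = Path(path)
        stack = tifffile.imread(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(
            labels=np.ascontiguousarray(stack.transpose(1, 2, 0)),
            pitch_nm=tuple(meta["pitch_nm"]),
            origin_nm=tuple(meta["origin_nm"]),
            label_map={int(k): v for k, v in meta["label_map"].items()},
        )


@dataclass
class MorphometricsRecord:
    """Per-synapse geometric summary.

    svr is the astrocytic surface/volume ratio in 1/µm; coverages and
    fractions are dimensionless in [0, 1].
    """

    svr: float
    coverage_pre: float
    coverage_post: float
    ecs_fraction: float
    astro_fraction: float

    def __post_init__(self) -> None:
        for name in ("coverage_pre", "coverage_post", "ecs_fraction", "astro_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.svr < 0:
            raise ValueError(f"svr must be >= 0, got {self.svr}")


@dataclass
class SynapseRecord:
    """A sampled synapse environment plus the attributes the selection
    filter needs (axon type, terminal, multisynaptic bouton, spine target)."""

    volume: LabelVolume
    centroid_nm: tuple[float, float, float]
    axon_type: str | None = "excitatory"
    has_terminal: bool | None = True
    is_multisynaptic: bool | None = False
    target_is_spine: bool | None = True
    synapse_id: str = ""
    morphometrics: MorphometricsRecord | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid_nm, dtype=float)
        lo = np.asarray(self.volume.origin_nm)
        hi = lo + np.asarray(self.volume.extent_nm)
        if not np.all((c >= lo) & (c < hi)):
            raise ValueError(
                f"centroid {tuple(c)} outside volume extent [{tuple(lo)}, {tuple(hi)})"
            )
        self.centroid_nm = tuple(float(x) for x in c)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_ecs_correction(vol: LabelVolume, shrink_nm: float = 6.0) -> LabelVolume:
    """Correct fixation-induced swelling by shrinking every cellular
    segment and relabelling the eroded shell as ECS.

    Each non-ECS segment is morphologically eroded in the imaging plane
    (x/y) by ``shrink_nm``; the removed shell becomes ECS.  Erosion is
    in-plane only: the section thickness (z pitch) exceeds the shrink
    distance, so eroding along z would over-correct.  Faces on the sample
    boundary are treated as segment-continuation (not eroded).

    The ECS fraction never decreases, and no voxel changes between two
    non-ECS labels.
    """
    dx = vol.pitch_nm[0]
    n_iter = shrink_nm / dx
    if shrink_nm <= 0 or abs(n_iter - round(n_iter)) > 1e-9:
        raise ValueError(
            f"shrink_nm={shrink_nm} must be a positive multiple of the in-plane "
            f"pitch ({dx} nm)"
        )
    n_iter = int(round(n_iter))
    # in-plane 4-neighbourhood structuring element
    structure = np.zeros((3, 3, 1), dtype=bool)
    structure[1, 1, 0] = structure[0, 1, 0] = structure[2, 1, 0] = True
    structure[1, 0, 0] = structure[1, 2, 0] = True

    ecs_id = vol.ecs_id
    out = vol.labels.copy()
    for seg_id, role in vol.label_map.items():
        if role == "ecs":
            continue
        m = vol.labels == seg_id
        if not m.any():
            continue
        eroded = ndimage.binary_erosion(
            m, structure=structure, iterations=n_iter, border_value=1
        )
        out[m & ~eroded] = ecs_id
    return replace(vol, labels=out)


def compartment_fractions(vol: LabelVolume) -> dict[str, float]:
    """Volume fraction of each role present in the volume (sums to 1)."""
    counts = np.bincount(vol.labels.ravel())
    total = vol.labels.size
    out: dict[str, float] = {}
    for seg_id, role in vol.label_map.items():
        n = counts[seg_id] if seg_id < len(counts) else 0
        out[role] = out.get(role, 0.0) + n / total
    return out


def _face_areas_nm2(pitch_nm: Sequence[float]) -> tuple[float, float, float]:
    """Area of a voxel face normal to each axis."""
    dx, dy, dz = pitch_nm
    return (dy * dz, dx * dz, dx * dy)


def surface_face_masks(vol: LabelVolume, role: str) -> list[tuple[np.ndarray, int, int, float]]:
    """Enumerate exposed faces of a segment as boolean masks.

    Returns a list of ``(mask, axis, direction, face_area_nm2)`` tuples
    where ``mask`` flags the *role* voxels whose face towards
    ``direction`` (+1/-1) along ``axis`` abuts a differently-labelled
    voxel.  Sample-boundary faces are excluded.
    """
    m = vol.mask(role)
    areas = _face_areas_nm2(vol.pitch_nm)
    out = []
    for axis in range(3):
        for direction in (+1, -1):
            exposed = np.zeros_like(m)
            sl_src = [slice(None)] * 3
            sl_nb = [slice(None)] * 3
            if direction == +1:
                sl_src[axis] = slice(None, -1)
                sl_nb[axis] = slice(1, None)
            else:
                sl_src[axis] = slice(1, None)
                sl_nb[axis] = slice(None, -1)
            exposed[tuple(sl_src)] = m[tuple(sl_src)] & ~m[tuple(sl_nb)]
            out.append((exposed, axis, direction, areas[axis]))
    return out


def astro_surface_area_volume(vol: LabelVolume) -> tuple[float, float, float]:
    """Astrocytic surface area (µm²), volume (µm³) and SVR (1/µm).

    The surface is the set of astrocyte voxel faces exposed to any other
    label, weighted by the anisotropic face areas; sample-boundary faces
    are not counted.  SVR = area / volume.
    """
    m = vol.mask("astro")
    n_vox = int(m.sum())
    if n_vox == 0:
        raise EmptySegmentError("volume contains no astrocyte voxels")
    area_nm2 = 0.0
    for mask, _axis, _direction, face_area in surface_face_masks(vol, "astro"):
        area_nm2 += float(mask.sum()) * face_area
    vol_nm3 = n_vox * vol.voxel_volume_nm3
    area_um2 = area_nm2 * 1e-6
    vol_um3 = vol_nm3 * 1e-9
    return area_um2, vol_um3, area_um2 / vol_um3


def _shift(a: np.ndarray, axis: int, direction: int, fill) -> np.ndarray:
    """Shift array by one voxel along axis, filling the vacated border."""
    out = np.empty_like(a)
    sl_dst = [slice(None)] * 3
    sl_src = [slice(None)] * 3
    sl_fill = [slice(None)] * 3
    if direction == +1:
        sl_dst[axis] = slice(1, None)
        sl_src[axis] = slice(None, -1)
        sl_fill[axis] = slice(0, 1)
    else:
        sl_dst[axis] = slice(None, -1)
        sl_src[axis] = slice(1, None)
        sl_fill[axis] = slice(-1, None)
    out[tuple(sl_dst)] = a[tuple(sl_src)]
    out[tuple(sl_fill)] = fill
    return out


def _geodesic_distance_through_ecs(vol: LabelVolume, max_dist_nm: float) -> np.ndarray:
    """Distance from the astrocyte through face-connected ECS paths.

    Astrocyte voxels are sources at distance 0; distances propagate only
    through ECS voxels with per-step costs equal to the pitch along the
    stepped axis.  Distances above ``max_dist_nm`` are left at +inf.
    Implemented as repeated relaxation sweeps (the number of sweeps
    bounds the path length, which suffices for small contact distances).
    """
    astro = vol.mask("astro")
    ecs = vol.mask("ecs")
    dist = np.full(vol.shape, np.inf, dtype=np.float32)
    dist[astro] = 0.0
    n_sweeps = int(np.ceil(max_dist_nm / min(vol.pitch_nm))) + 1
    for _ in range(n_sweeps):
        updated = False
        for axis in range(3):
            step = vol.pitch_nm[axis]
            for direction in (+1, -1):
                cand = _shift(dist, axis, direction, np.inf) + step
                better = ecs & (cand < dist)
                if better.any():
                    dist[better] = cand[better]
                    updated = True
        if not updated:
            break
    return dist


def synaptic_coverage(
    vol: LabelVolume, target_role: str, contact_dist_nm: float = 12.0
) -> float:
    """Fraction of a bouton's or spine's surface in close astrocytic contact.

    A target surface voxel counts as covered when an astrocyte voxel is
    reachable within ``contact_dist_nm`` along face-connected paths
    through the ECS (direct astrocyte adjacency always counts).  The
    default 12 nm admits up to two in-plane ECS voxels between the
    membranes.
    """
    if target_role not in ("bouton", "spine"):
        raise ValueError(f"target_role must be 'bouton' or 'spine', got {target_role!r}")
    target = vol.mask(target_role)
    if not target.any():
        raise EmptySegmentError(f"volume contains no {target_role} voxels")
    if not vol.mask("astro").any():
        return 0.0

    # surface voxels of the target (any exposed interior face)
    surface = np.zeros(vol.shape, dtype=bool)
    for mask, _a, _d, _area in surface_face_masks(vol, target_role):
        surface |= mask
    n_surface = int(surface.sum())
    if n_surface == 0:
        # segment fills the whole volume; no interior surface
        return 0.0

    dist = _geodesic_distance_through_ecs(vol, contact_dist_nm)
    covered = np.zeros(vol.shape, dtype=bool)
    for axis in range(3):
        for direction in (+1, -1):
            nb = _shift(dist, axis, direction, np.inf)
            covered |= surface & (nb <= contact_dist_nm)
    return float((covered & surface).sum()) / n_surface


def select_synapses(
    records: Iterable[SynapseRecord], min_astro_fraction: float = 0.02
) -> list[SynapseRecord]:
    """Filter to "classical" single excitatory spine synapses.

    A record passes iff all five criteria hold: (1) the axon is
    excitatory; (2) an axon terminal is present (not en-passant); (3) the
    bouton is not multi-synaptic; (4) the postsynaptic element is a
    spine; (5) the astrocytic volume fraction is at least
    ``min_astro_fraction`` (inclusive).  Order is preserved.
    """
    out = []
    for i, rec in enumerate(records):
        for attr in ("axon_type", "has_terminal", "is_multisynaptic", "target_is_spine"):
            if getattr(rec, attr) is None:
                raise ValueError(
                    f"record {rec.synapse_id or i}: missing attribute {attr!r}"
                )
        astro_frac = rec.volume.role_fraction("astro")
        if (
            rec.axon_type == "excitatory"
            and rec.has_terminal
            and not rec.is_multisynaptic
            and rec.target_is_spine
            and astro_frac >= min_astro_fraction
        ):
            out.append(rec)
    return out


def morphometrics(
    record: SynapseRecord | LabelVolume, contact_dist_nm: float = 12.0
) -> MorphometricsRecord:
    """Compute the full morphometric summary of a synapse environment."""
    vol = record.volume if isinstance(record, SynapseRecord) else record
    fractions = compartment_fractions(vol)
    _, _, svr = astro_surface_area_volume(vol)
    cov_pre = (
        synaptic_coverage(vol, "bouton", contact_dist_nm)
        if vol.mask("bouton").any()
        else 0.0
    )
    cov_post = (
        synaptic_coverage(vol, "spine", contact_dist_nm)
        if vol.mask("spine").any()
        else 0.0
    )
    return MorphometricsRecord(
        svr=svr,
        coverage_pre=cov_pre,
        coverage_post=cov_post,
        ecs_fraction=fractions.get("ecs", 0.0),
        astro_fraction=fractions.get("astro", 0.0),
    )


def morphometrics_table(records: Sequence[SynapseRecord], contact_dist_nm: float = 12.0):
    """Morphometrics of a population as a pandas DataFrame (one row per synapse)."""
    import pandas as pd

    rows = []
    for i, rec in enumerate(records):
        m = rec.morphometrics or morphometrics(rec, contact_dist_nm)
        rows.append(
            {
                "synapse_id": rec.synapse_id or f"syn{i:04d}",
                "svr_um_inv": m.svr,
                "coverage_pre": m.coverage_pre,
                "coverage_post": m.coverage_post,
                "ecs_fraction": m.ecs_fraction,
                "astro_fraction": m.astro_fraction,
            }
        )
    return pd.DataFrame(rows)


def load_vast_export(path: str | Path) -> list[SynapseRecord]:
    """Adapter for segmentation-tool exports of EM reconstructions.

    Not implemented: wiring a concrete EM database export into
    :class:`LabelVolume` requires the exporting tool's file layout.  An
    adapter should produce, per synapse, an integer label grid at the
    native pitch, a label-id-to-role mapping, the postsynaptic-density
    centroid, and the axon/terminal/spine annotations, then return
    :class:`SynapseRecord` objects.  The synthetic generator
    (:mod:`calfluct.synthetic`) provides statistically matched stand-ins.
    """
    raise NotImplementedError(
        "EM export parsing is not implemented; construct SynapseRecord objects "
        "directly or use calfluct.synthetic.make_population"
    )
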