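"""Seeded generators for every input type, with known ground truth.

Each generator takes one explicit seed and uses no global random state,
so identical ``(params, seed)`` always yield identical outputs.

``make_stack`` builds two-channel stacks in which the enclosure status of
every planted red punctum is guaranteed by construction and robust to the
analysis pipeline's per-slice median filter: planted-enclosed puncta keep
a 2-voxel margin of astrocyte cytoplasm around them, planted-non-enclosed
puncta keep a 2-voxel margin of background, and puncta are pairwise
separated by more than 2 voxels (Chebyshev) so the filter can never merge
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .mitoquant import VoxelStack
from .scqpcr import CtTable
from .stats import IOPSeries

__all__ = [
    "PlacementError",
    "PackingError",
    "MitoRecord",
    "StackTruth",
    "CtTruth",
    "make_stack",
    "make_ct_table",
    "make_iop_series",
    "make_retina_field",
]


class PlacementError(RuntimeError):
    """Requested object could not be placed (e.g. astrocyte too thin)."""


class PackingError(RuntimeError):
    """Requested point pattern infeasible at the given minimum spacing."""


_CUBE = np.ones((3, 3, 3), dtype=bool)  # Chebyshev-1 structuring element


# ---------------------------------------------------------------------------
# image stacks


@dataclass
class MitoRecord:
    id: int
    voxels: np.ndarray  # (n, 3) int (z, y, x)
    planted_enclosed: bool


@dataclass
class StackTruth:
    astro_masks: list[np.ndarray]
    mito_records: list[MitoRecord]
    voxel_size_um: float


def _stamp_ellipsoid(mask: np.ndarray, center: np.ndarray, radii: np.ndarray) -> None:
    """Set voxels of a solid ellipsoid, clipped to the volume."""
    lo = np.maximum(np.floor(center - radii).astype(int), 0)
    hi = np.minimum(np.ceil(center + radii).astype(int) + 1, mask.shape)
    if (lo >= hi).any():
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d <= 1.0


def _ellipsoid_voxels(shape, center, radii) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    _stamp_ellipsoid(m, np.asarray(center, float), np.asarray(radii, float))
    return np.argwhere(m)


def _make_astrocyte(
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    soma_radius_range: tuple[float, float],
    n_processes_range: tuple[int, int],
    process_radius_range: tuple[float, float],
) -> np.ndarray:
    """Ellipsoid soma plus tubular processes traced by seeded random walks."""
    shape_a = np.array(shape, float)
    mask = np.zeros(shape, dtype=bool)
    center = rng.uniform(0.3, 0.7, 3) * shape_a
    soma_r = rng.uniform(*soma_radius_range, size=3)
    soma_r = np.minimum(soma_r, shape_a / 4)
    _stamp_ellipsoid(mask, center, soma_r)

    n_proc = int(rng.integers(n_processes_range[0], n_processes_range[1] + 1))
    walk_len = 0.35 * min(shape)
    for _ in range(n_proc):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = center + direction * soma_r * 0.8
        tube_r = rng.uniform(*process_radius_range)
        n_steps = max(3, int(walk_len / 2.0))
        for _ in range(n_steps):
            pos = pos + direction * 2.0
            if (pos < 2).any() or (pos > shape_a - 3).any():
                break
            _stamp_ellipsoid(mask, pos, np.full(3, tube_r))
            direction = direction + 0.35 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
    return mask


def _punctum_ok(
    shape: np.ndarray,
    voxels: np.ndarray,
    union_mask: np.ndarray,
    occupancy: np.ndarray,
    require_inside: bool | None,
) -> bool:
    """Exact feasibility check for a candidate punctum.

    ``require_inside=True``: the punctum dilated by Chebyshev radius 2 must
    lie fully inside the astrocyte union mask and the volume.
    ``require_inside=False``: the dilated punctum must lie fully outside the
    mask.  ``None`` skips the inside/outside constraint (border puncta).
    Always requires no overlap with the occupancy mask (previous puncta
    dilated by 2).
    """
    if voxels.size == 0:
        return False
    lo = np.maximum(voxels.min(axis=0) - 2, 0)
    hi = np.minimum(voxels.max(axis=0) + 3, shape)
    local = np.zeros(hi - lo, dtype=bool)
    local[tuple((voxels - lo).T)] = True
    dil = ndimage.binary_dilation(local, structure=_CUBE, iterations=2)
    if require_inside is True:
        # dilated set must not be clipped by the volume border
        if (voxels.min(axis=0) < 2).any() or (voxels.max(axis=0) > shape - 3).any():
            return False
        if not union_mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][dil].all():
            return False
    elif require_inside is False:
        if union_mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][dil].any():
            return False
    if occupancy[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][local].any():
        return False
    return True


def _mark_occupancy(occupancy: np.ndarray, voxels: np.ndarray) -> None:
    shape = np.array(occupancy.shape)
    lo = np.maximum(voxels.min(axis=0) - 2, 0)
    hi = np.minimum(voxels.max(axis=0) + 3, shape)
    local = np.zeros(hi - lo, dtype=bool)
    local[tuple((voxels - lo).T)] = True
    dil = ndimage.binary_dilation(local, structure=_CUBE, iterations=2)
    occupancy[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dil


def make_stack(
    shape: tuple[int, int, int] = (64, 64, 64),
    n_astrocytes: int = 1,
    n_enclosed: int = 3,
    n_external: int = 3,
    n_border: int = 0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    voxel_size_um: float = 0.4,
    green_fg: int = 180,
    green_bg: int = 20,
    red_fg: int = 200,
    red_bg: int = 0,
    punctum_radius_range: tuple[float, float] = (2.0, 3.0),
    soma_radius_range: tuple[float, float] = (9.0, 12.0),
    n_processes_range: tuple[int, int] = (4, 8),
    process_radius_range: tuple[float, float] = (2.5, 3.5),
    max_tries: int = 3000,
) -> tuple[VoxelStack, StackTruth]:
    """Generate a two-channel stack with planted mitochondria ground truth.

    Raises :class:`PlacementError` when a requested punctum cannot be
    placed (never silently truncates the requested counts).
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 16:
        raise ValueError("stack dimensions must be >= 16 voxels")
    if min(n_astrocytes, n_enclosed, n_external, n_border) < 0:
        raise ValueError("counts must be >= 0")
    if punctum_radius_range[0] < 2.0:
        raise ValueError(
            "punctum radius < 2 voxels does not survive the 3x3 median filter"
        )
    rng = np.random.default_rng(seed)
    shape_a = np.array(shape)

    astro_masks = [
        _make_astrocyte(
            shape, rng, soma_radius_range, n_processes_range, process_radius_range
        )
        for _ in range(n_astrocytes)
    ]
    union = np.zeros(shape, dtype=bool)
    for m in astro_masks:
        union |= m

    if n_enclosed > 0 and n_astrocytes == 0:
        raise PlacementError("cannot place enclosed mitochondria without astrocytes")

    occupancy = np.zeros(shape, dtype=bool)
    records: list[MitoRecord] = []
    next_id = 1

    # interior candidates: conservative EDT prefilter, then exact check
    if n_enclosed > 0:
        edt = ndimage.distance_transform_edt(union)
        interior = np.argwhere(edt > punctum_radius_range[0] + 2.0)
        if interior.shape[0] == 0:
            raise PlacementError(
                "astrocytes too thin to enclose any punctum of the requested size"
            )
    for _ in range(n_enclosed):
        placed = False
        for _attempt in range(max_tries):
            center = interior[rng.integers(interior.shape[0])] + rng.uniform(
                -0.5, 0.5, 3
            )
            # shrink toward the minimum radius as attempts accumulate so a
            # crowded but feasible request still succeeds
            shrink = 1.0 - _attempt / max_tries
            r_lo, r_hi = punctum_radius_range
            radii = rng.uniform(r_lo, r_lo + (r_hi - r_lo) * shrink, size=3)
            voxels = _ellipsoid_voxels(shape, center, radii)
            if _punctum_ok(shape_a, voxels, union, occupancy, True):
                records.append(MitoRecord(next_id, voxels, True))
                _mark_occupancy(occupancy, voxels)
                next_id += 1
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place enclosed punctum {next_id} after {max_tries} tries "
                "(astrocyte too thin or too crowded)"
            )

    for _ in range(n_external):
        placed = False
        for _attempt in range(max_tries):
            center = rng.uniform(4, shape_a - 5)
            radii = rng.uniform(*punctum_radius_range, size=3)
            voxels = _ellipsoid_voxels(shape, center, radii)
            # keep external puncta off the border so their failure mode is
            # a shell gap, not border contact
            if voxels.size and (
                (voxels.min(axis=0) < 1).any()
                or (voxels.max(axis=0) > shape_a - 2).any()
            ):
                continue
            if _punctum_ok(shape_a, voxels, union, occupancy, False):
                records.append(MitoRecord(next_id, voxels, False))
                _mark_occupancy(occupancy, voxels)
                next_id += 1
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place external punctum {next_id} after {max_tries} tries"
            )

    for _ in range(n_border):
        placed = False
        for _attempt in range(max_tries):
            axis = int(rng.integers(3))
            side = int(rng.integers(2))
            center = rng.uniform(4, shape_a - 5)
            center[axis] = 0.0 if side == 0 else shape[axis] - 1.0
            radii = rng.uniform(*punctum_radius_range, size=3)
            voxels = _ellipsoid_voxels(shape, center, radii)
            if voxels.size == 0:
                continue
            on_face = (voxels[:, axis] == (0 if side == 0 else shape[axis] - 1)).any()
            if not on_face:
                continue
            # keep border puncta in background so they are never enclosed
            if _punctum_ok(shape_a, voxels, union, occupancy, False):
                records.append(MitoRecord(next_id, voxels, False))
                _mark_occupancy(occupancy, voxels)
                next_id += 1
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place border punctum {next_id} after {max_tries} tries"
            )

    green = np.full(shape, green_bg, dtype=np.float64)
    green[union] = green_fg
    red = np.full(shape, red_bg, dtype=np.float64)
    for rec in records:
        red[tuple(rec.voxels.T)] = red_fg
    if noise_sigma > 0:
        green = green + rng.normal(0.0, noise_sigma, shape)
        red = red + rng.normal(0.0, noise_sigma, shape)
    green = np.clip(np.rint(green), 0, 255).astype(np.uint8)
    red = np.clip(np.rint(red), 0, 255).astype(np.uint8)

    stack = VoxelStack(green=green, red=red, voxel_size_um=voxel_size_um)
    truth = StackTruth(astro_masks, records, voxel_size_um)
    return stack, truth


# ---------------------------------------------------------------------------
# single-cell Ct tables


@dataclass
class CtTruth:
    """Parameters of the reactive-subpopulation mixture generator."""

    reactive_fraction: float = 0.0
    fold_change: Union[float, Mapping[str, float]] = 1.0
    baseline_dct_mean: float = 5.0
    baseline_dct_sd: float = 1.0
    dropout_prob: float = 0.0
    ct_ceiling: float = 40.0
    reactive_cells: list[str] = field(default_factory=list)

    def fold_for(self, gene: str) -> float:
        if isinstance(self.fold_change, Mapping):
            return float(self.fold_change.get(gene, 1.0))
        return float(self.fold_change)

    def validate(self, genes: Sequence[str]) -> None:
        if not 0.0 <= self.reactive_fraction <= 1.0:
            raise ValueError("reactive_fraction must be in [0, 1]")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        for g in genes:
            if self.fold_for(g) <= 0:
                raise ValueError(f"fold_change for {g!r} must be > 0")
        if self.baseline_dct_sd < 0:
            raise ValueError("baseline_dct_sd must be >= 0")


def make_ct_table(
    truth: CtTruth,
    n_cells: Union[int, tuple[int, int]],
    genes: Sequence[str],
    seed: int | None = None,
    groups: tuple[str, str] = ("saline", "microbead"),
    control_genes: tuple[str, str] = ("Gapdh", "Oaz1"),
    reference_gene: str = "Gapdh",
    control_ct_mean: tuple[float, float] = (20.0, 22.0),
    control_ct_sd: float = 0.5,
    control_dropout_prob: float | None = None,
) -> tuple[CtTable, CtTruth]:
    """Generate a cells x genes Ct table with a reactive treated mixture.

    The second entry of ``groups`` is the treated group; a seeded fraction
    ``truth.reactive_fraction`` of its cells has every target gene's
    baseline dCt shifted down by ``log2(fold_change)``.  Dropout replaces
    a measurement with the censoring ceiling.  Returns the table and a
    copy of the truth completed with the reactive cell ids.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must not be empty")
    truth.validate(genes)
    if isinstance(n_cells, int):
        n_cells = (n_cells, n_cells)
    n_ctrl, n_trt = n_cells
    if min(n_ctrl, n_trt) < 2:
        raise ValueError("need at least 2 cells per group")
    if control_dropout_prob is None:
        control_dropout_prob = truth.dropout_prob

    rng = np.random.default_rng(seed)
    targets = [g for g in genes if g not in control_genes]
    columns = list(control_genes) + targets

    rows = []
    cell_ids, labels, reactive_cells = [], [], []
    for gi, (glabel, n) in enumerate(zip(groups, (n_ctrl, n_trt))):
        treated = gi == 1
        for ci in range(n):
            cell = f"{glabel}_{ci:03d}"
            reactive = treated and (rng.random() < truth.reactive_fraction)
            if reactive:
                reactive_cells.append(cell)
            ct_ref = rng.normal(control_ct_mean[0], control_ct_sd)
            ct_oaz = rng.normal(control_ct_mean[1], control_ct_sd)
            row = {control_genes[0]: ct_ref, control_genes[1]: ct_oaz}
            for g in targets:
                dct = rng.normal(truth.baseline_dct_mean, truth.baseline_dct_sd)
                if reactive:
                    dct -= math.log2(truth.fold_for(g))
                row[g] = ct_ref + dct
            for g in columns:
                p = control_dropout_prob if g in control_genes else truth.dropout_prob
                if rng.random() < p:
                    row[g] = truth.ct_ceiling
            rows.append([row[g] for g in columns])
            cell_ids.append(cell)
            labels.append(glabel)

    ct = pd.DataFrame(rows, index=pd.Index(cell_ids, name="cell_id"), columns=columns)
    ct = ct.clip(upper=truth.ct_ceiling)
    table = CtTable(
        ct=ct,
        group=pd.Series(labels, index=ct.index, name="group"),
        control_genes=control_genes,
        reference_gene=reference_gene,
        ceiling=truth.ct_ceiling,
    )
    out_truth = CtTruth(
        reactive_fraction=truth.reactive_fraction,
        fold_change=truth.fold_change,
        baseline_dct_mean=truth.baseline_dct_mean,
        baseline_dct_sd=truth.baseline_dct_sd,
        dropout_prob=truth.dropout_prob,
        ct_ceiling=truth.ct_ceiling,
        reactive_cells=reactive_cells,
    )
    return table, out_truth


# ---------------------------------------------------------------------------
# IOP time series


def make_iop_series(
    profile: str,
    days: Sequence[float] | None = None,
    seed: int | None = None,
    baseline: float = 15.0,
    peak_iop: float = 30.0,
    peak_day: float = 7.0,
    shape_k: float = 2.0,
    noise_sd: float = 0.0,
    label: str | None = None,
) -> IOPSeries:
    """IOP curve: stationary for saline, peaked at ``peak_day`` for microbead.

    The microbead profile is ``baseline + (peak-baseline) * g(t)`` with a
    gamma-shaped pulse ``g(t) = (t/T)^k exp(k (1 - t/T))`` that equals 1
    exactly at ``t = T`` and decays back toward baseline.
    """
    if profile not in ("saline", "microbead"):
        raise ValueError("profile must be 'saline' or 'microbead'")
    if days is None:
        days = np.arange(0.0, 28.0 + 1e-9, 3.5)  # twice weekly for a month
    days = np.asarray(days, dtype=float)
    if days.size < 2:
        raise ValueError("need at least 2 measurement days")
    if not (np.diff(days) > 0).all():
        raise ValueError("days must be strictly increasing")

    rng = np.random.default_rng(seed)
    if profile == "saline":
        iop = np.full(days.shape, float(baseline))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = days / peak_day
            pulse = np.where(t > 0, t**shape_k * np.exp(shape_k * (1 - t)), 0.0)
        iop = baseline + (peak_iop - baseline) * pulse
    if noise_sd > 0:
        iop = iop + rng.normal(0.0, noise_sd, days.shape)
    iop = np.maximum(iop, 1.0)
    return IOPSeries(day=days, iop=iop, label=label or profile)


# ---------------------------------------------------------------------------
# retinal nuclei fields


def make_retina_field(
    density: float,
    field_area_mm2: float,
    seed: int | None = None,
    um_per_px: float = 2.0,
    nucleus_radius_um: float = 5.0,
    min_spacing_um: float | None = None,
    n_nuclei: int | None = None,
    noise_sd: float = 0.0,
    fg: int = 220,
    bg: int = 15,
    max_attempts_per_nucleus: int = 200,
) -> tuple[np.ndarray, int]:
    """Render a field of nuclei disks; returns ``(image, true_count)``.

    The nucleus count is Poisson with mean ``density * field_area_mm2``
    unless ``n_nuclei`` fixes it.  Disks are never clipped by the field
    border.  ``min_spacing_um`` enforces a minimum center-to-center
    distance; an infeasible packing raises :class:`PackingError`.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if field_area_mm2 <= 0:
        raise ValueError("field_area_mm2 must be > 0")
    rng = np.random.default_rng(seed)
    side_px = int(round(math.sqrt(field_area_mm2) * 1000.0 / um_per_px))
    r_px = nucleus_radius_um / um_per_px
    count = int(n_nuclei if n_nuclei is not None else rng.poisson(density * field_area_mm2))

    margin = r_px + 1.0
    if count > 0 and side_px - 2 * margin <= 0:
        raise PackingError("field too small for the nucleus radius")
    min_sp_px = (min_spacing_um / um_per_px) if min_spacing_um else 0.0

    centers: list[np.ndarray] = []
    for i in range(count):
        ok = False
        for _ in range(max_attempts_per_nucleus):
            c = rng.uniform(margin, side_px - margin, size=2)
            if min_sp_px > 0 and centers:
                d = np.linalg.norm(np.asarray(centers) - c, axis=1)
                if (d < min_sp_px).any():
                    continue
            centers.append(c)
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place nucleus {i + 1}/{count} at minimum spacing "
                f"{min_spacing_um} um"
            )

    img = np.full((side_px, side_px), float(bg))
    if centers:
        yy, xx = np.ogrid[:side_px, :side_px]
        for cy, cx in centers:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2] = fg
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, count
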