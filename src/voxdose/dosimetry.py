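"""Voxel-level dose computation: masses, S-value convolution, DVH metrics.

The absorbed-dose model is the voxel S-value formalism: the dose map is
the discrete 3D convolution of the voxelised cumulated activity Ã
(Bq·s per voxel) with a kernel of S-values — absorbed dose to a target
voxel per unit cumulated activity in a source voxel, Gy/(Bq·s).  For
¹⁷⁷Lu the emitted electrons have sub-voxel range at typical SPECT voxel
sizes, so a single-voxel local-deposition kernel

    s₀ = E_per_decay [J] / voxel_mass [kg]

is a physically sensible default; externally computed voxel-S tables can
be loaded from CSV instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .kinetics import BiExpFit, ExtendedMask, cumulated_activity
from .volumes import BinaryMask, GeometryError, VoxelGrid

#: Joules per MeV.
MEV_TO_J = 1.602176634e-13

#: Mean energy (MeV) carried by electrons (β⁻ + conversion + Auger) per
#: ¹⁷⁷Lu decay, from standard decay-data compilations (ICRP 107).  A
#: configuration value, not a physics assertion: override per study.
LU177_ELECTRON_MEV_PER_DECAY = 0.1479

#: Soft-tissue density used for organ masses, g/cc.
DEFAULT_DENSITY_G_PER_CC = 1.06


@dataclass
class DoseKernel:
    """Voxel S-value kernel: Gy to target voxel per Bq·s in source voxel."""

    values: np.ndarray  # odd extents on all axes; centre = self-dose S-value
    spacing_mm: tuple[float, float, float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or any(s % 2 == 0 for s in self.values.shape):
            raise ValueError("kernel must be 3D with odd extents")
        if (self.values < 0).any():
            raise ValueError("S-values must be non-negative")
        center = tuple(s // 2 for s in self.values.shape)
        if self.values[center] < self.values.max():
            raise ValueError("kernel centre must hold the maximum S-value")

    @property
    def center_value(self) -> float:
        return float(self.values[tuple(s // 2 for s in self.values.shape)])

    def matches_spacing(self, v: VoxelGrid, tol: float = 1e-6) -> bool:
        return np.allclose(self.spacing_mm, v.spacing, atol=tol)


def organ_mass(
    m: BinaryMask, density_g_per_cc: float = DEFAULT_DENSITY_G_PER_CC
) -> float:
    """Organ mass in grams: voxel count × voxel volume × density (1.06 g/cc)."""
    if m.voxel_count == 0:
        import warnings

        warnings.warn(f"mask {m.label!r} is empty; mass is 0 g", stacklevel=2)
        return 0.0
    return m.voxel_count * m.grid.voxel_volume_ml * density_g_per_cc


def local_deposition_kernel(
    spacing_mm: tuple[float, float, float],
    energy_per_decay_mev: float = LU177_ELECTRON_MEV_PER_DECAY,
    density_g_per_cc: float = DEFAULT_DENSITY_G_PER_CC,
) -> DoseKernel:
    """Single-voxel kernel depositing all electron energy in the source voxel.

    s₀ = E_per_decay (J) / voxel mass (kg), in Gy/(Bq·s).  Valid when the
    emission range is small against the voxel size, as for ¹⁷⁷Lu
    electrons at SPECT resolutions.
    """
    if any(s <= 0 for s in spacing_mm) or density_g_per_cc <= 0:
        raise ValueError("spacing and density must be positive")
    if energy_per_decay_mev < 0:
        raise ValueError("energy per decay must be >= 0")
    voxel_cm3 = math.prod(spacing_mm) / 1000.0
    voxel_kg = voxel_cm3 * density_g_per_cc / 1000.0
    s0 = energy_per_decay_mev * MEV_TO_J / voxel_kg
    return DoseKernel(
        values=np.array([[[s0]]]),
        spacing_mm=tuple(float(s) for s in spacing_mm),
        provenance=f"local deposition, {energy_per_decay_mev} MeV/decay",
    )


def load_kernel(path: str | Path, octant: bool = False) -> DoseKernel:
    """Load a voxel-S kernel from CSV (columns dx, dy, dz, s_value_gy_per_bq_s).

    Offsets are integer voxel indices relative to the source voxel.  With
    ``octant=True`` the file stores only the non-negative octant and is
    mirrored across all three axes.  Spacing comes from header comment
    lines ``# spacing_mm: dx dy dz`` or defaults to 1 mm isotropic.
    """
    path = Path(path)
    spacing = (1.0, 1.0, 1.0)
    for line in path.read_text().splitlines():
        if line.startswith("#") and "spacing_mm:" in line:
            spacing = tuple(float(x) for x in line.split(":", 1)[1].split())
        if not line.startswith("#"):
            break
    df = pd.read_csv(path, comment="#")
    required = {"dx", "dy", "dz", "s_value_gy_per_bq_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"kernel CSV must have columns {sorted(required)}")
    if (df["s_value_gy_per_bq_s"] < 0).any():
        raise ValueError("S-values must be non-negative")
    if octant:
        if (df[["dx", "dy", "dz"]] < 0).to_numpy().any():
            raise ValueError("octant kernels must have non-negative offsets")
        frames = [df]
        for axis in ("dx", "dy", "dz"):
            mirrored = pd.concat(frames, ignore_index=True)
            mirrored = mirrored[mirrored[axis] > 0].copy()
            mirrored[axis] = -mirrored[axis]
            frames.append(mirrored)
        df = pd.concat(frames, ignore_index=True).drop_duplicates(["dx", "dy", "dz"])
    rmax = int(df[["dx", "dy", "dz"]].abs().to_numpy().max())
    extent = 2 * rmax + 1
    if not ((df.dx == 0) & (df.dy == 0) & (df.dz == 0)).any():
        raise ValueError("kernel CSV is missing the centre (0,0,0) entry")
    values = np.zeros((extent, extent, extent))
    values[
        df.dx.to_numpy() + rmax, df.dy.to_numpy() + rmax, df.dz.to_numpy() + rmax
    ] = df.s_value_gy_per_bq_s.to_numpy()
    return DoseKernel(values=values, spacing_mm=spacing, provenance=str(path))


def save_kernel(k: DoseKernel, path: str | Path) -> None:
    """Write a kernel in the CSV dialect read by :func:`load_kernel`."""
    rmax = tuple(s // 2 for s in k.values.shape)
    idx = np.argwhere(k.values != 0)
    rows = [
        {
            "dx": int(i - rmax[0]),
            "dy": int(j - rmax[1]),
            "dz": int(kk - rmax[2]),
            "s_value_gy_per_bq_s": float(k.values[i, j, kk]),
        }
        for i, j, kk in idx
    ]
    header = f"# spacing_mm: {k.spacing_mm[0]} {k.spacing_mm[1]} {k.spacing_mm[2]}\n"
    body = pd.DataFrame(rows, columns=["dx", "dy", "dz", "s_value_gy_per_bq_s"])
    Path(path).write_text(header + body.to_csv(index=False))


def cumulated_activity_map(
    spect_series: dict[float, VoxelGrid],
    em: ExtendedMask,
    fit: BiExpFit,
    mode: str = "organ_scaled",
    reference_time_h: float = 24.0,
) -> VoxelGrid:
    """Distribute the organ cumulated activity Ã over voxels (Bq·s).

    The extended mask's role is retrieval: its margin recaptures counts
    spilled outside the organ border by the limited SPECT resolution.
    The deposition support, however, is the anatomical organ (the base
    mask): the spilled counts are a measurement artifact, and ¹⁷⁷Lu
    electron self-dose is deposited where the activity physically is.

    ``organ_scaled`` (default): each organ voxel receives Ã × its share
    of the measured activity at the reference time point, so the map
    inherits the measured spatial distribution while Σ voxel Ã = organ Ã
    exactly.  ``per_voxel``: an independent bi-exponential fit per voxel
    from its own concentration time course (organ-shape fallback on
    failure), renormalised to the organ Ã; closer to a literal
    voxel-wise integration but fragile with only four noisy samples.
    """
    organ_cum = cumulated_activity(fit)
    sel = em.base.as_bool() if isinstance(em, ExtendedMask) else em.as_bool()
    if mode == "organ_scaled":
        if reference_time_h not in spect_series:
            raise ValueError(
                f"reference time {reference_time_h} h not in series "
                f"{sorted(spect_series)}"
            )
        ref = spect_series[reference_time_h]
        weights = np.where(sel, np.clip(ref.data, 0, None), 0.0)
        total = weights.sum()
        if total <= 0:
            # No signal at the reference time: fall back to uniform.
            weights = sel.astype(np.float64)
            total = weights.sum()
        amap = organ_cum * weights / total
    elif mode == "per_voxel":
        times = np.array(sorted(spect_series), dtype=float)
        vox_ml = next(iter(spect_series.values())).voxel_volume_ml
        stack = np.stack(
            [np.clip(spect_series[t].data, 0, None) * vox_ml for t in times], axis=-1
        )
        amap = np.zeros(sel.shape)
        shape_w = None
        for idx in np.argwhere(sel):
            y = stack[tuple(idx)]
            try:
                from .kinetics import TimeActivitySample, fit_biexponential

                vfit = fit_biexponential(
                    [TimeActivitySample(t, max(a, 0.0)) for t, a in zip(times, y)],
                )
                amap[tuple(idx)] = cumulated_activity(vfit)
            except ValueError:
                if shape_w is None:
                    shape_w = np.clip(stack[..., -1], 0, None)
                    shape_total = shape_w[sel].sum()
                amap[tuple(idx)] = organ_cum * shape_w[tuple(idx)] / max(shape_total, 1e-30)
        total = amap.sum()
        if total > 0:
            amap *= organ_cum / total  # enforce Σ voxel Ã = organ Ã
    else:
        raise ValueError(f"unknown mode {mode!r}")
    grid = next(iter(spect_series.values()))
    return VoxelGrid(
        amap, spacing=grid.spacing, origin=grid.origin,
        intensity_kind="cumulated_activity_Bq_s",
    )


def convolve_dose(amap: VoxelGrid, k: DoseKernel) -> VoxelGrid:
    """Dose map (Gy) = Ã map ⊛ voxel-S kernel, zero-padded at the edges."""
    if amap.intensity_kind != "cumulated_activity_Bq_s":
        raise ValueError(f"expected a cumulated-activity map, got {amap.intensity_kind!r}")
    if not k.matches_spacing(amap):
        raise GeometryError(
            f"kernel spacing {k.spacing_mm} does not match activity-map spacing "
            f"{amap.spacing}; regenerate or resample the kernel"
        )
    if k.values.size == 1:
        dose = amap.data * k.center_value
    else:
        dose = ndimage.convolve(amap.data, k.values, mode="constant", cval=0.0)
    return amap.with_data(dose, intensity_kind="dose_Gy")


def mean_dose(d: VoxelGrid, m: BinaryMask) -> float:
    """Arithmetic mean dose (Gy) over the mask voxels."""
    if not m.grid.same_geometry(d):
        raise GeometryError("dose map and mask grids differ")
    if m.voxel_count == 0:
        raise ValueError("cannot average dose over an empty mask")
    return float(d.data[m.as_bool()].mean())


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one organ.

    ``dose_gy`` is ascending; ``volume_fraction[i]`` is the fraction of
    the organ receiving at least ``dose_gy[i]`` — non-increasing, 1.0 at
    zero dose, 0 beyond the maximum.
    """

    dose_gy: np.ndarray
    volume_fraction: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.dose_gy) < 0) or np.any(np.diff(self.volume_fraction) > 0):
            raise ValueError("DVH must be sorted in dose with non-increasing volume")


def dvh(d: VoxelGrid, m: BinaryMask) -> DVHCurve:
    """Cumulative DVH from the sorted in-mask dose values."""
    if not m.grid.same_geometry(d):
        raise GeometryError("dose map and mask grids differ")
    doses = np.sort(d.data[m.as_bool()].astype(np.float64))
    if doses.size == 0:
        raise ValueError("cannot build a DVH from an empty mask")
    n = doses.size
    unique, first_idx = np.unique(doses, return_index=True)
    # volume fraction receiving >= each unique dose level
    frac = (n - first_idx) / n
    dose_axis = np.concatenate([[0.0], unique]) if unique[0] > 0 else unique
    frac_axis = np.concatenate([[1.0], frac]) if unique[0] > 0 else frac
    return DVHCurve(dose_gy=dose_axis, volume_fraction=frac_axis, label=m.label)


def dvh_at(c: DVHCurve, x: float) -> float:
    """DVH-x: the minimum dose received by the hottest x % of the volume.

    Returns the largest dose D with volume-fraction(dose ≥ D) ≥ x/100,
    e.g. DVH-30 is higher than DVH-70 for any non-uniform distribution.
    """
    if not 0 < x < 100:
        raise ValueError("x must lie in (0, 100)")
    ok = c.volume_fraction >= x / 100.0
    if not ok.any():
        return float(c.dose_gy[0])
    return float(c.dose_gy[np.nonzero(ok)[0][-1]])
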