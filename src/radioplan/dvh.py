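"""Dose-volume histograms and plan-quality metrics.

Conventions (fixed, documented here once):

* Default DVH bin width is 10 cGy.
* ``d_min``/``d_max`` come from the raw masked voxel list, not from DVH
  percentiles. The homogeneity check uses D98%/D2% as near-min/near-max.
* The standard deviation is the population estimator (divide by n).
* Dx%/Vx interpolation is linear between tabulated cumulative points;
  plateau ties resolve to the lowest dose attaining the volume level.
* The conformity index defaults to the single-ratio (RTOG) variant; the
  Paddick variant is available via ``variant="paddick"``.
* The gradient measure is the difference of equivalent-sphere radii of the
  50% and 100% prescription isodose volumes, reported in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DoseGrid, StructureMask

__all__ = [
    "DifferentialDVH",
    "CumulativeDVH",
    "DoseMetrics",
    "HomogeneityResult",
    "grid_to_differential_dvh",
    "differential_to_cumulative",
    "dose_at_volume",
    "volume_at_dose",
    "summary_metrics",
    "conformity_index",
    "gradient_measure",
    "homogeneity_check",
    "DEFAULT_BIN_WIDTH_CGY",
]

DEFAULT_BIN_WIDTH_CGY = 10.0


@dataclass
class DifferentialDVH:
    """Binned dose-volume data: absolute volume (cc) per dose bin (cGy)."""

    bin_edges: np.ndarray  # length n_bins + 1, monotone increasing, cGy
    bin_volume: np.ndarray  # length n_bins, cc, >= 0
    structure: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_volume = np.asarray(self.bin_volume, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("bin_edges must be a 1D array of at least two boundaries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.bin_volume.shape != (self.bin_edges.size - 1,):
            raise ValueError("bin_volume length must be len(bin_edges) - 1")
        if np.any(self.bin_volume < 0):
            raise ValueError("bin volumes must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_volume(self) -> float:
        return float(self.bin_volume.sum())

    @property
    def relative_volume(self) -> np.ndarray:
        """Per-bin volume fractions v_i, normalised to sum to 1."""
        tot = self.total_volume
        if tot <= 0:
            raise ValueError(f"structure {self.structure!r} has zero total volume")
        return self.bin_volume / tot

    def rebinned_doses(self, doses: np.ndarray) -> "DifferentialDVH":
        """Return a copy with bin-centre doses replaced (volumes unchanged).

        Used by dose transforms (e.g. EQD2) that remap each bin's dose. The
        result stores degenerate per-bin edges centred on the new doses.
        """
        doses = np.asarray(doses, dtype=float)
        if doses.shape != self.bin_centers.shape:
            raise ValueError("remapped doses must match number of bins")
        order = np.argsort(doses, kind="stable")
        widths = np.diff(self.bin_edges)[order]
        centers = doses[order]
        # Rebuild edges around the sorted centres; widths only matter for
        # plotting, all downstream maths uses centres and volumes.
        edges = np.concatenate([[max(centers[0] - widths[0] / 2, 0.0)], centers + widths / 2])
        edges = np.maximum.accumulate(edges)
        edges += np.arange(edges.size) * 1e-9  # enforce strict monotonicity
        return DifferentialDVH(edges, self.bin_volume[order], self.structure)


@dataclass
class CumulativeDVH:
    """Volume receiving at least each tabulated dose."""

    dose_axis: np.ndarray  # cGy, monotone increasing
    volume_at_least: np.ndarray  # cc, monotone non-increasing
    structure: str = ""

    def __post_init__(self) -> None:
        self.dose_axis = np.asarray(self.dose_axis, dtype=float)
        self.volume_at_least = np.asarray(self.volume_at_least, dtype=float)
        if self.dose_axis.shape != self.volume_at_least.shape:
            raise ValueError("dose_axis and volume_at_least must have equal length")
        if np.any(np.diff(self.dose_axis) <= 0):
            raise ValueError("dose_axis must be strictly increasing")
        if np.any(np.diff(self.volume_at_least) > 1e-9):
            raise ValueError("volume_at_least must be monotone non-increasing")

    @property
    def total_volume(self) -> float:
        return float(self.volume_at_least[0])


@dataclass
class DoseMetrics:
    """Summary dosimetric metrics for one structure (all doses in cGy)."""

    structure: str
    d_min: float
    d_max: float
    d_mean: float
    d_median: float
    d_mode: float
    d_std: float
    d2: float
    d50: float
    d98: float
    ci: float | None = None
    gm: float | None = None
    vx: dict[float, float] = field(default_factory=dict)


@dataclass
class HomogeneityResult:
    passed: bool
    lower_margin: float  # (near_min - prescription) / prescription, signed
    upper_margin: float  # (near_max - prescription) / prescription, signed
    near_min: float
    near_max: float


def _masked_doses(grid: DoseGrid, mask: StructureMask) -> np.ndarray:
    mask.check_congruent(grid)
    if mask.is_empty():
        raise ValueError(f"structure {mask.name!r} is empty: DVH/metrics undefined")
    return grid.values[mask.voxels]


def grid_to_differential_dvh(
    grid: DoseGrid,
    mask: StructureMask,
    bin_width: float = DEFAULT_BIN_WIDTH_CGY,
) -> DifferentialDVH:
    """Histogram the masked voxel doses into fixed-width bins.

    Bins cover [0, max masked dose]; the sum of bin volumes equals the
    masked volume exactly (each voxel lands in exactly one bin).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    doses = _masked_doses(grid, mask)
    n_bins = max(int(np.floor(doses.max() / bin_width)) + 1, 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    return DifferentialDVH(edges, counts * mask.voxel_volume_cc, mask.name)


def differential_to_cumulative(dvh: DifferentialDVH) -> CumulativeDVH:
    """Convert to a cumulative DVH via suffix sums over the bins.

    The cumulative curve is tabulated at the bin lower edges (every dose in
    bin i is >= its lower edge) plus a terminal zero at the last edge.
    """
    suffix = np.concatenate([np.cumsum(dvh.bin_volume[::-1])[::-1], [0.0]])
    return CumulativeDVH(dvh.bin_edges.copy(), suffix, dvh.structure)


def volume_at_dose(cdvh: CumulativeDVH, dose: float, relative: bool = True) -> float:
    """Volume receiving at least ``dose``, linearly interpolated.

    Returns percent of total volume when ``relative`` (default), else cc.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    axis, vol = cdvh.dose_axis, cdvh.volume_at_least
    if dose <= axis[0]:
        v = vol[0]
    elif dose >= axis[-1]:
        v = vol[-1]
    else:
        v = float(np.interp(dose, axis, vol))
    return 100.0 * v / cdvh.total_volume if relative else float(v)


def dose_at_volume(cdvh: CumulativeDVH, volume_percent: float) -> float:
    """Dose D such that ``volume_percent`` of the structure receives >= D.

    Linear interpolation between tabulated points; on plateaus the lowest
    dose attaining the volume level is returned.
    """
    if not 0 < volume_percent <= 100:
        raise ValueError(f"volume_percent must be in (0, 100], got {volume_percent}")
    target = volume_percent / 100.0 * cdvh.total_volume
    axis, vol = cdvh.dose_axis, cdvh.volume_at_least
    if target >= vol[0] - 1e-12:
        # full-volume level: end of the leading total-volume plateau
        return float(axis[np.nonzero(vol >= vol[0] - 1e-12)[0][-1]])
    # first index where the curve has dropped to (or below) the target
    i = int(np.argmax(vol <= target + 1e-12))
    if vol[i] >= target - 1e-12:  # exact hit, possibly a plateau: lowest dose wins
        return float(axis[i])
    d0, d1 = axis[i - 1], axis[i]
    v0, v1 = vol[i - 1], vol[i]
    return float(d0 + (v0 - target) / (v0 - v1) * (d1 - d0))


def summary_metrics(
    grid: DoseGrid,
    mask: StructureMask,
    bin_width: float = DEFAULT_BIN_WIDTH_CGY,
    vx_thresholds: tuple[float, ...] = (),
) -> DoseMetrics:
    """All voxel-list summary statistics plus DVH-derived D2/D50/D98 and Vx.

    The mode is the centre of the most occupied differential-DVH bin; the
    standard deviation is the population estimator.
    """
    doses = _masked_doses(grid, mask)
    ddvh = grid_to_differential_dvh(grid, mask, bin_width)
    cdvh = differential_to_cumulative(ddvh)
    return DoseMetrics(
        structure=mask.name,
        d_min=float(doses.min()),
        d_max=float(doses.max()),
        d_mean=float(doses.mean()),
        d_median=float(np.median(doses)),
        d_mode=float(ddvh.bin_centers[int(np.argmax(ddvh.bin_volume))]),
        d_std=float(doses.std(ddof=0)),
        d2=dose_at_volume(cdvh, 2.0),
        d50=dose_at_volume(cdvh, 50.0),
        d98=dose_at_volume(cdvh, 98.0),
        vx={float(t): volume_at_dose(cdvh, float(t)) for t in vx_thresholds},
    )


def conformity_index(
    grid: DoseGrid,
    target: StructureMask,
    prescription: float,
    variant: str = "rtog",
    body: StructureMask | None = None,
) -> float:
    """Conformity of the prescription isodose to the target.

    ``rtog``: V_prescription / V_target (ideal 1, >1 means spill).
    ``paddick``: (V_target∩prescription)^2 / (V_target * V_prescription),
    in (0, 1] with 1 iff the isodose region equals the target.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    target.check_congruent(grid)
    iso = grid.values >= prescription
    if body is not None:
        body.check_congruent(grid)
        iso &= body.voxels
    v_iso = int(iso.sum())
    v_target = int(target.voxels.sum())
    if v_iso == 0:
        raise ValueError("prescription isodose volume is empty")
    if v_target == 0:
        raise ValueError(f"target {target.name!r} is empty")
    if variant == "rtog":
        return v_iso / v_target
    if variant == "paddick":
        v_both = int((iso & target.voxels).sum())
        return v_both**2 / (v_target * v_iso)
    raise ValueError(f"unknown conformity variant {variant!r}")


def _equivalent_sphere_radius_cm(volume_cc: float) -> float:
    return (3.0 * volume_cc / (4.0 * np.pi)) ** (1.0 / 3.0)


def gradient_measure(
    grid: DoseGrid,
    body: StructureMask,
    prescription: float,
) -> float:
    """Dose falloff measure in cm.

    Difference of equivalent-sphere radii of the 50% and 100% prescription
    isodose volumes inside the body.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    body.check_congruent(grid)
    vv = body.voxel_volume_cc
    v100 = int((body.voxels & (grid.values >= prescription)).sum()) * vv
    v50 = int((body.voxels & (grid.values >= 0.5 * prescription)).sum()) * vv
    if v100 <= 0:
        raise ValueError("100% prescription isodose volume is empty")
    return _equivalent_sphere_radius_cm(v50) - _equivalent_sphere_radius_cm(v100)


def homogeneity_check(
    metrics: DoseMetrics,
    prescription: float,
    lower: float = -0.05,
    upper: float = 0.07,
) -> HomogeneityResult:
    """ICRU62-style homogeneity gate: near-min/near-max within [-5%, +7%].

    Near-min and near-max are D98% and D2% respectively.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    near_min, near_max = metrics.d98, metrics.d2
    lower_margin = (near_min - prescription) / prescription
    upper_margin = (near_max - prescription) / prescription
    passed = (lower_margin >= lower) and (upper_margin <= upper)
    return HomogeneityResult(passed, lower_margin, upper_margin, near_min, near_max)
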