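"""Synthetic two-reporter thymus sections and light-sheet stacks.

The generator emulates cryosections (and cleared-organ stacks) of a thymus in
which every thymic epithelial cell (TEC) carries a nuclear fluorescent
reporter, the way Foxn1-promoter-driven double-transgenic lines mark TEC
nuclei.  A section consists of an outer, thymocyte-dense cortex and an inner,
sparser medulla; TEC nuclei appear as bright Gaussian blobs in the
``nuclear_reporter`` channel, while the ``dapi`` channel contains every
nucleus (TECs plus thymocytes).  All placements are recorded as ground truth
so downstream counting, segmentation and morphometry are testable without any
real data.

Coordinates are physical micrometres with the origin at the image corner;
pixel centres sit at ``(i + 0.5) * pixel_size``.  Counts use half-open image
bounds.  Rendering is a pure function of ``(scenario, size, seed)``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TissueScenario",
    "SectionImage",
    "GroundTruth",
    "PackingError",
    "AGE_PRESETS",
    "make_scenario",
    "render_section",
    "render_stack",
    "render_z_merge_pair",
]

# Label encoding shared with the segment module (bit-exact in TIFF output).
OUTSIDE, CORTEX, MEDULLA = 0, 1, 2
LABEL_NAMES = {OUTSIDE: "outside", CORTEX: "cortex", MEDULLA: "medulla"}

# Intensity model: arbitrary units, uniform background, blobs peaking at
# 10x background, Poisson shot noise.
BACKGROUND_MEAN = 100.0
BLOB_PEAK_FACTOR = 10.0

# Default optics: widefield sections at 0.645 um/pixel; light-sheet stacks
# at 0.229 um/pixel laterally and 0.589 um/pixel axially.
PIXEL_SIZE_2D = 0.645
PIXEL_SIZE_3D_XY = 0.229
PIXEL_SIZE_3D_Z = 0.589

THYMOCYTE_DIAMETER_UM = 3.5


class PackingError(ValueError):
    """Requested point density is infeasible under the hard-core constraint."""


@dataclass(frozen=True)
class TissueScenario:
    """Parameters of one developmental stage of the thymus.

    Densities are areal counts per 10^4 um^2 as measured in 8-um cryosections.
    ``cortical_ti`` / ``medullary_ti`` are reference thymopoietic indices
    (thymocytes per TEC) for the stage; they parameterise the morphometry and
    reconciliation steps, not the rendered images (see docs/methods.md for why
    thymocyte *densities* are independent generator parameters).
    """

    age_label: str
    cortical_tec_density: float  # TECs per 10^4 um^2
    medullary_tec_density: float  # TECs per 10^4 um^2
    cortex_area_fraction: float  # fraction of tissue area in [0, 1]
    thymocyte_density_cortex: float  # nuclei per 10^4 um^2
    thymocyte_density_medulla: float  # nuclei per 10^4 um^2
    organ_volume: float  # ul
    section_thickness: float = 8.0  # um
    mean_nuclear_diameter: float = 6.0  # um (TEC nuclei)
    foxn1_negative_fraction: float = 0.0  # TECs dark in the reporter channel
    cortical_ti: float | None = None  # reference thymocytes per cortical TEC
    medullary_ti: float | None = None  # reference thymocytes per medullary TEC

    def __post_init__(self) -> None:
        if min(self.cortical_tec_density, self.medullary_tec_density,
               self.thymocyte_density_cortex, self.thymocyte_density_medulla) < 0:
            raise ValueError("densities must be >= 0")
        if not 0.0 <= self.cortex_area_fraction <= 1.0:
            raise ValueError("cortex_area_fraction must lie in [0, 1]")
        if self.organ_volume <= 0:
            raise ValueError("organ_volume must be > 0")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be > 0")
        if not 0.0 <= self.foxn1_negative_fraction <= 1.0:
            raise ValueError("foxn1_negative_fraction must lie in [0, 1]")

    def replace(self, **kwargs) -> "TissueScenario":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TissueScenario":
        return cls(**d)


# Printed stage parameters where the source study provides them; remaining
# values (thymocyte densities, embryonic reference TIs, E15.5 volume) are
# generator choices documented in docs/methods.md.
AGE_PRESETS: dict[str, TissueScenario] = {
    "E15.5": TissueScenario(
        age_label="E15.5", cortical_tec_density=13.0, medullary_tec_density=23.0,
        cortex_area_fraction=0.84, thymocyte_density_cortex=200.0,
        thymocyte_density_medulla=50.0, organ_volume=1.1,
        cortical_ti=8.0, medullary_ti=1.6),
    "E16.5": TissueScenario(
        age_label="E16.5", cortical_tec_density=11.0, medullary_tec_density=20.0,
        cortex_area_fraction=0.82, thymocyte_density_cortex=210.0,
        thymocyte_density_medulla=52.0, organ_volume=2.1,
        cortical_ti=12.0, medullary_ti=2.4),
    "P0": TissueScenario(
        age_label="P0", cortical_tec_density=4.0, medullary_tec_density=9.0,
        cortex_area_fraction=0.80, thymocyte_density_cortex=230.0,
        thymocyte_density_medulla=55.0, organ_volume=10.6,
        cortical_ti=32.3, medullary_ti=6.46),
    "P10": TissueScenario(
        age_label="P10", cortical_tec_density=0.9, medullary_tec_density=5.0,
        cortex_area_fraction=0.85, thymocyte_density_cortex=250.0,
        thymocyte_density_medulla=60.0, organ_volume=55.5,
        cortical_ti=100.0, medullary_ti=20.0),
    "P28": TissueScenario(
        age_label="P28", cortical_tec_density=0.7, medullary_tec_density=4.0,
        cortex_area_fraction=0.82, thymocyte_density_cortex=250.0,
        thymocyte_density_medulla=60.0, organ_volume=130.3,
        foxn1_negative_fraction=0.189, cortical_ti=120.0, medullary_ti=24.0),
}


def make_scenario(age_label: str, **overrides) -> TissueScenario:
    """Return the preset scenario for a developmental stage.

    ``age_label`` must be one of the presets (E15.5, E16.5, P0, P10, P28) or
    ``"custom"``, in which case every parameter must be given explicitly as a
    keyword argument.  Presets may be partially overridden via keywords.
    """
    if age_label == "custom":
        return TissueScenario(age_label="custom", **overrides)
    try:
        preset = AGE_PRESETS[age_label]
    except KeyError:
        valid = ", ".join(list(AGE_PRESETS) + ["custom"])
        raise ValueError(
            f"unknown age preset {age_label!r}; valid presets: {valid}") from None
    return preset.replace(**overrides) if overrides else preset


@dataclass
class SectionImage:
    """Multi-channel 2D or 3D fluorescence image with physical pixel sizes.

    ``channels`` maps a role name (``nuclear_reporter``, ``cytoplasm_reporter``,
    ``dapi``, ...) to an intensity array; all channels share one shape.  2D
    arrays are ``(ny, nx)``; 3D stacks are ``(nz, ny, nx)``.
    """

    channels: dict[str, np.ndarray]
    pixel_size_xy: float  # um / pixel
    pixel_size_z: float | None = None  # um / pixel, stacks only
    thickness: float | None = None  # physical section thickness, um

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree in shape: {shapes}")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be > 0")
        if self.pixel_size_z is not None and self.pixel_size_z <= 0:
            raise ValueError("pixel_size_z must be > 0")

    @property
    def is_3d(self) -> bool:
        return next(iter(self.channels.values())).ndim == 3

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def extent_um(self) -> tuple[float, ...]:
        """Physical size along each axis, matching array axis order."""
        shp = self.shape
        if self.is_3d:
            return (shp[0] * self.pixel_size_z, shp[1] * self.pixel_size_xy,
                    shp[2] * self.pixel_size_xy)
        return (shp[0] * self.pixel_size_xy, shp[1] * self.pixel_size_xy)

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel {role!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass
class GroundTruth:
    """True nuclear placements and compartment map backing a rendered image.

    ``tec_centroids`` / ``thymocyte_centroids`` are DataFrames with columns
    ``x_um, y_um[, z_um], compartment``; ``compartment_map`` is the 2D label
    image {0 outside, 1 cortex, 2 medulla} at the section's xy resolution.
    ``metadata`` records designed hard cases (e.g. ``z_merge_pairs``).
    """

    tec_centroids: pd.DataFrame
    thymocyte_centroids: pd.DataFrame
    compartment_map: np.ndarray
    pixel_size_xy: float
    metadata: dict = field(default_factory=dict)

    @property
    def tec_count(self) -> int:
        return len(self.tec_centroids)

    def centroid_table(self) -> pd.DataFrame:
        """All centroids, one row per nucleus, with a ``population`` column."""
        tec = self.tec_centroids.assign(population="tec")
        thy = self.thymocyte_centroids.assign(population="thymocyte")
        return pd.concat([tec, thy], ignore_index=True)

    def compartment_areas_um2(self) -> dict[str, float]:
        px_area = self.pixel_size_xy ** 2
        return {
            name: float(np.count_nonzero(self.compartment_map == lab)) * px_area
            for lab, name in LABEL_NAMES.items()
        }


# ---------------------------------------------------------------------------
# geometry

def _smooth_radial_profile(rng: np.random.Generator, n_theta: int = 720,
                           amplitude: float = 0.10, n_modes: int = 4) -> np.ndarray:
    """Multiplicative radial perturbation r(theta)/r0, low-frequency and smooth."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    prof = np.ones(n_theta)
    for k in range(2, 2 + n_modes):
        amp = amplitude * rng.uniform(0.2, 1.0) / n_modes * 2.0
        prof += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return prof


def _compartment_map_2d(shape_px: tuple[int, int], pixel_size: float,
                        cortex_fraction: float, rng: np.random.Generator,
                        fill_field: bool = False) -> np.ndarray:
    """Tissue ellipse (or full field) with a smoothed star-shaped inner medulla.

    The medullary radius is rescaled iteratively so the realized medulla area
    fraction of tissue matches ``1 - cortex_fraction`` within 2%.
    """
    ny, nx = shape_px
    yy = (np.arange(ny) + 0.5) * pixel_size
    xx = (np.arange(nx) + 0.5) * pixel_size
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    cy, cx = ny * pixel_size / 2.0, nx * pixel_size / 2.0
    a, b = 0.46 * nx * pixel_size, 0.46 * ny * pixel_size  # semi-axes
    if fill_field:
        tissue = np.ones(shape_px, dtype=bool)
        a, b = 0.9 * cx, 0.9 * cy
    else:
        tissue = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0

    labels = np.full(shape_px, OUTSIDE, dtype=np.uint8)
    labels[tissue] = CORTEX
    medulla_fraction = 1.0 - cortex_fraction
    if medulla_fraction <= 0.0:
        return labels
    tissue_area = int(np.count_nonzero(tissue))
    if medulla_fraction >= 1.0:
        labels[tissue] = MEDULLA
        return labels

    prof = _smooth_radial_profile(rng)
    n_theta = prof.size
    theta = np.arctan2(Y - cy, X - cx)
    r = np.hypot(X - cx, Y - cy)
    idx = ((theta % (2 * np.pi)) / (2 * np.pi) * n_theta).astype(int) % n_theta
    r_profile = prof[idx]

    # mean radius for the target area, then fix up against the discrete mask
    R = math.sqrt(medulla_fraction * tissue_area * pixel_size ** 2 / math.pi)
    R = min(R, 0.85 * min(a, b))
    target = medulla_fraction * tissue_area
    for _ in range(6):
        medulla = tissue & (r <= R * r_profile)
        realized = int(np.count_nonzero(medulla))
        if realized > 0 and abs(realized - target) / target <= 0.005:
            break
        scale = math.sqrt(target / max(realized, 1))
        R = min(R * scale, 0.9 * min(a, b))
    labels[medulla] = MEDULLA
    return labels


# ---------------------------------------------------------------------------
# hard-core point placement

def _hardcore_sample(rng: np.random.Generator, n: int, in_region,
                     bounds_um: np.ndarray, min_sep: float,
                     density_per_um: float) -> np.ndarray:
    """Place ``n`` points uniformly in a region with pairwise separation
    >= ``min_sep`` (hard-core thinning of a binomial/Poisson process).

    ``in_region(pts) -> bool mask`` restricts candidates; ``bounds_um`` is the
    physical extent per coordinate axis.  Uses a spatial hash grid, so cost is
    ~O(n).  Raises :class:`PackingError` when the request is clearly beyond the
    packing limit or placement stalls.
    """
    dim = bounds_um.size
    if n == 0:
        return np.empty((0, dim))
    if min_sep > 0:
        # hexagonal/ sphere packing bound; refuse anything past half of it
        if dim == 2:
            limit = 0.9069 / (math.pi / 4.0 * min_sep ** 2)
        else:
            limit = 0.7405 / (math.pi / 6.0 * min_sep ** 3)
        if density_per_um > 0.55 * limit:
            raise PackingError(
                f"requested density {density_per_um:.4g}/um^{dim} exceeds ~55% of "
                f"the hard-core packing limit {limit:.4g}/um^{dim} "
                f"for min separation {min_sep} um")
    cell = max(min_sep, 1e-6)
    grid: dict[tuple, list[int]] = {}
    pts = np.empty((n, dim))
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 2000
    neighbor_offsets = np.array(
        np.meshgrid(*([[-1, 0, 1]] * dim), indexing="ij")).reshape(dim, -1).T
    min_sep2 = min_sep ** 2
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"placed only {placed}/{n} points after {attempts} attempts; "
                f"density infeasible under min separation {min_sep} um")
        cand = rng.uniform(0.0, bounds_um)
        if not in_region(cand[None, :])[0]:
            continue
        key = tuple((cand // cell).astype(int))
        ok = True
        if min_sep > 0:
            for off in neighbor_offsets:
                for j in grid.get(tuple(key + off), ()):
                    d2 = float(np.sum((pts[j] - cand) ** 2))
                    if d2 < min_sep2:
                        ok = False
                        break
                if not ok:
                    break
        if ok:
            pts[placed] = cand
            grid.setdefault(key, []).append(placed)
            placed += 1
    return pts


def _place_population(rng: np.random.Generator, density_per_1e4um2: float,
                      labels: np.ndarray, compartment: int, pixel_size: float,
                      min_sep: float, extent_um: tuple[float, float]) -> np.ndarray:
    """Poisson-distributed count at the compartment areal density, hard-core
    placed inside that compartment.  Returns (n, 2) array of (x_um, y_um)."""
    area_um2 = float(np.count_nonzero(labels == compartment)) * pixel_size ** 2
    if area_um2 == 0.0 or density_per_1e4um2 == 0.0:
        return np.empty((0, 2))
    lam = density_per_1e4um2 / 1e4 * area_um2
    n = int(rng.poisson(lam))

    def in_region(xy: np.ndarray) -> np.ndarray:
        ix = np.clip((xy[:, 0] / pixel_size).astype(int), 0, labels.shape[1] - 1)
        iy = np.clip((xy[:, 1] / pixel_size).astype(int), 0, labels.shape[0] - 1)
        return labels[iy, ix] == compartment

    bounds = np.array([extent_um[1], extent_um[0]])  # (x, y) order
    return _hardcore_sample(rng, n, in_region, bounds, min_sep,
                            density_per_1e4um2 / 1e4)


# ---------------------------------------------------------------------------
# rendering

def _stamp_blobs_2d(canvas: np.ndarray, xy_um: np.ndarray, amplitudes,
                    sigma_um: float, pixel_size: float) -> None:
    """Add Gaussian blobs at subpixel centres (in place)."""
    if len(xy_um) == 0:
        return
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(xy_um),))
    s = sigma_um / pixel_size
    r = max(int(math.ceil(3.0 * s)), 2)
    ny, nx = canvas.shape
    for (x, y), amp in zip(xy_um, amplitudes):
        px, py = x / pixel_size - 0.5, y / pixel_size - 0.5
        cx, cy = int(round(px)), int(round(py))
        x0, x1 = max(cx - r, 0), min(cx + r + 1, nx)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.exp(-((np.arange(x0, x1) - px) ** 2) / (2 * s * s))
        gy = np.exp(-((np.arange(y0, y1) - py) ** 2) / (2 * s * s))
        canvas[y0:y1, x0:x1] += amp * gy[:, None] * gx[None, :]


def _stamp_blobs_3d(canvas: np.ndarray, xyz_um: np.ndarray, amplitudes,
                    sigma_xy_um: float, sigma_z_um: float,
                    psz_xy: float, psz_z: float) -> None:
    if len(xyz_um) == 0:
        return
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(xyz_um),))
    sx = sigma_xy_um / psz_xy
    sz = sigma_z_um / psz_z
    rx = max(int(math.ceil(3.0 * sx)), 2)
    rz = max(int(math.ceil(3.0 * sz)), 2)
    nz, ny, nx = canvas.shape
    for (x, y, z), amp in zip(xyz_um, amplitudes):
        px, py, pz = x / psz_xy - 0.5, y / psz_xy - 0.5, z / psz_z - 0.5
        cx, cy, cz = int(round(px)), int(round(py)), int(round(pz))
        x0, x1 = max(cx - rx, 0), min(cx + rx + 1, nx)
        y0, y1 = max(cy - rx, 0), min(cy + rx + 1, ny)
        z0, z1 = max(cz - rz, 0), min(cz + rz + 1, nz)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        gx = np.exp(-((np.arange(x0, x1) - px) ** 2) / (2 * sx * sx))
        gy = np.exp(-((np.arange(y0, y1) - py) ** 2) / (2 * sx * sx))
        gz = np.exp(-((np.arange(z0, z1) - pz) ** 2) / (2 * sz * sz))
        canvas[z0:z1, y0:y1, x0:x1] += (
            amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :])


def _labels_at(labels: np.ndarray, xy_um: np.ndarray, pixel_size: float) -> np.ndarray:
    if len(xy_um) == 0:
        return np.empty(0, dtype=np.uint8)
    ix = np.clip((xy_um[:, 0] / pixel_size).astype(int), 0, labels.shape[1] - 1)
    iy = np.clip((xy_um[:, 1] / pixel_size).astype(int), 0, labels.shape[0] - 1)
    return labels[iy, ix]


def _centroid_frame(xy: np.ndarray, labels: np.ndarray, pixel_size: float,
                    z: np.ndarray | None = None) -> pd.DataFrame:
    comp = [LABEL_NAMES[int(v)] for v in _labels_at(labels, xy, pixel_size)]
    data = {"x_um": xy[:, 0] if len(xy) else np.empty(0),
            "y_um": xy[:, 1] if len(xy) else np.empty(0)}
    if z is not None:
        data["z_um"] = z
    data["compartment"] = comp
    return pd.DataFrame(data)


def render_section(scenario: TissueScenario,
                   field_size: tuple[float, float] = (500.0, 500.0),
                   seed: int = 0,
                   pixel_size: float = PIXEL_SIZE_2D,
                   fill_field: bool = False,
                   ) -> tuple[SectionImage, GroundTruth]:
    """Render one synthetic cryosection plus its ground truth.

    ``field_size`` is (width, height) in um.  TEC nuclei are hard-core placed
    (minimum separation = mean nuclear diameter) at the per-compartment
    densities, realized counts Poisson around density x area; thymocyte nuclei
    likewise in the DAPI channel.  The nuclear-reporter channel carries only
    reporter-positive TEC nuclei.  With ``fill_field`` the tissue occupies the
    whole frame (no background margin) — convenient for density calibration.
    """
    if field_size[0] <= 0 or field_size[1] <= 0:
        raise ValueError("field_size must be positive")
    rng = np.random.default_rng(seed)
    nx = int(round(field_size[0] / pixel_size))
    ny = int(round(field_size[1] / pixel_size))
    labels = _compartment_map_2d((ny, nx), pixel_size,
                                 scenario.cortex_area_fraction, rng,
                                 fill_field=fill_field)
    extent = (ny * pixel_size, nx * pixel_size)

    tec_sigma = scenario.mean_nuclear_diameter / 4.0
    thy_sigma = THYMOCYTE_DIAMETER_UM / 4.0

    tec_xy = np.concatenate([
        _place_population(rng, scenario.cortical_tec_density, labels, CORTEX,
                          pixel_size, scenario.mean_nuclear_diameter, extent),
        _place_population(rng, scenario.medullary_tec_density, labels, MEDULLA,
                          pixel_size, scenario.mean_nuclear_diameter, extent),
    ])
    thy_xy = np.concatenate([
        _place_population(rng, scenario.thymocyte_density_cortex, labels, CORTEX,
                          pixel_size, THYMOCYTE_DIAMETER_UM, extent),
        _place_population(rng, scenario.thymocyte_density_medulla, labels,
                          MEDULLA, pixel_size, THYMOCYTE_DIAMETER_UM, extent),
    ])

    # reporter-negative TECs stay visible in DAPI but not the reporter channel
    reporter_on = rng.random(len(tec_xy)) >= scenario.foxn1_negative_fraction

    amp = BACKGROUND_MEAN * (BLOB_PEAK_FACTOR - 1.0)
    nuclear = np.full((ny, nx), BACKGROUND_MEAN)
    _stamp_blobs_2d(nuclear, tec_xy[reporter_on], amp, tec_sigma, pixel_size)

    dapi = np.full((ny, nx), BACKGROUND_MEAN)
    _stamp_blobs_2d(dapi, thy_xy, amp, thy_sigma, pixel_size)
    _stamp_blobs_2d(dapi, tec_xy, amp, tec_sigma, pixel_size)

    # diffuse cytoplasmic reporter: blurred TEC presence, no reticular detail
    cyto = np.full((ny, nx), BACKGROUND_MEAN)
    _stamp_blobs_2d(cyto, tec_xy[reporter_on], amp / 4.0,
                    2.0 * tec_sigma, pixel_size)

    channels = {
        "nuclear_reporter": rng.poisson(nuclear).astype(np.float32),
        "cytoplasm_reporter": rng.poisson(cyto).astype(np.float32),
        "dapi": rng.poisson(dapi).astype(np.float32),
    }
    image = SectionImage(channels=channels, pixel_size_xy=pixel_size,
                         thickness=scenario.section_thickness)
    truth = GroundTruth(
        tec_centroids=_centroid_frame(tec_xy, labels, pixel_size),
        thymocyte_centroids=_centroid_frame(thy_xy, labels, pixel_size),
        compartment_map=labels, pixel_size_xy=pixel_size,
        metadata={"seed": seed, "age_label": scenario.age_label,
                  "reporter_negative_tecs": int(np.sum(~reporter_on))})
    return image, truth


def _find_z_merge_pairs(xyz: np.ndarray, sigma_xy: float,
                        sigma_z: float) -> list[tuple[int, int]]:
    """Index pairs closer than the blur scales (designed z-merge hard cases)."""
    pairs = []
    for i in range(len(xyz)):
        for j in range(i + 1, len(xyz)):
            dxy = math.hypot(xyz[i, 0] - xyz[j, 0], xyz[i, 1] - xyz[j, 1])
            dz = abs(xyz[i, 2] - xyz[j, 2])
            if dxy < 2.0 * sigma_xy and dz < 2.0 * sigma_z:
                pairs.append((i, j))
    return pairs


def render_stack(scenario: TissueScenario,
                 volume: tuple[float, float, float] = (100.0, 100.0, 50.0),
                 seed: int = 0,
                 pixel_size_xy: float = PIXEL_SIZE_3D_XY,
                 pixel_size_z: float = PIXEL_SIZE_3D_Z,
                 tec_density_per_1e4um3: float | None = None,
                 ) -> tuple[SectionImage, GroundTruth]:
    """Render an anisotropic 3D light-sheet-like stack of TEC nuclei.

    ``volume`` is (x, y, z) extent in um.  The TEC volumetric density defaults
    to the scenario's areal density divided by the effective section thickness
    (thickness + nuclear diameter), the same convention the stereology module
    inverts; it can be overridden in nuclei per 10^4 um^3.  Axial blur is twice
    the lateral blur, emulating the light-sheet z-merging failure mode.
    Thymocytes are omitted (reporter channel only).
    """
    if min(volume) <= 0:
        raise ValueError("volume must be positive")
    rng = np.random.default_rng(seed)
    wx, wy, wz = volume
    nx = int(round(wx / pixel_size_xy))
    ny = int(round(wy / pixel_size_xy))
    nz = int(round(wz / pixel_size_z))
    labels = _compartment_map_2d((ny, nx), pixel_size_xy,
                                 scenario.cortex_area_fraction, rng)
    if tec_density_per_1e4um3 is None:
        t_eff = scenario.section_thickness + scenario.mean_nuclear_diameter
        # tissue-average areal density -> volumetric
        f_c = scenario.cortex_area_fraction
        areal = (scenario.cortical_tec_density * f_c
                 + scenario.medullary_tec_density * (1.0 - f_c))
        tec_density_per_1e4um3 = areal / t_eff

    tissue_area = float(np.count_nonzero(labels != OUTSIDE)) * pixel_size_xy ** 2
    lam = tec_density_per_1e4um3 / 1e4 * tissue_area * (nz * pixel_size_z)
    n = int(rng.poisson(lam)) if lam > 0 else 0

    def in_region(xyz: np.ndarray) -> np.ndarray:
        ix = np.clip((xyz[:, 0] / pixel_size_xy).astype(int), 0, nx - 1)
        iy = np.clip((xyz[:, 1] / pixel_size_xy).astype(int), 0, ny - 1)
        return labels[iy, ix] != OUTSIDE

    bounds = np.array([nx * pixel_size_xy, ny * pixel_size_xy, nz * pixel_size_z])
    xyz = _hardcore_sample(rng, n, in_region, bounds,
                           scenario.mean_nuclear_diameter,
                           tec_density_per_1e4um3 / 1e4)

    sigma_xy = scenario.mean_nuclear_diameter / 4.0
    sigma_z = 2.0 * sigma_xy  # light-sheet axial spread
    canvas = np.full((nz, ny, nx), BACKGROUND_MEAN)
    _stamp_blobs_3d(canvas, xyz, BACKGROUND_MEAN * (BLOB_PEAK_FACTOR - 1.0),
                    sigma_xy, sigma_z, pixel_size_xy, pixel_size_z)
    channels = {"nuclear_reporter": rng.poisson(canvas).astype(np.float32)}
    image = SectionImage(channels=channels, pixel_size_xy=pixel_size_xy,
                         pixel_size_z=pixel_size_z)

    xy = xyz[:, :2] if len(xyz) else np.empty((0, 2))
    z = xyz[:, 2] if len(xyz) else np.empty(0)
    truth = GroundTruth(
        tec_centroids=_centroid_frame(xy, labels, pixel_size_xy, z=z),
        thymocyte_centroids=_centroid_frame(
            np.empty((0, 2)), labels, pixel_size_xy, z=np.empty(0)),
        compartment_map=labels, pixel_size_xy=pixel_size_xy,
        metadata={"seed": seed, "age_label": scenario.age_label,
                  "pixel_size_z": pixel_size_z,
                  "z_merge_pairs": _find_z_merge_pairs(xyz, sigma_xy, sigma_z)})
    return image, truth


def render_z_merge_pair(separation_z_um: float = 0.4,
                        volume: tuple[float, float, float] = (40.0, 40.0, 30.0),
                        nuclear_diameter: float = 6.0,
                        seed: int = 0) -> tuple[SectionImage, GroundTruth]:
    """Designed hard case: two nuclei coincident in xy, ``separation_z_um``
    apart in z — closer than the axial blur, so a single blob is rendered.

    The pair is flagged in ``GroundTruth.metadata['z_merge_pairs']``; counting
    software is expected to find one spot and raise its undercount-risk flag.
    """
    rng = np.random.default_rng(seed)
    wx, wy, wz = volume
    nx = int(round(wx / PIXEL_SIZE_3D_XY))
    ny = int(round(wy / PIXEL_SIZE_3D_XY))
    nz = int(round(wz / PIXEL_SIZE_3D_Z))
    cx, cy, cz = wx / 2.0, wy / 2.0, wz / 2.0
    xyz = np.array([[cx, cy, cz - separation_z_um / 2.0],
                    [cx, cy, cz + separation_z_um / 2.0]])
    sigma_xy = nuclear_diameter / 4.0
    sigma_z = 2.0 * sigma_xy
    canvas = np.full((nz, ny, nx), BACKGROUND_MEAN)
    _stamp_blobs_3d(canvas, xyz, BACKGROUND_MEAN * (BLOB_PEAK_FACTOR - 1.0),
                    sigma_xy, sigma_z, PIXEL_SIZE_3D_XY, PIXEL_SIZE_3D_Z)
    channels = {"nuclear_reporter": rng.poisson(canvas).astype(np.float32)}
    image = SectionImage(channels=channels, pixel_size_xy=PIXEL_SIZE_3D_XY,
                         pixel_size_z=PIXEL_SIZE_3D_Z)
    labels = np.full((ny, nx), CORTEX, dtype=np.uint8)
    truth = GroundTruth(
        tec_centroids=_centroid_frame(xyz[:, :2], labels, PIXEL_SIZE_3D_XY,
                                      z=xyz[:, 2]),
        thymocyte_centroids=_centroid_frame(
            np.empty((0, 2)), labels, PIXEL_SIZE_3D_XY, z=np.empty(0)),
        compartment_map=labels, pixel_size_xy=PIXEL_SIZE_3D_XY,
        metadata={"z_merge_pairs": [(0, 1)],
                  "separation_z_um": separation_z_um,
                  "pixel_size_z": PIXEL_SIZE_3D_Z})
    return image, truth
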