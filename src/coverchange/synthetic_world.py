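"""Two-epoch synthetic landscape generator with known ground truth.

Emulates the ingredients of a two-epoch Landsat-style land-cover study:
a spatially clumped seven-class truth map, a pixelwise Markov change
process with a known transition kernel, multiple dated six-band
reflectance scenes per epoch with Gaussian class spectra, cloud discs
with paired shadows encoded in a QA bitmask, a smooth elevation surface,
and nested analysis masks (protected areas, host-plant potential
distribution, and their intersection).

The change process is pixelwise-independent Markov — no spatial
contagion — so the expected transition table equals the kernel weighted
by the epoch-1 composition, which gives every downstream stage an
analytic recovery target.  All randomness flows from a single integer
seed via independent child generators per product, so a bundle is
bit-reproducible.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .compositing import N_BANDS, QA_BITS, SpectralScene
from .raster_core import (
    CLASS_CODES,
    NODATA,
    ClassMap,
    ElevationRaster,
    Grid,
    MaskSet,
    write_class_map,
    write_continuous,
    write_mask,
)

__all__ = [
    "DEFAULT_CLASS_SPECTRA",
    "DEFAULT_TRANSITION_KERNEL",
    "WorldSpec",
    "WorldBundle",
    "generate_truth_map",
    "evolve_truth_map",
    "render_scenes",
    "generate_elevation",
    "generate_masks",
    "generate_world",
    "write_world",
]

K = len(CLASS_CODES)

# Six-band mean reflectance per class (rows = class codes 1..7).  Shapes are
# loosely vegetation / water / soil like — bright soil, dark water with a
# near-zero infrared tail, vegetated classes separated in the middle bands —
# but make no claim to real sensor radiometry.  Pairwise Euclidean
# separations are all > 0.12 so the default noise regime is learnable.
DEFAULT_CLASS_SPECTRA = np.array(
    [
        [0.04, 0.06, 0.05, 0.45, 0.22, 0.10],  # forest_shrubs
        [0.05, 0.08, 0.07, 0.30, 0.14, 0.06],  # mangrove
        [0.22, 0.26, 0.32, 0.38, 0.42, 0.35],  # bare_soil
        [0.08, 0.12, 0.10, 0.22, 0.10, 0.05],  # wetland
        [0.03, 0.05, 0.04, 0.33, 0.16, 0.07],  # pine_forest
        [0.10, 0.14, 0.16, 0.40, 0.30, 0.18],  # agriculture
        [0.06, 0.05, 0.03, 0.02, 0.01, 0.01],  # water
    ]
)

# Default change kernel: high persistence everywhere except the dominant
# signal of the study system — a large agriculture -> forest/shrub flow.
DEFAULT_TRANSITION_KERNEL = np.array(
    [
        # F     M     S     W     P     A     Wa
        [0.96, 0.01, 0.00, 0.01, 0.01, 0.01, 0.00],  # forest_shrubs
        [0.03, 0.94, 0.00, 0.02, 0.00, 0.00, 0.01],  # mangrove
        [0.10, 0.02, 0.80, 0.03, 0.00, 0.04, 0.01],  # bare_soil
        [0.05, 0.04, 0.01, 0.88, 0.00, 0.01, 0.01],  # wetland
        [0.07, 0.00, 0.00, 0.00, 0.92, 0.01, 0.00],  # pine_forest
        [0.35, 0.00, 0.01, 0.01, 0.01, 0.61, 0.01],  # agriculture
        [0.01, 0.01, 0.00, 0.01, 0.00, 0.00, 0.97],  # water
    ]
)

_SHADOW_OFFSET = (12, -12)  # rows down, cols left of the casting cloud


@dataclass
class WorldSpec:
    """Full parameterization of a synthetic two-epoch world."""

    grid: Grid = field(default_factory=lambda: Grid(128, 128))
    class_spectra: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_SPECTRA.copy()
    )
    class_proportions: np.ndarray = field(
        default_factory=lambda: np.full(K, 1.0 / K)
    )
    patch_scale: float = 8.0
    transition_kernel: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION_KERNEL.copy()
    )
    elevation_base: float = 20.0
    elevation_relief: float = 300.0
    elevation_smoothness: float = 16.0
    cloud_fraction: float = 0.15
    cloud_radius_range: tuple[float, float] = (4.0, 12.0)
    protected_fraction: float = 0.17
    od_fraction: float = 0.25
    scenes_per_epoch: int = 3
    noise_sd: float = 0.04
    seed: int = 0
    epoch_labels: tuple[str, str] = ("1985", "2020")
    epoch_windows: tuple[tuple[int, int], tuple[int, int]] = (
        (1984, 1988),
        (2020, 2021),
    )

    def __post_init__(self) -> None:
        self.class_spectra = np.asarray(self.class_spectra, dtype=float)
        self.transition_kernel = np.asarray(self.transition_kernel, dtype=float)
        self.class_proportions = np.asarray(self.class_proportions, dtype=float)
        if self.class_spectra.shape != (K, N_BANDS):
            raise ValueError("class_spectra must be 7 x 6")
        if self.transition_kernel.shape != (K, K):
            raise ValueError("transition_kernel must be 7 x 7")
        _check_row_stochastic(self.transition_kernel)
        if not np.allclose(self.class_proportions.sum(), 1.0, atol=1e-9):
            raise ValueError("class_proportions must sum to 1")
        # mean spectra must be pairwise distinct
        d = np.linalg.norm(
            self.class_spectra[:, None] - self.class_spectra[None, :], axis=-1
        )
        if np.any(d[~np.eye(K, dtype=bool)] == 0):
            raise ValueError("class spectra means must be pairwise distinct")
        if not (0.0 <= self.cloud_fraction <= 1.0):
            raise ValueError("cloud fraction outside [0,1]")
        if self.scenes_per_epoch < 1:
            raise ValueError("scenes_per_epoch must be >= 1")


@dataclass
class WorldBundle:
    """Everything a pipeline run consumes, plus the generating spec."""

    truth_map_1: ClassMap
    truth_map_2: ClassMap
    scenes_1: list[SpectralScene]
    scenes_2: list[SpectralScene]
    elevation: ElevationRaster
    masks: MaskSet
    spec: WorldSpec


def _check_row_stochastic(kernel: np.ndarray) -> None:
    if np.any(kernel < 0) or not np.allclose(kernel.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition kernel must be row-stochastic")


def _smooth_field(grid: Grid, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ~scale."""
    noise = rng.standard_normal(grid.shape)
    if scale > 0:
        field_ = ndimage.gaussian_filter(noise, sigma=scale, mode="wrap")
    else:
        field_ = noise
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_truth_map(spec: WorldSpec, seed: int | None = None) -> ClassMap:
    """Clumped categorical map with near-exact requested class proportions.

    A single smoothed Gaussian field is thresholded at the cumulative
    quantiles of ``class_proportions`` (neutral-landscape style), so the
    realized proportions match the request up to quantile ties and the
    patches have correlation length ``patch_scale``.
    """
    if spec.patch_scale <= 0:
        raise ValueError("patch_scale must be positive")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    field_ = _smooth_field(spec.grid, spec.patch_scale, rng)
    cuts = np.quantile(field_, np.cumsum(spec.class_proportions)[:-1])
    values = np.digitize(field_, cuts) + 1  # codes 1..K
    return ClassMap(spec.grid, values.astype(np.int64), spec.epoch_labels[0])


def evolve_truth_map(
    map1: ClassMap, kernel: np.ndarray, seed: int
) -> ClassMap:
    """Second-epoch map: each valid pixel's class drawn independently from
    the kernel row of its first-epoch class; nodata preserved."""
    kernel = np.asarray(kernel, dtype=float)
    _check_row_stochastic(kernel)
    rng = np.random.default_rng(seed)
    values = map1.values.astype(np.int64)
    out = np.zeros_like(values)
    u = rng.random(values.shape)
    cdf = np.cumsum(kernel, axis=1)
    for code in CLASS_CODES:
        sel = values == code
        if not sel.any():
            continue
        out[sel] = np.searchsorted(cdf[code - 1], u[sel], side="right") + 1
    out = np.minimum(out, K)  # guard float roundoff at u ~ 1
    out[values == NODATA] = NODATA
    return ClassMap(map1.grid, out, "")


_COASTAL_CLASSES = (2, 4, 7)  # mangrove, wetland, water sit near sea level


def generate_elevation(
    spec: WorldSpec, seed: int, class_map: ClassMap | None = None
) -> ElevationRaster:
    """Smooth terrain surface; coastal classes are pinned near sea level.

    Mangrove, wetland, and water occur at low elevation in the landscapes
    this generator emulates — which is exactly the physical premise of
    the elevation post-processing rules downstream.
    """
    rng = np.random.default_rng(seed)
    relief = _smooth_field(spec.grid, spec.elevation_smoothness, rng)
    relief = relief - relief.min()
    values = spec.elevation_base + spec.elevation_relief * relief / max(
        relief.max(), 1e-12
    )
    if class_map is not None:
        coastal = np.isin(class_map.values, _COASTAL_CLASSES)
        values[coastal] = rng.uniform(0.0, 5.0, int(coastal.sum()))
    return ElevationRaster(spec.grid, values)


def _stamp_discs(
    shape: tuple[int, int],
    target_fraction: float,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Union of random discs covering roughly ``target_fraction`` of pixels."""
    mask = np.zeros(shape, dtype=bool)
    if target_fraction <= 0:
        return mask
    n_pix = mask.size
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    for _ in range(10_000):
        if mask.sum() / n_pix >= target_fraction:
            break
        r = rng.uniform(*radius_range)
        cy = rng.uniform(0, shape[0])
        cx = rng.uniform(0, shape[1])
        mask |= (rows - cy) ** 2 + (cols - cx) ** 2 <= r**2
    return mask


def render_scenes(
    class_map: ClassMap, spec: WorldSpec, epoch: int, seed: int
) -> list[SpectralScene]:
    """Dated reflectance scenes for one epoch (0 or 1).

    Per-pixel reflectance is the class mean plus iid Gaussian noise;
    cloud discs and their paired shadows overwrite reflectance (bright
    and dark respectively) and set the corresponding QA bits, and each
    scene's header cloud percentage equals its realized flagged
    fraction.
    """
    if epoch not in (0, 1):
        raise ValueError("epoch must be 0 or 1")
    rng = np.random.default_rng(seed)
    year_lo, year_hi = spec.epoch_windows[epoch]
    mean_img = np.zeros((N_BANDS, *spec.grid.shape))
    for code in CLASS_CODES:
        sel = class_map.values == code
        mean_img[:, sel] = spec.class_spectra[code - 1][:, None]

    scenes: list[SpectralScene] = []
    years = np.linspace(year_lo, year_hi, spec.scenes_per_epoch)
    for i in range(spec.scenes_per_epoch):
        bands = mean_img + rng.normal(0.0, spec.noise_sd, mean_img.shape)
        bands = np.clip(bands, 0.0, 1.0)
        qa = np.zeros(spec.grid.shape, dtype=np.uint16)

        cloud = _stamp_discs(
            spec.grid.shape, spec.cloud_fraction, spec.cloud_radius_range, rng
        )
        shadow = np.roll(cloud, _SHADOW_OFFSET, axis=(0, 1)) & ~cloud
        bands[:, cloud] = rng.uniform(0.85, 1.0, (N_BANDS, int(cloud.sum())))
        bands[:, shadow] = rng.uniform(0.0, 0.05, (N_BANDS, int(shadow.sum())))
        qa[cloud] |= 1 << QA_BITS["cloud"]
        qa[shadow] |= 1 << QA_BITS["cloud_shadow"]

        flagged = cloud.mean()  # header counts cloud cover; shadows only flag QA
        date = _dt.date(int(round(years[i])), 1 + (i * 5) % 12, 15)
        scenes.append(
            SpectralScene(
                grid=spec.grid,
                bands=bands,
                qa=qa,
                acquisition_date=date,
                cloud_cover_percent=100.0 * float(flagged),
            )
        )
    return scenes


def generate_masks(
    map1: ClassMap, elevation: ElevationRaster, spec: WorldSpec, seed: int
) -> MaskSet:
    """Nested analysis masks.

    ``protected`` is a smoothed-blob mask covering ``protected_fraction``
    of the region; ``od`` (host-plant potential distribution) is a
    smoothed suitability field with a bonus on forest/shrub pixels,
    thresholded to ``od_fraction``; their intersection completes the set.
    """
    rng = np.random.default_rng(seed)
    full = np.ones(spec.grid.shape, dtype=bool)

    f_prot = _smooth_field(spec.grid, spec.patch_scale * 2, rng)
    protected = f_prot >= np.quantile(f_prot, 1.0 - spec.protected_fraction)

    f_od = _smooth_field(spec.grid, spec.patch_scale * 2, rng)
    f_od = f_od + 0.8 * (map1.values == 1)  # bias toward forest_shrubs
    od = f_od >= np.quantile(f_od, 1.0 - spec.od_fraction)

    return MaskSet(
        grid=spec.grid,
        full_region=full,
        protected=protected,
        od=od,
        od_in_protected=od & protected,
    )


def generate_world(spec: WorldSpec) -> WorldBundle:
    """Deterministic full bundle; all randomness derives from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]
    map1 = generate_truth_map(spec, seeds[0])
    map1.epoch_label = spec.epoch_labels[0]
    map2 = evolve_truth_map(map1, spec.transition_kernel, seeds[1])
    map2.epoch_label = spec.epoch_labels[1]
    elevation = generate_elevation(spec, seeds[2], map1)
    scenes_1 = render_scenes(map1, spec, 0, seeds[3])
    scenes_2 = render_scenes(map2, spec, 1, seeds[4])
    masks = generate_masks(map1, elevation, spec, seeds[5])
    return WorldBundle(map1, map2, scenes_1, scenes_2, elevation, masks, spec)


def write_world(bundle: WorldBundle, out_dir: str | Path) -> None:
    """Write the bundle as TIFFs plus a YAML spec file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_class_map(bundle.truth_map_1, out / "truth_epoch1.tif")
    write_class_map(bundle.truth_map_2, out / "truth_epoch2.tif")
    write_continuous(
        bundle.elevation.values, bundle.elevation.grid, out / "elevation.tif",
        nodata=bundle.elevation.nodata,
    )
    for name, mask in bundle.masks.items():
        write_mask(mask, bundle.masks.grid, out / f"mask_{name}.tif")
    for label, scenes in (("epoch1", bundle.scenes_1), ("epoch2", bundle.scenes_2)):
        for i, scene in enumerate(scenes):
            write_continuous(
                scene.bands, scene.grid, out / f"scene_{label}_{i:02d}.tif",
                extra_meta={
                    "acquisition_date": scene.acquisition_date.isoformat(),
                    "cloud_cover_percent": scene.cloud_cover_percent,
                },
            )
            write_continuous(
                scene.qa.astype(np.float32), scene.grid,
                out / f"scene_{label}_{i:02d}_qa.tif",
            )
    spec = bundle.spec
    spec_doc = {
        "grid": {"n_rows": spec.grid.n_rows, "n_cols": spec.grid.n_cols,
                 "pixel_size": spec.grid.pixel_size, "origin": list(spec.grid.origin)},
        "class_proportions": spec.class_proportions.tolist(),
        "patch_scale": spec.patch_scale,
        "transition_kernel": spec.transition_kernel.tolist(),
        "cloud_fraction": spec.cloud_fraction,
        "protected_fraction": spec.protected_fraction,
        "od_fraction": spec.od_fraction,
        "scenes_per_epoch": spec.scenes_per_epoch,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "epoch_labels": list(spec.epoch_labels),
    }
    (out / "world_spec.yaml").write_text(yaml.safe_dump(spec_doc, sort_keys=False))
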