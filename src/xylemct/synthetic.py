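"""Ground-truth cross-section and dehydration-experiment simulators.

Synthetic organs are discs (or annuli) of xylem populated with circular
conduits placed by rejection sampling: diameters follow a truncated
lognormal, and each conduit independently draws an embolism-threshold
water potential from a negated Weibull distribution, so the expected
embolised fraction at tension psi is the Weibull CDF. Rendering uses
three gray levels (background, water-filled, air-filled; air darker than
water) plus optional Gaussian pixel noise, matching what the segmentation
stage assumes.

Everything is reproducible: the same (config, psi, seed) yields the same
image and ground truth bit-for-bit, and for a fixed seed the conduit
geometry and thresholds do not depend on psi, so dehydration series share
their geometry and embolise monotonically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import PackingError, ValidationError
from .vulnerability import solve_weibull_parameters

__all__ = [
    "DiameterDistribution",
    "XylemRegion",
    "OrganSimConfig",
    "GroundTruthConduit",
    "GroundTruth",
    "generate_cross_section",
    "generate_final_scan",
    "generate_plc_observations",
    "organ_preset",
    "ORGAN_PRESETS",
]


def _trunc_lognorm_moment(k: int, mu: float, sigma: float,
                          lo: float, hi: float) -> float:
    """k-th raw moment of a lognormal truncated to [lo, hi]."""
    a = (math.log(lo) - mu) / sigma
    b = (math.log(hi) - mu) / sigma
    z = norm.cdf(b) - norm.cdf(a)
    if z < 1e-12:
        # distribution pushed (numerically) entirely past a bound; the
        # conditional moment degenerates to that bound
        return lo**k if mu < math.log(lo) else hi**k
    num = norm.cdf(b - k * sigma) - norm.cdf(a - k * sigma)
    return math.exp(k * mu + 0.5 * k * k * sigma * sigma) * num / z


@dataclass(frozen=True)
class DiameterDistribution:
    """Truncated lognormal conduit-diameter distribution (um)."""

    mu: float
    sigma: float
    min_um: float
    max_um: float
    family: str = "lognormal"

    def __post_init__(self):
        if self.family != "lognormal":
            raise ValidationError("only the lognormal family is implemented")
        if not (0 < self.min_um < self.max_um):
            raise ValidationError("truncation bounds must be positive and ordered")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")

    def moment(self, k: int) -> float:
        return _trunc_lognorm_moment(k, self.mu, self.sigma, self.min_um, self.max_um)

    @property
    def mean_um(self) -> float:
        return self.moment(1)

    @property
    def hydraulic_mean_um(self) -> float:
        """Expected sum(d^5)/sum(d^4) weighting, i.e. m5/m4."""
        return self.moment(5) / self.moment(4)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size)
        have = 0
        while have < size:
            batch = rng.lognormal(self.mu, self.sigma, max(2 * (size - have), 16))
            keep = batch[(batch >= self.min_um) & (batch <= self.max_um)]
            take = min(keep.size, size - have)
            out[have:have + take] = keep[:take]
            have += take
        return out

    @classmethod
    def from_targets(cls, mean_um: float, hydraulic_mean_um: float,
                     min_um: float, max_um: float) -> "DiameterDistribution":
        """Calibrate (mu, sigma) so the truncated mean and hydraulic mean hit targets.

        The hydraulic-to-arithmetic mean ratio pins sigma (it is monotone
        increasing in sigma); mu then shifts the mean at fixed sigma.
        """
        if not (min_um < mean_um < hydraulic_mean_um < max_um):
            raise ValidationError(
                "need min < mean < hydraulic mean < max for calibration")
        target_ratio = hydraulic_mean_um / mean_um

        def ratio_err(sigma: float) -> float:
            # re-solve mu for the mean at this sigma, then compare ratios
            mu = _solve_mu(mean_um, sigma, min_um, max_um)
            d = cls(mu, sigma, min_um, max_um)
            return d.hydraulic_mean_um / d.mean_um - target_ratio

        sigma = brentq(ratio_err, 1e-3, 1.5, xtol=1e-10)
        mu = _solve_mu(mean_um, sigma, min_um, max_um)
        return cls(mu, sigma, min_um, max_um)


def _solve_mu(mean_um: float, sigma: float, lo: float, hi: float) -> float:
    def err(mu: float) -> float:
        return _trunc_lognorm_moment(1, mu, sigma, lo, hi) - mean_um

    centre = math.log(mean_um) - 0.5 * sigma * sigma
    return brentq(err, centre - 4.0, centre + 4.0, xtol=1e-12)


@dataclass(frozen=True)
class XylemRegion:
    """Disc (inner radius 0) or annulus of xylem, in um.

    ``centre_um=None`` places the region at the image centre.
    """

    outer_radius_um: float
    inner_radius_um: float = 0.0
    centre_um: tuple[float, float] | None = None

    def __post_init__(self):
        if self.outer_radius_um <= 0 or self.inner_radius_um < 0:
            raise ValidationError("region radii must be positive/nonnegative")
        if self.inner_radius_um >= self.outer_radius_um:
            raise ValidationError("inner radius must be smaller than outer")

    @property
    def area_mm2(self) -> float:
        return math.pi * (self.outer_radius_um**2 - self.inner_radius_um**2) / 1e6

    def resolve_centre(self, image_size_px: tuple[int, int],
                       pixel_size_um: float) -> tuple[float, float]:
        if self.centre_um is not None:
            return self.centre_um
        h, w = image_size_px
        return ((w - 1) * pixel_size_um / 2.0, (h - 1) * pixel_size_um / 2.0)

    def mask(self, image_size_px: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        cx, cy = self.resolve_centre(image_size_px, pixel_size_um)
        h, w = image_size_px
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = (xx * pixel_size_um - cx) ** 2 + (yy * pixel_size_um - cy) ** 2
        return (r2 <= self.outer_radius_um**2) & (r2 >= self.inner_radius_um**2)


@dataclass(frozen=True)
class OrganSimConfig:
    """Generative parameters for one synthetic organ."""

    organ_label: str
    vessel_density_per_mm2: float
    diameter_dist: DiameterDistribution
    weibull_scale_mpa: float
    weibull_shape: float
    xylem_region: XylemRegion
    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.0
    gray_levels: tuple[float, float, float] = (0.45, 0.75, 0.10)  # bg, water, air
    noise_sd: float = 0.0
    min_wall_um: float | None = None  # None -> 2 px
    seed: int = 0

    def __post_init__(self):
        if self.vessel_density_per_mm2 <= 0:
            raise ValidationError("vessel density must be > 0")
        if self.weibull_scale_mpa <= 0 or self.weibull_shape <= 0:
            raise ValidationError("Weibull scale and shape must be > 0")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel size must be > 0")
        bg, water, air = self.gray_levels
        if not all(0.0 <= g <= 1.0 for g in self.gray_levels):
            raise ValidationError("gray levels must lie in [0, 1]")
        if air >= water:
            raise ValidationError("air-filled gray must be darker than water-filled")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        h, w = self.image_size_px
        if h < 8 or w < 8:
            raise ValidationError("image too small")
        cx, cy = self.xylem_region.resolve_centre(self.image_size_px, self.pixel_size_um)
        extent = self.xylem_region.outer_radius_um
        if (cx - extent < 0 or cy - extent < 0
                or cx + extent > (w - 1) * self.pixel_size_um
                or cy + extent > (h - 1) * self.pixel_size_um):
            raise ValidationError("xylem region does not fit inside the image")
        # mean disc area (incl. half the wall clearance) times density
        wall = self.wall_um
        m1, m2 = self.diameter_dist.moment(1), self.diameter_dist.moment(2)
        packing = (self.vessel_density_per_mm2
                   * math.pi / 4.0 * (m2 + 2 * wall * m1 + wall * wall) / 1e6)
        if packing >= 0.5:
            raise ValidationError(
                f"requested density is incompatible with non-overlap packing "
                f"(estimated packing fraction {packing:.2f} >= 0.5)")

    @property
    def wall_um(self) -> float:
        return (2.0 * self.pixel_size_um if self.min_wall_um is None
                else self.min_wall_um)


@dataclass(frozen=True)
class GroundTruthConduit:
    id: int
    centre_um: tuple[float, float]
    diameter_um: float
    threshold_psi_mpa: float  # negative; conduit is air-filled iff psi <= threshold
    state: str  # at the psi the section was generated for


@dataclass
class GroundTruth:
    conduits: list[GroundTruthConduit]
    xylem_area_mm2: float
    psi_mpa: float = 0.0

    def __len__(self) -> int:
        return len(self.conduits)

    def diameters_um(self, state: str | None = None) -> np.ndarray:
        return np.array([c.diameter_um for c in self.conduits
                         if state is None or c.state == state], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.conduits],
                "x_um": [c.centre_um[0] for c in self.conduits],
                "y_um": [c.centre_um[1] for c in self.conduits],
                "d_um": [c.diameter_um for c in self.conduits],
                "threshold_psi_mpa": [c.threshold_psi_mpa for c in self.conduits],
                "state": [c.state for c in self.conduits],
            }
        )


_MAX_ATTEMPTS_PER_CONDUIT = 3000


def _place_conduits(config: OrganSimConfig, rng: np.random.Generator,
                    n: int) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping circle centres; returns (centres, d)."""
    region = config.xylem_region
    cx, cy = region.resolve_centre(config.image_size_px, config.pixel_size_um)
    wall = config.wall_um
    diameters = np.sort(config.diameter_dist.sample(rng, n))[::-1]  # big first
    centres = np.empty((n, 2))
    attempts = 0
    for i, d in enumerate(diameters):
        r = d / 2.0
        lo = region.inner_radius_um + r if region.inner_radius_um > 0 else 0.0
        hi = region.outer_radius_um - r
        if hi <= lo:
            raise PackingError(i, n, attempts)
        placed = False
        for _ in range(_MAX_ATTEMPTS_PER_CONDUIT):
            attempts += 1
            rad = math.sqrt(rng.uniform(lo * lo, hi * hi))
            theta = rng.uniform(0.0, 2.0 * math.pi)
            p = np.array([cx + rad * math.cos(theta), cy + rad * math.sin(theta)])
            if i:
                gap = (np.hypot(*(centres[:i] - p).T)
                       - diameters[:i] / 2.0 - r - wall)
                if np.min(gap) < 0:
                    continue
            centres[i] = p
            placed = True
            break
        if not placed:
            raise PackingError(i, n, attempts)
    return centres, diameters


def _render(config: OrganSimConfig, centres: np.ndarray, diameters: np.ndarray,
            air: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    bg, water_gray, air_gray = config.gray_levels
    h, w = config.image_size_px
    px = config.pixel_size_um
    img = np.full((h, w), bg, dtype=float)
    for (x, y), d, is_air in zip(centres, diameters, air):
        r = d / 2.0
        c0 = max(int(math.floor((x - r) / px)) - 1, 0)
        c1 = min(int(math.ceil((x + r) / px)) + 2, w)
        r0 = max(int(math.floor((y - r) / px)) - 1, 0)
        r1 = min(int(math.ceil((y + r) / px)) + 2, h)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        inside = (xx * px - x) ** 2 + (yy * px - y) ** 2 <= r * r
        img[r0:r1, c0:c1][inside] = air_gray if is_air else water_gray
    if rng is not None and config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_cross_section(config: OrganSimConfig, psi_mpa: float,
                           seed: int | None = None
                           ) -> tuple[np.ndarray, GroundTruth]:
    """Simulate one cross-section at water potential ``psi_mpa``.

    Conduit count is the configured density times the region area
    (rounded). Each conduit draws its embolism threshold from
    ``-scale * Weibull(shape)`` independently of its diameter and is
    rendered air-filled iff ``psi_mpa <= threshold``. Geometry, thresholds
    and noise depend only on the seed, not on psi.
    """
    if psi_mpa > 0:
        raise ValidationError("psi must be <= 0 (negative MPa convention)")
    region = config.xylem_region
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(config.vessel_density_per_mm2 * region.area_mm2))
    if n == 0:
        truth = GroundTruth([], region.area_mm2, psi_mpa)
        return _render(config, np.empty((0, 2)), np.empty(0),
                       np.empty(0, bool), rng), truth
    centres, diameters = _place_conduits(config, rng, n)
    thresholds = -config.weibull_scale_mpa * rng.weibull(config.weibull_shape, n)
    air = psi_mpa <= thresholds
    image = _render(config, centres, diameters, air, rng)
    truth = GroundTruth(
        conduits=[
            GroundTruthConduit(
                id=i,
                centre_um=(float(centres[i, 0]), float(centres[i, 1])),
                diameter_um=float(diameters[i]),
                threshold_psi_mpa=float(thresholds[i]),
                state="air" if air[i] else "water",
            )
            for i in range(n)
        ],
        xylem_area_mm2=region.area_mm2,
        psi_mpa=psi_mpa,
    )
    return image, truth


def generate_final_scan(truth: GroundTruth, config: OrganSimConfig,
                        seed: int | None = None) -> np.ndarray:
    """Render the same geometry fully embolised (every conduit air-filled)."""
    n = len(truth)
    centres = np.array([c.centre_um for c in truth.conduits]).reshape(n, 2)
    diameters = np.array([c.diameter_um for c in truth.conduits])
    rng = (np.random.default_rng(config.seed if seed is None else seed)
           if config.noise_sd > 0 else None)
    return _render(config, centres, diameters, np.ones(n, dtype=bool), rng)


def generate_plc_observations(scale_mpa: float, shape: float, n: int,
                              psi_range: tuple[float, float],
                              noise_sd_plc: float, seed: int) -> pd.DataFrame:
    """Simulate one vulnerability-curve observation set.

    Psi is uniform on ``psi_range``; PLC is the Weibull curve plus Gaussian
    noise, clamped to [0, 100]. Columns: ``psi_mpa``, ``plc_pct``.
    """
    if scale_mpa <= 0 or shape <= 0:
        raise ValidationError("Weibull scale and shape must be > 0")
    if n < 4:
        raise ValidationError("need n >= 4 observations")
    lo, hi = min(psi_range), max(psi_range)
    if lo < -10.0 or hi > 0.0:
        raise ValidationError("psi_range must lie within [-10, 0]")
    if noise_sd_plc < 0:
        raise ValidationError("noise_sd_plc must be >= 0")
    rng = np.random.default_rng(seed)
    psi = rng.uniform(lo, hi, n)
    plc = 100.0 * (1.0 - np.exp(-((np.abs(psi) / scale_mpa) ** shape)))
    if noise_sd_plc > 0:
        plc = plc + rng.normal(0.0, noise_sd_plc, n)
    return pd.DataFrame({"psi_mpa": psi, "plc_pct": np.clip(plc, 0.0, 100.0)})


# ---------------------------------------------------------------------------
# Built-in organ presets for seedling demos and tests. Anatomical targets
# (mean diameter, hydraulic mean diameter, vessel density) and the
# vulnerability thresholds (psi50, psi88) used to derive the generating
# Weibull are published organ-level values for maple (Acer pseudoplatanus)
# and beech (Fagus sylvatica) seedlings.
ORGAN_PRESETS: dict[str, dict] = {
    "maple_stem": dict(mean_d_um=17.24, dh_um=25.06, vd_per_mm2=211.5,
                       psi50=-2.51, psi88=-4.69, d_min_um=6.0, d_max_um=55.0),
    "maple_root": dict(mean_d_um=11.15, dh_um=15.63, vd_per_mm2=1284.0,
                       psi50=-1.78, psi88=-2.08, d_min_um=5.0, d_max_um=40.0),
    "maple_petiole": dict(mean_d_um=10.47, dh_um=13.96, vd_per_mm2=908.3,
                          psi50=-1.13, psi88=-3.01, d_min_um=5.0, d_max_um=35.0),
    "beech_stem": dict(mean_d_um=18.36, dh_um=23.72, vd_per_mm2=314.4,
                       psi50=-2.74, psi88=-4.00, d_min_um=6.0, d_max_um=38.0),
    "beech_root": dict(mean_d_um=14.51, dh_um=22.65, vd_per_mm2=741.3,
                       psi50=-2.75, psi88=-3.74, d_min_um=5.0, d_max_um=48.0),
    "beech_vein": dict(mean_d_um=12.01, dh_um=16.42, vd_per_mm2=2551.3,
                       psi50=-2.26, psi88=-3.25, d_min_um=5.0, d_max_um=35.0,
                       min_wall_um=2.0),
}


def organ_preset(name: str, *, image_size_px: tuple[int, int] = (600, 600),
                 pixel_size_um: float = 2.0, noise_sd: float = 0.0,
                 seed: int = 0, margin_um: float = 40.0) -> OrganSimConfig:
    """Build a calibrated :class:`OrganSimConfig` from a named preset."""
    if name not in ORGAN_PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(ORGAN_PRESETS)}")
    p = ORGAN_PRESETS[name]
    dist = DiameterDistribution.from_targets(
        p["mean_d_um"], p["dh_um"], p["d_min_um"], p["d_max_um"])
    wfit = solve_weibull_parameters(p["psi50"], 50.0, p["psi88"], 88.0)
    h, w = image_size_px
    outer = min(h - 1, w - 1) * pixel_size_um / 2.0 - margin_um
    return OrganSimConfig(
        organ_label=name,
        vessel_density_per_mm2=p["vd_per_mm2"],
        diameter_dist=dist,
        weibull_scale_mpa=wfit.scale_mpa,
        weibull_shape=wfit.shape,
        xylem_region=XylemRegion(outer_radius_um=outer),
        image_size_px=image_size_px,
        pixel_size_um=pixel_size_um,
        noise_sd=noise_sd,
        min_wall_um=p.get("min_wall_um"),
        seed=seed,
    )


def with_seed(config: OrganSimConfig, seed: int) -> OrganSimConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
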