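"""Virtual environments, virtual species, and decoupled future scenarios.

Everything downstream of raw data ingestion can be exercised against known
ground truth: spatially autocorrelated climate fields, a compositional
land-cover mosaic whose collinearity with climate is a tunable dial
(``alpha_cov``), a logistic suitability function with linear and quadratic
terms, effort-biased occurrence sampling, and additively/multiplicatively
perturbed "future" layer sets that mimic mid-century scenario contrasts.

Climate fields are Gaussian random fields (white noise smoothed with a
Gaussian kernel, affinely rescaled); their target means/spreads follow the
magnitudes typical of temperate-zone 5-arcminute climatologies (tmin ~ 1.6
+- 2.9 degC, tmax = tmin + ~28 degC, annual precipitation ~ 674 mm,
precipitation seasonality ~ 0.43). Land-cover percentages are 100 x softmax
over six latent fields, each a mix of a linear map of the standardized
climate fields (weight ``alpha_cov``) and an independent random field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .grid import CLIMATE_LAYERS, LANDCOVER_LAYERS, EnvGrid, ScenarioSpec
from .range_metrics import SuitabilityMap

log = logging.getLogger(__name__)


@dataclass
class FieldSpec:
    """Controls for the virtual environment generator."""

    n_rows: int = 50
    n_cols: int = 50
    correlation_length: float = 8.0  # cells; Gaussian smoothing scale
    alpha_cov: float = 0.5  # climate share of each land-cover latent, in [0, 1]
    seed: int = 0
    origin_lon: float = -10.0
    origin_lat: float = 44.0
    res_arcmin: float = 5.0
    lat_gradient_degc: float = 3.0  # north-south temperature contrast (north colder)

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_cov <= 1:
            raise ValueError("alpha_cov must lie in [0, 1]")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")


@dataclass
class VirtualSpecies:
    """A species with a known logistic suitability function.

    Suitability = logistic(intercept + sum beta_l * z_l + sum beta_sq_l * z_l^2)
    where z_l is the named layer standardized over unmasked cells.
    """

    species_id: str = "virtual"
    beta: dict[str, float] = field(default_factory=dict)
    beta_sq: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    detection_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.detection_gamma < 0:
            raise ValueError("detection_gamma must be >= 0")


@dataclass
class OccurrenceSet:
    """Point records of one species (lon, lat in decimal degrees)."""

    species_id: str
    points: list[tuple[float, float]]
    source_label: str = "synthetic"

    def __post_init__(self) -> None:
        for lon, lat in self.points:
            if not (np.isfinite(lon) and np.isfinite(lat)):
                raise ValueError("occurrence coordinates must be finite")


def _random_field(rng: np.random.Generator, shape: tuple[int, int],
                  corr_len: float) -> np.ndarray:
    """Smoothed white noise, standardized to zero mean / unit variance."""
    z = rng.standard_normal(shape)
    if corr_len > 0:
        z = gaussian_filter(z, sigma=corr_len, mode="reflect")
    sd = z.std()
    if sd == 0:
        return np.zeros(shape)
    return (z - z.mean()) / sd


# Fixed linear map from the four standardized climate fields to the six
# land-cover latents; rows = land-cover classes, columns = (tmin, tmax, pan, pcv).
_LC_FROM_CLIMATE = np.array([
    [-0.8, -0.6, 0.7, -0.3],   # needleleaf: cold and wet
    [0.2, 0.3, 0.8, -0.4],     # broadleaf: mild and wet
    [-0.3, -0.2, -0.4, 0.6],   # grassland: seasonal, drier
    [0.6, 0.7, -0.8, 0.5],     # shrub: hot and dry
    [0.7, 0.4, 0.1, -0.2],     # crop: warm lowlands
    [0.3, 0.2, -0.1, 0.0],     # urban: weakly climate-linked
])
_LC_LATENT_SCALE = 1.5


def generate_environment(spec: FieldSpec) -> EnvGrid:
    """Generate climate and compositional land-cover layers with known structure.

    Returns an EnvGrid with layers tmin, tmax, pan, pcv and six land-cover
    percentage layers summing to 100 at every cell. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)
    L = spec.correlation_length

    g = [_random_field(rng, shape, L) for _ in range(4)]
    # deterministic meridional gradient: northern rows colder, as in real
    # mid-latitude climatologies; enables poleward-shift dynamics downstream
    lat_norm = np.linspace(1.0, -1.0, spec.n_rows)[:, None] * np.ones((1, spec.n_cols))
    tmin = 1.6 + 2.9 * g[0] - spec.lat_gradient_degc * lat_norm
    tmax = tmin + 26.0 + 4.0 * expit(g[1])  # strictly positive offset
    pan = 674.0 * np.exp(0.45 * g[2])       # >= 0, right-skewed
    pcv = expit(logit(0.43) + 0.5 * g[3])   # in (0, 1)
    layers = {"tmin": tmin, "tmax": tmax, "pan": pan, "pcv": pcv}

    clim_std = np.stack([(x - x.mean()) / x.std() for x in (tmin, tmax, pan, pcv)])
    latents = np.empty((6,) + shape)
    for k in range(6):
        clim_part = np.tensordot(_LC_FROM_CLIMATE[k], clim_std, axes=1)
        clim_part /= max(np.linalg.norm(_LC_FROM_CLIMATE[k]), 1e-12)
        noise_part = _random_field(rng, shape, L)
        latents[k] = _LC_LATENT_SCALE * (
            spec.alpha_cov * clim_part + (1 - spec.alpha_cov) * noise_part
        )
    pct = 100.0 * _softmax(latents)
    for name, k in zip(LANDCOVER_LAYERS, range(6)):
        layers[name] = pct[k]
    return EnvGrid(spec.origin_lon, spec.origin_lat, spec.res_arcmin, layers)


def _softmax(latents: np.ndarray) -> np.ndarray:
    e = np.exp(latents - latents.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


def standardized_layer(env: EnvGrid, name: str) -> np.ndarray:
    """Layer z-scored over unmasked cells (constant layers map to zeros)."""
    if name not in env.layers:
        raise KeyError(f"unknown layer {name!r}")
    a = env.layers[name]
    v = a[~env.mask]
    sd = v.std()
    if sd == 0:
        return np.zeros_like(a)
    return (a - v.mean()) / sd


def true_suitability(env: EnvGrid, sp: VirtualSpecies) -> SuitabilityMap:
    """Ground-truth suitability of a virtual species on its environment."""
    eta = np.full(env.shape, sp.intercept, float)
    for name, b in sp.beta.items():
        eta += b * standardized_layer(env, name)
    for name, b in sp.beta_sq.items():
        eta += b * standardized_layer(env, name) ** 2
    vals = expit(eta)
    vals = np.where(env.mask, np.nan, vals)
    return SuitabilityMap(env.origin_lon, env.origin_lat, env.res_arcmin,
                          np.nan_to_num(vals), env.mask, sp.species_id,
                          "current", "current")


def sample_occurrences(suit: SuitabilityMap, bias: np.ndarray, n_target: int,
                       sp: VirtualSpecies, seed: int) -> OccurrenceSet:
    """Draw presence cells with probability proportional to suit * bias^gamma.

    Cell-level Bernoulli draws scaled so the expected number of presences is
    approximately ``n_target``; returns cell-center points. Deterministic
    given ``seed``.
    """
    bias = np.asarray(bias, float)
    if bias.shape != suit.shape:
        raise ValueError("bias layer shape != suitability shape")
    if np.nanmin(bias) < -1e-9 or np.nanmax(bias) > 1 + 1e-9:
        raise ValueError("bias layer must lie in [0, 1]")
    ok = ~suit.mask
    n_avail = int(ok.sum())
    if n_target > n_avail:
        raise ValueError(f"n_target={n_target} exceeds {n_avail} unmasked cells")
    w = np.where(ok, suit.values * np.power(np.clip(bias, 0, 1), sp.detection_gamma), 0.0)
    total = w.sum()
    if total == 0:
        return OccurrenceSet(sp.species_id, [])
    p = np.clip(n_target * w / total, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    hits = rng.random(suit.shape) < p
    rows, cols = np.nonzero(hits)
    lons = suit.lon_centers
    lats = suit.lat_centers
    pts = [(float(lons[c]), float(lats[r])) for r, c in zip(rows, cols)]
    return OccurrenceSet(sp.species_id, pts)


def generate_future(env: EnvGrid, delta: dict[str, float], name: str = "scenario",
                    gcm_label: str = "synthetic") -> ScenarioSpec:
    """Perturb a current environment into an aligned future layer set.

    Temperatures shift additively (delta in degC); ``pan`` shifts
    multiplicatively (delta is a factor); ``pcv`` shifts additively and is
    clipped into (0, 1) with a warning. Land-cover deltas are applied to the
    log-percentage latents before re-applying softmax, so the six
    percentages remain a 100-sum composition.
    """
    unknown = [k for k in delta if k not in env.layers]
    if unknown:
        raise KeyError(f"perturbations name unknown layers: {unknown}")
    out = env.copy()
    lc_delta = {k: v for k, v in delta.items() if k in LANDCOVER_LAYERS}
    for key, d in delta.items():
        if key in lc_delta:
            continue
        if key == "pan":
            out.layers[key] = env.layers[key] * d
        elif key == "pcv":
            shifted = env.layers[key] + d
            eps = 1e-6
            if np.any(shifted <= 0) or np.any(shifted >= 1):
                log.warning("pcv perturbation left (0, 1); clipping")
                shifted = np.clip(shifted, eps, 1 - eps)
            out.layers[key] = shifted
        else:  # temperatures and any other additive layer
            out.layers[key] = env.layers[key] + d
    if lc_delta:
        pct = np.stack([env.layers[n] for n in LANDCOVER_LAYERS])
        latents = np.log(np.clip(pct / 100.0, 1e-12, None))
        for k, n in enumerate(LANDCOVER_LAYERS):
            latents[k] = latents[k] + lc_delta.get(n, 0.0)
        new_pct = 100.0 * _softmax(latents)
        for k, n in enumerate(LANDCOVER_LAYERS):
            out.layers[n] = new_pct[k]
    return ScenarioSpec(name, gcm_label, out)


#: Scenario perturbation presets mirroring mid-century contrasts between a
#: sustainable and an intermediate-emissions pathway: warming of ~1.4-4.7
#: degC, 8%-12% precipitation decline, and forest/crop expansion at the
#: expense of open habitats under the milder pathway.
SCENARIO_PRESETS: dict[str, dict[str, float]] = {
    "mild": {"tmin": 1.4, "tmax": 3.2, "pan": 0.92, "pcv": 0.01,
             "needleleaf": 0.55, "broadleaf": 0.55, "crop": 0.20,
             "grassland": -0.22, "shrub": -0.27},
    "strong": {"tmin": 2.2, "tmax": 4.7, "pan": 0.88, "pcv": 0.01,
               "needleleaf": 0.08, "broadleaf": 0.08, "crop": 0.12,
               "grassland": -0.07, "shrub": -0.08},
}
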