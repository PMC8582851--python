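"""Synthetic mountainous landscapes with known causal structure.

Real inputs to this kind of analysis — interpreted satellite land
use, interpolated climate surfaces, gridded census data — are not
redistributable, so the pipeline is exercised on simulated study
areas that emulate their structure: octave-noise terrain, an
elevation-structured climate (temperature lapse, orographic
precipitation), settlement-driven human pressure, and land use drawn
from a multinomial logit over the covariates with *known* weights.
Because the generating weights are recorded, downstream driver
attribution can be scored against ground truth.

Conventions: 6 land classes (cropland, forestland, grassland, water,
construction, unused) held as per-cell area fractions that sum to 1;
15 covariates in :data:`esvpipe.importance.FACTOR_NAMES` order; all
distances planar Euclidean on cell centres in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage
from skimage.draw import line as draw_line

from .errors import ConfigurationError
from .grids import GridSpec, block_regions
from .importance import FACTOR_NAMES
from .valuation import LAND_CLASSES, LandComposition

#: NDVI class-conditional means in LAND_CLASSES order
#: (cropland, forestland, grassland, water, construction, unused).
NDVI_CLASS_MEANS = (0.50, 0.85, 0.60, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class TransitionRule:
    """Move a share of one class into another where a condition holds.

    At each year step, ``probability`` of the ``source`` fraction is
    transferred to ``target`` on cells where ``factor op threshold``
    (op is ">" or "<"). probability=0 leaves the composition unchanged.
    """

    source: str
    target: str
    factor: str
    op: str
    threshold: float
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ConfigurationError(f"probability must be in [0,1], got {self.probability}")
        if self.op not in (">", "<"):
            raise ConfigurationError(f"op must be '>' or '<', got {self.op!r}")
        for cls in (self.source, self.target):
            if cls not in LAND_CLASSES:
                raise ConfigurationError(f"unknown land class {cls!r}")

    def mask(self, layers: dict[str, np.ndarray]) -> np.ndarray:
        f = layers[self.factor]
        return f > self.threshold if self.op == ">" else f < self.threshold


def _default_weights() -> np.ndarray:
    """Plausible land-class logit weights over the 15 covariates.

    Rows in LAND_CLASSES order, columns in FACTOR_NAMES order. NDVI is
    left at 0 because it is an outcome of land use here, not a cause.
    """
    w = np.zeros((len(LAND_CLASSES), len(FACTOR_NAMES)))
    f = {name: i for i, name in enumerate(FACTOR_NAMES)}
    # cropland: warm, flat, low, near settlements, silty soils
    w[0, f["temperature"]] = 0.5
    w[0, f["slope"]] = -0.8
    w[0, f["elevation"]] = -0.5
    w[0, f["dist_settlement"]] = -0.4
    w[0, f["soil_silt"]] = 0.3
    # forestland: high, wet, steep
    w[1, f["elevation"]] = 1.0
    w[1, f["precipitation"]] = 0.8
    w[1, f["slope"]] = 0.4
    # grassland: mid elevations
    w[2, f["elevation"]] = 0.3
    w[2, f["precipitation"]] = 0.2
    # water: hugs the river network
    w[3, f["dist_river"]] = -1.5
    # construction: dense, urban, near cities
    w[4, f["pop_density"]] = 1.0
    w[4, f["urbanization"]] = 0.8
    w[4, f["dist_urban"]] = -1.0
    # unused: high and dry
    w[5, f["elevation"]] = 0.4
    w[5, f["precipitation"]] = -0.8
    return w


def _default_transitions() -> list[TransitionRule]:
    return [
        # returning farmland to forests on steep slopes
        TransitionRule("cropland", "forestland", "slope", ">", 15.0, 0.10),
        # construction growth near urban centres
        TransitionRule("cropland", "construction", "dist_urban", "<", 3000.0, 0.03),
    ]


@dataclass
class Scenario:
    """Configuration of one synthetic study area.

    The defaults emulate a mid-latitude mountain water-conservation
    region observed at four five-yearly epochs: forest/grass dominated
    uplands, cropland valleys, reforestation of steep cropland and
    peri-urban construction growth between epochs.
    """

    seed: int = 0
    years: tuple[str, ...] = ("2000", "2005", "2010", "2015")
    class_weights: np.ndarray = field(default_factory=_default_weights)
    intercepts: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.8, 0.4, -1.5, -1.5, -2.0])
    )
    transition_rules: list[TransitionRule] = field(default_factory=_default_transitions)
    # climate model
    temperature_baseline: float = 15.0   # °C at sea level
    lapse_rate: float = 6.5e-3           # °C per m
    temperature_noise_sd: float = 0.5
    precip_baseline: float = 600.0       # mm
    orographic_coeff: float = 0.5        # mm per m of elevation
    precip_noise_sd: float = 80.0
    # human features
    settlement_density: float = 0.01     # fraction of cells
    n_urban_centers: int = 3
    n_roads: int = 3
    n_rivers: int = 2
    ndvi_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.class_weights.shape != (len(LAND_CLASSES), len(FACTOR_NAMES)):
            raise ConfigurationError(
                f"class_weights must be {len(LAND_CLASSES)}x{len(FACTOR_NAMES)}"
            )
        if not np.all(np.isfinite(self.class_weights)):
            raise ConfigurationError("class_weights must be finite")
        if list(self.years) != sorted(set(self.years)):
            raise ConfigurationError("years must be strictly ordered and unique")

    def driver_ranking(self) -> list[str]:
        """Ground-truth factor ordering: total |logit weight| per covariate."""
        strength = np.abs(self.class_weights).sum(axis=0)
        order = np.argsort(-strength, kind="stable")
        return [FACTOR_NAMES[i] for i in order]

    @classmethod
    def strong_signal(cls, factor: str = "elevation", weight: float = 8.0, seed: int = 0) -> "Scenario":
        """One dominant driver: forest share is a sharp logit of ``factor``.

        Used to test whether downstream importance attribution recovers
        the known top driver.
        """
        if factor not in FACTOR_NAMES:
            raise ConfigurationError(f"unknown factor {factor!r}")
        w = np.zeros((len(LAND_CLASSES), len(FACTOR_NAMES)))
        w[LAND_CLASSES.index("forestland"), FACTOR_NAMES.index(factor)] = weight
        return cls(
            seed=seed,
            class_weights=w,
            intercepts=np.zeros(len(LAND_CLASSES)),
            transition_rules=[],
        )

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "years": list(self.years),
            "class_weights": self.class_weights.tolist(),
            "intercepts": self.intercepts.tolist(),
            "transition_rules": [
                [r.source, r.target, r.factor, r.op, r.threshold, r.probability]
                for r in self.transition_rules
            ],
            "temperature_baseline": self.temperature_baseline,
            "lapse_rate": self.lapse_rate,
            "temperature_noise_sd": self.temperature_noise_sd,
            "precip_baseline": self.precip_baseline,
            "orographic_coeff": self.orographic_coeff,
            "precip_noise_sd": self.precip_noise_sd,
            "settlement_density": self.settlement_density,
            "n_urban_centers": self.n_urban_centers,
            "n_roads": self.n_roads,
            "n_rivers": self.n_rivers,
            "ndvi_noise_sd": self.ndvi_noise_sd,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rules = [TransitionRule(*r) for r in data.pop("transition_rules", [])]
        data["years"] = tuple(str(y) for y in data.get("years", ()))
        data["class_weights"] = np.asarray(data["class_weights"], dtype=float)
        data["intercepts"] = np.asarray(data["intercepts"], dtype=float)
        return cls(transition_rules=rules, **data)


@dataclass
class FactorStack:
    """The 15 aligned covariate layers for one epoch."""

    layers: dict[str, np.ndarray]
    spec: GridSpec

    def __post_init__(self) -> None:
        missing = set(FACTOR_NAMES) - set(self.layers)
        if missing:
            raise ConfigurationError(f"factor stack missing layers: {sorted(missing)}")

    def as_matrix(self) -> np.ndarray:
        """(n_cells, 15) observation matrix in canonical factor order."""
        return np.column_stack([self.layers[f].ravel() for f in FACTOR_NAMES])

    def with_layer(self, name: str, layer: np.ndarray) -> "FactorStack":
        layers = dict(self.layers)
        layers[name] = layer
        return FactorStack(layers=layers, spec=self.spec)


@dataclass
class SyntheticBundle:
    """Everything one simulated study area provides to the pipeline."""

    spec: GridSpec
    scenario: Scenario
    elevation: np.ndarray
    slope: np.ndarray
    compositions: dict[str, LandComposition]  # year -> composition
    stacks: dict[str, FactorStack]            # year -> covariates (NDVI varies)
    regions: np.ndarray
    truth_ranking: list[str]


def _octave_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Three octaves of Gaussian-smoothed white noise, roughly unit scale.

    The correlation length is fixed in cells (2 km at the default cell
    size) rather than scaled with the grid, so terrain roughness — and
    with it the slope distribution — does not depend on study-area
    size. Short correlation keeps the landscape rugged enough that the
    steep-slope classes (> 15°) are populated, as in real mountain
    terrain observed on a 1 km grid.
    """
    base_sigma = 2.0
    field_sum = np.zeros(shape)
    for octave in range(3):
        sigma = base_sigma / (2**octave)
        amp = 1.0 / (2**octave)
        raw = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(raw, sigma)
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        field_sum += amp * smooth
    return field_sum


def generate_terrain(spec: GridSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Elevation (m, in [0, 2000]) and slope (degrees) rasters.

    Elevation is octave-summed smoothed noise rescaled to [0, 2000];
    slope comes from central finite differences of elevation
    (one-sided at borders), converted to degrees.
    """
    rng = np.random.default_rng(seed)
    noise = _octave_noise(spec.shape, rng)
    lo, hi = noise.min(), noise.max()
    elevation = (noise - lo) / (hi - lo) * 2000.0 if hi > lo else np.zeros(spec.shape)
    return elevation, slope_from_elevation(elevation, spec.cell_size)


def slope_from_elevation(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Slope in degrees from finite differences of an elevation raster."""
    gy, gx = np.gradient(np.asarray(elevation, dtype=float), cell_size)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def _place_weighted(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask with k cells sampled without replacement ∝ weights."""
    p = weights.ravel() / weights.sum()
    idx = rng.choice(weights.size, size=min(k, weights.size), replace=False, p=p)
    mask = np.zeros(weights.size, dtype=bool)
    mask[idx] = True
    return mask.reshape(weights.shape)


def _river_paths(elevation: np.ndarray, n_rivers: int, rng) -> np.ndarray:
    """Steepest-descent walks from high ground; crude but river-shaped."""
    nr, nc = elevation.shape
    mask = np.zeros_like(elevation, dtype=bool)
    flat = np.argsort(elevation.ravel())[::-1]
    starts = flat[rng.choice(max(nr * nc // 20, n_rivers), size=n_rivers, replace=False)]
    for s in starts:
        r, c = divmod(int(s), nc)
        for _ in range(2 * (nr + nc)):
            mask[r, c] = True
            window = elevation[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
            dr, dc = np.unravel_index(np.argmin(window), window.shape)
            nr_, nc_ = max(r - 1, 0) + dr, max(c - 1, 0) + dc
            if (nr_, nc_) == (r, c):
                break  # local minimum: lake outlet
            r, c = nr_, nc_
            if r in (0, nr - 1) or c in (0, nc - 1):
                mask[r, c] = True
                break
    return mask


def _distance_m(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Euclidean distance (m) from each cell centre to the nearest masked cell."""
    if not mask.any():
        raise ConfigurationError("cannot compute distances to an empty feature set")
    return ndimage.distance_transform_edt(~mask) * cell_size


def generate_covariates(
    elevation: np.ndarray,
    slope: np.ndarray,
    spec: GridSpec,
    scenario: Scenario,
    seed: int,
) -> FactorStack:
    """All covariate layers except NDVI (which is epoch-specific).

    Climate follows elevation (lapse-rate temperature, orographic
    precipitation clipped to [300, 1600] mm); soils are a smoothed
    Dirichlet field; settlements, urban centres, roads and rivers are
    placed with probability decreasing in slope, and X12–X15 are
    Euclidean distances to them; population density is a kernel sum
    over settlements and urban centres, with economic density and
    urbanization level derived from it. NDVI is initialised to 0 and
    overwritten per epoch by :func:`generate_landuse`.
    """
    rng = np.random.default_rng(seed)
    layers: dict[str, np.ndarray] = {"elevation": elevation, "slope": slope}

    layers["temperature"] = (
        scenario.temperature_baseline
        - scenario.lapse_rate * elevation
        + scenario.temperature_noise_sd * rng.standard_normal(spec.shape)
    )
    precip_noise = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 3.0)
    layers["precipitation"] = np.clip(
        scenario.precip_baseline
        + scenario.orographic_coeff * elevation
        + scenario.precip_noise_sd * precip_noise,
        300.0,
        1600.0,
    )

    # smoothed Dirichlet soil-texture field: smoothed gamma variates, normalized
    gammas = [
        ndimage.gaussian_filter(rng.gamma(2.0, size=spec.shape), 2.0)
        for _ in range(3)
    ]
    total = np.maximum(sum(gammas), 1e-12)
    layers["soil_silt"] = gammas[0] / total
    layers["soil_clay"] = gammas[1] / total
    layers["soil_sand"] = gammas[2] / total

    # human features prefer flat, low ground
    lowland = np.exp(-slope / 5.0) * np.exp(-elevation / 800.0)
    n_settlements = max(1, round(scenario.settlement_density * spec.n_cells))
    settlements = _place_weighted(rng, lowland, n_settlements)
    urban = _place_weighted(rng, np.exp(-slope / 3.0) * np.exp(-elevation / 300.0),
                            scenario.n_urban_centers)

    roads = np.zeros(spec.shape, dtype=bool)
    urban_cells = np.argwhere(urban)
    for _ in range(scenario.n_roads):
        r0, c0 = urban_cells[rng.integers(len(urban_cells))]
        side = rng.integers(4)
        if side == 0:
            r1, c1 = 0, rng.integers(spec.n_cols)
        elif side == 1:
            r1, c1 = spec.n_rows - 1, rng.integers(spec.n_cols)
        elif side == 2:
            r1, c1 = rng.integers(spec.n_rows), 0
        else:
            r1, c1 = rng.integers(spec.n_rows), spec.n_cols - 1
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        roads[rr, cc] = True

    rivers = _river_paths(elevation, scenario.n_rivers, rng)

    layers["dist_urban"] = _distance_m(urban, spec.cell_size)
    layers["dist_settlement"] = _distance_m(settlements, spec.cell_size)
    layers["dist_road"] = _distance_m(roads, spec.cell_size)
    layers["dist_river"] = _distance_m(rivers, spec.cell_size)

    # kernel population density (persons/km²) around settlements and cities
    pop = (
        6e5 * ndimage.gaussian_filter(urban.astype(float), 3.0)
        + 2e4 * ndimage.gaussian_filter(settlements.astype(float), 2.0)
        + np.abs(0.5 * rng.standard_normal(spec.shape))
    )
    layers["pop_density"] = pop
    layers["econ_density"] = np.clip(
        20.0 * pop**1.05 * (1.0 + 0.1 * rng.standard_normal(spec.shape)), 0.0, None
    )
    layers["urbanization"] = 1.0 / (1.0 + np.exp(-(pop - 500.0) / 150.0))

    layers["ndvi"] = np.zeros(spec.shape)
    return FactorStack(layers=layers, spec=spec)


def _softmax_composition(stack: FactorStack, scenario: Scenario) -> np.ndarray:
    """Per-cell class probabilities: multinomial logit over standardized covariates."""
    X = stack.as_matrix()  # (n_cells, 15)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    logits = scenario.intercepts[None, :] + Z @ scenario.class_weights.T
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    return probs.T.reshape(len(LAND_CLASSES), *stack.spec.shape)


def _ndvi_for(fractions: np.ndarray, scenario: Scenario, rng) -> np.ndarray:
    means = np.asarray(NDVI_CLASS_MEANS)
    ndvi = np.tensordot(means, fractions, axes=1)
    ndvi = ndvi + scenario.ndvi_noise_sd * rng.standard_normal(fractions.shape[1:])
    return np.clip(ndvi, 0.0, 1.0)


def generate_landuse(
    factors: FactorStack,
    scenario: Scenario,
    seed: int,
) -> tuple[dict[str, LandComposition], dict[str, np.ndarray]]:
    """Fractional land composition per year, plus the per-year NDVI layer.

    The first year is the multinomial-logit equilibrium; later years
    apply the scenario's transition rules step by step. NDVI is the
    class-conditional mean mixture plus noise, clipped to [0, 1].
    """
    if not np.all(np.isfinite(scenario.class_weights)):
        raise ConfigurationError("class_weights must be finite")
    rng = np.random.default_rng(seed)
    fractions = _softmax_composition(factors, scenario)

    compositions: dict[str, LandComposition] = {}
    ndvi_by_year: dict[str, np.ndarray] = {}
    current = fractions
    for step, year in enumerate(scenario.years):
        if step > 0:
            current = current.copy()
            for rule in scenario.transition_rules:
                mask = rule.mask(factors.layers)
                src = LAND_CLASSES.index(rule.source)
                dst = LAND_CLASSES.index(rule.target)
                transfer = rule.probability * current[src] * mask
                current[src] -= transfer
                current[dst] += transfer
        compositions[year] = LandComposition(
            fractions=current, spec=factors.spec, year=year
        )
        ndvi_by_year[year] = _ndvi_for(current, scenario, rng)
    return compositions, ndvi_by_year


def generate_bundle(
    spec: GridSpec | None = None,
    scenario: Scenario | None = None,
    seed: int | None = None,
) -> SyntheticBundle:
    """End-to-end simulation of one study area.

    Defaults: 100×100 grid of 1 km cells, the default scenario, and
    the scenario's own seed. Identical (spec, scenario, seed) yield a
    bit-identical bundle.
    """
    spec = spec or GridSpec(100, 100)
    scenario = scenario or Scenario()
    seed = scenario.seed if seed is None else seed

    elevation, slope = generate_terrain(spec, seed)
    base_stack = generate_covariates(elevation, slope, spec, scenario, seed + 1)
    compositions, ndvi_by_year = generate_landuse(base_stack, scenario, seed + 2)
    stacks = {
        year: base_stack.with_layer("ndvi", ndvi_by_year[year])
        for year in scenario.years
    }
    return SyntheticBundle(
        spec=spec,
        scenario=scenario,
        elevation=elevation,
        slope=slope,
        compositions=compositions,
        stacks=stacks,
        regions=block_regions(spec),
        truth_ranking=scenario.driver_ranking(),
    )
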