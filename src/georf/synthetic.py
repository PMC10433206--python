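"""Synthetic ZIP-level cohort generator with planted, known structure.

Real suicide-attempt cohorts are protected health information, so every
downstream stage of this package is exercised on synthetic data whose
generative mechanism is fully known.  The generator emulates the *shape*
of the real data layers:

* a climate block of 12 measurement types x 12 months (144 monthly
  columns) plus 30 static columns such as elevation and urban cover;
* a block of sociodemographic proportions in [0, 1] (census-style
  population shares) plus population density and a water/land area ratio;
* firearms and alcohol vendors per 10,000 residents, drawn from a
  zero-inflated gamma because per-capita business counts are skewed with
  many zero-vendor ZIP codes;
* optional groups of near-duplicate columns with pairwise |Pearson r|
  at or above a configurable target (>= 0.90), planted to exercise the
  correlation-pruning stage;
* a patient table whose binary outcome is drawn from a sparse logistic
  model on that patient's ZIP features, with age-band-specific
  prevalence and coefficients, and an age distribution that peaks near
  60 and declines steeply above it.

Everything is a pure function of the configuration (including its seed):
identical configurations produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

AGE_BANDS = ("under_60", "60_plus")
#: Age (in integer years) at and above which a patient belongs to the
#: older stratum.
AGE_CUTOFF = 60

MONTHLY_TYPES = (
    "tmin", "tmax", "tavg", "prcp", "srad", "wind",
    "vapr", "dewp", "cldy", "snow", "rhum", "pevt",
)

STATIC_CLIMATE = (
    "elevation", "slope", "aspect", "ruggedness", "urban_cover",
    "forest_cover", "crop_cover", "water_cover", "impervious_surface",
    "canopy_height", "soil_moisture", "soil_ph", "aridity_index",
    "frost_days", "growing_season_length", "heat_wave_days",
    "cold_wave_days", "annual_precip", "annual_snowfall",
    "sunshine_hours", "uv_index", "ozone", "pm25", "no2",
    "distance_to_coast", "distance_to_river", "lake_density",
    "wetland_fraction", "drought_index", "lightning_density",
)

VENDOR_FEATURES = ("firearms_per_10k", "alcohol_per_10k")


def monthly_climate_columns() -> list[str]:
    """Names of the 144 monthly climate columns (12 types x 12 months)."""
    return [f"clim_{t}_m{m:02d}" for t in MONTHLY_TYPES for m in range(1, 13)]


def static_climate_columns() -> list[str]:
    """Names of the 30 static climate/terrain columns."""
    return [f"clim_static_{name}" for name in STATIC_CLIMATE]


def demographic_columns(n_demo_features: int) -> list[str]:
    """Names of the demographic block: shares plus density and water ratio."""
    cols = [f"acs_share_{i:04d}" for i in range(n_demo_features)]
    cols += ["population_density", "water_land_ratio"]
    return cols


@dataclass(frozen=True)
class CausalFeature:
    """A planted effect: ``coef`` > 0 raises risk, < 0 is protective.

    ``band`` restricts the effect to one age stratum ("under_60" or
    "60_plus") or applies it to "both".
    """

    name: str
    coef: float
    band: str = "both"

    def __post_init__(self) -> None:
        if self.band not in AGE_BANDS + ("both",):
            raise ValueError(f"unknown age band {self.band!r}")
        if self.coef == 0:
            raise ValueError(f"causal feature {self.name!r} has zero coefficient")

    @property
    def sign(self) -> int:
        return 1 if self.coef > 0 else -1


@dataclass(frozen=True)
class CorrGroup:
    """A planted group of near-duplicate columns.

    ``r`` is the minimum pairwise sample |Pearson correlation| the group
    must realize; values below 0.90 are rejected because the groups exist
    to exercise the pruning threshold.
    """

    size: int
    r: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("correlated group size must be >= 2")
        if not 0.90 <= self.r < 1.0:
            raise ValueError(
                f"correlated group target |r| must be in [0.90, 1), got {self.r}"
            )


def _default_prevalence() -> dict[str, float]:
    # Stratum-level case fractions mirroring a cohort where attempts are
    # rarer above age 60 (~1.6%) than below it (~7.2%).
    return {"under_60": 0.072, "60_plus": 0.016}


def _default_causal() -> tuple[CausalFeature, ...]:
    return (
        CausalFeature("acs_share_0000", -0.8, "both"),
        CausalFeature("acs_share_0001", +0.8, "both"),
        CausalFeature("firearms_per_10k", +0.5, "both"),
        CausalFeature("alcohol_per_10k", +0.4, "both"),
        CausalFeature("clim_static_elevation", +0.6, "under_60"),
    )


def _default_corr_groups() -> tuple[CorrGroup, ...]:
    return (CorrGroup(3, 0.95), CorrGroup(2, 0.93))


@dataclass
class SyntheticConfig:
    """Full description of a synthetic study.

    Defaults are desk-scale: 2,000 ZIP codes, 200 demographic share
    columns (standing in for the ~1,600 census variables of a national
    table) and 50,000 patients, preserving the many-features/many-ZIPs
    shape of a real cohort at one to two orders of magnitude reduction.
    """

    n_zips: int = 2000
    n_demo_features: int = 200
    n_patients: int = 50_000
    prevalence_by_age: Mapping[str, float] = field(default_factory=_default_prevalence)
    causal_features: Sequence[CausalFeature] = field(default_factory=_default_causal)
    corr_groups: Sequence[CorrGroup] = field(default_factory=_default_corr_groups)
    seed: int = 0

    def __post_init__(self) -> None:
        self.causal_features = tuple(
            c if isinstance(c, CausalFeature) else CausalFeature(*c)
            for c in self.causal_features
        )
        self.corr_groups = tuple(
            g if isinstance(g, CorrGroup) else CorrGroup(*g) for g in self.corr_groups
        )
        if self.n_zips < 2:
            raise ValueError("n_zips must be >= 2")
        if self.n_demo_features < 1:
            raise ValueError("n_demo_features must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if set(self.prevalence_by_age) != set(AGE_BANDS):
            raise ValueError(f"prevalence_by_age must map exactly the bands {AGE_BANDS}")
        for band, p in self.prevalence_by_age.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {band!r} must be in (0, 1), got {p}")
        total = sum(g.size for g in self.corr_groups)
        if total > len(monthly_climate_columns()):
            raise ValueError("correlated groups exceed the monthly climate block")

    @property
    def feature_columns(self) -> list[str]:
        return (
            monthly_climate_columns()
            + static_climate_columns()
            + demographic_columns(self.n_demo_features)
            + list(VENDOR_FEATURES)
        )


@dataclass
class PlantedTruth:
    """Ground truth of the generating mechanism, for recovery tests.

    ``causal`` lists the planted effects with their signed coefficients
    and age bands; ``corr_groups`` lists the member columns of every
    planted near-duplicate group; ``intercepts`` are the per-band
    logistic intercepts solved to hit the configured prevalences.
    """

    causal: tuple[CausalFeature, ...]
    corr_groups: tuple[tuple[str, ...], ...]
    intercepts: dict[str, float]

    @property
    def causal_names(self) -> list[str]:
        return [c.name for c in self.causal]

    def sign_of(self, name: str) -> int:
        for c in self.causal:
            if c.name == name:
                return c.sign
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "causal": [asdict(c) for c in self.causal],
            "corr_groups": [list(g) for g in self.corr_groups],
            "intercepts": dict(self.intercepts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            causal=tuple(CausalFeature(**c) for c in d["causal"]),
            corr_groups=tuple(tuple(g) for g in d["corr_groups"]),
            intercepts={k: float(v) for k, v in d["intercepts"].items()},
        )


def corr_group_columns(config: SyntheticConfig) -> list[tuple[str, ...]]:
    """Columns hosting each planted correlated group.

    Groups are planted over the tail of the monthly climate block
    (deterministically, back to front) so the demographic share columns
    keep their [0, 1] range.
    """
    monthly = monthly_climate_columns()
    out: list[tuple[str, ...]] = []
    stop = len(monthly)
    for g in config.corr_groups:
        out.append(tuple(monthly[stop - g.size : stop]))
        stop -= g.size
    return out


def _plant_group(rng: np.random.Generator, base: np.ndarray, size: int,
                 target: float) -> np.ndarray:
    """Columns (n x size) whose pairwise sample |r| all reach ``target``.

    Members are noised, rescaled copies of a shared latent; the common
    loading starts above sqrt(target) (pairwise copy-copy correlation is
    the loading squared) and the noise is shrunk until the sample check
    passes, so the guarantee holds for any draw.
    """
    n = base.shape[0]
    z = (base - base.mean()) / base.std()
    rho = min(0.999, np.sqrt(target) + 0.6 * (1.0 - np.sqrt(target)))
    noise = rng.normal(size=(n, size - 1))
    scales = rng.uniform(0.5, 2.0, size=size)
    offsets = rng.normal(0.0, 1.0, size=size)
    signs = np.ones(size)
    signs[-1] = -1.0  # one anti-correlated member, to exercise |r|
    for _ in range(20):
        cols = np.empty((n, size))
        cols[:, 0] = z
        cols[:, 1:] = rho * z[:, None] + np.sqrt(1.0 - rho * rho) * noise
        r = np.corrcoef(cols, rowvar=False)
        if np.min(np.abs(r[np.triu_indices(size, 1)])) >= target:
            break
        rho = rho + 0.5 * (0.999 - rho)
    cols = cols * (signs * scales) + offsets
    return cols


def generate_zip_features(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the ZIP-level feature table.

    Returns a DataFrame with a ``zip_id`` string column followed by
    exactly 144 monthly climate, 30 static climate, ``n_demo_features``
    demographic share, population density, water/land ratio and 2 vendor
    columns.  A mild shared latitude latent induces weak (|r| <~ 0.5)
    correlation across climate columns; strong correlation appears only
    in the planted groups.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_zips
    zip_ids = [f"Z{i:05d}" for i in range(n)]
    lat = rng.uniform(-1.0, 1.0, size=n)

    data: dict[str, np.ndarray] = {}
    for col in monthly_climate_columns():
        a = rng.uniform(-0.7, 0.7)
        mu = rng.normal(0.0, 3.0)
        sd = rng.uniform(0.5, 2.0)
        data[col] = mu + sd * (a * lat + np.sqrt(1.0 - a * a) * rng.normal(size=n))
    for col in static_climate_columns():
        a = rng.uniform(-0.7, 0.7)
        mu = rng.normal(0.0, 3.0)
        sd = rng.uniform(0.5, 2.0)
        data[col] = mu + sd * (a * lat + np.sqrt(1.0 - a * a) * rng.normal(size=n))
    for i in range(config.n_demo_features):
        alpha = rng.uniform(0.8, 8.0)
        beta = rng.uniform(0.8, 8.0)
        data[f"acs_share_{i:04d}"] = rng.beta(alpha, beta, size=n)
    data["population_density"] = rng.lognormal(mean=5.0, sigma=1.2, size=n)
    data["water_land_ratio"] = rng.beta(1.0, 8.0, size=n)
    for col in VENDOR_FEATURES:
        zero = rng.random(n) < 0.35
        rates = rng.gamma(shape=1.4, scale=1.2, size=n)
        rates[zero] = 0.0
        data[col] = rates

    for members, group in zip(corr_group_columns(config), config.corr_groups):
        cols = _plant_group(rng, data[members[0]], group.size, group.r)
        for j, name in enumerate(members):
            data[name] = cols[:, j]

    cols = {"zip_id": zip_ids}
    cols.update((c, data[c]) for c in config.feature_columns)
    return pd.DataFrame(cols)


def _draw_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    """Integer ages in [18, 95]: mass peaking near 60, steep decline above.

    A mixture of a broad normal below the cutoff (45% weight) and an
    exponential tail of scale 7 years starting at 60 (55% weight).
    """
    older = rng.random(n) < 0.55
    young = np.clip(np.round(rng.normal(52.0, 10.0, size=n)), 18, AGE_CUTOFF - 1)
    old = np.clip(np.floor(AGE_CUTOFF + rng.exponential(7.0, size=n)), AGE_CUTOFF, 95)
    return np.where(older, old, young).astype(np.int64)


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + eta)) == target on these patients."""
    if eta.size == 0 or np.allclose(eta, 0.0):
        return float(logit(target))
    return float(brentq(lambda c: expit(c + eta).mean() - target, -40.0, 40.0))


def generate_patients(
    zips: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate the patient table and its ground truth.

    Each patient is assigned a ZIP code by a nonuniform multinomial
    (probability proportional to population density), an integer age,
    and a label drawn Bernoulli(sigmoid(intercept_band + sum coef * z))
    where z are the ZIP-table z-scores of the planted causal features
    active in that patient's age band.  Per-band intercepts are solved
    so the realized expected prevalence matches the configuration.
    """
    if len(zips) == 0:
        raise ValueError("ZIP feature table is empty")
    missing = [c.name for c in config.causal_features if c.name not in zips.columns]
    if missing:
        raise ValueError(f"causal features absent from ZIP table: {missing}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_patients
    dens = zips["population_density"].to_numpy()
    pz = dens / dens.sum()
    zip_idx = rng.choice(len(zips), size=n, p=pz)
    ages = _draw_ages(rng, n)
    bands = np.where(ages >= AGE_CUTOFF, "60_plus", "under_60")

    eta = np.zeros(n)
    for c in config.causal_features:
        x = zips[c.name].to_numpy()
        sd = x.std()
        if sd == 0:
            raise ValueError(f"causal feature {c.name!r} has zero variance")
        z = (x - x.mean()) / sd
        contrib = c.coef * z[zip_idx]
        if c.band == "both":
            eta += contrib
        else:
            eta += np.where(bands == c.band, contrib, 0.0)

    intercepts: dict[str, float] = {}
    p = np.zeros(n)
    for band in AGE_BANDS:
        mask = bands == band
        c0 = _solve_intercept(eta[mask], config.prevalence_by_age[band])
        intercepts[band] = c0
        p[mask] = expit(c0 + eta[mask])
    labels = (rng.random(n) < p).astype(np.int64)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "zip_id": zips["zip_id"].to_numpy()[zip_idx],
            "age": ages,
            "label": labels,
        }
    )
    truth = PlantedTruth(
        causal=tuple(config.causal_features),
        corr_groups=tuple(corr_group_columns(config)),
        intercepts=intercepts,
    )
    return patients, truth


def planted_dependency_matrix(
    n_features: int = 50,
    n_deps: int = 5,
    n_samples: int = 1000,
    n_sources: int = 6,
    n_parents: int = 3,
    noise_var: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """A feature matrix with planted linear dependencies, for network tests.

    ``n_deps`` target columns are each a standardized linear combination
    of ``n_parents`` parent columns drawn round-robin from a pool of
    ``n_sources`` independent source columns, plus ``noise_var`` residual
    variance.  Multi-parent targets mimic real geospatial covariates,
    which are composites of several upstream quantities: predictive
    importance must split across the parents, and each source is in turn
    predicted by the targets it feeds.  Every pairwise correlation stays
    below 0.90 (parent-target r is about sqrt((1 - noise_var)/n_parents)),
    so the matrix survives correlation pruning intact.  The remaining
    columns are independent standard normals.

    Returns the matrix (with a ``zip_id`` column, so it can stand in for
    a pruned ZIP feature table) and the list of all planted directed
    (parent, target) edges — ``n_parents`` per dependency.
    """
    if n_features < n_sources + n_deps + 1:
        raise ValueError("need at least n_sources + n_deps + 1 features")
    if not 2 <= n_parents <= n_sources:
        raise ValueError("n_parents must be in [2, n_sources]")
    if not 0.0 < noise_var < 1.0:
        raise ValueError("noise_var must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    X = rng.normal(size=(n_samples, n_features))
    sources = X[:, :n_sources]
    deps: list[tuple[str, str]] = []
    for i in range(n_deps):
        t = n_sources + i
        parents = [(i + j) % n_sources for j in range(n_parents)]
        combo = sources[:, parents].sum(axis=1) / np.sqrt(n_parents)
        X[:, t] = (
            np.sqrt(1.0 - noise_var) * combo
            + np.sqrt(noise_var) * rng.normal(size=n_samples)
        )
        deps.extend((f"f{p:02d}", f"f{t:02d}") for p in parents)
    cols = [f"f{i:02d}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "zip_id", [f"Z{i:05d}" for i in range(n_samples)])
    return df, deps
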