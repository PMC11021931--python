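"""Synthetic specimen tables with the statistical structure of the study system.

Three generators:

* :func:`generate_fossil_series` — an 18-sample fossil time series spanning
  ~16 363 years.  Armour traits follow fast-then-plateau (exponential
  approach) trajectories, non-armour traits near-linear ones; continuous
  traits carry an allometric component of standard length; per-specimen noise
  is correlated across traits; count traits are rounded and clamped.
* :func:`generate_species_pairs` — five lakes x two ecotypes, with per-lake
  benthic-limnetic mean contrasts scaled so the true multivariate distances
  span the observed range (~8-27 on the mixed mm/count scale).
* :func:`generate_armour_scenario` — joint pelvic-score / dorsal-spine
  phenotypes for the association test, with a hybridization rate parameter
  interpolating between perfect association (0) and independence (1).

Every generated table is accompanied by a :class:`SyntheticTruth` holding the
realized per-sample true means (expectations under the rounding/clamping
noise model, so the noise-free limit is exact) and the true first-vs-last
multivariate distance.

Default trajectory endpoints, noise levels and per-trait sample sizes are
calibrated from the published summary table in :mod:`sticklediv.reference`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import reference
from .io_model import META_COLUMNS, SpecimenTable, TraitRegistry, default_registry
from .streams import substream

logger = logging.getLogger(__name__)

__all__ = [
    "TraitTrajectory",
    "FossilSeriesParams",
    "PairLakesParams",
    "ArmourScenarioParams",
    "SyntheticTruth",
    "generate_fossil_series",
    "generate_species_pairs",
    "generate_armour_scenario",
    "default_fossil_params",
    "default_pair_params",
]

# Armour traits reduce fast then plateau; the pelvic traits additionally lag.
_PLATEAU_TRAITS = {"mds", "mpt", "lps.sc", "tpg.sc", "ds1.sc", "ds2.sc", "ds3.sc", "lpt.sc"}
_PELVIC_TRAITS = {"lps.sc", "tpg.sc"}
_PELVIC_LAG_YEARS = 3000.0
_DEFAULT_TAU_YEARS = 3000.0

# Realistic absolute start means for the fossil series (mm for lengths); only
# the start-minus-end contrast matters for the divergence statistics, which is
# taken from the published table.
_START_MEANS = {
    "lps.sc": 8.0,
    "tpg.sc": 10.5,
    "ds1.sc": 5.3,
    "ds2.sc": 6.5,
    "ds3.sc": 2.0,
    "lpt.sc": 2.0,
    "ect.sc": 4.2,
    "pmx.sc": 2.1,
    "cle.sc": 12.0,
    "mds": 3.0,
    "mcv": 14.0,
    "mpt": 5.0,
    "maf": 8.0,
    "mdf": 11.0,
    "mav": 16.0,
    "stl": 55.0,
}

# Admissible integer range for count traits (clamping bounds).
_COUNT_RANGES = {
    "mds": (0, 3),
    "mcv": (0, 40),
    "mpt": (0, 20),
    "maf": (0, 30),
    "mdf": (0, 30),
    "mav": (0, 40),
}

#: default allometric slope (mm per mm standard length) for corrected traits
_DEFAULT_ALLOMETRY_SLOPE = 0.05


@dataclass(frozen=True)
class TraitTrajectory:
    """True mean trajectory of one trait through the fossil series.

    ``plateau`` means an exponential approach
    ``m(t) = end + (start - end) * exp(-max(t - lag, 0) / tau)`` (monotone
    non-increasing after the lag for a reducing trait); ``linear``
    interpolates the endpoints.
    """

    start_mean: float
    end_mean: float
    shape: str = "linear"  # "plateau" | "linear"
    lag_years: float = 0.0
    tau_years: float = _DEFAULT_TAU_YEARS
    sd: float = 1.0
    n_first: int | None = None  # target non-missing count, first sample
    n_last: int | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("plateau", "linear"):
            raise ValueError(f"unknown trajectory shape {self.shape!r}")
        if self.shape == "plateau" and self.end_mean > self.start_mean:
            raise ValueError(
                "plateau trajectory is monotone non-increasing: "
                f"end_mean {self.end_mean} > start_mean {self.start_mean}"
            )
        if self.lag_years < 0 or self.tau_years <= 0 or self.sd < 0:
            raise ValueError("lag_years >= 0, tau_years > 0 and sd >= 0 required")

    def mean_at(self, t: float | np.ndarray, span_years: float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.shape == "linear":
            frac = np.clip(t / span_years, 0.0, 1.0)
            return self.start_mean + frac * (self.end_mean - self.start_mean)
        dt = np.maximum(t - self.lag_years, 0.0)
        return self.end_mean + (self.start_mean - self.end_mean) * np.exp(-dt / self.tau_years)


@dataclass(frozen=True)
class FossilSeriesParams:
    """Parameters of the fossil time-series generator."""

    n_samples: int = 18
    span_years: float = 16363.0
    n_range: tuple[int, int] = (12, 67)
    trait_trajectories: dict[str, TraitTrajectory] = field(default_factory=dict)
    allometry: dict[str, float] = field(default_factory=dict)
    sl_mean_drift: tuple[float, float] | None = None  # overrides stl endpoints
    noise_correlation: float = 0.3
    missingness: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two temporal samples")
        if not (0.0 <= self.noise_correlation < 1.0):
            raise ValueError("noise_correlation must be in [0, 1)")
        if self.n_range[0] < 1 or self.n_range[0] > self.n_range[1]:
            raise ValueError("invalid n_range")


@dataclass(frozen=True)
class PairLakesParams:
    """Parameters of the species-pair (benthic vs limnetic) generator."""

    lakes: tuple[str, ...] = tuple(reference.SPECIES_PAIR_MEAN_D)
    n_range: tuple[int, int] = (22, 69)
    #: per-lake scale applied to the benthic-limnetic contrast template
    lake_offset_scales: dict[str, float] = field(default_factory=dict)
    contrast_template: dict[str, float] = field(default_factory=dict)
    allometry: dict[str, float] = field(default_factory=dict)
    trait_sds: dict[str, float] = field(default_factory=dict)
    noise_correlation: float = 0.3
    seed: int = 0

    @property
    def n_lakes(self) -> int:
        return len(self.lakes)


@dataclass(frozen=True)
class ArmourScenarioParams:
    """Joint pelvic/dorsal-spine scenario for the association test.

    ``hybridization_rate`` is the probability that a specimen's pelvis and
    spine states are drawn independently from the pooled marginals rather
    than jointly from its armour morph: 0 gives perfect association, 1 gives
    independence.
    """

    n_low: int
    n_high: int
    hybridization_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 0 or self.n_high < 0 or self.n_low + self.n_high < 4:
            raise ValueError("need n_low + n_high >= 4 specimens")
        if not (0.0 <= self.hybridization_rate <= 1.0):
            raise ValueError("hybridization_rate must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth stored alongside every generated table."""

    group_means: pd.DataFrame  # index = trait codes, columns = group labels
    allometric_slopes: dict[str, float]
    true_d: float  # first-vs-last (fossil) — NaN for multi-lake truth
    lake_true_d: dict[str, float]
    params: object


# ---------------------------------------------------------------------------
# defaults calibrated from the published summary table


def default_fossil_params(seed: int = 0, **overrides) -> FossilSeriesParams:
    """Fossil-series defaults: endpoints, noise and sample sizes from the
    published first-vs-last comparison table."""
    trajectories: dict[str, TraitTrajectory] = {}
    for row in reference.KSERIES_TRAIT_TESTS:
        start = _START_MEANS[row.code]
        end = start + row.mean_diff
        shape = "plateau" if row.code in _PLATEAU_TRAITS else "linear"
        lag = _PELVIC_LAG_YEARS if row.code in _PELVIC_TRAITS else 0.0
        trajectories[row.code] = TraitTrajectory(
            start_mean=start,
            end_mean=end,
            shape=shape,
            lag_years=lag,
            sd=reference.derived_within_sample_sd(row),
            n_first=row.n_first,
            n_last=row.n_last,
        )
    registry = default_registry()
    allometry = {c: _DEFAULT_ALLOMETRY_SLOPE for c in registry.size_corrected_codes}
    params = FossilSeriesParams(
        trait_trajectories=trajectories, allometry=allometry, seed=seed
    )
    return replace(params, **overrides) if overrides else params


def default_pair_params(seed: int = 0, **overrides) -> PairLakesParams:
    """Species-pair defaults: contrast template shaped like the fossil
    first-vs-last contrast, scaled per lake to the published mean d values."""
    template = {row.code: -row.mean_diff for row in reference.KSERIES_TRAIT_TESTS}
    norm_d = math.sqrt(sum(v * v for v in template.values()))
    scales = {lake: d / norm_d for lake, d in reference.SPECIES_PAIR_MEAN_D.items()}
    sds = {row.code: reference.derived_within_sample_sd(row) for row in reference.KSERIES_TRAIT_TESTS}
    registry = default_registry()
    allometry = {c: _DEFAULT_ALLOMETRY_SLOPE for c in registry.size_corrected_codes}
    params = PairLakesParams(
        lake_offset_scales=scales,
        contrast_template=template,
        allometry=allometry,
        trait_sds=sds,
        seed=seed,
    )
    return replace(params, **overrides) if overrides else params


# ---------------------------------------------------------------------------
# realized-mean helpers (expectations under clamping/rounding)


def _truncated_normal_mean(mu: float, sd: float) -> float:
    """E[max(X, 0)] for X ~ N(mu, sd)."""
    if sd == 0.0:
        return max(mu, 0.0)
    a = mu / sd
    return mu * norm.cdf(a) + sd * norm.pdf(a)


def _rounded_clamped_mean(mu: float, sd: float, lo: int, hi: int) -> float:
    """E[clip(round(X), lo, hi)] for X ~ N(mu, sd)."""
    if sd == 0.0:
        return float(np.clip(np.round(mu), lo, hi))
    ks = np.arange(lo, hi + 1)
    upper = np.where(ks == hi, np.inf, ks + 0.5)
    lower = np.where(ks == lo, -np.inf, ks - 0.5)
    probs = norm.cdf((upper - mu) / sd) - norm.cdf((lower - mu) / sd)
    return float(np.sum(ks * probs))


def _realized_mean(code: str, registry: TraitRegistry, mu: float, sd_eff: float) -> float:
    if registry.spec(code).kind == "count":
        lo, hi = _COUNT_RANGES.get(code, (0, 10**6))
        return _rounded_clamped_mean(mu, sd_eff, lo, hi)
    return _truncated_normal_mean(mu, sd_eff)


def _correlated_noise(
    rng: np.random.Generator, n: int, codes: list[str], rho: float
) -> dict[str, np.ndarray]:
    """Per-specimen unit-variance noise with exchangeable correlation rho.

    Standard length is excluded from the shared factor: correlation with body
    size is modelled only through the explicit allometric term, so that the
    size correction removes exactly the configured slope and nothing else.
    """
    shared = rng.standard_normal(n)
    out = {}
    for code in codes:
        own = rng.standard_normal(n)
        if code == "stl":
            out[code] = own
        else:
            out[code] = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own
    return out


def _empty_meta(n: int) -> dict[str, np.ndarray]:
    return {c: np.full(n, np.nan) for c in ("pelvic_score", "dorsal_spine_count")}


# ---------------------------------------------------------------------------
# generators


def generate_fossil_series(
    params: FossilSeriesParams | None = None,
) -> tuple[SpecimenTable, SyntheticTruth]:
    """Generate the fossil time series and its ground truth.

    Samples are evenly spaced over ``span_years``.  Within each sample the
    number of non-missing values per trait interpolates between the trait's
    configured first/last counts (clipped to ``n_range``); standard length is
    fully observed since it is the size covariate.
    """
    if params is None:
        params = default_fossil_params()
    registry = default_registry()
    trajectories = dict(params.trait_trajectories)
    missing_traits = set(registry.codes) - set(trajectories)
    if missing_traits:
        raise ValueError(f"no trajectory configured for traits: {sorted(missing_traits)}")
    if params.sl_mean_drift is not None:
        stl = trajectories["stl"]
        trajectories["stl"] = replace(
            stl, start_mean=params.sl_mean_drift[0], end_mean=params.sl_mean_drift[1]
        )

    rng = substream(params.seed, "generate")
    rng_miss = substream(params.seed, "missingness")
    ages = np.linspace(0.0, params.span_years, params.n_samples)
    lo_n, hi_n = params.n_range
    span = params.span_years
    codes = list(registry.codes)
    stl_traj = trajectories["stl"]
    # reference length for the generative allometric component
    sl_ref = float(np.mean(stl_traj.mean_at(ages, span)))

    frames: list[pd.DataFrame] = []
    truth_cols: dict[str, list[float]] = {}
    group_labels = [f"K{k + 1:02d}" for k in range(params.n_samples)]
    sid = 0

    for k, (group, age) in enumerate(zip(group_labels, ages)):
        frac = k / (params.n_samples - 1)
        # per-trait target non-missing counts for this sample
        n_target: dict[str, int] = {}
        for code, traj in trajectories.items():
            if traj.n_first is None or traj.n_last is None:
                n_target[code] = hi_n
            else:
                n_interp = traj.n_first + frac * (traj.n_last - traj.n_first)
                n_target[code] = int(np.clip(round(n_interp), lo_n, hi_n))
        n_g = max(n_target.values())

        noise = _correlated_noise(rng, n_g, codes, params.noise_correlation)
        stl_mu = float(stl_traj.mean_at(age, span))
        stl_vals = np.maximum(stl_mu + stl_traj.sd * noise["stl"], 0.0)
        sl_dev = stl_vals - sl_ref

        cols: dict[str, np.ndarray] = {"stl": stl_vals}
        for code, traj in trajectories.items():
            if code == "stl":
                continue
            mu = float(traj.mean_at(age, span))
            vals = mu + traj.sd * noise[code]
            slope = params.allometry.get(code, 0.0)
            if slope:
                vals = vals + slope * sl_dev
            if registry.spec(code).kind == "count":
                lo, hi = _COUNT_RANGES.get(code, (0, 10**6))
                vals = np.clip(np.round(vals), lo, hi)
            else:
                vals = np.maximum(vals, 0.0)
            if params.missingness and n_target[code] < n_g:
                mask = rng_miss.choice(n_g, size=n_g - n_target[code], replace=False)
                vals = vals.astype(float)
                vals[mask] = np.nan
            cols[code] = vals

        meta = {
            "specimen_id": [f"F{sid + i:05d}" for i in range(n_g)],
            "dataset": ["fossil"] * n_g,
            "group": [group] * n_g,
            "sample_order": np.full(n_g, k + 1, dtype=float),
            "age_years": np.full(n_g, age),
            **_empty_meta(n_g),
        }
        sid += n_g
        frames.append(pd.DataFrame({**meta, **{c: cols[c] for c in codes}}))

        # realized truth means on the corrected scale: expectation of the
        # clamped raw value minus the allometric component that the size
        # correction removes (the group-level shift b*(stl_mu - sl_ref))
        truth_col = []
        for code in codes:
            traj = trajectories[code]
            mu = float(traj.mean_at(age, span))
            slope = params.allometry.get(code, 0.0)
            sd_eff = math.hypot(traj.sd, slope * stl_traj.sd)
            shift = slope * (stl_mu - sl_ref)
            truth_col.append(_realized_mean(code, registry, mu + shift, sd_eff) - shift)
        truth_cols[group] = truth_col

    data = pd.concat(frames, ignore_index=True)
    table = SpecimenTable(
        data, registry, provenance=f"synthetic fossil series (seed={params.seed})"
    )
    means = pd.DataFrame(truth_cols, index=codes)
    true_d = float(
        np.linalg.norm(means[group_labels[-1]].to_numpy() - means[group_labels[0]].to_numpy())
    )
    truth = SyntheticTruth(
        group_means=means,
        allometric_slopes=dict(params.allometry),
        true_d=true_d,
        lake_true_d={},
        params=params,
    )
    return table, truth


def generate_species_pairs(
    params: PairLakesParams | None = None,
) -> tuple[SpecimenTable, SyntheticTruth]:
    """Generate benthic/limnetic specimens for each species-pair lake."""
    if params is None:
        params = default_pair_params()
    registry = default_registry()
    codes = list(registry.codes)
    template = params.contrast_template
    missing = set(codes) - set(template)
    if missing:
        raise ValueError(f"contrast template missing traits: {sorted(missing)}")
    sds = params.trait_sds

    rng = substream(params.seed, "generate")
    rng_sizes = substream(params.seed, "sizes")
    base = dict(_START_MEANS)
    sl_ref = base["stl"]

    frames: list[pd.DataFrame] = []
    truth_cols: dict[str, list[float]] = {}
    lake_true_d: dict[str, float] = {}
    sid = 0

    for lake in params.lakes:
        scale = params.lake_offset_scales.get(lake, 1.0)
        for ecotype, sign in (("benthic", 0.5), ("limnetic", -0.5)):
            group = f"{lake}_{ecotype}"
            n_g = int(rng_sizes.integers(params.n_range[0], params.n_range[1] + 1))
            noise = _correlated_noise(rng, n_g, codes, params.noise_correlation)

            stl_mu = base["stl"] + sign * scale * template["stl"]
            stl_sd = sds["stl"]
            stl_vals = np.maximum(stl_mu + stl_sd * noise["stl"], 0.0)
            sl_dev = stl_vals - sl_ref

            cols: dict[str, np.ndarray] = {"stl": stl_vals}
            truth_col: dict[str, float] = {}
            for code in codes:
                if code == "stl":
                    truth_col[code] = _truncated_normal_mean(stl_mu, stl_sd)
                    continue
                mu = base[code] + sign * scale * template[code]
                vals = mu + sds[code] * noise[code]
                slope = params.allometry.get(code, 0.0)
                if slope:
                    vals = vals + slope * sl_dev
                if registry.spec(code).kind == "count":
                    lo, hi = _COUNT_RANGES.get(code, (0, 10**6))
                    vals = np.clip(np.round(vals), lo, hi)
                else:
                    vals = np.maximum(vals, 0.0)
                cols[code] = vals
                sd_eff = math.hypot(sds[code], slope * stl_sd)
                shift = slope * (stl_mu - sl_ref)
                truth_col[code] = _realized_mean(code, registry, mu + shift, sd_eff) - shift

            meta = {
                "specimen_id": [f"E{sid + i:05d}" for i in range(n_g)],
                "dataset": ["extant"] * n_g,
                "group": [group] * n_g,
                "sample_order": np.full(n_g, np.nan),
                "age_years": np.full(n_g, np.nan),
                **_empty_meta(n_g),
            }
            sid += n_g
            frames.append(pd.DataFrame({**meta, **{c: cols[c] for c in codes}}))
            truth_cols[group] = [truth_col[c] for c in codes]

        b = np.array(truth_cols[f"{lake}_benthic"])
        l = np.array(truth_cols[f"{lake}_limnetic"])
        lake_true_d[lake] = float(np.linalg.norm(b - l))

    data = pd.concat(frames, ignore_index=True)
    table = SpecimenTable(
        data, registry, provenance=f"synthetic species pairs (seed={params.seed})"
    )
    truth = SyntheticTruth(
        group_means=pd.DataFrame(truth_cols, index=codes),
        allometric_slopes=dict(params.allometry),
        true_d=float("nan"),
        lake_true_d=lake_true_d,
        params=params,
    )
    return table, truth


# low-armour morph marginals: pelvic score weights over {0, 0.5, 1} and
# dorsal spine weights over {0, 1, 2} (a few two-spined fish occur)
_LOW_PELVIC = ((0.0, 0.45), (0.5, 0.30), (1.0, 0.25))
_LOW_SPINES = ((0, 0.50), (1, 0.45), (2, 0.05))


def generate_armour_scenario(params: ArmourScenarioParams) -> SpecimenTable:
    """Generate a mixed high-/low-armour sample.

    High-armour specimens carry the fully armoured template (pelvic score 3,
    three dorsal spines); low-armour specimens draw a reduced pelvis
    (score <= 1) and fewer than three spines.  With hybridization rate ``h``
    each specimen's two armour states are drawn independently from the pooled
    marginals with probability ``h``.
    """
    rng = substream(params.seed, "generate")
    n = params.n_low + params.n_high
    p_high = params.n_high / n

    low_pelvic_vals = np.array([v for v, _ in _LOW_PELVIC])
    low_pelvic_p = np.array([p for _, p in _LOW_PELVIC])
    low_spine_vals = np.array([v for v, _ in _LOW_SPINES], dtype=float)
    low_spine_p = np.array([p for _, p in _LOW_SPINES])

    def draw_low_pelvis(size: int) -> np.ndarray:
        return rng.choice(low_pelvic_vals, size=size, p=low_pelvic_p)

    def draw_low_spines(size: int) -> np.ndarray:
        return rng.choice(low_spine_vals, size=size, p=low_spine_p)

    morph = np.array(["high"] * params.n_high + ["low"] * params.n_low)
    independent = rng.random(n) < params.hybridization_rate

    pelvic = np.empty(n)
    spines = np.empty(n)
    for i in range(n):
        if independent[i]:
            # pelvis and spine states drawn independently from pooled marginals
            pelvic[i] = 3.0 if rng.random() < p_high else draw_low_pelvis(1)[0]
            spines[i] = 3.0 if rng.random() < p_high else draw_low_spines(1)[0]
        elif morph[i] == "high":
            pelvic[i], spines[i] = 3.0, 3.0
        else:
            pelvic[i] = draw_low_pelvis(1)[0]
            spines[i] = draw_low_spines(1)[0]

    registry = default_registry()
    meta = {
        "specimen_id": [f"A{i:05d}" for i in range(n)],
        "dataset": ["fossil"] * n,
        "group": ["armour_sample"] * n,
        "sample_order": np.full(n, np.nan),
        "age_years": np.full(n, np.nan),
        "pelvic_score": pelvic,
        "dorsal_spine_count": spines,
    }
    traits = {c: np.full(n, np.nan) for c in registry.codes}
    data = pd.DataFrame({**meta, **traits})
    return SpecimenTable(
        data, registry, provenance=f"synthetic armour scenario (seed={params.seed})"
    )
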