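"""Synthetic registry, questionnaire and trait data with planted truth.

Every pipeline stage is testable without the deposited registry and
questionnaire files: these generators emulate their structure and record
the planted ground truth (peak geometry, true correlations, breed means)
so recovery can be asserted.

* :func:`gen_peak_series` builds a boom-bust registration series shaped
  like the classic fashion-cycle narrative (e.g. a breed climbing from
  ~2,500 to ~60,000 registrations over 13 years and collapsing again):
  piecewise-exponential rise and fall between a low baseline and the peak,
  with optional multiplicative lognormal noise.  The piecewise-exponential
  shape is chosen because its threshold-crossing years have closed forms,
  making the planted truth exact in the noiseless limit.
* :func:`gen_neutral_copying` is a Wright-Fisher style neutral copying
  process: a drift-only null in which each owner copies a random
  previous-year registration (or innovates uniformly), producing
  popularity fluctuations without any intrinsic breed preference.
* :func:`gen_trait_table` plants an exact target correlation between any
  popularity vector and each breed-level trait.
* :func:`gen_dog_records` emulates per-dog questionnaire records with
  controllable between-breed and within-breed variance.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CBARQ_SCALES, RegistrationMatrix, write_registrations

__all__ = [
    "PeakTruth",
    "gen_peak_series",
    "gen_registration_matrix",
    "gen_neutral_copying",
    "gen_trait_table",
    "gen_dog_records",
    "write_preset",
]

SCALE_RANGE = (0.0, 4.0)  # questionnaire instrument range
SCALE_CENTER = 2.0


@dataclass
class PeakTruth:
    """Planted peak geometry, recorded on the noiseless integer curve."""

    t_begin: int
    t_peak: int
    t_end: int
    peak_count: int
    total: int
    rise_rate: float  # (N(t_peak) - N(t_begin)) / (t_peak - t_begin)
    fall_rate: float  # (N(t_peak) - N(t_end)) / (t_end - t_peak)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


def gen_peak_series(
    years: tuple[int, int],
    peak_height: float = 60_000,
    t_peak: int | None = None,
    rise_years: int = 13,
    fall_years: int = 12,
    baseline_frac: float = 0.04,
    noise_cv: float = 0.0,
    threshold: float = 0.10,
    seed=None,
) -> tuple[pd.Series, PeakTruth]:
    """One boom-bust registration series with planted peak geometry.

    The noiseless curve sits at ``baseline_frac * peak_height`` outside the
    episode and rises/falls exponentially over ``rise_years``/``fall_years``
    to the peak.  ``baseline_frac`` must be below ``threshold`` so the peak
    boundaries exist.  Noise is multiplicative lognormal with coefficient
    of variation ``noise_cv``, applied before rounding to integer counts.
    The returned truth holds the threshold-crossing years, rates and total
    of the noiseless integer curve.
    """
    y0, y1 = years
    if rise_years < 1 or fall_years < 1:
        raise ValueError("rise_years and fall_years must be >= 1")
    if not 0 < baseline_frac < threshold:
        raise ValueError("baseline_frac must lie in (0, threshold)")
    if t_peak is None:
        t_peak = y0 + (y1 - y0) // 2
    g_rise = math.log(1 / baseline_frac) / rise_years
    g_fall = math.log(1 / baseline_frac) / fall_years
    k_begin = math.ceil(math.log(1 / threshold) / g_rise)
    k_end = math.ceil(math.log(1 / threshold) / g_fall)
    if t_peak - k_begin < y0 or t_peak + k_end > y1:
        raise ValueError(
            "infeasible peak geometry: threshold crossings fall outside the span"
        )
    t = np.arange(y0, y1 + 1)
    curve = np.full(t.shape, baseline_frac * peak_height)
    rise = (t >= t_peak - rise_years) & (t <= t_peak)
    curve[rise] = peak_height * np.exp(-g_rise * (t_peak - t[rise]))
    fall = (t > t_peak) & (t <= t_peak + fall_years)
    curve[fall] = peak_height * np.exp(-g_fall * (t[fall] - t_peak))
    clean = np.rint(curve).astype(int)

    # Crossing years on the rounded noiseless curve (rounding can shift the
    # analytic crossing by one year at the threshold boundary).
    i_peak = t_peak - y0
    cut = threshold * clean[i_peak]
    t_begin = next(
        int(t[i]) for i in range(i_peak - 1, -1, -1) if clean[i] <= cut
    )
    t_end = next(
        int(t[i]) for i in range(i_peak + 1, len(t)) if clean[i] <= cut
    )
    truth = PeakTruth(
        t_begin=t_begin,
        t_peak=int(t_peak),
        t_end=t_end,
        peak_count=int(clean[i_peak]),
        total=int(clean.sum()),
        rise_rate=(clean[i_peak] - clean[t_begin - y0]) / (t_peak - t_begin),
        fall_rate=(clean[i_peak] - clean[t_end - y0]) / (t_end - t_peak),
    )
    rng = _as_rng(seed)
    noisy = np.rint(clean * _lognormal_noise(rng, noise_cv, len(clean))).astype(int)
    series = pd.Series(noisy if noise_cv > 0 else clean, index=t)
    series.index.name = "year"
    return series, truth


def gen_registration_matrix(
    n_breeds: int = 50,
    n_peaked: int = 30,
    years: tuple[int, int] = (1926, 2005),
    noise_cv: float = 0.0,
    seed=None,
) -> tuple[RegistrationMatrix, pd.DataFrame]:
    """Registration matrix with a planted boom-bust peak in some breeds.

    The remaining breeds are flat series (constant level plus noise) that
    never dip to 10% of their maximum, hence have no peak.  Returns the
    matrix and a truth table indexed by breed with the planted geometry
    (NaN rows for peakless breeds).
    """
    if n_peaked > n_breeds:
        raise ValueError("n_peaked cannot exceed n_breeds")
    rng = _as_rng(seed)
    y0, y1 = years
    breeds = [f"breed_{i:03d}" for i in range(n_breeds)]
    cols: dict[str, pd.Series] = {}
    rows = []
    for i, breed in enumerate(breeds):
        if i < n_peaked:
            rise = int(rng.integers(5, 16))
            fall = int(rng.integers(5, 16))
            margin = max(rise, fall) + 3
            t_pk = int(rng.integers(y0 + margin, y1 - margin + 1))
            series, truth = gen_peak_series(
                years,
                peak_height=float(rng.uniform(5_000, 60_000)),
                t_peak=t_pk,
                rise_years=rise,
                fall_years=fall,
                baseline_frac=float(rng.uniform(0.02, 0.08)),
                noise_cv=noise_cv,
                seed=rng,
            )
            rows.append({"breed": breed, "has_peak": True, **vars(truth)})
        else:
            level = float(rng.uniform(1_000, 20_000))
            t = np.arange(y0, y1 + 1)
            counts = np.rint(
                level * _lognormal_noise(rng, noise_cv, len(t))
            ).astype(int)
            series = pd.Series(counts, index=t)
            rows.append(
                {
                    "breed": breed,
                    "has_peak": False,
                    "total": int(counts.sum()),
                }
            )
        cols[breed] = series
    matrix = RegistrationMatrix(pd.DataFrame(cols))
    truth_df = pd.DataFrame(rows).set_index("breed")
    return matrix, truth_df


def gen_neutral_copying(
    n_breeds: int,
    years: tuple[int, int],
    population_size: int,
    innovation: float = 0.01,
    seed=None,
) -> RegistrationMatrix:
    """Neutral (drift-only) copying process over breed registrations.

    Each year ``population_size`` owners register one dog: with
    probability ``1 - innovation`` the owner copies the breed of a
    uniformly random previous-year registration, otherwise picks a breed
    uniformly at random.  Yearly counts are the resulting multinomial
    draws, so total registrations are conserved at ``population_size``
    every year.  The first year is uniform-multinomial.
    """
    if population_size < n_breeds:
        raise ValueError("population_size must be >= n_breeds")
    if not 0 <= innovation <= 1:
        raise ValueError("innovation must lie in [0, 1]")
    rng = _as_rng(seed)
    y0, y1 = years
    n_years = y1 - y0 + 1
    counts = np.empty((n_years, n_breeds), dtype=int)
    probs = np.full(n_breeds, 1 / n_breeds)
    counts[0] = rng.multinomial(population_size, probs)
    for i in range(1, n_years):
        freq = counts[i - 1] / population_size
        probs = (1 - innovation) * freq + innovation / n_breeds
        counts[i] = rng.multinomial(population_size, probs)
    df = pd.DataFrame(
        counts,
        index=pd.Index(np.arange(y0, y1 + 1), name="year"),
        columns=[f"breed_{i:03d}" for i in range(n_breeds)],
    )
    return RegistrationMatrix(df.astype(float))


def _planted_vector(
    z: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Standard-scale vector with population correlation rho to z."""
    if abs(rho) > 0.99:
        raise ValueError("|rho| must be <= 0.99")
    eps = rng.standard_normal(len(z))
    return rho * z + math.sqrt(1 - rho**2) * eps


def gen_trait_table(
    popularity: pd.Series,
    rho_scales: dict[str, float] | float = 0.0,
    rho_disorders: float = 0.0,
    rho_longevity: float = 0.0,
    seed=None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Breed-level trait table with planted popularity correlations.

    Each trait t is built as ``rho_t * z + sqrt(1 - rho_t^2) * eps`` with
    z the standardized popularity vector, then affinely mapped onto a
    plausible range: questionnaire scales around 2.0 on the 0-4 scale,
    survey longevity around 11.5 years with veterinary-hospital estimates
    systematically lower, disorder counts around a median of ~32 (rounded,
    floored at 1).  Returns the table (indexed like ``popularity``) and
    the dict of planted correlations.
    """
    rng = _as_rng(seed)
    pop = popularity.astype(float)
    z = (pop - pop.mean()) / pop.std(ddof=0)
    z = z.to_numpy()
    if np.isscalar(rho_scales):
        rho_scales = {s: float(rho_scales) for s in CBARQ_SCALES}
    truth: dict[str, float] = {}
    out: dict[str, np.ndarray] = {}
    for scale in CBARQ_SCALES:
        rho = float(rho_scales.get(scale, 0.0))
        truth[scale] = rho
        out[scale] = np.clip(
            SCALE_CENTER + 0.5 * _planted_vector(z, rho, rng), *SCALE_RANGE
        )
    w_long = _planted_vector(z, rho_longevity, rng)
    out["longevity_survey"] = np.clip(11.5 + 1.5 * w_long, 6.0, 14.5)
    vet_gap = rng.uniform(3.5, 5.5, size=len(z))
    out["longevity_vet"] = np.clip(out["longevity_survey"] - vet_gap, 3.0, 9.5)
    truth["longevity_survey"] = rho_longevity
    w_dis = _planted_vector(z, rho_disorders, rng)
    out["n_disorders"] = np.maximum(1, np.rint(32.0 + 15.0 * w_dis)).astype(int)
    truth["n_disorders"] = rho_disorders
    table = pd.DataFrame(out, index=pop.index)
    table.index.name = "breed"
    return table, truth


def gen_dog_records(
    n_breeds: int = 92,
    n_small_breeds: int = 12,
    dogs_per_breed: tuple[int, int] = (20, 200),
    between_breed_sd: float = 0.4,
    within_breed_sd: float = 0.6,
    breeds: list[str] | None = None,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dog questionnaire records with a real between-breed effect.

    Breed-typical means per scale are drawn from a normal with SD
    ``between_breed_sd`` around the scale center; individual dog scores
    add within-breed noise (SD ``within_breed_sd``) and are clipped to the
    instrument range.  ``n_small_breeds`` of the breeds receive fewer than
    20 dogs to exercise the minimum-count filter; the rest draw their dog
    count uniformly from ``dogs_per_breed``.  Returns (records, truth)
    where truth holds the planted breed means and dog counts.
    """
    if between_breed_sd < 0 or within_breed_sd <= 0:
        raise ValueError("SDs must be positive")
    if n_small_breeds > n_breeds:
        raise ValueError("n_small_breeds cannot exceed n_breeds")
    rng = _as_rng(seed)
    if breeds is None:
        breeds = [f"breed_{i:03d}" for i in range(n_breeds)]
    elif len(breeds) != n_breeds:
        raise ValueError("breeds list must have length n_breeds")
    small = set(rng.choice(n_breeds, size=n_small_breeds, replace=False))
    lo, hi = dogs_per_breed
    records = []
    truth_rows = []
    dog_id = 0
    for i, breed in enumerate(breeds):
        n_dogs = (
            int(rng.integers(3, 20)) if i in small else int(rng.integers(lo, hi + 1))
        )
        means = SCALE_CENTER + between_breed_sd * rng.standard_normal(
            len(CBARQ_SCALES)
        )
        truth_rows.append(
            {"breed": breed, "n_dogs": n_dogs}
            | {s: m for s, m in zip(CBARQ_SCALES, means)}
        )
        scores = np.clip(
            means + within_breed_sd * rng.standard_normal((n_dogs, len(CBARQ_SCALES))),
            *SCALE_RANGE,
        )
        for row in scores:
            records.append(
                {"dog_id": f"dog_{dog_id:06d}", "breed": breed}
                | {s: v for s, v in zip(CBARQ_SCALES, row)}
            )
            dog_id += 1
    return pd.DataFrame(records), pd.DataFrame(truth_rows).set_index("breed")


def write_preset(preset: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a named synthetic dataset as the CSV files the pipeline reads.

    Presets: ``peaks`` (registration matrix with planted peaks + truth),
    ``neutral`` (drift-only registration matrix), ``dogs`` (per-dog
    questionnaire records + breed-mean truth), ``traits`` (a complete
    input set: registrations, per-dog records, longevity, disorders, and
    truth with planted trait-popularity correlations).  Returns the paths
    written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    def _w(df: pd.DataFrame, name: str, index: bool) -> None:
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)

    if preset == "peaks":
        matrix, truth = gen_registration_matrix(noise_cv=0.1, seed=rng)
        write_registrations(matrix, out / "registrations.csv")
        written.append(out / "registrations.csv")
        _w(truth, "truth.csv", index=True)
    elif preset == "neutral":
        matrix = gen_neutral_copying(
            n_breeds=50, years=(1926, 2005), population_size=100_000, seed=rng
        )
        write_registrations(matrix, out / "registrations.csv")
        written.append(out / "registrations.csv")
        _w(
            pd.DataFrame(
                {"parameter": ["n_breeds", "population_size", "innovation"],
                 "value": [50, 100_000, 0.01]}
            ),
            "truth.csv",
            index=False,
        )
    elif preset == "dogs":
        records, truth = gen_dog_records(seed=rng)
        _w(records, "cbarq.csv", index=False)
        _w(truth, "truth.csv", index=True)
    elif preset == "traits":
        matrix, peak_truth = gen_registration_matrix(
            n_breeds=92, n_peaked=60, noise_cv=0.1, seed=rng
        )
        # 80 of the 92 questionnaire breeds also appear in the registry
        reg_breeds = matrix.breeds[:80]
        write_registrations(
            RegistrationMatrix(matrix.counts[reg_breeds]),
            out / "registrations.csv",
        )
        written.append(out / "registrations.csv")
        records, _ = gen_dog_records(
            n_breeds=92, n_small_breeds=12, breeds=matrix.breeds, seed=rng
        )
        _w(records, "cbarq.csv", index=False)
        totals = matrix.counts.sum(axis=0)
        traits, rho_truth = gen_trait_table(
            totals, rho_scales=0.0, rho_disorders=0.5, seed=rng
        )
        _w(
            traits[["longevity_survey", "longevity_vet"]].reset_index(),
            "longevity.csv",
            index=False,
        )
        _w(traits[["n_disorders"]].reset_index(), "disorders.csv", index=False)
        truth = peak_truth.join(
            pd.DataFrame({"planted_rho_disorders": rho_truth["n_disorders"]},
                         index=peak_truth.index)
        )
        _w(truth, "truth.csv", index=True)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return written
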