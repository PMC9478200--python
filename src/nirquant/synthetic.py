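"""Synthetic NIR mixture spectra with known ground truth.

The generator emulates the statistical structure a diffuse-reflectance
calibration of powdered plant material assumes: Beer–Lambert-linear
mixing of Gaussian absorption bands for the two triterpenoid analytes
(oleanolic and ursolic acid) and a few interfering matrix components,
a smooth baseline, per-sample multiplicative scatter (slope and offset),
optional mild nonlinearity, and per-replicate instrument noise.
Triplicate acquisitions are averaged, as in routine FT-NIR practice.

Because the two analytes are isomers, their band models share centers
with only small shifts and amplitude differences: single-analyte
regressions are deliberately ill-posed while their sum is well
determined — the regime in which the *total* content is the natural
modeling target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .spectra import (ReferenceValues, SpectraSet, Spectrum, WavenumberGrid,
                      average_replicates)

__all__ = [
    "BandModel",
    "ComponentSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "pure_component_spectrum",
    "simulate_dataset",
    "split_dataset",
    "default_config",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band: amplitude in AU per mg/g at unit
    concentration, center and width (sigma) in cm^-1."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")


@dataclass(frozen=True)
class ComponentSpec:
    """A mixture component: its bands and its concentration distribution.

    Concentrations are drawn from a normal distribution truncated to
    [lo, hi] — reproducing the mean/SD/range structure a field survey of
    real samples shows, rather than an unrealistic uniform spread.
    """

    name: str
    bands: tuple
    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


# Band centers follow the NIR assignments for the triterpenoid acids:
# carboxylic C=O stretch combination near 5,177 cm^-1, methyl C-H
# combinations near 7,230 and 5,784 cm^-1, O-H combination at 4,712 and
# C-H combinations at 4,400 / 4,329 / 4,260 cm^-1.  The ursolic-acid
# bands are shifted by ~10 cm^-1 with slightly different amplitudes:
# isomers with nearly identical NIR signatures.
_OA_BANDS = (
    BandModel(7230.0, 70.0, 0.0045),
    BandModel(5784.0, 55.0, 0.0085),
    BandModel(5177.0, 60.0, 0.0110),
    BandModel(4712.0, 45.0, 0.0090),
    BandModel(4400.0, 40.0, 0.0080),
    BandModel(4329.0, 38.0, 0.0070),
    BandModel(4260.0, 36.0, 0.0060),
)
_UA_BANDS = (
    BandModel(7241.0, 68.0, 0.0047),
    BandModel(5795.0, 56.0, 0.0082),
    BandModel(5186.0, 59.0, 0.0113),
    BandModel(4722.0, 46.0, 0.0087),
    BandModel(4409.0, 41.0, 0.0083),
    BandModel(4337.0, 37.0, 0.0068),
    BandModel(4269.0, 36.0, 0.0062),
)
# Matrix interferents: broad water/carbohydrate-like features across the
# working range, concentrations on an arbitrary unit scale.
_INTERFERENT_SPECS = (
    ComponentSpec("water", (
        BandModel(6900.0, 180.0, 0.055),
        BandModel(5180.0, 150.0, 0.045),
    ), mean=1.0, sd=0.25, lo=0.3, hi=1.7),
    ComponentSpec("carbohydrate", (
        BandModel(4750.0, 160.0, 0.050),
        BandModel(5600.0, 200.0, 0.030),
        BandModel(8300.0, 260.0, 0.018),
    ), mean=1.0, sd=0.30, lo=0.2, hi=1.8),
    ComponentSpec("protein", (
        BandModel(4590.0, 90.0, 0.030),
        BandModel(6520.0, 140.0, 0.020),
    ), mean=1.0, sd=0.20, lo=0.4, hi=1.6),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions.

    Concentration distributions (mg/g): oleanolic acid truncated normal
    mean 7.7, SD 2.6 on [1.9, 13.4]; ursolic acid mean 1.5, SD 1.0 on
    [0.2, 5.0].  Grid 12,500–4,000 cm^-1 at 8 cm^-1.  Scatter slope
    lognormal around 1, offset normal around 0, plus a fixed smooth
    baseline; noise is added per replicate and the three replicates are
    averaged.  ``gamma`` adds an element-wise quadratic term to the clean
    mixture spectrum (0 = purely Beer–Lambert linear).
    """

    n_samples: int = 122
    grid_hi: float = 12500.0
    grid_lo: float = 4000.0
    grid_step: float = 8.0
    oa: ComponentSpec = ComponentSpec("oa", _OA_BANDS, 7.7, 2.6, 1.9, 13.4)
    ua: ComponentSpec = ComponentSpec("ua", _UA_BANDS, 1.5, 1.0, 0.2, 5.0)
    interferents: tuple = _INTERFERENT_SPECS
    scatter_slope_sigma: float = 0.08     # lognormal sigma of the slope
    scatter_offset_sigma: float = 0.01    # AU
    baseline_coefs: tuple = (0.05, -0.02, 0.01)  # in normalized wavenumber
    noise_sd: float = 0.008               # AU per replicate
    gamma: float = 0.0                    # analyte-load response saturation
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def grid(self) -> WavenumberGrid:
        return WavenumberGrid.from_range(self.grid_hi, self.grid_lo,
                                         self.grid_step)


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent draws behind a simulated dataset, for recovery tests."""

    concentrations: dict          # component name -> (n,) array
    slopes: np.ndarray            # (n,)
    offsets: np.ndarray           # (n,)
    baseline: np.ndarray          # (p,)
    pure_spectra: dict            # component name -> (p,) unit response
    config: SyntheticConfig


def pure_component_spectrum(bands: Sequence[BandModel],
                            grid: WavenumberGrid) -> Spectrum:
    """Unit-concentration response: a sum of Gaussian bands,
    amplitude * exp(-(v - center)^2 / (2 width^2))."""
    v = grid.values
    total = np.zeros(v.size)
    for band in bands:
        total += band.amplitude * np.exp(
            -((v - band.center) ** 2) / (2.0 * band.width ** 2))
    return Spectrum(grid, total)


def _baseline(config: SyntheticConfig, grid: WavenumberGrid) -> np.ndarray:
    v = grid.values
    mid = 0.5 * (v[0] + v[-1])
    span = 0.5 * (v[0] - v[-1])
    u = (v - mid) / span
    return sum(c * u ** k for k, c in enumerate(config.baseline_coefs))


def simulate_dataset(config: SyntheticConfig
                     ) -> tuple[SpectraSet, list[ReferenceValues], SyntheticTruth]:
    """Draw a full dataset: spectra (replicate-averaged), reference
    values, and the latent truth record.  Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    n = config.n_samples
    ids = tuple(f"s{i + 1:03d}" for i in range(n))

    components = (config.oa, config.ua) + tuple(config.interferents)
    pure = {c.name: pure_component_spectrum(c.bands, grid).absorbance
            for c in components}
    if all(b.amplitude == 0 for c in components for b in c.bands):
        logger.warning("all band amplitudes are zero; spectra carry no signal")

    conc = {c.name: c.draw(n, rng) for c in components}
    # Optional mild nonlinearity: the spectral response of the isomer pair
    # saturates with the *total* analyte load (self/mutual absorption), so
    # the well-determined sum coordinate in spectral space is a curved
    # function g(T) = T*(1 - gamma*T/(2*T_max)) of the assayed total T.
    # No linear functional of the spectra can then read T exactly, while a
    # smooth nonlinear reader of the PLS scores can invert g.  gamma = 0 is
    # the purely Beer-Lambert-linear limit.
    total = conc[config.oa.name] + conc[config.ua.name]
    t_max = config.oa.hi + config.ua.hi
    response_factor = 1.0 - config.gamma * total / (2.0 * t_max)
    clean = np.zeros((n, grid.n_points))
    for c in components:
        values = conc[c.name]
        if c.name in (config.oa.name, config.ua.name):
            values = values * response_factor
        clean += np.outer(values, pure[c.name])
    base = _baseline(config, grid)
    clean = clean + base

    slopes = np.exp(rng.normal(0.0, config.scatter_slope_sigma, size=n))
    offsets = rng.normal(0.0, config.scatter_offset_sigma, size=n)

    replicates = []
    for _ in range(config.n_replicates):
        noise = rng.normal(0.0, config.noise_sd, size=clean.shape)
        observed = slopes[:, None] * clean + offsets[:, None] + noise
        replicates.append(SpectraSet(ids, grid, observed))
    spectra = average_replicates(replicates)

    refs = [ReferenceValues(sid, round(float(o), 4), round(float(u), 4),
                            round(float(o), 4) + round(float(u), 4))
            for sid, o, u in zip(ids, conc["oa"], conc["ua"])]
    truth = SyntheticTruth(conc, slopes, offsets, base, pure, config)
    return spectra, refs, truth


def split_dataset(ids: Sequence[str], proportion: tuple[int, int] = (2, 1),
                  seed: int = 0) -> tuple[list[str], list[str]]:
    """Random a:b split into (calibration, validation), seed-deterministic.

    Sizes are round(n*a/(a+b)) and the remainder; each subset preserves
    the input order of its members.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    a, b = proportion
    if a < 1 or b < 1 or a != int(a) or b != int(b):
        raise ValueError("proportion must be two positive integers")
    n_cal = int(round(n * a / (a + b)))
    n_cal = min(max(n_cal, 1), n - 1)
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=n_cal, replace=False).tolist())
    calibration = [s for i, s in enumerate(ids) if i in chosen]
    validation = [s for i, s in enumerate(ids) if i not in chosen]
    return calibration, validation


def default_config(**overrides) -> SyntheticConfig:
    """The default study conditions, with keyword overrides."""
    return replace(SyntheticConfig(), **overrides)
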