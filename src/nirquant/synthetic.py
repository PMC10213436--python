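"""Synthetic NIR spectra with known ground-truth analyte concentrations.

The generator follows a Beer-Lambert mixing model: each of ``n_components``
chemical components has a fixed pure spectrum built from random Gaussian
absorption bands; a sample's spectrum is the concentration-weighted sum of
the pure spectra, distorted by a per-sample multiplicative scatter factor,
a per-sample low-order polynomial baseline, and additive white noise.
Component 0 is the analyte whose concentration is the regression target.
These are exactly the artifacts the preprocessing operators are designed
to remove, so preprocessing-versus-model comparisons on this data are
meaningful.

The default shape (620 samples, 1,557 points, 3,999-10,001 cm^-1) mirrors
a typical FT-NIR tobacco dataset; the analyte statistics (mean 2.5, sd
0.6) mimic a plausible nicotine concentration range and are generator
choices, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import ReferenceValues, SpectraSet


class GenerationError(RuntimeError):
    """Raised when truncated sampling fails to produce valid draws."""


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 620
    n_points: int = 1557
    wn_min: float = 3999.0
    wn_max: float = 10001.0
    n_components: int = 5  # component 0 is the analyte
    peaks_per_component: int = 6
    peak_width_range: tuple[float, float] = (50.0, 300.0)  # cm^-1
    analyte_mean: float = 2.5
    analyte_sd: float = 0.6
    baseline_order: int = 2
    baseline_sd: float = 0.05  # sd of each per-sample polynomial coefficient
    scatter_sd: float = 0.05
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wn_min >= self.wn_max:
            raise ValueError("wn_min must be < wn_max")
        if self.n_components < 1:
            raise ValueError("need at least the analyte component")
        if min(self.analyte_sd, self.scatter_sd, self.noise_sd, self.baseline_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_points < 3 or self.n_samples < 0:
            raise ValueError("invalid grid/sample sizes")


def _truncated_positive(
    rng: np.random.Generator, mean: float, sd: float, size: int, retries: int = 100
) -> np.ndarray:
    """Normal(mean, sd) draws truncated to > 0 by bounded redrawing."""
    out = rng.normal(mean, sd, size)
    for _ in range(retries):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise GenerationError(
        f"could not draw positive values from Normal({mean}, {sd}) "
        f"after {retries} retries"
    )


def generate(
    cfg: SyntheticConfig,
) -> tuple[SpectraSet, ReferenceValues, np.ndarray]:
    """Generate spectra, analyte concentrations and the pure component
    spectra. Fully reproducible from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_pure, rng_conc, rng_base, rng_scatter, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n, p = cfg.n_samples, cfg.n_points
    wn = np.linspace(cfg.wn_min, cfg.wn_max, p)

    # fixed pure spectra: sums of Gaussian absorption bands
    lo_w, hi_w = cfg.peak_width_range
    pure = np.zeros((cfg.n_components, p))
    for k in range(cfg.n_components):
        centers = rng_pure.uniform(cfg.wn_min, cfg.wn_max, cfg.peaks_per_component)
        widths = rng_pure.uniform(lo_w, hi_w, cfg.peaks_per_component)
        amps = rng_pure.uniform(0.05, 0.30, cfg.peaks_per_component)
        for c, w, a in zip(centers, widths, amps):
            pure[k] += a * np.exp(-0.5 * ((wn - c) / w) ** 2)

    # concentrations: truncated-normal analyte, interfering components with
    # unit-scale positive concentrations
    conc = np.empty((n, cfg.n_components))
    if n:
        conc[:, 0] = _truncated_positive(rng_conc, cfg.analyte_mean, cfg.analyte_sd, n)
        for k in range(1, cfg.n_components):
            conc[:, k] = _truncated_positive(rng_conc, 1.0, 0.3, n)

    mixture = conc @ pure

    # per-sample polynomial baseline drift on a normalized axis
    t = np.linspace(0.0, 1.0, p)
    powers = np.vander(t, cfg.baseline_order + 1, increasing=True)  # (p, d+1)
    coeffs = rng_base.normal(0.0, cfg.baseline_sd, (n, cfg.baseline_order + 1))
    baseline = coeffs @ powers.T

    scatter = (
        _truncated_positive(rng_scatter, 1.0, cfg.scatter_sd, n)
        if (n and cfg.scatter_sd > 0)
        else np.ones(n)
    )
    noise = rng_noise.normal(0.0, cfg.noise_sd, (n, p)) if cfg.noise_sd > 0 else 0.0

    A = scatter[:, None] * mixture + baseline + noise
    ids = tuple(f"synth-{i:04d}" for i in range(n))
    return (
        SpectraSet(A, wn, ids),
        ReferenceValues(conc[:, 0] if n else np.empty(0)),
        pure,
    )


FIXTURES = ("tiny", "standard", "noisy")


def fixture_config(kind: str, seed: int) -> SyntheticConfig:
    """The named study conditions: ``tiny`` (24 x 64, fast unit tests),
    ``standard`` (620 x 1,557, the full-scale shape), ``noisy`` (standard
    with 5x additive noise and 3x scatter, stressing preprocessing)."""
    if kind == "tiny":
        return SyntheticConfig(
            n_samples=24,
            n_points=64,
            peaks_per_component=3,
            peak_width_range=(300.0, 900.0),
            seed=seed,
        )
    if kind == "standard":
        return SyntheticConfig(seed=seed)
    if kind == "noisy":
        base = SyntheticConfig(seed=seed)
        return replace(base, noise_sd=5 * base.noise_sd, scatter_sd=3 * base.scatter_sd)
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURES}")


def make_fixture(kind: str, seed: int) -> tuple[SpectraSet, ReferenceValues]:
    """Generate one of the named fixtures."""
    s, y, _ = generate(fixture_config(kind, seed))
    return s, y
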