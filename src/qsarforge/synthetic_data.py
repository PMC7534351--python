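"""Synthetic descriptor pools with planted linear responses.

Generates data with the statistical structure the QSAR analysis assumes:
a small compound set (n of order 10-22), a pool of correlated numeric
descriptors on heterogeneous scales, and a response that is a linear
combination of a few "active" descriptors plus Gaussian noise. Knowing the
ground truth lets the test suite assert parameter recovery, selection
power, and cross-validation behaviour without any external data.

Descriptors are drawn from an equicorrelated Gaussian latent structure and
rescaled column-wise to ranges mimicking real molecular descriptors
(vector interaction moments of order 0.01-0.1, flexibility indices of
order 3-5, polar surface areas of order 100-140), so selection is
stressed by both collinearity and wildly different coefficient scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset_io import QsarDataset

#: Per-column (low, high) target ranges cycled over the descriptor pool,
#: mimicking the spread of typical molecular-descriptor magnitudes.
DEFAULT_RANGES: tuple[tuple[float, float], ...] = (
    (0.01, 0.05),     # small vector moment (IW1-like)
    (0.02, 0.13),     # second vector moment
    (2.7, 5.0),       # flexibility index
    (99.0, 140.0),    # polar surface area
    (5.9, 29.0),      # pharmacophore triplet count
    (0.0, 3.0),       # hydrophobic volume difference
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth specification of one synthetic QSAR dataset.

    ``correlation`` is the common pairwise correlation of the Gaussian
    latent variables behind the descriptor columns; ``active_set`` indexes
    (0-based) the descriptors that truly drive the response, with
    coefficients ``betas`` on the *standardised* latent scale so that every
    active descriptor contributes comparably regardless of its printed
    range. ``noise_sd`` is the residual standard deviation in response
    (pIC50) units.
    """

    n: int = 22
    p: int = 6
    correlation: float = 0.3
    active_set: tuple[int, ...] = (0, 2)
    betas: tuple[float, ...] = (-0.6, -0.4)
    intercept: float = 7.5
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError(f"correlation must be in [0, 1), got {self.correlation}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.active_set) != len(self.betas):
            raise ValueError("one beta per active descriptor required")
        if any(not 0 <= j < self.p for j in self.active_set):
            raise ValueError(f"active_set must index descriptors 0..{self.p - 1}")


def _column_ranges(p: int) -> list[tuple[float, float]]:
    return [DEFAULT_RANGES[j % len(DEFAULT_RANGES)] for j in range(p)]


def make_descriptor_pool(spec: SyntheticSpec) -> QsarDataset:
    """Draw the n x p descriptor matrix (response left as zeros).

    Latents are equicorrelated standard Gaussians at ``spec.correlation``,
    generated via the one-factor construction
    z = sqrt(rho) * g + sqrt(1 - rho) * e; each column is then affinely
    mapped so its +/-2 sd interval spans the target descriptor range.
    Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.correlation
    g = rng.standard_normal((spec.n, 1))
    e = rng.standard_normal((spec.n, spec.p))
    z = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e
    X = np.empty_like(z)
    for j, (lo, hi) in enumerate(_column_ranges(spec.p)):
        centre, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        X[:, j] = centre + z[:, j] * (half / 2.0)   # +/-2 sd covers the range
    names = [f"D{j + 1}" for j in range(spec.p)]
    ids = [f"c{i + 1}" for i in range(spec.n)]
    return QsarDataset(ids, names, X, np.zeros(spec.n))


def _standardise_columns(X: np.ndarray, p: int) -> np.ndarray:
    """Map descriptor columns back to the unit latent scale used by betas."""
    out = np.empty_like(X)
    for j, (lo, hi) in enumerate(_column_ranges(p)):
        centre, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        out[:, j] = (X[:, j] - centre) / (half / 2.0)
    return out


def true_coefficients(spec: SyntheticSpec) -> tuple[np.ndarray, float]:
    """Planted slopes on the raw descriptor scale, and the matching intercept.

    The generator plants effects on the standardised latent scale; this
    converts them to the raw-column slopes an OLS fit on X should recover.
    """
    ranges = _column_ranges(spec.p)
    slopes = np.zeros(spec.p)
    intercept = spec.intercept
    for j, beta in zip(spec.active_set, spec.betas):
        lo, hi = ranges[j]
        centre, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        scale = half / 2.0
        slopes[j] = beta / scale
        intercept -= beta * centre / scale
    return slopes, intercept


def plant_response(X: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Generate y = intercept + sum(betas * standardised active columns) + noise.

    The noise stream is seeded independently of the descriptor draw
    (seed + 1) so the same pool can carry different noise realisations.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < (max(spec.active_set) + 1 if spec.active_set else 0):
        raise ValueError("X has fewer columns than the largest active index")
    z = _standardise_columns(X, spec.p)
    y = np.full(len(X), spec.intercept)
    for j, beta in zip(spec.active_set, spec.betas):
        y = y + beta * z[:, j]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        y = y + rng.normal(0.0, spec.noise_sd, size=len(X))
    return y


def make_dataset(spec: SyntheticSpec) -> QsarDataset:
    """Descriptor pool plus planted response as one fitting-ready dataset."""
    pool = make_descriptor_pool(spec)
    y = plant_response(pool.X, spec)
    return QsarDataset(pool.ids, pool.descriptor_names, pool.X, y)


def noise_sd_for_r2(spec: SyntheticSpec, target_r2: float) -> float:
    """Noise level giving approximately the requested true R².

    With unit-variance standardised active columns at pairwise correlation
    rho, the signal variance is b'Cb for C the active-set correlation
    block; solving R² = signal / (signal + noise²) for the noise sd.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    k = len(spec.active_set)
    b = np.asarray(spec.betas)
    C = np.full((k, k), spec.correlation) + (1.0 - spec.correlation) * np.eye(k)
    signal = float(b @ C @ b)
    return float(np.sqrt(signal * (1.0 - target_r2) / target_r2))


def make_recovery_suite(
    count: int,
    base_spec: SyntheticSpec,
) -> list[tuple[QsarDataset, SyntheticSpec]]:
    """``count`` datasets sharing one ground truth, differing only by seed.

    Seeds are spaced (base seed + 1000*i) so descriptor and noise streams
    never collide across replicates.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    suite = []
    for i in range(count):
        spec_i = replace(base_spec, seed=base_spec.seed + 1000 * i)
        suite.append((make_dataset(spec_i), spec_i))
    return suite
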