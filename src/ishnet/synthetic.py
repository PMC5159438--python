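"""Synthetic fixtures with planted ground truth.

Two families of generators stand in for the data the pipeline was designed
around, so every stage can be exercised end-to-end with known answers and
no download:

* ISH-like section triplets (signal image, Nissl reference, region-label
  mask) where each rectangular ROI has a planted signal-pixel fraction
  ``p`` and signal gray distribution N(μ, σ) clipped into the detectable
  range [0, 191].  Signal pixels are placed by exact count
  (``round(p * area)``), not per-pixel Bernoulli draws, so density
  round-trip tests are exact rather than statistical.

* Gene × sample matrices with planted correlated modules: each module has
  a latent standard-normal factor ``u`` over samples and member genes
  ``sqrt(rho) * u + sqrt(1 - rho) * eps``, giving expected within-module
  pairwise correlation ``rho``; noise genes are pure ``eps``.  Default
  module sizes (16, 40, 70) span the module-size range typical of small
  co-expression studies, with 60 samples and rho = 0.8.  The default
  background of 600 noise genes keeps the modules a small fraction of the
  network, as in real transcriptome data; this matters for permutation
  preservation tests, whose null draws random gene sets from the whole
  network and is biased when most genes belong to a few strong modules.

Everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpr import SampleMatrix
from .ish_scoring import (
    DEFAULT_DENSITY_BINS,
    DEFAULT_LUT,
    DensityBins,
    IntensityLUT,
)

__all__ = [
    "RoiSpec",
    "IshFixtureSpec",
    "CoexprFixtureSpec",
    "gen_ish_fixture",
    "gen_coexpr_fixture",
    "gen_preservation_pair",
]


@dataclass(frozen=True)
class RoiSpec:
    """One rectangular ROI with planted signal truth.

    ``rect`` is (row0, col0, row1, col1), half-open.  ``p`` is the signal
    fraction of the ROI area; signal grays come from N(mu, sigma) clipped
    to [0, 191].  The fixture contract asks for mu at least 3 gray levels
    inside its LUT bin so clipping bias cannot move the recovered scale.
    """

    label: int
    name: str
    rect: tuple[int, int, int, int]
    p: float
    mu: float
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("signal fraction p must be in [0, 1]")
        if not 0 <= self.mu <= 191:
            raise ValueError("signal mean gray must be in [0, 191]")
        if self.label <= 0:
            raise ValueError("ROI labels must be positive")

    @property
    def area(self) -> int:
        r0, c0, r1, c1 = self.rect
        return (r1 - r0) * (c1 - c0)


@dataclass(frozen=True)
class IshFixtureSpec:
    """Specification of one synthetic ISH/Nissl/mask triplet."""

    shape: tuple[int, int] = (256, 256)
    rois: tuple[RoiSpec, ...] = ()
    background: tuple[int, int] = (200, 255)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.background
        if not 192 <= lo <= hi <= 255:
            raise ValueError("background gray range must lie within [192, 255]")
        covered = np.zeros(self.shape, dtype=bool)
        for roi in self.rois:
            r0, c0, r1, c1 = roi.rect
            if not (0 <= r0 < r1 <= self.shape[0] and 0 <= c0 < c1 <= self.shape[1]):
                raise ValueError(f"ROI {roi.label} rectangle outside image")
            if covered[r0:r1, c0:c1].any():
                raise ValueError("ROIs overlap")
            covered[r0:r1, c0:c1] = True


def _expected_scales(
    roi: RoiSpec, lut: IntensityLUT, bins: DensityBins
) -> tuple[int, int]:
    """Planted (L, D) truth for one ROI from its spec alone."""
    n_signal = round(roi.p * roi.area)
    if n_signal == 0:
        return 0, 0
    L = lut.scale_for(roi.mu)
    np_pct = 100.0 * n_signal / roi.area
    D = bins.scale_for(min(np_pct, 100.0))
    return L, D


def gen_ish_fixture(
    spec: IshFixtureSpec,
    lut: IntensityLUT = DEFAULT_LUT,
    density_bins: DensityBins = DEFAULT_DENSITY_BINS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[int, str], pd.DataFrame]:
    """Generate (ish, nissl, mask, names, truth) for one section.

    Within each ROI exactly ``round(p * area)`` uniformly chosen pixels
    receive signal gray drawn from the ROI's clipped normal; every other
    pixel (inside or outside ROIs) is background.  The Nissl reference
    marks every ROI pixel as positive (gray 100 < 192) on the same
    background, so the density denominator is the full ROI area.  The
    truth table lists per-ROI planted (p, mu, n_signal, expected L/D/E).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    lo, hi = spec.background
    ish = rng.integers(lo, hi + 1, size=(h, w)).astype(np.uint8)
    nissl = rng.integers(lo, hi + 1, size=(h, w)).astype(np.uint8)
    mask = np.zeros((h, w), dtype=np.int32)
    names: dict[int, str] = {}
    rows = []
    for roi in spec.rois:
        r0, c0, r1, c1 = roi.rect
        mask[r0:r1, c0:c1] = roi.label
        names[roi.label] = roi.name
        nissl[r0:r1, c0:c1] = 100  # every ROI pixel Nissl-positive
        area = roi.area
        n_signal = round(roi.p * area)
        if n_signal > 0:
            flat = rng.choice(area, size=n_signal, replace=False)
            grays = np.clip(
                np.rint(rng.normal(roi.mu, roi.sigma, size=n_signal)), 0, 191
            ).astype(np.uint8)
            block = ish[r0:r1, c0:c1].reshape(-1)
            block[flat] = grays
            ish[r0:r1, c0:c1] = block.reshape(r1 - r0, c1 - c0)
        L, D = _expected_scales(roi, lut, density_bins)
        rows.append(
            {
                "label": roi.label,
                "name": roi.name,
                "area": area,
                "p": roi.p,
                "mu": roi.mu,
                "sigma": roi.sigma,
                "n_signal": n_signal,
                "expected_L": L,
                "expected_D": D,
                "expected_E": float(L * D),
            }
        )
    truth = pd.DataFrame(rows)
    return ish, nissl, mask, names, truth


@dataclass(frozen=True)
class CoexprFixtureSpec:
    """Specification of a gene × sample matrix with planted modules."""

    module_sizes: tuple[int, ...] = (16, 40, 70)
    n_noise_genes: int = 600
    n_samples: int = 60
    rho: float = 0.8
    noise_sd: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")


def gen_coexpr_fixture(spec: CoexprFixtureSpec) -> tuple[SampleMatrix, pd.Series]:
    """Generate a planted-module expression matrix and its truth labels.

    Module m's member genes are ``sqrt(rho) * u_m + sqrt(1 - rho) * eps``
    with a shared latent factor ``u_m`` and independent noise, so the
    expected within-module correlation is rho (exactly, when noise_sd is
    1) and between-module correlation is 0.  Truth labels are 1-based
    module ids; noise genes are labeled 0.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    blocks = []
    labels = []
    gene_names = []
    for m, size in enumerate(spec.module_sizes, start=1):
        u = rng.standard_normal(n)
        eps = rng.normal(0.0, spec.noise_sd, size=(size, n))
        blocks.append(np.sqrt(spec.rho) * u + np.sqrt(1.0 - spec.rho) * eps)
        labels.extend([m] * size)
        gene_names.extend(f"M{m}G{i:03d}" for i in range(size))
    if spec.n_noise_genes:
        blocks.append(rng.normal(0.0, spec.noise_sd, size=(spec.n_noise_genes, n)))
        labels.extend([0] * spec.n_noise_genes)
        gene_names.extend(f"N0G{i:03d}" for i in range(spec.n_noise_genes))
    values = pd.DataFrame(
        np.vstack(blocks),
        index=gene_names,
        columns=[f"S{j:03d}" for j in range(n)],
    )
    return SampleMatrix(values=values), pd.Series(labels, index=gene_names, name="module")


def gen_preservation_pair(
    spec: CoexprFixtureSpec, scramble_module: int | None = None
) -> tuple[SampleMatrix, SampleMatrix, pd.Series]:
    """Reference/test matrix pair sharing module structure.

    Both matrices are drawn independently from ``spec`` (sub-seeds derived
    from ``spec.seed``), so modules exist in both but with independent
    noise — the preserved condition.  When ``scramble_module`` is given,
    that module's genes in the test matrix are replaced by pure noise,
    destroying its density and connectivity there.  Labels come from the
    reference.
    """
    seed_ref = (spec.seed * 2 + 1) % (2**31)
    seed_test = (spec.seed * 2 + 2) % (2**31)
    X_ref, labels = gen_coexpr_fixture(
        CoexprFixtureSpec(
            module_sizes=spec.module_sizes,
            n_noise_genes=spec.n_noise_genes,
            n_samples=spec.n_samples,
            rho=spec.rho,
            noise_sd=spec.noise_sd,
            seed=seed_ref,
        )
    )
    X_test, _ = gen_coexpr_fixture(
        CoexprFixtureSpec(
            module_sizes=spec.module_sizes,
            n_noise_genes=spec.n_noise_genes,
            n_samples=spec.n_samples,
            rho=spec.rho,
            noise_sd=spec.noise_sd,
            seed=seed_test,
        )
    )
    if scramble_module is not None:
        if scramble_module not in set(labels):
            raise KeyError(f"unknown module id {scramble_module}")
        rng = np.random.default_rng((spec.seed * 2 + 3) % (2**31))
        members = labels.index[labels == scramble_module]
        X_test.values.loc[members] = rng.normal(
            0.0, spec.noise_sd, size=(len(members), spec.n_samples)
        )
    return X_ref, X_test, labels
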