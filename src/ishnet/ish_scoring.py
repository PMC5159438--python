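"""Semi-quantitative scoring of ISH brain-section images.

In situ hybridization (ISH) darkens tissue where a transcript is present,
but the stain is not linear in copy number.  This module implements a
semi-quantitative schema that converts an 8-bit ISH section (0 = strongest
signal, 255 = white background) into, per region of interest (ROI):

* an intensity scale ``L`` (7..0) read off a fixed 8-bin pseudocolor
  lookup table applied to the mean gray value of the expressing pixels;
* a density scale ``D`` (1..4) from the percentage ``Np`` of expressing
  pixels relative to the cell-occupied area of the same ROI in a matched
  Nissl-stained reference section;
* an expression factor ``E`` — the average over 2-3 sections of the
  per-section product ``L_i * D_i`` — in [0, 28], and a verbal category
  (none / very low / low / moderate / high / very high).

Scoring is fully deterministic: no random number generator is used
anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityLUT",
    "DensityBins",
    "SectionScore",
    "RegionExpression",
    "DEFAULT_LUT",
    "DEFAULT_DENSITY_BINS",
    "BACKGROUND_THRESHOLD",
    "PIXEL_AREA_UM2",
    "CATEGORIES",
    "to_gray8",
    "apply_pseudocolor",
    "expressing_pixel_mask",
    "mean_gray_expressing",
    "intensity_scale",
    "count_positive_pixels",
    "density_percent",
    "density_scale",
    "expression_factor",
    "categorize_expression",
    "score_section",
    "score_gene_region",
    "scores_to_frame",
    "read_label_names",
    "load_gray8",
]

#: Gray values at or above this index position fall in the LUT's
#: "no signal" bin and are treated as background when selecting
#: expressing pixels.
BACKGROUND_THRESHOLD: int = 192

#: Area of the smallest pixel in the source imagery, in μm².  It cancels
#: in the density ratio and is kept only as a documented constant.
PIXEL_AREA_UM2: float = 0.17

#: Expression-factor categories in increasing order of expression.
CATEGORIES = ("none", "very low", "low", "moderate", "high", "very high")


# --------------------------------------------------------------------------
# lookup tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityLUT:
    """8-bin pseudocolor lookup table over gray index positions 0-255.

    Each bin is ``(index_lo, index_hi, scale, rgb)``; the bins partition
    [0, 255] with no gaps or overlaps and the scales strictly decrease
    from 7 (strongest signal, red) to 0 (no signal, black).  Bin lookup
    for a float mean gray value uses half-open intervals
    ``[index_lo, index_hi + 1)`` so the mapping is total on [0, 255].
    """

    bins: tuple[tuple[int, int, int, tuple[int, int, int]], ...] = (
        (0, 31, 7, (255, 0, 0)),
        (32, 63, 6, (255, 124, 0)),
        (64, 95, 5, (255, 190, 0)),
        (96, 127, 4, (255, 255, 0)),
        (128, 159, 3, (0, 255, 0)),
        (160, 175, 2, (0, 123, 255)),
        (176, 191, 1, (0, 0, 255)),
        (192, 255, 0, (0, 0, 0)),
    )

    def __post_init__(self) -> None:
        if len(self.bins) != 8:
            raise ValueError("intensity LUT must have exactly 8 bins")
        expected_lo = 0
        prev_scale = None
        for lo, hi, scale, rgb in self.bins:
            if lo != expected_lo or hi < lo:
                raise ValueError("LUT bins must partition [0,255] without gaps")
            if prev_scale is not None and scale >= prev_scale:
                raise ValueError("LUT scales must strictly decrease")
            if len(rgb) != 3:
                raise ValueError("LUT colors must be RGB triples")
            prev_scale = scale
            expected_lo = hi + 1
        if expected_lo != 256:
            raise ValueError("LUT bins must end at index 255")

    def scale_for(self, gray: float) -> int:
        """Intensity scale of the bin containing ``gray`` (float, 0-255)."""
        if not 0 <= gray <= 255:
            raise ValueError(f"gray value {gray} outside [0, 255]")
        for lo, hi, scale, _ in self.bins:
            if lo <= gray < hi + 1:
                return scale
        return self.bins[-1][2]  # gray == 255 exactly

    def rgb_for(self, gray: float) -> tuple[int, int, int]:
        """Pseudocolor of the bin containing ``gray``."""
        if not 0 <= gray <= 255:
            raise ValueError(f"gray value {gray} outside [0, 255]")
        for lo, hi, _, rgb in self.bins:
            if lo <= gray < hi + 1:
                return rgb
        return self.bins[-1][3]


@dataclass(frozen=True)
class DensityBins:
    """Four-level binning of the signal density percentage ``Np``.

    Bins are ``(lo_pct, hi_pct, scale)`` half-open ``[lo, hi)``, except the
    last bin which is closed at 100.  Defaults: 0-5% sparse (1), 5-20%
    scattered (2), 20-70% medium (3), >70% wide-spread (4).
    """

    bins: tuple[tuple[float, float, int], ...] = (
        (0.0, 5.0, 1),
        (5.0, 20.0, 2),
        (20.0, 70.0, 3),
        (70.0, 100.0, 4),
    )

    def __post_init__(self) -> None:
        lo0 = self.bins[0][0]
        hi_last = self.bins[-1][1]
        if lo0 != 0.0 or hi_last != 100.0:
            raise ValueError("density bins must cover [0, 100]")
        for (_, hi_a, s_a), (lo_b, _, s_b) in zip(self.bins, self.bins[1:]):
            if lo_b != hi_a or s_b <= s_a:
                raise ValueError("density bins must be contiguous with increasing scales")

    def scale_for(self, np_pct: float) -> int:
        if not 0 <= np_pct <= 100:
            raise ValueError(f"density percentage {np_pct} outside [0, 100]")
        for lo, hi, scale in self.bins[:-1]:
            if lo <= np_pct < hi:
                return scale
        return self.bins[-1][2]


DEFAULT_LUT = IntensityLUT()
DEFAULT_DENSITY_BINS = DensityBins()


# --------------------------------------------------------------------------
# image primitives
# --------------------------------------------------------------------------

def _as_array(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    return arr


def to_gray8(image, *, luminance: bool = False) -> np.ndarray:
    """Convert an RGB(A) raster to 8-bit grayscale.

    By default each pixel becomes the unweighted mean of its channels,
    rounded half-up and clipped to [0, 255] (the behaviour of ImageJ/Fiji's
    plain 8-bit conversion); ``luminance=True`` uses ITU-R 601 weights
    instead.  A 2-D input is validated and passed through unchanged.
    """
    arr = _as_array(image)
    if arr.ndim == 2:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("gray image values must lie in [0, 255]")
        return arr.astype(np.uint8)
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D gray or 3-D color image, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    rgb = arr[..., :3].astype(np.float64)
    if luminance:
        gray = rgb @ np.array([0.299, 0.587, 0.114])
    else:
        gray = rgb.mean(axis=-1)
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def apply_pseudocolor(img: np.ndarray, lut: IntensityLUT = DEFAULT_LUT) -> np.ndarray:
    """Render a gray image through the pseudocolor LUT.

    Returns a new ``(H, W, 3)`` uint8 raster; the input gray values are
    never modified — the false-color view is for visualization only and
    plays no part in scoring.
    """
    gray = _as_array(img)
    if gray.ndim != 2:
        raise ValueError("apply_pseudocolor expects a 2-D gray image")
    palette = np.zeros((256, 3), dtype=np.uint8)
    for lo, hi, _, rgb in lut.bins:
        palette[lo : hi + 1] = rgb
    return palette[gray.astype(np.intp)]


def expressing_pixel_mask(
    img: np.ndarray,
    roi: np.ndarray,
    label: int,
    background_threshold: int = BACKGROUND_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of expressing pixels: inside the ROI and below background.

    A pixel expresses when its gray value falls in any detectable LUT bin,
    i.e. strictly below ``background_threshold`` (default 192, the start of
    the "no signal" bin).
    """
    gray = _as_array(img)
    labels = np.asarray(roi)
    if labels.shape != gray.shape:
        raise ValueError("region mask shape does not match image")
    if not np.any(labels == label):
        raise KeyError(f"label {label} not present in region mask")
    return (labels == label) & (gray < background_threshold)


def mean_gray_expressing(img: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean gray value over the expressing-pixel mask.

    Raises ``ValueError`` when the mask is empty; callers treat that as
    "no signal" and record L = 0 without a mean.
    """
    gray = _as_array(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("no expressing pixels under mask")
    return float(gray[mask].mean())


def intensity_scale(mean_gray: float, lut: IntensityLUT = DEFAULT_LUT) -> int:
    """Intensity scale L (0-7) for a mean gray value via LUT bin lookup."""
    return lut.scale_for(float(mean_gray))


def count_positive_pixels(
    img: np.ndarray,
    roi: np.ndarray,
    label: int,
    background_threshold: int = BACKGROUND_THRESHOLD,
    watershed: bool = False,
) -> int:
    """Number of expressing pixels of one ROI.

    ``watershed=True`` additionally splits touching signal blobs before
    (optional) blob-level statistics are derived elsewhere; splitting
    redraws blob boundaries but never changes which pixels are positive,
    so the returned count is identical either way.
    """
    mask = expressing_pixel_mask(img, roi, label, background_threshold)
    if watershed and mask.any():
        # Blob splitting via distance-transform watershed; counts unchanged.
        from scipy import ndimage
        from skimage.segmentation import watershed as _watershed

        distance = ndimage.distance_transform_edt(mask)
        markers, _ = ndimage.label(mask)
        _watershed(-distance, markers, mask=mask)
    return int(mask.sum())


def density_percent(
    n_signal: int, n_reference: int, pixel_area: float = PIXEL_AREA_UM2
) -> float:
    """Signal density Np as a percentage of the Nissl-positive area.

    Np = 100 * (n_signal / pixel_area) / (n_reference / pixel_area); the
    pixel area (0.17 μm² in the source imagery) cancels analytically and
    is retained only for documentation.  The result is capped at 100
    because signal and reference come from different images.
    """
    if n_reference <= 0:
        raise ZeroDivisionError("reference (Nissl) pixel count must be positive")
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    np_pct = 100.0 * (n_signal / pixel_area) / (n_reference / pixel_area)
    return min(np_pct, 100.0)


def density_scale(np_pct: float, bins: DensityBins = DEFAULT_DENSITY_BINS) -> int:
    """Density scale D (1-4) for a density percentage via bin lookup."""
    return bins.scale_for(float(np_pct))


def expression_factor(pairs: Sequence[tuple[float, float]]) -> float:
    """Expression factor E: mean over sections of the product L_i * D_i.

    Each pair is one section's (intensity scale, density scale); a section
    with no signal contributes (0, 0).  For the three-section worked case
    this is [L1*D1 + L2*D2 + L3*D3] / 3.  E ranges from 0 (no signal) to
    28 (= 7 * 4) when scales are in range.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("expression_factor requires at least one (L, D) pair")
    for L, D in pairs:
        if not (0 <= L <= 7 and 0 <= D <= 4):
            raise ValueError(f"(L={L}, D={D}) outside valid scale ranges")
    return float(np.mean([L * D for L, D in pairs]))


def expression_factor_of_averages(pairs: Sequence[tuple[float, float]]) -> float:
    """Alternative reading E = mean(L) * mean(D) (product of averages).

    Coincides with :func:`expression_factor` whenever D is constant across
    sections; exposed as a configuration switch, not the default.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("expression_factor requires at least one (L, D) pair")
    Ls, Ds = zip(*pairs)
    return float(np.mean(Ls) * np.mean(Ds))


def categorize_expression(E: float) -> str:
    """Verbal category for an expression factor E in [0, 28].

    E = 0 is "none"; otherwise lower-inclusive bins: (0,6) very low,
    [6,11) low, [11,17) moderate, [17,22) high, [22,28] very high.
    """
    if not 0 <= E <= 28:
        raise ValueError(f"expression factor {E} outside [0, 28]")
    if E == 0:
        return "none"
    if E < 6:
        return "very low"
    if E < 11:
        return "low"
    if E < 17:
        return "moderate"
    if E < 22:
        return "high"
    return "very high"


# --------------------------------------------------------------------------
# per-section and per-region scoring
# --------------------------------------------------------------------------

@dataclass
class SectionScore:
    """All intermediates from scoring one ISH/Nissl section pair in one ROI."""

    gene: str
    region_label: int
    plane: str
    section_id: str
    mean_gray: float  # NaN when no expressing pixel
    L: int
    n_signal: int
    n_reference: int
    Np: float
    D: int


@dataclass
class RegionExpression:
    """Scored expression of one gene in one named region, one section plane."""

    gene: str
    region: str
    plane: str
    section_scores: list[SectionScore]
    E: float
    category: str


def score_section(
    ish: np.ndarray,
    nissl: np.ndarray,
    roi: np.ndarray,
    label: int,
    *,
    gene: str = "",
    plane: str = "",
    section_id: str = "",
    lut: IntensityLUT = DEFAULT_LUT,
    density_bins: DensityBins = DEFAULT_DENSITY_BINS,
    background_threshold: int = BACKGROUND_THRESHOLD,
    watershed: bool = False,
) -> SectionScore:
    """Score a single section: expressing mask → mean gray → L; counts → Np → D.

    The Nissl reference defines the denominator: its positive pixels in the
    same ROI approximate the cell-occupied area.  A section with no
    expressing ISH pixel scores L = 0, D = 0, Np = 0.
    """
    mask = expressing_pixel_mask(ish, roi, label, background_threshold)
    n_signal = count_positive_pixels(ish, roi, label, background_threshold, watershed)
    n_reference = count_positive_pixels(nissl, roi, label, background_threshold)
    if n_signal == 0:
        mean_gray, L, Np, D = float("nan"), 0, 0.0, 0
    else:
        mean_gray = mean_gray_expressing(ish, mask)
        L = intensity_scale(mean_gray, lut)
        Np = density_percent(n_signal, n_reference)
        D = density_scale(Np, density_bins)
    return SectionScore(
        gene=gene,
        region_label=label,
        plane=plane,
        section_id=section_id,
        mean_gray=mean_gray,
        L=L,
        n_signal=n_signal,
        n_reference=n_reference,
        Np=Np,
        D=D,
    )


def score_gene_region(
    ish_images: Sequence[np.ndarray],
    nissl_images: Sequence[np.ndarray],
    roi: np.ndarray,
    label: int,
    gene: str,
    *,
    region_name: str | None = None,
    plane: str = "parasagittal",
    lut: IntensityLUT = DEFAULT_LUT,
    density_bins: DensityBins = DEFAULT_DENSITY_BINS,
    background_threshold: int = BACKGROUND_THRESHOLD,
    watershed: bool = False,
    mean_of_products: bool = True,
) -> RegionExpression:
    """Score a gene in one ROI across the 2-3 sections of one plane.

    Every ISH image must have a matched Nissl reference sharing the region
    mask.  Per section the full chain runs (mask → mean gray → L,
    counts → Np → D); E then averages the per-section products L_i * D_i
    (or, with ``mean_of_products=False``, multiplies the averaged L and D).
    """
    ish_images = list(ish_images)
    nissl_images = list(nissl_images)
    if not ish_images:
        raise ValueError("at least one ISH section is required")
    if len(ish_images) != len(nissl_images):
        raise ValueError("each ISH section needs a matched Nissl reference")
    scores = [
        score_section(
            ish,
            nissl,
            roi,
            label,
            gene=gene,
            plane=plane,
            section_id=f"s{i + 1}",
            lut=lut,
            density_bins=density_bins,
            background_threshold=background_threshold,
            watershed=watershed,
        )
        for i, (ish, nissl) in enumerate(zip(ish_images, nissl_images))
    ]
    pairs = [(s.L, s.D) for s in scores]
    combine = expression_factor if mean_of_products else expression_factor_of_averages
    E = combine(pairs)
    return RegionExpression(
        gene=gene,
        region=region_name if region_name is not None else str(label),
        plane=plane,
        section_scores=scores,
        E=E,
        category=categorize_expression(E),
    )


# --------------------------------------------------------------------------
# I/O helpers
# --------------------------------------------------------------------------

def scores_to_frame(records: Iterable[RegionExpression]) -> pd.DataFrame:
    """Flatten RegionExpression records into the tabular TSV layout."""
    rows = []
    for rec in records:
        for s in rec.section_scores:
            rows.append(
                {
                    "gene": rec.gene,
                    "region": rec.region,
                    "plane": rec.plane,
                    "section_id": s.section_id,
                    "mean_gray": s.mean_gray,
                    "L": s.L,
                    "n_signal": s.n_signal,
                    "n_reference": s.n_reference,
                    "Np": s.Np,
                    "D": s.D,
                    "E": rec.E,
                    "category": rec.category,
                }
            )
    return pd.DataFrame(rows)


def read_label_names(path) -> dict[int, str]:
    """Read a two-column label,name CSV mapping mask labels to region names."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("label file needs columns: label, name")
    col_l, col_n = df.columns[:2]
    return {int(k): str(v) for k, v in zip(df[col_l], df[col_n])}


def load_gray8(path, *, luminance: bool = False) -> np.ndarray:
    """Load an image file (PNG/TIFF, gray or RGB) as an 8-bit gray array."""
    import imageio.v3 as iio

    return to_gray8(iio.imread(path), luminance=luminance)
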