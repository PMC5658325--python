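"""Densitometric extraction of the T/C ratio from a strip image.

The reader images the cassette window as a grayscale raster with the flow
axis along the columns.  Quantification reduces the 2-D image to a 1-D
intensity profile and measures the two reagent lines as local minima:

1. crop a fixed region of interest (cassette registration, not content
   analysis);
2. convert to grayscale (ITU-R BT.601 luminance weights 0.299/0.587/0.114);
3. Gaussian denoising in 2-D;
4. collapse to 1-D by a per-column median across the strip width, followed
   by a running median along the flow axis;
5. detect the test and control lines as the two most prominent local minima
   at the expected separation, test line upstream;
6. report T/C as the ratio of *baseline-relative* trough depths.

Depths are measured relative to the blank-membrane baseline (median of the
profile outside both line windows), which makes the ratio invariant to a
global intensity offset and to uniform exposure scaling.  Raw trough values
would not be: a competitive assay can produce T/C ratios well above 1, which
is only meaningful for background-subtracted depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .errors import (
    ConfigError,
    FormatError,
    GeometryError,
    InvalidStripError,
    MissingLineError,
)

__all__ = [
    "StripImage",
    "IntensityProfile",
    "LinePeak",
    "TCResult",
    "ExtractionConfig",
    "crop_roi",
    "to_grayscale",
    "denoise",
    "collapse_to_profile",
    "detect_lines",
    "compute_tc",
    "quantify_image",
]

#: BT.601 luminance weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class StripImage:
    """2-D grayscale raster of the cassette window.

    Rows run across the strip, columns along the flow axis; values lie in
    [0, 1].  ``roi`` records the crop applied relative to the original
    frame as a half-open ``(row0, row1, col0, col1)`` rectangle.
    """

    pixels: np.ndarray
    pixels_per_mm: float
    roi: tuple[int, int, int, int] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class IntensityProfile:
    """1-D intensity signal along the flow axis with smoothing metadata."""

    values: np.ndarray
    pixels_per_mm: float
    gaussian_sigma_px: float = 0.0
    median_window_px: int = 1

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LinePeak:
    """A detected reagent line: a local minimum of the intensity profile.

    ``depth`` is the baseline-relative darkening (baseline minus trough
    value), the quantity whose test/control ratio forms the assay readout.
    """

    position_px: int
    raw_min: float
    baseline: float
    depth: float
    prominence: float


@dataclass(frozen=True)
class TCResult:
    test: LinePeak
    control: LinePeak
    tc_ratio: float
    qc_flags: frozenset[str] = frozenset()
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the extraction chain.

    None of these are intrinsic to the assay; they are reader configuration
    (fixed per cassette/camera combination) and all are exposed here.
    """

    roi: tuple[int, int, int, int] | None = None
    gaussian_sigma_px: float = 2.0
    median_window_px: int = 5
    expected_separation_px: float = 80.0
    min_prominence: float = 0.02
    line_width_px: float | None = None  # default: expected_separation_px / 4
    min_control_depth: float = 0.01
    test_upstream: bool = True  # flip for mirrored images

    def __post_init__(self):
        if self.gaussian_sigma_px < 0:
            raise ConfigError("gaussian_sigma_px must be >= 0")
        if self.median_window_px < 1 or self.median_window_px % 2 == 0:
            raise ConfigError("median_window_px must be an odd integer >= 1")
        if self.expected_separation_px <= 0:
            raise ConfigError("expected_separation_px must be > 0")
        if self.min_prominence <= 0:
            raise ConfigError("min_prominence must be > 0")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def crop_roi(image: StripImage, roi: tuple[int, int, int, int]) -> StripImage:
    """Crop to a half-open ``(row0, row1, col0, col1)`` rectangle.

    The ROI comes from fixed cassette registration; it is validated against
    the frame and must leave at least 3 rows and 20 columns for the
    downstream statistics to be meaningful.
    """
    r0, r1, c0, c1 = (int(v) for v in roi)
    nr, nc = image.pixels.shape[:2]
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise GeometryError(f"roi {roi} outside image bounds {(nr, nc)} or degenerate")
    if (r1 - r0) < 3 or (c1 - c0) < 20:
        raise GeometryError("cropped window must keep at least 3 rows and 20 columns")
    return replace(
        image,
        pixels=image.pixels[r0:r1, c0:c1],
        roi=(r0, r1, c0, c1),
        meta=dict(image.meta),
    )


def to_grayscale(raster: np.ndarray) -> np.ndarray:
    """Collapse an RGB raster to luminance; single-channel passes through."""
    raster = np.asarray(raster, dtype=float)
    if raster.ndim == 2:
        return raster
    if raster.ndim == 3 and raster.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        return raster @ w
    raise FormatError(f"expected a 2-D or (H, W, 3) raster, got shape {raster.shape}")


def denoise(image: StripImage, gaussian_sigma_px: float) -> StripImage:
    """2-D Gaussian smoothing with reflective boundaries; sigma 0 is identity."""
    if gaussian_sigma_px < 0:
        raise ConfigError("gaussian_sigma_px must be >= 0")
    if gaussian_sigma_px == 0:
        out = image.pixels.copy()
    else:
        out = ndimage.gaussian_filter(image.pixels, sigma=gaussian_sigma_px, mode="reflect")
    return replace(image, pixels=out, meta=dict(image.meta))


def collapse_to_profile(image: StripImage, median_window_px: int = 1) -> IntensityProfile:
    """Reduce the 2-D image to a 1-D flow-axis signal.

    A per-column median across the strip width rejects across-strip
    outliers (dust, scratches); the optional running median along the flow
    axis (odd window, 1 = skip) removes residual speckle.
    """
    if median_window_px < 1 or median_window_px % 2 == 0:
        raise ConfigError("median window must be an odd integer >= 1")
    prof = np.median(image.pixels, axis=0)
    if median_window_px > len(prof):
        raise ConfigError("median window larger than the profile")
    if median_window_px > 1:
        prof = ndimage.median_filter(prof, size=median_window_px, mode="reflect")
    return IntensityProfile(
        values=prof,
        pixels_per_mm=image.pixels_per_mm,
        median_window_px=median_window_px,
    )


def _baseline(
    values: np.ndarray, peak: float, all_positions: Sequence[float], half_window: float
) -> float:
    """Local background estimate for one line.

    Median of the background annulus on each side of the peak (offsets in
    ``(half_window, 2 * half_window]``, excluding every line window), then
    the mean of the two side medians.  The symmetric average cancels a
    linear illumination gradient exactly; the per-side median is robust to
    residual speckle.  Falls back to one side at a profile edge, and to the
    global out-of-window median in pathological configurations.
    """
    idx = np.arange(len(values))
    outside = np.ones(len(values), dtype=bool)
    for p in all_positions:
        outside &= np.abs(idx - p) > half_window
    offset = idx - peak
    side_medians = []
    for sign in (-1, 1):
        band = outside & (sign * offset > half_window) & (sign * offset <= 2 * half_window)
        if band.any():
            side_medians.append(float(np.median(values[band])))
    if side_medians:
        return float(np.mean(side_medians))
    if outside.any():
        return float(np.median(values[outside]))
    return float(np.median(values))


def detect_lines(
    profile: IntensityProfile,
    expected_separation_px: float,
    min_prominence: float = 0.02,
    line_width_px: float | None = None,
    test_upstream: bool = True,
) -> tuple[LinePeak, LinePeak, frozenset[str]]:
    """Locate the test and control lines as local minima of the profile.

    Minima with topographic prominence >= ``min_prominence`` are candidate
    lines; the pair whose separation lies within +/-25% of
    ``expected_separation_px`` and whose summed prominence is largest is
    retained, the upstream (lower-index) member being the test line.

    If only the control line qualifies — the test line legitimately
    vanishes at high analyte concentration in a competitive assay — the
    test depth is measured at its expected position and flagged
    ``weak_test``.  The single detected line is taken to be the control:
    a valid strip always develops a control line, so a lone prominent
    minimum with room for a test line upstream cannot be anything else,
    and one *without* such room means the control region produced no peak
    (failed strip), raising :class:`MissingLineError`.

    Returns ``(test, control, qc_flags)``.
    """
    vals = np.asarray(profile.values, dtype=float)
    sep = float(expected_separation_px)
    if len(vals) <= sep:
        raise GeometryError("profile shorter than the expected line separation")
    w = float(line_width_px) if line_width_px is not None else sep / 4.0
    flags: set[str] = set()

    peaks, props = signal.find_peaks(-vals, prominence=min_prominence)
    proms = props["prominences"]

    if len(peaks) == 0:
        raise MissingLineError("both", "no local minima of sufficient prominence")

    if len(peaks) == 1:
        return _single_peak(vals, int(peaks[0]), float(proms[0]), sep, w, test_upstream, flags)

    if len(peaks) > 2:
        flags.add("extra_peaks")

    best, best_score = None, -np.inf
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            gap = peaks[j] - peaks[i]
            if 0.75 * sep <= gap <= 1.25 * sep:
                score = proms[i] + proms[j]
                if score > best_score:
                    best, best_score = (i, j), score
    if best is None:
        raise MissingLineError(
            "both", "no pair of minima at the expected separation (+/-25%)"
        )
    i, j = best
    positions = [peaks[i], peaks[j]]
    up = _make_peak(
        vals, int(peaks[i]), float(proms[i]), _baseline(vals, peaks[i], positions, 1.5 * w)
    )
    down = _make_peak(
        vals, int(peaks[j]), float(proms[j]), _baseline(vals, peaks[j], positions, 1.5 * w)
    )
    test, control = (up, down) if test_upstream else (down, up)
    return test, control, frozenset(flags)


def _make_peak(vals: np.ndarray, pos: int, prom: float, baseline: float) -> LinePeak:
    raw = float(vals[pos])
    return LinePeak(
        position_px=pos,
        raw_min=raw,
        baseline=baseline,
        depth=max(baseline - raw, 0.0),
        prominence=prom,
    )


def _single_peak(vals, pos, prom, sep, w, test_upstream, flags):
    """Resolve a lone prominent minimum: control present, test absent/weak."""
    direction = -1 if test_upstream else 1
    expected_test = pos + direction * sep
    if not (0 <= expected_test <= len(vals) - 1):
        raise MissingLineError(
            "control", "single line detected with no room for a test line; control missing"
        )
    positions = [pos, expected_test]
    control = _make_peak(vals, pos, prom, _baseline(vals, pos, positions, 1.5 * w))
    lo = max(int(round(expected_test - w)), 0)
    hi = min(int(round(expected_test + w)) + 1, len(vals))
    tpos = lo + int(np.argmin(vals[lo:hi]))
    test = _make_peak(vals, tpos, 0.0, _baseline(vals, expected_test, positions, 1.5 * w))
    flags.add("weak_test")
    return test, control, frozenset(flags)


def compute_tc(
    test: LinePeak,
    control: LinePeak,
    qc_flags: frozenset[str] = frozenset(),
    min_control_depth: float = 0.01,
    provenance: dict | None = None,
) -> TCResult:
    """T/C ratio of baseline-relative depths; rejects failed strips.

    A control depth at or below ``min_control_depth`` means the strip did
    not develop (no flow or dead conjugate) and the test is invalid.
    """
    if control.depth <= min_control_depth:
        raise InvalidStripError(
            f"control line depth {control.depth:.4f} <= minimum {min_control_depth:.4f}"
        )
    flags = set(qc_flags)
    if test.raw_min <= 0.0 or control.raw_min <= 0.0:
        flags.add("saturated")
    return TCResult(
        test=test,
        control=control,
        tc_ratio=test.depth / control.depth,
        qc_flags=frozenset(flags),
        provenance=provenance or {},
    )


def quantify_image(image: StripImage, config: ExtractionConfig = ExtractionConfig()) -> TCResult:
    """Full extraction chain: crop, denoise, collapse, detect, ratio.

    Deterministic composition of the stage functions above; every stage
    parameter is recorded in the result's provenance.  Stage failures
    propagate with the stage name attached as an exception note.
    """
    stage = "crop"
    try:
        img = crop_roi(image, config.roi) if config.roi is not None else image
        stage = "denoise"
        img = denoise(img, config.gaussian_sigma_px)
        stage = "collapse"
        prof = collapse_to_profile(img, config.median_window_px)
        prof.gaussian_sigma_px = config.gaussian_sigma_px
        stage = "detect"
        test, control, flags = detect_lines(
            prof,
            config.expected_separation_px,
            config.min_prominence,
            config.line_width_px,
            config.test_upstream,
        )
        stage = "ratio"
        return compute_tc(
            test,
            control,
            flags,
            config.min_control_depth,
            provenance={
                "roi": config.roi,
                "gaussian_sigma_px": config.gaussian_sigma_px,
                "median_window_px": config.median_window_px,
                "expected_separation_px": config.expected_separation_px,
                "min_prominence": config.min_prominence,
                "line_width_px": config.line_width_px,
                "min_control_depth": config.min_control_depth,
                "test_upstream": config.test_upstream,
            },
        )
    except Exception as exc:
        exc.add_note(f"stage: {stage}")
        raise
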