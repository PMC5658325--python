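"""Synthetic strip images and cohorts with known ground truth.

No public dataset of reader images exists for the assay this package
models, so validation rests on a forward simulator: it renders the cassette
window — a light nitrocellulose membrane carrying two dark reagent lines —
with a known true T/C ratio, and samples cohorts of subjects whose T/C
values follow a chosen calibration curve plus replicate noise.

The optical model is deliberately minimal: each dispensed line is a
rectangle of darkening convolved with a Gaussian (edge spreading), placed
on a uniform background with an optional linear illumination gradient and
i.i.d. pixel noise.  The *competitive* signal polarity is built in — the
test-line darkening is ``control_depth * tc_ratio_true``, so a deficient
(low-analyte) sample has the darker test line and the higher T/C ratio.

Everything is reproducible: a fixed seed yields bit-identical images and
cohorts.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import erf

from . import calibration as _cal
from .classification import ENDOCRINE_SOCIETY, Status, ThresholdSet, classify
from .errors import ConfigError, GeometryError, RenderSaturationError
from .signal_extraction import StripImage

__all__ = [
    "StripGeometry",
    "OpticalModel",
    "GroundTruth",
    "SimulatedSample",
    "concentration_to_tc",
    "render_strip",
    "simulate_cohort",
    "cohort_frame",
    "write_cohort",
]

#: Printed edge-to-edge gap between the two dispensed lines, mm.
EDGE_TO_EDGE_GAP_MM = 3.0
#: Printed width of each dispensed line, mm.
LINE_WIDTH_MM = 1.0


@dataclass(frozen=True)
class StripGeometry:
    """Physical layout of the imaged membrane.

    ``line_separation_mm`` is the *center-to-center* distance.  The strips
    are specified by an edge-to-edge gap of 3 mm between 1 mm lines, which
    reads as 4 mm center-to-center; pass ``line_separation_mm=3.0`` to adopt
    the alternative center-to-center reading of that figure.
    """

    membrane_length_mm: float = 25.0
    line_width_mm: float = LINE_WIDTH_MM
    line_separation_mm: float = EDGE_TO_EDGE_GAP_MM + LINE_WIDTH_MM
    test_line_position_mm: float = 10.0
    pixels_per_mm: float = 20.0
    strip_width_px: int = 60

    def __post_init__(self):
        for name in (
            "membrane_length_mm",
            "line_width_mm",
            "line_separation_mm",
            "test_line_position_mm",
            "pixels_per_mm",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.strip_width_px < 3:
            raise GeometryError("strip_width_px must be >= 3")
        half = self.line_width_mm / 2
        if self.test_line_position_mm - half < 0:
            raise GeometryError("test line extends past the upstream membrane edge")
        if self.control_line_position_mm + half > self.membrane_length_mm:
            raise GeometryError("control line extends past the downstream membrane edge")

    @property
    def control_line_position_mm(self) -> float:
        """Control line center; downstream of the test line."""
        return self.test_line_position_mm + self.line_separation_mm

    @property
    def n_cols(self) -> int:
        return int(round(self.membrane_length_mm * self.pixels_per_mm))

    @property
    def separation_px(self) -> float:
        return self.line_separation_mm * self.pixels_per_mm

    def hash(self) -> str:
        """Short stable digest identifying this geometry in manifests."""
        key = repr(self).encode()
        return hashlib.sha256(key).hexdigest()[:12]


@dataclass(frozen=True)
class OpticalModel:
    """Intensity model of the rendered strip, on the [0, 1] pixel scale.

    ``control_depth`` is the maximal darkening of the control line below
    background; the test line darkens by ``control_depth * tc_ratio_true``.
    ``illumination_slope`` is intensity units per mm along the flow axis,
    applied symmetrically around the membrane center.
    """

    background_intensity: float = 0.85
    control_depth: float = 0.12
    tc_ratio_true: float = 1.0
    line_profile_sigma_mm: float = 0.1
    noise_sigma: float = 0.0
    illumination_slope: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.background_intensity <= 1):
            raise ConfigError("background_intensity must lie in (0, 1]")
        if self.control_depth <= 0:
            raise ConfigError("control_depth must be > 0")
        if self.tc_ratio_true < 0:
            raise ConfigError("tc_ratio_true must be >= 0")
        if self.line_profile_sigma_mm < 0 or self.noise_sigma < 0:
            raise ConfigError("sigmas must be >= 0")
        floor = self.background_intensity - self.control_depth * max(1.0, self.tc_ratio_true)
        if floor < 0:
            raise RenderSaturationError(
                f"line troughs would clip below 0 (floor {floor:.3f}); "
                "reduce control_depth or tc_ratio_true"
            )


@dataclass(frozen=True)
class GroundTruth:
    """True state of one simulated sample."""

    concentration_nmol_per_L: float
    tc_ratio_true: float
    label: Status


@dataclass(frozen=True)
class SimulatedSample:
    """One cohort member: ground truth, measured T/C, optional rendered strip."""

    sample_id: str
    truth: GroundTruth
    tc_measured: float
    image: StripImage | None = None


def concentration_to_tc(conc, model: _cal.CalibrationModel):
    """Forward assay response: T/C ratio at ``conc`` nmol/L.

    Shared with :func:`lfaquant.calibration.predict_tc`; the simulator and
    the calibration module evaluate the identical function.
    """
    return _cal.predict_tc(model, conc)


def _line_shape(x_mm: np.ndarray, center: float, width: float, sigma: float) -> np.ndarray:
    """Unit-amplitude cross-section: rectangle convolved with a Gaussian."""
    lo, hi = center - width / 2, center + width / 2
    if sigma == 0:
        return ((x_mm >= lo) & (x_mm < hi)).astype(float)
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((x_mm - lo) / s) - erf((x_mm - hi) / s))


def render_strip(
    geom: StripGeometry = StripGeometry(),
    optics: OpticalModel = OpticalModel(),
    truth: GroundTruth | None = None,
) -> StripImage:
    """Render a strip image with known ground-truth T/C.

    The noiseless column profile is background plus illumination gradient
    minus the two Gaussian-edged line troughs; i.i.d. Gaussian pixel noise
    is added from the optics seed and the result clipped to [0, 1].  A
    parameter set whose noiseless troughs would clip at 0 is refused
    (:class:`RenderSaturationError`): a saturated strip cannot be
    quantified, so simulating one silently would poison round-trip checks.
    """
    x = (np.arange(geom.n_cols) + 0.5) / geom.pixels_per_mm
    base = optics.background_intensity + optics.illumination_slope * (
        x - geom.membrane_length_mm / 2
    )
    test_depth = optics.control_depth * optics.tc_ratio_true
    profile = (
        base
        - test_depth
        * _line_shape(x, geom.test_line_position_mm, geom.line_width_mm, optics.line_profile_sigma_mm)
        - optics.control_depth
        * _line_shape(
            x, geom.control_line_position_mm, geom.line_width_mm, optics.line_profile_sigma_mm
        )
    )
    if profile.min() < 0:
        raise RenderSaturationError(
            f"noiseless trough reaches {profile.min():.3f} < 0; unquantifiable render refused"
        )
    if profile.max() > 1:
        raise RenderSaturationError("illumination gradient pushes background above 1")

    img = np.tile(profile, (geom.strip_width_px, 1))
    if optics.noise_sigma > 0:
        rng = np.random.default_rng(optics.seed)
        img = img + rng.normal(0.0, optics.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    meta = {
        "geometry": geom,
        "optics": optics,
        "truth": truth,
        "tc_ratio_true": optics.tc_ratio_true,
        "test_line_px": geom.test_line_position_mm * geom.pixels_per_mm,
        "control_line_px": geom.control_line_position_mm * geom.pixels_per_mm,
    }
    return StripImage(pixels=img, pixels_per_mm=geom.pixels_per_mm, meta=meta)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def _make_sampler(spec: dict, rng: np.random.Generator):
    """Build a concentration sampler from a distribution spec dict."""
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigError("concentration sampler spec must be a dict with a 'kind' key")
    kind = spec["kind"]
    if kind == "uniform":
        lo, hi = float(spec["low"]), float(spec["high"])
        if not (0 <= lo < hi):
            raise ConfigError("uniform sampler requires 0 <= low < high")
        return lambda n: rng.uniform(lo, hi, n)
    if kind == "normal":
        mean, sd = float(spec["mean"]), float(spec["sd"])
        # physiological concentrations are non-negative; truncate at 0
        return lambda n: np.clip(rng.normal(mean, sd, n), 0.0, None)
    if kind == "lognormal":
        return lambda n: rng.lognormal(float(spec["mean_log"]), float(spec["sigma_log"]), n)
    if kind == "grid":
        values = np.asarray(spec["values"], dtype=float)
        if values.ndim != 1 or len(values) == 0 or (values < 0).any():
            raise ConfigError("grid sampler needs a non-empty list of non-negative values")
        return lambda n: np.resize(values, n)
    raise ConfigError(f"unsupported sampler kind {spec.get('kind')!r}")


def simulate_cohort(
    n: int,
    conc_sampler: dict,
    model: _cal.CalibrationModel,
    replicate_cv: float = 0.0,
    seed: int | None = None,
    thresholds: ThresholdSet = ENDOCRINE_SOCIETY,
    render: bool = False,
    geometry: StripGeometry | None = None,
    optics: OpticalModel | None = None,
) -> list[SimulatedSample]:
    """Sample a cohort of subjects with known concentration and T/C.

    Concentrations are drawn from ``conc_sampler`` (see :func:`_make_sampler`
    kinds: uniform, normal, lognormal, grid); the measured T/C is the forward
    calibration response perturbed multiplicatively by a Gaussian with
    relative sd ``replicate_cv``, emulating strip-to-strip variation.  With
    ``render=True`` each sample also carries a rendered strip whose true T/C
    is the perturbed value (the strip *is* the replicate); ``optics`` then
    supplies background/noise defaults and per-strip seeds derive from
    ``seed``.
    """
    if n < 1:
        raise ConfigError("cohort size n must be >= 1")
    if replicate_cv < 0:
        raise ConfigError("replicate_cv must be >= 0")
    rng = np.random.default_rng(seed)
    conc = np.asarray(_make_sampler(conc_sampler, rng)(n), dtype=float)
    tc_true = np.asarray([float(_cal.predict_tc(model, c)) for c in conc])
    if replicate_cv > 0:
        tc_meas = np.clip(tc_true * (1.0 + rng.normal(0.0, replicate_cv, n)), 0.0, None)
    else:
        tc_meas = tc_true.copy()

    geom = geometry or StripGeometry()
    base_optics = optics or OpticalModel()
    samples = []
    for i in range(n):
        truth = GroundTruth(float(conc[i]), float(tc_true[i]), classify(conc[i], thresholds))
        image = None
        if render:
            strip_optics = OpticalModel(
                background_intensity=base_optics.background_intensity,
                control_depth=base_optics.control_depth,
                tc_ratio_true=float(tc_meas[i]),
                line_profile_sigma_mm=base_optics.line_profile_sigma_mm,
                noise_sigma=base_optics.noise_sigma,
                illumination_slope=base_optics.illumination_slope,
                seed=None if seed is None else int((seed + 1) * 100003 + i) % (2**31),
            )
            image = render_strip(geom, strip_optics, truth=truth)
        samples.append(SimulatedSample(f"strip_{i:04d}", truth, float(tc_meas[i]), image))
    return samples


def cohort_frame(samples: list[SimulatedSample]):
    """Cohort as a pandas DataFrame (one row per strip)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "concentration_nmol_L": [s.truth.concentration_nmol_per_L for s in samples],
            "tc_true": [s.truth.tc_ratio_true for s in samples],
            "tc_measured": [s.tc_measured for s in samples],
            "label": [s.truth.label.value for s in samples],
        }
    )


def write_cohort(
    samples: list[SimulatedSample],
    out_dir,
    image_format: str = "png",
    seed: int | None = None,
    geometry: StripGeometry | None = None,
) -> Path:
    """Write rendered strips plus a ground-truth manifest CSV.

    Returns the manifest path.  Samples without images get a manifest row
    with an empty image field.
    """
    from ._raster import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = geometry or StripGeometry()
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "image", "concentration_nmol_L", "tc_true", "tc_measured",
             "label", "seed", "geometry_hash"]
        )
        for s in samples:
            img_name = ""
            if s.image is not None:
                img_name = f"{s.sample_id}.{image_format}"
                write_image(out / img_name, s.image.pixels)
            writer.writerow(
                [
                    s.sample_id,
                    img_name,
                    f"{s.truth.concentration_nmol_per_L:.6g}",
                    f"{s.truth.tc_ratio_true:.6g}",
                    f"{s.tc_measured:.6g}",
                    s.truth.label.value,
                    "" if seed is None else seed,
                    geom.hash(),
                ]
            )
    return manifest
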