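"""Domain containers shared across the fazmorph pipeline.

Conventions used throughout the package:

* lengths are micrometres (μm) unless a name says ``_px``;
* angles are degrees in ``[0, 180)``, ``0°`` = image horizontal, measured
  counter-clockwise in a right-handed frame (the y-flip from image
  row-coordinates is handled by the morphometry layer);
* ``group`` is ``"control"`` or ``"dr"``; ``layer`` is ``"superficial"``
  or ``"deep"`` (the two retinal capillary plexuses of an OCT-A scan).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Group = Literal["control", "dr"]
Layer = Literal["superficial", "deep"]
AngleClass = Literal["typical", "atypical"]

GROUPS: tuple[Group, ...] = ("control", "dr")
LAYERS: tuple[Layer, ...] = ("superficial", "deep")

#: Scan-head sampling of the en-face frame (A-scans per B-scan).
DEFAULT_RESOLUTION = 304
#: Pixel pitch of a 2 mm × 2 mm macular scan sampled at 304 × 304.
DEFAULT_UM_PER_PIXEL = 6.579


@dataclass(frozen=True)
class GroupLayerParams:
    """Printed cohort statistics for one (group, layer) cell.

    ``mean_h_um``/``sd_h_um`` describe the horizontal Feret diameter of the
    FAZ, ``mean_max_um``/``sd_max_um`` the maximum Feret diameter, and
    ``typical_fraction`` the proportion of eyes whose maximum-diameter angle
    lies within 15° of the horizontal or vertical axis.
    """

    mean_h_um: float
    sd_h_um: float
    mean_max_um: float
    sd_max_um: float
    typical_fraction: float

    def __post_init__(self) -> None:
        if self.sd_h_um <= 0 or self.sd_max_um <= 0:
            raise ValueError("diameter SDs must be positive")
        if self.mean_h_um <= 0 or self.mean_max_um <= 0:
            raise ValueError("diameter means must be positive")
        if not 0.0 <= self.typical_fraction <= 1.0:
            raise ValueError("typical_fraction must lie in [0, 1]")
        if self.mean_max_um < self.mean_h_um:
            raise ValueError("mean maximum diameter cannot be below the horizontal mean")


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of a synthetic case-control cohort.

    ``groups`` maps ``(group, layer)`` to :class:`GroupLayerParams`.  The
    visual-acuity model is linear in the eye's mean maximum FAZ diameter:
    ``BCVA = bcva_intercept + bcva_slope * max_diameter + N(0, bcva_noise_sd)``
    clipped to the 0–100 ETDRS letter range.  ``layer_corr`` couples the FAZ
    size of the two plexuses of one eye on the latent normal scale.
    """

    n_control: int
    n_dr: int
    groups: dict[tuple[Group, Layer], GroupLayerParams]
    bcva_intercept: float = 96.0
    bcva_slope: float = -0.015  # letters per μm; larger FAZ -> fewer letters
    bcva_noise_sd: float = 8.0
    layer_corr: float = 0.8
    sampling: str = "stratified"  # "stratified" (cohort-exact) or "iid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_dr < 1:
            raise ValueError("both groups need at least one eye")
        if self.bcva_slope > 0:
            raise ValueError("bcva_slope must be <= 0 (larger FAZ cannot add letters)")
        if self.bcva_noise_sd < 0:
            raise ValueError("bcva_noise_sd must be >= 0")
        if not -1.0 < self.layer_corr < 1.0:
            raise ValueError("layer_corr must lie in (-1, 1)")
        if self.sampling not in ("stratified", "iid"):
            raise ValueError("sampling must be 'stratified' or 'iid'")
        missing = [(g, l) for g in GROUPS for l in LAYERS if (g, l) not in self.groups]
        if missing:
            raise ValueError(f"missing group/layer parameter cells: {missing}")


@dataclass(frozen=True)
class EyeGroundTruth:
    """Generative parameters of one synthetic eye in one layer.

    The FAZ is an ellipse with semi-axes ``faz_semi_major_um >=
    faz_semi_minor_um`` rotated by ``faz_orientation_deg``.  DR eyes carry
    ``n_gaps`` interruptions of the perifoveal arcade, each of angular width
    ``gap_arc_deg``, plus a ``dropout_fraction`` of deleted capillary
    segments away from the arcade.
    """

    eye_id: str
    group: Group
    layer: Layer
    faz_semi_major_um: float
    faz_semi_minor_um: float
    faz_orientation_deg: float
    n_gaps: int
    gap_arc_deg: float
    dropout_fraction: float
    bcva_letters: float
    render_seed: int

    def __post_init__(self) -> None:
        if not self.faz_semi_major_um >= self.faz_semi_minor_um > 0:
            raise ValueError("need semi_major >= semi_minor > 0")
        if not 0.0 <= self.faz_orientation_deg < 180.0:
            raise ValueError("orientation must lie in [0, 180)")
        if self.group == "control" and (self.n_gaps != 0 or self.dropout_fraction != 0):
            raise ValueError("control eyes have closed arcades (no gaps, no dropout)")
        if self.n_gaps < 0 or not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("invalid gap/dropout parameters")
        if not 0.0 <= self.bcva_letters <= 100.0:
            raise ValueError("BCVA must lie in [0, 100] ETDRS letters")

    @property
    def max_diameter_um(self) -> float:
        """Ground-truth maximum Feret diameter (the full major axis)."""
        return 2.0 * self.faz_semi_major_um

    def feret_um(self, direction_deg: float) -> float:
        """Analytic Feret extent of the ground-truth ellipse along a direction."""
        rel = math.radians(direction_deg - self.faz_orientation_deg)
        a, b = self.faz_semi_major_um, self.faz_semi_minor_um
        return 2.0 * math.hypot(a * math.cos(rel), b * math.sin(rel))

    @property
    def horizontal_um(self) -> float:
        return self.feret_um(0.0)

    @property
    def vertical_um(self) -> float:
        return self.feret_um(90.0)


@dataclass
class EnFaceAngiogram:
    """One en-face OCT-A frame: grayscale flow map plus its pixel scale.

    Intensity convention: 0 = no de-correlation signal (no flow), larger
    values = flow.  Frames are square.
    """

    pixels: np.ndarray
    um_per_pixel: float
    layer: Layer
    eye_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("angiogram frames must be square 2-D arrays")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")

    @property
    def field_um(self) -> float:
        return self.pixels.shape[0] * self.um_per_pixel


@dataclass
class FazRegion:
    """Segmented FAZ: binary mask, sub-pixel boundary polygon, centroid.

    ``boundary`` is an (N, 2) array of (x, y) pixel coordinates tracing a
    closed, simple polygon; ``centroid`` is (x, y) in pixels.
    """

    mask: np.ndarray
    boundary: np.ndarray
    centroid: tuple[float, float]
    um_per_pixel: float

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.um_per_pixel**2


@dataclass
class FazMeasurement:
    """The five FAZ measurements of one eye/layer plus the angle class."""

    horizontal_um: float
    vertical_um: float
    max_um: float
    perp_um: float
    angle_deg: float
    angle_class: AngleClass
    eye_id: str | None = None
    layer: Layer | None = None

    def __post_init__(self) -> None:
        small = 1e-6
        if min(self.horizontal_um, self.vertical_um, self.max_um, self.perp_um) <= 0:
            raise ValueError("all diameters must be positive")
        if self.max_um + small < max(self.horizontal_um, self.vertical_um, self.perp_um):
            raise ValueError("max_um must dominate every other diameter")
        if not 0.0 <= self.angle_deg < 180.0:
            raise ValueError("angle must lie in [0, 180)")


@dataclass
class DiagnosticResult:
    """Angle-typicality rule evaluated as a diagnostic test for DR.

    ``table`` rows are (DR, control), columns (atypical, typical); an
    atypical angle is the positive test.  Confidence intervals are exact
    (Clopper–Pearson) binomial intervals.
    """

    table: np.ndarray
    sensitivity: float
    specificity: float
    sens_ci95: tuple[float, float]
    spec_ci95: tuple[float, float]
    chi2_stat: float
    chi2_p: float

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        if self.table.shape != (2, 2) or (self.table < 0).any():
            raise ValueError("table must be a non-negative 2x2 count matrix")
        for point, (lo, hi) in (
            (self.sensitivity, self.sens_ci95),
            (self.specificity, self.spec_ci95),
        ):
            if not 0.0 <= lo <= point <= hi <= 1.0:
                raise ValueError("CI must bracket its point estimate inside [0, 1]")


@dataclass
class StatResult:
    """One statistical test: name, statistic, p-value, n, and method notes."""

    name: str
    statistic: float
    p_value: float
    n: int
    method_notes: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RatingsMatrix:
    """Complete n_subjects × n_raters matrix of repeated measurements."""

    values: np.ndarray
    rater_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("ratings must be 2-D (subjects × raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need >= 2 subjects and >= 2 raters")
        if not self.rater_ids:
            self.rater_ids = tuple(f"grader_{i + 1}" for i in range(k))
        if len(self.rater_ids) != k:
            raise ValueError("rater_ids length must match the number of columns")
        if np.isnan(self.values.astype(float)).any():
            raise ValueError("ratings matrix must be complete (no missing cells)")
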