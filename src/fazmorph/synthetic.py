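"""Synthetic OCT-A cohorts: ground-truth sampling, angiogram rendering,
and two-grader measurement noise.

The generator emulates the statistical structure of a published 54-eye
case-control OCT-A cohort (25 healthy eyes, 29 eyes with diabetic
retinopathy), so that the full measure/diagnose/stats pipeline can be
exercised without any patient data:

* the FAZ of each eye is an ellipse; healthy eyes keep a closed perifoveal
  capillary arcade, DR eyes receive arcade gaps and peripheral capillary
  dropout;
* the horizontal Feret diameter of each (group, layer) cell is drawn from a
  truncated normal with the cell's configured mean/SD, and the ellipse
  aspect ratio is calibrated per cell so that the maximum Feret diameter
  reproduces the cell's configured maximum-diameter mean (see
  :func:`calibrate_aspect_ratio`);
* the maximum-diameter orientation is assigned by exact stratification:
  ``round(typical_fraction * n)`` eyes per cell draw their angle uniformly
  from the typical set ``[-15°, 15°] ∪ [75°, 105°]`` (mod 180), the rest
  uniformly from its complement, so the printed typicality proportions are
  reproduced exactly at the study's n;
* visual acuity is linear in the eye's FAZ size with Gaussian noise,
  clipped to the 0-100 ETDRS letter range.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy import ndimage
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.spatial import Delaunay
from scipy.stats import norm, truncnorm
from skimage.draw import line as draw_line

from .morphometry import TYPICAL_BAND_DEG, classify_angle
from .types import (
    DEFAULT_RESOLUTION,
    DEFAULT_UM_PER_PIXEL,
    LAYERS,
    CohortParams,
    EnFaceAngiogram,
    EyeGroundTruth,
    FazMeasurement,
    Group,
    GroupLayerParams,
    Layer,
)

#: Group statistics of the reference clinical cohort (μm, proportions):
#: per (group, layer): horizontal-diameter mean/SD, maximum-diameter
#: mean/SD, and the fraction of eyes with a typical maximum-diameter angle.
REFERENCE_GROUP_STATS: dict[tuple[Group, Layer], GroupLayerParams] = {
    ("control", "superficial"): GroupLayerParams(573.0, 177.0, 661.0, 171.0, 0.720),
    ("control", "deep"): GroupLayerParams(659.0, 194.0, 731.0, 189.0, 0.760),
    ("dr", "superficial"): GroupLayerParams(753.0, 272.0, 953.0, 393.0, 0.069),
    ("dr", "deep"): GroupLayerParams(1009.0, 342.0, 1227.0, 484.0, 0.138),
}

#: Cohort sizes of the reference study (eyes per group, per layer).
REFERENCE_N_CONTROL = 25
REFERENCE_N_DR = 29

#: Standard macular scan widths offered by OCT-A instruments (μm); the
#: renderer picks the smallest one that holds the eye's FAZ with margin.
STANDARD_FIELDS_UM = (2000.0, 3000.0, 4000.0, 6000.0)

#: Two-grader diameter noise (μm) calibrated so that the simulated ICC(2,1)
#: over a pooled 54-eye layer matches the agreement observed clinically
#: (between-eye SD ≈ 343 μm and ICC ≈ 0.857 imply σ_e ≈ 140 μm).
DEFAULT_DIAM_NOISE_SD_UM = 140.0
#: Two-grader angle-reading noise (degrees, applied modulo 180).
DEFAULT_ANGLE_NOISE_SD_DEG = 5.0


def reference_cohort_params(seed: int = 0) -> CohortParams:
    """Cohort parameters reproducing the reference study's group statistics."""
    return CohortParams(
        n_control=REFERENCE_N_CONTROL,
        n_dr=REFERENCE_N_DR,
        groups=dict(REFERENCE_GROUP_STATS),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# orientation stratification and aspect-ratio calibration
# ---------------------------------------------------------------------------

_BAND = TYPICAL_BAND_DEG  # 15°


def _typical_angle(u: float) -> float:
    """Map u ~ U[0,1) onto the typical orientation set, uniformly.

    The set is [0,15] ∪ [75,105] ∪ [165,180) (i.e. ±15° around 0° and 90°,
    modulo 180), total measure 60°.
    """
    t = u * 4 * _BAND
    if t < 2 * _BAND:
        return (t - _BAND) % 180.0
    return 90.0 - _BAND + (t - 2 * _BAND)


def _atypical_angle(u: float) -> float:
    """Map u ~ U[0,1) uniformly onto the complement (15,75) ∪ (105,165)."""
    t = u * (180.0 - 4 * _BAND)
    half = 90.0 - 2 * _BAND
    if t < half:
        return _BAND + t
    return 90.0 + _BAND + (t - half)


def _directional_factor(theta_deg: float, aspect: float) -> float:
    """Normalized horizontal Feret extent of an aspect-q ellipse at
    orientation theta: g = sqrt(cos²θ + q² sin²θ), so horizontal = 2 a g."""
    th = math.radians(theta_deg)
    return math.hypot(math.cos(th), aspect * math.sin(th))


def _mean_inverse_factor(aspect: float, typical_fraction: float) -> float:
    """E[1 / g(θ; q)] under the stratified orientation distribution."""

    def inv_g(theta):
        return 1.0 / _directional_factor(theta, aspect)

    # the typical set is symmetric: average over [0,15] and [75,90] quadrants
    t1, _ = quad(inv_g, 0.0, _BAND)
    t2, _ = quad(inv_g, 90.0 - _BAND, 90.0)
    e_typ = (t1 + t2) / (2 * _BAND)
    a1, _ = quad(inv_g, _BAND, 90.0 - _BAND)
    e_atyp = a1 / (90.0 - 2 * _BAND)
    f = typical_fraction
    return f * e_typ + (1 - f) * e_atyp


def calibrate_aspect_ratio(
    mean_h_um: float, mean_max_um: float, typical_fraction: float
) -> float:
    """Ellipse aspect ratio (minor/major) matching a cell's printed means.

    Given that the horizontal Feret diameter h is drawn with mean
    ``mean_h_um`` and the orientation is stratified with ``typical_fraction``,
    the major axis is 2a = h / g(θ; q) and its mean is
    ``mean_h_um * E[1/g]``.  This solves ``E[1/g(θ; q)] = mean_max / mean_h``
    for the aspect ratio q, so the maximum-diameter group mean matches its
    printed value as well.
    """
    target = mean_max_um / mean_h_um
    if target < 1.0:
        raise ValueError("maximum-diameter mean must be >= horizontal mean")
    if target == 1.0:
        return 1.0 - 1e-9

    def fun(q):
        return _mean_inverse_factor(q, typical_fraction) - target

    lo, hi = 0.02, 1.0 - 1e-9
    if fun(lo) < 0:
        raise ValueError("requested max/horizontal ratio is too large for an ellipse")
    return float(brentq(fun, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Quantile function of a normal truncated at zero from below."""
    a = (0.0 - mean) / sd
    return truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def sample_cohort(params: CohortParams) -> list[EyeGroundTruth]:
    """Draw ground truths for every eye of a synthetic cohort, both layers.

    Returns ``(n_control + n_dr) * 2`` records, one per eye per layer;
    the two layer records of one physical eye share its ``eye_id``, its
    visual acuity, and a latent size factor (``params.layer_corr`` on the
    normal-quantile scale), since both plexuses belong to the same retina.

    With the default ``sampling="stratified"`` the horizontal-diameter
    quantiles of each (group, layer) cell are drawn by randomized Latin
    hypercube (one uniform draw per quantile stratum, assigned to eyes by
    size rank), so every cohort reproduces the configured group statistics
    at the study's own n — the same exact-reproduction design used for the
    typical-angle stratification.  ``sampling="iid"`` gives plain
    independent draws instead.  Either way each diameter is marginally
    truncated-normal with the configured mean/SD.

    Fully reproducible from ``params.seed``: the master seed spawns one
    stream for sampling and one child seed per (eye, layer) for rendering.
    """
    master = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(master.spawn(1)[0])

    n = {"control": params.n_control, "dr": params.n_dr}
    eye_ids = {
        "control": [f"C{i + 1:03d}" for i in range(params.n_control)],
        "dr": [f"D{i + 1:03d}" for i in range(params.n_dr)],
    }

    # latent per-eye size factor shared by the two layers
    z_eye = {g: rng.standard_normal(n[g]) for g in ("control", "dr")}

    records: dict[tuple[str, Layer], dict] = {}
    for layer in LAYERS:
        for group in ("control", "dr"):
            cell = params.groups[(group, layer)]
            m = n[group]
            # calibrate against the realized (truncated) horizontal mean so
            # the maximum-diameter group mean lands on its configured value
            trunc_mean_h = float(
                truncnorm.mean(
                    -cell.mean_h_um / cell.sd_h_um, np.inf,
                    loc=cell.mean_h_um, scale=cell.sd_h_um,
                )
            )
            aspect = calibrate_aspect_ratio(
                trunc_mean_h, cell.mean_max_um, round(cell.typical_fraction * m) / m
            )
            rho = params.layer_corr
            z = rho * z_eye[group] + math.sqrt(1 - rho**2) * rng.standard_normal(m)
            if params.sampling == "stratified":
                # one quantile stratum per eye, assigned by the latent size
                # rank so the two layers of one eye stay correlated
                ranks = np.argsort(np.argsort(z))
                u = (ranks + rng.random(m)) / m
            else:
                u = norm.cdf(z)
            h = _truncnorm_ppf(u, cell.mean_h_um, cell.sd_h_um)

            n_typ = int(round(cell.typical_fraction * m))
            typical = np.zeros(m, dtype=bool)
            typical[rng.permutation(m)[:n_typ]] = True
            u = rng.random(m)
            theta = np.array(
                [
                    _typical_angle(u[i]) if typical[i] else _atypical_angle(u[i])
                    for i in range(m)
                ]
            )

            g = np.array([_directional_factor(t, aspect) for t in theta])
            semi_major = h / (2.0 * g)
            semi_minor = aspect * semi_major

            if group == "dr":
                n_gaps = rng.integers(1, 4, size=m)
                gap_arc = rng.uniform(15.0, 35.0, size=m)
                dropout = rng.uniform(0.05, 0.25, size=m)
            else:
                n_gaps = np.zeros(m, dtype=int)
                gap_arc = np.zeros(m)
                dropout = np.zeros(m)

            for i, eid in enumerate(eye_ids[group]):
                records[(eid, layer)] = dict(
                    eye_id=eid,
                    group=group,
                    layer=layer,
                    faz_semi_major_um=float(semi_major[i]),
                    faz_semi_minor_um=float(semi_minor[i]),
                    faz_orientation_deg=float(theta[i]),
                    n_gaps=int(n_gaps[i]),
                    gap_arc_deg=float(gap_arc[i]),
                    dropout_fraction=float(dropout[i]),
                )

    # one acuity per physical eye, driven by its mean maximum diameter
    bcva: dict[str, float] = {}
    for group in ("control", "dr"):
        for eid in eye_ids[group]:
            mean_max = float(
                np.mean([records[(eid, ly)]["faz_semi_major_um"] * 2 for ly in LAYERS])
            )
            letters = (
                params.bcva_intercept
                + params.bcva_slope * mean_max
                + rng.normal(0.0, params.bcva_noise_sd)
            )
            bcva[eid] = float(np.clip(letters, 0.0, 100.0))

    # per-(eye, layer) render seeds from a documented spawn order
    out: list[EyeGroundTruth] = []
    order = [
        (eid, layer)
        for layer in LAYERS
        for group in ("control", "dr")
        for eid in eye_ids[group]
    ]
    children = master.spawn(1 + len(order))[1:]
    for (eid, layer), child in zip(order, children):
        rec = records[(eid, layer)]
        out.append(
            EyeGroundTruth(
                bcva_letters=bcva[eid],
                render_seed=int(child.generate_state(1)[0] % 2**31),
                **rec,
            )
        )
    return out


# ---------------------------------------------------------------------------
# angiogram rendering
# ---------------------------------------------------------------------------


def choose_field_um(gt: EyeGroundTruth, margin_factor: float = 2.7) -> float:
    """Smallest standard scan width that holds the eye's FAZ with margin."""
    need = margin_factor * gt.faz_semi_major_um
    for f in STANDARD_FIELDS_UM:
        if f >= need:
            return f
    return STANDARD_FIELDS_UM[-1]


def _mesh_sites(
    rng: np.random.Generator,
    res: int,
    spacing_px: float,
    a_px: float,
    b_px: float,
    theta_deg: float,
    ring_offset_px: float,
) -> np.ndarray:
    """Capillary-network node positions: a jittered lattice over the frame
    plus a dense ring of nodes hugging the arcade, which keeps the mesh
    faces adjacent to the FAZ shallow (so arcade gaps enlarge the avascular
    region only modestly)."""
    coords = np.arange(spacing_px / 2, res, spacing_px)
    xx, yy = np.meshgrid(coords, coords)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts = pts + rng.uniform(-0.35 * spacing_px, 0.35 * spacing_px, size=pts.shape)

    # ring of sites just outside the arcade band
    c = (res - 1) / 2.0
    th = math.radians(theta_deg)
    peri = 2 * math.pi * math.sqrt((a_px**2 + b_px**2) / 2)
    n_ring = max(16, int(peri / 3.0))
    t = np.linspace(0, 2 * math.pi, n_ring, endpoint=False)
    t += rng.uniform(0, 2 * math.pi / n_ring)
    ex = (a_px + ring_offset_px) * np.cos(t)
    ey = (b_px + ring_offset_px) * np.sin(t)
    # rotate by theta (y-down frame: clockwise screen rotation = CCW anatomical)
    rx = c + ex * math.cos(th) + ey * math.sin(th)
    ry = c - ex * math.sin(th) + ey * math.cos(th)
    ring = np.column_stack([rx, ry])
    pts = np.vstack([pts, ring])
    keep = (pts[:, 0] > 1) & (pts[:, 0] < res - 2) & (pts[:, 1] > 1) & (pts[:, 1] < res - 2)
    return pts[keep]


def render_angiogram(
    gt: EyeGroundTruth,
    resolution: int = DEFAULT_RESOLUTION,
    field_um: float | None = None,
    capillary_spacing_um: float = 55.0,
    arcade_thickness_px: float = 2.0,
    vessel_thickness_px: int = 2,
    shadow_rate: float = 0.25,
) -> EnFaceAngiogram:
    """Render one synthetic en-face angiogram frame for an eye/layer.

    The FAZ ellipse interior carries no vessel signal; a perifoveal arcade
    (a closed capillary ring on the ellipse boundary) surrounds it, and a
    randomized planar capillary mesh (jittered-lattice Delaunay edges)
    fills the rest of the frame.  For DR eyes, ``gt.n_gaps`` contiguous
    arcs of the arcade (each ``gt.gap_arc_deg`` wide) are erased so the
    measurable avascular region grows through the gaps, a
    ``gt.dropout_fraction`` of peripheral mesh edges is deleted, and
    signal-void shadow artifacts may be stamped.  Deterministic given
    ``gt.render_seed``.

    If ``field_um`` is omitted the smallest standard scan width that holds
    the FAZ with >= 10% margin is used (mirroring the 2 mm / 3 mm scan
    choice made at acquisition time).
    """
    if field_um is None:
        field_um = choose_field_um(gt)
    upp = field_um / resolution
    a_px = gt.faz_semi_major_um / upp
    b_px = gt.faz_semi_minor_um / upp
    if 2 * a_px > 0.8 * resolution:
        raise ValueError(
            f"FAZ (major axis {2 * gt.faz_semi_major_um:.0f} μm) does not fit a "
            f"{field_um:.0f} μm frame with 10% margin"
        )
    rng = np.random.default_rng(gt.render_seed)
    c = (resolution - 1) / 2.0

    yy, xx = np.mgrid[0:resolution, 0:resolution].astype(float)
    th = math.radians(gt.faz_orientation_deg)
    dx, dy = xx - c, yy - c
    # rotate into the ellipse frame; the y-flip makes theta CCW-anatomical
    u = dx * math.cos(th) - dy * math.sin(th)
    v = dx * math.sin(th) + dy * math.cos(th)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0

    dist_out = ndimage.distance_transform_edt(~inside)
    arcade = (dist_out > 0) & (dist_out <= arcade_thickness_px)

    spacing_px = max(3.5, capillary_spacing_um / upp)
    sites = _mesh_sites(
        rng, resolution, spacing_px, a_px, b_px, gt.faz_orientation_deg,
        ring_offset_px=arcade_thickness_px + 1.5,
    )
    tri = Delaunay(sites)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            e = (simplex[i], simplex[(i + 1) % 3])
            edges.add((min(e), max(e)))
    edges = sorted(edges)

    mesh = np.zeros((resolution, resolution), dtype=bool)
    protect_px = arcade_thickness_px + 6.0  # dropout never opens the inner ring
    drop_u = rng.random(len(edges))
    site_dist = dist_out[
        np.clip(sites[:, 1].astype(int), 0, resolution - 1),
        np.clip(sites[:, 0].astype(int), 0, resolution - 1),
    ]
    for k, (i, j) in enumerate(edges):
        if gt.dropout_fraction > 0 and drop_u[k] < gt.dropout_fraction:
            if site_dist[i] > protect_px and site_dist[j] > protect_px:
                continue  # dropped capillary segment
        r0, c0 = int(round(sites[i][1])), int(round(sites[i][0]))
        r1, c1 = int(round(sites[j][1])), int(round(sites[j][0]))
        rr, cc = draw_line(r0, c0, r1, c1)
        mesh[rr, cc] = True
    if vessel_thickness_px > 1:
        mesh = ndimage.binary_dilation(mesh, np.ones((2, 2)))
    mesh &= dist_out > arcade_thickness_px  # mesh never invades the arcade band

    vessels = arcade | mesh

    if gt.n_gaps > 0:
        phi = np.degrees(np.arctan2(v, u)) % 360.0
        centers = rng.uniform(0.0, 360.0, size=gt.n_gaps)
        in_gap = np.zeros_like(inside)
        for ctr in centers:
            d = np.abs((phi - ctr + 180.0) % 360.0 - 180.0)
            in_gap |= d <= gt.gap_arc_deg / 2.0
        # erase the arcade band inside the gap sectors, contiguous with the
        # FAZ interior; the dense site ring just outside bounds the growth
        vessels &= ~(in_gap & (dist_out <= arcade_thickness_px))

    if gt.group == "dr" and shadow_rate > 0 and rng.random() < shadow_rate:
        # signal-void artifact (e.g. overlying hemorrhage or edema shadowing);
        # placed clear of the arcade so it cannot merge with the FAZ — real
        # graders reject frames whose FAZ outline is obscured by artifact
        sr = rng.uniform(80.0, 200.0) / upp
        for _ in range(50):
            sx = rng.uniform(0.1 * resolution, 0.9 * resolution)
            sy = rng.uniform(0.1 * resolution, 0.9 * resolution)
            d = dist_out[int(round(sy)), int(round(sx))]
            if d > sr + arcade_thickness_px + 8.0:
                shadow = (xx - sx) ** 2 + (yy - sy) ** 2 <= sr**2
                vessels &= ~shadow
                break

    img = rng.uniform(0.0, 40.0, size=(resolution, resolution))
    img[vessels] = rng.uniform(170.0, 255.0, size=int(vessels.sum()))
    return EnFaceAngiogram(
        pixels=img.astype(np.uint8),
        um_per_pixel=upp,
        layer=gt.layer,
        eye_id=gt.eye_id,
    )


# ---------------------------------------------------------------------------
# grader simulation
# ---------------------------------------------------------------------------


def simulate_graders(
    true_measure: FazMeasurement,
    diam_noise_sd: float = DEFAULT_DIAM_NOISE_SD_UM,
    angle_noise_sd: float = DEFAULT_ANGLE_NOISE_SD_DEG,
    n_graders: int = 2,
    seed: int = 0,
) -> list[FazMeasurement]:
    """Simulate independent masked graders re-reading one eye's measurement.

    Each grader's diameters are the truth plus i.i.d. Gaussian noise
    truncated to stay positive; the angle is perturbed modulo 180° and the
    typicality class re-derived.  The maximum diameter is re-asserted as the
    largest of the grader's four readings (a grader's longest chord cannot
    be shorter than another diameter they drew).
    """
    if diam_noise_sd < 0 or angle_noise_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    if n_graders < 2:
        raise ValueError("agreement analyses need at least two graders")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_graders):
        def _noisy(x: float) -> float:
            if diam_noise_sd == 0:
                return x
            while True:
                val = x + rng.normal(0.0, diam_noise_sd)
                if val > 0:
                    return val

        h = _noisy(true_measure.horizontal_um)
        v = _noisy(true_measure.vertical_um)
        p = _noisy(true_measure.perp_um)
        mx = _noisy(true_measure.max_um)
        mx = max(mx, h, v, p)
        if angle_noise_sd > 0:
            ang = (true_measure.angle_deg + rng.normal(0.0, angle_noise_sd)) % 180.0
        else:
            ang = true_measure.angle_deg
        out.append(
            replace(
                true_measure,
                horizontal_um=h,
                vertical_um=v,
                perp_um=p,
                max_um=mx,
                angle_deg=ang,
                angle_class=classify_angle(ang),
            )
        )
    return out
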