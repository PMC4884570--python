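"""End-to-end orchestration: simulate → render → measure → diagnose → stats.

One :func:`run_pipeline` call takes a :class:`RunConfig`, renders and
measures every eye of a synthetic cohort in both plexus layers, evaluates
the angle-typicality diagnostic, runs the cohort statistical battery, and
writes per-layer CSV/JSON artifacts plus a markdown report juxtaposing the
computed values with the reference cohort statistics the simulator targets.
Outputs are byte-identical for identical config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .diagnostics import sens_spec_ci
from .morphometry import FazExtractionError, measure_angiogram
from .stats import cohen_kappa, icc_2_1, mann_whitney_u, shapiro_wilk_gate, spearman_rho
from .synthetic import (
    DEFAULT_ANGLE_NOISE_SD_DEG,
    DEFAULT_DIAM_NOISE_SD_UM,
    REFERENCE_GROUP_STATS,
    CohortParams,
    reference_cohort_params,
    render_angiogram,
    sample_cohort,
    simulate_graders,
)
from .types import LAYERS, EyeGroundTruth, FazMeasurement, GroupLayerParams

log = logging.getLogger("fazmorph")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    cohort: CohortParams
    out_dir: Path
    layers: tuple[str, ...] = LAYERS
    vessel_threshold: float = 100.0
    closing_radius_px: int = 2
    resolution: int = 304
    save_images: bool = False
    grader_diam_noise_sd: float = DEFAULT_DIAM_NOISE_SD_UM
    grader_angle_noise_sd: float = DEFAULT_ANGLE_NOISE_SD_DEG

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        if seed is not None:
            cohort_raw["seed"] = seed
        groups_raw = cohort_raw.pop("groups", None)
        base = reference_cohort_params(seed=cohort_raw.pop("seed", 0))
        groups = dict(base.groups)
        if groups_raw:
            for key, cell in groups_raw.items():
                grp, layer = key.split("/")
                groups[(grp, layer)] = GroupLayerParams(**cell)
        cohort = dataclasses.replace(base, groups=groups, **cohort_raw)
        out_dir = Path(raw.pop("out_dir", "fazmorph_run"))
        return cls(cohort=cohort, out_dir=out_dir, **raw)


def _measure_cohort(
    eyes: list[EyeGroundTruth], config: RunConfig
) -> tuple[list[FazMeasurement], list[dict]]:
    """Render and measure every eye; failures are logged and excluded."""
    measurements: list[FazMeasurement] = []
    failures: list[dict] = []
    for gt in eyes:
        try:
            img = render_angiogram(gt, resolution=config.resolution)
            if config.save_images:
                fio.write_angiogram(
                    img, Path(config.out_dir) / "images" / f"{gt.eye_id}_{gt.layer}.tif"
                )
            m = measure_angiogram(
                img,
                vessel_threshold=config.vessel_threshold,
                closing_radius_px=config.closing_radius_px,
            )
        except FazExtractionError as exc:
            log.warning("excluding %s/%s: %s", gt.eye_id, gt.layer, exc)
            failures.append(
                dict(eye_id=gt.eye_id, layer=gt.layer, reason=str(exc))
            )
            continue
        measurements.append(m)
    return measurements, failures


def _layer_stats(df: pd.DataFrame, cohort_df: pd.DataFrame, layer: str,
                 config: RunConfig, seed: int) -> list[dict]:
    """Statistical battery for one layer's measurement table."""
    out: list[dict] = []
    merged = df.merge(
        cohort_df[cohort_df.layer == layer][["eye_id", "group", "bcva_etdrs"]],
        on="eye_id",
    )
    ctrl = merged[merged.group == "control"]
    dr = merged[merged.group == "dr"]

    for col in ("horizontal_um", "vertical_um", "max_um", "perp_um"):
        for grp_name, grp in (("control", ctrl), ("dr", dr)):
            try:
                sw = shapiro_wilk_gate(grp[col])
                out.append(dict(name=f"shapiro_{col}_{grp_name}", layer=layer,
                                statistic=sw.statistic, p_value=sw.p_value,
                                n=sw.n, notes=sw.method_notes))
            except ValueError:
                pass
        mw = mann_whitney_u(ctrl[col], dr[col])
        out.append(dict(name=f"mann_whitney_{col}", layer=layer,
                        statistic=mw.statistic, p_value=mw.p_value, n=mw.n,
                        notes=mw.method_notes))

    for col in ("max_um", "perp_um"):
        sub = merged.dropna(subset=[col, "bcva_etdrs"])
        rho = spearman_rho(sub[col], sub["bcva_etdrs"])
        out.append(dict(name=f"spearman_{col}_vs_bcva", layer=layer,
                        statistic=rho.statistic, p_value=rho.p_value, n=rho.n,
                        notes=rho.method_notes))

    # two simulated masked graders re-reading every eye: ICC on diameters,
    # kappa on the typicality labels
    rng_seed = (seed * 1009 + {"superficial": 1, "deep": 2}.get(layer, 3)) % 2**31
    diam_a, diam_b, lab_a, lab_b = [], [], [], []
    for i, row in enumerate(df.itertuples()):
        m = FazMeasurement(
            horizontal_um=row.horizontal_um, vertical_um=row.vertical_um,
            max_um=row.max_um, perp_um=row.perp_um, angle_deg=row.angle_deg,
            angle_class=row.angle_class, eye_id=row.eye_id,
        )
        ga, gb = simulate_graders(
            m,
            diam_noise_sd=config.grader_diam_noise_sd,
            angle_noise_sd=config.grader_angle_noise_sd,
            seed=(rng_seed + i) % 2**31,
        )
        diam_a.append(ga.max_um)
        diam_b.append(gb.max_um)
        lab_a.append(ga.angle_class)
        lab_b.append(gb.angle_class)
    icc = icc_2_1(np.column_stack([diam_a, diam_b]))
    out.append(dict(name="icc_2_1_max_um", layer=layer, statistic=icc.statistic,
                    p_value=icc.p_value, n=icc.n, notes=icc.method_notes))
    try:
        kap = cohen_kappa(lab_a, lab_b)
        out.append(dict(name="cohen_kappa_angle_class", layer=layer,
                        statistic=kap.statistic, p_value=kap.p_value, n=kap.n,
                        notes=kap.method_notes))
    except ValueError as exc:
        log.warning("kappa unavailable for %s: %s", layer, exc)
    return out


def _report_markdown(results: dict, n_control: int, n_dr: int) -> str:
    lines = [
        "# FAZ morphometry pipeline report",
        "",
        f"Synthetic cohort: {n_control} control eyes, {n_dr} DR eyes, both layers.",
        "",
        "| layer | quantity | computed | reference |",
        "|---|---|---|---|",
    ]
    for layer in results:
        r = results[layer]
        for grp in ("control", "dr"):
            ref = REFERENCE_GROUP_STATS[(grp, layer)]
            lines.append(
                f"| {layer} | {grp} mean horizontal (μm) | "
                f"{r['group_means'][grp]['horizontal_um']:.0f} | {ref.mean_h_um:.0f} |"
            )
            lines.append(
                f"| {layer} | {grp} mean maximum (μm) | "
                f"{r['group_means'][grp]['max_um']:.0f} | {ref.mean_max_um:.0f} |"
            )
            lines.append(
                f"| {layer} | {grp} typical fraction | "
                f"{r['typical_fraction'][grp]:.3f} | {ref.typical_fraction:.3f} |"
            )
        d = r["diagnostics"]
        lines.append(
            f"| {layer} | sensitivity (atypical→DR) | "
            f"{d['sensitivity'] * 100:.1f}% ({d['sens_ci95'][0] * 100:.1f}–"
            f"{d['sens_ci95'][1] * 100:.1f}) | — |"
        )
        lines.append(
            f"| {layer} | specificity | "
            f"{d['specificity'] * 100:.1f}% ({d['spec_ci95'][0] * 100:.1f}–"
            f"{d['spec_ci95'][1] * 100:.1f}) | — |"
        )
        lines.append(
            f"| {layer} | excluded eyes | {len(r['failures'])} | 0 |"
        )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the report dict (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    eyes = sample_cohort(config.cohort)
    fio.write_ground_truth(eyes, out_dir / "ground_truth.json")
    cohort_df = fio.cohort_frame(eyes)
    fio.write_cohort_csv(eyes, out_dir / "cohort.csv")

    results: dict = {}
    for layer in config.layers:
        layer_eyes = [e for e in eyes if e.layer == layer]
        measurements, failures = _measure_cohort(layer_eyes, config)
        fio.write_measurements_csv(measurements, out_dir / f"measurements_{layer}.csv")
        df = fio.measurements_frame(measurements)
        merged = df.merge(
            cohort_df[cohort_df.layer == layer][["eye_id", "group"]], on="eye_id"
        )

        diag = sens_spec_ci(
            np.array(
                [
                    [
                        int(((merged.group == g) & (merged.angle_class == c)).sum())
                        for c in ("atypical", "typical")
                    ]
                    for g in ("dr", "control")
                ]
            )
        )
        stats_rows = _layer_stats(df, cohort_df, layer, config, config.cohort.seed)
        pd.DataFrame(stats_rows).to_csv(
            out_dir / f"stats_{layer}.csv", index=False, float_format="%.8g"
        )

        group_means = {
            g: merged[merged.group == g][
                ["horizontal_um", "vertical_um", "max_um", "perp_um"]
            ].mean().to_dict()
            for g in ("control", "dr")
        }
        typical_fraction = {
            g: float(
                (merged[merged.group == g].angle_class == "typical").mean()
            )
            for g in ("control", "dr")
        }
        results[layer] = dict(
            group_means=group_means,
            typical_fraction=typical_fraction,
            diagnostics=dict(
                table=diag.table.tolist(),
                sensitivity=diag.sensitivity,
                specificity=diag.specificity,
                sens_ci95=list(diag.sens_ci95),
                spec_ci95=list(diag.spec_ci95),
                chi2_stat=diag.chi2_stat,
                chi2_p=diag.chi2_p,
            ),
            failures=failures,
            n_measured=len(measurements),
        )
        (out_dir / f"diagnostics_{layer}.json").write_text(
            json.dumps(results[layer]["diagnostics"], indent=1, sort_keys=True) + "\n"
        )

    report = dict(
        seed=config.cohort.seed,
        n_control=config.cohort.n_control,
        n_dr=config.cohort.n_dr,
        layers=results,
    )
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float) + "\n"
    )
    (out_dir / "report.md").write_text(
        _report_markdown(results, config.cohort.n_control, config.cohort.n_dr)
    )
    return report
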