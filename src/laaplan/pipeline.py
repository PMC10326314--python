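"""End-to-end workflows and the command-line interface.

Three batch workflows bind the stages together:

* ``accuracy``   — given per-case mesh + XR pose + 2D annotation, localize
  the landing zone in 3D, section the mesh there, and compare the
  resulting d' diameters against the supplied projective measurements.
* ``planning``   — given per-case mesh + a prospectively chosen landing
  plane, compute the full sizing report and the predicted optimal C-arm
  angulation, and classify it against the angulation actually used.
* ``phantom-study`` — generate a synthetic cohort with analytic ground
  truth, simulate annotations and reader panels, run both workflows, and
  emit the agreement tables and confusion matrix analogs.

Each case is isolated: one failing case is logged and skipped, never
aborting the batch (real cohorts routinely contain unusable acquisitions).
Every run writes a manifest with the configuration, seeds and package
version so outputs are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import PairedMeasurements, analyze, report_table
from .angulation import (
    RECOMMENDED_RANGE,
    classify_agreement,
    confusion_matrix,
    format_confusion_matrix,
    in_recommended_range,
    optimal_angulation,
)
from .carm import CArmPose
from .landing_zone import LandingZone, localize_landing_zone, measure_cross_section, projected_diameter
from .mesh_ops import load_mesh, plane_section
from .phantom import PhantomSpec, generate_mesh, phantom_family, simulate_annotation, simulate_reader_panel
from .sizing import sizing_from_section

log = logging.getLogger("laaplan")

WORKFLOWS = ("accuracy", "planning", "phantom-study", "agree")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one batch run."""

    workflow: str
    output_dir: Path
    cases: list = dataclasses.field(default_factory=list)
    measurements_csv: Path | None = None
    threshold_deg: float = 10.0
    recommended_range: tuple = RECOMMENDED_RANGE
    n_cases: int = 13
    annotation_noise_mm: float = 0.0
    reader_noise_mm: float = 0.0
    modality_bias_mm: float = 0.0
    seed: int = 7

    def __post_init__(self):
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"workflow must be one of {WORKFLOWS}, got {self.workflow!r}")
        self.output_dir = Path(self.output_dir)


def _write_manifest(cfg: RunConfig, out: Path) -> None:
    payload = {
        "workflow": cfg.workflow,
        "seed": cfg.seed,
        "version": __version__,
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(cfg).items()
            if k != "cases"
        },
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def _pose_from_dict(d: dict) -> CArmPose:
    return CArmPose(
        alpha_deg=float(d["alpha_deg"]),
        beta_deg=float(d["beta_deg"]),
        sod_mm=float(d.get("sod_mm", 765.0)),
        sid_mm=float(d.get("sid_mm", 1100.0)),
    )


def run_accuracy(cfg: RunConfig) -> pd.DataFrame:
    """Accuracy workflow: localize annotated landing zones, measure d'.

    Each case dict needs: ``case_id``, ``mesh`` (path or SurfaceMesh),
    ``pose`` (CArmPose or dict), ``qa``/``qb`` (2D detector mm) and
    optionally ``d_xr_mm``, the periprocedural projective measurement.
    Returns the per-case d' sizing table; agreement statistics against
    d_xr are written alongside when supplied.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    rows, failures = [], 0
    for case in cfg.cases:
        cid = case.get("case_id", "?")
        try:
            mesh = case["mesh"] if not isinstance(case["mesh"], (str, Path)) else load_mesh(case["mesh"])
            pose = case["pose"] if isinstance(case["pose"], CArmPose) else _pose_from_dict(case["pose"])
            zone = localize_landing_zone(mesh, pose, np.asarray(case["qa"], float),
                                         np.asarray(case["qb"], float))
            section = measure_cross_section(mesh, zone)
            rep = sizing_from_section(section, source="d'")
            rows.append({
                "case_id": cid,
                "d_prime_max_mm": rep.d_max_mm,
                "d_prime_min_mm": rep.d_min_mm,
                "d_prime_proj_mm": projected_diameter(section, pose),
                "ovality_mm": rep.ovality_mm,
                "d_xr_mm": case.get("d_xr_mm", np.nan),
            })
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            failures += 1
            log.warning("case %s failed: %s", cid, exc)
    if not rows:
        raise RuntimeError("all cases failed in accuracy workflow")
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = failures
    df.to_csv(out / "accuracy_cases.csv", index=False)

    if df["d_xr_mm"].notna().all() and len(df) >= 3:
        results = []
        for col, label in (("d_prime_max_mm", "d'_max"), ("d_prime_proj_mm", "d'_proj")):
            pm = PairedMeasurements(list(df.case_id), df[col].to_numpy(),
                                    df.d_xr_mm.to_numpy(), label, "d_XR")
            results.append(dataclasses.replace(analyze(pm), comparison=f"{label} vs. d_XR"))
        report_table(results).to_csv(out / "accuracy_agreement.csv", index=False)
    _write_manifest(cfg, out)
    return df


def run_planning(cfg: RunConfig) -> pd.DataFrame:
    """Planning workflow: prospective sizing + angulation prediction.

    Each case dict needs: ``case_id``, ``mesh``, ``plane_point``,
    ``plane_normal`` and optionally ``used_pose`` (the angulation chosen
    in the procedure).  Emits the sizing table, per-case angulation
    comparison, and the 2x2 recommended/different confusion matrix.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    rows, pairs, failures = [], [], 0
    for case in cfg.cases:
        cid = case.get("case_id", "?")
        try:
            mesh = case["mesh"] if not isinstance(case["mesh"], (str, Path)) else load_mesh(case["mesh"])
            section = plane_section(mesh, np.asarray(case["plane_point"], float),
                                    np.asarray(case["plane_normal"], float))
            rep = sizing_from_section(section)
            poly = section.polygons[0]
            from .mesh_ops import polygon_max_diameter

            _, dmax_dir2d = polygon_max_diameter(poly)
            a0, a1 = section.in_plane_axes
            dmax_dir = dmax_dir2d[0] * a0 + dmax_dir2d[1] * a1
            used = case.get("used_pose")
            if used is not None and not isinstance(used, CArmPose):
                used = _pose_from_dict(used)
            ang = optimal_angulation(section.plane_normal, dmax_dir, reference=used,
                                     range_cfg=cfg.recommended_range)
            row = {"case_id": cid, **rep.to_dict(),
                   "pred_alpha_deg": ang.chosen.alpha_deg,
                   "pred_beta_deg": ang.chosen.beta_deg,
                   "pred_in_recommended": ang.in_recommended}
            if used is not None:
                row.update({
                    "used_alpha_deg": used.alpha_deg,
                    "used_beta_deg": used.beta_deg,
                    "delta_deg": ang.delta_to_reference_deg,
                    "label": classify_agreement(ang.chosen, used, cfg.threshold_deg),
                    "used_in_recommended": in_recommended_range(used, cfg.recommended_range),
                })
                pairs.append((ang.in_recommended, row["used_in_recommended"]))
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            failures += 1
            log.warning("case %s failed: %s", cid, exc)
    if not rows:
        raise RuntimeError("all cases failed in planning workflow")
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = failures
    df.to_csv(out / "planning_cases.csv", index=False)
    if pairs:
        cm = confusion_matrix(pairs)
        (out / "confusion_matrix.json").write_text(json.dumps({
            "counts": cm["counts"].tolist(),
            "percent": cm["percent"].tolist(),
            "percent_display": cm["percent_display"].tolist(),
            "n": int(cm["n"]),
        }, indent=2))
        (out / "confusion_matrix.txt").write_text(format_confusion_matrix(cm))
    _write_manifest(cfg, out)
    return df


def run_phantom_study(cfg: RunConfig) -> dict:
    """Full synthetic study: cohort generation through agreement tables.

    Generates ``n_cases`` phantoms, simulates tangential-view annotations
    (with ``annotation_noise_mm`` jitter) and a reader panel, runs the
    accuracy and planning workflows against the analytic ground truth,
    and writes agreement-table and confusion-matrix analogs whose
    reference columns are exact.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    specs = phantom_family(cfg.n_cases, seed=cfg.seed)
    acc_cases, plan_cases, truths = [], [], []
    for i, spec in enumerate(specs):
        mesh, truth = generate_mesh(spec)
        truths.append(truth)
        pose = truth.tangential_pose
        qa, qb = simulate_annotation(spec, truth, pose,
                                     endpoint_noise_mm=cfg.annotation_noise_mm,
                                     seed=cfg.seed + 1000 + i)
        acc_cases.append({"case_id": i, "mesh": mesh, "pose": pose, "qa": qa, "qb": qb,
                          "d_xr_mm": truth.d_max_mm})
        plan_cases.append({"case_id": i, "mesh": mesh,
                           "plane_point": truth.plane_point,
                           "plane_normal": truth.plane_normal,
                           "used_pose": pose})

    acc_cfg = dataclasses.replace(cfg, workflow="accuracy", cases=acc_cases,
                                  output_dir=out / "accuracy")
    plan_cfg = dataclasses.replace(cfg, workflow="planning", cases=plan_cases,
                                   output_dir=out / "planning")
    acc_df = run_accuracy(acc_cfg)
    plan_df = run_planning(plan_cfg)

    rm, pm = simulate_reader_panel(
        truths, reader_noise_mm=cfg.reader_noise_mm,
        modality_bias_mm=cfg.modality_bias_mm,
        modality_noise_mm=cfg.reader_noise_mm, seed=cfg.seed + 2000,
    )
    from .agreement import icc_2_1

    icc, lo, hi, label = icc_2_1(rm)
    truth_dmax = np.array([t.d_max_mm for t in truths])
    comparisons = []
    for col, lab in (("d_max_mm", "d_max"), ("d_peri_mm", "d_peri"), ("d_area_mm", "d_area")):
        pm_t = PairedMeasurements(list(plan_df.case_id), plan_df[col].to_numpy(),
                                  truth_dmax[plan_df.case_id.to_numpy()],
                                  lab, "d_truth")
        comparisons.append(dataclasses.replace(analyze(pm_t), comparison=f"{lab} vs. d_truth"))
    report_table(comparisons).to_csv(out / "sizing_agreement.csv", index=False)
    summary = {
        "n_cases": cfg.n_cases,
        "icc_readers": {"icc": icc, "ci": [lo, hi], "label": label},
        "accuracy_bias_mm": float(np.mean(acc_df.d_prime_proj_mm - acc_df.d_xr_mm)),
        "planning_dmax_bias_mm": float(np.mean(plan_df.d_max_mm.to_numpy()
                                               - truth_dmax[plan_df.case_id.to_numpy()])),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(cfg, out)
    return {"accuracy": acc_df, "planning": plan_df, "summary": summary,
            "ratings": rm, "modality_pairs": pm}


def run_agree(cfg: RunConfig) -> pd.DataFrame:
    """Agreement workflow on a tidy measurement CSV.

    Expects columns case_id, quantity, method, value_mm; every quantity
    with exactly two methods yields one comparison row.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(cfg.measurements_csv)
    results = []
    for quantity, sub in df.groupby("quantity"):
        methods = sorted(sub.method.unique())
        if len(methods) != 2:
            log.warning("quantity %s has %d methods, skipping", quantity, len(methods))
            continue
        wide = sub.pivot_table(index="case_id", columns="method", values="value_mm")
        wide = wide.dropna()
        pm = PairedMeasurements(list(wide.index), wide[methods[0]].to_numpy(),
                                wide[methods[1]].to_numpy(), *methods)
        results.append(dataclasses.replace(
            analyze(pm), comparison=f"{quantity}: {methods[0]} vs. {methods[1]}"))
    table = report_table(results)
    table.to_csv(out / "agreement.csv", index=False)
    _write_manifest(cfg, out)
    return table


# --- CLI -------------------------------------------------------------------

@click.group()
@click.version_option(__version__)
def cli():
    """Preprocedural planning toolkit for appendage-closure sizing."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.argument("mesh_path", type=click.Path(exists=True))
@click.option("--alpha", type=float, required=True, help="primary angle (deg, LAO+)")
@click.option("--beta", type=float, required=True, help="secondary angle (deg, CRAN+)")
@click.option("--qa", nargs=2, type=float, required=True, help="endpoint A (detector mm)")
@click.option("--qb", nargs=2, type=float, required=True, help="endpoint B (detector mm)")
def localize(mesh_path, alpha, beta, qa, qb):
    """Localize a 2D landing-zone annotation in 3D on a surface mesh."""
    mesh = load_mesh(mesh_path)
    pose = CArmPose(alpha_deg=alpha, beta_deg=beta)
    zone = localize_landing_zone(mesh, pose, np.asarray(qa), np.asarray(qb))
    click.echo(json.dumps({
        "endpoint_a_mm": zone.endpoint_a.tolist(),
        "endpoint_b_mm": zone.endpoint_b.tolist(),
        "diameter_mm": zone.diameter_mm,
        "plane_normal": zone.plane_normal.tolist(),
    }, indent=2))


@cli.command()
@click.argument("mesh_path", type=click.Path(exists=True))
@click.option("--point", nargs=3, type=float, required=True, help="plane point (mm)")
@click.option("--normal", nargs=3, type=float, required=True, help="plane normal")
def measure(mesh_path, point, normal):
    """Section a mesh with a plane and print the sizing report."""
    mesh = load_mesh(mesh_path)
    section = plane_section(mesh, np.asarray(point), np.asarray(normal))
    rep = sizing_from_section(section)
    click.echo(json.dumps(rep.to_dict(), indent=2))


@cli.command()
@click.argument("mesh_path", type=click.Path(exists=True))
@click.option("--point", nargs=3, type=float, required=True)
@click.option("--normal", nargs=3, type=float, required=True)
def angulate(mesh_path, point, normal):
    """Predict the optimal C-arm angulation for a landing-zone plane."""
    from .mesh_ops import polygon_max_diameter

    mesh = load_mesh(mesh_path)
    section = plane_section(mesh, np.asarray(point), np.asarray(normal))
    _, d2 = polygon_max_diameter(section.polygons[0])
    a0, a1 = section.in_plane_axes
    res = optimal_angulation(section.plane_normal, d2[0] * a0 + d2[1] * a1)
    click.echo(json.dumps({
        "alpha_deg": res.chosen.alpha_deg,
        "beta_deg": res.chosen.beta_deg,
        "in_recommended": res.in_recommended,
    }, indent=2))


@cli.command()
@click.argument("measurements_csv", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), default="agree_out")
def agree(measurements_csv, out_dir):
    """Run agreement statistics on a tidy measurement CSV."""
    cfg = RunConfig(workflow="agree", output_dir=out_dir,
                    measurements_csv=Path(measurements_csv))
    table = run_agree(cfg)
    click.echo(table.to_string(index=False))


@cli.command("phantom")
@click.option("--out", "out_path", type=click.Path(), default="phantom.stl")
@click.option("--a", type=float, default=15.0, help="major semi-axis (mm)")
@click.option("--b", type=float, default=10.0, help="minor semi-axis (mm)")
@click.option("--length", type=float, default=60.0)
def phantom_cmd(out_path, a, b, length):
    """Generate a phantom mesh and print its analytic ground truth."""
    from .mesh_ops import save_mesh

    spec = PhantomSpec(semi_axis_a_mm=(a, a), semi_axis_b_mm=(b, b), length_mm=length)
    mesh, truth = generate_mesh(spec)
    save_mesh(mesh, out_path)
    click.echo(json.dumps({
        "d_max_mm": truth.d_max_mm, "d_min_mm": truth.d_min_mm,
        "d_peri_mm": truth.d_peri_mm, "d_area_mm": truth.d_area_mm,
        "ovality_mm": truth.ovality_mm,
        "tangential_pose": {"alpha_deg": truth.tangential_pose.alpha_deg,
                            "beta_deg": truth.tangential_pose.beta_deg},
    }, indent=2))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="study YAML (n_cases, seed, noise levels)")
@click.option("--out", "out_dir", type=click.Path(), default="study_out")
def study(config_path, out_dir):
    """Run the full synthetic phantom study."""
    params = {}
    if config_path:
        params = yaml.safe_load(Path(config_path).read_text()) or {}
    cfg = RunConfig(workflow="phantom-study", output_dir=out_dir, **params)
    res = run_phantom_study(cfg)
    click.echo(json.dumps(res["summary"], indent=2))
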