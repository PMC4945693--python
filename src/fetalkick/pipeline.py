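"""Configuration-driven orchestration of the four analysis stages.

For every kick scenario the pipeline synthesizes a ground-truthed image
sequence, tracks the hip/knee/ankle through it, measures the uterine-wall
deflection, solves the wall-indentation finite-element model at the
tracked deflection, and feeds the tracked kinematics plus the computed
wall reaction into the musculoskeletal stage.  All randomness derives
from one global seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_cine, tracking
from .errors import FetalKickError
from .fe.mesh import UterusGeometry
from .fe.uterus import build_uterus_model, solve_indentation
from .geometry import ellipse_outward_normal, nearest_point_on_ellipse
from .msk.model import reference_model, scale_model
from .msk.pipeline import KickInput, ramped_contact_force, run_kick
from .scenarios import KickScenario, default_cohort
from .tracking import TrackingConfig, summarize

log = logging.getLogger("fetalkick")


@dataclass
class PipelineConfig:
    scenarios: list = field(default_factory=default_cohort)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    fe_size_near_mm: float = 1.0
    fe_size_far_mm: float = 4.0
    fe_increments: int = 10
    out_dir: Path | None = None
    global_seed: int = 0

    def __post_init__(self):
        if not self.scenarios:
            raise FetalKickError("pipeline needs at least one scenario")


@dataclass
class FetusResult:
    name: str
    tracked_femur_mm: float
    tracked_tibia_mm: float
    max_deflection_mm: float
    fe_total_contact_n: float
    fe_max_nodal_n: float
    knee_group_max_n: float
    hip_group_max_n: float
    muscle_maxima: dict
    error: str | None = None


@dataclass
class ResultsBundle:
    per_fetus: list
    cohort: dict

    def to_json(self) -> str:
        payload = {
            "per_fetus": [vars(f).copy() for f in self.per_fetus],
            "cohort": self.cohort,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _scenario_seeds(config: PipelineConfig) -> list[int]:
    ss = np.random.SeedSequence(config.global_seed)
    return [int(s) for s in ss.generate_state(len(config.scenarios)) % (2**31)]


def run_scenario(scenario: KickScenario, config: PipelineConfig,
                 out_dir: Path | None = None) -> FetusResult:
    t0 = time.time()
    truth = synthetic_cine.generate_kick_kinematics(scenario)
    seq = synthetic_cine.render_frames(truth, scenario)
    seeds = tracking.seeds_from_truth(truth, seq)
    hip, knee, ankle = tracking.track_sequence(seq, seeds, config.tracking)
    femur_mm, tibia_mm = tracking.segment_lengths(hip, knee, ankle)
    defl = tracking.wall_deflection(ankle, scenario.inner_semi_axes)
    log.info("%s: tracked deflection %.2f mm (%.1fs)", scenario.name,
             defl.max_displacement_mm, time.time() - t0)

    geom = UterusGeometry(major_axis_mm=scenario.uterus_major_axis_mm,
                          minor_axis_mm=scenario.uterus_minor_axis_mm)
    model = build_uterus_model(geom, size_near_mm=config.fe_size_near_mm,
                               size_far_mm=config.fe_size_far_mm)
    sol = solve_indentation(model, defl.max_displacement_mm,
                            n_increments=config.fe_increments)
    log.info("%s: FE total %.3f N, max nodal %.3f N (%.1fs)", scenario.name,
             sol.total_contact_force, sol.max_nodal_reaction,
             time.time() - t0)

    # wall normal at the tracked contact site (from the cavity ellipse)
    ai, bi = scenario.inner_semi_axes
    if defl.window is not None:
        p_contact = ankle.mm[defl.window[0]]
    else:
        p_contact = ankle.mm[-1]
    _, theta = nearest_point_on_ellipse(p_contact, ai, bi)
    inward = -ellipse_outward_normal(theta, ai, bi)

    msk_model = scale_model(reference_model(), femur_mm, tibia_mm)
    force = ramped_contact_force(defl.displacement_mm,
                                 sol.total_contact_force, inward)
    kick = KickInput(hip_mm=hip.mm, knee_mm=knee.mm, ankle_mm=ankle.mm,
                     force_n=force,
                     frame_interval_s=scenario.frame_interval_s)
    res = run_kick(msk_model, kick)
    knee_max = res.forces.group_max("knee")
    hip_max = res.forces.group_max("hip")
    log.info("%s: knee-group max %.2f N, hip-group max %.2f N (%.1fs total)",
             scenario.name, knee_max, hip_max, time.time() - t0)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        synthetic_cine.write_fixture(truth, seq, out_dir / "fixture")
        _write_trajectories(out_dir / "tracked.csv", seq, hip, knee, ankle,
                            defl)
        from .fe.io import write_reaction_history
        write_reaction_history(out_dir / "fe_reactions.csv", sol)
        pd.DataFrame(res.maxima_table,
                     columns=["muscle", "group", "max_force_N"]).to_csv(
            out_dir / "muscle_maxima.csv", index=False)

    return FetusResult(
        name=scenario.name,
        tracked_femur_mm=femur_mm, tracked_tibia_mm=tibia_mm,
        max_deflection_mm=defl.max_displacement_mm,
        fe_total_contact_n=sol.total_contact_force,
        fe_max_nodal_n=sol.max_nodal_reaction,
        knee_group_max_n=knee_max, hip_group_max_n=hip_max,
        muscle_maxima=res.forces.per_muscle_max,
    )


def _write_trajectories(path, seq, hip, knee, ankle, defl) -> None:
    n = len(hip)
    df = pd.DataFrame({
        "frame": np.arange(n),
        "time_s": np.arange(n) * seq.frame_interval_s,
        "hip_x": hip.mm[:, 0], "hip_y": hip.mm[:, 1],
        "knee_x": knee.mm[:, 0], "knee_y": knee.mm[:, 1],
        "ankle_x": ankle.mm[:, 0], "ankle_y": ankle.mm[:, 1],
        "contact": [
            int(defl.window is not None
                and defl.window[0] <= i <= defl.window[1]) for i in range(n)
        ],
        "deflection_mm": defl.displacement_mm,
    })
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run every scenario; failures abort that scenario only."""
    per_fetus = []
    for scenario, seed in zip(config.scenarios, _scenario_seeds(config)):
        scenario = scenario.with_seed(seed)
        out = None
        if config.out_dir is not None:
            out = Path(config.out_dir) / scenario.name
        try:
            per_fetus.append(run_scenario(scenario, config, out))
        except FetalKickError as exc:
            log.error("%s failed: %s", scenario.name, exc)
            per_fetus.append(FetusResult(
                name=scenario.name, tracked_femur_mm=np.nan,
                tracked_tibia_mm=np.nan, max_deflection_mm=np.nan,
                fe_total_contact_n=np.nan, fe_max_nodal_n=np.nan,
                knee_group_max_n=np.nan, hip_group_max_n=np.nan,
                muscle_maxima={}, error=str(exc),
            ))
    ok = [f for f in per_fetus if f.error is None]
    cohort = {}
    if ok:
        for key in ("tracked_femur_mm", "tracked_tibia_mm",
                    "max_deflection_mm", "fe_total_contact_n",
                    "fe_max_nodal_n", "knee_group_max_n", "hip_group_max_n"):
            stat = summarize([getattr(f, key) for f in ok])
            cohort[key] = {"mean": stat.mean, "sd": stat.spread}
    bundle = ResultsBundle(per_fetus=per_fetus, cohort=cohort)
    if config.out_dir is not None:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        (Path(config.out_dir) / "summary.json").write_text(bundle.to_json())
    return bundle


def report(bundle: ResultsBundle, out_dir) -> dict:
    """Cohort tables (CSV) and a headline-numbers JSON."""
    if not bundle.per_fetus:
        raise FetalKickError("empty results bundle")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in bundle.per_fetus:
        rows.append({
            "fetus": f.name, "femur_mm": f.tracked_femur_mm,
            "tibia_mm": f.tracked_tibia_mm,
            "max_deflection_mm": f.max_deflection_mm,
            "max_nodal_reaction_N": f.fe_max_nodal_n,
        })
    df = pd.DataFrame(rows)
    mean = df.drop(columns="fetus").mean()
    sd = df.drop(columns="fetus").std(ddof=0)
    df.loc[len(df)] = ["average"] + [
        f"{m:.2f} +/- {s:.2f}" for m, s in zip(mean, sd)
    ]
    df.to_csv(out_dir / "cohort_table.csv", index=False)

    muscles = {}
    for f in bundle.per_fetus:
        for nm, v in f.muscle_maxima.items():
            muscles.setdefault(nm, {})[f.name] = v
    pd.DataFrame(muscles).T.to_csv(out_dir / "muscle_maxima_table.csv")

    headline = json.loads(bundle.to_json())
    (out_dir / "report.json").write_text(json.dumps(headline, indent=1,
                                                    sort_keys=True))
    return headline
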