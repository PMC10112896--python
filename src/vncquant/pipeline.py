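"""End-to-end synthetic experiments mirroring the quantified comparisons.

Each scenario generates ``2 * n_per_group`` stacks (control and perturbed)
with child seeds derived from the master seed via a counter-based
``SeedSequence``, so adding a larva never reshuffles earlier larvae. Larva
labels are blinded through quantification and only joined back to their
group for statistics. Every threshold, parameter and seed actually used is
written into the provenance record.

Scenarios
---------
``ablation_puncta``
    Nociceptor ablation vs control; Li neuron mask -> masked presynaptic
    channel -> rolling-ball (r=3 px) -> 3D peak detection -> medial
    restriction by the landmark tracts -> per-larva medial puncta sums,
    total counts, thresholded cIII volume, and puncta density. Per-larva
    puncta counts are Poisson-distributed around the configured linear
    density so ablation adds medial axon and medial puncta at the same
    per-length rate (density is constructed to be unchanged).
``ablation_grasp``
    GRASP medial-extension ratio within dendritic-field ROIs.
``lateralization_crossing``
    Per-segment midline-crossing counts for the cIV and cIII masks.
``dendrite_shift_linescan``
    Vertically averaged line scans (0.29 µm pixels) of the dendrite channel;
    peak distance from the midline per larva.
``ablation_timecourse``
    Per-segment intact / blebbed / ablated staging of the cIV scaffold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imagecore, morphometry, puncta, stats, synthvnc
from .errors import ConfigurationError
from .grid import MultiChannelStack
from .synthvnc import CIII, CIV, DENDRITE, GRASP, LANDMARK, PUNCTA, GroundTruth, ScaffoldSpec

__all__ = ["ExperimentConfig", "ExperimentResult", "default_spec_for_scenario", "run_experiment"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SCENARIOS = (
    "ablation_puncta",
    "ablation_grasp",
    "lateralization_crossing",
    "dendrite_shift_linescan",
    "ablation_timecourse",
)

_SCENARIO_MODE = {
    "ablation_puncta": "civ_ablation",
    "ablation_grasp": "civ_ablation",
    "lateralization_crossing": "lateralization",
    "dendrite_shift_linescan": "dendrite_shift",
    "ablation_timecourse": "civ_ablation",
}

# channels each scenario's quantification chain reads
_SCENARIO_CHANNELS = {
    "ablation_puncta": (CIII, PUNCTA, LANDMARK),
    "ablation_grasp": (GRASP,),
    "lateralization_crossing": (CIV, CIII),
    "dendrite_shift_linescan": (DENDRITE,),
    "ablation_timecourse": (CIV,),
}

_SCENARIO_METRIC = {
    "ablation_puncta": "medial_puncta_sum",
    "ablation_grasp": "grasp_extension_ratio",
    "lateralization_crossing": "ciii_crossing_segments",
    "dendrite_shift_linescan": "peak_distance_um",
    "ablation_timecourse": "fraction_ablated",
}


def default_spec_for_scenario(scenario: str) -> ScaffoldSpec:
    """Study-condition geometry per scenario.

    The puncta/volume scenarios use the acquisition scale of the puncta
    imaging (0.1 µm lateral pixels, 0.5 µm z-step); the line-scan scenario
    uses 0.29 µm lateral pixels and a footprint wide enough for a 35 µm
    scan.
    """
    if scenario == "dendrite_shift_linescan":
        return ScaffoldSpec(
            voxel_dims=(0.5, 0.29, 0.29),
            shape=(8, 200, 140),
            midline_x=20.0,
        )
    return ScaffoldSpec()


@dataclass
class ExperimentConfig:
    scenario: str
    n_per_group: int = 10
    base_spec: ScaffoldSpec | None = None
    perturbation_params: dict = field(default_factory=dict)
    detection: puncta.DetectionParams | str | None = None  # None=default, or "optimize"
    seed: int = 0
    output_dir: str | Path | None = None
    n_grasp_rois: int = 6
    stage_probabilities: dict | None = None  # ablation_timecourse perturbed group

    def validate(self) -> ScaffoldSpec:
        if self.scenario not in _SCENARIOS:
            raise ConfigurationError(f"scenario must be one of {_SCENARIOS}, got {self.scenario!r}")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        spec = self.base_spec or default_spec_for_scenario(self.scenario)
        spec.validate()
        if not 4 <= self.n_grasp_rois <= 6:
            raise ConfigurationError("n_grasp_rois must be 4-6")
        return spec


@dataclass
class ExperimentResult:
    summaries: pd.DataFrame  # one row per larva
    report: stats.TestReport | None
    provenance: dict
    blinding_key: pd.DataFrame

    @property
    def groups(self) -> dict[str, pd.DataFrame]:
        return {g: df for g, df in self.summaries.groupby("group")}


def _child_seed(master: int, *key: int) -> int:
    """Counter-based child seed keyed by (group, index, ...): adding a larva
    never reshuffles the seeds of earlier larvae in either group."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ------------------------------------------------------------------ quantifiers
def _quantify_puncta(stack: MultiChannelStack, truth: GroundTruth,
                     params: puncta.DetectionParams, prov: dict) -> dict:
    ciii = stack[CIII]
    mask = imagecore.make_neuron_mask(ciii, method="li", min_component_voxels=5)
    masked = imagecore.mask_channel(stack[PUNCTA], mask)
    cleaned = imagecore.rolling_ball_subtract(masked, radius_px=3)
    detected = puncta.detect_puncta(cleaned, params)
    x_left, x_right = morphometry.landmark_interval(stack[LANDMARK], truth.midline_x)
    nz = stack.shape[0]
    dz = stack.voxel_dims[0]
    rois = [
        {"x0": x_left, "x1": x_right, "y0": ya, "y1": yb, "z0": 0.0, "z1": nz * dz}
        for (ya, yb) in truth.segment_bounds_y
    ]
    per_roi, medial_sum = puncta.count_in_rois(detected, rois)
    volume = imagecore.voxel_volume(mask)
    medial_volume = morphometry.medial_region_volume(mask, stack[LANDMARK], truth.midline_x)
    prov.setdefault("li_thresholds", []).append(float(imagecore.threshold_li(ciii)))
    prov.setdefault("detection_background", []).append(detected.background_threshold)
    return {
        "medial_puncta_sum": medial_sum,
        "per_roi_counts": json.dumps(per_roi),
        "total_puncta": len(detected),
        "ciii_volume_um3": volume,
        "medial_ciii_volume_um3": medial_volume,
        "puncta_density_per_um3": puncta.puncta_density(len(detected), volume),
    }


def _quantify_grasp(stack: MultiChannelStack, truth: GroundTruth, n_rois: int, prov: dict) -> dict:
    rois = truth.dendrite_roi[:n_rois]
    mean_ratio, ratios = morphometry.grasp_extension_ratio(stack[GRASP], rois)
    prov.setdefault("grasp_threshold_rule", "otsu_within_roi")
    return {
        "grasp_extension_ratio": mean_ratio,
        "per_roi_ratios": json.dumps([round(r, 4) for r in ratios]),
    }


def _quantify_crossing(stack: MultiChannelStack, truth: GroundTruth, spec: ScaffoldSpec, prov: dict) -> dict:
    out = {}
    for role, offsets, label in (
        (CIV, spec.civ_tract_offsets, "civ"),
        (CIII, spec.ciii_tract_offsets, "ciii"),
    ):
        grid = stack[role]
        if grid.data.max() <= 0 or np.ptp(grid.data) == 0:
            n_crossing = 0
        else:
            mask = imagecore.make_neuron_mask(grid, method="otsu", min_component_voxels=5)
            scores = morphometry.score_midline_crossing(
                mask, truth.midline_x, truth.segment_bounds_y, offsets
            )
            n_crossing = sum(1 for s in scores if s.crossing == "crossing")
        out[f"{label}_crossing_segments"] = n_crossing
    return out


def _quantify_linescan(stack: MultiChannelStack, truth: GroundTruth, prov: dict) -> dict:
    dend = stack[DENDRITE]
    distances = []
    for seg_index in (0, 2):  # neuromeres A2 and A4
        ya, yb = truth.segment_bounds_y[seg_index]
        scan = morphometry.line_scan_profile(
            dend, center_um=(truth.midline_x, 0.5 * (ya + yb)), width_x_um=35.0, height_y_um=20.0
        )
        distances.append(morphometry.peak_distance_from_center(scan))
    prov.setdefault("line_scan", {"width_x_um": 35.0, "height_y_um": 20.0})
    return {"peak_distance_um": float(np.mean(distances))}


def _quantify_timecourse(stack: MultiChannelStack, truth: GroundTruth, spec: ScaffoldSpec, prov: dict) -> dict:
    amp = spec.intensity_levels.get(CIV, 150.0)
    feats = morphometry.ablation_features(
        stack[CIV], truth.segment_bounds_y, truth.midline_x, spec.civ_tract_offsets, amp
    )
    stages = [morphometry.classify_ablation_stage(*f) for f in feats]
    true_stages = [s["stage"] for s in truth.civ_stages]
    n = len(stages)
    return {
        "fraction_intact": stages.count("intact") / n,
        "fraction_blebbed": stages.count("blebbed") / n,
        "fraction_ablated": stages.count("ablated") / n,
        "stage_agreement": float(np.mean([a == b for a, b in zip(stages, true_stages)])),
    }


# ------------------------------------------------------------------ spec builders
def _poissonized_counts(spec: ScaffoldSpec, rng: np.random.Generator,
                        medial_expected: float | None) -> dict[str, int]:
    """Per-larva puncta counts: Poisson around the configured linear density."""
    lam_lat = spec.puncta_count_per_region.get("lateral", 0)
    counts = {"lateral": int(rng.poisson(lam_lat)) if lam_lat else 0, "medial": 0}
    if medial_expected:
        counts["medial"] = int(rng.poisson(medial_expected))
    return counts


def _build_spec(config: ExperimentConfig, base: ScaffoldSpec, group: str, index: int) -> ScaffoldSpec:
    group_id = 0 if group == "control" else 1
    seed = _child_seed(config.seed, group_id, index)
    rng = np.random.default_rng(_child_seed(config.seed, group_id, index, 1))
    spec = dataclasses.replace(base, seed=seed)
    scenario = config.scenario
    mode = _SCENARIO_MODE[scenario]
    params = dict(config.perturbation_params)

    if scenario in ("ablation_puncta", "ablation_grasp"):
        if group == "perturbed":
            frac = params.setdefault("medial_branch_fraction", 1.0)
            probe = synthvnc.apply_perturbation(spec, mode, {"medial_branch_fraction": frac})
            if scenario == "ablation_puncta":
                # hold the linear puncta density fixed: medial branches gain
                # puncta at the same per-µm rate as the lateral tracts
                lam = spec.puncta_count_per_region.get("lateral", 0) / synthvnc.lateral_ciii_length(spec)
                lateral_expected = lam * synthvnc.lateral_ciii_length(probe)
                medial_expected = lam * synthvnc.medial_branch_length(probe)
                params.setdefault("medial_puncta_count", int(rng.poisson(medial_expected)))
                spec = dataclasses.replace(
                    spec,
                    puncta_count_per_region={"lateral": int(rng.poisson(lateral_expected)), "medial": 0},
                )
            return synthvnc.apply_perturbation(spec, mode, params)
        if scenario == "ablation_puncta":
            counts = _poissonized_counts(spec, rng, None)
            spec = dataclasses.replace(spec, puncta_count_per_region=counts)
        return spec

    if scenario == "lateralization_crossing":
        if group == "perturbed":
            return synthvnc.apply_perturbation(spec, mode, params)
        return spec

    if scenario == "dendrite_shift_linescan":
        if group == "perturbed":
            params.setdefault("shift_um", 3.0)
            return synthvnc.apply_perturbation(spec, mode, params)
        return spec

    # ablation_timecourse: control all intact; perturbed segments drawn from
    # the configured stage distribution
    if group == "control":
        return spec
    probs = config.stage_probabilities or {"intact": 0.2, "blebbed": 0.3, "ablated": 0.5}
    names = sorted(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    p = p / p.sum()
    stages = []
    for _ in range(spec.n_segments):
        stage = names[rng.choice(len(names), p=p)]
        if stage == "intact":
            stages.append(synthvnc.SegmentStage("intact", int(rng.integers(0, 2)), ()))
        elif stage == "blebbed":
            stages.append(synthvnc.SegmentStage("blebbed", 2 + int(rng.poisson(1.0)), ()))
        else:
            sides = [("left",), ("right",), ("left", "right")][int(rng.integers(3))]
            stages.append(synthvnc.SegmentStage("ablated", 0, sides))
    params.setdefault("medial_branch_fraction", 0.0)
    params["stage_per_segment"] = stages
    return synthvnc.apply_perturbation(spec, mode, params)


def _optimize_detection(config: ExperimentConfig, base: ScaffoldSpec):
    """Grid-search detection parameters on dedicated annotated training
    stacks (two per group, counters disjoint from the cohort's)."""
    rois = []
    for j, group in enumerate(("control", "perturbed", "control", "perturbed")):
        spec = _build_spec(config, base, group, 20_000 + j)
        stack, truth = synthvnc.generate_stack(spec)
        mask = imagecore.make_neuron_mask(stack[CIII], "li", 5)
        cleaned = imagecore.rolling_ball_subtract(imagecore.mask_channel(stack[PUNCTA], mask), 3)
        rois.append((cleaned, truth.puncta_xyz))
    space = {
        "background_param": [10.0, 15.0, 25.0, 40.0],
        "min_peak_height": [5.0, 10.0, 20.0],
        "min_size": [2, 4],
    }
    best, pooled = puncta.optimize_params(rois, space)
    return best, {"search_space": space, "pooled": pooled.to_dict()}


# ------------------------------------------------------------------ main entry
def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run one scenario end to end; see the module docstring."""
    base = config.validate()
    for role in _SCENARIO_CHANNELS[config.scenario]:
        if role not in synthvnc._CHANNEL_ORDER:
            raise ConfigurationError(f"scenario requires unknown channel role {role!r}")

    detection = config.detection
    if detection is None:
        detection = puncta.DetectionParams()
    if isinstance(detection, str) and detection != "optimize":
        raise ConfigurationError("detection must be DetectionParams, None, or 'optimize'")
    optimization_report = None
    if detection == "optimize":
        if config.scenario != "ablation_puncta":
            raise ConfigurationError("detection='optimize' applies to the ablation_puncta scenario")
        detection, optimization_report = _optimize_detection(config, base)

    larva_ids = [f"{grp}_{i:03d}" for grp in ("control", "perturbed") for i in range(config.n_per_group)]
    blinded, key = stats.blind_labels(larva_ids, seed=_child_seed(config.seed, 999_999))

    rows = []
    provenance: dict = {
        "schema_version": SCHEMA_VERSION,
        "scenario": config.scenario,
        "master_seed": config.seed,
        "n_per_group": config.n_per_group,
        "base_spec": base.to_dict(),
        "perturbation_params": {
            k: v for k, v in config.perturbation_params.items() if not isinstance(v, (list, tuple))
        },
        "child_seeds": {},
    }

    if optimization_report is not None:
        provenance["detection_optimization"] = optimization_report

    for counter, (group, index) in enumerate(
        (g, i) for g in ("control", "perturbed") for i in range(config.n_per_group)
    ):
        spec = _build_spec(config, base, group, index)
        provenance["child_seeds"][larva_ids[counter]] = spec.seed
        stack, truth = synthvnc.generate_stack(spec)

        row: dict = {"larva_id": blinded[counter]}
        if config.scenario == "ablation_puncta":
            row.update(_quantify_puncta(stack, truth, detection, provenance))
        elif config.scenario == "ablation_grasp":
            row.update(_quantify_grasp(stack, truth, config.n_grasp_rois, provenance))
        elif config.scenario == "lateralization_crossing":
            row.update(_quantify_crossing(stack, truth, spec, provenance))
        elif config.scenario == "dendrite_shift_linescan":
            row.update(_quantify_linescan(stack, truth, provenance))
        else:
            row.update(_quantify_timecourse(stack, truth, spec, provenance))
        rows.append(row)

    df = pd.DataFrame(rows)
    # unblind: join group labels back only now that quantification is done
    mapping = dict(zip(key["blinded"], key["original"]))
    df["group"] = [mapping[b].rsplit("_", 1)[0] for b in df["larva_id"]]

    metric = _SCENARIO_METRIC[config.scenario]
    report = None
    if config.n_per_group >= 3:
        a = df.loc[df["group"] == "control", metric].to_numpy()
        b = df.loc[df["group"] == "perturbed", metric].to_numpy()
        report = stats.compare_two_groups(a, b)
    else:
        logger.info("insufficient n for statistics (n_per_group=%d < 3)", config.n_per_group)
        provenance["statistics"] = "insufficient n"

    if isinstance(detection, puncta.DetectionParams):
        provenance["detection_params"] = dataclasses.asdict(detection)
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance["base_spec"], sort_keys=True).encode()
    ).hexdigest()[:16]
    try:
        from importlib.metadata import version

        provenance["package_version"] = version("vncquant")
    except Exception:  # pragma: no cover - not installed
        provenance["package_version"] = "unknown"

    result = ExperimentResult(summaries=df, report=report, provenance=provenance, blinding_key=key)
    if config.output_dir is not None:
        _write_bundle(result, Path(config.output_dir))
    return result


def _write_bundle(result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "per_larva.csv"
    with open(csv_path, "w") as fh:
        fh.write(f"# vncquant per-larva summary schema v{SCHEMA_VERSION}\n")
        result.summaries.to_csv(fh, index=False)
    result.blinding_key.to_csv(outdir / "blinding_key.csv", index=False)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, default=str)
    if result.report is not None:
        with open(outdir / "test_report.json", "w") as fh:
            json.dump(result.report.to_dict(), fh, indent=2)
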