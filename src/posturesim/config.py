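"""Configuration loading, validation and the master seeding policy.

One YAML file with sections ``model``, ``controller``, ``simulation``,
``perturbation`` and ``optimization``; omitted keys take the package
defaults, unknown keys are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import yaml

from .params import (ContactSphere, ControllerParams, ModelConfig,
                     MuscleGains, MuscleParams, NoiseModel, OptConfig,
                     PerturbationSpec, SegmentParams, SimConfig)


@dataclass
class ConfigBundle:
    model: ModelConfig = field(default_factory=ModelConfig)
    controller: ControllerParams = field(default_factory=ControllerParams)
    simulation: SimConfig = field(default_factory=SimConfig)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    optimization: OptConfig = field(default_factory=OptConfig)

    def validate(self) -> None:
        self.model.validate()
        self.controller.validate()
        self.simulation.validate()
        self.perturbation.validate()
        self.optimization.validate()


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Per-component seeds from one master seed (documented offsets via a
    SeedSequence spawn), so a single integer reproduces a whole run."""
    ss = np.random.SeedSequence(master_seed)
    noise, perturb, cma = ss.spawn(3)
    return {
        "master": int(master_seed),
        "noise": int(noise.generate_state(1)[0] % (2 ** 31)),
        "perturbation": int(perturb.generate_state(1)[0] % (2 ** 31)),
        "cma": int(cma.generate_state(1)[0] % (2 ** 31)),
    }


# ---------------------------------------------------------------------------
# dict <-> dataclasses
# ---------------------------------------------------------------------------

def _set_fields(obj, d: dict, path: str, skip=()):
    valid = {f.name for f in fields(obj)}
    for k, v in d.items():
        if k in skip:
            continue
        if k not in valid:
            raise ValueError(f"unknown config key {path}.{k}")
        current = getattr(obj, k)
        if isinstance(current, tuple) and isinstance(v, list):
            v = tuple(v)
        setattr(obj, k, v)


def _bundle_from_dict(data: dict) -> ConfigBundle:
    bundle = ConfigBundle()
    known = {"model", "controller", "simulation", "perturbation",
             "optimization"}
    for k in data:
        if k not in known:
            raise ValueError(f"unknown config section {k!r}")

    mdl = data.get("model", {}) or {}
    _set_fields(bundle.model, mdl, "model",
                skip=("segments", "muscles", "spheres", "joint_stop_deg"))
    if "joint_stop_deg" in mdl:
        bundle.model.joint_stop_deg = {
            j: tuple(v) for j, v in mdl["joint_stop_deg"].items()}
    for name, sd in (mdl.get("segments") or {}).items():
        if name not in bundle.model.segments:
            raise ValueError(f"unknown config key model.segments.{name}")
        _set_fields(bundle.model.segments[name], sd,
                    f"model.segments.{name}", skip=("name",))
    for name, md in (mdl.get("muscles") or {}).items():
        if name not in bundle.model.muscles:
            raise ValueError(f"unknown config key model.muscles.{name}")
        arms = md.pop("moment_arms", None)
        _set_fields(bundle.model.muscles[name], md,
                    f"model.muscles.{name}", skip=("name",))
        if arms is not None:
            bundle.model.muscles[name].moment_arms = {
                j: tuple(r) for j, r in arms.items()}
    if "spheres" in mdl and mdl["spheres"] is not None:
        spheres = []
        for sd in mdl["spheres"]:
            sp = ContactSphere(site=sd.pop("site"),
                               offset=tuple(sd.pop("offset")),
                               radius=sd.pop("radius"))
            _set_fields(sp, sd, "model.spheres", skip=("site", "offset",
                                                       "radius"))
            spheres.append(sp)
        bundle.model.spheres = spheres

    ctl = data.get("controller", {}) or {}
    for k in ctl:
        if k not in ("shared", "gains"):
            raise ValueError(f"unknown config key controller.{k}")
    for k, v in (ctl.get("shared") or {}).items():
        if k not in ("x_cop0", "phi0_deg", "x0"):
            raise ValueError(f"unknown config key controller.shared.{k}")
        setattr(bundle.controller, k, v)
    for name, gd in (ctl.get("gains") or {}).items():
        if name not in bundle.controller.gains:
            raise ValueError(f"unknown config key controller.gains.{name}")
        _set_fields(bundle.controller.gains[name], gd,
                    f"controller.gains.{name}")

    simd = dict(data.get("simulation", {}) or {})
    noised = simd.pop("noise", None)
    _set_fields(bundle.simulation, simd, "simulation", skip=("noise",))
    if noised:
        _set_fields(bundle.simulation.noise, noised, "simulation.noise")
    _set_fields(bundle.perturbation, data.get("perturbation", {}) or {},
                "perturbation")
    _set_fields(bundle.optimization, data.get("optimization", {}) or {},
                "optimization")
    bundle.validate()
    return bundle


def _bundle_to_dict(bundle: ConfigBundle) -> dict:
    mdl = dataclasses.asdict(bundle.model)
    mdl["segments"] = {k: {f: v for f, v in d.items() if f != "name"}
                       for k, d in mdl["segments"].items()}
    muscles = {}
    for k, d in mdl["muscles"].items():
        d = {f: v for f, v in d.items() if f != "name"}
        d["moment_arms"] = {j: list(r) for j, r in d["moment_arms"].items()}
        muscles[k] = d
    mdl["muscles"] = muscles
    mdl["foot_com"] = list(mdl["foot_com"])
    mdl["reference_pose_deg"] = list(mdl["reference_pose_deg"])
    mdl["spheres"] = [dict(s, offset=list(s["offset"]))
                      for s in mdl["spheres"]]
    mdl["joint_stop_deg"] = {j: list(v)
                             for j, v in mdl["joint_stop_deg"].items()}
    ctl = {
        "shared": {k: getattr(bundle.controller, k)
                   for k in ("x_cop0", "phi0_deg", "x0")},
        "gains": {m: dataclasses.asdict(g)
                  for m, g in bundle.controller.gains.items()},
    }
    simd = dataclasses.asdict(bundle.simulation)
    if simd.get("initial_posture_deg") is not None:
        simd["initial_posture_deg"] = list(simd["initial_posture_deg"])
    pert = dataclasses.asdict(bundle.perturbation)
    pert["amplitudes_cm"] = list(pert["amplitudes_cm"])
    pert["stage_durations_s"] = list(pert["stage_durations_s"])
    optd = dataclasses.asdict(bundle.optimization)
    optd["muscles"] = list(optd["muscles"])
    return {"model": mdl, "controller": ctl, "simulation": simd,
            "perturbation": pert, "optimization": optd}


def load_config(path) -> ConfigBundle:
    """Load and validate a YAML config; defaults fill whatever is omitted."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _bundle_from_dict(data)


def save_config(bundle: ConfigBundle, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_bundle_to_dict(bundle), fh, sort_keys=False)


def default_config() -> ConfigBundle:
    return ConfigBundle()
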