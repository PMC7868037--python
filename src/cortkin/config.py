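"""YAML configuration for the simulator and the analysis pipeline."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any

import yaml

from .compare import AnalysisConfig
from .model import Priors, SamplerSettings
from .simulate import KineticsParams, StudyDesign, TrialSpec


def _design_from_dict(d: dict[str, Any]) -> StudyDesign:
    kwargs: dict[str, Any] = {}
    if "trials" in d:
        kwargs["trials"] = tuple(
            TrialSpec(t["name"], t["treatment_tanks"], t["control_tanks"])
            for t in d["trials"]
        )
    for key in ("fish_per_tank", "min_resample_gap"):
        if key in d:
            kwargs[key] = d[key]
    for key in ("sampling_times", "first_window", "second_window"):
        if key in d:
            kwargs[key] = tuple(float(x) for x in d[key])
    return StudyDesign(**kwargs)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a study config; returns a dict with typed sections.

    Keys (all optional, defaults apply): ``seed`` (int), ``params``
    (KineticsParams fields), ``design`` (StudyDesign fields, trials as a
    list of mappings), ``sampler`` (SamplerSettings fields), ``priors``,
    ``analysis`` (grid_step, curve_grid_step, pairing_seed, ci_level).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = KineticsParams(**raw.get("params", {}))
    design = _design_from_dict(raw.get("design", {}))
    sampler = SamplerSettings(**raw.get("sampler", {}))
    priors = Priors(**raw.get("priors", {}))
    analysis = AnalysisConfig(
        settings=sampler, priors=priors, **raw.get("analysis", {})
    )
    return {
        "seed": int(raw.get("seed", 0)),
        "params": params,
        "design": design,
        "sampler": sampler,
        "priors": priors,
        "analysis": analysis,
    }


def dump_default_config(path: str | Path) -> None:
    """Write a fully populated config with all defaults spelled out."""
    design = StudyDesign()
    doc = {
        "seed": 0,
        "params": asdict(KineticsParams()),
        "design": {
            "trials": [
                {
                    "name": t.name,
                    "treatment_tanks": t.treatment_tanks,
                    "control_tanks": t.control_tanks,
                }
                for t in design.trials
            ],
            "fish_per_tank": design.fish_per_tank,
            "sampling_times": list(design.sampling_times),
            "first_window": list(design.first_window),
            "second_window": list(design.second_window),
            "min_resample_gap": design.min_resample_gap,
        },
        "sampler": asdict(SamplerSettings()),
        "priors": asdict(Priors()),
        "analysis": {
            "grid_step": 0.1,
            "curve_grid_step": 0.1,
            "pairing_seed": 0,
            "ci_level": 0.9,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
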