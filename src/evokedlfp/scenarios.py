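"""Bundled simulation scenarios.

A scenario bundles per-age-group :class:`~evokedlfp.simulate.SimConfig`
objects with the cohort layout (number of subjects, condition list).  The
built-ins mirror the study design this package analyses:

``p30-demo``
    Young-adult-like cortex: besides early evoked activity common to all
    conditions, C-fiber-attributed γ (gain 3), β (gain 2.5) and α (gain 2)
    bursts appear 500–1000 ms post-stimulus — but only under A+C-fiber
    stimulation ("AC"/"AC_preQX"), not under A-fiber-only stimulation or
    after C-fiber silencing ("AC_postQX").
``p14-demo``
    Immature-like cortex: the same early activity, no C-fiber bursts.
``null``
    No evoked content at all (no EP, no induced bursts): background noise
    plus spontaneous bursts only.  Used for calibration checks.

Scenarios can also be loaded from YAML files with the same structure as
:func:`scenario_to_dict` emits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .simulate import BurstSpec, SimConfig

__all__ = ["Scenario", "build_scenario", "scenario_from_dict", "scenario_to_dict", "BUILTIN_SCENARIOS"]

_C_CONDITIONS = frozenset({"AC", "AC_preQX"})
_ALL_CONDITIONS = frozenset({"A", "AC", "AC_preQX", "AC_postQX"})


@dataclass
class Scenario:
    name: str
    config_by_age: dict
    conditions: tuple
    n_subjects: int = 6


def _early_bursts() -> tuple[BurstSpec, ...]:
    # fast A-fiber-mediated evoked activity, common to every condition
    return (
        BurstSpec(2.0, 7.0, onset_latency_ms=10.0, duration_ms=400.0, amplitude_gain=2.5, conditions=_ALL_CONDITIONS),
        BurstSpec(8.0, 12.0, onset_latency_ms=30.0, duration_ms=300.0, amplitude_gain=2.0, conditions=_ALL_CONDITIONS),
    )


def _c_fiber_bursts() -> tuple[BurstSpec, ...]:
    # slow C-fiber-attributed induced activity (>500 ms post-stimulus)
    return (
        BurstSpec(30.0, 90.0, onset_latency_ms=500.0, duration_ms=500.0, amplitude_gain=3.0, conditions=_C_CONDITIONS),
        BurstSpec(15.0, 29.0, onset_latency_ms=500.0, duration_ms=500.0, amplitude_gain=2.5, conditions=_C_CONDITIONS),
        BurstSpec(8.0, 12.0, onset_latency_ms=500.0, duration_ms=500.0, amplitude_gain=2.0, conditions=_C_CONDITIONS),
    )


def _builtin(name: str, seed: int) -> Scenario:
    if name == "p30-demo":
        cfg = SimConfig(burst_specs=_early_bursts() + _c_fiber_bursts(), rng_seed=seed)
        return Scenario(name, {"P30": cfg}, ("A", "AC"), 6)
    if name == "p14-demo":
        cfg = SimConfig(burst_specs=_early_bursts(), rng_seed=seed)
        return Scenario(name, {"P14": cfg}, ("A", "AC"), 6)
    if name == "silencing-demo":
        cfg = SimConfig(burst_specs=_early_bursts() + _c_fiber_bursts(), rng_seed=seed)
        return Scenario(name, {"P30": cfg}, ("AC_preQX", "AC_postQX"), 6)
    if name == "null":
        cfg = SimConfig(burst_specs=(), ep_amplitude=0.0, rng_seed=seed)
        return Scenario(name, {"P30": cfg}, ("A", "AC"), 6)
    raise ValueError(f"unknown scenario {name!r}; built-ins: {sorted(BUILTIN_SCENARIOS)}")


BUILTIN_SCENARIOS = ("p30-demo", "p14-demo", "silencing-demo", "null")


def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "name": sc.name,
        "n_subjects": sc.n_subjects,
        "conditions": list(sc.conditions),
        "ages": {age: cfg.to_dict() for age, cfg in sc.config_by_age.items()},
    }


def scenario_from_dict(d: Mapping) -> Scenario:
    return Scenario(
        name=str(d.get("name", "custom")),
        config_by_age={age: SimConfig.from_dict(c) for age, c in d["ages"].items()},
        conditions=tuple(d.get("conditions", ("A", "AC"))),
        n_subjects=int(d.get("n_subjects", 6)),
    )


def build_scenario(
    name_or_path: str,
    seed: int = 0,
    sampling_rate: Optional[float] = None,
    n_subjects: Optional[int] = None,
    conditions: Optional[Sequence[str]] = None,
) -> Scenario:
    """Resolve a built-in scenario name or a YAML scenario file.

    ``sampling_rate`` overrides the scenario's acquisition rate (useful for
    fast runs; the canonical default is 16 kHz), ``seed`` reseeds every age
    config deterministically, and ``n_subjects``/``conditions`` override the
    cohort layout.
    """
    if name_or_path in BUILTIN_SCENARIOS:
        sc = _builtin(name_or_path, seed)
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ValueError(
                f"scenario {name_or_path!r} is neither a built-in "
                f"({sorted(BUILTIN_SCENARIOS)}) nor an existing file"
            )
        sc = scenario_from_dict(yaml.safe_load(path.read_text()))
        sc.config_by_age = {
            age: replace(cfg, rng_seed=(seed + i) & 0x7FFFFFFF)
            for i, (age, cfg) in enumerate(sc.config_by_age.items())
        }
    if sampling_rate is not None:
        sc.config_by_age = {
            age: replace(cfg, sampling_rate=float(sampling_rate))
            for age, cfg in sc.config_by_age.items()
        }
    if n_subjects is not None:
        sc.n_subjects = int(n_subjects)
    if conditions is not None:
        sc.conditions = tuple(conditions)
    return sc
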