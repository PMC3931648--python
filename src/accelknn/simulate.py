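"""Synthetic labelled tri-axial accelerometer recordings.

Each behaviour is a :class:`BehaviorTemplate`: a device posture (pitch and
roll relative to gravity) giving the static acceleration component, a set of
sinusoidal dynamic components emulating gait or body-motion oscillations, and
i.i.d. Gaussian per-axis sensor noise.  A sample at time t on a given axis is

    static_axis + sum over components on that axis of a * sin(2*pi*f*t + phi)
    + Normal(0, noise_sd)

Conventions (fixed so fixtures are reproducible):

* an upright device reads (0, 0, -1) g — gravity pulls the z axis down;
* ``pitch`` rotates about the x axis, then ``roll`` about the y axis, both in
  degrees, so the static vector always has magnitude 1 g;
* component frequencies must stay below the Nyquist limit (sample_rate / 2).

:func:`simulate_dataset` reproduces a two-occasion train/test design: two
independently seeded recordings with the identical behaviour schedule, each
concatenating one fixed-duration segment per behaviour.  A posture-offset
option perturbs the *test* templates only, emulating a device (e.g. collar)
that shifted position between the training and testing occasions, which
degrades classification by moving the static component.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from accelknn.io import Dataset, LabeledSample

__all__ = [
    "Component",
    "BehaviorTemplate",
    "SimSpec",
    "simulate_segment",
    "simulate_dataset",
    "default_ethogram",
    "read_sim_spec",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class Component:
    """One sinusoidal dynamic-acceleration component on a single axis."""

    axis: str
    frequency: float  # Hz
    amplitude: float  # g
    phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of x, y, z; got {self.axis!r}")
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")


@dataclass(frozen=True)
class BehaviorTemplate:
    """Simulator recipe for one behaviour: posture + dynamics + noise."""

    name: str
    pitch: float = 0.0  # degrees, rotation about x
    roll: float = 0.0  # degrees, rotation about y
    components: tuple[Component, ...] = ()
    noise_sd: float = 0.0  # g

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("behaviour name must be non-empty")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        object.__setattr__(self, "components", tuple(self.components))

    def static_vector(self) -> np.ndarray:
        """Unit gravity vector seen by the device in this posture, in g."""
        p = math.radians(self.pitch)
        r = math.radians(self.roll)
        g = np.array([0.0, 0.0, -1.0])
        rx = np.array(
            [[1, 0, 0], [0, math.cos(p), -math.sin(p)], [0, math.sin(p), math.cos(p)]]
        )
        ry = np.array(
            [[math.cos(r), 0, math.sin(r)], [0, 1, 0], [-math.sin(r), 0, math.cos(r)]]
        )
        return ry @ (rx @ g)


@dataclass(frozen=True)
class SimSpec:
    """A full simulated deployment: one segment per behaviour template."""

    templates: tuple[BehaviorTemplate, ...]
    seconds_per_behavior: float = 10.0
    sample_rate: float = 20.0
    seed: int = 0
    phase_jitter: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "templates", tuple(self.templates))
        if len(self.templates) == 0:
            raise ValueError("need at least one behaviour template")
        names = [t.name for t in self.templates]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate template names: {names}")
        if self.seconds_per_behavior <= 0:
            raise ValueError("seconds_per_behavior must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def samples_per_behavior(self) -> int:
        return round(self.seconds_per_behavior * self.sample_rate)


def _check_nyquist(template: BehaviorTemplate, sample_rate: float) -> None:
    for c in template.components:
        if c.frequency >= sample_rate / 2:
            raise ValueError(
                f"component frequency {c.frequency} Hz violates the Nyquist "
                f"limit {sample_rate / 2} Hz for template {template.name!r}"
            )


def simulate_segment(
    template: BehaviorTemplate,
    seconds: float,
    sample_rate: float,
    seed: int | Sequence[int] = 0,
    start_time: float = 0.0,
) -> Dataset:
    """Generate one fully labelled segment of a single behaviour.

    Deterministic given ``seed``.  Raises if any component frequency reaches
    the Nyquist limit ``sample_rate / 2``.
    """
    if seconds <= 0:
        raise ValueError("seconds must be positive")
    _check_nyquist(template, sample_rate)
    n = round(seconds * sample_rate)
    t = start_time + np.arange(n) / sample_rate
    signal = np.tile(template.static_vector(), (n, 1))
    for c in template.components:
        signal[:, _AXES[c.axis]] += c.amplitude * np.sin(
            2 * math.pi * c.frequency * (t - start_time) + c.phase
        )
    if template.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal += rng.normal(0.0, template.noise_sd, size=(n, 3))
    samples = tuple(
        LabeledSample(t=float(t[i]), x=float(signal[i, 0]), y=float(signal[i, 1]),
                      z=float(signal[i, 2]), label=template.name)
        for i in range(n)
    )
    return Dataset(samples=samples, sample_rate=sample_rate)


def _simulate_one(
    spec: SimSpec,
    seed: int,
    pitch_offset: float = 0.0,
    roll_offset: float = 0.0,
) -> Dataset:
    samples: list[LabeledSample] = []
    for i, tpl in enumerate(spec.templates):
        if pitch_offset or roll_offset:
            tpl = replace(tpl, pitch=tpl.pitch + pitch_offset, roll=tpl.roll + roll_offset)
        if spec.phase_jitter and tpl.components:
            jitter_rng = np.random.default_rng([seed, i, 7])
            tpl = replace(
                tpl,
                components=tuple(
                    replace(c, phase=c.phase + float(jitter_rng.uniform(0, 2 * math.pi)))
                    for c in tpl.components
                ),
            )
        seg = simulate_segment(
            tpl,
            seconds=spec.seconds_per_behavior,
            sample_rate=spec.sample_rate,
            seed=[seed, i],
            start_time=i * spec.seconds_per_behavior,
        )
        samples.extend(seg.samples)
    return Dataset(samples=tuple(samples), sample_rate=spec.sample_rate)


def simulate_dataset(
    spec: SimSpec,
    test_pitch_offset: float = 0.0,
    test_roll_offset: float = 0.0,
) -> tuple[Dataset, Dataset]:
    """Generate a (training, testing) pair for a two-occasion design.

    Both datasets follow the identical behaviour schedule but are seeded
    independently (``spec.seed`` and ``spec.seed + 1``); the test set keeps
    its true labels for later verification.  ``test_pitch_offset`` /
    ``test_roll_offset`` (degrees) perturb only the test-set postures,
    emulating a device that shifted between occasions.
    """
    training = _simulate_one(spec, seed=spec.seed)
    testing = _simulate_one(
        spec,
        seed=spec.seed + 1,
        pitch_offset=test_pitch_offset,
        roll_offset=test_roll_offset,
    )
    return training, testing


def default_ethogram(
    seed: int = 0,
    sample_rate: float = 20.0,
    seconds_per_behavior: float = 10.0,
    noise_sd: float = 0.05,
) -> SimSpec:
    """A packaged five-behaviour human-like ethogram.

    Postures separate the stationary behaviours (Stand upright, Lying flat,
    Crawl inclined); the gaits (Walk, Run) share a forward-lean axis but
    differ in lean, stride frequency and amplitude.  Dynamic components sit
    on the x axis so the postural (y, z) separation stays informative for
    every sample.  Template numbers are fixture choices — plausible
    human-scale values — not measurements.
    """
    tpl = (
        BehaviorTemplate("Stand", pitch=0.0, roll=0.0, noise_sd=noise_sd),
        BehaviorTemplate("Lying", pitch=90.0, roll=0.0, noise_sd=noise_sd),
        BehaviorTemplate(
            "Walk",
            pitch=10.0,
            components=(Component("x", frequency=2.0, amplitude=0.30),),
            noise_sd=noise_sd,
        ),
        BehaviorTemplate(
            "Run",
            pitch=25.0,
            components=(Component("x", frequency=3.5, amplitude=0.80),),
            noise_sd=noise_sd,
        ),
        BehaviorTemplate(
            "Crawl",
            pitch=60.0,
            components=(Component("x", frequency=1.0, amplitude=0.15),),
            noise_sd=noise_sd,
        ),
    )
    return SimSpec(
        templates=tpl,
        seconds_per_behavior=seconds_per_behavior,
        sample_rate=sample_rate,
        seed=seed,
        phase_jitter=True,
    )


def read_sim_spec(path: str | Path) -> SimSpec:
    """Load a :class:`SimSpec` from a JSON config file.

    Schema::

        {
          "sample_rate": 20, "seconds_per_behavior": 10, "seed": 0,
          "phase_jitter": true,
          "templates": [
            {"name": "Walk", "pitch": 10, "roll": 0, "noise_sd": 0.05,
             "components": [{"axis": "x", "frequency": 2,
                             "amplitude": 0.3, "phase": 0}]}
          ]
        }
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        templates = tuple(
            BehaviorTemplate(
                name=t["name"],
                pitch=float(t.get("pitch", 0.0)),
                roll=float(t.get("roll", 0.0)),
                components=tuple(
                    Component(
                        axis=c["axis"],
                        frequency=float(c["frequency"]),
                        amplitude=float(c["amplitude"]),
                        phase=float(c.get("phase", 0.0)),
                    )
                    for c in t.get("components", [])
                ),
                noise_sd=float(t.get("noise_sd", 0.0)),
            )
            for t in raw["templates"]
        )
        return SimSpec(
            templates=templates,
            seconds_per_behavior=float(raw.get("seconds_per_behavior", 10.0)),
            sample_rate=float(raw.get("sample_rate", 20.0)),
            seed=int(raw.get("seed", 0)),
            phase_jitter=bool(raw.get("phase_jitter", False)),
        )
    except KeyError as e:
        raise ValueError(f"simulator spec {path} missing required key {e}") from e
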