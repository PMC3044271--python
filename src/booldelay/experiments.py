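"""Experiment specifications: stimulus protocol + knockouts + observations.

An :class:`ExperimentSpec` pairs the in-silico protocol (what is applied and
what is deleted) with optional binarized observations used as training data.
The YAML form is::

    stimuli:
      - {node: TNF, start: 0, end: 45}
    knockouts: [A20]
    horizon: 720

The module also bundles the in-silico experiments of the NF-kB model: acute
TNF / IL-1 pulses, persistent LPS and chronic TNF stimulation, each in wild
type and under A20 or IkBa deletion.  Persistent LPS stands in for the LPS
treatments: endotoxin engages TLR4 lastingly, and the model's LPS edges carry
activation delays (87 and 125 minutes) longer than a 45-minute pulse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .binarize import BinaryProfile
from .simulate import StimulusProtocol

__all__ = [
    "ExperimentSpec",
    "load_experiment",
    "save_experiment",
    "bundled_experiments",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """One stimulation/knockout experiment, optionally with observed profiles."""

    name: str
    protocol: StimulusProtocol
    knockouts: frozenset[str] = frozenset()
    observations: tuple[BinaryProfile, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        object.__setattr__(self, "observations", tuple(self.observations))
        for obs in self.observations:
            if len(obs.minutes) and obs.minutes.max() > self.protocol.horizon:
                raise ValueError(
                    f"experiment {self.name!r}: observation grid for "
                    f"{obs.node!r} exceeds the horizon"
                )

    def with_observations(self, observations) -> "ExperimentSpec":
        return ExperimentSpec(
            self.name, self.protocol, self.knockouts, tuple(observations)
        )


def load_experiment(path: str | Path, name: str | None = None) -> ExperimentSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    horizon = int(data.get("horizon", 720))
    events = [
        (str(s["node"]), int(s["start"]), int(s["end"]), int(s.get("level", 1)))
        for s in data.get("stimuli", [])
    ]
    return ExperimentSpec(
        name=name or data.get("name", Path(path).stem),
        protocol=StimulusProtocol(events, horizon),
        knockouts=frozenset(data.get("knockouts", [])),
    )


def save_experiment(spec: ExperimentSpec, path: str | Path) -> None:
    data = {
        "name": spec.name,
        "stimuli": [
            {"node": e.node, "start": e.start, "end": e.end}
            for e in spec.protocol.events
        ],
        "knockouts": sorted(spec.knockouts),
        "horizon": spec.protocol.horizon,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def bundled_experiments(horizon: int = 720) -> dict[str, ExperimentSpec]:
    """The in-silico experiments of the bundled NF-kB model, by panel name."""

    def spec(name, events, knockouts=()):
        return ExperimentSpec(
            name, StimulusProtocol(events, horizon), frozenset(knockouts)
        )

    return {
        "fig4a-tnf-wt": spec("fig4a-tnf-wt", [("TNF", 0, 45)]),
        "fig4a-tnf-a20ko": spec("fig4a-tnf-a20ko", [("TNF", 0, 45)], {"A20"}),
        "fig4b-lps-wt": spec("fig4b-lps-wt", [("LPS", 0, horizon)]),
        "fig4b-lps-a20ko": spec("fig4b-lps-a20ko", [("LPS", 0, horizon)], {"A20"}),
        "fig4c-il1-wt": spec("fig4c-il1-wt", [("IL1", 0, 15)]),
        "fig4c-il1-ikbako": spec("fig4c-il1-ikbako", [("IL1", 0, 15)], {"IkBa"}),
        "fig5-tnf-ikbako": spec("fig5-tnf-ikbako", [("TNF", 0, 45)], {"IkBa"}),
        "fig5-lps-ikbako": spec("fig5-lps-ikbako", [("LPS", 0, 45)], {"IkBa"}),
        "fig6-chronic-tnf": spec("fig6-chronic-tnf", [("TNF", 0, horizon)]),
    }
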