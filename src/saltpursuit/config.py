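"""Run configuration: YAML files over task defaults.

The schema mirrors the parameter blocks of the task definition (task /
body / evolution), so an empty file resolves to the full default set
(T=600, T_T=100, dt=0.05, d=29, lambda=2, phi=0.01, gamma=3, delta=2,
eps=pi/6, f=0.9, o=2, s_P=0.3, s_I=20, population 400, 1000 generations).
The four study conditions are named by a two-letter label: signal
reliability (R / U) times movement dependence of perception (I / D).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .body import BodyParams
from .evolution import EvolutionConfig
from .task import TaskConfig

__all__ = ["RunConfig", "load_config", "condition_flags", "CONDITIONS"]

CONDITIONS = ("RI", "UI", "RD", "UD")


def condition_flags(label: str) -> tuple[bool, bool]:
    """(signal_reliable, movement_dependent) for a condition label."""
    label = label.upper()
    if label not in CONDITIONS:
        raise ValueError(f"unknown condition {label!r}; expected one of "
                         f"{CONDITIONS}")
    return label[0] == "R", label[1] == "D"


@dataclass
class RunConfig:
    condition: str = "RI"
    master_seed: int = 1
    output_dir: str = "out"
    task: TaskConfig = field(default_factory=TaskConfig)
    body: BodyParams = field(default_factory=BodyParams)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)

    def __post_init__(self) -> None:
        reliable, dependent = condition_flags(self.condition)
        self.condition = self.condition.upper()
        if self.task.signal_reliable != reliable \
                or self.body.movement_dependent != dependent:
            raise ValueError(
                f"condition {self.condition} inconsistent with "
                f"signal_reliable={self.task.signal_reliable}, "
                f"movement_dependent={self.body.movement_dependent}")

    @classmethod
    def for_condition(cls, label: str, master_seed: int = 1,
                      **overrides) -> "RunConfig":
        reliable, dependent = condition_flags(label)
        task = overrides.pop("task", TaskConfig(signal_reliable=reliable))
        body = overrides.pop("body", BodyParams(movement_dependent=dependent))
        return cls(condition=label.upper(), master_seed=master_seed,
                   task=task, body=body, **overrides)


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid [{name}] configuration: {err}") from err


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, merging the file over the defaults.

    An empty (or absent) file yields the full default parameter set.
    Unknown keys and out-of-range values are rejected with a descriptive
    error.  The ``condition`` label sets the signal-reliability and
    movement-dependence flags; stating those flags inconsistently in the
    task/body sections is an error.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must be a YAML mapping")
            doc = loaded

    top_known = {"condition", "master_seed", "output_dir", "task", "body",
                 "evolution"}
    unknown = set(doc) - top_known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")

    condition = str(doc.get("condition", "RI")).upper()
    reliable, dependent = condition_flags(condition)
    task_sec = dict(doc.get("task") or {})
    body_sec = dict(doc.get("body") or {})
    task_sec.setdefault("signal_reliable", reliable)
    body_sec.setdefault("movement_dependent", dependent)
    task = _build(TaskConfig, task_sec, "task")
    body = _build(BodyParams, body_sec, "body")
    evolution = _build(EvolutionConfig, dict(doc.get("evolution") or {}),
                       "evolution")
    return RunConfig(condition=condition,
                     master_seed=int(doc.get("master_seed", 1)),
                     output_dir=str(doc.get("output_dir", "out")),
                     task=task, body=body, evolution=evolution)
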