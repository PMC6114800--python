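"""JSON serialization for machines and sensors.

Schemas (nested lists are indexed ``[symbol][dest][src]``):

* machine: ``{"num_states", "alphabet_size", "transition", "seed"}``
* sensor:  ``{"num_states", "alphabet_size", "transition", "support_size",
  "provenance"}``

Round-trips are bit-exact: floats pass through Python's repr, which is
shortest-exact for IEEE doubles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .machines import EpsilonMachine
from .sensors import Sensor

__all__ = [
    "machine_to_dict", "machine_from_dict", "save_machine", "load_machine",
    "sensor_to_dict", "sensor_from_dict", "save_sensor", "load_sensor",
]


def machine_to_dict(machine: EpsilonMachine) -> dict:
    return {
        "num_states": machine.num_states,
        "alphabet_size": machine.alphabet_size,
        "transition": machine.transition.tolist(),
        "seed": machine.seed,
    }


def machine_from_dict(d: dict) -> EpsilonMachine:
    return EpsilonMachine(
        num_states=int(d["num_states"]),
        alphabet_size=int(d["alphabet_size"]),
        transition=np.array(d["transition"], dtype=float),
        seed=d.get("seed"),
    )


def save_machine(machine: EpsilonMachine, path) -> None:
    Path(path).write_text(json.dumps(machine_to_dict(machine)))


def load_machine(path) -> EpsilonMachine:
    return machine_from_dict(json.loads(Path(path).read_text()))


def sensor_to_dict(sensor: Sensor) -> dict:
    return {
        "num_states": sensor.num_states,
        "alphabet_size": sensor.alphabet_size,
        "transition": sensor.transition.tolist(),
        "support_size": sensor.support_size,
        "provenance": sensor.provenance,
    }


def sensor_from_dict(d: dict) -> Sensor:
    return Sensor(
        num_states=int(d["num_states"]),
        alphabet_size=int(d["alphabet_size"]),
        transition=np.array(d["transition"], dtype=float),
        support_size=d.get("support_size", "dense"),
        provenance=d.get("provenance", {}),
    )


def save_sensor(sensor: Sensor, path) -> None:
    Path(path).write_text(json.dumps(sensor_to_dict(sensor)))


def load_sensor(path) -> Sensor:
    return sensor_from_dict(json.loads(Path(path).read_text()))
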