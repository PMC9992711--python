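"""Named condition presets loaded from the bundled YAML registry.

Each preset couples a :class:`~gqfret.kinetics.ConditionSpec`, a
reciprocally calibrated :class:`~gqfret.kinetics.RateSet`, a FRET-pair
coefficient table, a stimulus protocol and a target signal-to-noise ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ConfigurationError
from .kinetics import (ConditionSpec, RateSet, StimulusProtocol,
                       YM_UNBLOCKED_FRACTION, standard_protocol)
from .photometry import FretPairSpec, OpticsSpec

__all__ = ["Preset", "get_preset", "list_presets", "get_pair", "load_registry"]


@dataclass(frozen=True)
class Preset:
    name: str
    description: str
    condition: ConditionSpec
    rates: RateSet
    pair: FretPairSpec
    baseline_s: float
    agonist_s: float
    washout_s: float
    hz: float
    ym_windows: tuple
    snr_target: float
    fit_on: str   # "single" | "two"
    fit_off: str
    ym_unblocked_fraction: float = YM_UNBLOCKED_FRACTION
    optics: OpticsSpec = field(default_factory=OpticsSpec)

    def make_protocol(self, hz: float | None = None) -> StimulusProtocol:
        return standard_protocol(
            baseline_s=self.baseline_s, agonist_s=self.agonist_s,
            washout_s=self.washout_s, conc=self.condition.concentration,
            hz=hz if hz is not None else self.hz,
            ym_windows=self.ym_windows)


def _load_yaml() -> dict:
    path = resources.files("gqfret").joinpath("data/presets.yaml")
    return yaml.safe_load(path.read_text())


_REGISTRY_CACHE: dict = {}


def load_registry() -> dict:
    """Parse the bundled registry into Preset objects (cached)."""
    if _REGISTRY_CACHE:
        return _REGISTRY_CACHE
    doc = _load_yaml()
    pairs = {
        name: FretPairSpec(name=name, epsilon=dict(spec["epsilon"]),
                           direction=spec["direction"])
        for name, spec in doc["pairs"].items()
    }
    for name, spec in doc["presets"].items():
        taus = spec.get("taus", {})
        kw = {}
        if "tau1_on" in taus:
            kw["k_couple"] = 1.0 / taus["tau1_on"]
        if "tau2_on" in taus:
            kw["k_exch"] = 1.0 / taus["tau2_on"]
        if "tau1_off" in taus:
            kw["k_bg_off"] = 1.0 / taus["tau1_off"]
        if "tau2_off" in taus:
            kw["k_hyd"] = 1.0 / taus["tau2_off"]
        kd = spec.get("ligand_kd_uM")
        rates = RateSet(**kw)
        if kd:
            rates = rates.replace(k_L_on=rates.k_L_off / kd)
        rates = rates.replace(**spec.get("rates", {}))
        proto = spec["protocol"]
        condition = ConditionSpec(
            ym_schedule=tuple(tuple(w) for w in proto.get("ym_windows", ())),
            **spec.get("condition", {}))
        pair_name = spec["pair"]
        if pair_name not in pairs:
            raise ConfigurationError(f"preset {name!r}: unknown pair {pair_name!r}")
        fit = spec.get("fit", {})
        _REGISTRY_CACHE[name] = Preset(
            name=name, description=spec.get("description", ""),
            condition=condition, rates=rates, pair=pairs[pair_name],
            baseline_s=float(proto["baseline_s"]),
            agonist_s=float(proto["agonist_s"]),
            washout_s=float(proto["washout_s"]), hz=float(proto.get("hz", 10)),
            ym_windows=tuple(tuple(w) for w in proto.get("ym_windows", ())),
            snr_target=float(spec.get("snr_target", 0.0)),
            fit_on=fit.get("activation", "single"),
            fit_off=fit.get("deactivation", "single"),
            ym_unblocked_fraction=float(
                spec.get("ym_unblocked_fraction", YM_UNBLOCKED_FRACTION)))
    _REGISTRY_CACHE["_pairs"] = pairs
    return _REGISTRY_CACHE


def get_preset(name: str) -> Preset:
    reg = load_registry()
    if name not in reg or name == "_pairs":
        known = sorted(k for k in reg if k != "_pairs")
        raise ConfigurationError(f"unknown preset {name!r}; known: {known}")
    return reg[name]


def get_pair(name: str) -> FretPairSpec:
    pairs = load_registry()["_pairs"]
    if name not in pairs:
        raise ConfigurationError(f"unknown FRET pair {name!r}")
    return pairs[name]


def list_presets() -> list:
    return sorted(k for k in load_registry() if k != "_pairs")
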