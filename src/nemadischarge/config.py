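"""Configuration loading and result serialization for the CLI.

Configs are flat YAML with one section per parameter group (``transport``,
``geometry``, ``shape``, ``restraint``, ``inertia``, ``discharge``, ``qcm``).
Unknown keys are rejected; every default that influences a result is echoed
into the output bundle.  Scaled units are the default working mode (lengths
in stylet lengths, pressures in units of Y); supplying SI values in the
transport/geometry sections simply makes the electrostatic outputs SI.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from . import electrostatics as es
from . import mechanics as mech
from .discharge import DischargeParams

__all__ = ["RunConfig", "load_config", "config_echo", "ResultBundle", "round_sig"]

SCHEMA_VERSION = 1

_SECTION_KEYS = {
    "transport": {"n0", "mu", "D", "eps", "e"},
    "geometry": {"R"},
    "shape": {"a", "l", "d"},
    "restraint": {"Y", "alpha", "beta0", "r0"},
    "inertia": {"m", "Rx"},
    "discharge": {
        "p_operculum",
        "n_steps",
        "chi_max",
        "eversion_speed",
        "tubule_length",
    },
    "electrostatics": {"y_surface", "n_grid"},
    "qcm": {"input", "dnu_tol", "temp_tol", "skip_initial"},
}
_TOP_KEYS = set(_SECTION_KEYS) | {"schema_version"}


class ConfigError(ValueError):
    """A config file violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults applied."""

    transport: Optional[es.IonTransport]
    geom: Optional[es.CapsuleGeometry]
    shape: mech.StyletShape
    restraint: mech.ElasticRestraint
    inertia: mech.StyletInertia
    discharge: dict
    electrostatics: dict
    qcm: dict
    schema_version: int = SCHEMA_VERSION
    defaults_applied: dict = field(default_factory=dict)

    def discharge_params(self) -> DischargeParams:
        if self.transport is None or self.geom is None:
            raise ConfigError("transport and geometry sections are required to simulate")
        import numpy as np

        n_steps = int(self.discharge["n_steps"])
        chi_max = float(self.discharge["chi_max"])
        return DischargeParams(
            transport=self.transport,
            geom=self.geom,
            shape=self.shape,
            restraint=self.restraint,
            inertia=self.inertia,
            p_operculum=self.discharge["p_operculum"],
            efflux_schedule=np.linspace(0.0, chi_max, n_steps + 1),
            eversion_speed=float(self.discharge["eversion_speed"]),
            tubule_length=float(self.discharge["tubule_length"]),
        )


def _check_keys(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _SECTION_KEYS[section]
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run config, applying documented defaults.

    Raises :class:`ConfigError` listing offending keys on schema violations;
    physical-invariant violations surface as the domain errors of the
    underlying types.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"{path}: unsupported schema_version {version}")

    defaults: dict = {}

    def section(name: str) -> dict:
        sec = raw.get(name) or {}
        if not isinstance(sec, dict):
            raise ConfigError(f"{path}: section {name!r} must be a mapping")
        _check_keys(name, sec)
        return sec

    tr = section("transport")
    transport = es.IonTransport(**tr) if tr else None
    ge = section("geometry")
    geom = es.CapsuleGeometry(**ge) if ge else None

    sh = section("shape")
    shape = mech.StyletShape(
        a=float(sh.get("a", 0.2)), l=float(sh.get("l", 1.0)), d=float(sh.get("d", 0.01))
    )
    for k, v in (("a", 0.2), ("l", 1.0), ("d", 0.01)):
        if k not in sh:
            defaults[f"shape.{k}"] = v

    re_ = section("restraint")
    restraint = mech.ElasticRestraint(
        Y=float(re_.get("Y", 1.0)),
        alpha=float(re_.get("alpha", 1.0)),
        beta0=float(re_.get("beta0", 0.005)),
        r0=float(re_["r0"]) if "r0" in re_ else None,
    )
    for k, v in (("Y", 1.0), ("alpha", 1.0), ("beta0", 0.005)):
        if k not in re_:
            defaults[f"restraint.{k}"] = v
    if "r0" not in re_:
        defaults["restraint.r0"] = restraint.r0  # defaulted to beta0

    ine = section("inertia")
    apex = mech.stylet_apex(shape)
    rx = float(ine.get("Rx", apex.beta_x))
    inertia = mech.StyletInertia(m=float(ine.get("m", 1.0)), Rx=rx)
    if "m" not in ine:
        defaults["inertia.m"] = 1.0
    if "Rx" not in ine:
        defaults["inertia.Rx"] = apex.beta_x  # defaulted to the apex radius

    di = section("discharge")
    discharge = {
        "p_operculum": di.get("p_operculum"),  # None -> half the fold threshold
        "n_steps": int(di.get("n_steps", 100)),
        "chi_max": float(di.get("chi_max", 1.0)),
        "eversion_speed": float(di.get("eversion_speed", 1.0)),
        "tubule_length": float(di.get("tubule_length", 1.0)),
    }
    for k, v in (
        ("p_operculum", "0.5 * numeric threshold"),
        ("n_steps", 100),
        ("chi_max", 1.0),
        ("eversion_speed", 1.0),
        ("tubule_length", 1.0),
    ):
        if k not in di:
            defaults[f"discharge.{k}"] = v

    el = section("electrostatics")
    electro = {
        "y_surface": float(el.get("y_surface", -0.99)),
        "n_grid": int(el.get("n_grid", 512)),
    }
    for k, v in (("y_surface", -0.99), ("n_grid", 512)):
        if k not in el:
            defaults[f"electrostatics.{k}"] = v

    qc = section("qcm")
    qcm_opts = {
        "input": qc.get("input"),
        "dnu_tol": float(qc.get("dnu_tol", 100.0)),
        "temp_tol": float(qc.get("temp_tol", 1.0)),
        "skip_initial": bool(qc.get("skip_initial", True)),
    }
    for k, v in (("dnu_tol", 100.0), ("temp_tol", 1.0), ("skip_initial", True)):
        if k not in qc:
            defaults[f"qcm.{k}"] = v

    return RunConfig(
        transport=transport,
        geom=geom,
        shape=shape,
        restraint=restraint,
        inertia=inertia,
        discharge=discharge,
        electrostatics=electro,
        qcm=qcm_opts,
        schema_version=version,
        defaults_applied=defaults,
    )


def config_echo(cfg: RunConfig) -> dict:
    """Complete, JSON-serializable echo of the effective configuration."""
    echo = {
        "schema_version": cfg.schema_version,
        "shape": {"a": cfg.shape.a, "l": cfg.shape.l, "d": cfg.shape.d},
        "restraint": {
            "Y": cfg.restraint.Y,
            "alpha": cfg.restraint.alpha,
            "beta0": cfg.restraint.beta0,
            "r0": cfg.restraint.r0,
        },
        "inertia": {"m": cfg.inertia.m, "Rx": cfg.inertia.Rx},
        "discharge": dict(cfg.discharge),
        "electrostatics": dict(cfg.electrostatics),
        "qcm": dict(cfg.qcm),
        "defaults_applied": {k: (v if isinstance(v, (int, float, bool, str)) else str(v))
                             for k, v in cfg.defaults_applied.items()},
    }
    if cfg.transport is not None:
        t = cfg.transport
        echo["transport"] = {"n0": t.n0, "mu": t.mu, "D": t.D, "eps": t.eps, "e": t.e}
    if cfg.geom is not None:
        echo["geometry"] = {"R": cfg.geom.R, "volume": cfg.geom.volume}
    return echo


def round_sig(x, digits: int = 12):
    """Round floats (recursively through dict/list) to ``digits`` significant
    figures so serialized payloads are byte-stable across platforms."""
    if isinstance(x, dict):
        return {k: round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [round_sig(v, digits) for v in x]
    if isinstance(x, bool) or x is None:
        return x
    if isinstance(x, float):
        if x == 0 or not math.isfinite(x):
            return x
        return float(f"{x:.{digits}g}")
    return x


@dataclass(frozen=True)
class ResultBundle:
    """Deterministic result payload plus provenance metadata."""

    subcommand: str
    config: dict
    outputs: dict
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "tool": "nemadischarge",
            "version": self.version,
            "subcommand": self.subcommand,
            "timestamp": self.timestamp,
            "config": round_sig(self.config),
            "outputs": round_sig(self.outputs),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)
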