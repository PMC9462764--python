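"""Run configuration: strict YAML round-tripping onto the model parameter
dataclasses. Keys mirror the published parameter-table names (k, gamma,
alpha_0, k_phi, eta, dt, ...); unknown keys are rejected."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from ..coupling import CouplingConfig, ModelParams
from ..desquamation import DesquamationParams
from ..kinetics import ChemParams, PHModel, RateConstants, ScalingSpec, scale_rates
from ..mechanics import Domain, MechanicsParams, ProliferationParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_MECH_KEYS = {
    "k": "k_rep",
    "gamma": "gamma",
    "alpha_0": "alpha_0",
    "F_max": "F_max",
    "k_phi": "k_phi",
    "eta": "eta",
    "dt": "dt",
    "R_0": "R_0",
    "neighbour_cutoff": "neighbour_cutoff",
}

_SECTIONS = {
    "mechanics", "domain", "desquamation", "proliferation", "chemistry",
    "rates", "ph", "scaling", "coupling", "scenario", "seed", "outdir",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, serialisable bundle of every run parameter."""

    model: ModelParams = field(default_factory=ModelParams)
    scaled: bool = True  # whether model.rates are on the tissue clock
    outdir: str = "results"

    def to_dict(self) -> dict:
        mp = self.model
        mech = mp.mechanics
        return {
            "mechanics": {k: getattr(mech, attr) for k, attr in _MECH_KEYS.items()},
            "domain": {"Lx": mp.domain.Lx, "Ly": mp.domain.Ly},
            "desquamation": asdict(mp.desquamation),
            "proliferation": asdict(mp.prolif),
            "chemistry": {"s_0": mp.chem.s_0, "e_T": mp.chem.e_T, "i_T": mp.chem.i_T},
            "rates": {  # single-cell clock values; rescaled on load when scaled=true
                "k_plus1": mp.rates.k_plus1, "k_minus1": mp.rates.k_minus1,
                "k_2": mp.rates.k_2, "K_M": mp.rates.K_M,
                "a3": mp.rates.a3, "b3": mp.rates.b3,
                "A3": mp.rates.A3, "B3": mp.rates.B3,
            },
            "ph": asdict(mp.ph_model),
            "scaling": {"scaled": self.scaled},
            "coupling": asdict(mp.coupling),
            "scenario": {
                "inhibitor_fraction": mp.inhibitor_fraction,
                "normal_stem_fraction": mp.normal_stem_fraction,
            },
            "seed": mp.coupling.seed,
            "outdir": self.outdir,
        }


def _build(data: dict) -> RunConfig:
    unknown = set(data) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def section(name, cls, keymap=None, **extra):
        raw = dict(data.get(name, {}) or {})
        if keymap:
            bad = set(raw) - set(keymap)
            if bad:
                raise ValueError(f"unknown keys in '{name}': {sorted(bad)}")
            raw = {keymap[k]: v for k, v in raw.items()}
        try:
            return cls(**raw, **extra)
        except TypeError as exc:
            raise ValueError(f"invalid keys in '{name}': {exc}") from exc

    mech = section("mechanics", MechanicsParams, keymap=_MECH_KEYS)
    domain = section("domain", Domain)
    desq = section("desquamation", DesquamationParams)
    prolif = section("proliferation", ProliferationParams)
    chem = section("chemistry", ChemParams)
    rates = section("rates", RateConstants)
    ph = section("ph", PHModel)
    coupling_raw = dict(data.get("coupling", {}) or {})
    if "seed" in data:
        coupling_raw["seed"] = data["seed"]
    try:
        coupling = CouplingConfig(**coupling_raw)
    except TypeError as exc:
        raise ValueError(f"invalid keys in 'coupling': {exc}") from exc
    scaled = bool((data.get("scaling") or {}).get("scaled", True))
    if scaled:
        rates = scale_rates(rates, ScalingSpec())
    scenario = dict(data.get("scenario", {}) or {})
    bad = set(scenario) - {"inhibitor_fraction", "normal_stem_fraction"}
    if bad:
        raise ValueError(f"unknown keys in 'scenario': {sorted(bad)}")
    mp = ModelParams(
        domain=domain, mechanics=mech, desquamation=desq, prolif=prolif,
        chem=chem, rates=rates, ph_model=ph, coupling=coupling,
        inhibitor_fraction=float(scenario.get("inhibitor_fraction", 1.0)),
        normal_stem_fraction=scenario.get("normal_stem_fraction"),
    )
    desq.validate_domain(domain)
    domain.validate(mech.neighbour_cutoff)
    return RunConfig(model=mp, scaled=scaled, outdir=str(data.get("outdir", "results")))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    try:
        return _build(data)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_config(cfg: RunConfig, path) -> None:
    data = cfg.to_dict()
    if cfg.scaled:
        # persist single-cell clock rates so load -> save round-trips
        lam = ScalingSpec().lam
        for key in ("k_plus1", "k_minus1", "k_2", "a3", "b3", "A3"):
            data["rates"][key] = data["rates"][key] / lam
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Short content hash of the full configuration."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
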