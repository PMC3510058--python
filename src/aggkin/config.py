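"""Run configuration: defaults, YAML round-trip, validation."""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field

import yaml

from .sheet_clustering import Criteria
from .structure_metrics import BetaWindows


class ConfigError(ValueError):
    pass


@dataclass
class CriteriaBlock:
    hb_energy_cutoff: float = -0.5        # kcal/mol
    min_hbonds: int = 2
    min_beta_residues: int = 3
    contact_cutoff: float = 6.5           # Angstrom
    phi_windows: list = field(default_factory=lambda: [[-180.0, 0.0], [150.0, 180.0]])
    psi_windows: list = field(default_factory=lambda: [[-180.0, -150.0], [0.0, 180.0]])

    def to_criteria(self) -> Criteria:
        return Criteria(
            hb_energy_cutoff=self.hb_energy_cutoff,
            min_hbonds=self.min_hbonds,
            min_beta_residues=self.min_beta_residues,
            contact_cutoff=self.contact_cutoff,
            windows=BetaWindows(phi=tuple(tuple(w) for w in self.phi_windows),
                                psi=tuple(tuple(w) for w in self.psi_windows)),
        )


@dataclass
class KineticsBlock:
    bin_width: float = 5.0                # ps (event-total binning)
    n_star: int | None = None             # None -> use thermo critical nucleus
    hold_time: float = 500.0              # ps
    dissolve_threshold: int = 2
    align_threshold: float = -80.0        # kcal/mol
    align_window: float = 5000.0          # ps
    max_curve_size: int = 9


@dataclass
class ThermoBlock:
    temperature: float = 280.0            # K
    weighting: str = "per_aggregate"
    tie_tolerance: float = 0.5            # kT


@dataclass
class RunConfig:
    topology: str | None = None
    trajectory: str | None = None
    energies: str | None = None           # CSV: time, E_total, E_hbond, E_hydrophobic
    out_dir: str = "aggkin_out"
    seed: int = 0
    save_interval: float = 7.5            # ps
    criteria: CriteriaBlock = field(default_factory=CriteriaBlock)
    kinetics: KineticsBlock = field(default_factory=KineticsBlock)
    thermo: ThermoBlock = field(default_factory=ThermoBlock)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(data)

    @staticmethod
    def from_dict(data: dict) -> "RunConfig":
        def build(cls, d):
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(d) - names
            if unknown:
                raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
            return cls(**d)

        data = dict(data)
        sub = {}
        for key, cls in (("criteria", CriteriaBlock), ("kinetics", KineticsBlock),
                         ("thermo", ThermoBlock)):
            if key in data:
                sub[key] = build(cls, data.pop(key) or {})
        cfg = build(RunConfig, data)
        for key, value in sub.items():
            setattr(cfg, key, value)
        if cfg.thermo.weighting not in ("per_aggregate", "per_peptide"):
            raise ConfigError(f"invalid weighting {cfg.thermo.weighting!r}")
        if cfg.kinetics.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        return cfg
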