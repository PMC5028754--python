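"""Plain-text (YAML) pipeline configuration.

The default configuration reproduces the screen's standard settings:
confidence thresholds 80% (test) / 10% (controls), a tryptic library
digest, and the printed full-length titration protocol (30 x 9 uL of
1.42 mM ligand into 1.43 mL of 97 uM protein at 298.15 K).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .itc import InjectionProtocol, OneSiteParams, TwoSiteParams
from .synthetic_data import TRYPSIN, DigestRule, NoiseSettings, ProteaseSpec


@dataclass
class TitrationConfig:
    """One simulated titration: protocol + generating model."""

    name: str = "full_length"
    model: str = "one_site"  # or "two_sites"
    n_injections: int = 30
    injection_volume_uL: float = 9.0
    cell_volume_mL: float = 1.43
    cell_conc_uM: float = 97.0
    syringe_conc_uM: float = 1420.0
    temperature_K: float = 298.15
    params: dict = field(default_factory=lambda: {"N": 2.0, "Kd": 320.0, "dH": -5.0})
    noise_sd: float = 0.0

    def protocol(self) -> InjectionProtocol:
        return InjectionProtocol.uniform(
            self.n_injections,
            self.injection_volume_uL,
            self.cell_volume_mL,
            self.cell_conc_uM,
            self.syringe_conc_uM,
            self.temperature_K,
        )

    def binding_params(self):
        if self.model == "one_site":
            return OneSiteParams(**self.params)
        if self.model == "two_sites":
            return TwoSiteParams(**self.params)
        raise ValueError(f"unknown model {self.model!r}")


@dataclass
class PipelineConfig:
    """Everything the simulate / pics / itc commands need."""

    seed: int = 0
    test_confidence: float = 80.0
    control_confidence: float = 10.0
    n_proteins: int = 100
    length_min: int = 200
    length_max: int = 400
    digest: DigestRule = field(default_factory=lambda: TRYPSIN)
    protease_preference: dict = field(
        default_factory=lambda: {"P1": {"F": 1.0}}
    )
    protease_efficiency: float = 1.0
    noise: NoiseSettings = field(default_factory=NoiseSettings)
    titrations: list[TitrationConfig] = field(default_factory=lambda: [TitrationConfig()])

    def protease(self) -> ProteaseSpec:
        return ProteaseSpec(
            preference=self.protease_preference, efficiency=self.protease_efficiency
        )

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["digest"]["cleave_after"] = sorted(self.digest.cleave_after)
        doc["digest"]["blocked_by_next"] = sorted(self.digest.blocked_by_next)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kwargs = dict(doc)
        if "digest" in kwargs:
            d = dict(kwargs["digest"])
            d["cleave_after"] = frozenset(d.get("cleave_after", ()))
            d["blocked_by_next"] = frozenset(d.get("blocked_by_next", ()))
            kwargs["digest"] = DigestRule(**d)
        if "noise" in kwargs:
            n = dict(kwargs["noise"])
            for key in ("product_confidence", "background_confidence"):
                if key in n:
                    n[key] = tuple(n[key])
            kwargs["noise"] = NoiseSettings(**n)
        if "titrations" in kwargs:
            kwargs["titrations"] = [TitrationConfig(**t) for t in kwargs["titrations"]]
        return cls(**kwargs)
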