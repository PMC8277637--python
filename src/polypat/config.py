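"""Flat key-value run configuration.

Config files are plain text, one ``key = value`` per line, '#' comments,
dotted namespaces (``design.n_blocks``, ``mating.cross_flower_rate``, ...).
Values parse as int, float, bool, or comma-separated lists thereof; anything
else stays a string. Per-genotype parameters may be given as a single scalar
or as a comma list aligned with ``design.genotypes``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
import numpy as np

from .errors import ConfigurationError
from .simulate import MatingParams, NoiseModel, PolycrossDesign
from .syngen import SynMatingModel

DEFAULTS = {
    "seed": 1,
    "design.genotypes": [f"G{i + 1}" for i in range(8)],
    "design.n_blocks": 8,
    "design.plants_per_genotype_per_block": 8,
    "design.years": [1],
    "mating.cross_flower_rate": 0.5,
    "mating.donor_weight": 1.0,
    "mating.include_intra": True,
    "noise.missing_rate": 0.0,
    "noise.error_rate": 0.0,
    "sampling.seeds_per_plant": 12,
    "syngen.scenario": "one",
    "syngen.n_founders": 8,
    "syngen.generations": 2,
    "syngen.null_p_mode": "recessive",
}


def _parse_scalar(text: str):
    t = text.strip()
    low = t.lower()
    if low in ("true", "yes"):
        return True
    if low in ("false", "no"):
        return False
    for cast in (int, float):
        try:
            return cast(t)
        except ValueError:
            pass
    return t


def parse_value(text: str):
    if "," in text:
        return [_parse_scalar(p) for p in text.split(",")]
    return _parse_scalar(text)


def load_config_text(text: str) -> dict:
    values = dict(DEFAULTS)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"config line {lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key = key.strip()
        if not key:
            raise ConfigurationError(f"config line {lineno}: empty key")
        values[key] = parse_value(val)
    return values


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


@dataclass
class RunConfig:
    values: dict = field(default_factory=lambda: dict(DEFAULTS))
    hash: str = ""

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        return cls(values=load_config_text(text), hash=config_hash(text))

    @classmethod
    def default(cls) -> "RunConfig":
        return cls(values=dict(DEFAULTS), hash=config_hash(""))

    def __getitem__(self, key):
        return self.values[key]

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def _aslist(self, key):
        v = self.values[key]
        return v if isinstance(v, list) else [v]

    def _per_genotype(self, key, genotypes):
        v = self.values[key]
        if isinstance(v, list):
            if len(v) != len(genotypes):
                raise ConfigurationError(
                    f"{key}: {len(v)} values for {len(genotypes)} genotypes"
                )
            return dict(zip(genotypes, (float(x) for x in v)))
        return float(v)

    def design(self) -> PolycrossDesign:
        genotypes = [str(g) for g in self._aslist("design.genotypes")]
        return PolycrossDesign(
            genotypes=genotypes,
            n_blocks=int(self.values["design.n_blocks"]),
            plants_per_genotype_per_block=int(
                self.values["design.plants_per_genotype_per_block"]
            ),
            years=[int(y) for y in self._aslist("design.years")],
        )

    def mating_params(self) -> MatingParams:
        genotypes = [str(g) for g in self._aslist("design.genotypes")]
        year_effects = None
        if "mating.year_effects" in self.values:
            years = [int(y) for y in self._aslist("design.years")]
            shifts = [float(x) for x in self._aslist("mating.year_effects")]
            if len(shifts) != len(years):
                raise ConfigurationError(
                    "mating.year_effects must match design.years"
                )
            year_effects = dict(zip(years, shifts))
        return MatingParams(
            cross_flower_rate=self._per_genotype("mating.cross_flower_rate", genotypes),
            donor_weight=self._per_genotype("mating.donor_weight", genotypes),
            include_intra=bool(self.values["mating.include_intra"]),
            year_effects=year_effects,
        )

    def noise(self) -> NoiseModel:
        return NoiseModel(
            missing_rate=float(self.values["noise.missing_rate"]),
            error_rate=float(self.values["noise.error_rate"]),
        )

    def seeds_per_plant(self) -> int:
        return int(self.values["sampling.seeds_per_plant"])

    def syngen_model(self):
        n = int(self.values["syngen.n_founders"])
        scenario = str(self.values["syngen.scenario"])
        if scenario == "custom":
            weights = np.array(
                [float(x) for x in self._aslist("syngen.weights")], dtype=float
            )
            if len(weights) != n:
                raise ConfigurationError("syngen.weights must match n_founders")
            model = SynMatingModel(
                cross_rate=float(self.values.get("syngen.C", 0.5)),
                founder_weights=weights,
                null_mode=str(self.values["syngen.null_p_mode"]),
            )
            return scenario, n, model
        if scenario not in ("one", "two"):
            raise ConfigurationError(f"unknown syngen.scenario {scenario!r}")
        return scenario, n, None
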