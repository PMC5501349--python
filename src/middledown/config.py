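"""Run configuration: one YAML file describing tail, rules, tolerances and
the simulated mixture, round-tripping losslessly.

Unknown keys are rejected at every level — a typo in a tolerance name
must fail loudly, not fall back to a default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import (
    DEFAULT_MOD_RULES,
    H3_MODIFIABLE_SITES,
    H3_TAIL,
    LabelScheme,
    TailSequence,
)
from .search import SearchConfig
from .synth import MixtureSpec, NoiseModel


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    """Everything one run needs, with middle-down histone defaults."""

    tail: TailSequence = H3_TAIL
    modifiable_sites: tuple[int, ...] | None = H3_MODIFIABLE_SITES
    mod_rules: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOD_RULES)
    )
    scheme: LabelScheme = LabelScheme()
    precursor_tol: float = 2.1
    fragment_tol_search: float = 0.01
    fragment_tol_filter_ppm: float = 30.0
    isobaric_window: float = 0.05
    max_mods: int = 9
    max_candidates: int = 200_000
    components: tuple[tuple[str, str, float], ...] = ()
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    base_intensity: float = 1000.0
    charge: int = 8

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            precursor_tol=self.precursor_tol,
            fragment_tol_search=self.fragment_tol_search,
            fragment_tol_filter_ppm=self.fragment_tol_filter_ppm,
            isobaric_window=self.isobaric_window,
            mod_rules=dict(self.mod_rules),
            modifiable_sites=self.modifiable_sites,
            max_mods=self.max_mods,
            max_candidates=self.max_candidates,
            scheme=self.scheme,
        )

    def mixture_spec(self) -> MixtureSpec:
        if not self.components:
            raise ConfigError("config has no simulate.components")
        return MixtureSpec(
            tail=self.tail,
            components=self.components,
            noise=self.noise,
            seed=self.seed,
            base_intensity=self.base_intensity,
            charge=self.charge,
            isobaric_window=self.isobaric_window,
        )

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tail": {
                "name": self.tail.name,
                "residues": self.tail.residues,
                "first_position": self.tail.first_position,
                "cleavage_context": self.tail.cleavage_context,
            },
            "modifiable_sites": (
                list(self.modifiable_sites) if self.modifiable_sites else None
            ),
            "mod_rules": {k: list(v) for k, v in self.mod_rules.items()},
            "label_scheme": {
                "heavy_K_delta": self.scheme.heavy_K_delta,
                "heavy_R_delta": self.scheme.heavy_R_delta,
                "heavy_methyl_delta": self.scheme.heavy_methyl_delta,
                "sequence_channel_enabled": self.scheme.sequence_channel_enabled,
                "methyl_channel_enabled": self.scheme.methyl_channel_enabled,
                "allow_methionine_tails": self.scheme.allow_methionine_tails,
            },
            "search": {
                "precursor_tol": self.precursor_tol,
                "fragment_tol_search": self.fragment_tol_search,
                "fragment_tol_filter_ppm": self.fragment_tol_filter_ppm,
                "isobaric_window": self.isobaric_window,
                "max_mods": self.max_mods,
                "max_candidates": self.max_candidates,
            },
            "simulate": {
                "seed": self.seed,
                "base_intensity": self.base_intensity,
                "charge": self.charge,
                "noise": {
                    "intensity_cv": self.noise.intensity_cv,
                    "dropout": self.noise.dropout,
                    "mass_jitter_ppm": self.noise.mass_jitter_ppm,
                },
                "components": [list(c) for c in self.components],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(
            d,
            {"tail", "modifiable_sites", "mod_rules", "label_scheme", "search",
             "simulate"},
            "config",
        )
        kwargs: dict = {}
        if "tail" in d:
            td = d["tail"]
            _check_keys(
                td,
                {"name", "residues", "first_position", "cleavage_context"},
                "tail",
            )
            kwargs["tail"] = TailSequence(
                name=td["name"],
                residues=td["residues"],
                first_position=td.get("first_position", 1),
                cleavage_context=td.get("cleavage_context", ""),
            )
        if "modifiable_sites" in d:
            ms = d["modifiable_sites"]
            kwargs["modifiable_sites"] = tuple(ms) if ms else None
        if "mod_rules" in d:
            kwargs["mod_rules"] = {
                k: tuple(v) for k, v in d["mod_rules"].items()
            }
        if "label_scheme" in d:
            ld = dict(d["label_scheme"])
            _check_keys(
                ld,
                {"heavy_K_delta", "heavy_R_delta", "heavy_methyl_delta",
                 "sequence_channel_enabled", "methyl_channel_enabled",
                 "allow_methionine_tails"},
                "label_scheme",
            )
            kwargs["scheme"] = LabelScheme(**ld)
        if "search" in d:
            sd = d["search"]
            _check_keys(
                sd,
                {"precursor_tol", "fragment_tol_search",
                 "fragment_tol_filter_ppm", "isobaric_window", "max_mods",
                 "max_candidates"},
                "search",
            )
            kwargs.update(sd)
        if "simulate" in d:
            md = d["simulate"]
            _check_keys(
                md,
                {"seed", "base_intensity", "charge", "noise", "components"},
                "simulate",
            )
            for k in ("seed", "base_intensity", "charge"):
                if k in md:
                    kwargs[k] = md[k]
            if "noise" in md:
                nd = md["noise"]
                _check_keys(
                    nd, {"intensity_cv", "dropout", "mass_jitter_ppm"}, "noise"
                )
                kwargs["noise"] = NoiseModel(**nd)
            if "components" in md:
                kwargs["components"] = tuple(
                    (str(n), str(ch), float(p)) for n, ch, p in md["components"]
                )
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml_text(Path(path).read_text())

    @classmethod
    def from_yaml_text(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config top level must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=None)
        )


def demo_config() -> RunConfig:
    """The packaged demo: a six-component H3 mixture with an isobaric
    K9me2/K14me2 pair, a hybrid heavy mark and one heavy-KR component."""
    from importlib.resources import files

    return RunConfig.from_yaml_text(
        files("middledown").joinpath("data/demo_config.yaml").read_text()
    )
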