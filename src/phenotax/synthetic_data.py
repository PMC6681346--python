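"""Synthetic species-labelled phenol profiles.

No per-sample compound table is published for the six Bale Mountains taxa,
so this generator produces datasets with the compositional structure the
analysis pipeline assumes: six species with the study's sample counts
(29 Erica, 5 Alchemilla, 7 Festuca, 4 Helichrysum, 1 Kniphofia, 1 Lobelia)
and per-species mean total phenol contents (Alchemilla 18, Erica 16,
Helichrysum 22, Kniphofia 6, Lobelia 22, Festuca 51 g kg^-1 TOC).

Each sample draws a 16-compound composition from a Dirichlet centered on
its species' mean composition, an independent log-normal total content,
and a uniform internal-standard recovery fraction.  The *stored* contents
are the post-loss values (true contents times recovery) so the
recovery-correction stage is exercised end to end.

Species mean compositions are synthetic: the group-level contrasts follow
the qualitative field picture (Erica's coumaryl fraction above 0.20 with
benzoic acids inside 0.05-0.12 while every other species violates at
least one condition; Helichrysum highest and Erica lowest in p-hydroxy
phenols; Festuca coumaryl-rich, about one third of its phenols, with low
vanillyl and benzoic acids; Kniphofia and Lobelia rich in benzoic acids;
Kniphofia the most even profile), and each group fraction is spread
uniformly over that group's member compounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry_io import (
    BENZOIC,
    COUMARYL,
    GROUP_MEMBERS,
    HYDROXY_BENZOIC,
    P_HYDROXY,
    SYRINGYL,
    VANILLYL,
    CompoundRegistry,
    Dataset,
    SampleProfile,
    default_registry,
)

__all__ = [
    "SpeciesSpec",
    "GeneratorConfig",
    "SPECIES_GROUP_FRACTIONS",
    "SPECIES_TOTALS",
    "SPECIES_COUNTS",
    "composition_from_group_fractions",
    "default_config",
    "generate",
    "planted_threshold_dataset",
    "planted_rule_dataset",
]

#: Within-species Dirichlet precision.  The group-level compositional sd is
#: roughly sqrt(f(1-f)/(c+1)); at c=800 the coumaryl/benzoic rule thresholds
#: sit >3 sd from Erica's means and the six species clouds are compact
#: enough that Ward clustering of the 47-sample default dataset recovers
#: them.  This is a deliberately idealized, low-dispersion regime; real
#: within-species variability is far larger (see the methods note).
DEFAULT_CONCENTRATION = 800.0
#: Log-normal coefficient of variation of per-sample total phenol content;
#: kept small for the same reason as the Dirichlet precision.
DEFAULT_TOTAL_CV = 0.05
#: Internal-standard recovery fractions drawn uniformly from this interval.
DEFAULT_RECOVERY_RANGE = (0.70, 0.95)

#: Study sample counts per species.
SPECIES_COUNTS: dict[str, int] = {
    "Erica": 29,
    "Alchemilla": 5,
    "Festuca": 7,
    "Helichrysum": 4,
    "Kniphofia": 1,
    "Lobelia": 1,
}

#: Mean total phenol content per species, g kg^-1 TOC.
SPECIES_TOTALS: dict[str, float] = {
    "Alchemilla": 18.0,
    "Erica": 16.0,
    "Helichrysum": 22.0,
    "Kniphofia": 6.0,
    "Lobelia": 22.0,
    "Festuca": 51.0,
}

#: Synthetic group-level mean fractions of total phenols.  The six bins are
#: disjoint for allocation purposes: the hydroxy-benzoic bin covers only the
#: two compounds not already counted under p-hydroxy (4-hydroxybenzoic acid
#: is allocated once, inside the p-hydroxy bin).
SPECIES_GROUP_FRACTIONS: dict[str, dict[str, float]] = {
    "Erica": {
        P_HYDROXY: 0.06,
        VANILLYL: 0.25,
        SYRINGYL: 0.125,
        COUMARYL: 0.28,
        BENZOIC: 0.085,
        HYDROXY_BENZOIC: 0.20,
    },
    "Alchemilla": {
        P_HYDROXY: 0.12,
        VANILLYL: 0.15,
        SYRINGYL: 0.25,
        COUMARYL: 0.12,
        BENZOIC: 0.09,
        HYDROXY_BENZOIC: 0.27,
    },
    "Festuca": {
        P_HYDROXY: 0.10,
        VANILLYL: 0.06,
        SYRINGYL: 0.24,
        COUMARYL: 0.33,
        BENZOIC: 0.025,
        HYDROXY_BENZOIC: 0.245,
    },
    "Helichrysum": {
        P_HYDROXY: 0.32,
        VANILLYL: 0.20,
        SYRINGYL: 0.16,
        COUMARYL: 0.10,
        BENZOIC: 0.10,
        HYDROXY_BENZOIC: 0.12,
    },
    "Kniphofia": {
        P_HYDROXY: 0.16,
        VANILLYL: 0.17,
        SYRINGYL: 0.15,
        COUMARYL: 0.14,
        BENZOIC: 0.20,
        HYDROXY_BENZOIC: 0.18,
    },
    "Lobelia": {
        P_HYDROXY: 0.14,
        VANILLYL: 0.28,
        SYRINGYL: 0.07,
        COUMARYL: 0.10,
        BENZOIC: 0.18,
        HYDROXY_BENZOIC: 0.23,
    },
}


@dataclass
class SpeciesSpec:
    """Generative parameters for one species."""

    name: str
    n_samples: int
    mean_composition: np.ndarray  # 16 positive weights summing to 1
    concentration: float = DEFAULT_CONCENTRATION
    total_mean: float = 20.0
    total_cv: float = DEFAULT_TOTAL_CV
    recovery_range: tuple[float, float] = DEFAULT_RECOVERY_RANGE

    def validate(self) -> "SpeciesSpec":
        comp = np.asarray(self.mean_composition, dtype=float)
        if comp.shape != (16,):
            raise ValueError(f"{self.name}: mean_composition must have 16 entries")
        if (comp <= 0).any():
            raise ValueError(f"{self.name}: mean_composition must be strictly positive")
        if not np.isclose(comp.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: mean_composition must sum to 1")
        if self.n_samples < 1:
            raise ValueError(f"{self.name}: n_samples must be >= 1")
        if self.concentration <= 0:
            raise ValueError(f"{self.name}: concentration must be positive")
        if self.total_mean <= 0 or self.total_cv < 0:
            raise ValueError(f"{self.name}: invalid total parameters")
        lo, hi = self.recovery_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"{self.name}: recovery_range must lie within (0, 1]")
        return self


@dataclass
class GeneratorConfig:
    """A full synthetic-dataset request."""

    species: list[SpeciesSpec]
    seed: int = 0
    scale_factor: int = 1

    def validate(self) -> "GeneratorConfig":
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        for spec in self.species:
            spec.validate()
        return self


def composition_from_group_fractions(
    fractions: dict[str, float], registry: CompoundRegistry | None = None
) -> np.ndarray:
    """16-compound mean composition from six group-level fractions.

    Each group's fraction is spread uniformly over its member compounds;
    the hydroxy-benzoic bin excludes 4-hydroxybenzoic acid, which is
    allocated once under p-hydroxy (the groups overlap in that compound).
    """
    registry = registry or default_registry()
    if not np.isclose(sum(fractions.values()), 1.0, atol=1e-9):
        raise ValueError("group fractions must sum to 1")
    allocation = {g: list(m) for g, m in GROUP_MEMBERS.items()}
    allocation[HYDROXY_BENZOIC] = [
        c for c in allocation[HYDROXY_BENZOIC] if c != "4-hydroxybenzoic acid"
    ]
    comp = {c: 0.0 for c in registry.compounds}
    for group, fraction in fractions.items():
        members = allocation[group]
        for c in members:
            comp[c] += fraction / len(members)
    return np.array([comp[c] for c in registry.compounds], dtype=float)


def default_config(seed: int = 0, scale_factor: int = 1) -> GeneratorConfig:
    """The study-shaped default configuration: 47 samples over six species."""
    species = []
    for name in SPECIES_COUNTS:
        species.append(
            SpeciesSpec(
                name=name,
                n_samples=SPECIES_COUNTS[name],
                mean_composition=composition_from_group_fractions(
                    SPECIES_GROUP_FRACTIONS[name]
                ),
                total_mean=SPECIES_TOTALS[name],
            )
        )
    return GeneratorConfig(species=species, seed=seed, scale_factor=scale_factor).validate()


def generate(config: GeneratorConfig, registry: CompoundRegistry | None = None) -> Dataset:
    """Draw a species-labelled synthetic dataset.

    Per sample: composition ~ Dirichlet(concentration * mean_composition);
    total ~ log-normal matching the species mean and CV; true contents =
    composition * total; recovery ~ Uniform(recovery_range).  Stored
    contents are true contents times recovery (the post-loss measurement),
    with the recovery fraction recorded so ``recovery_correct`` restores
    the true values exactly.
    """
    config.validate()
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    samples: list[SampleProfile] = []
    for spec in config.species:
        n = spec.n_samples * config.scale_factor
        alpha = spec.concentration * np.asarray(spec.mean_composition, dtype=float)
        compositions = rng.dirichlet(alpha, size=n)
        sigma2 = np.log1p(spec.total_cv**2)
        mu = np.log(spec.total_mean) - sigma2 / 2.0
        totals = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
        lo, hi = spec.recovery_range
        recoveries = rng.uniform(lo, hi, size=n)
        for i in range(n):
            true_contents = compositions[i] * totals[i]
            raw = true_contents * recoveries[i]
            samples.append(
                SampleProfile(
                    sample_id=f"{spec.name}_{i + 1:03d}",
                    species=spec.name,
                    contents=dict(zip(registry.compounds, raw.tolist())),
                    recovery=float(recoveries[i]),
                )
            )
    return Dataset(samples).validate(registry)


def planted_threshold_dataset(
    n: int, cut: float = 0.21, noise_features: int = 5, seed: int = 0
):
    """Two-class data separated only by one feature at a planted cut.

    The informative ``coumaryl`` column is uniform on (0, 0.45) and the
    class is 1 exactly when it exceeds ``cut``; noise columns are uniform
    on (0, 1) and label-independent.  Returns ``(X, y)`` with X a named
    DataFrame.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    signal = rng.uniform(0.0, 0.45, size=n)
    y = (signal > cut).astype(int)
    columns = {"coumaryl": signal}
    for j in range(noise_features):
        columns[f"noise_{j + 1}"] = rng.uniform(0.0, 1.0, size=n)
    return pd.DataFrame(columns), y


def planted_rule_dataset(
    n: int,
    coumaryl_cut: float = 0.20,
    benzoic_range: tuple[float, float] = (0.05, 0.12),
    noise_features: int = 4,
    seed: int = 0,
):
    """Two informative features among noise, mirroring the biomarker rule.

    ``coumaryl`` ~ U(0, 0.45) and ``benzoic`` ~ U(0, 0.2); the label is
    ``"Erica"`` exactly when coumaryl exceeds its cut and benzoic lies in
    its range, ``"other"`` otherwise.  Noise columns are U(0, 1).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    coumaryl = rng.uniform(0.0, 0.45, size=n)
    benzoic = rng.uniform(0.0, 0.20, size=n)
    lo, hi = benzoic_range
    y = np.where(
        (coumaryl > coumaryl_cut) & (benzoic >= lo) & (benzoic <= hi), "Erica", "other"
    )
    columns = {"coumaryl": coumaryl, "benzoic": benzoic}
    for j in range(noise_features):
        columns[f"noise_{j + 1}"] = rng.uniform(0.0, 1.0, size=n)
    return pd.DataFrame(columns), y


# -- JSON configuration ------------------------------------------------------

def config_to_json(config: GeneratorConfig, path: str | Path) -> None:
    payload = {
        "seed": config.seed,
        "scale_factor": config.scale_factor,
        "species": [
            {
                "name": s.name,
                "n_samples": s.n_samples,
                "mean_composition": list(np.asarray(s.mean_composition, dtype=float)),
                "concentration": s.concentration,
                "total_mean": s.total_mean,
                "total_cv": s.total_cv,
                "recovery_range": list(s.recovery_range),
            }
            for s in config.species
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def config_from_json(path: str | Path) -> GeneratorConfig:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    species = [
        SpeciesSpec(
            name=s["name"],
            n_samples=int(s["n_samples"]),
            mean_composition=np.asarray(s["mean_composition"], dtype=float),
            concentration=float(s.get("concentration", DEFAULT_CONCENTRATION)),
            total_mean=float(s["total_mean"]),
            total_cv=float(s.get("total_cv", DEFAULT_TOTAL_CV)),
            recovery_range=tuple(s.get("recovery_range", DEFAULT_RECOVERY_RANGE)),
        )
        for s in payload["species"]
    ]
    return GeneratorConfig(
        species=species,
        seed=int(payload.get("seed", 0)),
        scale_factor=int(payload.get("scale_factor", 1)),
    ).validate()
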