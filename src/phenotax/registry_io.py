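"""Canonical CuO-oxidation phenol compound registry and sample-table I/O.

Mild alkaline CuO oxidation of plant tissue releases a reproducible set of
sixteen phenolic monomers that are quantified by GC-MS and normalized to
total organic carbon (g kg^-1 TOC).  This module fixes the canonical
compound list, the six diagnostic group memberships (p-hydroxy, vanillyl,
syringyl, coumaryl, benzoic acids, hydroxy-benzoic acids), and the CSV
schema used to move per-sample compound tables in and out of the package.

Groups are *not* a partition: 4-hydroxybenzoic acid belongs to both the
p-hydroxy family and the hydroxy-benzoic acids, so the flattened membership
table has 17 (compound, group) pairs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "P_HYDROXY",
    "VANILLYL",
    "SYRINGYL",
    "COUMARYL",
    "BENZOIC",
    "HYDROXY_BENZOIC",
    "GROUP_NAMES",
    "GROUP_MEMBERS",
    "COMPOUNDS",
    "SPECIES",
    "UNKNOWN_SPECIES",
    "CompoundRegistry",
    "SampleProfile",
    "Dataset",
    "canonical_compound_name",
    "default_registry",
    "read_sample_table",
    "write_sample_table",
]

# Group identifiers
P_HYDROXY = "p_hydroxy"
VANILLYL = "vanillyl"
SYRINGYL = "syringyl"
COUMARYL = "coumaryl"
BENZOIC = "benzoic"
HYDROXY_BENZOIC = "hydroxy_benzoic"

GROUP_NAMES: tuple[str, ...] = (
    P_HYDROXY,
    VANILLYL,
    SYRINGYL,
    COUMARYL,
    BENZOIC,
    HYDROXY_BENZOIC,
)

#: Defining group memberships.  4-hydroxybenzoic acid appears twice
#: (p-hydroxy and hydroxy-benzoic acids); every other compound exactly once.
GROUP_MEMBERS: dict[str, tuple[str, ...]] = {
    P_HYDROXY: (
        "4-hydroxybenzaldehyde",
        "4-hydroxyacetophenone",
        "4-hydroxybenzoic acid",
    ),
    VANILLYL: (
        "vanillin",
        "4-hydroxy-3-methoxyacetophenone",
        "vanillic acid",
    ),
    SYRINGYL: (
        "syringaldehyde",
        "3,5-dimethoxy-4-hydroxyacetophenone",
        "syringic acid",
    ),
    COUMARYL: (
        "p-coumaric acid",
        "ferulic acid",
    ),
    BENZOIC: (
        "benzoic acid",
        "salicylic acid",
        "phthalic acid",
    ),
    HYDROXY_BENZOIC: (
        "3-hydroxybenzoic acid",
        "4-hydroxybenzoic acid",
        "3,5-dihydroxybenzoic acid",
    ),
}

#: Canonical column order: the sixteen compounds in group-definition order.
COMPOUNDS: tuple[str, ...] = (
    "4-hydroxybenzaldehyde",
    "4-hydroxyacetophenone",
    "4-hydroxybenzoic acid",
    "vanillin",
    "4-hydroxy-3-methoxyacetophenone",
    "vanillic acid",
    "syringaldehyde",
    "3,5-dimethoxy-4-hydroxyacetophenone",
    "syringic acid",
    "p-coumaric acid",
    "ferulic acid",
    "benzoic acid",
    "salicylic acid",
    "phthalic acid",
    "3-hydroxybenzoic acid",
    "3,5-dihydroxybenzoic acid",
)

SPECIES: tuple[str, ...] = (
    "Erica",
    "Alchemilla",
    "Festuca",
    "Helichrysum",
    "Kniphofia",
    "Lobelia",
)
UNKNOWN_SPECIES = "unknown"

# Spelling variants seen in the field literature, mapped onto canonical
# names after lower-casing and dash/space normalization.
_SYNONYMS: dict[str, str] = {
    "3,5-dimethoxy-4-acetophenone": "3,5-dimethoxy-4-hydroxyacetophenone",
    "acetosyringone": "3,5-dimethoxy-4-hydroxyacetophenone",
    "4-hydroxybenzacetophenone": "4-hydroxyacetophenone",
    "acetovanillone": "4-hydroxy-3-methoxyacetophenone",
    "coumaric acid": "p-coumaric acid",
    "3,5-dihydroxy-benzoic acid": "3,5-dihydroxybenzoic acid",
}

_DASHES = re.compile(r"[‐‑‒–—−]")


def canonical_compound_name(name: str) -> str:
    """Normalize a compound column label to its canonical registry spelling.

    Lower-cases, converts typographic dashes to ``-``, treats underscores as
    separators, collapses whitespace, and resolves known spelling variants.
    The result is canonical only if it names a registry compound; callers
    decide how to handle anything else.
    """
    s = _DASHES.sub("-", str(name)).lower()
    s = s.replace("_", " ")
    s = re.sub(r"\s+", " ", s).strip()
    s = re.sub(r"\s*-\s*", "-", s)
    # Table-style labels sometimes glue a leading digit with a separator,
    # e.g. " 4 hydroxybenzaldehyde"; put the dashes back for digit prefixes.
    s = re.sub(r"^(\d) ", r"\1-", s)
    s = re.sub(r"(\d) (\d)", r"\1,\2", s)
    s = re.sub(r"(\d) ", r"\1-", s)
    return _SYNONYMS.get(s, s)


@dataclass(frozen=True)
class CompoundRegistry:
    """The sixteen canonical CuO-oxidation phenols and their group memberships."""

    compounds: tuple[str, ...] = COMPOUNDS
    group_members: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(GROUP_MEMBERS)
    )

    def __post_init__(self) -> None:
        members = {c for group in self.group_members.values() for c in group}
        missing = members.symmetric_difference(self.compounds)
        if missing:
            raise ValueError(f"registry compounds and group members disagree: {sorted(missing)}")

    @property
    def group_membership(self) -> dict[str, frozenset[str]]:
        """Mapping compound -> set of groups it belongs to."""
        out: dict[str, frozenset[str]] = {}
        for compound in self.compounds:
            out[compound] = frozenset(
                g for g, members in self.group_members.items() if compound in members
            )
        return out

    def membership_pairs(self) -> list[tuple[str, str]]:
        """Flattened (compound, group) pairs; 17 entries for the default registry."""
        return [
            (c, g)
            for g in self.group_members
            for c in self.group_members[g]
        ]

    def resolve(self, name: str) -> str | None:
        """Canonical compound name for ``name``, or None if not a registry compound."""
        canonical = canonical_compound_name(name)
        return canonical if canonical in self.compounds else None


_DEFAULT = CompoundRegistry()


def default_registry() -> CompoundRegistry:
    return _DEFAULT


@dataclass
class SampleProfile:
    """One sample's per-compound phenol contents in g kg^-1 TOC.

    ``recovery`` is the measured internal-standard (ethylvanillin) recovery
    fraction in (0, 1]; ``None`` means no recovery information.
    """

    sample_id: str
    species: str
    contents: dict[str, float]
    recovery: float | None = None

    def validate(self, registry: CompoundRegistry | None = None) -> "SampleProfile":
        registry = registry or _DEFAULT
        missing = [c for c in registry.compounds if c not in self.contents]
        if missing:
            raise ValueError(f"sample {self.sample_id!r}: missing compounds {missing}")
        for compound, value in self.contents.items():
            if value < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: negative content {value} for {compound!r}"
                )
        if self.recovery is not None and not (0.0 < self.recovery <= 1.0):
            raise ValueError(
                f"sample {self.sample_id!r}: recovery {self.recovery} outside (0, 1]"
            )
        return self

    def total(self, registry: CompoundRegistry | None = None) -> float:
        registry = registry or _DEFAULT
        return float(sum(self.contents[c] for c in registry.compounds))

    def copy(self) -> "SampleProfile":
        return replace(self, contents=dict(self.contents))


@dataclass
class Dataset:
    """An ordered collection of sample profiles sharing the registry's compounds."""

    samples: list[SampleProfile] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleProfile]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> SampleProfile:
        return self.samples[i]

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.samples]

    def validate(self, registry: CompoundRegistry | None = None) -> "Dataset":
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        for sample in self.samples:
            sample.validate(registry)
        return self

    def to_frame(self, registry: CompoundRegistry | None = None) -> pd.DataFrame:
        """Tabular view: sample_id, species, 16 compound columns, recovery."""
        registry = registry or _DEFAULT
        rows = []
        for s in self.samples:
            row: dict[str, object] = {"sample_id": s.sample_id, "species": s.species}
            row.update({c: s.contents[c] for c in registry.compounds})
            row["recovery"] = s.recovery
            rows.append(row)
        columns = ["sample_id", "species", *registry.compounds, "recovery"]
        return pd.DataFrame(rows, columns=columns)

    def contents_matrix(self, registry: CompoundRegistry | None = None):
        """(n_samples, 16) array of contents in canonical compound order."""
        registry = registry or _DEFAULT
        import numpy as np

        return np.array(
            [[s.contents[c] for c in registry.compounds] for s in self.samples],
            dtype=float,
        )


def read_sample_table(
    path: str | Path, registry: CompoundRegistry | None = None
) -> Dataset:
    """Read a per-sample phenol content CSV into a validated :class:`Dataset`.

    The CSV must carry ``sample_id``, ``species`` and one column per
    canonical compound (matched case-insensitively after normalization and
    synonym resolution); a ``recovery`` column is optional.

    Raises ``ValueError`` naming the missing compounds if any are absent and
    on negative contents; species labels outside the study's six genera are
    kept as ``"unknown"`` with a warning.
    """
    registry = registry or _DEFAULT
    frame = pd.read_csv(path)
    colmap: dict[str, str] = {}
    for col in frame.columns:
        lowered = str(col).strip().lower()
        if lowered in ("sample_id", "species", "recovery"):
            colmap[lowered] = col
            continue
        canonical = registry.resolve(col)
        if canonical is not None:
            colmap[canonical] = col
    for required in ("sample_id", "species"):
        if required not in colmap:
            raise ValueError(f"missing required column {required!r} in {path}")
    missing = [c for c in registry.compounds if c not in colmap]
    if missing:
        raise ValueError(f"missing compound columns in {path}: {missing}")

    samples: list[SampleProfile] = []
    for idx, row in frame.iterrows():
        contents: dict[str, float] = {}
        for compound in registry.compounds:
            value = float(row[colmap[compound]])
            if value < 0:
                raise ValueError(
                    f"negative content {value} at row {idx}, column "
                    f"{colmap[compound]!r} in {path}"
                )
            contents[compound] = value
        species = str(row[colmap["species"]]).strip()
        if species not in SPECIES and species != UNKNOWN_SPECIES:
            warnings.warn(
                f"row {idx}: unknown species label {species!r}; recorded as "
                f"{UNKNOWN_SPECIES!r}",
                stacklevel=2,
            )
            species = UNKNOWN_SPECIES
        recovery: float | None = None
        if "recovery" in colmap:
            raw = row[colmap["recovery"]]
            if pd.notna(raw):
                recovery = float(raw)
        samples.append(
            SampleProfile(
                sample_id=str(row[colmap["sample_id"]]),
                species=species,
                contents=contents,
                recovery=recovery,
            )
        )
    return Dataset(samples).validate(registry)


def write_sample_table(
    dataset: Dataset, path: str | Path, registry: CompoundRegistry | None = None
) -> None:
    """Write a Dataset to CSV in the canonical column order.

    Numeric formatting keeps 12 significant digits so a read/write round
    trip is the identity within 1e-9 relative error.
    """
    registry = registry or _DEFAULT
    frame = dataset.to_frame(registry)
    if frame["recovery"].isna().all():
        frame = frame.drop(columns=["recovery"])
    frame.to_csv(path, index=False, float_format="%.12g")
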