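"""Per-sample phenol features: group sums, relative abundances, source
proxies and the Shannon-Wiener diversity index.

The six diagnostic group sums aggregate the sixteen CuO-oxidation phenols
into the p-hydroxy, vanillyl (V), syringyl (S), coumaryl (C), benzoic-acid
and hydroxy-benzoic-acid families.  Because 4-hydroxybenzoic acid is a
member of both the p-hydroxy and the hydroxy-benzoic group, the six sums
exceed the plain 16-compound total by exactly that compound's content;
relative abundances keep the per-group definitions and divide by the plain
total, so the six fractions may sum slightly above 1.

S/V and C/V are the classical lignin-source proxies (syringyl over
vanillyl, coumaryl a.k.a. cinnamyl over vanillyl).  The diversity index is
the Shannon-Wiener entropy H = -sum p_i ln(p_i) of the sixteen-compound
composition, in nats, bounded by ln(16).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry_io import (
    BENZOIC,
    COUMARYL,
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
    "GroupAbundances",
    "RelativeGroupAbundances",
    "ProxyRatios",
    "DiversityIndex",
    "recovery_correct",
    "group_sums",
    "relative_group_abundances",
    "proxy_ratios",
    "shannon_index",
    "feature_table",
]

#: Entropy upper bound for a 16-compound composition, in nats.
MAX_DIVERSITY = math.log(16)


@dataclass(frozen=True)
class GroupAbundances:
    """Six group sums plus the plain 16-compound total, all in g kg^-1 TOC."""

    p_hydroxy: float
    vanillyl: float
    syringyl: float
    coumaryl: float
    benzoic: float
    hydroxy_benzoic: float
    total_phenols: float

    def as_dict(self) -> dict[str, float]:
        return {
            P_HYDROXY: self.p_hydroxy,
            VANILLYL: self.vanillyl,
            SYRINGYL: self.syringyl,
            COUMARYL: self.coumaryl,
            BENZOIC: self.benzoic,
            HYDROXY_BENZOIC: self.hydroxy_benzoic,
        }


@dataclass(frozen=True)
class RelativeGroupAbundances:
    """Group sums divided by the plain 16-compound total (fractions)."""

    p_hydroxy: float
    vanillyl: float
    syringyl: float
    coumaryl: float
    benzoic: float
    hydroxy_benzoic: float

    def as_dict(self) -> dict[str, float]:
        return {
            P_HYDROXY: self.p_hydroxy,
            VANILLYL: self.vanillyl,
            SYRINGYL: self.syringyl,
            COUMARYL: self.coumaryl,
            BENZOIC: self.benzoic,
            HYDROXY_BENZOIC: self.hydroxy_benzoic,
        }


@dataclass(frozen=True)
class ProxyRatios:
    """Dimensionless lignin-source proxies S/V and C/V."""

    s_over_v: float
    c_over_v: float


@dataclass(frozen=True)
class DiversityIndex:
    """Shannon-Wiener entropy of the 16-compound composition, in nats."""

    h: float


def recovery_correct(profile: SampleProfile) -> SampleProfile:
    """Scale all contents by 1/recovery to undo internal-standard loss.

    The internal standard (ethylvanillin) quantifies the fraction of
    analyte surviving work-up; dividing by it restores the pre-loss
    contents.  The returned profile has recovery set to 1.
    """
    if profile.recovery is None or profile.recovery <= 0:
        raise ValueError(f"sample {profile.sample_id!r}: no recovery information")
    r = profile.recovery
    corrected = {c: v / r for c, v in profile.contents.items()}
    return SampleProfile(
        sample_id=profile.sample_id,
        species=profile.species,
        contents=corrected,
        recovery=1.0,
    )


def group_sums(
    profile: SampleProfile, registry: CompoundRegistry | None = None
) -> GroupAbundances:
    """Aggregate a profile into the six diagnostic group sums.

    ``total_phenols`` is the plain sum over the sixteen compounds; the six
    group sums together exceed it by the 4-hydroxybenzoic acid content,
    which is counted in two groups.
    """
    registry = registry or default_registry()
    sums = {
        group: float(sum(profile.contents[c] for c in members))
        for group, members in registry.group_members.items()
    }
    total = float(sum(profile.contents[c] for c in registry.compounds))
    return GroupAbundances(
        p_hydroxy=sums[P_HYDROXY],
        vanillyl=sums[VANILLYL],
        syringyl=sums[SYRINGYL],
        coumaryl=sums[COUMARYL],
        benzoic=sums[BENZOIC],
        hydroxy_benzoic=sums[HYDROXY_BENZOIC],
        total_phenols=total,
    )


def relative_group_abundances(g: GroupAbundances) -> RelativeGroupAbundances:
    """Divide each group sum by the plain 16-compound total."""
    if g.total_phenols <= 0:
        raise ValueError("empty profile: total phenol content is zero")
    t = g.total_phenols
    return RelativeGroupAbundances(
        p_hydroxy=g.p_hydroxy / t,
        vanillyl=g.vanillyl / t,
        syringyl=g.syringyl / t,
        coumaryl=g.coumaryl / t,
        benzoic=g.benzoic / t,
        hydroxy_benzoic=g.hydroxy_benzoic / t,
    )


def proxy_ratios(g: GroupAbundances) -> ProxyRatios:
    """Syringyl/vanillyl and coumaryl/vanillyl source-proxy ratios."""
    if g.vanillyl <= 0:
        raise ValueError("undefined ratio: vanillyl content is zero")
    return ProxyRatios(
        s_over_v=g.syringyl / g.vanillyl,
        c_over_v=g.coumaryl / g.vanillyl,
    )


def shannon_index(
    profile: SampleProfile, registry: CompoundRegistry | None = None
) -> DiversityIndex:
    """Shannon-Wiener diversity H = -sum p_i ln(p_i) over the 16 compounds.

    p_i is each compound's share of the sample's total phenol content;
    0*ln(0) counts as 0.  H is scale-invariant and lies in [0, ln 16].
    """
    registry = registry or default_registry()
    values = np.array([profile.contents[c] for c in registry.compounds], dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError(f"sample {profile.sample_id!r}: all-zero profile")
    p = values / total
    nonzero = p[p > 0]
    h = float(-(nonzero * np.log(nonzero)).sum())
    return DiversityIndex(h=max(h, 0.0))


def feature_table(
    dataset: Dataset,
    registry: CompoundRegistry | None = None,
    correct_recovery: bool = True,
) -> pd.DataFrame:
    """Per-sample feature table: group sums, relative abundances, proxies, H.

    Profiles carrying a recovery fraction are recovery-corrected first
    (disable with ``correct_recovery=False``).  Ratio columns are NaN where
    undefined (zero vanillyl).
    """
    registry = registry or default_registry()
    rows = []
    for sample in dataset:
        profile = sample
        if correct_recovery and sample.recovery is not None:
            profile = recovery_correct(sample)
        g = group_sums(profile, registry)
        rel = relative_group_abundances(g)
        try:
            ratios = proxy_ratios(g)
            s_over_v, c_over_v = ratios.s_over_v, ratios.c_over_v
        except ValueError:
            s_over_v = c_over_v = float("nan")
        h = shannon_index(profile, registry).h
        row: dict[str, object] = {
            "sample_id": profile.sample_id,
            "species": profile.species,
        }
        row.update(g.as_dict())
        row["total_phenols"] = g.total_phenols
        row.update({f"rel_{k}": v for k, v in rel.as_dict().items()})
        row["s_over_v"] = s_over_v
        row["c_over_v"] = c_over_v
        row["shannon_h"] = h
        rows.append(row)
    return pd.DataFrame(rows)
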