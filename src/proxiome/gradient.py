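"""Polysome-anchored occupancy ratios across sucrose-gradient fractions.

Sucrose gradients resolve free subunits, 80S monosomes and polysomes into 20
fractions (top to bottom).  Band intensities of two r-proteins (e.g. Rpl1 and
Rpl4, both 60S components) are made comparable by dividing each protein's
per-fraction signal by its mean signal in two polysomal fractions (13 and
14): translating ribosomes are assumed to carry both proteins, so the
polysome region serves as the common anchor.  The per-fraction ratio of the
two normalized profiles then estimates the proportion of
denominator-containing particles that also carry the numerator protein --
e.g. the fraction of free 60S subunits that contain Rpl1.

The statistic is invariant to per-protein global scaling (different blot
exposures for the two antibodies drop out exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "N_FRACTIONS",
    "DEFAULT_REFERENCE_FRACTIONS",
    "DEFAULT_GROUPS",
    "GradientProfile",
    "GroupStat",
    "OccupancyTable",
    "normalize_profile",
    "occupancy_ratio",
    "replicate_stats",
    "occupancy_from_profiles",
    "read_gradient_table",
    "write_gradient_table",
]

N_FRACTIONS = 20
DEFAULT_REFERENCE_FRACTIONS = (13, 14)
#: Fraction groups of the bar-graph readout: free 60S peak, 80S monosome
#: peak, and the polysomal region.
DEFAULT_GROUPS = {"60S": (9,), "80S": (10, 11), "polysomes": (13, 14, 15)}


@dataclass(frozen=True)
class GradientProfile:
    """One protein's band intensities across the 20 gradient fractions.

    ``intensities[i]`` is fraction ``i+1`` (fractions are numbered 1..20, top
    to bottom).  ``reference_fractions`` are the polysomal anchor fractions.
    """

    protein_id: str
    replicate_id: str
    intensities: tuple[float, ...]
    reference_fractions: tuple[int, ...] = DEFAULT_REFERENCE_FRACTIONS

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.intensities)
        if len(vals) != N_FRACTIONS:
            raise ValueError(f"expected {N_FRACTIONS} fractions, got {len(vals)}")
        if any(v < 0 for v in vals):
            raise ValueError(
                f"negative intensity in profile {self.protein_id}/{self.replicate_id}"
            )
        refs = tuple(int(f) for f in self.reference_fractions)
        if not refs or any(f < 1 or f > N_FRACTIONS for f in refs):
            raise ValueError("reference fractions must be within 1..20")
        object.__setattr__(self, "intensities", vals)
        object.__setattr__(self, "reference_fractions", refs)

    def fraction(self, f: int) -> float:
        """Intensity of fraction ``f`` (1-based)."""
        return self.intensities[f - 1]

    @property
    def reference_mean(self) -> float:
        return float(np.mean([self.fraction(f) for f in self.reference_fractions]))


def normalize_profile(p: GradientProfile) -> GradientProfile:
    """Divide every fraction by the mean intensity of the anchor fractions.

    The anchor-fraction average of the output is 1 by construction.  A zero
    anchor mean is a hard error naming the profile.
    """
    ref = p.reference_mean
    if not ref > 0:
        raise ValueError(
            f"zero reference-fraction mean for protein {p.protein_id!r}, "
            f"replicate {p.replicate_id!r}"
        )
    return replace(p, intensities=tuple(v / ref for v in p.intensities))


def occupancy_ratio(num: GradientProfile, den: GradientProfile) -> np.ndarray:
    """Element-wise ratio of two normalized profiles from the same replicate.

    Returns a length-20 array (index 0 = fraction 1); fractions where the
    denominator is zero are NaN (undefined, never imputed).
    """
    if num.replicate_id != den.replicate_id:
        raise ValueError(
            f"replicate mismatch: {num.replicate_id!r} vs {den.replicate_id!r}"
        )
    n = np.asarray(num.intensities, dtype=float)
    d = np.asarray(den.intensities, dtype=float)
    out = np.full(N_FRACTIONS, np.nan)
    ok = d > 0
    out[ok] = n[ok] / d[ok]
    return out


@dataclass(frozen=True)
class GroupStat:
    """Mean/SD of the pooled replicate x fraction ratios of one group."""

    mean: float
    sd: float
    n: int
    n_excluded: int = 0


@dataclass(frozen=True)
class OccupancyTable:
    """Per-fraction ratios (replicates x 20) plus per-group summaries."""

    ratios: tuple[tuple[float, ...], ...]  # one row per replicate
    groups: dict

    def per_fraction_mean(self) -> np.ndarray:
        return np.nanmean(np.asarray(self.ratios, dtype=float), axis=0)


def replicate_stats(
    ratio_tables: list[np.ndarray],
    groups: dict | None = None,
    pool: str = "values",
) -> OccupancyTable:
    """Summarize per-fraction ratios over replicates within fraction groups.

    ``pool="values"`` (default) pools every replicate x fraction value of a
    group before taking mean and SD; ``pool="per_fraction_mean"`` first
    averages each fraction over replicates and then summarizes those means.
    SD uses denominator n-1 and is 0 for n = 1.  Undefined (NaN) ratios are
    excluded and counted.
    """
    if not ratio_tables:
        raise ValueError("need >=1 replicate ratio table")
    if groups is None:
        groups = DEFAULT_GROUPS
    mat = np.vstack([np.asarray(r, dtype=float) for r in ratio_tables])
    stats = {}
    for name, fractions in groups.items():
        idx = [int(f) - 1 for f in fractions]
        if any(i < 0 or i >= N_FRACTIONS for i in idx):
            raise ValueError(f"group {name!r} references fractions outside 1..20")
        if pool == "per_fraction_mean":
            vals = np.nanmean(mat[:, idx], axis=0)
        elif pool == "values":
            vals = mat[:, idx].ravel()
        else:
            raise ValueError(f"unknown pool mode {pool!r}")
        finite = vals[~np.isnan(vals)]
        n_excluded = int(vals.size - finite.size)
        if finite.size == 0:
            stats[name] = GroupStat(float("nan"), float("nan"), 0, n_excluded)
            continue
        mean = float(np.mean(finite))
        sd = 0.0 if finite.size == 1 else float(np.std(finite, ddof=1))
        stats[name] = GroupStat(mean, sd, int(finite.size), n_excluded)
    return OccupancyTable(
        ratios=tuple(tuple(float(v) for v in row) for row in mat), groups=stats
    )


def occupancy_from_profiles(
    profiles: list[GradientProfile],
    numerator_id: str,
    denominator_id: str,
    groups: dict | None = None,
    pool: str = "values",
) -> OccupancyTable:
    """Full pipeline: anchor-normalize, ratio per replicate, summarize.

    ``profiles`` holds both proteins for every replicate; replicates are
    matched by ``replicate_id`` and processed in sorted replicate order.
    """
    by_rep: dict[str, dict[str, GradientProfile]] = {}
    for p in profiles:
        by_rep.setdefault(p.replicate_id, {})[p.protein_id] = p
    tables = []
    for rep in sorted(by_rep):
        pair = by_rep[rep]
        if numerator_id not in pair or denominator_id not in pair:
            raise ValueError(
                f"replicate {rep!r} lacks a profile for "
                f"{numerator_id!r} or {denominator_id!r}"
            )
        num = normalize_profile(pair[numerator_id])
        den = normalize_profile(pair[denominator_id])
        tables.append(occupancy_ratio(num, den))
    return replicate_stats(tables, groups=groups, pool=pool)


def read_gradient_table(path) -> list[GradientProfile]:
    """Read a TSV with columns protein_id, replicate_id, f1..f20."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "replicate_id": str})
    cols = [f"f{i}" for i in range(1, N_FRACTIONS + 1)]
    missing = [c for c in ["protein_id", "replicate_id", *cols] if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return [
        GradientProfile(
            protein_id=row["protein_id"],
            replicate_id=row["replicate_id"],
            intensities=tuple(float(row[c]) for c in cols),
        )
        for _, row in df.iterrows()
    ]


def write_gradient_table(profiles: list[GradientProfile], path) -> None:
    cols = [f"f{i}" for i in range(1, N_FRACTIONS + 1)]
    rows = [
        {"protein_id": p.protein_id, "replicate_id": p.replicate_id,
         **{c: v for c, v in zip(cols, p.intensities)}}
        for p in profiles
    ]
    pd.DataFrame(rows, columns=["protein_id", "replicate_id", *cols]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
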