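"""Control-referenced log2 enrichment scoring and cross-assay summaries.

Each protein detected in a bait purification gets an enrichment score::

    log2_enrichment = log2(normalized bait abundance)
                      - aggregate( log2(normalized reference abundances) )

under one of three reference schemes:

``paired_controls``
    Reference = the two localization-matched reporter controls of the series
    (GFP-ligase and NLS-GFP-ligase); aggregator = mean of the log2 values.
``pooled_median``
    Reference = the controls plus the bait runs of the remaining baits of the
    same series (used for the dedicated-chaperone series); aggregator =
    median.  Baits may be reciprocally excluded from each other's reference
    (e.g. two cooperating chaperones that share genuine neighbours would
    otherwise cancel each other's signal).
``replicate_averaged``
    Replicated design (HeLa miniTurbo): per protein, the *linear* mean over
    non-missing bait replicates and over control replicates is taken first,
    then the log2 difference.

The plotted pair for each protein is (normalized abundance on a log10 scale,
log2 enrichment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .normalize import NormalizedMatrix
from .quant_io import RunMeta

__all__ = [
    "ReferenceScheme",
    "EnrichmentRecord",
    "AssaySummary",
    "build_reference",
    "compute_enrichment",
    "aggregate_replicates",
    "summarize_across_assays",
    "rank_candidates",
]

VARIANTS = ("paired_controls", "pooled_median", "replicate_averaged")
_VARIANT_AGGREGATOR = {
    "paired_controls": "mean",
    "pooled_median": "median",
    "replicate_averaged": "mean",
}


@dataclass(frozen=True)
class ReferenceScheme:
    """How a bait's reference run set is assembled.

    ``exclusions`` maps a bait to the set of other baits whose runs are
    removed from its pooled reference (only meaningful for
    ``pooled_median``).
    """

    variant: str
    control_run_ids: tuple[str, ...]
    candidate_bait_ids: tuple[str, ...] = ()
    exclusions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        object.__setattr__(self, "control_run_ids", tuple(self.control_run_ids))
        object.__setattr__(self, "candidate_bait_ids", tuple(self.candidate_bait_ids))

    @property
    def aggregator(self) -> str:
        return _VARIANT_AGGREGATOR[self.variant]


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per protein per bait: plotted abundance and log2 enrichment."""

    protein_id: str
    bait: str
    normalized_abundance: float
    log2_enrichment: float
    n_reference_runs: int
    any_imputed_reference: bool
    gene_name: str = ""

    def __post_init__(self) -> None:
        if not (self.normalized_abundance > 0):
            raise ValueError("normalized_abundance must be > 0 for emitted records")

    @property
    def log10_abundance(self) -> float:
        return math.log10(self.normalized_abundance)


@dataclass(frozen=True)
class AssaySummary:
    """Distribution of one protein's enrichment across assays (boxplot stats)."""

    protein_id: str
    enrichments: tuple[float, ...]
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    outliers: tuple[float, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def build_reference(
    meta: list[RunMeta], scheme: ReferenceScheme, bait: str
) -> list[str]:
    """Return the ordered reference run-id list for ``bait``.

    The bait's own run(s) are never part of its reference; for
    ``pooled_median`` the runs of excluded baits are removed as well.  An
    empty result is a hard error.
    """
    by_id = {m.run_id: m for m in meta}
    if not any(m.bait_name == bait and m.role == "bait" for m in meta):
        raise ValueError(f"bait {bait!r} not present in run metadata")
    own = {m.run_id for m in meta if m.bait_name == bait and m.role == "bait"}

    ref: list[str] = [r for r in scheme.control_run_ids if r not in own]
    if scheme.variant == "pooled_median":
        excluded_baits = set(scheme.exclusions.get(bait, ())) | {bait}
        for m in meta:  # metadata order keeps the result deterministic
            if (
                m.role == "bait"
                and m.bait_name in scheme.candidate_bait_ids
                and m.bait_name not in excluded_baits
                and m.run_id not in ref
            ):
                ref.append(m.run_id)
    for r in ref:
        if r not in by_id:
            raise ValueError(f"reference run {r!r} missing from metadata")
    if not ref:
        raise ValueError(f"empty reference set for bait {bait!r}")
    return ref


def compute_enrichment(
    nm: NormalizedMatrix,
    bait_runs: list[str],
    reference_runs: list[str],
    aggregator: str = "mean",
    bait: str = "",
) -> tuple[list[EnrichmentRecord], int]:
    """Score every protein observed in the bait run(s) against a reference.

    Returns ``(records, n_dropped)`` where ``n_dropped`` counts proteins that
    were observed in the bait but had no usable reference value (can only
    happen if imputation of the reference runs was skipped).

    Only *observed* bait values count as detections (imputed bait cells do
    not create records); reference values may be observed or imputed, and
    ``any_imputed_reference`` reports whether any imputed one entered the
    aggregate.  With several bait runs the bait term is the mean of the log2
    observed bait values.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    for r in list(bait_runs) + list(reference_runs):
        if r not in nm.values.columns:
            raise ValueError(f"run {r!r} not in matrix")
    agg = np.mean if aggregator == "mean" else np.median
    bait_name = bait or (bait_runs[0] if bait_runs else "")
    observed = nm.observed()
    records: list[EnrichmentRecord] = []
    n_dropped = 0
    for pid in nm.values.index:
        bait_vals = [
            float(nm.values.at[pid, r]) for r in bait_runs if bool(observed.at[pid, r])
        ]
        if not bait_vals:
            continue
        ref_vals = []
        ref_imputed = False
        for r in reference_runs:
            v = nm.values.at[pid, r]
            if not np.isnan(v):
                ref_vals.append(float(v))
                ref_imputed = ref_imputed or bool(nm.imputed.at[pid, r])
        if not ref_vals:
            n_dropped += 1
            continue
        log2_bait = float(np.mean(np.log2(bait_vals)))
        log2_ref = float(agg(np.log2(ref_vals)))
        abundance = float(np.exp2(log2_bait)) if len(bait_vals) > 1 else bait_vals[0]
        records.append(
            EnrichmentRecord(
                protein_id=str(pid),
                bait=bait_name,
                normalized_abundance=abundance,
                log2_enrichment=log2_bait - log2_ref,
                n_reference_runs=len(ref_vals),
                any_imputed_reference=ref_imputed,
                gene_name=str(nm.gene_names.at[pid]),
            )
        )
    return records, n_dropped


def aggregate_replicates(
    nm: NormalizedMatrix,
    meta: list[RunMeta],
    bait: str,
    controls: list[str] | None = None,
) -> list[EnrichmentRecord]:
    """Replicate-averaged scoring (miniTurbo / HeLa mode).

    Per protein, the linear mean over the non-missing bait replicates and
    over the control replicates is computed *before* the log2 transform, then
    the two log2 values are differenced -- averaging {1, 4} scores
    ``log2(2.5)``, not 1.  A protein missing in every bait replicate is
    dropped.
    """
    bait_runs = [m.run_id for m in meta if m.bait_name == bait and m.role == "bait"]
    if controls is None:
        controls = [m.run_id for m in meta if m.role == "control"]
    if not bait_runs or not controls:
        raise ValueError("need >=1 bait replicate and >=1 control replicate")
    observed = nm.observed()
    records: list[EnrichmentRecord] = []
    for pid in nm.values.index:
        bait_vals = [
            float(nm.values.at[pid, r]) for r in bait_runs if bool(observed.at[pid, r])
        ]
        if not bait_vals:
            continue
        ref_vals = []
        ref_imputed = False
        for r in controls:
            v = nm.values.at[pid, r]
            if not np.isnan(v):
                ref_vals.append(float(v))
                ref_imputed = ref_imputed or bool(nm.imputed.at[pid, r])
        if not ref_vals:
            continue
        mean_bait = float(np.mean(bait_vals))
        mean_ref = float(np.mean(ref_vals))
        records.append(
            EnrichmentRecord(
                protein_id=str(pid),
                bait=bait,
                normalized_abundance=mean_bait,
                log2_enrichment=math.log2(mean_bait) - math.log2(mean_ref),
                n_reference_runs=len(ref_vals),
                any_imputed_reference=ref_imputed,
                gene_name=str(nm.gene_names.at[pid]),
            )
        )
    return records


def summarize_across_assays(
    tables: dict[str, list[EnrichmentRecord]],
    proteins: list[str] | None = None,
    whisker: float = 1.5,
) -> list[AssaySummary]:
    """Boxplot-style summary of each protein's enrichment across assays.

    Quantiles use linear interpolation between order statistics; outliers are
    values beyond ``whisker`` x IQR from the quartiles (Tukey rule).  Assay
    order does not affect the result.
    """
    per_protein: dict[str, list[float]] = {}
    for assay in tables:
        for rec in tables[assay]:
            per_protein.setdefault(rec.protein_id, []).append(rec.log2_enrichment)
    if proteins is None:
        proteins = sorted(per_protein)
    out = []
    for pid in proteins:
        vals = per_protein.get(pid)
        if not vals:
            raise ValueError(f"protein {pid!r} present in no assay")
        arr = np.sort(np.asarray(vals, dtype=float))
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
        lo, hi = q1 - whisker * (q3 - q1), q3 + whisker * (q3 - q1)
        outliers = tuple(float(v) for v in arr if v < lo or v > hi)
        out.append(
            AssaySummary(
                protein_id=pid,
                enrichments=tuple(float(v) for v in arr),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                minimum=float(arr[0]),
                maximum=float(arr[-1]),
                outliers=outliers,
            )
        )
    return out


def rank_candidates(
    records: list[EnrichmentRecord],
    min_enrichment: float = 0.0,
    min_abundance: float = 0.0,
    exclude_flagged: bool = False,
    flags=None,
) -> list[EnrichmentRecord]:
    """Threshold and order records for candidate selection.

    Sort: descending log2 enrichment, ties by descending abundance, then
    protein id.  With ``exclude_flagged`` and a flags DataFrame, contaminant
    and endogenous-biotin proteins are removed first.
    """
    kept = [
        r
        for r in records
        if r.log2_enrichment >= min_enrichment and r.normalized_abundance >= min_abundance
    ]
    if exclude_flagged and flags is not None:
        bad = set(
            flags.index[flags["contaminant"] | flags["endogenous_biotin"]].astype(str)
        )
        kept = [r for r in kept if r.protein_id not in bad]
    return sorted(
        kept,
        key=lambda r: (-r.log2_enrichment, -r.normalized_abundance, r.protein_id),
    )
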