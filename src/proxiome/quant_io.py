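"""Reading, validating, filtering and writing protein-group intensity tables.

The central object is :class:`IntensityMatrix`, a proteins x runs table of
non-negative iBAQ intensities with an explicit missing marker (``NaN``).
MaxQuant-style tables record a value of 0 for "not detected"; on ingest every
zero is converted to the missing marker, matching the downstream convention
that run medians are taken over nonzero values only.

Run design (which columns are bait purifications, which are controls, how
runs group into experimental series) lives in a YAML file parsed into
:class:`RunMeta` records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FLAG_COLUMNS",
    "DEFAULT_ENDOGENOUS_BIOTIN_GENES",
    "IntensityMatrix",
    "RunMeta",
    "load_run_config",
    "read_intensity_table",
    "write_intensity_table",
    "filter_proteins",
    "write_enrichment_table",
    "read_enrichment_table",
]

FLAG_COLUMNS = ("contaminant", "decoy", "endogenous_biotin")

#: Proteins biotinylated by the endogenous yeast biotin ligase Bpl1; they are
#: recovered in every streptavidin purification irrespective of the bait and
#: are therefore flagged on ingest (Acc1/Hfa1, Arc1, Dur1,2, Pyc1/Pyc2).
DEFAULT_ENDOGENOUS_BIOTIN_GENES = frozenset(
    {"ACC1", "HFA1", "ARC1", "DUR1,2", "DUR12", "PYC1", "PYC2"}
)


@dataclass(frozen=True)
class RunMeta:
    """Design metadata for one purification run.

    Parameters
    ----------
    run_id : str
        Unique run identifier; by default also the intensity column name.
    bait_name : str
        Name of the TurboID/miniTurbo-fused bait (for controls, the reporter
        name, e.g. ``GFP``).
    tag_terminus : str
        ``"N"`` or ``"C"`` -- which terminus carries the biotin ligase.
    role : str
        ``"bait"`` or ``"control"``.
    series_id : str
        Experimental series the run belongs to (controls are shared within a
        series).
    replicate_index : int
        1-based replicate number.
    mode : str
        ``"yeast"`` (single replicate per bait, paired controls) or ``"hela"``
        (replicate-averaged scoring).
    column : str
        Name of the intensity column in the source table (defaults to
        ``run_id``).
    """

    run_id: str
    bait_name: str
    tag_terminus: str = "C"
    role: str = "bait"
    series_id: str = "series1"
    replicate_index: int = 1
    mode: str = "yeast"
    column: str = ""

    def __post_init__(self) -> None:
        if self.tag_terminus not in ("N", "C"):
            raise ValueError(f"tag_terminus must be 'N' or 'C', got {self.tag_terminus!r}")
        if self.role not in ("bait", "control"):
            raise ValueError(f"role must be 'bait' or 'control', got {self.role!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be a positive integer")
        if not self.column:
            object.__setattr__(self, "column", self.run_id)


@dataclass
class IntensityMatrix:
    """Proteins x runs table of non-negative intensities with missing markers.

    ``values`` is a float DataFrame indexed by unique protein ids with one
    column per run; missing measurements are ``NaN``.  ``flags`` is a boolean
    DataFrame with columns ``contaminant``, ``decoy`` and
    ``endogenous_biotin`` aligned to the same index.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    gene_names: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_names is None:
            self.gene_names = pd.Series("", index=self.values.index, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate run identifiers")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative intensity at protein {idx[r]!r}, run {self.values.columns[c]!r}"
            )
        for col in FLAG_COLUMNS:
            if col not in self.flags.columns:
                raise ValueError(f"missing flag column {col!r}")
        if not self.flags.index.equals(idx) or not self.gene_names.index.equals(idx):
            raise ValueError("flags/gene_names not aligned to protein ids")

    # -- convenience -----------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def runs(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.values.index)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.flags.copy(), self.gene_names.copy()
        )


def load_run_config(path) -> list[RunMeta]:
    """Parse a YAML run-metadata file into a list of :class:`RunMeta`.

    Expected layout::

        runs:
          - run_id: Rpl3_TurboID
            bait: Rpl3
            terminus: C
            role: bait
            series: yeast_C
            replicate: 1
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = doc["runs"] if isinstance(doc, dict) else doc
    metas = []
    for e in entries:
        metas.append(
            RunMeta(
                run_id=str(e["run_id"]),
                bait_name=str(e.get("bait", e.get("bait_name", ""))),
                tag_terminus=str(e.get("terminus", e.get("tag_terminus", "C"))),
                role=str(e.get("role", "bait")),
                series_id=str(e.get("series", e.get("series_id", "series1"))),
                replicate_index=int(e.get("replicate", e.get("replicate_index", 1))),
                mode=str(e.get("mode", "yeast")),
                column=str(e.get("column", "")),
            )
        )
    _check_meta(metas)
    return metas


def _check_meta(metas: list[RunMeta]) -> None:
    ids = [m.run_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate run_id in run metadata")
    series: dict[str, list[RunMeta]] = {}
    for m in metas:
        series.setdefault(m.series_id, []).append(m)
    for sid, ms in series.items():
        if not any(m.role == "control" for m in ms):
            raise ValueError(f"series {sid!r} has no control run")


def read_intensity_table(
    path,
    run_config,
    endogenous_biotin_genes=DEFAULT_ENDOGENOUS_BIOTIN_GENES,
) -> tuple[IntensityMatrix, list[RunMeta]]:
    """Read a protein-group TSV plus run-metadata YAML.

    The TSV must carry ``protein_id`` plus one intensity column per configured
    run; optional columns: ``gene_name`` and the flag columns (values ``+`` or
    ``1``/``true`` mark the flag).  Zeros become missing markers; negative
    values are a hard error naming the offending cell.
    """
    if isinstance(run_config, list):
        metas = run_config
        _check_meta(metas)
    else:
        metas = load_run_config(run_config)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise ValueError("missing required column 'protein_id'")
    for m in metas:
        if m.column not in df.columns:
            raise ValueError(f"missing run column {m.column!r} (run {m.run_id!r})")
    if df["protein_id"].duplicated().any():
        dups = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValueError(f"duplicate protein ids: {dups}")
    df = df.set_index("protein_id")

    values = pd.DataFrame(index=df.index)
    for m in metas:
        col = pd.to_numeric(df[m.column], errors="raise").astype(float)
        neg = col[col < 0]
        if len(neg):
            raise ValueError(
                f"negative intensity {neg.iloc[0]!r} at protein "
                f"{neg.index[0]!r}, column {m.column!r}"
            )
        values[m.run_id] = col.replace(0.0, np.nan)

    flags = pd.DataFrame(False, index=df.index, columns=list(FLAG_COLUMNS))
    for col in ("contaminant", "decoy"):
        if col in df.columns:
            flags[col] = df[col].map(_truthy).astype(bool)
    gene_names = (
        df["gene_name"].fillna("").astype(str)
        if "gene_name" in df.columns
        else pd.Series("", index=df.index, dtype=object)
    )
    biotin_genes = {g.upper() for g in endogenous_biotin_genes}
    flags["endogenous_biotin"] = gene_names.str.upper().isin(biotin_genes)
    if "endogenous_biotin" in df.columns:
        flags["endogenous_biotin"] |= df["endogenous_biotin"].map(_truthy).astype(bool)

    return IntensityMatrix(values, flags, gene_names), metas


def _truthy(v) -> bool:
    if isinstance(v, str):
        return v.strip() in ("+", "1", "true", "True", "yes")
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return False
    return bool(v)


def write_intensity_table(m: IntensityMatrix, path) -> None:
    """Write an :class:`IntensityMatrix` back to TSV (missing written as 0).

    Values are formatted with 6 significant digits; read_intensity_table of
    the output reproduces the matrix up to that formatting.
    """
    out = pd.DataFrame(index=m.values.index)
    out.index.name = "protein_id"
    out["gene_name"] = m.gene_names
    for col in FLAG_COLUMNS:
        out[col] = np.where(m.flags[col], "+", "")
    for run in m.runs:
        out[run] = m.values[run].fillna(0.0)
    out.to_csv(path, sep="\t", float_format="%.6g")


def filter_proteins(
    m: IntensityMatrix,
    drop_contaminants: bool = False,
    drop_decoys: bool = False,
    drop_endogenous_biotin: bool = False,
) -> IntensityMatrix:
    """Return a new matrix without the proteins whose selected flags are set.

    The input is left untouched; surviving rows keep their values verbatim.
    """
    keep = pd.Series(True, index=m.values.index)
    if drop_contaminants:
        keep &= ~m.flags["contaminant"]
    if drop_decoys:
        keep &= ~m.flags["decoy"]
    if drop_endogenous_biotin:
        keep &= ~m.flags["endogenous_biotin"]
    return IntensityMatrix(
        m.values.loc[keep].copy(), m.flags.loc[keep].copy(), m.gene_names.loc[keep].copy()
    )


ENRICHMENT_COLUMNS = (
    "protein_id",
    "gene_name",
    "bait",
    "normalized_abundance",
    "log10_abundance",
    "log2_enrichment",
    "n_reference_runs",
    "any_imputed_reference",
)


def write_enrichment_table(records, path) -> None:
    """Write enrichment records as TSV with a fixed column order.

    Rows are sorted by descending log2 enrichment, ties broken by protein id,
    so output is deterministic for diffing.
    """
    rows = [
        {
            "protein_id": r.protein_id,
            "gene_name": r.gene_name,
            "bait": r.bait,
            "normalized_abundance": r.normalized_abundance,
            "log10_abundance": r.log10_abundance,
            "log2_enrichment": r.log2_enrichment,
            "n_reference_runs": r.n_reference_runs,
            "any_imputed_reference": r.any_imputed_reference,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS))
    if len(df):
        df = df.sort_values(
            ["log2_enrichment", "protein_id"], ascending=[False, True]
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_enrichment_table(path):
    """Read back a table written by :func:`write_enrichment_table`."""
    from .enrichment import EnrichmentRecord

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_name": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            EnrichmentRecord(
                protein_id=row["protein_id"],
                gene_name="" if pd.isna(row["gene_name"]) else str(row["gene_name"]),
                bait=row["bait"],
                normalized_abundance=float(row["normalized_abundance"]),
                log2_enrichment=float(row["log2_enrichment"]),
                n_reference_runs=int(row["n_reference_runs"]),
                any_imputed_reference=bool(row["any_imputed_reference"]),
            )
        )
    return records
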