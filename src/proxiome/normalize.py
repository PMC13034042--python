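"""Per-run median normalization and left-censored Gaussian imputation.

Normalization: every intensity is divided by the median of the nonzero
(observed) intensities of its own run, so the bulk of the proteome sits at a
normalized abundance of 1 regardless of purification yield or injection
amount.  This removes per-run scale exactly, which is what makes downstream
log2 enrichment invariant to multiplying any run by a positive constant.

Imputation: streptavidin-capture proteomics data are missing not at random --
values are absent preferentially below the detection limit.  Missing values
in designated runs (by default the control purifications) are therefore drawn
from a down-shifted, shrunken Gaussian fitted per run in log2 space:
``Normal(mu - d*sigma, (w*sigma)^2)`` with defaults ``w = 0.3``, ``d = 1.8``
-- the canonical "width"/"down shift" defaults of the Perseus software family.
Both parameters are configurable and recorded alongside the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant_io import IntensityMatrix

__all__ = ["ImputationParams", "NormalizedMatrix", "median_normalize", "impute_missing"]

MEDIAN_TOL = 1e-12


@dataclass(frozen=True)
class ImputationParams:
    """Left-censored imputation settings.

    width
        Multiplier of the per-run log2 SD used as the SD of the imputation
        distribution (unitless, >= 0).
    downshift
        Shift of the imputation mean below the per-run log2 mean, in per-run
        log2-SD units (unitless, >= 0).
    target_runs
        Runs whose missing cells are imputed (typically the controls).
    seed
        Integer seed of the dedicated random generator; with protein and run
        order fixed by the matrix, results are platform-reproducible.
    """

    target_runs: tuple[str, ...]
    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 0 or self.downshift < 0:
            raise ValueError("width and downshift must be >= 0")
        object.__setattr__(self, "target_runs", tuple(self.target_runs))


@dataclass
class NormalizedMatrix:
    """Median-normalized intensity matrix with per-cell provenance.

    ``imputed`` is a boolean DataFrame (same shape as ``values``) marking
    cells filled by :func:`impute_missing`; observed cells are never altered.
    ``run_medians`` records the per-run nonzero median of the *input* (the
    divisor); after normalization the observed nonzero median of every run is
    1 within 1e-12 (checked, the normalization certificate).
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    run_medians: pd.Series
    flags: pd.DataFrame = None  # type: ignore[assignment]
    gene_names: pd.Series = None  # type: ignore[assignment]
    imputation: ImputationParams | None = None

    def __post_init__(self) -> None:
        if self.flags is None:
            from .quant_io import FLAG_COLUMNS

            self.flags = pd.DataFrame(
                False, index=self.values.index, columns=list(FLAG_COLUMNS)
            )
        if self.gene_names is None:
            self.gene_names = pd.Series("", index=self.values.index, dtype=object)

    @property
    def runs(self) -> list[str]:
        return list(self.values.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    def observed(self) -> pd.DataFrame:
        """Boolean mask of cells that are present and not imputed."""
        return self.values.notna() & ~self.imputed

    def certificate(self) -> pd.Series:
        """Per-run nonzero median over observed values (should all be 1)."""
        masked = self.values.where(self.observed())
        return masked.median(axis=0, skipna=True)


def median_normalize(m: IntensityMatrix) -> NormalizedMatrix:
    """Divide each run by the median of its nonzero observed intensities.

    Missing cells stay missing.  A run with no observed value is a hard error
    naming the run.
    """
    medians = {}
    for run in m.runs:
        col = m.values[run]
        obs = col.dropna()
        if obs.empty:
            raise ValueError(f"run {run!r} has no observed (nonzero) values")
        medians[run] = float(np.median(obs.to_numpy()))
    med = pd.Series(medians, dtype=float).reindex(m.values.columns)
    values = m.values.div(med, axis=1)
    nm = NormalizedMatrix(
        values=values,
        imputed=pd.DataFrame(False, index=values.index, columns=values.columns),
        run_medians=med,
        flags=m.flags.copy(),
        gene_names=m.gene_names.copy(),
    )
    cert = nm.certificate()
    if (cert - 1.0).abs().max() > MEDIAN_TOL:
        raise AssertionError(f"normalization certificate violated: {cert.to_dict()}")
    return nm


def impute_missing(nm: NormalizedMatrix, p: ImputationParams) -> NormalizedMatrix:
    """Fill missing cells of the target runs from a down-shifted Gaussian.

    Per target run: mu and sigma (denominator n-1) of the log2 of observed
    values; each missing cell draws independently from
    ``Normal(mu - downshift*sigma, (width*sigma)^2)`` in log2 space and is
    back-transformed.  Runs are processed in matrix column order and cells in
    protein order, so draws are reproducible from the seed alone.
    """
    unknown = set(p.target_runs) - set(nm.runs)
    if unknown:
        raise ValueError(f"target runs not in matrix: {sorted(unknown)}")
    values = nm.values.copy()
    imputed = nm.imputed.copy()
    rng = np.random.default_rng(p.seed)
    targets = set(p.target_runs)
    for run in nm.runs:  # matrix column order, not caller order
        if run not in targets:
            continue
        col = values[run]
        obs = col.dropna().to_numpy(dtype=float)
        if obs.size < 3:
            raise ValueError(
                f"run {run!r} has {obs.size} observed values; >=3 required to fit mu, sigma"
            )
        log2_obs = np.log2(obs)
        mu = float(np.mean(log2_obs))
        sigma = float(np.std(log2_obs, ddof=1))
        missing = col.index[col.isna()]
        if len(missing) == 0:
            continue
        draws = rng.normal(mu - p.downshift * sigma, p.width * sigma, size=len(missing))
        values.loc[missing, run] = np.exp2(draws)
        imputed.loc[missing, run] = True
    return NormalizedMatrix(
        values=values,
        imputed=imputed,
        run_medians=nm.run_medians.copy(),
        flags=nm.flags.copy(),
        gene_names=nm.gene_names.copy(),
        imputation=p,
    )
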