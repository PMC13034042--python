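"""Seeded generators for TurboID-like intensity matrices and gradient bands.

Both generators produce data with the statistical structure the analysis
assumes, together with the ground truth needed to verify recovery.

TurboID series
    Protein base abundances are log-normal; each run multiplies them by a
    run-specific scale factor, by 2**effect (bait self-labelling, configured
    log2 effects for proximal proteins, a constant boost for the endogenously
    biotinylated background proteins), and by 2**noise.  Missingness is
    intensity-dependent (left-censored): ``P(missing | x) =
    1/(1 + exp((log2 x - tau)/s))``, the regime that justifies down-shifted
    imputation.  Bait, proximal and endogenous-biotin roles are assigned to
    proteins whose base abundance lies above the cohort median, the regime
    median normalization assumes (the bulk of the proteome is unaffected
    background, so the per-run median is identical across runs and the
    configured effects are recovered exactly in the noise-free case).

Sucrose gradient
    Four component templates over 20 fractions (free pool, 60S, 80S,
    polysomes).  The denominator protein (e.g. Rpl4) carries every component;
    the numerator (e.g. Rpl1) carries each ribosomal component scaled by a
    per-component occupancy theta.  Polysomal occupancy defaults to 1 --
    translating ribosomes are assumed fully co-occupied, which is exactly the
    anchoring assumption of the analysis.  Each band gets multiplicative
    log-normal noise of the configured CV, and each profile a random blot
    exposure factor (which the analysis must cancel).

Draw order is fixed (proteins, then runs, then per-run cells), so a given
seed yields identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .gradient import N_FRACTIONS, GradientProfile
from .quant_io import FLAG_COLUMNS, IntensityMatrix, RunMeta

__all__ = [
    "TurboidSimConfig",
    "SimTruth",
    "simulate_turboid_series",
    "GradientSimConfig",
    "GradientSimTruth",
    "simulate_gradient",
    "DEFAULT_TEMPLATES",
]


@dataclass(frozen=True)
class TurboidSimConfig:
    """Design and distributional parameters of a simulated TurboID series.

    The default design mirrors a yeast series: one run per bait plus two
    reporter controls.  ``delta`` is the log2 effect of a proximal protein in
    its bait's run; ``bait_self_effect`` the bait's own self-labelling boost.
    ``tau``/``slope`` parametrize the logistic left-censoring midpoint and
    width on the log2-intensity scale; ``tau=None`` disables missingness.
    """

    n_proteins: int = 2000
    baits: tuple[str, ...] = ("Bait1", "Bait2", "Bait3", "Bait4", "Bait5")
    controls: tuple[str, ...] = ("ctrl_GFP", "ctrl_NLS_GFP")
    n_proximal_per_bait: int = 10
    delta: float = 6.0
    bait_self_effect: float = 8.0
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.5
    scale_log2_range: tuple[float, float] = (-1.0, 1.0)
    noise_sd: float = 0.5
    tau: float | None = 14.8
    slope: float = 1.0
    n_endogenous_biotin: int = 4
    biotin_boost_log2: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not self.baits:
            raise ValueError("need >= 1 bait")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        needed = len(self.baits) * (1 + self.n_proximal_per_bait) + self.n_endogenous_biotin
        if needed > self.n_proteins // 2:
            raise ValueError(
                "design needs more effect-bearing proteins than fit in the "
                "above-median half of the proteome"
            )
        object.__setattr__(self, "baits", tuple(self.baits))
        object.__setattr__(self, "controls", tuple(self.controls))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated TurboID series.

    ``expected_log2_enrichment`` is a proteins x baits DataFrame: delta for
    proximal proteins, the self-effect for the bait's own protein, 0
    otherwise (the endogenous-biotin boost applies to every run equally and
    cancels).
    """

    proximal: dict
    bait_protein: dict
    biotin_proteins: tuple[str, ...]
    expected_log2_enrichment: pd.DataFrame
    scale_log2: pd.Series
    seed: int


def simulate_turboid_series(
    cfg: TurboidSimConfig,
) -> tuple[IntensityMatrix, list[RunMeta], SimTruth]:
    """Generate an intensity matrix, run metadata and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(1, n + 1)]

    # 1. proteins: base abundances (log2 scale)
    base_log2 = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n)

    # Roles are assigned among strictly-above-median proteins so configured
    # effects never move a run's median (see module docstring).
    median_base = float(np.median(base_log2))
    eligible = np.flatnonzero(base_log2 > median_base)
    n_roles = len(cfg.baits) * (1 + cfg.n_proximal_per_bait) + cfg.n_endogenous_biotin
    chosen = rng.choice(eligible, size=n_roles, replace=False)
    pos = 0
    bait_protein: dict[str, str] = {}
    proximal: dict[str, dict[str, float]] = {}
    for b in cfg.baits:
        bait_protein[b] = protein_ids[chosen[pos]]
        pos += 1
    for b in cfg.baits:
        prox_idx = chosen[pos : pos + cfg.n_proximal_per_bait]
        pos += cfg.n_proximal_per_bait
        proximal[b] = {protein_ids[i]: cfg.delta for i in prox_idx}
    biotin_idx = chosen[pos : pos + cfg.n_endogenous_biotin]
    biotin_proteins = tuple(protein_ids[i] for i in biotin_idx)

    # 2. runs: scale factors (bait runs first, then controls)
    run_ids = [f"{b}_run" for b in cfg.baits] + list(cfg.controls)
    lo, hi = cfg.scale_log2_range
    scale_log2 = rng.uniform(lo, hi, size=len(run_ids))

    # per-run log2 effect matrix
    effect = np.zeros((n, len(run_ids)))
    id_index = {p: i for i, p in enumerate(protein_ids)}
    for j, b in enumerate(cfg.baits):
        effect[id_index[bait_protein[b]], j] += cfg.bait_self_effect
        for p, d in proximal[b].items():
            effect[id_index[p], j] += d
    for p in biotin_proteins:
        effect[id_index[p], :] += cfg.biotin_boost_log2

    # 3. cells: per run, noise then missingness (protein order)
    values = np.empty((n, len(run_ids)))
    for j in range(len(run_ids)):
        noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
        log2_v = base_log2 + scale_log2[j] + effect[:, j] + noise
        values[:, j] = np.exp2(log2_v)
        if cfg.tau is not None:
            # logistic left-censoring; expit avoids overflow at extreme tau
            p_miss = expit((cfg.tau - log2_v) / cfg.slope)
            miss = rng.uniform(size=n) < p_miss
            if miss.all():
                raise ValueError(
                    f"left-censoring removed every value of run {run_ids[j]!r} "
                    f"(tau={cfg.tau}, slope={cfg.slope})"
                )
            values[miss, j] = np.nan

    vdf = pd.DataFrame(values, index=protein_ids, columns=run_ids)
    flags = pd.DataFrame(False, index=vdf.index, columns=list(FLAG_COLUMNS))
    flags.loc[list(biotin_proteins), "endogenous_biotin"] = True
    gene_names = pd.Series(protein_ids, index=vdf.index, dtype=object)
    for b in cfg.baits:
        gene_names.at[bait_protein[b]] = b
    matrix = IntensityMatrix(vdf, flags, gene_names)

    meta = [
        RunMeta(run_id=f"{b}_run", bait_name=b, role="bait", series_id="sim")
        for b in cfg.baits
    ] + [
        RunMeta(run_id=c, bait_name=c, role="control", series_id="sim")
        for c in cfg.controls
    ]

    expected = pd.DataFrame(0.0, index=protein_ids, columns=list(cfg.baits))
    for b in cfg.baits:
        expected.loc[bait_protein[b], b] = cfg.bait_self_effect
        for p, d in proximal[b].items():
            expected.loc[p, b] = d
    truth = SimTruth(
        proximal=proximal,
        bait_protein=bait_protein,
        biotin_proteins=biotin_proteins,
        expected_log2_enrichment=expected,
        scale_log2=pd.Series(scale_log2, index=run_ids),
        seed=cfg.seed,
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# Sucrose gradient
# ---------------------------------------------------------------------------

def _template(entries: dict[int, float]) -> tuple[float, ...]:
    t = [0.0] * N_FRACTIONS
    for f, v in entries.items():
        t[f - 1] = v
    return tuple(t)


#: Component shapes over the 20 fractions: free pool near the top, the free
#: 60S peak, the 80S monosome peak, and the polysomal region.  Supports are
#: disjoint so each diagnostic fraction reports a single particle class.
DEFAULT_TEMPLATES = {
    "free": _template({1: 4.0, 2: 3.0, 3: 1.5, 4: 0.5}),
    "60S": _template({8: 0.6, 9: 3.0}),
    "80S": _template({10: 4.0, 11: 2.5}),
    "polysomes": _template(
        {12: 1.0, 13: 2.5, 14: 2.5, 15: 2.0, 16: 1.2, 17: 0.8, 18: 0.5, 19: 0.3, 20: 0.2}
    ),
}


@dataclass(frozen=True)
class GradientSimConfig:
    """Occupancies, noise and replication of a simulated gradient experiment.

    ``theta`` maps component name to the fraction of denominator-bearing
    particles of that component that also carry the numerator protein; the
    free-pool entry scales the numerator's own free pool.  ``noise_cv`` is
    the coefficient of variation of the multiplicative log-normal band noise;
    ``exposure_sd`` the log-SD of the per-profile blot-exposure factor.
    """

    theta: dict = field(
        default_factory=lambda: {"free": 1.0, "60S": 1.0, "80S": 1.0, "polysomes": 1.0}
    )
    templates: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    noise_cv: float = 0.10
    exposure_sd: float = 0.2
    n_replicates: int = 2
    numerator_id: str = "Rpl1"
    denominator_id: str = "Rpl4"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, t in self.templates.items():
            if len(t) != N_FRACTIONS or any(v < 0 for v in t):
                raise ValueError(f"template {name!r} invalid")
        for name, th in self.theta.items():
            if name not in self.templates:
                raise ValueError(f"theta for unknown component {name!r}")
            if not (0.0 <= th <= 1.0):
                raise ValueError(f"theta[{name!r}]={th} outside [0, 1]")
        if self.noise_cv < 0 or self.exposure_sd < 0:
            raise ValueError("noise_cv and exposure_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class GradientSimTruth:
    theta: dict
    seed: int


def simulate_gradient(
    cfg: GradientSimConfig,
) -> tuple[list[GradientProfile], GradientSimTruth]:
    """Generate numerator/denominator profiles for each replicate."""
    rng = np.random.default_rng(cfg.seed)
    comp = {k: np.asarray(v, dtype=float) for k, v in cfg.templates.items()}
    den_clean = sum(comp.values())
    num_clean = sum(cfg.theta.get(k, 1.0) * comp[k] for k in comp)
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))  # log-normal, mean 1
    profiles: list[GradientProfile] = []
    for r in range(1, cfg.n_replicates + 1):
        rep = f"rep{r}"
        for pid, clean in ((cfg.numerator_id, num_clean), (cfg.denominator_id, den_clean)):
            exposure = (
                float(np.exp(rng.normal(0.0, cfg.exposure_sd)))
                if cfg.exposure_sd > 0
                else 1.0
            )
            if sigma > 0:
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=N_FRACTIONS))
            else:
                noise = np.ones(N_FRACTIONS)
            profiles.append(
                GradientProfile(
                    protein_id=pid,
                    replicate_id=rep,
                    intensities=tuple(exposure * clean * noise),
                )
            )
    return profiles, GradientSimTruth(theta=dict(cfg.theta), seed=cfg.seed)
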