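import numpy as np
import pandas as pd
import pytest

from proxiome.quant_io import FLAG_COLUMNS, IntensityMatrix, RunMeta


def make_matrix(values: dict, flags: dict | None = None, genes: dict | None = None):
    """Build a small IntensityMatrix from {run: {protein: value}} (None = missing)."""
    vdf = pd.DataFrame(values, dtype=float)
    fdf = pd.DataFrame(False, index=vdf.index, columns=list(FLAG_COLUMNS))
    if flags:
        for col, ids in flags.items():
            fdf.loc[list(ids), col] = True
    gn = pd.Series("", index=vdf.index, dtype=object)
    if genes:
        for pid, g in genes.items():
            gn.at[pid] = g
    return IntensityMatrix(vdf, fdf, gn)


def paired_meta(baits=("Rpl3",), controls=("ctrl_GFP", "ctrl_NLS_GFP")):
    """Yeast-style design: one bait run per bait plus shared controls."""
    meta = [
        RunMeta(run_id=f"{b}_run", bait_name=b, role="bait", series_id="s1")
        for b in baits
    ]
    meta += [
        RunMeta(run_id=c, bait_name=c, role="control", series_id="s1") for c in controls
    ]
    return meta


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def tiny_table(tmp_path):
    """Hand-written 3-protein, 2-run protein-group TSV plus run YAML."""
    tsv = tmp_path / "groups.tsv"
    tsv.write_text(
        "protein_id\tgene_name\tcontaminant\tdecoy\trunA\trunB\n"
        "P1\tRPL3\t\t\t100\t0\n"
        "P2\tKRT1\t+\t\t50\t60\n"
        "P3\tARC1\t\t\t10\t20\n"
    )
    yml = tmp_path / "runs.yaml"
    yml.write_text(
        "runs:\n"
        "  - {run_id: runA, bait: Rpl3, role: bait, series: s1}\n"
        "  - {run_id: runB, bait: GFP, role: control, series: s1}\n"
    )
    return tsv, yml
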