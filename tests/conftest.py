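"""Shared fixtures: small simulated datasets and tiny hand-written tables."""

from __future__ import annotations

import pandas as pd
import pytest

from crosstrait.sumstats_io import VariantTable, harmonize_pair, p_from_z
from crosstrait.synthetic import SimulationConfig, simulate_pair


def make_table(rows: list[dict]) -> VariantTable:
    """Build a validated VariantTable from partial row dicts (z defaults given)."""
    df = pd.DataFrame(rows)
    if "P" not in df.columns:
        df["P"] = p_from_z(df["Z"].to_numpy(float))
    defaults = {"CHR": 1, "N": 10_000.0}
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return VariantTable(df[["SNP", "CHR", "BP", "A1", "A2", "Z", "P", "N"]])


@pytest.fixture(scope="session")
def demo_sim():
    """Mid-sized two-trait simulation under the standard study conditions."""
    config = SimulationConfig(m=20_000, seed=1)
    template, ld, truth, t1, t2, deltas = simulate_pair(config)
    return {
        "config": config,
        "template": template,
        "ld": ld,
        "truth": truth,
        "t1": t1,
        "t2": t2,
        "deltas": deltas,
        "pair": harmonize_pair(t1, t2),
    }


@pytest.fixture(scope="session")
def null_sim():
    """All-null two-trait simulation (no causal variants)."""
    config = SimulationConfig(m=20_000, pis=(1.0, 0.0, 0.0, 0.0), seed=2)
    template, ld, truth, t1, t2, deltas = simulate_pair(config)
    return {
        "config": config,
        "template": template,
        "ld": ld,
        "truth": truth,
        "t1": t1,
        "t2": t2,
        "deltas": deltas,
        "pair": harmonize_pair(t1, t2),
    }
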