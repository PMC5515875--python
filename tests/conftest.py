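"""Shared fixtures: in-memory tracing tables and hand-built compiled conditions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rootplates.compile import CompiledCondition
from rootplates.smartroot_io import (
    FileMeta,
    TracingRecord,
    TracingTable,
    parse_structure_label,
)

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def make_table(condition, day, rows, genotype="Zak", seedling_image_from_label=False):
    """Build a TracingTable from (label, length, plate) tuples.

    On day 2 with ``seedling_image_from_label`` the per-seedling image index
    is taken from the label, mirroring the one-file-per-seedling convention.
    """
    records = []
    for label_text, length, plate in rows:
        label = parse_structure_label(label_text)
        meta = FileMeta(
            condition=condition,
            plate_index=plate,
            day=day,
            genotype=genotype,
            seedling_image=(
                label.seedling_index if (day == 2 and seedling_image_from_label) else None
            ),
            filename=f"20160413 {genotype} wt {condition}{plate} day{day}.csv",
        )
        records.append(TracingRecord(label, length, meta))
    return TracingTable(records, provenance=[f"memory-{condition}-day{day}"])


def compiled_from_values(condition, values, genotype="Zak", seedlings_per_plate=8):
    """Hand-build a CompiledCondition: values[(seedling, structure, day)] = length.

    Every listed cell is 'measured'; use np.nan for occluded and ('absent',)
    semantics are not needed for the stats oracles this serves.
    """
    rows = []
    for (seedling, structure, day), length in sorted(values.items()):
        plate = (seedling - 1) // seedlings_per_plate + 1
        occluded = isinstance(length, float) and np.isnan(length)
        rows.append(
            {
                "plate_index": plate,
                "seedling_index": seedling,
                "structure": structure,
                "day": day,
                "length_mm": np.nan if occluded else float(length),
                "status": "occluded" if occluded else "measured",
                "reason": "missing_record" if occluded else "",
            }
        )
    return CompiledCondition(
        genotype=genotype, condition=condition, data=pd.DataFrame(rows)
    )


@pytest.fixture(scope="session")
def default_experiment():
    """One simulated default experiment (seed 1), compiled for both conditions."""
    import rootplates as rp
    from rootplates import compile as cmod

    tables, truth = rp.simulate_tables(seed=1)
    ww = cmod.compile_condition(*tables["WW"])
    ws = cmod.compile_condition(*tables["WS"])
    return {"tables": tables, "truth": truth, "ww": ww, "ws": ws}


@pytest.fixture(scope="session")
def default_differences(default_experiment):
    from rootplates import stats

    return stats.summary_ws_vs_ww(
        default_experiment["ww"], default_experiment["ws"]
    )
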