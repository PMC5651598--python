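"""Shared fixtures: synthetic chains and matrices built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from rnalcs.synth import A_FORM_TORSIONS, build_chain_from_torsions


def varied_torsion_table(n: int, seed: int = 0) -> list[dict]:
    """Per-residue torsion tables with seeded variation around A-form values,
    so that windows are distinguishable (identical rows would make every
    placement equivalent)."""
    rng = np.random.default_rng(seed)
    table = []
    for _ in range(n):
        row = {
            k: float((v + rng.uniform(-25.0, 25.0) + 180.0) % 360.0 - 180.0)
            for k, v in A_FORM_TORSIONS.items()
        }
        table.append(row)
    return table


@pytest.fixture(scope="session")
def aform_chain():
    """12-residue A-form-like chain with uniform prescribed torsions."""
    return build_chain_from_torsions(A_FORM_TORSIONS, n=12, identifier="aform12")


@pytest.fixture()
def varied_chain():
    """10-residue chain with per-residue prescribed torsions (seed 42)."""
    table = varied_torsion_table(10, seed=42)
    return build_chain_from_torsions(table, identifier="varied10"), table
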