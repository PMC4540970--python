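"""Shared fixtures: small synthetic experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import thermonorm as tn
from thermonorm.classify import build_profiles

TRUTH_TO_COMBINED = {
    "conserved": "conserved|none",
    "increasing-linear": "increasing|linear",
    "increasing-quadratic": "increasing|quadratic",
    "decreasing-linear": "decreasing|linear",
    "decreasing-quadratic": "decreasing|quadratic",
    "U": "U|quadratic",
    "bell": "bell|quadratic",
}


def make_matrix(counts: np.ndarray, temperatures, gene_ids=None) -> tn.CountMatrix:
    """CountMatrix from a raw array and per-library temperatures."""
    counts = np.asarray(counts)
    temperatures = np.asarray(temperatures, dtype=float)
    libs = [f"L{i}" for i in range(counts.shape[1])]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(counts.shape[0])]
    reps = []
    seen: dict[float, int] = {}
    for t in temperatures:
        seen[t] = seen.get(t, 0) + 1
        reps.append(seen[t])
    samples = pd.DataFrame(
        {"library_id": libs, "temperature": temperatures, "replicate": reps}
    ).set_index("library_id")
    return tn.CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=libs), samples
    )


@pytest.fixture(scope="session")
def mixed_run():
    """A 1,200-gene mixed-class experiment fitted end to end (shared)."""
    cfg = tn.SimulationConfig(n_genes=1200, seed=42)
    matrix, truth = tn.simulate_counts(cfg)
    matrix, _ = tn.filter_expressed(matrix)
    truth = truth.loc[matrix.gene_ids]
    norm = tn.tmm_factors(matrix)
    model = tn.ReactionNormModel().fit(matrix, norm)
    cpm = matrix.counts / norm.effective_library_sizes.to_numpy() * 1e6
    profiles = build_profiles(model.results_, cpm, matrix.temperatures)
    return {
        "config": cfg,
        "matrix": matrix,
        "truth": truth,
        "norm": norm,
        "fits": model.results_,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def linked_run(mixed_run):
    """mixed_run plus a matched architecture table and linkage results."""
    arch = tn.simulate_architecture(mixed_run["truth"], seed=7)
    result = tn.link_architecture(mixed_run["profiles"], arch, seed=11)
    return {**mixed_run, "arch": arch, "linkage": result}
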