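"""Shared fixtures and independent (naive) oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mfps.core import LEVELS
from mfps.probe_matrix import ProbeMatrix
from mfps.synthetic import SyntheticSpec, generate, plant_random, random_probes
from mfps.workflow import PipelineConfig, run_pipeline


# ---------------------------------------------------------------------------
# Naive oracles (pure-python, independent of the packed-bits fast path)
# ---------------------------------------------------------------------------


def naive_fingerprints(pm: ProbeMatrix, probe_indices) -> dict[tuple, list[int]]:
    """Group sequence indices by their fingerprint tuple."""
    groups: dict[tuple, list[int]] = {}
    for s in range(pm.n_sequences):
        fp = tuple(int(pm.incidence[j, s]) for j in probe_indices)
        groups.setdefault(fp, []).append(s)
    return groups


def naive_mfps_cost(pm: ProbeMatrix, probe_indices, penalties) -> float:
    """Direct evaluation of C = 1/2 sum_f sum_i P_i gamma (gamma - 1)."""
    groups = naive_fingerprints(pm, probe_indices)
    total = 0.0
    for lvl, p in zip(LEVELS, penalties):
        codes = pm.codes(lvl)
        for members in groups.values():
            g = len({int(codes[s]) for s in members})
            total += p * g * (g - 1)
    return total / 2


def naive_mdps_cost(pm: ProbeMatrix, probe_indices) -> float:
    groups = naive_fingerprints(pm, probe_indices)
    return sum(len(m) * (len(m) - 1) for m in groups.values()) / 2


def exhaustive_min_cost(pm: ProbeMatrix, k: int, cost: str, penalties=(1.0, 30.0, 0.0)):
    """Brute force over all C(n, k) probe subsets; returns (cost, subset)."""
    from itertools import combinations

    best = None
    for subset in combinations(range(pm.n_probes), k):
        if cost == "mdps":
            c = naive_mdps_cost(pm, subset)
        else:
            c = naive_mfps_cost(pm, subset, penalties)
        if best is None or c < best[0]:
            best = (c, subset)
    return best


# ---------------------------------------------------------------------------
# Random instances with nested taxonomy
# ---------------------------------------------------------------------------


def random_instance(
    seed: int,
    n_probes: int = 12,
    n_seqs: int = 15,
    otus_per_genus: int = 2,
    genera_per_phylum: int = 2,
    n_phyla: int = 2,
) -> ProbeMatrix:
    """Random incidence matrix with properly nested random taxonomy."""
    rng = np.random.default_rng(seed)
    incidence = rng.integers(0, 2, size=(n_probes, n_seqs)).astype(np.uint8)
    n_genera = n_phyla * genera_per_phylum
    n_otus = n_genera * otus_per_genus
    otu = rng.integers(0, n_otus, size=n_seqs)
    genus = otu // otus_per_genus
    phylum = genus // genera_per_phylum
    probes = random_probes(n_probes, 10, rng)
    return ProbeMatrix(
        probes=probes,
        incidence=incidence,
        seq_ids=[f"s{i}" for i in range(n_seqs)],
        tax_codes={
            "otu": otu.astype(np.int64),
            "genus": genus.astype(np.int64),
            "phylum": phylum.astype(np.int64),
        },
        group_names={
            "otu": [f"o{i}" for i in range(n_otus)],
            "genus": [f"g{i}" for i in range(n_genera)],
            "phylum": [f"p{i}" for i in range(n_phyla)],
        },
    )


def singleton_otu_matrix(pm: ProbeMatrix) -> ProbeMatrix:
    """Relabel so each sequence is its own OTU (MDPS reduction)."""
    n = pm.n_sequences
    codes = np.arange(n, dtype=np.int64)
    return ProbeMatrix(
        probes=list(pm.probes),
        incidence=pm.incidence.copy(),
        seq_ids=list(pm.seq_ids),
        tax_codes={"otu": codes, "genus": codes.copy(), "phylum": codes.copy()},
        group_names={lvl: [f"s{i}" for i in range(n)] for lvl in LEVELS},
    )


# ---------------------------------------------------------------------------
# Session-scoped synthetic study fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study():
    """The standard synthetic study: 3 phyla x 3 genera x 4 OTUs x 5 seqs,
    one planted probe per OTU, full pipeline keeping all candidates."""
    spec = SyntheticSpec(seed=7)
    aln = generate(spec)
    planted, placements = plant_random(aln, "otu", np.random.default_rng(71))
    result = run_pipeline(planted, planted.taxonomy, PipelineConfig(top_n=None))
    return {
        "spec": spec,
        "raw": aln,
        "planted": planted,
        "placements": placements,
        "result": result,
        "matrix": result.matrix,
    }


@pytest.fixture(scope="session")
def study_matrix_top(study):
    """The same study cut to the most conserved probes (selection pool)."""
    from mfps.probe_matrix import build_training_matrix

    return build_training_matrix(study["result"].processed, top_n=1000)
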