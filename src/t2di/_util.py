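"""Shared helpers: seeded substreams, empirical p-values, GMT I/O."""

from __future__ import annotations

from pathlib import Path

import numpy as np

# Fixed offsets for per-stage RNG substreams.  Each simulation stage draws
# from default_rng([master_seed, offset]) so regenerating one stage never
# perturbs another.
STAGE_OFFSETS = {
    "interactome": 11,
    "expression": 23,
    "gwas": 37,
    "annotations": 53,
    "comorbidity": 71,
    "discovery": 89,
    "topology": 101,
    "enrichment": 113,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one simulation stage of a master seed."""
    return np.random.default_rng([int(seed), STAGE_OFFSETS[stage]])


def empirical_p(n_at_least: int, n_rand: int) -> float:
    """Plus-one empirical p-value (k+1)/(N+1); never returns 0."""
    return (n_at_least + 1) / (n_rand + 1)


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    """Write gene sets as GMT (name, description, members...)."""
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into {name: (description, members)}."""
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line has fewer than 3 fields: {line!r}")
            out[parts[0]] = (parts[1], parts[2:])
    return out
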