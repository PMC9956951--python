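"""Shared fixtures: small simulated datasets reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from subfamnet.io_formats import ConsensusRecord
from subfamnet.pipeline import RunConfig, run_pipeline
from subfamnet.synthetic_data import SimulationConfig, simulate_subfamily_tree


def make_instances(consensus: str, n: int, divergence: float,
                   rng: np.random.Generator, prefix: str,
                   polya: tuple[int, int] = (0, 0)) -> dict[str, str]:
    """Instance copies of a consensus with Bernoulli substitutions."""
    out = {}
    for k in range(n):
        arr = np.array(list(consensus))
        for pos in np.flatnonzero(rng.random(len(arr)) < divergence):
            arr[pos] = [b for b in "ACGT" if b != arr[pos]][int(rng.integers(0, 3))]
        tail = "A" * int(rng.integers(polya[0], polya[1] + 1)) if polya[1] else ""
        out[f"{prefix}_{k:04d}"] = "".join(arr) + tail
    return out


def mutate_positions(seq: str, positions: list[int],
                     rng: np.random.Generator | None = None) -> str:
    """Deterministically substitute the given positions (first alternative
    base, or a random one when an rng is supplied)."""
    arr = list(seq)
    for pos in positions:
        alts = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alts[int(rng.integers(0, 3))] if rng is not None else alts[0]
    return "".join(arr)


@pytest.fixture(scope="session")
def family_consensus() -> ConsensusRecord:
    rng = np.random.default_rng(2024)
    seq = "".join(rng.choice(list("ACGT"), 300))
    seq = seq[:130] + "A" * 20 + seq[150:]
    return ConsensusRecord("family", seq, "repbase", "S")


@pytest.fixture(scope="session")
def five_subfamily_tree():
    """Balanced five-node subfamily tree with 3 diagnostic mutations/edge."""
    spec = {"name": "fam", "children": [
        {"name": "A", "mutations": 3, "children": [
            {"name": "C", "mutations": 3, "children": []}]},
        {"name": "B", "mutations": 3, "children": [
            {"name": "D", "mutations": 3, "children": []}]},
    ]}
    cfg = SimulationConfig(subfamily_tree_spec=spec, seed=11)
    return simulate_subfamily_tree(cfg), cfg


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run under the default study conditions (seed 1)."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = RunConfig(outdir=str(outdir), seed=1)
    result = run_pipeline(config)
    return config, result
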