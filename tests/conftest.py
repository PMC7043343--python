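import csv
import json
from pathlib import Path

import numpy as np
import pytest

from strainprio import PipelineConfig, run_all


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def mutate_interior(seq: str, k: int, rng: np.random.Generator, margin: int = 10) -> str:
    """Substitute k distinct interior positions, each to a different base."""
    out = list(seq)
    positions = rng.choice(len(seq) - 2 * margin, size=k, replace=False) + margin
    for pos in positions:
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end run on the default synthetic study, seed 1."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(outdir=str(outdir), seed=1)
    report = run_all(config)
    truth = json.loads((outdir / "sim" / "truth.json").read_text())
    return {"config": config, "outdir": outdir, "report": report, "truth": truth}


def read_tsv(path: Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
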