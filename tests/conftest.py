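"""Shared fixtures: synthetic pore model, two-class reference, noisy dataset.

Everything is generated programmatically from fixed seeds; the only
on-disk fixture is a toy k=2 pore-model table used by format tests.
"""

from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

from squigbin import (
    build_index,
    build_reference,
    make_bins,
    synthetic_pore_model,
)
from squigbin.classify import shred_complexity
from squigbin.simulate import SimParams, random_nucleotides, simulate_dataset

DATA_DIR = Path(__file__).parent / "data"
TOY_MODEL_PATH = DATA_DIR / "toy_pore_model.tsv"

REF_LENGTH = 50_000
DATASET_SEED = 2024


@pytest.fixture(scope="session")
def model():
    return synthetic_pore_model(k=6, seed=7)


@pytest.fixture(scope="session")
def cfg(model):
    return make_bins(model, 6)


@pytest.fixture(scope="session")
def two_class_setup(tmp_path_factory, model, cfg):
    """Two synthetic 50 kbp references (positive/null), built and indexed."""
    rng = np.random.default_rng(101)
    d = tmp_path_factory.mktemp("refs")
    seqs = {}
    for name in ("refA", "refB"):
        seq = random_nucleotides(REF_LENGTH, rng)
        seqs[name] = seq
        (d / f"{name}.fa").write_text(f">{name}\n{seq}\n")
    ref = build_reference(
        [(d / "refA.fa", "classA"), (d / "refB.fa", "classB")],
        model, cfg,
        class_roles={"classA": "positive", "classB": "null"},
    )
    index = build_index(ref)
    complexity = shred_complexity(ref)
    return SimpleNamespace(dir=d, seqs=seqs, ref=ref, index=index,
                           complexity=complexity,
                           classes={"refA": "classA", "refB": "classB"})


@pytest.fixture(scope="session")
def noisy_dataset(two_class_setup, model):
    """200 reads (100 per class) at the default study noise settings."""
    params = SimParams()  # amplitude noise 2.0, dwell sd 8.0, 10 kb mean length
    reads, truths = [], []
    for i, name in enumerate(("refA", "refB")):
        label = two_class_setup.classes[name]
        r, t = simulate_dataset(
            [(name, two_class_setup.seqs[name], label)],
            100, model, params, seed=DATASET_SEED + i, id_prefix=label,
        )
        reads.extend(r)
        truths.append(t)
    import pandas as pd

    truth = pd.concat(truths, ignore_index=True)
    return SimpleNamespace(reads=reads, truth=truth, params=params)
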