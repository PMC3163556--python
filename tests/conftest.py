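"""Shared fixtures: reference molecules and a session-scoped synthetic study."""
from __future__ import annotations

import json
from pathlib import Path

import pytest

from drugscout import FixtureSpec, generate_run_directory
from drugscout.chemistry import read_smiles_file
from drugscout.concordance import run_pipeline


@pytest.fixture(scope="session")
def reference_molecules():
    """Named reference drugs shipped with the package (fenofibrate etc.)."""
    from importlib import resources

    ref = resources.files("drugscout.data") / "reference_compounds.smi"
    with resources.as_file(ref) as path:
        return {m.id: m for m in read_smiles_file(path)}


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory) -> Path:
    """A complete synthetic study (seed 17) with planted ground truth."""
    out = tmp_path_factory.mktemp("study") / "fix17"
    return generate_run_directory(FixtureSpec(seed=17), out)


@pytest.fixture(scope="session")
def pipeline_run(study_dir, tmp_path_factory) -> Path:
    """The full pipeline executed once on the seed-17 study."""
    out = tmp_path_factory.mktemp("run") / "out"
    cfg = json.load(open(study_dir / "config.json"))
    return run_pipeline(cfg, base_dir=study_dir, out_dir=out)
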