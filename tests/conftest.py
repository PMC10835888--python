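import numpy as np
import pandas as pd
import pytest

from tilescan import (
    KILL_CONTROL,
    NEG_CONTROL,
    TILING,
    ScreenSimConfig,
    SgRNARecord,
    build_library,
    simulate_counts,
    simulate_library,
)


@pytest.fixture
def tiny_library():
    """5 guides: 3 tiling at nt 10/50/100 over a 300-nt CDS, 1 neg, 1 kill."""
    records = [
        SgRNARecord("t1", "A" * 20, TILING, 10, "+"),
        SgRNARecord("t2", "C" * 20, TILING, 50, "+"),
        SgRNARecord("t3", "G" * 20, TILING, 100, "-"),
        SgRNARecord("n1", "ACGT" * 5, NEG_CONTROL),
        SgRNARecord("k1", "TGCA" * 5, KILL_CONTROL),
    ]
    return build_library(records, cds_length_nt=300)


@pytest.fixture
def small_sim_config():
    """Desk-scale screen: 40 tiling + 8 neg + 6 kill over a 300-nt CDS."""
    return ScreenSimConfig(
        cds_length_nt=300, n_tiling=40, n_neg=8, n_kill=6,
        depth=50_000, read_length=40, seed=11,
    )


@pytest.fixture
def small_screen(small_sim_config):
    lib = simulate_library(small_sim_config)
    counts = simulate_counts(lib, small_sim_config)
    return lib, counts, small_sim_config


def write_library_file(tmp_path, text, name="lib.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
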