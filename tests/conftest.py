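import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seroscreen import SimConfig, generate_array_cohort, plant_markers

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

CHANNEL_MAP = {"532": "IgG", "635": "IgM"}


def write_toy_gpr(path, rows, header=None):
    """Write a minimal GPR-dialect file from (name, replicate, f532, b532, f635, b635) rows."""
    header = header or [
        "Block", "Row", "Column", "Name", "Replicate",
        "F532 Median", "B532 Median", "F635 Median", "B635 Median",
    ]
    lines = ["\t".join(header)]
    for i, (name, rep, f532, b532, f635, b635) in enumerate(rows):
        fields = {
            "Block": "1", "Row": str(i + 1), "Column": "1",
            "Name": name, "Replicate": str(rep),
            "F532 Median": str(f532), "B532 Median": str(b532),
            "F635 Median": str(f635), "B635 Median": str(b635),
        }
        lines.append("\t".join(fields[h] for h in header))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A 16v16 cohort of 150 proteins with 10 strong planted IgG-Up markers."""
    config = SimConfig(
        n_proteins=150,
        planted=plant_markers(10, "IgG", "Up", effect_size=4.0, prevalence=0.8),
    )
    tables, manifest, truth = generate_array_cohort(config, seed=11)
    return tables, manifest, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
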