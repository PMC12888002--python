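import numpy as np
import pandas as pd
import pytest

from proxitome import Comparison, DesignSpec, LfqSimConfig, simulate_lfq


def make_maxquant_tsv(path, rows, samples):
    """Write a minimal MaxQuant-dialect proteinGroups file.

    ``rows`` is a list of dicts with keys id, gene, flags (set of
    'reverse'/'contaminant'/'only_by_site') and intensities (list aligned
    with ``samples``).
    """
    header = ["Protein IDs", "Gene names", "Reverse", "Potential contaminant",
              "Only identified by site"] + [f"LFQ intensity {s}" for s in samples]
    lines = ["\t".join(header)]
    for row in rows:
        flags = row.get("flags", set())
        cells = [row["id"], row.get("gene", ""),
                 "+" if "reverse" in flags else "",
                 "+" if "contaminant" in flags else "",
                 "+" if "only_by_site" in flags else ""]
        cells += [str(v) for v in row["intensities"]]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def maxquant_file(tmp_path):
    def _build(rows, samples=("S1", "S2", "S3")):
        return make_maxquant_tsv(tmp_path / "proteinGroups.txt", rows, list(samples))

    return _build


@pytest.fixture
def design_3v3():
    samples = pd.DataFrame(
        {
            "condition": ["bait"] * 3 + ["control"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index([f"bait_{i}" for i in (1, 2, 3)] + [f"control_{i}" for i in (1, 2, 3)],
                       name="sample"),
    )
    return DesignSpec(samples=samples, comparisons=[Comparison("bait_vs_control", "bait", "control")])


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset reused across tests (read-only)."""
    return simulate_lfq(LfqSimConfig(n_proteins=400, seed=42,
                                     frac_contaminant=0.02, frac_only_by_site=0.02,
                                     frac_reverse=0.01))
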