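"""Shared fixtures: tiny hand-checkable tables and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

import serumgp as sg

# 12 runs (4 samples x 3 technical replicates) and a toy protein set that
# exercises every identification-filtering rule, including the boundary
# cases retained because removal is strictly "<".
TOY_RUNS = [f"S{i}_r{j}" for i in range(1, 5) for j in (1, 2, 3)]
TOY_REPLICATE_MAP = {r: r.split("_")[0] for r in TOY_RUNS}


def _toy_rows():
    # protein_id, gene, unique peptides, reverse, mod-site-only, runs-quantified
    return [
        ("KEEP_ALL", "G1", 5, "", "", 12),     # quantified everywhere
        ("KEEP_25PCT", "G2", 3, "", "", 3),    # 3/12 = 25% boundary: kept
        ("DROP_COVERAGE", "G3", 3, "", "", 2), # 2/12 = 16.7% < 25%: removed
        ("DROP_PEPTIDES", "G4", 1, "", "", 12),
        ("DROP_REVERSE", "G5", 4, "+", "", 12),
        ("DROP_MODSITE", "G6", 4, "", "+", 12),
    ]


@pytest.fixture
def toy_protein_groups(tmp_path):
    """Tab-delimited toy protein-groups file in the MaxQuant dialect."""
    header = ["Protein IDs", "Gene names", "Unique peptides", "Reverse",
              "Only identified by site"] + \
        [f"LFQ intensity {r}" for r in TOY_RUNS]
    lines = ["\t".join(header)]
    for pid, gene, pep, rev, mod, n_quant in _toy_rows():
        inten = [str(100.0 * (i + 1)) if i < n_quant else "0"
                 for i in range(len(TOY_RUNS))]
        lines.append("\t".join([pid, gene, str(pep), rev, mod] + inten))
    path = tmp_path / "proteinGroups.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_table(toy_protein_groups):
    return sg.read_protein_groups(toy_protein_groups)


@pytest.fixture(scope="session")
def small_annotation():
    """Follow-up-only cohort annotation at the default study design."""
    return sg.simulate_design(sg.StudyDesign(seed=11, include_cord=False))


@pytest.fixture(scope="session")
def small_design(small_annotation):
    return sg.design_matrix(small_annotation)


def random_design(rng, n, n_subjects=3):
    """Small random covariate frame for oracle checks."""
    return pd.DataFrame({
        "age": rng.uniform(3, 36, n),
        "season": rng.uniform(0, 12, n),
        "gender": rng.choice(["girl", "boy"], n),
        "location": rng.choice(["Espoo", "Tartu"], n),
        "id": rng.choice([f"C{i}" for i in range(n_subjects)], n),
    })


def full_model_spec(rng=None):
    """An additive spec with every component kind, random-ish parameters."""
    r = rng or np.random.default_rng(0)
    return sg.AdditiveModelSpec(
        components=(
            sg.KernelSpec("se_age", ("age",), float(r.uniform(0.3, 2.0)),
                          float(r.uniform(3, 30))),
            sg.KernelSpec("periodic_season", ("season",),
                          float(r.uniform(0.1, 1.0)),
                          float(r.uniform(0.6, 3.0))),
            sg.KernelSpec("categorical", ("gender",),
                          float(r.uniform(0.1, 1.0))),
            sg.KernelSpec("categorical", ("id",), float(r.uniform(0.1, 1.0))),
            sg.KernelSpec("product", ("age", "id"),
                          float(r.uniform(0.1, 1.0)),
                          float(r.uniform(3, 30))),
        ),
        noise_variance=float(r.uniform(0.05, 1.0)),
    )
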