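import numpy as np
import pandas as pd
import pytest

from pkdscreen import ProteinGroupTable, make_design


@pytest.fixture
def design3():
    """Three paired control/treatment replicates (the standard screen design)."""
    return make_design(["C1", "C2", "C3"], ["T1", "T2", "T3"])


def build_table(lfq_rows, peptides=None, accessions=None, labels=None):
    """In-memory ProteinGroupTable from a list of per-sample intensity rows."""
    n = len(lfq_rows)
    labels = labels or ["C1", "C2", "C3", "T1", "T2", "T3"]
    accessions = accessions or [f"P{i + 1}" for i in range(n)]
    peptides = peptides if peptides is not None else [5] * n
    meta = pd.DataFrame({
        "group_id": [str(i) for i in range(n)],
        "accessions": [[a] for a in accessions],
        "leading_accession": accessions,
        "gene_names": [[f"G{i + 1}"] for i in range(n)],
        "razor_unique_peptides": peptides,
        "reverse": False,
        "contaminant": False,
    })
    lfq = pd.DataFrame(np.asarray(lfq_rows, dtype=float), columns=labels)
    return ProteinGroupTable(meta=meta, lfq=lfq)


@pytest.fixture
def toy_table():
    """Four proteins, no missing values, simple round intensities."""
    return build_table([
        [1e7, 1e7, 1e7, 1e7, 1e7, 1e7],
        [1e6, 1e6, 1e6, 2e6, 2e6, 2e6],
        [1e7, 2e7, 1e7, 1e7, 2e7, 1e7],
        [1e5, 1e5, 1e5, 1e5, 1e5, 1e5],
    ])


@pytest.fixture
def toy_protein_groups_tsv(tmp_path):
    """A 3-row MaxQuant-style proteinGroups file."""
    lines = [
        "Majority protein IDs\tGene names\tRazor + unique peptides\t"
        "LFQ intensity C1\tLFQ intensity C2\tLFQ intensity T1\tLFQ intensity T2\t"
        "Reverse\tPotential contaminant",
        "P1;P9\tGnA\t5\t1e7\t2e7\t3e7\t4e7\t\t",
        "P2\tGnB;GnB2\t1\t0\t1e6\t1e6\t2e6\t\t",
        "P3\tGnC\t3\t1e5\t1e5\t1e5\t1e5\t\t",
    ]
    path = tmp_path / "proteinGroups.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path
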