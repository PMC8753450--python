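import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from clonodyn.repertoire_io import Clone, Repertoire

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_repertoire(rows, subject="P1", timepoint="Day0", compartment="PB") -> Repertoire:
    """Build a repertoire from (cdr3_nt, v, j, templates, productive) tuples."""
    rep = Repertoire(subject_id=subject, timepoint=timepoint, compartment=compartment)
    aa = {"": ""}
    for cdr3_nt, v, j, templates, productive in rows:
        rep.add(
            Clone(
                cdr3_nt=cdr3_nt,
                cdr3_aa="CASSF"[: max(1, len(cdr3_nt) // 3)] if productive else "",
                v_call=v,
                j_call=j,
                templates=templates,
                productive=productive,
            )
        )
    return rep


@pytest.fixture
def small_repertoire():
    return make_repertoire(
        [
            ("TGTGCCAGCAGC", "TRBV5-1", "TRBJ2-1", 8, True),
            ("TGTGCCAGCTTT", "TRBV6-1", "TRBJ2-3", 1, True),
            ("TGTGCCTTTTTT", "TRBV7-2", "TRBJ1-1", 1, True),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_cells(adt_rows, markers, clonotypes=None, subsets=None):
    """Build a tiny SingleCellTable from explicit ADT counts."""
    from scipy import sparse

    from clonodyn.sc_link import SingleCellTable

    n = len(adt_rows)
    barcodes = [f"BC{i:03d}" for i in range(n)]
    clonotypes = clonotypes or [""] * n
    obs = pd.DataFrame(
        {
            "trb_cdr3_nt": clonotypes,
            "trb_cdr3_aa": ["CASS" if c else "" for c in clonotypes],
            "trb_v_gene": ["TRBV5-1" if c else "" for c in clonotypes],
            "trb_j_gene": ["TRBJ2-1" if c else "" for c in clonotypes],
            "tra_cdr3_aa": [""] * n,
            "subset": subsets or ["unassigned"] * n,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    adt = pd.DataFrame(adt_rows, index=obs.index, columns=markers)
    gex = sparse.csr_matrix(np.zeros((n, 3), dtype=int))
    return SingleCellTable(obs=obs, adt=adt, gene_counts=gex, genes=["G1", "G2", "G3"])
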