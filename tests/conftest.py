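import pandas as pd
import pytest

from crossgsea import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeLabels,
    ProbeAnnotation,
    SymbolRecord,
    SymbolTable,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 probes x 4 samples, linear scale."""
    values = pd.DataFrame(
        [[4.0, 16.0, 2.0, 8.0],
         [1.0, 2.0, 4.0, 8.0],
         [0.005, 0.02, 0.5, 5.0],
         [3.0, 3.0, 3.0, 3.0]],
        index=pd.Index(["p1", "p2", "p3", "p4"], name="NAME"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values=values, scale="linear")


@pytest.fixture
def two_class_labels() -> PhenotypeLabels:
    return PhenotypeLabels(
        sample_ids=["s1", "s2", "s3", "s4"],
        class_names=("treated", "control"),
        assignment=["treated", "treated", "control", "control"],
    )


@pytest.fixture
def hgnc_like_table() -> SymbolTable:
    """A tiny approved-symbol table with aliases and accessions."""
    return SymbolTable(
        [
            SymbolRecord("TNF", aliases={"TNFA", "TNFSF2"},
                         protein_ids={"NP_000585"}, mrna_ids={"NM_000594"}),
            SymbolRecord("IL6", aliases={"IFNB2"},
                         protein_ids={"NP_000591"}, mrna_ids={"NM_000600"}),
            SymbolRecord("FASN", protein_ids={"NP_004095"}, mrna_ids={"NM_004104"}),
        ]
    )


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("APOPTOSIS", "programmed cell death", frozenset({"TNF", "IL6", "CASP3"})),
            GeneSet("LIPID", "liver lipid metabolism", frozenset({"FASN", "SCD", "ACACA", "ELOVL6", "DGAT1"})),
        ]
    )


@pytest.fixture
def toy_annotation() -> ProbeAnnotation:
    table = pd.DataFrame(
        {"symbol": ["TNF", "TNF", "IL6", ""],
         "title": ["t", "t", "i", "below_threshold"]},
        index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id"),
    )
    return ProbeAnnotation(table=table)
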