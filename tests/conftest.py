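import numpy as np
import pytest

from gbsig.faers import ReportRecord, ReportSet


def make_record(
    case_id: str,
    drugs=(("DrugA", "PS"),),
    reactions=("Guillain-Barre syndrome",),
    version: int = 0,
    sex: str = "Male",
    age: float | None = 50.0,
    reporter: str = "Physician",
    country: str = "United States",
    quarter: str = "2020Q1",
    indications=("Rheumatoid arthritis",),
) -> ReportRecord:
    return ReportRecord(
        case_id=case_id,
        case_version=version,
        quarter=quarter,
        sex=sex,
        age_years=age,
        reporter=reporter,
        country=country,
        drugs=tuple(drugs),
        reactions=tuple(reactions),
        indications=tuple(indications),
    )


@pytest.fixture
def four_cell_reports() -> ReportSet:
    """One report per contingency cell for (DrugX, GBS)."""
    recs = [
        make_record("c1", drugs=(("DrugX", "PS"),), reactions=("Guillain-Barre syndrome",)),
        make_record("c2", drugs=(("DrugX", "PS"),), reactions=("Nausea",)),
        make_record("c3", drugs=(("DrugY", "PS"),), reactions=("Guillain-Barre syndrome",)),
        make_record("c4", drugs=(("DrugY", "PS"),), reactions=("Nausea",)),
    ]
    return ReportSet(records=tuple(recs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
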