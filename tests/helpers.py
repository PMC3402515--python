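"""Small builders shared across the test modules."""

from casenoncase import Dataset, DrugEntry, ReactionEntry, ReportRecord


def report(rid="R1", age=67, sex="F", year=2000, reactions=("Nausea",), drugs=(),
           reporter_type=None, country=None, onset=None):
    """Build a ReportRecord from terse specs.

    ``reactions`` items are terms or ReactionEntry; ``drugs`` items are
    (atc_code, role) pairs or DrugEntry.
    """
    rxns = tuple(
        r if isinstance(r, ReactionEntry) else ReactionEntry(term=r, onset_days=onset)
        for r in reactions
    )
    ds = tuple(
        d if isinstance(d, DrugEntry)
        else DrugEntry(drug_name=d[0], atc_code=d[0], role=d[1])
        for d in drugs
    )
    return ReportRecord(report_id=rid, age_years=age, sex=sex, report_year=year,
                        reporter_type=reporter_type, country=country,
                        reactions=rxns, drugs=ds)


def dataset(*reports_):
    return Dataset(reports=list(reports_))
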