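import itertools

import pytest

from trioscreen.pedigree import Individual, Pedigree, Phenotype, Sex
from trioscreen.segregation import (
    CandidateDecision,
    GenotypeTable,
    SegregationStatus,
    check_recessive_segregation,
    evaluate_candidate,
    read_calls_tsv,
)
from trioscreen.variants import GenotypeCall

HR, HET, HA, MISS = (
    GenotypeCall.HOM_REF,
    GenotypeCall.HET,
    GenotypeCall.HOM_ALT,
    GenotypeCall.MISSING,
)
KEY = ("chr1", 8421731, "C", "T")


def table(calls):
    return GenotypeTable.from_calls(KEY, calls)


def reference_verdict(ped, calls):
    """Independent rule-by-rule evaluator, written literally from the model.

    Re-derives obligate carriers and applies each rule separately rather
    than intersecting allowed-call sets.
    """
    obligate = set()
    for m in ped.members:
        if m.phenotype is Phenotype.AFFECTED:
            if m.father_id:
                obligate.add(m.father_id)
            if m.mother_id:
                obligate.add(m.mother_id)
    informative = 0
    violators = set()
    for iid, call in calls.items():
        if call is MISS:
            continue
        m = ped.get(iid)
        rules = []
        if m.phenotype is Phenotype.AFFECTED:
            rules.append(call is HA)
        if m.phenotype is Phenotype.UNAFFECTED:
            rules.append(call is not HA)
        if iid in obligate:
            rules.append(call in (HET, HA))
        if not rules:
            continue
        informative += 1
        if not all(rules):
            violators.add(iid)
    if informative == 0:
        status = SegregationStatus.INCONCLUSIVE
    elif violators:
        status = SegregationStatus.INCONSISTENT
    else:
        status = SegregationStatus.CONSISTENT
    return status, violators, informative


FAMILY1_PATTERN = {"FA": HET, "MO": HET, "C1": HA, "C2": HA, "C3": HET, "C4": HR}


class TestCheckRecessiveSegregation:
    def test_confirmed_family_pattern_is_consistent(self, family1):
        # carrier parents het, both affected offspring hom-alt, asymptomatic
        # siblings one carrier and one wild-type homozygote
        v = check_recessive_segregation(family1, table(FAMILY1_PATTERN))
        assert v.status is SegregationStatus.CONSISTENT
        assert v.violations == []
        assert v.n_informative == 6

    def test_affected_heterozygote_excludes(self, family1):
        calls = dict(FAMILY1_PATTERN, C2=HET)
        v = check_recessive_segregation(family1, table(calls))
        assert v.status is SegregationStatus.INCONSISTENT
        assert [x.individual_id for x in v.violations] == ["C2"]

    def test_unaffected_hom_alt_excludes(self, family1):
        calls = dict(FAMILY1_PATTERN, C3=HA)
        v = check_recessive_segregation(family1, table(calls))
        assert v.status is SegregationStatus.INCONSISTENT

    def test_obligate_carrier_hom_ref_excludes(self, family1):
        calls = dict(FAMILY1_PATTERN, FA=HR)
        v = check_recessive_segregation(family1, table(calls))
        assert v.status is SegregationStatus.INCONSISTENT
        assert v.violations[0].individual_id == "FA"

    def test_all_missing_is_inconclusive(self, family1):
        v = check_recessive_segregation(
            family1, table({i: MISS for i in FAMILY1_PATTERN})
        )
        assert v.status is SegregationStatus.INCONCLUSIVE
        assert v.n_informative == 0

    def test_phenotype_unknown_nonparent_is_uninformative(self, family1):
        ped = Pedigree(
            family_id="F",
            members=family1.members
            + [Individual("C5", "FA", "MO", Sex.MALE, Phenotype.UNKNOWN)],
        )
        v = check_recessive_segregation(ped, table(dict(FAMILY1_PATTERN, C5=HA)))
        assert v.status is SegregationStatus.CONSISTENT
        assert v.n_informative == 6

    def test_unknown_phenotype_parent_still_obligate_carrier(self):
        ped = Pedigree(
            "F",
            [
                Individual("FA", phenotype=Phenotype.UNKNOWN),
                Individual("MO", phenotype=Phenotype.UNKNOWN),
                Individual("K", "FA", "MO", phenotype=Phenotype.AFFECTED),
            ],
        )
        v = check_recessive_segregation(
            ped, GenotypeTable.from_calls(KEY, {"FA": HR, "K": HA})
        )
        assert v.status is SegregationStatus.INCONSISTENT
        assert v.violations[0].individual_id == "FA"

    def test_foreign_individual_raises(self, family1):
        with pytest.raises(KeyError):
            check_recessive_segregation(family1, table({"stranger": HET}))

    def test_exhaustive_enumeration_matches_reference(self, family1):
        # every assignment of the four call states to the six members
        ids = [m.individual_id for m in family1.members]
        states = (HR, HET, HA, MISS)
        for combo in itertools.product(states, repeat=6):
            calls = dict(zip(ids, combo))
            v = check_recessive_segregation(family1, table(calls))
            status, violators, informative = reference_verdict(family1, calls)
            assert v.status is status, calls
            assert {x.individual_id for x in v.violations} == violators
            assert v.n_informative == informative

    def test_missing_call_individual_never_changes_verdict(self, family1):
        ped = Pedigree(
            family_id="F",
            members=family1.members
            + [Individual("C5", "FA", "MO", Sex.FEMALE, Phenotype.UNAFFECTED)],
        )
        ids = [m.individual_id for m in family1.members]
        for combo in itertools.product((HR, HET, HA), repeat=3):
            calls = dict(zip(ids, combo + (HA, HET, HR)))
            base = check_recessive_segregation(ped, table(calls))
            extended = check_recessive_segregation(ped, table(dict(calls, C5=MISS)))
            assert base.status is extended.status
            assert base.n_informative == extended.n_informative


@pytest.fixture
def family2():
    """Independent validation family with one affected offspring."""
    return Pedigree(
        family_id="F2",
        members=[
            Individual("FA2", sex=Sex.MALE, phenotype=Phenotype.UNAFFECTED),
            Individual("MO2", sex=Sex.FEMALE, phenotype=Phenotype.UNAFFECTED),
            Individual("K1", "FA2", "MO2", Sex.MALE, Phenotype.AFFECTED),
            Individual("K2", "FA2", "MO2", Sex.FEMALE, Phenotype.UNAFFECTED),
        ],
    )


class TestEvaluateCandidate:
    def test_one_inconsistent_family_excludes(self, family1, family2):
        # the validation family's affected member is only heterozygous:
        # the candidate cannot be causal under a fully penetrant model
        tables = {
            "F1": table(FAMILY1_PATTERN),
            "F2": GenotypeTable.from_calls(
                KEY, {"FA2": HET, "MO2": HET, "K1": HET, "K2": HR}
            ),
        }
        decision, verdicts = evaluate_candidate([family1, family2], tables)
        assert decision is CandidateDecision.EXCLUDED
        assert verdicts["F1"].status is SegregationStatus.CONSISTENT
        assert verdicts["F2"].status is SegregationStatus.INCONSISTENT

    def test_all_calls_missing_is_inconclusive(self, family1):
        tables = {"F1": table({i: MISS for i in FAMILY1_PATTERN})}
        decision, _ = evaluate_candidate([family1], tables)
        assert decision is CandidateDecision.INCONCLUSIVE

    def test_two_consistent_informative_families_support(self, family1, family2):
        tables = {
            "F1": table(FAMILY1_PATTERN),
            "F2": GenotypeTable.from_calls(
                KEY, {"FA2": HET, "MO2": HET, "K1": HA, "K2": HET}
            ),
        }
        decision, _ = evaluate_candidate([family1, family2], tables)
        assert decision is CandidateDecision.SUPPORTED

    def test_consistent_but_thin_evidence_is_inconclusive(self, family1):
        # a single informative call cannot support a candidate
        tables = {"F1": table({"C1": HA})}
        decision, verdicts = evaluate_candidate([family1], tables)
        assert verdicts["F1"].status is SegregationStatus.CONSISTENT
        assert decision is CandidateDecision.INCONCLUSIVE

    def test_order_invariant(self, family1, family2):
        tables = {
            "F1": table(FAMILY1_PATTERN),
            "F2": GenotypeTable.from_calls(KEY, {"K1": HET}),
        }
        d1, _ = evaluate_candidate([family1, family2], tables)
        d2, _ = evaluate_candidate([family2, family1], tables)
        assert d1 is d2 is CandidateDecision.EXCLUDED

    def test_no_family_with_calls_rejected(self, family1):
        with pytest.raises(ValueError):
            evaluate_candidate([family1], {})


def test_read_calls_tsv(tmp_path, family1):
    p = tmp_path / "calls.tsv"
    p.write_text(
        "individual\tcall\nFA\t0/1\nMO\t0/1\nC1\t1/1\nC2\t1/1\nC3\t0/1\nC4\t0/0\n"
    )
    t = read_calls_tsv(p, KEY)
    v = check_recessive_segregation(family1, t)
    assert v.status is SegregationStatus.CONSISTENT
    assert v.n_informative == 6
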