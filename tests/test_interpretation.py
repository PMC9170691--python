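import itertools

import pytest

from mutyhtms.classifier import classify
from mutyhtms.interpretation import (
    ClinVarClass,
    Evidence,
    Grade,
    MutyhCategory,
    VariantAnnotation,
    categorize,
    grade_variant,
    reclassification_evidence,
)
from mutyhtms.studydata import TABLE1_CALLS, TABLE1_VARIANTS


def V(hgvs_c, hgvs_p=None, clinvar=ClinVarClass.ABSENT, cadd=None, revel=None,
      zygosity="het", origin="germline"):
    return VariantAnnotation(hgvs_c, hgvs_p, clinvar, cadd, revel, None, zygosity, origin)


def graded_table1(tumor_id):
    germ, som = [], []
    for tid, c, p, clin, cadd, revel, zyg, origin in TABLE1_VARIANTS:
        if tid != tumor_id:
            continue
        gv = grade_variant(V(c, p, clin, cadd, revel, zyg, origin))
        (germ if origin == "germline" else som).append(gv)
    return germ, som


def test_clinvar_pathogenic_grades_pathogenic():
    gv = grade_variant(V("c.1187G>A", "p.G396D", ClinVarClass.PATHOGENIC, 29.4, 0.551))
    assert gv.grade is Grade.PATHOGENIC


def test_clinvar_vus_grades_potentially_pathogenic_regardless_of_scores():
    gv = grade_variant(V("c.1141G>T", "p.G381W", ClinVarClass.VUS, 23.8, 0.521))
    assert gv.grade is Grade.POTENTIALLY_PATHOGENIC
    low = grade_variant(V("c.912C>G", "p.S304R", ClinVarClass.VUS, 12.8, 0.229))
    assert low.grade is Grade.POTENTIALLY_PATHOGENIC


def test_absent_from_clinvar_uses_in_silico_thresholds():
    assert grade_variant(V("c.1", cadd=10, revel=0.1)).grade is Grade.NOT_RETAINED
    assert grade_variant(V("c.2", cadd=20.1)).grade is Grade.POTENTIALLY_PATHOGENIC
    assert grade_variant(V("c.3", revel=0.61)).grade is Grade.POTENTIALLY_PATHOGENIC
    assert grade_variant(V("c.4", cadd=20.0, revel=0.6)).grade is Grade.NOT_RETAINED  # strict >
    benign = V("c.5", clinvar=ClinVarClass.BENIGN, cadd=35.0, revel=0.9)
    assert grade_variant(benign).grade is Grade.NOT_RETAINED


def test_five_group_definitions():
    y179c = grade_variant(V("c.536A>G", "p.Y179C", ClinVarClass.PATHOGENIC))
    g396d = grade_variant(V("c.1187G>A", "p.G396D", ClinVarClass.PATHOGENIC))
    r426c = grade_variant(V("c.1276C>T", "p.R426C", ClinVarClass.VUS))
    f532l_som = grade_variant(V("c.1596C>A", "p.F532L", ClinVarClass.VUS, origin="somatic"))
    assert categorize([y179c, g396d]) is MutyhCategory.POSITIVE
    hom = grade_variant(V("c.1187G>A", "p.G396D", ClinVarClass.PATHOGENIC, zygosity="hom"))
    assert categorize([hom]) is MutyhCategory.POSITIVE
    assert categorize([g396d]) is MutyhCategory.MONOALLELIC
    assert categorize([]) is MutyhCategory.NEGATIVE
    assert categorize([g396d, r426c]) is MutyhCategory.POTENTIAL_BIALLELIC
    assert categorize([g396d], [f532l_som]) is MutyhCategory.POTENTIAL_BIALLELIC
    hom_vus = grade_variant(V("c.925C>T", "p.R309C", ClinVarClass.VUS, zygosity="hom"))
    assert categorize([hom_vus]) is MutyhCategory.POTENTIAL_BIALLELIC
    assert categorize([r426c]) is MutyhCategory.UNCERTAIN
    som_path = grade_variant(V("c.536A>G", "p.Y179C", ClinVarClass.PATHOGENIC, origin="somatic"))
    assert categorize([], [som_path]) is MutyhCategory.UNCERTAIN
    not_retained = grade_variant(V("c.9", cadd=3.0))
    assert categorize([not_retained]) is MutyhCategory.NEGATIVE


@pytest.mark.parametrize("tumor_id", sorted({t for t, *_ in TABLE1_VARIANTS}))
def test_published_potential_biallelic_tumors_all_land_in_that_group(tumor_id):
    germ, som = graded_table1(tumor_id)
    assert categorize(germ, som) is MutyhCategory.POTENTIAL_BIALLELIC


def test_category_is_invariant_to_variant_order():
    germ, som = graded_table1("C1701")
    baseline = categorize(germ, som)
    for perm in itertools.permutations(germ):
        assert categorize(list(perm), som) is baseline


def test_misplaced_origin_raises():
    g = grade_variant(V("c.1187G>A", "p.G396D", ClinVarClass.PATHOGENIC, origin="somatic"))
    with pytest.raises(ValueError):
        categorize([g], [])


def _call(tumor_id):
    row = next(r for r in TABLE1_CALLS if r[0] == tumor_id)
    return classify(row[1], row[2], row[3], 1.34)


def test_positive_call_with_single_vus_supports_pathogenic():
    germ, som = graded_table1("C2904")
    out = reclassification_evidence(MutyhCategory.POTENTIAL_BIALLELIC, _call("C2904"), germ + som)
    assert len(out) == 1
    assert out[0].variant.hgvs_p == "p.G381W"
    assert out[0].evidence is Evidence.SUPPORTS_PATHOGENIC
    assert not out[0].unresolvable


def test_negative_call_with_adequate_evidence_supports_benign():
    germ, som = graded_table1("C0302")
    out = reclassification_evidence(MutyhCategory.POTENTIAL_BIALLELIC, _call("C0302"), germ + som)
    assert len(out) == 1
    assert out[0].variant.hgvs_p == "p.R426C"
    assert out[0].evidence is Evidence.SUPPORTS_BENIGN


def test_positive_call_with_two_vus_is_unresolvable():
    germ, som = graded_table1("C5024")
    out = reclassification_evidence(MutyhCategory.POTENTIAL_BIALLELIC, _call("C5024"), germ + som)
    vus = [o for o in out if o.evidence is Evidence.SUPPORTS_PATHOGENIC]
    assert len(vus) == 2
    assert all(o.unresolvable for o in vus)


def test_negative_call_without_adequate_evidence_yields_none():
    germ, som = graded_table1("C1701")  # error 39.8%, 6 mutations: inadequate
    out = reclassification_evidence(MutyhCategory.POTENTIAL_BIALLELIC, _call("C1701"), germ + som)
    assert all(o.evidence is Evidence.NONE for o in out)


def test_evidence_requires_potential_biallelic_category():
    with pytest.raises(ValueError):
        reclassification_evidence(MutyhCategory.NEGATIVE, _call("C0302"), [])
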