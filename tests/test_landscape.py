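import numpy as np
import pytest

from mutyhtms.catalog import reduce_catalog
from mutyhtms.landscape import (
    ContingencyTable,
    clopper_pearson,
    fisher_enrichment,
    hotspot_rule,
    hypermutation_binomial,
    mean_relative_likelihood,
    relative_likelihood,
    summary_ttest,
    tmb,
)
from mutyhtms.refit import ExposureSolution
from mutyhtms.studydata import ENRICHMENT_TABLES, HYPERMUTATION, MUTATION_COUNT_SUMMARY


def test_tmb_arithmetic_and_strict_class_thresholds():
    m = tmb(15, 3, 1.34)
    assert m.tmb == pytest.approx(13.43, abs=0.01)
    assert m.hyper_class == "hypermutated"
    assert tmb(10, 0, 1.0).hyper_class == "normal"  # strict > 10
    ultra = tmb(150, 0, 1.34)
    assert ultra.tmb == pytest.approx(111.9, abs=0.1)
    assert ultra.hyper_class == "ultra"


def round_to_sf(x, sf):
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sf - 1)


def printed_sf(printed):
    # printed values carry 1 significant figure except 0.045
    return 2 if printed == 0.045 else 1


@pytest.mark.parametrize("name", list(ENRICHMENT_TABLES))
def test_enrichment_p_values_match_published_to_printed_precision(name):
    a, b, c, d, printed = ENRICHMENT_TABLES[name]
    p = fisher_enrichment(ContingencyTable(a, b, c, d))
    assert round_to_sf(p, printed_sf(printed)) == pytest.approx(printed, rel=1e-9)


def test_fisher_no_association_and_symmetry():
    assert fisher_enrichment(ContingencyTable(2, 2, 20, 20)) == pytest.approx(1.0)
    p1 = fisher_enrichment(ContingencyTable(16, 3, 127, 5237))
    p2 = fisher_enrichment(ContingencyTable(5237, 127, 3, 16))  # rows and columns swapped
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_hypermutation_binomial_reproduces_published_tail():
    p = hypermutation_binomial(
        HYPERMUTATION["k"], HYPERMUTATION["n"],
        HYPERMUTATION["baseline_k"] / HYPERMUTATION["baseline_n"],
    )
    assert p == pytest.approx(4e-8, rel=0.25)
    assert hypermutation_binomial(0, 19, 0.1) == pytest.approx(1.0)
    assert hypermutation_binomial(3, 3, 0.5) == pytest.approx(0.125)


def test_clopper_pearson_reproduces_published_bounds():
    assert clopper_pearson(5, 5)[0] == pytest.approx(47.8, abs=0.05)
    assert clopper_pearson(6, 6)[0] == pytest.approx(54.1, abs=0.05)
    lo, hi = clopper_pearson(2853, 2853)
    assert lo == pytest.approx(99.87, abs=0.005)
    assert hi == 100.0
    lo, hi = clopper_pearson(2385, 2430)
    assert lo == pytest.approx(97.5, abs=0.05)
    assert hi == pytest.approx(98.6, abs=0.05)


def test_clopper_pearson_k_equals_n_lower_bound_is_analytic():
    for n in (3, 10, 57):
        lo, hi = clopper_pearson(n, n)
        assert lo == pytest.approx(100 * 0.025 ** (1 / n), rel=1e-9)
        assert hi == 100.0
    with pytest.raises(ValueError):
        clopper_pearson(0, 0)


def test_summary_ttest_closed_forms():
    t, p = summary_ttest(10, 2, 50, 10, 2, 50)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    t, p = summary_ttest(10, 2, 50, 11, 2, 50)
    assert p == pytest.approx(0.0141, abs=0.0005)
    s = MUTATION_COUNT_SUMMARY
    _, p = summary_ttest(s["mean1"], s["sd1"], s["n1"], s["mean2"], s["sd2"], s["n2"])
    # published value comes from raw data; summary statistics agree in magnitude
    assert 1e-18 < p < 1e-15


def test_relative_likelihood_attribution(catalog):
    pure = ExposureSolution({"SBS18": 1.0}, 0.05, 20)
    assert relative_likelihood("T[C>A]T", pure, catalog) == pytest.approx(1.0)
    no_ber = ExposureSolution({"SBS1": 1.0}, 0.05, 20)
    assert relative_likelihood("T[C>A]T", no_ber, catalog) == 0.0


def test_relative_likelihood_hand_arithmetic():
    import pandas as pd

    from mutyhtms.catalog import CANONICAL_CLASSES, SignatureCatalog

    profiles = np.full((96, 2), (1 - 0.03 - 0.01) / 95)
    profiles[0, 0], profiles[0, 1] = 0.03, 0.01
    profiles[:, 0] *= 1.0 / profiles[:, 0].sum()
    profiles[:, 1] *= 1.0 / profiles[:, 1].sum()
    # adjust so row 0 is exactly (0.03, 0.01) after normalization
    profiles[0, 0], profiles[0, 1] = 0.03, 0.01
    profiles[1:, 0] = (1 - 0.03) / 95
    profiles[1:, 1] = (1 - 0.01) / 95
    cat = SignatureCatalog(
        pd.DataFrame(profiles, index=list(CANONICAL_CLASSES), columns=["A", "B"])
    )
    sol = ExposureSolution({"A": 0.5, "B": 0.5}, 0.0, 10)
    rl = relative_likelihood(CANONICAL_CLASSES[0], sol, cat, targets=["A"])
    assert rl == pytest.approx(0.75)


def test_mean_relative_likelihood_is_a_mean(catalog):
    sol = ExposureSolution({"SBS18": 0.5, "SBS1": 0.5}, 0.1, 10)
    single = relative_likelihood("T[C>A]T", sol, catalog)
    agg = mean_relative_likelihood(["T[C>A]T", "T[C>A]T"], sol, catalog)
    assert agg == pytest.approx(single)
    assert 0.0 <= agg <= 1.0


def test_hotspot_rule_requires_the_exact_alleles():
    assert hotspot_rule([{"gene": "KRAS", "hgvs_p": "p.G12C"}])
    assert hotspot_rule([{"gene": "PIK3CA", "hgvs_p": "p.Q546K"}])
    assert not hotspot_rule([{"gene": "KRAS", "hgvs_p": "p.G12D"}])
    assert not hotspot_rule([])
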