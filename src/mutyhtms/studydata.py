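"""Reference-cohort summary data for validating the classifier.

Printed per-tumor classifier inputs for the 17 potential-biallelic tumors of
the 5649-CRC reference cohort, somatic-enrichment contingency counts, and the
cohort-level summary statistics (confusion counts, hypermutation counts,
mutation-count summaries).  These are published summary values consumed as
inputs; nothing here is computed by this package.
"""

from __future__ import annotations

from .interpretation import ClinVarClass

# --- the 17 potential-biallelic tumors -------------------------------------
# (tumor_id, sbs18_36 %, reconstruction error %, somatic mutation count,
#  printed TMS-based prediction)
TABLE1_CALLS: list[tuple[str, float, float, int, str]] = [
    ("C2904", 62.0, 38.1, 15, "Positive"),
    ("O1016", 56.1, 17.1, 14, "Positive"),
    ("C5024", 76.7, 17.1, 26, "Positive"),
    ("C0302", 46.7, 23.9, 11, "Negative"),
    ("C4622", 26.4, 45.4, 9, "Negative"),
    ("O1569", 24.9, 45.8, 10, "Negative"),
    ("C5299", 8.7, 1.5, 175, "Negative"),
    ("C4551", 0.0, 3.6, 120, "Negative"),
    ("O0497", 0.0, 4.6, 19, "Negative"),
    ("C1060", 0.0, 50.3, 4, "Negative"),
    ("O2193", 35.0, 4.7, 9, "Negative"),
    ("O3288", 29.9, 41.7, 10, "Negative"),
    ("O3593", 9.0, 10.7, 251, "Negative"),
    ("O1434", 0.9, 25.8, 14, "Negative"),
    ("O3484", 0.0, 39.4, 4, "Negative"),
    ("C1701", 51.6, 39.8, 6, "Negative"),
    ("O3625", 3.2, 6.6, 86, "Negative"),
]

# --- the same tumors' MUTYH variants ----------------------------------------
# (tumor_id, hgvs_c, hgvs_p, clinvar, cadd, revel, zygosity, origin)
_PV = ClinVarClass.PATHOGENIC
_VUS = ClinVarClass.VUS
_ABS = ClinVarClass.ABSENT
TABLE1_VARIANTS: list[tuple[str, str, str | None, ClinVarClass, float | None, float | None, str, str]] = [
    ("C2904", "c.91delG", "p.A31PfsTer27", _PV, 23.0, None, "het", "germline"),
    ("C2904", "c.1141G>T", "p.G381W", _VUS, 23.8, 0.521, "het", "germline"),
    ("O1016", "c.536A>G", "p.Y179C", _PV, 24.7, 0.963, "het", "germline"),
    ("O1016", "c.577-5A>G", None, _VUS, 16.9, None, "het", "germline"),
    ("C5024", "c.536A>G", "p.Y179C", _PV, 24.7, 0.963, "het", "germline"),
    ("C5024", "c.933+3A>C", None, _VUS, 6.4, None, "het", "germline"),
    ("C5024", "c.1465G>A", "p.A489T", _VUS, 29.4, 0.724, "het", "germline"),
    ("C0302", "c.1187G>A", "p.G396D", _PV, 29.4, 0.551, "het", "germline"),
    ("C0302", "c.1276C>T", "p.R426C", _VUS, 22.9, 0.615, "het", "germline"),
    ("C4622", "c.1187G>A", "p.G396D", _PV, 29.4, 0.551, "het", "germline"),
    ("C4622", "c.912C>G", "p.S304R", _VUS, 12.8, 0.229, "het", "germline"),
    ("O1569", "c.1187G>A", "p.G396D", _PV, 29.4, 0.551, "het", "germline"),
    ("O1569", "c.821G>A", "p.R274Q", _VUS, 33.0, 0.229, "het", "germline"),
    ("C5299", "c.1187G>A", "p.G396D", _PV, 29.4, 0.551, "het", "germline"),
    ("C5299", "c.1596C>A", "p.F532L", _VUS, 12.3, 0.063, "het", "somatic"),
    ("C4551", "c.389-1G>A", None, _PV, 2.3, None, "het", "germline"),
    ("C4551", "c.926G>A", "p.R309H", _VUS, 13.9, 0.293, "het", "somatic"),
    ("O0497", "c.1187G>A", "p.G396D", _PV, 29.4, 0.551, "het", "germline"),
    ("O0497", "c.607C>T", "p.R203C", _VUS, 23.9, 0.358, "het", "somatic"),
    ("C1060", "c.1465G>A", "p.A489T", _VUS, 29.4, 0.724, "het", "germline"),
    ("C1060", "c.933+3A>C", None, _VUS, 6.4, None, "het", "germline"),
    ("O2193", "c.1431G>C", "p.T477T", _VUS, 4.6, 0.039, "het", "germline"),
    ("O2193", "c.932G>A", "p.R311K", _VUS, 5.3, 0.245, "het", "germline"),
    ("O3288", "c.1420C>T", "p.R474C", _VUS, 23.2, 0.546, "het", "germline"),
    ("O3288", "c.603G>T", "p.M201I", _VUS, 16.8, 0.26, "het", "germline"),
    ("O3593", "c.1276C>T", "p.R426C", _VUS, 22.9, 0.615, "het", "germline"),
    ("O3593", "c.389-13C>G", None, _VUS, 14.9, None, "het", "germline"),
    ("O1434", "c.925C>T", "p.R309C", _VUS, 13.9, 0.592, "hom", "germline"),
    ("O3484", "c.925C>T", "p.R309C", _VUS, 13.9, 0.592, "hom", "germline"),
    ("C1701", "c.1431G>C", "p.T477T", _VUS, 4.6, 0.039, "hom", "germline"),
    ("C1701", "c.74G>A", "p.G25D", _VUS, 14.2, 0.111, "het", "germline"),
    ("C1701", "c.53C>T", "p.P18L", _VUS, 16.7, 0.2, "het", "germline"),
    ("C1701", "c.165+37_1650+39delGTT", None, _VUS, 12.8, None, "het", "germline"),
    ("O3625", "c.1286G>T", "p.G429V", _ABS, 22.3, 0.658, "het", "somatic"),
    ("O3625", "c.404T>A", "p.V135D", _ABS, 28.9, 0.898, "het", "somatic"),
]

# --- somatic-enrichment 2x2 counts (carriers with/without, non-carriers
# --- with/without) and the printed two-sided Fisher p-value ------------------
ENRICHMENT_TABLES: dict[str, tuple[int, int, int, int, float]] = {
    "KRAS_pG12C": (16, 3, 127, 5364 - 127, 2e-23),
    "PIK3CA_pQ546K": (7, 12, 36, 5364 - 36, 6e-11),
    "KRAS_gene": (17, 2, 2025, 5364 - 2025, 5e-6),
    "AMER1_gene": (9, 10, 592, 5364 - 592, 8e-5),
    "PIK3CA_gene": (10, 9, 934, 5364 - 934, 5e-4),
    "ROBO2_gene": (3, 16, 55, 5364 - 55, 1e-3),
    "ERBB3_gene": (4, 15, 388, 5352 - 388, 0.045),
}

# --- cohort-level summary statistics ----------------------------------------
# independent test set: all 5 biallelic carriers and all 2848 non-carriers correct
TEST_SET = {"true_pos": 5, "pos": 5, "correct": 2853, "total": 2853}
# validation set: 6/6 carriers found; 45 of 2424 non-carriers false positive
VALIDATION_SET = {"true_pos": 6, "pos": 6, "false_pos": 45, "neg": 2424}
# hypermutation: 12 of 19 carriers hypermutated vs 469/4510 MSS non-carriers
HYPERMUTATION = {"k": 12, "n": 19, "baseline_k": 469, "baseline_n": 4510}
# somatic mutation counts, carriers (train+validation) vs validation false positives
MUTATION_COUNT_SUMMARY = {"mean1": 20.8, "sd1": 7.8, "n1": 14, "mean2": 5.1, "sd2": 2.6, "n2": 45}
# reconstruction error (%), same groups
ERROR_SUMMARY = {"mean1": 19.8, "sd1": 8.3, "n1": 14, "mean2": 54.0, "sd2": 11.5, "n2": 45}
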