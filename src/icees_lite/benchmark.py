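"""Published cystic-fibrosis subcohort benchmark.

Reference contingency counts from a published open-EHR analysis of a CF
subcohort (N = 163; 126 patients with zero ED/inpatient respiratory visits,
37 with ≥1; 42 of the 163 carried valid geocodes, so exposure features have
the smaller denominator). The counts are encoded as plain per-level tuples
and expanded programmatically into a synthetic 163-row feature table whose
cross-tabulations reproduce every reference table exactly — each printed
table constrains only one feature × outcome joint, so features can be
assigned independently within outcome groups.

This is the package's numerical acceptance surface: running the
multiple-comparison scan over this table must reproduce the published
chi-square statistics to the printed precision.
"""

from __future__ import annotations

import pandas as pd

N_BETTER = 126
N_POOR = 37
N_GEOCODED_BETTER = 23
N_GEOCODED_POOR = 19

# feature → list of (level, count among better, count among poor), scheme order
BENCHMARK_TABLES: dict[str, list[tuple[str, int, int]]] = {
    "age": [("<5", 7, 0), ("5–17", 40, 17), ("18–44", 63, 15),
            ("45–64", 13, 5), ("65–89", 3, 0)],
    "sex": [("Male", 66, 16), ("Female", 60, 21)],
    "anxiety": [("0", 88, 24), ("1", 4, 1), (">1", 34, 12)],
    "asthma": [("0", 108, 6), ("1", 1, 4), (">1", 17, 27)],
    "bronchiectasis": [("0", 98, 25), ("1", 6, 1), (">1", 22, 11)],
    "chronic_nasal_congestion": [("0", 119, 32), ("1", 3, 0), (">1", 4, 5)],
    "chronic_obstructive_pulmonary_disease": [("0", 124, 36), ("1", 1, 1), (">1", 1, 0)],
    "congenital_malformation_of_respiratory_system":
        [("0", 126, 37), ("1", 0, 0), (">1", 0, 0)],
    "cough": [("0", 108, 19), ("1", 10, 7), (">1", 8, 11)],
    "croup": [("0", 126, 37), ("1", 0, 0), (">1", 0, 0)],
    "depression": [("0", 93, 28), ("1", 1, 0), (">1", 32, 9)],
    "diabetes": [("0", 101, 25), ("1", 1, 1), (">1", 24, 11)],
    "male_infertility": [("0", 126, 37), ("1", 0, 0), (">1", 0, 0)],
    "middle_ear_disease": [("0", 125, 33), ("1", 0, 1), (">1", 1, 3)],
    "neonatal_respiratory_distress": [("0", 126, 36), ("1", 0, 1), (">1", 0, 0)],
    "obesity": [("0", 124, 35), ("1", 0, 0), (">1", 2, 2)],
    "pneumonia": [("0", 115, 16), ("1", 2, 4), (">1", 9, 17)],
    "reactive_airway_disease": [("0", 124, 36), ("1", 1, 1), (">1", 1, 0)],
}

# exposure feature → per-level counts among the 42 geocoded patients
BENCHMARK_EXPOSURE_TABLES: dict[str, list[tuple[str, int, int]]] = {
    "cafo_distance": [("<500", 1, 0), ("500–1,000", 0, 0), ("1,000–2,000", 1, 0),
                      ("2,000–4,000", 2, 3), (">4,000", 19, 16)],
    "landfill_distance": [("<500", 0, 0), ("500–1,000", 0, 0), ("1,000–2,000", 0, 0),
                          ("2,000–4,000", 4, 0), (">4,000", 19, 19)],
    "roadway_distance": [("0–49", 4, 3), ("50–99", 1, 1), ("100–149", 4, 3),
                         ("150–199", 3, 0), ("200–249", 0, 3), ("≥250", 11, 9)],
    "residential_density": [("rural", 15, 17), ("urban cluster", 8, 2),
                            ("urbanized area", 0, 0)],
}

# published chi-square statistics for the eleven non-degenerate scan features
BENCHMARK_CHI2: dict[str, float] = {
    "asthma": 66.5946,
    "pneumonia": 41.8167,
    "cough": 21.0553,
    "middle_ear_disease": 9.9371,
    "chronic_nasal_congestion": 6.6135,
    "anxiety": 0.4247,
    "bronchiectasis": 2.8042,
    "depression": 0.3201,
    "diabetes": 2.9560,
    "sex": 0.9553,
    "age": 5.3851,
}

BENCHMARK_FEATURES = list(BENCHMARK_TABLES) + list(BENCHMARK_EXPOSURE_TABLES)


def _expand_levels(table, n_group: dict[str, int]) -> dict[str, list[str]]:
    """Per outcome group, the level sequence implied by the per-level counts."""
    out = {}
    for gi, group in enumerate(("better", "poor")):
        seq: list[str] = []
        for row in table:
            seq.extend([row[0]] * row[1 + gi])
        if len(seq) != n_group[group]:
            raise ValueError(f"benchmark table does not sum to group size for {group}")
        out[group] = seq
    return out


def build_benchmark_feature_table() -> pd.DataFrame:
    """The 163-row de-identified feature table implied by the benchmark counts."""
    groups = {"better": N_BETTER, "poor": N_POOR}
    geocoded = {"better": N_GEOCODED_BETTER, "poor": N_GEOCODED_POOR}

    rows = []
    for group in ("better", "poor"):
        for i in range(groups[group]):
            rows.append({
                "patient_key": f"bm-{group}-{i:03d}",
                "outcome": group,
                "_geocoded": i < geocoded[group],
            })
    df = pd.DataFrame(rows)

    for feature, table in BENCHMARK_TABLES.items():
        seqs = _expand_levels(table, groups)
        values = []
        for group in ("better", "poor"):
            values.extend(seqs[group])
        df[feature] = values

    for feature, table in BENCHMARK_EXPOSURE_TABLES.items():
        seqs = _expand_levels(table, geocoded)
        values = []
        for group in ("better", "poor"):
            seq = iter(seqs[group])
            for i in range(groups[group]):
                values.append(next(seq) if i < geocoded[group] else "Missing")
        df[feature] = values

    return df.drop(columns="_geocoded")
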