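"""Builtin reference summary statistics for the default study cohort.

Per-analyte per-group means and standard deviations for 45 routine
hematological and biochemical parameters, plus the demographic summary
(group sizes, sex counts, age mean/SD per group) of the reference
case-control cohort.  These numbers parameterize the default synthetic
cohort generator; they are summary statistics, not patient data.
"""

from __future__ import annotations

# name, control_mean, control_sd, case_mean, case_sd
# Ordered by decreasing between-group significance in the reference cohort.
ANALYTE_STATS: list[tuple[str, float, float, float, float]] = [
    ("MO#", 0.53, 0.185, 0.619, 0.237),
    ("HCT", 44.356, 4.207, 42.358, 4.24),
    ("HGB", 15.256, 1.76, 14.371, 1.726),
    ("RBC", 5.112, 0.498, 4.91, 0.471),
    ("Iron", 53.547, 32.252, 73.258, 40.752),
    ("Calcium", 9.744, 0.182, 9.576, 0.371),
    ("Glucose", 93.312, 26.932, 83.039, 10.139),
    ("Potassium", 4.408, 0.171, 4.303, 0.305),
    ("MO%", 7.451, 1.876, 8.153, 2.024),
    ("MCHC", 34.106, 1.369, 33.602, 1.461),
    ("BA#", 0.016, 0.018, 0.021, 0.017),
    ("BA%", 0.21, 0.225, 0.279, 0.222),
    ("GGT", 22.385, 6.636, 30.212, 37.351),
    ("Triglyceride", 109.932, 33.427, 142.409, 153.837),
    ("RDW-SD", 40.514, 2.654, 41.342, 2.977),
    ("IG%", 0.316, 0.218, 0.389, 0.284),
    ("IG#", 0.025, 0.021, 0.031, 0.024),
    ("Sodium", 139.807, 1.048, 140.241, 1.969),
    ("MCH", 29.76, 2.202, 29.152, 2.199),
    ("RDW-CV", 12.94, 1.15, 13.215, 1.16),
    ("NRBC#", 0.0, 0.001, 0.0, 0.002),
    ("NE%", 58.646, 8.187, 56.64, 10.77),
    ("PLT", 252.594, 54.953, 241.248, 57.168),
    ("Creatinine", 0.802, 0.144, 0.83, 0.152),
    ("NRBC%", 0.001, 0.014, 0.004, 0.022),
    ("AST", 22.859, 10.654, 24.931, 15.562),
    ("PCT", 0.262, 0.049, 0.254, 0.056),
    ("WBC", 7.351, 2.72, 7.7, 2.204),
    ("MPV", 10.315, 0.805, 10.425, 0.931),
    ("MCV", 86.831, 4.376, 86.275, 4.605),
    ("LY%", 31.073, 7.887, 32.135, 9.922),
    ("ALP", 76.422, 20.669, 79.271, 29.164),
    ("EO#", 0.149, 0.13, 0.163, 0.144),
    ("NE#", 4.449, 1.554, 4.601, 1.888),
    ("LDL Cholesterole", 90.688, 12.292, 89.084, 24.059),
    ("LY#", 2.323, 1.592, 2.428, 0.782),
    ("tGFH", 118.88, 12.021, 119.621, 9.876),
    ("PDW", 12.056, 1.668, 12.159, 2.042),
    ("EO%", 2.058, 1.744, 2.144, 1.924),
    ("HDL Cholesterole", 43.37, 4.677, 43.665, 8.12),
    ("ALT", 24.953, 19.345, 25.778, 18.138),
    ("Urea", 24.536, 6.078, 24.281, 6.683),
    ("Total Cholesterole", 159.719, 16.99, 160.616, 34.498),
    ("BUN", 11.401, 2.867, 11.31, 3.154),
    ("NLR", 2.082, 0.923, 2.096, 1.351),
]

# Demographic summary of the reference cohort.
DEMOGRAPHICS = {
    "n_control": 192,
    "n_case": 203,
    "male_control": 130,
    "male_case": 154,
    "age_control_mean": 28.3,
    "age_control_sd": 10.7,
    "age_case_mean": 28.7,
    "age_case_sd": 3.9,
}
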