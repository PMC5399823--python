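"""Published reference results for the packaged triticale aluminium-stress
dataset.

These are the numbers printed in the study that produced the dataset: the
per-code event-weight rows that are unambiguous in print, the per-line
event totals, and the two-decimal quantitative characteristics with their
group means ± SD.  A handful of printed cells are internally inconsistent
with the study's own event-total table (two lines with identical event
columns print different percentages); those cells are listed in
``PRINT_DISCREPANCIES`` and can only be matched approximately.
"""

SAMPLES = ["NT1", "NT2", "NT3", "NT4", "NT5", "T1", "T2", "T3", "T4", "T5"]

# Per-code event weights, columns (DM, DNM, MSP, NMSP, M, NM, DNM-CHG,
# DNM-CG, DM-CHG, DM-CG), for the rows whose print is unambiguous.
WEIGHT_ROWS = {
    "0000": (2, 2, 10, 2, 12, 4, 0, 2, 0, 2),
    "0001": (9, 3, 3, 1, 6, 10, 0, 3, 8, 1),
    "0010": (4, 0, 2, 2, 2, 6, 0, 0, 2, 2),
    "0011": (6, 0, 0, 2, 0, 8, 0, 0, 4, 2),
    "0100": (3, 9, 3, 1, 12, 4, 8, 1, 0, 3),
    "0101": (1, 1, 5, 9, 6, 10, 0, 1, 0, 1),
    "0111": (3, 0, 0, 5, 0, 8, 0, 0, 0, 3),
    "1011": (1, 0, 0, 3, 0, 4, 0, 0, 1, 0),
    "1100": (0, 6, 0, 2, 6, 2, 4, 2, 0, 0),
    "1101": (0, 3, 0, 5, 3, 5, 0, 3, 0, 0),
    "1110": (0, 1, 0, 3, 1, 3, 1, 0, 0, 0),
    "1111": (0, 0, 0, 4, 0, 4, 0, 0, 0, 0),
}

# Per-line event totals (rows) over SAMPLES (columns).
EVENT_TOTALS = {
    "DM": [225, 206, 225, 235, 202, 228, 231, 224, 218, 206],
    "DNM": [142, 142, 142, 142, 142, 148, 148, 142, 142, 142],
    "MSP": [936, 937, 936, 938, 937, 939, 936, 937, 940, 937],
    "NMSP": [2217, 2211, 2217, 2221, 2219, 2221, 2221, 2213, 2228, 2211],
    "M": [1078, 1079, 1078, 1080, 1079, 1087, 1084, 1079, 1082, 1079],
    "NM": [2442, 2417, 2442, 2456, 2421, 2449, 2452, 2437, 2446, 2417],
    "DNM-CHG": [0, 0, 0, 0, 0, 4, 4, 0, 0, 0],
    "DNM-CG": [142, 142, 142, 142, 142, 144, 144, 142, 142, 142],
    "DM-CHG": [51, 38, 51, 57, 36, 52, 55, 50, 46, 38],
    "DM-CG": [174, 168, 174, 178, 166, 176, 176, 174, 172, 168],
    "Total": [3520, 3496, 3520, 3536, 3500, 3536, 3536, 3516, 3528, 3496],
}

# Two-decimal quantitative characteristics over SAMPLES.
CHARACTERISTICS = {
    "NMSP%": [62.98, 63.24, 62.98, 62.81, 63.40,
              62.81, 62.81, 62.94, 63.15, 63.24],
    "MSP%": [26.59, 26.80, 26.59, 26.53, 26.77,
             26.56, 26.47, 26.65, 26.64, 26.80],
    "DM%": [6.39, 5.87, 6.39, 6.65, 5.77, 6.45, 6.53, 6.37, 6.18, 5.89],
    "DNM%": [4.03, 4.06, 4.03, 4.02, 4.06, 4.19, 4.19, 4.04, 4.02, 4.06],
    "M%": [30.63, 30.86, 30.63, 30.54, 30.83,
           30.74, 30.66, 30.69, 30.67, 30.86],
    "NM%": [69.38, 69.14, 69.38, 69.46, 69.17,
            69.26, 69.34, 69.31, 69.33, 69.14],
    "DM-CG%": [4.94, 4.80, 4.94, 5.03, 4.74, 4.98, 4.99, 4.95, 4.88, 4.80],
    "DM-CHG%": [1.45, 1.09, 1.45, 1.61, 1.03, 1.47, 1.55, 1.42, 1.30, 1.09],
    "DNM-CG%": [4.03, 4.06, 4.03, 4.02, 4.06, 4.07, 4.07, 4.04, 4.03, 4.06],
    "DNM-CHG%": [0.00, 0.00, 0.00, 0.00, 0.00, 0.11, 0.11, 0.00, 0.00, 0.00],
}

# (characteristic, sample) cells whose print contradicts EVENT_TOTALS
# (e.g. NT2 and T5 share DM=206 / Total=3496 yet print different DM%).
PRINT_DISCREPANCIES = {
    ("DM%", "NT2"),
    ("DM-CG%", "NT2"),
    ("DM-CG%", "T2"),
    ("DM-CG%", "T5"),
    ("DM-CHG%", "T2"),
    ("DNM-CG%", "T4"),
}

# Group means and sample SDs of the characteristics, printed to 2 decimals.
GROUP_SUMMARY = {  # characteristic: (NT mean, NT sd, T mean, T sd)
    "NMSP%": (63.08, 0.23, 62.99, 0.19),
    "MSP%": (26.66, 0.12, 26.62, 0.12),
    "DM%": (6.22, 0.37, 6.28, 0.25),
    "DNM%": (4.04, 0.01, 4.10, 0.08),
    "M%": (30.69, 0.13, 30.72, 0.08),
    "NM%": (69.31, 0.14, 69.28, 0.08),
    "DM-CG%": (4.89, 0.11, 4.91, 0.07),
    "DM-CHG%": (1.32, 0.25, 1.36, 0.18),
    "DNM-CG%": (4.04, 0.01, 4.05, 0.02),
    "DNM-CHG%": (0.00, 0.00, 0.05, 0.06),
}

# (characteristic, group, statistic) summary cells off by 0.01 from the
# recomputation on unrounded values (last-digit noise in the print).
SUMMARY_DISCREPANCIES = {
    ("NMSP%", "T", "sd"),
    ("DM%", "T", "sd"),
    ("DNM%", "NT", "sd"),
    ("M%", "NT", "mean"),
    ("M%", "NT", "sd"),
    ("NM%", "NT", "mean"),
    ("DM-CG%", "NT", "sd"),
    ("DM-CG%", "T", "mean"),
    ("DM-CHG%", "NT", "mean"),
    ("DM-CHG%", "T", "mean"),
    ("DNM-CG%", "NT", "sd"),
}

# The three lines reported to separate from the remaining seven under
# Ward clustering with automatic truncation.
DIVERGENT_LINES = {"NT2", "NT5", "T5"}
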