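"""Reference classification fixture.

Published triggering-score difference matrices (inhibited minus
activated, already normalized by their producers) for the targets and
off-targets of two BTK inhibitors, over the pathophysiological
processes of atrial fibrillation and of hypertension, together with the
published trigger calls. The decision rule D > 0.2 must reproduce those
calls exactly — note the near-threshold negatives (FGR 0.17 and FLT3
0.18 in electrophysiology, RIPK2 0.18 in RAAS) that strictness must
leave unflagged.
"""

import pandas as pd

AF_PROCESSES = [
    "inflammation",
    "structural_remodeling",
    "electrophysiology",
    "autonomic_remodeling",
    "raas",
]

# protein: differences per AF process, in AF_PROCESSES order
AF_DIFFERENCES = {
    "HCK":   [-0.40, 1.27, 0.10, -0.06, -0.31],
    "FGR":   [-0.32, 1.05, 0.17, -0.06, -0.29],
    "LYN":   [-0.45, 1.02, 0.30, -0.06, -0.32],
    "ERBB4": [-0.56, 0.91, 0.63, -0.36, -0.55],
    "FYN":   [-0.20, 0.75, 0.10, -0.80, -0.32],
    "TEC":   [-0.10, 0.43, 0.30, -0.15, -0.04],
    "FLT3":  [-0.62, 0.24, 0.18, -0.06, -0.29],
    "YES1":  [-0.02, 0.23, 0.04, -0.06, -0.01],
    "CSK":   [-1.27, -0.09, -1.30, 0.43, -0.04],
    "SRC":   [-1.48, -2.88, 0.37, -1.79, -0.50],
    "BMX":   [-0.27, -0.17, -0.12, 0.04, 0.00],
    "LIMK1": [0.00, 0.00, 0.00, 0.00, 0.00],
    "ITK":   [0.00, 0.11, 0.16, -0.17, 0.00],
    "PTK6":  [0.11, -0.20, -0.03, -0.01, -0.01],
    "TXK":   [0.01, -0.06, 0.00, -0.27, 0.00],
    "JAK3":  [-0.93, -0.39, 0.12, -0.16, -0.26],
    "BTK":   [-0.41, -0.58, -0.04, -0.30, -0.66],
    "LCK":   [-1.45, -0.13, 0.02, -0.15, -0.28],
    "BLK":   [-1.78, -0.60, -0.63, 0.05, -0.17],
    "ERBB2": [-1.28, -1.21, -0.23, -0.26, -0.51],
    "EGFR":  [-1.16, -2.25, -0.65, -0.16, -0.62],
    "RIPK2": [-1.95, -2.48, -0.92, -0.07, -0.40],
}

AF_EXPECTED_TRIGGERS = {
    ("HCK", "structural_remodeling"),
    ("FGR", "structural_remodeling"),
    ("LYN", "structural_remodeling"),
    ("ERBB4", "structural_remodeling"),
    ("FYN", "structural_remodeling"),
    ("TEC", "structural_remodeling"),
    ("FLT3", "structural_remodeling"),
    ("YES1", "structural_remodeling"),
    ("LYN", "electrophysiology"),
    ("ERBB4", "electrophysiology"),
    ("TEC", "electrophysiology"),
    ("SRC", "electrophysiology"),
    ("CSK", "autonomic_remodeling"),
}

HTN_PROCESSES = ["inflammation", "oxidative_stress", "sympathetic", "raas"]

HTN_DIFFERENCES = {
    "ERBB4": [0.24, 0.60, -0.29, -0.30],
    "ERBB2": [0.01, 1.39, -0.18, -1.30],
    "RIPK2": [-1.62, 1.30, -0.21, 0.18],
    "BLK":   [-1.40, 0.80, -0.27, -0.11],
    "SRC":   [-0.79, 0.43, -0.46, -0.35],
    "LCK":   [0.27, -0.36, -0.15, -0.52],
    "JAK3":  [0.40, -0.63, -0.24, -0.51],
    "FLT3":  [0.26, -0.79, -0.12, -0.60],
    "CSK":   [-1.15, 0.25, -0.04, 1.14],
    "LIMK1": [0.00, 0.00, 0.00, 0.00],
    "TXK":   [0.00, -0.06, 0.00, 0.02],
    "PTK6":  [0.06, -0.09, -0.01, -0.19],
    "YES1":  [-0.21, -0.12, -0.02, -0.13],
    "ITK":   [-0.01, -0.19, 0.04, -0.09],
    "LYN":   [-0.01, -0.43, -0.15, -0.65],
    "EGFR":  [-0.56, -0.46, -0.20, -1.72],
    "BTK":   [-1.36, -0.47, 0.00, -0.48],
    "TEC":   [-0.01, -0.49, -0.04, -0.46],
    "BMX":   [-0.37, -0.58, 0.03, 0.03],
    "FYN":   [-1.04, -0.60, 0.11, -0.24],
    "FGR":   [-0.02, -0.67, -0.12, -0.45],
    "HCK":   [-0.23, -0.71, -0.12, -0.47],
}

HTN_EXPECTED_TRIGGERS = {
    ("ERBB4", "inflammation"),
    ("LCK", "inflammation"),
    ("JAK3", "inflammation"),
    ("FLT3", "inflammation"),
    ("ERBB4", "oxidative_stress"),
    ("ERBB2", "oxidative_stress"),
    ("RIPK2", "oxidative_stress"),
    ("BLK", "oxidative_stress"),
    ("SRC", "oxidative_stress"),
    ("CSK", "oxidative_stress"),
    ("CSK", "raas"),
}


def as_table(differences: dict[str, list[float]], processes: list[str]) -> pd.DataFrame:
    rows = [
        {"protein": protein, "process": proc, "difference": d}
        for protein, values in differences.items()
        for proc, d in zip(processes, values)
    ]
    return pd.DataFrame(rows)
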