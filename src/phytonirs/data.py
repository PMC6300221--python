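"""Reference tables from the B. sacra phytohormone NIRS survey that this
package's defaults emulate.

``reference_candidates`` holds the published preprocessing-selection
metrics (six candidate rows per hormone: calibration and external
prediction error for {no pretreatment, MSC, SG 13-point first derivative}
on full and reduced wavenumber windows).  The cross-validation column was
not published, so ``rmsecv`` is NaN in these reports.

``REFERENCE_PROFILES`` holds the reported per-population hormone contents
(mean ± SE over 3 replicates, µg per g fresh weight) for the thirteen
populations POP1..POP13.  They serve as ground truth for closed-loop
simulation studies.
"""

from __future__ import annotations

import math

from .calibration import CandidateReport
from .preprocess import PreprocessSpec

__all__ = ["reference_candidates", "REFERENCE_CANDIDATE_ROWS",
           "REFERENCE_PROFILES", "reference_profile_frame"]

# (method, window_low, window_high, rmsec, r2_cal, rmsep, r2_pred, n_factors)
REFERENCE_CANDIDATE_ROWS: dict[str, list[tuple]] = {
    "IAA": [
        ("none", 4000, 10000, 6.23, 0.829, 7.58, 0.746, 5),
        ("none", 4000, 6000, 6.94, 0.7877, 12.8, 0.276, 5),
        ("msc", 4000, 10000, 4.27, 0.91, 5.84, 0.85, 7),
        ("msc", 4000, 6000, 6.54, 0.80, 8.59, 0.67, 5),
        ("sg1d", 4000, 10000, 0.470, 0.99, 2.97, 0.94, 7),
        ("sg1d", 4000, 5000, 5.10, 0.86, 9.69, 0.58, 4),
    ],
    "GA": [
        ("none", 4000, 10000, 4.46, 0.91, 8.20, 0.70, 7),
        ("none", 4000, 7000, 5.300, 0.877, 12.8, 0.34, 7),
        ("msc", 4000, 10000, 4.31, 0.91, 4.51, 0.91, 7),
        ("msc", 4000, 7000, 8.31, 0.69, 7.37, 0.76, 5),
        ("sg1d", 4000, 10000, 0.903, 0.99, 1.29, 0.98, 7),
        ("sg1d", 4000, 7000, 4.31, 0.89, 6.85, 0.79, 7),
    ],
    "SA": [
        ("none", 4000, 10000, 0.08, 0.99, 1.36, 0.92, 7),
        ("none", 4000, 6000, 5.98, 0.10, 5.89, 0.1291, 1),
        ("msc", 4000, 10000, 0.9697, 0.97, 0.9880, -6.94, 5),
        ("msc", 4000, 6000, 1.78, 0.65, 12.16, -8.36, 3),
        ("sg1d", 4000, 10000, 0.85, 0.92, 12.48, -8.85, 4),
        ("sg1d", 4000, 6000, 1.61, 0.71, 13.02, -9.13, 4),
    ],
    "kinetin": [
        ("none", 4000, 10000, 0.715, 0.99, 1.45, 0.92, 7),
        ("none", 4000, 6000, 3.71, 0.93, 11.66, 0.4018, 1),
        ("msc", 4000, 10000, 5.94, 0.84, 8.59, 0.67, 4),
        ("msc", 4000, 6000, 4.37, 0.91, 14.52, 0.07, 4),
        ("sg1d", 4000, 10000, 2.63, 0.96, 7.93, 0.72, 5),
        ("sg1d", 4000, 7000, 5.99, 0.84, 9.63, 0.59, 3),
    ],
}

# population -> hormone -> (mean µg/g FW, SE µg/g FW); n = 3 replicates
REFERENCE_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "POP1": {"IAA": (123.7, 2.31), "GA": (112.4, 0.21), "SA": (136.9, 0.43), "kinetin": (61.5, 1.34)},
    "POP2": {"IAA": (143.6, 1.01), "GA": (164.7, 0.42), "SA": (193.3, 0.41), "kinetin": (42.6, 1.4)},
    "POP3": {"IAA": (119.8, 1.0), "GA": (151.7, 0.76), "SA": (172.5, 0.52), "kinetin": (51.0, 2.0)},
    "POP4": {"IAA": (108.7, 0.81), "GA": (143.1, 0.56), "SA": (152.8, 0.76), "kinetin": (53.8, 0.98)},
    "POP5": {"IAA": (128.6, 0.89), "GA": (117.9, 0.54), "SA": (135.6, 0.56), "kinetin": (68.9, 0.99)},
    "POP6": {"IAA": (130.2, 0.73), "GA": (127.8, 0.94), "SA": (168.2, 0.76), "kinetin": (57.2, 0.67)},
    "POP7": {"IAA": (116.5, 0.98), "GA": (124.7, 0.32), "SA": (150.9, 0.89), "kinetin": (55.9, 0.71)},
    "POP8": {"IAA": (125.2, 0.42), "GA": (141.9, 2.1), "SA": (171.1, 0.32), "kinetin": (59.9, 0.45)},
    "POP9": {"IAA": (124.3, 0.37), "GA": (135.4, 0.91), "SA": (146.9, 0.43), "kinetin": (69.4, 0.5)},
    "POP10": {"IAA": (113.5, 0.31), "GA": (149.5, 0.87), "SA": (129.4, 0.76), "kinetin": (66.9, 1.2)},
    "POP11": {"IAA": (138.3, 0.54), "GA": (146.2, 0.98), "SA": (164.1, 0.67), "kinetin": (65.4, 0.98)},
    "POP12": {"IAA": (146.9, 1.01), "GA": (148.5, 0.78), "SA": (156.0, 0.83), "kinetin": (58.3, 0.23)},
    "POP13": {"IAA": (308.791, 0.87), "GA": (244.364, 0.89), "SA": (382.657, 0.88), "kinetin": (103.847, 1.2)},
}


def reference_candidates(analyte: str) -> list[CandidateReport]:
    """The published candidate metrics for one hormone as CandidateReports."""
    rows = REFERENCE_CANDIDATE_ROWS[analyte]
    out = []
    for method, lo, hi, rmsec, r2c, rmsep, r2p, nf in rows:
        out.append(CandidateReport(
            spec=PreprocessSpec(method=method, window_low=lo, window_high=hi),
            rmsec=rmsec, r2_cal=r2c, rmsecv=math.nan,
            rmsep=rmsep, r2_pred=r2p, n_factors=nf, analyte=analyte,
        ))
    return out


def reference_profile_frame():
    """REFERENCE_PROFILES as a long-format pandas DataFrame."""
    import pandas as pd

    rows = []
    for pop, d in REFERENCE_PROFILES.items():
        for h, (m, se) in d.items():
            rows.append({"population": pop, "hormone": h,
                         "mean_ug_per_gfw": m, "se": se, "n": 3})
    return pd.DataFrame(rows)
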