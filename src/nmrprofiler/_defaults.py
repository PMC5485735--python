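"""Construction of the packaged default region scheme and effect template.

The 17 entries in ``PUBLISHED_REGIONS`` / ``PUBLISHED_EFFECTS`` are the
region boundaries, assignments and group summary statistics (arithmetic
mean ± SD of the relative concentration per group, n = 7 per group)
published for this plasma profiling protocol.  Everything else here —
filler region boundaries, null-variable means — is a synthetic stand-in
constructed so that the complete 110-variable scheme (15 glucose-flagged)
is executable end to end.  The packaged CSV resources are generated from
these builders and must stay in sync (enforced by tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regions import Region, RegionTable

# var_id, ppm_hi, ppm_lo, assignment, is_glucose
PUBLISHED_REGIONS: list[tuple[int, float, float, str, bool]] = [
    (18, 5.4300, 5.2752, "-HC=CH- in fatty acid chain", False),
    (24, 4.4100, 4.3159,
     "C1H and C3H in glycerol backbone of triglycerides + OCH2 of choline "
     "in sphingomyelin/phosphatidylcholine", False),
    (34, 4.0310, 4.0136, "L-serine", False),
    (35, 4.0136, 4.0010, "L-serine", False),
    (38, 3.9590, 3.8330, "D-glucose", True),
    (41, 3.7956, 3.7820, "D-glucose", True),
    (42, 3.7820, 3.7550, "D-glucose", True),
    (43, 3.7550, 3.7390, "D-glucose", True),
    (44, 3.7390, 3.7141, "D-glucose", True),
    (51, 3.5914, 3.5649, "D-glucose", True),
    (52, 3.5649, 3.5510, "D-glucose", True),
    (54, 3.5360, 3.3980, "D-glucose", True),
    (55, 3.3980, 3.3765, "L-tryptophan", False),
    (63, 3.1090, 3.0860, "L-cysteine", False),
    (91, 2.1230, 1.9720, "-CH2-CH=CH- in fatty acid chain", False),
    (100, 1.3450, 1.2458, "CH3-(CH2)n- in fatty acid chain", False),
    (110, 0.9660, 0.8000, "CH3-(CH2)n- in fatty acid chain", False),
]

# var_id: (mean_case, sd_case, mean_control, sd_control); case = T1DM
PUBLISHED_EFFECTS: dict[int, tuple[float, float, float, float]] = {
    18: (21.95, 3.63, 30.95, 4.00),
    24: (3.28, 1.16, 5.09, 1.16),
    34: (0.70, 0.26, 1.21, 0.22),
    35: (0.84, 0.28, 1.29, 0.23),
    38: (91.99, 16.9, 64.44, 6.58),
    41: (7.62, 0.60, 6.18, 0.60),
    42: (30.58, 5.63, 20.56, 1.95),
    43: (17.92, 3.83, 11.85, 1.35),
    44: (17.76, 3.24, 13.05, 1.49),
    51: (14.45, 2.19, 10.20, 1.06),
    52: (5.84, 1.10, 3.65, 0.50),
    54: (116.37, 30.40, 69.27, 8.54),
    55: (0.70, 0.32, 1.94, 0.41),
    63: (2.28, 0.47, 3.05, 0.39),
    91: (53.13, 7.19, 64.03, 3.76),
    100: (117.69, 17.62, 155.40, 22.01),
    110: (89.10, 14.79, 111.75, 7.83),
}

LIPID_VAR_IDS = [18, 24, 91, 100, 110]

# (first_var_id, last_var_id, ppm_hi, ppm_lo, is_glucose); equal-width split.
# The gap between 5.00 and 4.50 ppm is the water band, left uncovered.
_FILLER_SEGMENTS: list[tuple[int, int, float, float, bool]] = [
    (1, 17, 8.6000, 5.4300, False),
    (19, 19, 5.2752, 5.2200, True),    # anomeric glucose envelope
    (20, 21, 5.2200, 5.0000, False),
    (22, 23, 4.5000, 4.4100, False),
    (25, 33, 4.3159, 4.0310, False),
    (36, 37, 4.0010, 3.9590, True),    # glucose envelope 3.96-4.00 ppm
    (39, 40, 3.8330, 3.7956, False),
    (45, 50, 3.7141, 3.5914, False),
    (53, 53, 3.5510, 3.5360, False),
    (56, 59, 3.3765, 3.2000, True),    # glucose envelope 3.20-3.40 ppm
    (60, 62, 3.2000, 3.1090, False),
    (64, 90, 3.0860, 2.1230, False),
    (92, 99, 1.9720, 1.3450, False),
    (101, 109, 1.2458, 0.9660, False),
]

# Fixed stream for the null-variable means of the default template, so the
# default template is a reproducible constant rather than run-dependent.
_TEMPLATE_SEED = 110110

NULL_MEAN_RANGE = (0.5, 50.0)  # log-uniform draw for unpublished variables
NULL_CV = 0.15                 # SD as a fraction of the mean for null variables
GLUCOSE_BLOCK_RHO = 0.8
LIPID_BLOCK_RHO = 0.6


def build_default_regions() -> RegionTable:
    regions = [Region(*row) for row in PUBLISHED_REGIONS]
    for first, last, hi, lo, gluc in _FILLER_SEGMENTS:
        n = last - first + 1
        edges = np.linspace(hi, lo, n + 1)
        for i in range(n):
            regions.append(
                Region(
                    var_id=first + i,
                    ppm_hi=round(float(edges[i]), 4),
                    ppm_lo=round(float(edges[i + 1]), 4),
                    assignment="D-glucose (envelope)" if gluc else "unassigned",
                    is_glucose=gluc,
                )
            )
    return RegionTable(regions, name="default-110")


def build_default_template_frame() -> pd.DataFrame:
    """110-row effect template: published rows verbatim, null fillers."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    lo, hi = NULL_MEAN_RANGE
    rows = []
    for var_id in range(1, 111):
        if var_id in PUBLISHED_EFFECTS:
            mc, sc, mk, sk = PUBLISHED_EFFECTS[var_id]
        else:
            m = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            mc = mk = round(m, 6)
            sc = sk = round(NULL_CV * m, 6)
        rows.append((var_id, mc, sc, mk, sk))
    return pd.DataFrame(
        rows, columns=["var_id", "mean_case", "sd_case", "mean_control", "sd_control"]
    )
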