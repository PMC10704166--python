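"""Published reference medians for a 16-participant electrode-model comparison.

Median current densities (A/m^2) computed over the whole head and over the
brain for each of 16 older-adult head models, once with idealized
("artificial") electrode placement and once with as-placed ("real")
electrodes segmented from structural scans, together with the printed
percent differences (PD, 100*|artificial-real|/real, rounded to 2 decimals).
Used to validate the percent-difference arithmetic against an independent
published computation.
"""

from __future__ import annotations

import pandas as pd

# participant, J whole-head artificial, J whole-head real, printed PD,
# J brain artificial, J brain real, printed PD
_ROWS = [
    (1, 0.0227, 0.0284, 20.07, 0.0191, 0.0219, 12.79),
    (2, 0.0225, 0.0359, 37.33, 0.0215, 0.0308, 30.19),
    (3, 0.0349, 0.0469, 25.59, 0.0256, 0.0363, 29.48),
    (4, 0.0243, 0.0243, 0.00, 0.0206, 0.0232, 11.21),
    (5, 0.0211, 0.0272, 22.43, 0.0215, 0.0255, 15.69),
    (6, 0.0244, 0.0323, 24.46, 0.0234, 0.0280, 16.43),
    (7, 0.0306, 0.0293, 4.44, 0.0186, 0.0210, 11.43),
    (8, 0.0227, 0.0302, 24.83, 0.0186, 0.0231, 19.48),
    (9, 0.0236, 0.0317, 25.55, 0.0191, 0.0252, 24.21),
    (10, 0.0314, 0.0372, 15.59, 0.0242, 0.0310, 21.94),
    (11, 0.0225, 0.0264, 14.77, 0.0186, 0.0219, 15.07),
    (12, 0.0288, 0.0284, 1.41, 0.0220, 0.0256, 14.06),
    (13, 0.0306, 0.0362, 15.47, 0.0223, 0.0238, 6.30),
    (14, 0.0304, 0.0318, 4.40, 0.0189, 0.0216, 12.50),
    (15, 0.0237, 0.0360, 34.17, 0.0242, 0.0283, 14.49),
    (16, 0.0216, 0.0327, 33.94, 0.0204, 0.0240, 15.00),
]

COLUMNS = [
    "participant",
    "j_whole_head_artificial",
    "j_whole_head_real",
    "pd_whole_head",
    "j_brain_artificial",
    "j_brain_real",
    "pd_brain",
]


def reference_median_table() -> pd.DataFrame:
    """The reference medians as a DataFrame indexed by participant."""
    return pd.DataFrame(_ROWS, columns=COLUMNS).set_index("participant")
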