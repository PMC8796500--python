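"""Health-state space of the disease model.

Living states are EDSS (Expanded Disability Status Scale) bands.  Patients in
the two lowest bands are in the relapsing-remitting phase (RRMS) and receive
disease-modifying therapy; transition into EDSS >= 6 marks secondary
progression (SPMS), at which point therapy is stopped.  Death is absorbing.
"""

from __future__ import annotations

# Ordered living states; index order is the row/column order of every
# transition matrix and occupancy vector in the package.
LIVING_STATES: tuple[str, ...] = (
    "edss_0_2_5",
    "edss_3_5_5",
    "edss_6_7_5",
    "edss_8_9_5",
)

DEATH = "death"

RRMS_STATES: tuple[str, ...] = LIVING_STATES[:2]
SPMS_STATES: tuple[str, ...] = LIVING_STATES[2:]

STATE_LABELS = {
    "edss_0_2_5": "EDSS 0-2.5",
    "edss_3_5_5": "EDSS 3-5.5",
    "edss_6_7_5": "EDSS 6-7.5",
    "edss_8_9_5": "EDSS 8-9.5",
    DEATH: "Death",
}

N_LIVING = len(LIVING_STATES)
STATE_INDEX = {s: i for i, s in enumerate(LIVING_STATES)}
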