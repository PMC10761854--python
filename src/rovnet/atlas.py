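"""Published region-of-variance coordinate table.

Thirteen ROVs of the story-comprehension (semantic processing) network,
identified from the HCP young-adult cohort: six functional ROVs (peaks of
the activity-variance F-map) and seven structural ROVs (peaks of the
grey-matter-volume SD map). Peaks are MNI mm coordinates; every ROV is a
10-mm sphere around its peak. The left angular gyrus appears twice — as a
functional and a structural node at nearby but distinct peaks — and both
are kept as separate network nodes.

Abbreviations: SFGmed/SFGdor medial/dorsolateral superior frontal gyrus,
ANG angular gyrus, IFG inferior frontal gyrus (operc/triang: pars
opercularis/triangularis), STG superior temporal gyrus, PCUN precuneus,
PreCG precentral gyrus, CAU caudate nucleus; L/R hemisphere.
"""

from __future__ import annotations

import pandas as pd

RADIUS_MM = 10.0

#: (label, kind, x, y, z) in MNI mm
PUBLISHED_ROVS: list[tuple[str, str, float, float, float]] = [
    ("RSFGmed", "functional", 9, 51, 39),
    ("LANG_f", "functional", -42, -54, 24),
    ("LIFGoperc", "functional", -54, 18, 18),
    ("RSTG", "functional", 54, -24, 15),
    ("LPCUN", "functional", -3, -60, 36),
    ("LSTG", "functional", -39, -36, 12),
    ("LSFGdor", "structural", -20, 16, 45),
    ("RIFGtriang", "structural", 39, 18, 27),
    ("LIFGtriang", "structural", -36, 15, 27),
    ("LANG_s", "structural", -39, -57, 30),
    ("RANG", "structural", 45, -48, 27),
    ("RPreCG", "structural", 18, -18, 66),
    ("RCAU", "structural", 15, 6, 21),
]


def published_rovs() -> pd.DataFrame:
    """The 13-node published ROV table (label, kind, x, y, z, radius_mm)."""
    df = pd.DataFrame(PUBLISHED_ROVS, columns=["label", "kind", "x", "y", "z"])
    df["radius_mm"] = RADIUS_MM
    return df
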