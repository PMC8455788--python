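"""Bundled reader-study measurements used in worked examples.

Five ADPKD test exams (K1-K5, ordered by ascending total kidney volume) were
segmented independently by two trained readers and by the first-generation
automated model.  Total cyst volumes (mL) and per-exam cyst counts are the
published measurements; they serve as inputs to the agreement-statistics
worked examples and the acceptance checks.
"""

from __future__ import annotations

__all__ = ["INITIAL_TEST_TCV_ML", "INITIAL_TEST_CYST_COUNTS"]

#: Total cyst volume (mL) per exam, K1..K5.
INITIAL_TEST_TCV_ML = {
    "reader1": (43.1, 105.8, 614.7, 726.6, 1723.1),
    "reader2": (50.7, 124.2, 635.4, 793.8, 1732.5),
    "model": (74.4, 88.1, 603.2, 530.2, 1622.6),
}

#: Cyst count per exam, K1..K5.
INITIAL_TEST_CYST_COUNTS = {
    "reader1": (102, 96, 274, 676, 279),
    "reader2": (115, 99, 178, 755, 177),
    "model": (224, 105, 183, 721, 145),
}
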