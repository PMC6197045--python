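"""Published benchmark confusion matrix used as a worked example.

``PUBLISHED_TABLE`` is the ten-class cross-validation confusion matrix of
the reference waist-worn child-activity study, in its printed layout:
rows are PREDICTED (output) classes and columns are TRUE (input) classes,
both in canonical order WS..NA.  For example, 1,368 of the 1,915 true WS
windows were predicted WS, and 1,971 windows in total were predicted WS.

:func:`reference_confusion_matrix` transposes this into the package's
(true, predicted) orientation; all published metrics — overall accuracy
81.2 %, per-class recall/precision/F1, the merged seven-class matrix and
its 91.1 % accuracy — are recomputable from it with
:mod:`triact.evaluation`.
"""

from __future__ import annotations

import numpy as np

from triact.codes import CANONICAL_CODES
from triact.evaluation import ConfusionMatrix

LABELS: tuple[str, ...] = tuple(c.value for c in CANONICAL_CODES)

#: Printed layout: row = predicted class, column = true class.
PUBLISHED_TABLE = np.array(
    [
        #  WS    WF    RS    RF    SU    SD    JR    ST    SI    NA
        [1368,  428,   29,    5,  116,   19,    4,    0,    0,    2],  # ->WS
        [ 357, 1060,   52,   16,   43,    7,   10,    0,    0,    0],  # ->WF
        [   2,   47,  886,  366,   42,   44,   59,    0,    0,    0],  # ->RS
        [   1,    5,  536, 1321,   23,   40,   43,    0,    0,    0],  # ->RF
        [ 136,   66,    8,    6,  906,   64,   32,    2,    1,    0],  # ->SU
        [  33,   21,   51,   36,   65,  796,   70,    2,    2,    0],  # ->SD
        [  10,   14,   38,   23,  193,   67, 1621,    0,    0,    0],  # ->JR
        [   4,    1,    0,    0,    6,    1,    0, 2425,   66,    6],  # ->ST
        [   1,    1,    1,    0,    1,    3,    0,   73, 2468,    8],  # ->SI
        [   3,    1,    0,    0,   21,    0,    0,   13,   13, 2053],  # ->NA
    ],
    dtype=int,
)


def reference_confusion_matrix() -> ConfusionMatrix:
    """The benchmark matrix in (true class, predicted class) orientation."""
    return ConfusionMatrix(labels=LABELS, counts=PUBLISHED_TABLE.T)
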