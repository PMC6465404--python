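"""Small published reference inputs.

``PLAYER_TYPE_TABLE`` is the published 3x3 contingency table of 60
juvenile pigs cross-classified as initiator / mixed / joiner (rows) by
solitary / mixed / social (columns).  It is the worked example for the
ordinal association statistics: with these orderings Kendall's tau-b is
+0.614 (ASE 0.069); reversing either ordering flips the sign.
"""

import numpy as np

PLAYER_TYPE_TABLE = np.array(
    [
        [6, 0, 0],  # initiator
        [9, 14, 3],  # mixed (initiator/joiner)
        [0, 14, 14],  # joiner
    ],
    dtype=np.int64,
)

PLAYER_TYPE_ROWS = ("initiator", "mixed", "joiner")
PLAYER_TYPE_COLS = ("solitary", "mixed", "social")
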