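"""Published per-residue reference scales used by analyses and examples.

Three 20-value vectors, all in alphabetical residue order
(ACDEFGHIKLMNPQRSTVWY):

- ``REFERENCE_AA_SOLUBILITY_SCORES``: residue-level solubility propensity
  scores from a published scoring-card study of overexpression solubility in
  E. coli (initial statistical card derived from a 957-protein corpus, AX/XA
  dipeptide averaging).
- ``ALPHA_HELIX_PROPENSITY``: the classical alpha-helical propensity scale
  P_alpha (Chou-Fasman style conformational parameters).
- ``AAINDEX_KUMS000103``: AAindex entry KUMS000103, the percentage
  distribution of residues in the alpha-helices of thermophilic proteins.

The solubility scores correlate with P_alpha at R = 0.58 and with
KUMS000103 at R = 0.83 — helix-forming residues of thermophilic proteins
lean soluble.
"""

from __future__ import annotations

import numpy as np

from .seq_io import STANDARD_RESIDUES

__all__ = [
    "REFERENCE_AA_SOLUBILITY_SCORES",
    "ALPHA_HELIX_PROPENSITY",
    "AAINDEX_KUMS000103",
]

_TABLE = {
    #        score  P_alpha  KUMS000103 (%)
    "A": (494.3, 1.39, 14.1),
    "C": (303.0, 0.74, 0.1),
    "D": (386.2, 0.89, 5.7),
    "E": (445.6, 1.35, 8.8),
    "F": (320.6, 1.01, 5.0),
    "G": (313.4, 0.47, 4.1),
    "H": (317.9, 0.92, 2.0),
    "I": (360.4, 1.04, 7.1),
    "K": (358.5, 1.11, 7.7),
    "L": (357.3, 1.32, 9.1),
    "M": (333.6, 1.21, 3.3),
    "N": (311.4, 0.77, 3.2),
    "P": (319.5, 0.50, 0.7),
    "Q": (326.1, 1.29, 3.7),
    "R": (347.1, 1.17, 5.5),
    "S": (265.4, 0.82, 3.9),
    "T": (333.0, 0.76, 4.4),
    "V": (362.8, 0.89, 5.9),
    "W": (306.5, 1.06, 1.2),
    "Y": (293.7, 0.95, 4.5),
}

REFERENCE_AA_SOLUBILITY_SCORES = np.array(
    [_TABLE[r][0] for r in STANDARD_RESIDUES]
)
ALPHA_HELIX_PROPENSITY = np.array([_TABLE[r][1] for r in STANDARD_RESIDUES])
AAINDEX_KUMS000103 = np.array([_TABLE[r][2] for r in STANDARD_RESIDUES])
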