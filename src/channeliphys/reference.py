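"""Synthetic GluA2-numbered reference sequence and the deterministic site map.

The annotation module numbers query residues by alignment to the mature rat
GluA2 subunit. Because shipping the real UniProt P19491 sequence is not
possible here, the bundled reference is a SYNTHETIC stand-in: a deterministic
pseudo-random 850-residue sequence carrying the canonical GluA2 residues at
every position the annotation logic reads (ligand-binding contacts, the
Q/R/N and +4 pore sites, the SYTANLAAF gate motif, the lurcher alanine and
site G). All coordinate logic is driven by :data:`GLUA2_SITES`, so supplying
the real mature P19491 sequence as ``reference_seq`` yields identical
behaviour at these positions.

Positions are 1-based mature-peptide coordinates. Users holding full-length
precursor sequences should strip the signal peptide (or pass
``signal_peptide_offset``) before mapping.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_CONTACT_POSITIONS = (450, 478, 480, 485, 654, 705)
"""LBD positions contacting backbone atoms common to all amino-acid ligands."""

SIDECHAIN_CONTACT_POSITIONS = (653, 655, 704, 708, 732)
"""LBD positions contacting ligand side-chain atoms (specificity-determining)."""

QRN_POSITION = 607
"""Apex of the pore loop (Q/R/N site) in mature GluA2 numbering."""

PLUS4_POSITION = QRN_POSITION + 4
"""The +4 site (GluA2 611); an acidic residue here anchors polyamine block."""

M3_MOTIF_START = 613
M3_MOTIF = "SYTANLAAF"
LURCHER_POSITION = M3_MOTIF_START + 6  # first alanine of the AAF triplet
SITE_G_POSITIONS = (627, 628)

GLUA2_SITES = {
    "backbone": BACKBONE_CONTACT_POSITIONS,
    "sidechain": SIDECHAIN_CONTACT_POSITIONS,
    "qrn": QRN_POSITION,
    "plus4": PLUS4_POSITION,
    "m3_motif_start": M3_MOTIF_START,
    "lurcher": LURCHER_POSITION,
    "siteG": SITE_G_POSITIONS,
}

# Canonical GluA2 residues planted into the synthetic reference. The LBD
# triple (653 T, 655 T, 732 Y) satisfies the glutamate rule; the pore carries
# Q at the Q/R/N site and D at +4, matching the mutant names Q607S / D611A.
_PLANTED = {
    450: "Y",
    478: "P",
    480: "T",
    485: "R",
    653: "T",
    654: "S",
    655: "T",
    704: "E",
    705: "D",
    708: "T",
    732: "Y",
    QRN_POSITION: "Q",
    PLUS4_POSITION: "D",
}
_PLANTED.update({M3_MOTIF_START + i: aa for i, aa in enumerate(M3_MOTIF)})
_PLANTED.update({SITE_G_POSITIONS[0]: "A", SITE_G_POSITIONS[1]: "T"})

REFERENCE_LENGTH = 850
_REFERENCE_SEED = 20250703


def glua2_reference() -> str:
    """Return the synthetic mature-GluA2-numbered reference sequence.

    Deterministic: the background is drawn from a fixed-seed generator and
    the canonical residues are planted on top, so repeated calls (and
    repeated builds) return the identical string.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    idx = rng.integers(0, len(AMINO_ACIDS), size=REFERENCE_LENGTH)
    seq = [AMINO_ACIDS[i] for i in idx]
    for pos, aa in _PLANTED.items():
        seq[pos - 1] = aa
    return "".join(seq)
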