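"""Benchmark peptide sequences and synthetic parent fixtures.

The gephyrin E-domain (gephE) system is the benchmark: the glycine receptor
(GlyR) beta subunit and the GABA-A receptor alpha3 subunit bind gephE via a
conserved linear motif in their intracellular TM3-TM4 loops.  Only the
published peptide sequences and motif coordinates are bundled here; the
full-length loop parents are represented by *synthetic* stand-ins that
embed the published windows at their published coordinates, for tests and
examples that need a longer parent.
"""

from __future__ import annotations

import numpy as np

from .library import AMINO_ACIDS

__all__ = [
    "GLYR_BETA_WT_PEPTIDE",
    "GLYR_BETA_WT_START",
    "GLYR_BETA_WT_END",
    "GLYR_BETA_MOTIF",
    "GLYR_BETA_MOTIF_START",
    "GABAAR_A3_MOTIF",
    "GABAAR_A3_MOTIF_START",
    "GLYR_BETA_NEUTRALIZER",
    "GABAAR_A3_NEUTRALIZER",
    "TRACER_KD_M",
    "BENCHMARK_KI_M",
    "synthetic_glyr_beta_loop",
]

#: GlyR beta-derived WT peptide, residues 414-428 of the beta subunit.
GLYR_BETA_WT_PEPTIDE = "DLRSNDFSIVGSLPR"
GLYR_BETA_WT_START = 414
GLYR_BETA_WT_END = 428

#: Core gephyrin-binding motifs with their 1-based residue coordinates.
GLYR_BETA_MOTIF = "FSIVG"
GLYR_BETA_MOTIF_START = 420
GABAAR_A3_MOTIF = "FNIVG"
GABAAR_A3_MOTIF_START = 395

#: Preparative neutralizer peptides used for on-chip competition.
GLYR_BETA_NEUTRALIZER = "FSIVGSLPRDFELC"
GABAAR_A3_NEUTRALIZER = "FNIVGTTY"

#: Effective dissociation constant of the dimeric fluorescent tracer (molar).
TRACER_KD_M = 1.54e-9

#: Benchmark inhibition constant of the GlyR beta WT peptide (molar).
BENCHMARK_KI_M = 12.1e-6


def synthetic_glyr_beta_loop(
    start: int = 378, end: int = 455, seed: int = 20201207
) -> tuple:
    """SYNTHETIC stand-in for the GlyR beta TM3-TM4 loop region.

    The published 414-428 WT peptide is embedded at its published
    coordinates; all flanking residues are random draws (deterministic for
    a given seed) and carry no biological meaning.  Returns
    ``(sequence, start)`` where ``start`` anchors the 1-based numbering.
    """
    if not (start <= GLYR_BETA_WT_START and end >= GLYR_BETA_WT_END):
        raise ValueError("synthetic loop must contain residues 414-428")
    rng = np.random.default_rng(seed)
    n = end - start + 1
    aa = np.array(list(AMINO_ACIDS))
    seq = list(rng.choice(aa, size=n))
    i0 = GLYR_BETA_WT_START - start
    seq[i0 : i0 + len(GLYR_BETA_WT_PEPTIDE)] = list(GLYR_BETA_WT_PEPTIDE)
    return "".join(seq), start
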