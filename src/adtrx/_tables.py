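"""Bundled numeric lookup tables.

Three small tables live here so the scoring code stays free of literals:

* the Fickett TESTCODE position/composition probability tables (classic
  codon-periodicity statistic; bin edges and weights follow the published
  parameterization),
* a 16-entry nearest-neighbor stacking-energy table for ungapped
  RNA:RNA duplex scanning (kcal/mol, all stabilizing, symmetric under
  reverse complementation of the dinucleotide step),
* a non-uniform sense-codon weight table used by the synthetic-data
  generator to give coding ORFs a detectable hexamer bias.
"""

from __future__ import annotations

# --- Fickett TESTCODE -------------------------------------------------------
# A position value v is looked up in the first bin i with v >= POSITION_EDGES[i];
# likewise for composition values.  Probabilities are P(coding) estimates per bin.

FICKETT_POSITION_EDGES = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
FICKETT_CONTENT_EDGES = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

FICKETT_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
FICKETT_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.58, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}

# --- duplex nearest-neighbor stacking energies ------------------------------
# Keyed by the 5'->3' dinucleotide step on the query (lncRNA) strand; the
# paired target strand is its reverse complement.  Symmetric:
# NN_STACK[d] == NN_STACK[revcomp(d)] for every step d, which makes the duplex
# energy invariant under swapping the two strands.

NN_STACK = {
    "AA": -1.00, "AC": -1.44, "AG": -1.28, "AT": -0.88,
    "CA": -1.45, "CC": -1.84, "CG": -2.17, "CT": -1.28,
    "GA": -1.30, "GC": -2.24, "GG": -1.84, "GT": -1.44,
    "TA": -0.58, "TC": -1.30, "TG": -1.45, "TT": -1.00,
}

# --- synthetic codon usage --------------------------------------------------
# Weight per sense codon, proportional to 2**(G+C count).  GC-rich codons are
# preferred, giving planted ORFs both a composition and an in-frame hexamer
# signature that noncoding (uniform-random) sequence lacks.

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
CODON_WEIGHTS = {
    a + b + c: float(2 ** sum(x in "GC" for x in (a, b, c)))
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
}
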