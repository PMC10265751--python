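"""Published crossover tables for circRNA x risk-factor interaction in CAD.

The validation cohort of a published peripheral-blood circRNA case-control
study reported 2x2x2 crossover counts for two down-regulated circRNAs
(hsa_circRPRD1A, hsa_circHERPUD2) against three classical coronary risk
factors (smoking, drinking, hypertension).  The counts below are inputs for
re-analysis: cells are keyed (marker status, factor status) with values
(cases, controls); the (0,0) cell is the double-negative reference.

Note on row order: in the published layout the two single-exposure rows of
each panel carry each other's odds ratios (the printed OR next to counts
43/11 is the cross-product of counts 41/2, and vice versa).  RERI, AP and S
are symmetric under swapping the two single-exposure cells, so every
interaction measure is unaffected; here counts are keyed to cells and ORs
are always computed from the cell they describe.

``PUBLISHED_INTERVALS`` records the interaction estimates and 95% intervals
exactly as printed, for rule application and comparison.  Several printed
values differ from what the counts imply (see docs/methods.md): they are
data about what was published, never a substitute for computation.
"""

from __future__ import annotations

from .interaction import CrossoverTable

__all__ = ["TABLE_CROSSOVER", "PUBLISHED_INTERVALS"]

TABLE_CROSSOVER: dict[tuple[str, str], CrossoverTable] = {
    ("hsa_circRPRD1A", "smoking"): CrossoverTable(
        "hsa_circRPRD1A", "smoking",
        {(0, 0): (65, 2), (1, 0): (43, 11), (0, 1): (41, 2), (1, 1): (29, 5)},
        cutoff="published",
    ),
    ("hsa_circRPRD1A", "drinking"): CrossoverTable(
        "hsa_circRPRD1A", "drinking",
        {(0, 0): (79, 3), (1, 0): (51, 13), (0, 1): (27, 1), (1, 1): (20, 3)},
        cutoff="published",
    ),
    ("hsa_circRPRD1A", "hypertension"): CrossoverTable(
        "hsa_circRPRD1A", "hypertension",
        {(0, 0): (34, 2), (1, 0): (28, 8), (0, 1): (72, 2), (1, 1): (43, 8)},
        cutoff="published",
    ),
    ("hsa_circHERPUD2", "smoking"): CrossoverTable(
        "hsa_circHERPUD2", "smoking",
        {(0, 0): (56, 2), (1, 0): (66, 13), (0, 1): (39, 2), (1, 1): (46, 7)},
        cutoff="published",
    ),
    ("hsa_circHERPUD2", "drinking"): CrossoverTable(
        "hsa_circHERPUD2", "drinking",
        {(0, 0): (66, 2), (1, 0): (82, 17), (0, 1): (29, 2), (1, 1): (29, 3)},
        cutoff="published",
    ),
    ("hsa_circHERPUD2", "hypertension"): CrossoverTable(
        "hsa_circHERPUD2", "hypertension",
        {(0, 0): (35, 3), (1, 0): (42, 9), (0, 1): (60, 1), (1, 1): (69, 11)},
        cutoff="published",
    ),
}

# (estimate, ci_low, ci_high) exactly as printed
PUBLISHED_INTERVALS: dict[tuple[str, str], dict[str, tuple[float, float, float]]] = {
    ("hsa_circRPRD1A", "smoking"): {
        "S": (0.658, -0.727, 2.042),
        "AP": (2.395, -0.834, 5.624),
        "RERI": (0.428, -1.210, 2.065),
    },
    ("hsa_circRPRD1A", "drinking"): {
        "S": (0.905, -2.546, 4.355),
        "AP": (0.311, -0.605, 1.228),
        "RERI": (0.079, -2.752, 2.910),
    },
    ("hsa_circRPRD1A", "hypertension"): {
        "S": (-2.117, -16.124, 11.890),
        "AP": (-3.182, -9.144, 2.779),
        "RERI": (-1.007, -5.935, 3.922),
    },
    ("hsa_circHERPUD2", "smoking"): {
        "S": (0.682, -1.111, 2.474),
        "AP": (1.521, -0.405, 3.447),
        "RERI": (0.357, -1.555, 2.270),
    },
    ("hsa_circHERPUD2", "drinking"): {
        "S": (0.500, 0.218, 0.782),
        "AP": (4.415, 1.230, 7.599),
        "RERI": (0.707, 0.315, 1.099),
    },
    ("hsa_circHERPUD2", "hypertension"): {
        "S": (-0.130, -3.330, 3.069),
        "AP": (-7.457, -19.505, 4.590),
        "RERI": (-4.008, -17.065, 9.050),
    },
}
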