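"""Published reference values for the DREB2A : Med25-ACID interaction.

Small printed tables used as fixture inputs and consistency checks; none of
these numbers are produced by this package. Calorimetric rows are at 25 degC;
missing entries (no detectable binding, NMR-only affinities) are omitted.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["dreb2a_med25_thermo", "ISOMER_OBSERVABLES", "BIVALENCY_OBSERVABLES"]

# fragment/variant, N, N_sd, Kd_nM, Kd_sd_nM, dH, dH_sd, tds_neg, tds_neg_sd,
# dG, dG_sd  (energies kJ/mol)
_THERMO_ROWS = [
    ("151-335",            1.10, 0.06,  540,  40, -52.3, 0.8, 16.5, 1.0, -35.8, 0.2),
    ("195-276",            1.09, 0.02,  450,  30, -51.2, 0.6, 15.0, 0.7, -36.2, 0.2),
    ("234-335",            1.0,  0.2,   440,  60, -58,   1.0, 22,   2.0, -36.3, 0.3),
    ("234-276 (ABS-RIM)",  0.98, 0.08,  510,  20, -50.7, 0.3, 14.8, 0.4, -35.9, 0.1),
    ("234-272",            0.97, 0.05, 1800, 400, -43,   3.0, 10,   4.0, -32.8, 0.5),
    ("234-256 (ABS)",      0.86, 0.03, 6000, 200, -54.0, 0.5, 24.2, 0.6, -29.8, 0.1),
    ("195-335 d244-276",   1.02, 0.09, 5400, 600, -59,   2.0, 28,   2.0, -30.1, 0.3),
    ("L237A",              1.03, 0.06, 2400, 300, -22.9, 0.7, -9.2, 0.9, -32.1, 0.3),
    ("V239A",              0.95, 0.01, 2000, 200, -42,   1.0, 10,   1.0, -32.5, 0.3),
    ("D241A",              1.07, 0.06, 2000, 700, -37,   7.0,  5,   7.0, -32.5, 0.9),
    ("W244A",              1.0,  0.1,  1900, 200, -47,   1.0, 14,   2.0, -32.7, 0.3),
    ("P245A",              1.26, 0.01,  780,  60, -43.4, 0.8,  8.8, 0.8, -34.9, 0.2),
    ("F259A",              1.2,  0.1,   550,  50, -58.8, 0.9, 23,   1.0, -35.8, 0.2),
    ("E263P",              1.00, 0.06,  580,  40, -61.2, 0.8, 25.5, 1.0, -35.6, 0.2),
    ("F274A",              0.86, 0.02,  660,  90, -62,   2.0, 27,   2.0, -35.3, 0.3),
    ("Med25 R568A",        0.90, 0.01, 3100, 700, -46,   4.0, 14,   5.0, -31.5, 0.5),
]

_COLUMNS = ["fragment", "n_value", "n_value_sd", "kd_nM", "kd_sd_nM",
            "dh", "dh_sd", "tds_neg", "tds_neg_sd", "dg", "dg_sd"]


def dreb2a_med25_thermo() -> pd.DataFrame:
    """Reference single-site binding parameters (25 degC) for DREB2A
    fragments and point variants binding Med25-ACID."""
    return pd.DataFrame(_THERMO_ROWS, columns=_COLUMNS)


#: Observables of the branched cis/trans binding equilibrium of the
#: bivalent ABS-RIM fragment.
ISOMER_OBSERVABLES = {
    "f_cis": 0.30, "f_cis_sd": 0.01,
    "keq_trans_to_cis": 0.42, "keq_sd": 0.02,
    "kd_app_nM": 500.0, "kd_app_sd_nM": 20.0,
    "p_bound_trans": 0.036, "p_bound_trans_sd": 0.001,
    "p_bound_cis": 0.068, "p_bound_cis_sd": 0.001,
    "kd_trans_nM": 640.0, "kd_trans_sd_nM": 30.0,
    "kd_cis_nM": 330.0, "kd_cis_sd_nM": 20.0,
}

#: Secondary-site (RIM / binding surface) tethering observables.
BIVALENCY_OBSERVABLES = {
    "linker_length": 12.5, "linker_length_sd": 2.5,
    "ce_mM": 9.0, "ce_sd_mM": 3.0,
    "kd_surface_mM": 4.7, "kd_surface_sd_mM": 1.8,
    "saturation": 0.65, "saturation_sd": 0.10,
}
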