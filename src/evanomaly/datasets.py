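"""Published reference lists from the motivating bioactive-glass EV study.

The raw abundance matrix of that study is available only on request, but
its printed result tables are reusable fixtures: the accession lists of
the "extremely changing" proteins per biomaterial comparison, and the
per-protein p-values and within-group variances of the flagged proteins.
Biomaterials: SBA2 (silver-doped silica glass), SBA3 (copper-doped), ST
(tellurium-doped); "ctrl" is the undoped glass, "plast" the no-biomaterial
baseline.
"""

from __future__ import annotations

from types import MappingProxyType

import pandas as pd

__all__ = [
    "CTRL_VS_DOPED_ANOMALIES",
    "PLAST_VS_DOPED_ANOMALIES",
    "ctrl_vs_doped_variance_table",
    "plast_vs_doped_variance_table",
]

#: Extremely changing proteins, undoped control vs doped glass, per biomaterial.
CTRL_VS_DOPED_ANOMALIES = MappingProxyType({
    "SBA2": frozenset({"P02458", "P19338", "P14923", "Q9Y4Z0"}),
    "SBA3": frozenset({"P02656", "P38571", "Q9P2E9", "P02765", "P49720",
                       "P46940", "P59665"}),
    "ST": frozenset({"P24821-4", "P26583", "P22234", "P35555", "P24821",
                     "Q9P2E9", "P13611"}),
})

#: Extremely changing proteins, plastic baseline vs doped glass, per biomaterial.
PLAST_VS_DOPED_ANOMALIES = MappingProxyType({
    "SBA2": frozenset({"P35908", "P35527", "P04264", "P13645", "P60985",
                       "P12111", "P08493"}),
    "SBA3": frozenset({"P00734", "P12111", "P35908", "P35527", "P13645",
                       "P04264"}),
    "ST": frozenset({"O94985", "P22234", "P02545", "P04264", "P35527",
                     "Q16363", "P13645", "P35908", "P00734", "P26022",
                     "P60985"}),
})

# (experiment, accession, p_value, var_ref, var_trt) as printed.
_CTRL_VS_DOPED_VARIANCES = [
    ("SBA2", "P02458", 0.77209, 1.27, 2.26),
    ("SBA2", "P19338", 0.7934, 2.76, 0.16),
    ("SBA2", "P14923", 0.90066, 3.85, 1.55),
    ("SBA2", "Q9Y4Z0", 0.37355, 13.0, 0.72),
    ("SBA3", "P02656", 0.19829, 0.73, 0.18),
    ("SBA3", "P38571", 0.85016, 0.21, 2.61),
    ("SBA3", "Q9P2E9", 0.03166, 0.22, 0.08),
    ("SBA3", "P02765", 0.51954, 1.8, 0.2),
    ("SBA3", "P49720", 0.80732, 1.44, 1.55),
    ("SBA3", "P46940", 0.67908, 0.51, 1.66),
    ("SBA3", "P59665", 0.40182, 8.47, 2.79),
    ("ST", "P24821-4", 0.4643, 1.02, 1.73),
    ("ST", "P26583", 0.20189, 0.1, 0.71),
    ("ST", "P22234", 0.08797, 0.5, 0.17),
    ("ST", "P35555", 0.04938, 0.22, 0.34),
    ("ST", "P24821", 0.05846, 0.13, 0.96),
    ("ST", "Q9P2E9", 0.03078, 0.32, 0.23),
    ("ST", "P13611", 0.16264, 1.83, 5.37),
]

_PLAST_VS_DOPED_VARIANCES = [
    ("SBA2", "P35908", 0.00245, 0.07, 0.28),
    ("SBA2", "P35527", 0.00029, 0.02, 0.14),
    ("SBA2", "P04264", 0.00015, 0.01, 0.25),
    ("SBA2", "P13645", 0.00041, 0.02, 0.35),
    ("SBA2", "P60985", 0.08047, 0.27, 0.84),
    ("SBA2", "P12111", 0.00145, 0.54, 0.04),
    ("SBA2", "P08493", 0.10463, 2.05, 1.65),
    ("SBA3", "P00734", 0.0291, 0.25, 0.01),
    ("SBA3", "P12111", 0.05029, 0.54, 0.63),
    ("SBA3", "P35908", 0.00252, 0.07, 0.57),
    ("SBA3", "P35527", 0.00038, 0.02, 0.53),
    ("SBA3", "P13645", 0.00059, 0.02, 0.79),
    ("SBA3", "P04264", 0.00018, 0.01, 0.66),
    ("ST", "O94985", 0.02078, 0.01, 0.26),
    ("ST", "P22234", 0.03636, 1.17, 0.17),
    ("ST", "P02545", 0.08999, 2.02, 0.17),
    ("ST", "P04264", 0.00015, 0.01, 0.07),
    ("ST", "P35527", 0.00079, 0.02, 0.29),
    ("ST", "Q16363", 0.25842, 2.89, 1.69),
    ("ST", "P13645", 0.00037, 0.02, 0.07),
    ("ST", "P35908", 0.00244, 0.07, 0.16),
    ("ST", "P00734", 0.02785, 0.25, 0.03),
    ("ST", "P26022", 0.08427, 0.41, 2.51),
    ("ST", "P60985", 0.04855, 0.27, 0.69),
]

_COLS = ["experiment", "accession", "p_value", "var_ref", "var_trt"]


def ctrl_vs_doped_variance_table() -> pd.DataFrame:
    """Published p-values and within-group variances, ctrl vs doped."""
    return pd.DataFrame(_CTRL_VS_DOPED_VARIANCES, columns=_COLS)


def plast_vs_doped_variance_table() -> pd.DataFrame:
    """Published p-values and within-group variances, plast vs doped."""
    return pd.DataFrame(_PLAST_VS_DOPED_VARIANCES, columns=_COLS)
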