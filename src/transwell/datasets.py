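"""Bundled benchmark measurements for validation, examples, and tests.

These small tables come from a published bidirectional Transwell study of
three beta-blockers (metoprolol, atenolol, propranolol) across human Caco-2
and canine colonoid-derived monolayers: per-well recovery-corrected Papp
estimates, group-mean qPCR cycle thresholds, and a FITC-dextran leakage
series. They are *inputs* for the arithmetic this package implements
(condition summaries, efflux ratios, dCt normalization, leakage verdicts),
not outputs of it.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .model import DrugSpec

#: Physicochemical identities of the three probe drugs (free-base MW, g/mol).
#: Metoprolol and propranolol are commonly dosed as tartrate / hydrochloride
#: salts; their salt factors depend on the lot actually dosed and are left
#: at 1.0 here -- supply the appropriate ``salt_factor`` when converting
#: salt-dosed concentrations to molarity.
DRUGS: Dict[str, DrugSpec] = {
    "metoprolol": DrugSpec("metoprolol", 267.36, logp=2.15, pka_basic=9.56,
                           aqueous_solubility_mg_ml=1000.0),
    "atenolol": DrugSpec("atenolol", 266.34, logp=0.16, pka_basic=9.58,
                         aqueous_solubility_mg_ml=13.3),
    "propranolol": DrugSpec("propranolol", 259.339, logp=3.48, pka_basic=9.53,
                            aqueous_solubility_mg_ml=6.17e-5),
}

# per-well corrected Papp (1e-6 cm/s); NaN = below the limit of quantification
_PAPP_WELLS = [
    # drug, dose mg/mL, system, direction, apical pH, basolateral pH, well, papp
    ("metoprolol", 0.4, "caco2", "AP_to_BL", 6.8, 7.4, 1, 19.34),
    ("metoprolol", 0.4, "caco2", "AP_to_BL", 6.8, 7.4, 2, 16.45),
    ("metoprolol", 0.4, "caco2", "BL_to_AP", 7.4, 7.4, 1, 13.79),
    ("metoprolol", 0.4, "caco2", "BL_to_AP", 7.4, 7.4, 2, 12.37),
    ("metoprolol", 0.4, "colonoid", "AP_to_BL", 6.8, 7.4, 1, 8.33),
    ("metoprolol", 0.4, "colonoid", "AP_to_BL", 6.8, 7.4, 2, 9.10),
    ("metoprolol", 0.4, "colonoid", "AP_to_BL", 7.4, 7.4, 1, 11.19),
    ("metoprolol", 0.4, "colonoid", "AP_to_BL", 7.4, 7.4, 2, 9.90),
    ("metoprolol", 0.4, "colonoid", "BL_to_AP", 7.4, 7.4, 1, 9.88),
    ("metoprolol", 0.4, "colonoid", "BL_to_AP", 7.4, 7.4, 2, 9.94),
    ("metoprolol", 0.04, "caco2", "AP_to_BL", 6.8, 7.4, 1, 17.54),
    ("metoprolol", 0.04, "caco2", "AP_to_BL", 6.8, 7.4, 2, 13.13),
    ("metoprolol", 0.04, "caco2", "BL_to_AP", 7.4, 7.4, 1, 16.30),
    ("metoprolol", 0.04, "caco2", "BL_to_AP", 7.4, 7.4, 2, 19.03),
    ("metoprolol", 0.04, "colonoid", "AP_to_BL", 6.8, 7.4, 1, 16.83),
    ("metoprolol", 0.04, "colonoid", "AP_to_BL", 6.8, 7.4, 2, 18.52),
    ("metoprolol", 0.04, "colonoid", "AP_to_BL", 7.4, 7.4, 1, 13.44),
    ("metoprolol", 0.04, "colonoid", "AP_to_BL", 7.4, 7.4, 2, 13.50),
    ("metoprolol", 0.04, "colonoid", "BL_to_AP", 7.4, 7.4, 1, 11.19),
    ("metoprolol", 0.04, "colonoid", "BL_to_AP", 7.4, 7.4, 2, 12.67),
    ("atenolol", 0.2, "caco2", "AP_to_BL", 6.8, 7.4, 1, math.nan),
    ("atenolol", 0.2, "caco2", "AP_to_BL", 6.8, 7.4, 2, math.nan),
    ("atenolol", 0.2, "caco2", "BL_to_AP", 7.4, 7.4, 1, math.nan),
    ("atenolol", 0.2, "caco2", "BL_to_AP", 7.4, 7.4, 2, math.nan),
    ("atenolol", 0.2, "colonoid", "AP_to_BL", 6.8, 7.4, 1, math.nan),
    ("atenolol", 0.2, "colonoid", "AP_to_BL", 6.8, 7.4, 2, math.nan),
    ("atenolol", 0.2, "colonoid", "AP_to_BL", 7.4, 7.4, 1, math.nan),
    ("atenolol", 0.2, "colonoid", "AP_to_BL", 7.4, 7.4, 2, math.nan),
    ("atenolol", 0.2, "colonoid", "BL_to_AP", 7.4, 7.4, 1, math.nan),
    ("atenolol", 0.2, "colonoid", "BL_to_AP", 7.4, 7.4, 2, math.nan),
    ("atenolol", 2.0, "caco2", "AP_to_BL", 6.8, 7.4, 1, 7.25),
    ("atenolol", 2.0, "caco2", "AP_to_BL", 6.8, 7.4, 2, 8.01),
    ("atenolol", 2.0, "caco2", "BL_to_AP", 7.4, 7.4, 1, 3.69),
    ("atenolol", 2.0, "caco2", "BL_to_AP", 7.4, 7.4, 2, 4.97),
    ("atenolol", 2.0, "colonoid", "AP_to_BL", 6.8, 7.4, 1, math.nan),
    ("atenolol", 2.0, "colonoid", "AP_to_BL", 6.8, 7.4, 2, math.nan),
    ("atenolol", 2.0, "colonoid", "AP_to_BL", 7.4, 7.4, 1, math.nan),
    ("atenolol", 2.0, "colonoid", "AP_to_BL", 7.4, 7.4, 2, math.nan),
    ("atenolol", 2.0, "colonoid", "BL_to_AP", 7.4, 7.4, 1, math.nan),
    ("atenolol", 2.0, "colonoid", "BL_to_AP", 7.4, 7.4, 2, math.nan),
    ("propranolol", 1.0, "caco2", "AP_to_BL", 6.8, 7.4, 1, 12.12),
    ("propranolol", 1.0, "caco2", "AP_to_BL", 6.8, 7.4, 2, 12.75),
    ("propranolol", 1.0, "caco2", "BL_to_AP", 7.4, 7.4, 1, 11.45),
    ("propranolol", 1.0, "caco2", "BL_to_AP", 7.4, 7.4, 2, 12.43),
    ("propranolol", 1.0, "colonoid", "AP_to_BL", 6.8, 7.4, 1, 12.23),
    ("propranolol", 1.0, "colonoid", "AP_to_BL", 6.8, 7.4, 2, 11.05),
    ("propranolol", 1.0, "colonoid", "AP_to_BL", 7.4, 7.4, 1, 11.99),
    ("propranolol", 1.0, "colonoid", "AP_to_BL", 7.4, 7.4, 2, 11.97),
    ("propranolol", 1.0, "colonoid", "BL_to_AP", 7.4, 7.4, 1, 10.94),
    ("propranolol", 1.0, "colonoid", "BL_to_AP", 7.4, 7.4, 2, 12.03),
]


def beta_blocker_papp_wells() -> pd.DataFrame:
    """Per-well corrected Papp benchmark (column ``papp_1e6_cm_s``; NaN = BLQ)."""
    return pd.DataFrame(_PAPP_WELLS, columns=[
        "drug", "donor_concentration_mg_ml", "system", "direction",
        "apical_ph", "basolateral_ph", "well", "papp_1e6_cm_s"])


# group-mean cycle thresholds (mean, sd over 3 monolayers)
_CT_MEANS = {
    "colonoid": {
        "GAPDH": (20.67, 1.52), "CDH1": (24.49, 0.12), "OCLN": (25.92, 0.12),
        "TJP1": (29.80, 0.15), "MUC2": (25.83, 0.22), "NEUROG3": (33.75, 0.37),
        "ALP": (26.91, 0.76), "OLFM4": (22.19, 0.91), "HOPX": (25.85, 1.01),
        "PROM1": (26.48, 0.10), "SOX9": (26.27, 0.12), "LGR5": (30.38, 0.68),
        "Oatp2b1": (32.41, 0.28), "Mdr1": (25.36, 0.14), "Cyp3a12": (27.40, 0.70),
        "Cyp2b11": (30.48, 1.29), "Cyp2c21": (31.24, 0.08),
    },
    "caco2": {
        "GAPDH": (20.21, 0.08), "OATP2B1": (28.11, 0.10), "ABCB1": (35.53, 1.76),
        "CYP3A4": (32.39, 0.22), "CYP2B6": (33.22, 0.30), "CYP2C9": (31.34, 1.46),
        "CYP2C19": (38.34, 0.06),
    },
}


def monolayer_ct_means() -> pd.DataFrame:
    """Group-mean qPCR cycle thresholds per culture system (mean, sd, n=3)."""
    rows = []
    for system, genes in _CT_MEANS.items():
        for gene, (mean, sd) in genes.items():
            rows.append({"group": system, "gene": gene, "ct_mean": mean,
                         "ct_sd": sd, "n": 3})
    return pd.DataFrame(rows)


# FITC-dextran %RFU in the receiver chamber over the assay (group means)
_FITC_RECEIVER_PERCENT = {
    "fitc_alone": [0.020, 0.021, 0.024, 0.022, 0.024, 0.023, 0.022],
    "fitc_with_metoprolol": [0.021, 0.023, 0.020, 0.020, 0.022, 0.023, 0.020],
}
_FITC_TIMES_MIN = [0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0]
_FITC_DONOR_END_PERCENT = {"fitc_alone": 93.7, "fitc_with_metoprolol": 94.6}


def fitc_dextran_percent_rfu() -> pd.DataFrame:
    """Receiver %RFU time series for 4 kDa FITC-dextran +/- metoprolol."""
    rows = []
    for condition, values in _FITC_RECEIVER_PERCENT.items():
        for t, v in zip(_FITC_TIMES_MIN, values):
            rows.append({"condition": condition, "time_min": t,
                         "receiver_percent_rfu": v,
                         "donor_end_percent_rfu": _FITC_DONOR_END_PERCENT[condition]})
    return pd.DataFrame(rows)
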