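"""Built-in reference values for the AMB (Allii Macrostemonis Bulbus) assay.

These constants parameterize the default simulated panel and provide the
published determination table used by the validation/acceptance checks:

- per-analyte ELSD calibration lines (slope, intercept, linear range, R²,
  LOD, LOQ) for the six identified constituents;
- expected relative retention times of the two QAMS analytes versus the
  internal reference (macrostemonoside A);
- the reference ESM/QAMS content table for 18 batches of AMB.
"""

from __future__ import annotations

import io

import pandas as pd

#: Identified constituents, in elution order.
NAMED_ANALYTES = (
    "adenosine",
    "syringin",
    "macrostemonoside_t",
    "macrostemonoside_a",
    "macrostemonoside_u",
    "macrostemonoside_v",
)

#: Internal reference analyte for QAMS.
INTERNAL_REFERENCE = "macrostemonoside_a"

#: Calibration line (area = slope*C + intercept, C in µg/mL), linear range,
#: coefficient of determination and detection/quantification limits (µg/mL).
CALIBRATIONS: dict[str, dict[str, float]] = {
    "adenosine": {
        "slope": 2463.0, "intercept": -127.53,
        "c_min": 6.62, "c_max": 109.11,
        "r_squared": 0.9988, "lod": 1.43, "loq": 4.76,
    },
    "syringin": {
        "slope": 1254.7, "intercept": -78.93,
        "c_min": 14.24, "c_max": 96.31,
        "r_squared": 0.9974, "lod": 3.53, "loq": 11.78,
    },
    "macrostemonoside_t": {
        "slope": 861.0, "intercept": -69.574,
        "c_min": 25.83, "c_max": 81.35,
        "r_squared": 0.9968, "lod": 5.71, "loq": 19.05,
    },
    "macrostemonoside_a": {
        "slope": 2223.2, "intercept": -117.7,
        "c_min": 21.42, "c_max": 72.31,
        "r_squared": 0.9970, "lod": 5.67, "loq": 18.90,
    },
    "macrostemonoside_u": {
        "slope": 1308.1, "intercept": -71.569,
        "c_min": 24.37, "c_max": 86.44,
        "r_squared": 0.9965, "lod": 5.76, "loq": 19.19,
    },
    "macrostemonoside_v": {
        "slope": 1638.4, "intercept": -80.186,
        "c_min": 31.08, "c_max": 89.37,
        "r_squared": 0.9983, "lod": 8.16, "loq": 27.20,
    },
}

#: Nominal retention times (min) used by the simulator.  The two QAMS
#: analytes are placed so that their retention times relative to the
#: internal reference equal the expected localization constants below.
RETENTION_TIMES: dict[str, float] = {
    "adenosine": 6.00,
    "syringin": 12.50,
    "macrostemonoside_t": 37.576,   # 0.9394 * 40.0
    "macrostemonoside_a": 40.000,
    "macrostemonoside_u": 40.392,   # 1.0098 * 40.0
    "macrostemonoside_v": 42.50,
}

#: Expected relative retention time t_i / t_s versus the internal reference.
EXPECTED_RRT: dict[str, float] = {
    "macrostemonoside_t": 0.9394,
    "macrostemonoside_u": 1.0098,
}

#: Published mean relative correction factors versus the internal reference
#: (used as plausibility bands by tests, never as computed output).
PUBLISHED_RCF: dict[str, float] = {
    "macrostemonoside_t": 2.56,
    "macrostemonoside_u": 1.74,
}

#: RSD acceptance bound (%) for the durability study.
DURABILITY_RSD_BOUND = 2.0

#: Acceptance envelope (%) for the |relative deviation| between QAMS and ESM.
RD_ENVELOPE = 5.0

# Reference determination table for the 18-batch AMB panel: ESM content of
# the internal reference, and ESM/QAMS contents plus reported relative
# deviation for the two QAMS analytes (µg/g; rd in %).
_CONTENTS_CSV = """\
batch,mac_a_esm,mac_t_esm,mac_t_qams,mac_t_rd,mac_u_esm,mac_u_qams,mac_u_rd
S1,66.33,102.20,101.73,-0.46,77.98,77.15,-1.06
S2,168.46,346.97,345.51,-0.42,98.59,97.94,-0.66
S3,95.77,101.75,101.78,0.03,198.86,197.75,-0.56
S4,89.38,101.75,101.31,-0.43,84.27,84.07,-0.24
S5,180.09,344.05,344.87,0.24,98.09,97.90,-0.19
S6,96.92,102.25,102.10,-0.15,191.63,191.15,-0.25
S7,75.26,108.41,108.12,-0.27,92.24,91.92,-0.35
S8,162.42,352.36,351.77,-0.17,97.51,96.54,-0.99
S9,76.65,137.22,136.67,-0.40,79.35,80.11,0.96
S10,72.07,104.73,103.82,-0.87,135.57,134.61,-0.71
S11,154.23,309.27,308.73,-0.17,102.24,101.81,-0.42
S12,63.67,98.22,98.12,-0.10,116.00,115.63,-0.32
S13,63.02,97.46,97.08,-0.39,114.26,114.95,0.60
S14,82.52,234.76,234.73,-0.01,261.21,261.09,-0.05
S15,66.13,104.19,104.18,-0.01,111.98,112.00,0.02
S16,68.12,98.34,98.79,0.46,69.06,69.84,1.13
S17,78.46,250.43,250.31,-0.05,70.26,70.39,0.19
S18,63.51,99.26,99.17,-0.09,79.52,79.87,0.44
"""


def reference_contents(long: bool = True) -> pd.DataFrame:
    """Return the reference ESM/QAMS determination table.

    Parameters
    ----------
    long
        If True (default) return one row per (batch, analyte) for the two
        QAMS analytes with columns ``batch, analyte, esm_ug_per_g,
        qams_ug_per_g, rd_percent``.  Otherwise return the wide table as
        stored (including the internal reference's ESM column).
    """
    wide = pd.read_csv(io.StringIO(_CONTENTS_CSV))
    if not long:
        return wide
    rows = []
    for _, r in wide.iterrows():
        rows.append(("%s" % r["batch"], "macrostemonoside_t",
                     r["mac_t_esm"], r["mac_t_qams"], r["mac_t_rd"]))
        rows.append(("%s" % r["batch"], "macrostemonoside_u",
                     r["mac_u_esm"], r["mac_u_qams"], r["mac_u_rd"]))
    return pd.DataFrame(
        rows,
        columns=["batch", "analyte", "esm_ug_per_g", "qams_ug_per_g",
                 "rd_percent"],
    )
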