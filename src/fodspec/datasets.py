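"""Published reference measurements for the ASC–NIC (1:1) cocrystal assay.

These small tables are transcribed from the originating validation study
of the zero-crossing first-derivative method for ascorbic acid (ASC) and
nicotinamide (NIC). They serve as fixed inputs for cross-checking the
package's arithmetic (recovery percentages, precision statistics and the
stoichiometric mass balance) against independently reported values; they
are *data*, not fitted constants.

All concentrations are μg·mL⁻¹, masses mg, recoveries %.
"""

from __future__ import annotations

import pandas as pd

from .purity import BatchMeasurement

__all__ = [
    "simple_mixture_validation",
    "standard_addition_validation",
    "gas_batch_table",
    "gas_batch_measurements",
]

# Simple-mixture validation: five mixes of ASC and NIC prepared from
# 48.04 (ASC) and 47.50 (NIC) μg·mL⁻¹ stocks, quantified by the
# derivative method. Printed recoveries are 1-decimal roundings of
# unrounded internal values, so a few cells differ from recomputation on
# the rounded concentrations by up to ~0.15 points.
_SIMPLE_MIXTURES = [
    # mix, analyte, vol_uL, theoretical, found, printed recovery %
    (1, "ASC", 200, 4.80, 4.88, 101.8),
    (2, "ASC", 200, 4.80, 4.93, 102.7),
    (3, "ASC", 400, 9.61, 9.57, 99.7),
    (4, "ASC", 300, 7.21, 7.16, 99.4),
    (5, "ASC", 300, 7.21, 7.25, 100.7),
    (1, "NIC", 200, 4.75, 4.67, 98.3),
    (2, "NIC", 100, 2.38, 2.35, 98.7),
    (3, "NIC", 100, 2.38, 2.39, 100.4),
    (4, "NIC", 400, 9.51, 9.45, 99.4),
    (5, "NIC", 600, 12.96, 12.69, 97.9),
]

# Standard-addition validation: spikes added to a ~4.8 μg·mL⁻¹ mix of
# both analytes. The measured base concentration of each run was not
# reported, so these rows support only qualitative checks of the
# standard-addition recovery arithmetic.
_STANDARD_ADDITIONS = [
    # mix, analyte, added, total_theoretical, total_found, printed recovery %
    (1, "ASC", 7.3, 12.08, 12.11, 100.4),
    (2, "ASC", 4.9, 9.65, 9.47, 96.3),
    (3, "ASC", 2.4, 7.23, 7.30, 103.0),
    (4, "ASC", 2.4, 7.23, 7.34, 104.6),
    (5, "ASC", 2.4, 7.22, 7.25, 100.9),
    (1, "NIC", 2.4, 7.15, 7.18, 101.1),
    (2, "NIC", 2.4, 7.15, 7.20, 102.0),
    (3, "NIC", 2.4, 7.15, 7.24, 103.0),
    (4, "NIC", 4.8, 9.60, 9.43, 97.4),
    (5, "NIC", 7.2, 12.00, 11.88, 99.0),
]

# Eight gas-antisolvent (GAS) bulk batches, each with ASC/NIC totals
# determined both by LC-MS and by the derivative method, plus the
# cocrystal mass and wt % purity reported alongside.
_GAS_BATCHES = [
    # batch, m_collected, source, m_asc, m_nic, reported mass, reported purity
    ("GAS#1", 220.9, "LC-MS", 133.2, 88.0, 214.6, 97.13),
    ("GAS#1", 220.9, "FODS", 133.4, 87.1, 213.1, 96.46),
    ("GAS#4", 153.5, "LC-MS", 92.2, 61.6, 150.2, 97.85),
    ("GAS#4", 153.5, "FODS", 94.0, 59.7, 145.6, 94.85),
    ("GAS#5", 196.4, "LC-MS", 116.2, 80.5, 196.3, 99.96),
    ("GAS#5", 196.4, "FODS", 116.5, 79.8, 195.0, 99.30),
    ("GAS#7", 342.5, "LC-MS", 255.6, 87.7, 213.3, 62.28),
    ("GAS#7", 342.5, "FODS", 259.9, 81.7, 200.4, 58.50),
    ("GAS#9", 194.2, "LC-MS", 114.2, 80.0, 195.4, 100.60),
    ("GAS#9", 194.2, "FODS", 114.5, 79.7, 194.6, 100.20),
    ("GAS#10", 239.3, "LC-MS", 142.1, 97.9, 238.4, 99.62),
    ("GAS#10", 239.3, "FODS", 141.9, 97.3, 237.6, 99.30),
    ("GAS#13", 134.6, "LC-MS", 79.6, 55.3, 134.7, 100.10),
    ("GAS#13", 134.6, "FODS", 79.4, 54.4, 133.7, 99.31),
    ("GAS#15", 213.2, "LC-MS", 125.7, 87.7, 214.0, 100.34),
    ("GAS#15", 213.2, "FODS", 128.3, 85.8, 208.7, 97.87),
]


def simple_mixture_validation() -> pd.DataFrame:
    """Simple-mixture validation rows (one per mix × analyte)."""
    return pd.DataFrame(
        _SIMPLE_MIXTURES,
        columns=["mix", "analyte", "vol_uL", "conc_theoretical_ug_ml",
                 "conc_found_ug_ml", "recovery_pct_reported"],
    )


def standard_addition_validation() -> pd.DataFrame:
    """Standard-addition validation rows (one per mix × analyte)."""
    return pd.DataFrame(
        _STANDARD_ADDITIONS,
        columns=["mix", "analyte", "added_ug_ml", "total_theoretical_ug_ml",
                 "total_found_ug_ml", "recovery_pct_reported"],
    )


def gas_batch_table() -> pd.DataFrame:
    """GAS batch component totals with the independently reported
    cocrystal mass and purity for each (batch, source) cell."""
    return pd.DataFrame(
        _GAS_BATCHES,
        columns=["batch_id", "m_collected_mg", "source", "m_asc_total_mg",
                 "m_nic_total_mg", "reported_cocrystal_mass_mg",
                 "reported_purity_wt_pct"],
    )


def gas_batch_measurements() -> list[BatchMeasurement]:
    """The GAS batch table as :class:`BatchMeasurement` inputs."""
    return [
        BatchMeasurement(
            batch_id=b, m_collected_mg=mc, source=src,
            m_asc_total_mg=ma, m_nic_total_mg=mn,
        )
        for b, mc, src, ma, mn, _, _ in _GAS_BATCHES
    ]
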