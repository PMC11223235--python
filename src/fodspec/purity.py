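"""Cocrystal purity by stoichiometric mass balance.

Given the total ASC and NIC masses measured in a collected bulk powder,
and assuming (1) a fixed cocrystal stoichiometry (1:1 ASC:NIC by default)
and (2) that the coformer NIC precipitates entirely as cocrystal while
only excess ASC forms homocrystals, the cocrystal content follows from
the coformer alone:

    n_cc  = m_NIC / MM_NIC                      (mmol of cocrystal)
    m_cc  = n_cc · (R_s·MM_ASC + MM_NIC)        (mg of cocrystal)
    purity = 100 · m_cc / m_collected           (wt %)
    m_excess = m_ASC − n_cc · R_s·MM_ASC        (mg of ASC homocrystals)

with MM_ASC = 176.12 and MM_NIC = 122.12 g·mol⁻¹ and expected molar
ratio R_s = 1. The identity m_cc + m_excess = m_ASC + m_NIC holds exactly.
Purities above 100 % are possible from measurement error and are reported
as computed, with a warning, never clamped. A bulk molar ratio
ASC:NIC above R_s diagnoses ASC homocrystal impurities; below R_s it
violates assumption 2 and is warned about (excess coformer is normally
lost to the solvent phase during antisolvent processing, not retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .exceptions import DomainError, InputError, ParameterError

__all__ = [
    "BatchMeasurement",
    "StoichiometryModel",
    "PurityResult",
    "PurityReport",
    "molar_ratio",
    "purity_mass_balance",
    "batch_table_report",
]


@dataclass(frozen=True)
class BatchMeasurement:
    """Measured component totals for one bulk batch (all masses mg)."""

    batch_id: str
    m_collected_mg: float
    m_asc_total_mg: float
    m_nic_total_mg: float
    source: str = "FODS"  # "FODS", "LC-MS", or other reference method

    def __post_init__(self) -> None:
        for name in ("m_collected_mg", "m_asc_total_mg", "m_nic_total_mg"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0 for batch {self.batch_id!r}")


@dataclass(frozen=True)
class StoichiometryModel:
    """Expected cocrystal stoichiometry and molar masses.

    r_s is the expected ASC:NIC molar ratio of the cocrystal (1.0 for the
    1:1 phase). ``fully_cocrystallized_component`` names the component
    assumed to precipitate entirely as cocrystal (assumption 2); its
    counterpart may carry the homocrystal excess.
    """

    r_s: float = 1.0
    mm_asc_g_mol: float = 176.12
    mm_nic_g_mol: float = 122.12
    fully_cocrystallized_component: str = "NIC"

    def __post_init__(self) -> None:
        if self.r_s <= 0 or self.mm_asc_g_mol <= 0 or self.mm_nic_g_mol <= 0:
            raise DomainError("stoichiometric ratio and molar masses must be > 0")
        if self.fully_cocrystallized_component not in ("ASC", "NIC"):
            raise ParameterError("fully_cocrystallized_component must be 'ASC' or 'NIC'")

    @property
    def cocrystal_formula_mass(self) -> float:
        """Mass of one mmol of cocrystal units, R_s·MM_ASC + MM_NIC (mg)."""
        return self.r_s * self.mm_asc_g_mol + self.mm_nic_g_mol


@dataclass(frozen=True)
class PurityResult:
    batch_id: str
    source: str
    n_cocrystal_mmol: float
    m_cocrystal_mg: float
    purity_wt_pct: float
    m_excess_mg: float
    excess_component: str
    molar_ratio_asc_nic: float
    warnings: tuple[str, ...] = ()


class PurityReport(NamedTuple):
    """Per-batch purity rows plus FODS-vs-reference agreement rows."""

    purity: pd.DataFrame
    agreement: pd.DataFrame


def molar_ratio(m_asc_mg: float, m_nic_mg: float,
                stoich: StoichiometryModel = StoichiometryModel()) -> float:
    """Bulk ASC:NIC molar ratio, (m_ASC/MM_ASC)/(m_NIC/MM_NIC).

    A value above the expected stoichiometric ratio indicates ASC
    homocrystal impurities in the bulk.
    """
    if m_asc_mg <= 0 or m_nic_mg <= 0:
        raise DomainError("component masses must be > 0")
    return (m_asc_mg / stoich.mm_asc_g_mol) / (m_nic_mg / stoich.mm_nic_g_mol)


def purity_mass_balance(
    batch: BatchMeasurement,
    stoich: StoichiometryModel = StoichiometryModel(),
) -> PurityResult:
    """Convert measured ASC/NIC totals of one batch into cocrystal mass,
    wt % purity and homocrystal excess (see module docstring for the
    formula set)."""
    ratio = molar_ratio(batch.m_asc_total_mg, batch.m_nic_total_mg, stoich)
    warnings: list[str] = []

    if stoich.fully_cocrystallized_component == "NIC":
        n_cc = batch.m_nic_total_mg / stoich.mm_nic_g_mol
        excess_component = "ASC"
        m_excess = batch.m_asc_total_mg - n_cc * stoich.r_s * stoich.mm_asc_g_mol
        if ratio < stoich.r_s:
            warnings.append(
                "assumption-violation: NIC in molar excess "
                f"(ASC:NIC = {ratio:.3f} < R_s = {stoich.r_s:g})"
            )
    else:
        n_cc = batch.m_asc_total_mg / (stoich.r_s * stoich.mm_asc_g_mol)
        excess_component = "NIC"
        m_excess = batch.m_nic_total_mg - n_cc * stoich.mm_nic_g_mol
        if ratio > stoich.r_s:
            warnings.append(
                "assumption-violation: ASC in molar excess "
                f"(ASC:NIC = {ratio:.3f} > R_s = {stoich.r_s:g})"
            )

    m_cc = n_cc * stoich.cocrystal_formula_mass
    purity = 100.0 * m_cc / batch.m_collected_mg
    if purity > 100.0:
        warnings.append(f"purity {purity:.2f} wt % exceeds 100 (measurement error)")
    if m_excess < 0:
        warnings.append(
            f"negative excess mass ({m_excess:.2f} mg): measured totals "
            "are inconsistent with the limiting-component assumption"
        )
    return PurityResult(
        batch_id=batch.batch_id,
        source=batch.source,
        n_cocrystal_mmol=n_cc,
        m_cocrystal_mg=m_cc,
        purity_wt_pct=purity,
        m_excess_mg=m_excess,
        excess_component=excess_component,
        molar_ratio_asc_nic=ratio,
        warnings=tuple(warnings),
    )


def batch_table_report(
    batches: Sequence[BatchMeasurement],
    stoich: StoichiometryModel = StoichiometryModel(),
) -> PurityReport:
    """Purity table for a set of batch measurements.

    One purity row per (batch_id, source); duplicates are rejected. For
    every batch measured both by FODS and by a reference method, an
    agreement row reports the absolute purity difference (percentage
    points) and the relative accuracy 100·(1 − |p_FODS − p_ref|/p_ref).
    """
    if not batches:
        raise ParameterError("need at least one batch measurement")
    seen = set()
    for b in batches:
        key = (b.batch_id, b.source)
        if key in seen:
            raise InputError(f"duplicate batch/source row {key}")
        seen.add(key)

    rows = [purity_mass_balance(b, stoich) for b in batches]
    purity_df = pd.DataFrame(
        {
            "batch_id": [r.batch_id for r in rows],
            "source": [r.source for r in rows],
            "m_collected_mg": [b.m_collected_mg for b in batches],
            "m_asc_total_mg": [b.m_asc_total_mg for b in batches],
            "m_nic_total_mg": [b.m_nic_total_mg for b in batches],
            "n_cocrystal_mmol": [r.n_cocrystal_mmol for r in rows],
            "m_cocrystal_mg": [r.m_cocrystal_mg for r in rows],
            "purity_wt_pct": [r.purity_wt_pct for r in rows],
            "m_excess_mg": [r.m_excess_mg for r in rows],
            "molar_ratio_asc_nic": [r.molar_ratio_asc_nic for r in rows],
            "warnings": ["; ".join(r.warnings) for r in rows],
        }
    )

    agree_rows = []
    for batch_id, grp in purity_df.groupby("batch_id", sort=False):
        fods = grp[grp["source"] == "FODS"]
        ref = grp[grp["source"] != "FODS"]
        if len(fods) == 1 and len(ref) >= 1:
            p_f = float(fods["purity_wt_pct"].iloc[0])
            for _, rr in ref.iterrows():
                p_r = float(rr["purity_wt_pct"])
                agree_rows.append(
                    {
                        "batch_id": batch_id,
                        "reference_source": rr["source"],
                        "purity_fods_wt_pct": p_f,
                        "purity_ref_wt_pct": p_r,
                        "abs_diff_pp": abs(p_f - p_r),
                        "relative_accuracy_pct": 100.0 * (1.0 - abs(p_f - p_r) / p_r),
                    }
                )
    agreement_df = pd.DataFrame(
        agree_rows,
        columns=[
            "batch_id", "reference_source", "purity_fods_wt_pct",
            "purity_ref_wt_pct", "abs_diff_pp", "relative_accuracy_pct",
        ],
    )
    return PurityReport(purity=purity_df, agreement=agreement_df)
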