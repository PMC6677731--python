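"""Reference dosing regimens of the simulated clinical trials.

Builders for the regimens this simulator is benchmarked against: anti-PD-1
monotherapy every two weeks, anti-CTLA-4 every three weeks for four doses,
anti-PD-L1 every two weeks, concurrent combination dosing, and the two
sequential induction orders (12-week blocks).
"""

from __future__ import annotations

from .pbpk import Regimen, expand_schedule

__all__ = [
    "anti_pd1",
    "anti_ctla4",
    "anti_pdl1",
    "combination",
    "sequential_pd1_first",
    "sequential_ctla4_first",
    "no_therapy",
]


def no_therapy() -> Regimen:
    return Regimen(events=[], label="no therapy")


def anti_pd1(dose: float = 3.0, n_doses: int = 26) -> Regimen:
    """Anti-PD-1 Q2W (default 3 mg/kg for one year)."""
    return expand_schedule("antiPD1", dose, 14.0, n_doses, 0.0, 1.0,
                           label=f"anti-PD-1 {dose:g} mg/kg Q2W")


def anti_ctla4(dose: float = 3.0, n_doses: int = 4) -> Regimen:
    """Anti-CTLA-4 Q3W x 4 (1.5 h infusion)."""
    return expand_schedule("antiCTLA4", dose, 21.0, n_doses, 0.0, 1.5,
                           label=f"anti-CTLA-4 {dose:g} mg/kg Q3W")


def anti_pdl1(dose: float = 20.0, n_doses: int = 26) -> Regimen:
    """Anti-PD-L1 Q2W (default 20 mg/kg)."""
    return expand_schedule("antiPDL1", dose, 14.0, n_doses, 0.0, 1.0,
                           label=f"anti-PD-L1 {dose:g} mg/kg Q2W")


def combination(pd1_dose: float = 1.0, ctla4_dose: float = 3.0) -> Regimen:
    """Concurrent anti-PD-1 + anti-CTLA-4, both Q3W x 4."""
    reg = (expand_schedule("antiPD1", pd1_dose, 21.0, 4, 0.0, 1.0)
           + expand_schedule("antiCTLA4", ctla4_dose, 21.0, 4, 0.0, 1.5))
    reg.label = (f"anti-PD-1 {pd1_dose:g} + anti-CTLA-4 {ctla4_dose:g} mg/kg Q3W x4")
    return reg


def sequential_pd1_first(block_days: float = 84.0) -> Regimen:
    """Induction: anti-PD-1 3 mg/kg Q2W for 12 weeks, then anti-CTLA-4
    3 mg/kg Q3W x 4."""
    reg = (expand_schedule("antiPD1", 3.0, 14.0, 6, 0.0, 1.0)
           + expand_schedule("antiCTLA4", 3.0, 21.0, 4, block_days, 1.5))
    reg.label = "sequential anti-PD-1 first"
    return reg


def sequential_ctla4_first(block_days: float = 84.0) -> Regimen:
    """Induction: anti-CTLA-4 3 mg/kg Q3W x 4, then anti-PD-1 3 mg/kg Q2W."""
    reg = (expand_schedule("antiCTLA4", 3.0, 21.0, 4, 0.0, 1.5)
           + expand_schedule("antiPD1", 3.0, 14.0, 6, block_days, 1.0))
    reg.label = "sequential anti-CTLA-4 first"
    return reg
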