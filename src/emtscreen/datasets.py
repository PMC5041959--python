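"""Reference compound profiles used as worked examples.

Per-readout EMT IC50s (nM; focal adhesions / stress fibers / fibronectin)
for nine kinase inhibitors with reported EMT-blocking activity in
TGFb-treated NMuMG cells: the TGFBR inhibitors SB-431542, RepSox and
SB-525334, the SRC-family inhibitor PP1, and the multi-kinase inhibitors
PD-161570, PD-166285, nintedanib, sorafenib and pazopanib.  The combined
EMT IC50 of a compound is the arithmetic mean of the three readouts,
reported to one decimal.
"""

from __future__ import annotations

from .doseresponse import CensoredIC50, combined_emt_ic50

__all__ = ["REFERENCE_EMT_IC50S", "reference_combined_ic50"]

#: compound -> (IC50_FA, IC50_SF, IC50_FN) in nM
REFERENCE_EMT_IC50S: dict[str, tuple[float, float, float]] = {
    "SB-431542": (243.0, 184.0, 195.0),
    "RepSox": (47.0, 55.0, 44.0),
    "SB-525334": (276.0, 243.0, 261.0),
    "PP1": (910.0, 1136.0, 1515.0),
    "PD-161570": (337.0, 702.0, 1044.0),
    "PD-166285": (27.0, 79.0, 39.0),
    "Nintedanib": (2630.0, 5060.0, 1182.0),
    "Sorafenib": (2090.0, 3926.0, 1353.0),
    "Pazopanib": (8030.0, 7300.0, 3950.0),
}


def reference_combined_ic50(compound: str) -> float:
    """Combined EMT IC50 (nM, rounded to one decimal) for a reference
    compound, computed from its per-readout IC50s."""
    fa, sf, fn = REFERENCE_EMT_IC50S[compound]
    combined = combined_emt_ic50(
        CensoredIC50.measured(fa),
        CensoredIC50.measured(sf),
        CensoredIC50.measured(fn),
    )
    return round(combined.value, 1)
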