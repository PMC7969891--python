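"""Leave-one-out and single-SNP (forest) sensitivity analyses."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .estimators import EstimationError, MRResult, ivw, wald_ratio
from .harmonize import HarmonizedInstrument


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_rsid: str
    result: MRResult


def leave_one_out(insts: Sequence[HarmonizedInstrument],
                  effects_model: str = "multiplicative_random") -> list[LeaveOneOutRow]:
    """Re-estimate IVW omitting each instrument in turn (input order)."""
    if len(insts) < 2:
        raise EstimationError("leave_one_out needs at least 2 instruments")
    rows = []
    for k, omitted in enumerate(insts):
        rest = [inst for i, inst in enumerate(insts) if i != k]
        rows.append(LeaveOneOutRow(omitted_rsid=omitted.rsid,
                                   result=ivw(rest, effects_model)))
    return rows


def single_snp_results(insts: Sequence[HarmonizedInstrument]) -> list[MRResult]:
    """Per-SNP Wald-ratio estimates, forest-plot ready (input order)."""
    return [wald_ratio(inst) for inst in insts]
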