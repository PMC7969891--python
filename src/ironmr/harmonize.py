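"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs both studies' effects expressed for the same effect
allele. Four situations arise: identical allele pairs (keep), swapped
pairs (flip the outcome effect and frequency), pairs that match after
reverse-strand complementation, and palindromic SNPs (A/T or C/G) whose
strand cannot be resolved from alleles alone — these are resolved by
comparing which side of 0.5 each study's effect-allele frequency falls
on, and dropped as ambiguous when either frequency is too close to 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Union

from .gwas_io import AssociationRecord, SummaryStatError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Half-width of the EAF window around 0.5 within which a palindromic
#: SNP's orientation is declared ambiguous.
DEFAULT_PALINDROME_WINDOW = 0.08
#: |eaf_x - eaf_y| above this triggers a warning (possible allele mixup).
EAF_MISMATCH_WARN = 0.2


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP with exposure and outcome effects on a shared effect allele."""

    rsid: str
    effect_allele: str
    bx: float       # exposure effect, per SD of biomarker
    se_x: float
    by: float       # outcome effect, log-odds
    se_y: float
    eaf_x: float | None = None
    eaf_y: float | None = None
    palindromic: bool = False
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise SummaryStatError(f"{self.rsid}: standard errors must be positive")


@dataclass(frozen=True)
class Dropped:
    """A drop decision with its reason, for the harmonization log."""

    rsid: str
    reason: str


@dataclass(frozen=True)
class HarmonizationResult:
    instruments: tuple[HarmonizedInstrument, ...]
    dropped: tuple[Dropped, ...]
    missing: tuple[str, ...]


def _is_snv(allele: str) -> bool:
    return allele in _COMPLEMENT


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def harmonize(exposure: AssociationRecord, outcome: AssociationRecord,
              palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW,
              ) -> Union[HarmonizedInstrument, Dropped]:
    """Align one outcome record to the exposure's effect allele."""
    if exposure.rsid != outcome.rsid:
        raise SummaryStatError(f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}")
    rsid = exposure.rsid
    ex_ea, ex_oa = exposure.effect_allele, exposure.other_allele
    out_ea, out_oa = outcome.effect_allele, outcome.other_allele
    if not all(_is_snv(a) for a in (ex_ea, ex_oa, out_ea, out_oa)):
        return Dropped(rsid, "indel or multi-allelic record; only biallelic SNVs supported")

    if _is_palindromic(ex_ea, ex_oa):
        if (out_ea, out_oa) not in {(ex_ea, ex_oa), (ex_oa, ex_ea)}:
            return Dropped(rsid, f"irreconcilable alleles {out_ea}/{out_oa} vs {ex_ea}/{ex_oa}")
        return _harmonize_palindrome(exposure, outcome, palindrome_eaf_window)

    flipped = False
    by, eaf_y = outcome.beta, outcome.eaf
    pair = (out_ea, out_oa)
    if pair not in {(ex_ea, ex_oa), (ex_oa, ex_ea)}:
        pair = (_COMPLEMENT[out_ea], _COMPLEMENT[out_oa])  # try other strand
    if pair == (ex_ea, ex_oa):
        pass
    elif pair == (ex_oa, ex_ea):
        flipped = True
        by = -by
        eaf_y = None if eaf_y is None else 1.0 - eaf_y
    else:
        return Dropped(rsid, f"irreconcilable alleles {out_ea}/{out_oa} vs {ex_ea}/{ex_oa}")
    return _build(exposure, outcome, by=by, eaf_y=eaf_y, flipped=flipped, palindromic=False)


def _harmonize_palindrome(exposure: AssociationRecord, outcome: AssociationRecord,
                          window: float) -> Union[HarmonizedInstrument, Dropped]:
    rsid = exposure.rsid
    ex, ey = exposure.eaf, outcome.eaf
    if ex is None or ey is None:
        return Dropped(rsid, "palindromic SNP without allele frequencies")
    lo, hi = 0.5 - window, 0.5 + window
    if lo <= ex <= hi or lo <= ey <= hi:
        return Dropped(rsid, f"palindromic SNP with ambiguous EAF (window +/-{window:g} around 0.5)")
    same_side = (ex < 0.5) == (ey < 0.5)
    if same_side:
        return _build(exposure, outcome, by=outcome.beta, eaf_y=ey,
                      flipped=False, palindromic=True)
    return _build(exposure, outcome, by=-outcome.beta, eaf_y=1.0 - ey,
                  flipped=True, palindromic=True)


def _build(exposure: AssociationRecord, outcome: AssociationRecord, *, by: float,
           eaf_y: float | None, flipped: bool, palindromic: bool) -> HarmonizedInstrument:
    if exposure.eaf is not None and eaf_y is not None:
        if abs(exposure.eaf - eaf_y) > EAF_MISMATCH_WARN:
            logger.warning("%s: aligned EAFs differ by more than %.2f (%.3f vs %.3f)",
                           exposure.rsid, EAF_MISMATCH_WARN, exposure.eaf, eaf_y)
    return HarmonizedInstrument(
        rsid=exposure.rsid, effect_allele=exposure.effect_allele,
        bx=exposure.beta, se_x=exposure.se, by=by, se_y=outcome.se,
        eaf_x=exposure.eaf, eaf_y=eaf_y, palindromic=palindromic, flipped=flipped)


def harmonize_set(exposures, outcomes: Sequence[AssociationRecord],
                  palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW,
                  ) -> HarmonizationResult:
    """Harmonize each exposure instrument against the outcome records.

    ``exposures`` may be an InstrumentSet or any iterable of records.
    Exposure SNPs absent from the outcome list are reported as missing
    (no proxy search is attempted).
    """
    records = getattr(exposures, "records", exposures)
    out_map = {r.rsid: r for r in outcomes}
    kept: list[HarmonizedInstrument] = []
    dropped: list[Dropped] = []
    missing: list[str] = []
    for exp in records:
        if exp.rsid not in out_map:
            missing.append(exp.rsid)
            continue
        result = harmonize(exp, out_map[exp.rsid], palindrome_eaf_window)
        if isinstance(result, Dropped):
            logger.info("dropped %s: %s", result.rsid, result.reason)
            dropped.append(result)
        else:
            kept.append(result)
    if not kept:
        raise SummaryStatError("no exposure SNP could be harmonized against the outcome data")
    return HarmonizationResult(tuple(kept), tuple(dropped), tuple(missing))
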