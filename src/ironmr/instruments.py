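"""Instrument selection and strength statistics.

Selection follows three criteria: genome-wide significance (p < 5e-8),
pairwise linkage equilibrium (r^2 <= 0.01) and instrument strength
(F > 10). Two instrument sets are built from the exposure table:

* conservative — SNPs significant for all four iron biomarkers whose
  effect signs describe a concordant shift in systemic iron status
  (iron, ferritin and transferrin saturation moving together, transferrin
  opposite);
* liberal — per biomarker, every SNP significant for that biomarker.

Strength is summarised per SNP by the variance explained
R^2 = 2 * beta^2 * (1 - EAF) * EAF (standardized phenotype) and
F = R^2 (N - k - 1) / ((1 - R^2) k).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .gwas_io import BIOMARKERS, AssociationRecord, SummaryStatError

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
LD_R2_MAX = 0.01
WEAK_F = 10.0

#: Sign each biomarker's effect takes when systemic iron status rises.
IRON_STATUS_SIGNS = {"iron": +1, "ferritin": +1,
                     "transferrin_saturation": +1, "transferrin": -1}


@dataclass(frozen=True)
class StrengthStats:
    """Per-instrument strength: variance explained and F statistic."""

    rsid: str
    trait: str
    r2: float
    f_stat: float
    n: int
    k: int = 1


@dataclass(frozen=True)
class InstrumentSet:
    mode: str  # "conservative" | "liberal"
    trait: str
    records: tuple[AssociationRecord, ...]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        if len(rsids) != len(set(rsids)):
            raise SummaryStatError(f"duplicate rsIDs in instrument set: {rsids}")

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(r.rsid for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


def variance_explained(beta: float, eaf: float) -> float:
    """R^2 = 2 beta^2 (1-EAF) EAF for a standardized phenotype."""
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf must lie in (0,1), got {eaf}")
    return 2.0 * beta * beta * (1.0 - eaf) * eaf


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """F = R^2 (N - k - 1) / ((1 - R^2) k)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0,1), got {r2}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    return r2 * (n - k - 1) / ((1.0 - r2) * k)


def strength_stats(records: Iterable[AssociationRecord], k: int = 1) -> list[StrengthStats]:
    """Per-record R^2 and F (k=1: each SNP as its own instrument)."""
    out = []
    for r in records:
        if r.eaf is None or r.n is None:
            raise SummaryStatError(f"{r.rsid}: eaf and n required for strength statistics")
        r2 = variance_explained(r.beta, r.eaf)
        out.append(StrengthStats(rsid=r.rsid, trait=r.trait, r2=r2,
                                 f_stat=f_statistic(r2, r.n, k), n=r.n, k=k))
    return out


def set_strength(records: Sequence[AssociationRecord]) -> StrengthStats:
    """Set-level strength: summed R^2 with k = number of instruments."""
    per = strength_stats(records)
    r2 = sum(s.r2 for s in per)
    n = records[0].n
    k = len(records)
    return StrengthStats(rsid=";".join(s.rsid for s in per), trait=per[0].trait,
                         r2=r2, f_stat=f_statistic(r2, n, k), n=n, k=k)


def significance_filter(records: Iterable[AssociationRecord],
                        threshold: float = GENOME_WIDE_P) -> list[AssociationRecord]:
    """Keep records with p strictly below ``threshold``.

    Records without a stored p-value (the exposure fixture lists only
    genome-wide-significant hits) count as passing.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0,1)")
    return [r for r in records if r.pvalue is None or r.pvalue < threshold]


def ld_prune(records: Sequence[AssociationRecord],
             r2_matrix: Mapping[tuple[str, str], float],
             threshold: float = LD_R2_MAX,
             *, assume_unlinked: bool = False) -> list[AssociationRecord]:
    """Greedy LD pruning to pairwise r^2 <= ``threshold``.

    Records are visited by ascending p (missing p sorts first; ties keep
    input order); a record correlated above threshold (strict >) with an
    already-kept record is dropped.
    """
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].pvalue is not None,
                                  records[i].pvalue if records[i].pvalue is not None else 0.0,
                                  i))
    kept: list[int] = []
    for i in order:
        clash = False
        for j in kept:
            if _pair_r2(r2_matrix, records[i].rsid, records[j].rsid, assume_unlinked) > threshold:
                clash = True
                break
        if not clash:
            kept.append(i)
    kept.sort()
    return [records[i] for i in kept]


def _pair_r2(matrix: Mapping[tuple[str, str], float], a: str, b: str,
             assume_unlinked: bool) -> float:
    if a == b:
        return 1.0
    for key in ((a, b), (b, a)):
        if key in matrix:
            return float(matrix[key])
    if assume_unlinked:
        return 0.0
    raise KeyError(f"no LD entry for pair ({a}, {b})")


def read_ld_matrix(path) -> dict[tuple[str, str], float]:
    """Read a 3-column TSV (rsid_a, rsid_b, r2) into a pair map."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "r2"], comment="#")
    return {(str(r.a), str(r.b)): float(r.r2) for r in df.itertuples()}


def _by_rsid(records: Iterable[AssociationRecord]) -> dict[str, AssociationRecord]:
    return {r.rsid: r for r in records}


def conservative_set(table: Mapping[str, Sequence[AssociationRecord]],
                     trait: str = "iron") -> InstrumentSet:
    """SNPs with a concordant iron-status signature across all four biomarkers.

    A SNP qualifies when it is significant for (present in) all four
    biomarker columns and its signs satisfy
    sign(iron) = sign(ferritin) = sign(tsat) = -sign(transferrin);
    the test is symmetric under flipping all four signs at once, so it
    does not depend on which allele is labelled the effect allele.
    ``trait`` selects whose betas the returned records carry; the rsID
    set is the same for every choice.
    """
    for b in BIOMARKERS:
        if b not in table:
            raise SummaryStatError(f"biomarker {b!r} missing from exposure table")
    if trait not in BIOMARKERS:
        raise KeyError(f"unknown biomarker {trait!r}")
    maps = {b: _by_rsid(table[b]) for b in BIOMARKERS}
    chosen: list[AssociationRecord] = []
    provenance: dict[str, str] = {}
    for rec in table[trait]:
        rsid = rec.rsid
        if not all(rsid in maps[b] for b in BIOMARKERS):
            continue
        signs = {b: math.copysign(1.0, maps[b][rsid].beta) for b in BIOMARKERS}
        oriented = {signs[b] * IRON_STATUS_SIGNS[b] for b in BIOMARKERS}
        if len(oriented) == 1:  # concordant (either global orientation)
            chosen.append(rec)
            provenance[rsid] = "genome-wide significant for all four biomarkers, concordant signs"
    return InstrumentSet(mode="conservative", trait=trait,
                         records=tuple(chosen), provenance=provenance)


def liberal_set(table: Mapping[str, Sequence[AssociationRecord]],
                biomarker: str) -> InstrumentSet:
    """All SNPs significant for ``biomarker`` (the liberal per-trait set)."""
    if biomarker not in BIOMARKERS:
        raise KeyError(f"unknown biomarker {biomarker!r}; valid: {', '.join(BIOMARKERS)}")
    if biomarker not in table:
        raise SummaryStatError(f"biomarker {biomarker!r} missing from exposure table")
    records = tuple(table[biomarker])
    if not records:
        logger.warning("liberal set for %s is empty", biomarker)
    return InstrumentSet(mode="liberal", trait=biomarker, records=records,
                         provenance={r.rsid: f"genome-wide significant for {biomarker}"
                                     for r in records})
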