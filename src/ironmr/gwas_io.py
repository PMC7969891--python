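"""Reading, validating and writing GWAS summary statistics.

The packaged fixtures are the two association tables of the study this
package reproduces: genome-wide-significant SNPs for four biomarkers of
systemic iron status from the Genetics of Iron Status (GIS) consortium
meta-analysis (N = 48,972 Europeans), and the same SNPs' associations
with amyotrophic lateral sclerosis (ALS) from the ALS Variant Server
meta-analysis (20,806 cases, 59,804 controls).

Exposure betas are per standard deviation of the biomarker (ferritin on
the log scale); outcome betas are log-odds. Positions are 1-based on
genome build 37. The GIS table lists only genome-wide-significant
associations and prints no p-values, so exposure records carry
``pvalue=None``, which downstream selection treats as passing the
5e-8 threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BIOMARKERS = ("iron", "ferritin", "transferrin_saturation", "transferrin")

#: Exposure GWAS size (GIS consortium meta-analysis).
GIS_N = 48_972
#: Outcome GWAS: ALS cases, controls and total.
ALS_CASES = 20_806
ALS_CONTROLS = 59_804
ALS_N = ALS_CASES + ALS_CONTROLS


class SummaryStatError(ValueError):
    """Invalid summary-statistic input."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait association from a GWAS summary table."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None
    trait: str = ""
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise SummaryStatError("rsid must be nonempty")
        if not math.isfinite(self.beta):
            raise SummaryStatError(f"{self.rsid}: beta must be finite")
        if not (self.se > 0):
            raise SummaryStatError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise SummaryStatError(f"{self.rsid}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise SummaryStatError(f"{self.rsid}: eaf must lie strictly in (0,1), got {self.eaf}")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise SummaryStatError(f"{self.rsid}: pvalue must lie in (0,1], got {self.pvalue}")


@dataclass(frozen=True)
class StudyMeta:
    """Provenance of one GWAS: sizes, ancestry and measured traits."""

    n_total: int
    ancestry: str = "European"
    n_cases: int | None = None
    n_controls: int | None = None
    trait_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_cases is not None and self.n_controls is not None:
            if self.n_cases + self.n_controls != self.n_total:
                raise SummaryStatError("n_cases + n_controls must equal n_total")


GIS_META = StudyMeta(n_total=GIS_N, trait_set=BIOMARKERS)
ALS_META = StudyMeta(n_total=ALS_N, n_cases=ALS_CASES, n_controls=ALS_CONTROLS,
                     trait_set=("als",))

#: Default column names expected in a summary-statistics TSV.
DEFAULT_COLUMNS: dict[str, str] = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
}
_OPTIONAL_FIELDS = ("eaf", "pvalue", "n", "trait", "chrom", "pos")


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait: str = "",
    n: int | None = None,
    diagnostics: list[str] | None = None,
) -> list[AssociationRecord]:
    """Read a tab-delimited summary-statistics file into records.

    ``column_map`` maps record field names to file column names; the five
    required fields are rsid, effect_allele, other_allele, beta, se.
    Rows violating record invariants are rejected; each rejection is
    appended to ``diagnostics`` (if given) and logged with its 0-based
    data-row index. Raises if no row survives.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for fld in DEFAULT_COLUMNS:
        if cmap[fld] not in df.columns:
            raise SummaryStatError(f"mapped column {cmap[fld]!r} (field {fld!r}) not in header")

    records: list[AssociationRecord] = []
    for i, row in df.iterrows():
        try:
            kwargs: dict = {
                "rsid": _as_str(row[cmap["rsid"]]),
                "effect_allele": _as_str(row[cmap["effect_allele"]]).upper(),
                "other_allele": _as_str(row[cmap["other_allele"]]).upper(),
                "beta": float(row[cmap["beta"]]),
                "se": float(row[cmap["se"]]),
                "trait": trait,
                "n": n,
            }
            for fld in _OPTIONAL_FIELDS:
                col = cmap.get(fld)
                if col and col in df.columns and not _blank(row[col]):
                    if fld in ("eaf", "pvalue"):
                        kwargs[fld] = float(row[col])
                    elif fld in ("n", "pos"):
                        kwargs[fld] = int(float(row[col]))
                    else:
                        kwargs[fld] = _as_str(row[col])
            records.append(AssociationRecord(**kwargs))
        except (SummaryStatError, TypeError, ValueError) as exc:
            msg = f"row {i}: rejected ({exc})"
            logger.warning("%s: %s", path.name, msg)
            if diagnostics is not None:
                diagnostics.append(msg)
    if not records:
        raise SummaryStatError(f"{path}: no valid summary-statistic rows")
    return records


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == ""


def _as_str(value) -> str:
    if _blank(value):
        raise SummaryStatError("required field is blank")
    return str(value).strip()


def _fixture_path(name: str) -> Path:
    return Path(resources.files("ironmr.data") / name)


def _iron_table() -> pd.DataFrame:
    return pd.read_csv(_fixture_path("gis_iron_snps.tsv"), sep="\t", dtype=str)


def load_iron_fixture(biomarker: str) -> list[AssociationRecord]:
    """Exposure records for one iron-status biomarker from the GIS table.

    Only SNPs with a printed (genome-wide-significant) effect for that
    biomarker are returned; blank table cells mean the SNP did not reach
    significance for that biomarker. Records carry ``pvalue=None`` — the
    source table lists significant associations without printing p.
    """
    if biomarker not in BIOMARKERS:
        raise KeyError(f"unknown biomarker {biomarker!r}; valid: {', '.join(BIOMARKERS)}")
    df = _iron_table()
    out: list[AssociationRecord] = []
    for _, row in df.iterrows():
        beta = row[f"{biomarker}_beta"]
        if _blank(beta):
            continue
        out.append(AssociationRecord(
            rsid=row["rsid"], chrom=row["chrom"], pos=int(row["pos"]),
            effect_allele=row["effect_allele"], other_allele=row["other_allele"],
            eaf=float(row["eaf"]), beta=float(beta), se=float(row[f"{biomarker}_se"]),
            pvalue=None, n=GIS_N, trait=biomarker,
        ))
    return out


def load_iron_table() -> dict[str, list[AssociationRecord]]:
    """All four biomarkers' exposure records, keyed by biomarker."""
    return {b: load_iron_fixture(b) for b in BIOMARKERS}


def load_als_fixture() -> list[AssociationRecord]:
    """The 12 iron-status SNPs' associations with ALS (log-odds scale)."""
    return read_summary_table(_fixture_path("avs_als_snps.tsv"),
                              {"eaf": "eaf", "pvalue": "pvalue"},
                              trait="als", n=ALS_N)


RESULT_COLUMNS = ("exposure", "mode", "method", "nsnp", "beta", "se", "or",
                  "ci_low", "ci_high", "pvalue", "q", "egger_intercept",
                  "egger_intercept_p")


def write_results_tsv(results: Sequence, path: str | Path) -> None:
    """Write MR results as a fixed-column TSV (6 significant digits)."""
    if not results:
        raise SummaryStatError("results list is empty")
    rows = []
    for r in results:
        rows.append({
            "exposure": r.exposure, "mode": r.mode, "method": r.method,
            "nsnp": r.n_snp, "beta": _fmt(r.beta), "se": _fmt(r.se),
            "or": _fmt(r.or_value), "ci_low": _fmt(r.ci_low),
            "ci_high": _fmt(r.ci_high), "pvalue": _fmt(r.pvalue),
            "q": _fmt(r.q_stat), "egger_intercept": _fmt(r.egger_intercept),
            "egger_intercept_p": _fmt(r.egger_intercept_p),
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def _fmt(x) -> str:
    if x is None:
        return ""
    return f"{x:.6g}"
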