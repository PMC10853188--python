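"""Reading, validation and writing of GWAS summary-statistic tables.

The package consumes per-SNP association estimates from delimited text
files (one row per variant, header row naming the columns).  Because the
public cortisol, body-shape and BMI/WHR downloads all use different
column headers, the reader is parameterised by a *dialect*: a mapping
from :class:`SummaryRecord` field names to the column headers of the
file at hand.  The default dialect follows the common GWAS-catalog
style (``SNP, CHR, BP, EA, NEA, EAF, BETA, SE, P, N``).

Effect sizes are assumed to be on the standard-deviation scale of the
trait (per effect-allele copy), matching how both the cortisol and the
body-shape summary statistics were published.

The module also ships, as a packaged fixture, the printed table of
genetic instruments for morning plasma cortisol (17 variants grouped
into the main instrument set IV_A, the secondary single-locus set IV_B,
the replacement proxies used for BMI/WHR, and the high-CADD analogues).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, LDLookupError

__all__ = [
    "SummaryRecord",
    "LDMatrix",
    "RowDiagnostic",
    "DEFAULT_DIALECT",
    "read_summary_table",
    "write_summary_table",
    "filter_by_n",
    "read_ld_matrix",
    "write_ld_matrix",
    "Table1",
    "table1_fixture",
]

#: Default field -> column-header mapping (GWAS-catalog style).
DEFAULT_DIALECT: dict[str, str] = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "NEA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
    "cadd": "CADD",
    "gene": "GENE",
}

_MANDATORY_FIELDS = ("rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se")
_MISSING_TOKENS = {"", ".", "na", "nan", "none", "null"}

# |log10 p_printed - log10 p_implied| above which the reported p-value is
# considered inconsistent with beta/se.  Published tables round beta and se
# to a few significant digits, which moves the implied p by up to ~0.1-0.2
# decades, so inconsistency is a warning rather than a rejection.
_P_CONSISTENCY_DECADES = 0.3


@dataclass
class SummaryRecord:
    """One SNP's association estimate in one GWAS.

    ``beta`` is the effect per copy of ``effect_allele`` in SD units of
    the trait; ``se`` its standard error.  ``eaf`` is the effect-allele
    frequency, ``n`` the analysed sample size and ``cadd`` an optional
    deleteriousness score.  ``gene`` is pass-through annotation.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None
    cadd: float | None = None
    gene: str | None = None

    def validate(self) -> None:
        """Raise ``ValueError`` on a hard invariant violation."""
        if not self.rsid:
            raise ValueError("empty rsid")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite, got {self.beta}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf outside [0, 1]: {self.eaf}")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: pvalue outside (0, 1]: {self.pvalue}")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.rsid}: n must be positive, got {self.n}")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"{self.rsid}: cadd must be >= 0, got {self.cadd}")
        if self.pos <= 0:
            raise ValueError(f"{self.rsid}: position must be a positive 1-based coordinate")

    def zscore(self) -> float:
        return self.beta / self.se

    def pvalue_drift_decades(self) -> float | None:
        """|log10 p_reported - log10 p_implied by beta/se|, or ``None``.

        Returns ``None`` when no p-value is stored or the implied p
        underflows.
        """
        if self.pvalue is None:
            return None
        implied = 2.0 * stats.norm.sf(abs(self.zscore()))
        if implied <= 0.0:
            return None
        return abs(math.log10(self.pvalue) - math.log10(implied))


@dataclass
class RowDiagnostic:
    """Row-level outcome of reading or validating a table."""

    row: int
    rsid: str | None
    message: str
    severity: str = "error"  # "error" (row rejected) or "warning" (row kept)


def _parse_float(token: str) -> float | None:
    if token.strip().lower() in _MISSING_TOKENS:
        return None
    return float(token)


def _parse_int(token: str) -> int | None:
    value = _parse_float(token)
    if value is None:
        return None
    return int(round(value))


def read_summary_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
) -> tuple[list[SummaryRecord], list[RowDiagnostic]]:
    """Read a delimited summary-statistic table into records.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file (gzip transparently supported).
    dialect
        Field -> column-header mapping; defaults to :data:`DEFAULT_DIALECT`.
        Optional fields whose column is absent from the file are simply
        left missing.
    sep
        Explicit delimiter; autodetected when ``None``.

    Returns
    -------
    (records, diagnostics)
        One record per accepted row.  Rows violating hard invariants or
        failing numeric parsing are rejected and reported in
        ``diagnostics``; rounded p-values inconsistent with ``beta/se``
        are kept with a warning diagnostic.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    frame = pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c",
        dtype=str, keep_default_na=False, compression="infer",
    )
    missing = [dialect[f] for f in _MANDATORY_FIELDS if dialect.get(f) not in frame.columns]
    if missing:
        raise ConfigError(f"missing mandatory column(s) {missing} in {path}")

    def col(fieldname: str):
        header = dialect.get(fieldname)
        return frame[header] if header in frame.columns else None

    records: list[SummaryRecord] = []
    diagnostics: list[RowDiagnostic] = []
    columns = {f: col(f) for f in DEFAULT_DIALECT}
    for i in range(len(frame)):
        rsid = str(columns["rsid"].iloc[i]).strip()
        try:
            rec = SummaryRecord(
                rsid=rsid,
                chrom=str(columns["chrom"].iloc[i]).strip(),
                pos=_parse_int(columns["pos"].iloc[i]) or 0,
                effect_allele=str(columns["effect_allele"].iloc[i]).strip().upper(),
                other_allele=str(columns["other_allele"].iloc[i]).strip().upper(),
                beta=_parse_float(columns["beta"].iloc[i]),
                se=_parse_float(columns["se"].iloc[i]),
                eaf=_parse_float(columns["eaf"].iloc[i]) if columns["eaf"] is not None else None,
                pvalue=_parse_float(columns["pvalue"].iloc[i]) if columns["pvalue"] is not None else None,
                n=_parse_int(columns["n"].iloc[i]) if columns["n"] is not None else None,
                cadd=_parse_float(columns["cadd"].iloc[i]) if columns["cadd"] is not None else None,
                gene=(str(columns["gene"].iloc[i]).strip() or None) if columns["gene"] is not None else None,
            )
            if rec.beta is None or rec.se is None:
                raise ValueError(f"{rsid}: missing beta or se")
            rec.validate()
        except (ValueError, TypeError) as exc:
            diagnostics.append(RowDiagnostic(row=i, rsid=rsid or None, message=str(exc)))
            continue
        drift = rec.pvalue_drift_decades()
        if drift is not None and drift > _P_CONSISTENCY_DECADES:
            diagnostics.append(RowDiagnostic(
                row=i, rsid=rsid,
                message=f"p-value {rec.pvalue:.3g} inconsistent with |beta/se| "
                        f"(drift {drift:.2f} decades)",
                severity="warning",
            ))
        records.append(rec)
    return records, diagnostics


def write_summary_table(
    records: Iterable[SummaryRecord],
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    sep: str = "\t",
) -> None:
    """Write records as a delimited text table (inverse of the reader)."""
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    rows = []
    for rec in records:
        rows.append({
            dialect["rsid"]: rec.rsid,
            dialect["chrom"]: rec.chrom,
            dialect["pos"]: rec.pos,
            dialect["effect_allele"]: rec.effect_allele,
            dialect["other_allele"]: rec.other_allele,
            dialect["eaf"]: rec.eaf,
            dialect["beta"]: rec.beta,
            dialect["se"]: rec.se,
            dialect["pvalue"]: rec.pvalue,
            dialect["n"]: rec.n,
            dialect["cadd"]: rec.cadd,
            dialect["gene"]: rec.gene,
        })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def filter_by_n(records: Sequence[SummaryRecord], n_min: int) -> list[SummaryRecord]:
    """Keep records whose sample size is at least ``n_min``.

    Records with missing ``n`` are dropped (they cannot demonstrate the
    required sample size).  Order is preserved.
    """
    if n_min < 0:
        raise ValueError("n_min must be >= 0")
    if n_min == 0:
        return list(records)  # missing n acceptable at threshold 0
    kept = [r for r in records if r.n is not None and r.n >= n_min]
    n_missing = sum(1 for r in records if r.n is None)
    if n_missing:
        warnings.warn(f"filter_by_n dropped {n_missing} record(s) with missing n", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# LD matrices
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """Symmetric SNP x SNP squared-correlation (r^2) lookup."""

    rsids: list[str]
    r2: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ValueError(f"r2 matrix shape {self.r2.shape} does not match {n} rsids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValueError("r2 diagonal must be exactly 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1.0 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def r2_between(self, a: str, b: str, *, missing: str = "error") -> float:
        """r^2 between two SNPs.

        ``missing="zero"`` treats SNPs absent from the matrix as
        uncorrelated (r^2 = 0), mirroring reference-panel sparsity;
        ``missing="error"`` raises :class:`LDLookupError`.
        """
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            if missing == "zero":
                return 0.0
            absent = a if ia is None else b
            raise LDLookupError(f"SNP {absent} absent from LD matrix")
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LDMatrix":
        return cls(list(rsids), np.eye(len(rsids)))

    @classmethod
    def from_blocks(
        cls, rsids: Sequence[str], block_sizes: Sequence[int], within_r2: float | Sequence[float]
    ) -> "LDMatrix":
        """Block-diagonal r^2 with constant within-block correlation."""
        n = len(rsids)
        if sum(block_sizes) != n:
            raise ValueError("block sizes must sum to the number of rsids")
        if np.isscalar(within_r2):
            within = [float(within_r2)] * len(block_sizes)
        else:
            within = [float(v) for v in within_r2]
        mat = np.eye(n)
        start = 0
        for size, r2 in zip(block_sizes, within):
            sl = slice(start, start + size)
            block = np.full((size, size), r2)
            np.fill_diagonal(block, 1.0)
            mat[sl, sl] = block
            start += size
        return cls(list(rsids), mat)


def read_ld_matrix(path, *, sep: str = "\t") -> LDMatrix:
    """Read a square delimited r^2 matrix with rsid header row and column."""
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ConfigError("LD matrix row and column rsids differ")
    return LDMatrix([str(r) for r in frame.index], frame.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path, *, sep: str = "\t") -> None:
    pd.DataFrame(ld.r2, index=ld.rsids, columns=ld.rsids).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Packaged instrument-table fixture
# ---------------------------------------------------------------------------

@dataclass
class Table1:
    """The printed cortisol instrument table as structured data.

    ``records`` holds the 17 unique variants; ``groups`` maps each
    instrument set (``IV_A``, ``IV_B``, ``IV_replacement``,
    ``IV_high_CADD``) to its member rsids in printed order (a variant
    may belong to more than one set).  ``printed`` retains every printed
    column, including the published F statistics, panel minor-allele
    frequencies, and the r^2 of replacements/high-CADD analogues with
    their IV_A partner.
    """

    records: list[SummaryRecord]
    groups: dict[str, list[str]]
    printed: pd.DataFrame

    def group(self, name: str) -> list[SummaryRecord]:
        wanted = self.groups[name]
        by_rsid = {r.rsid: r for r in self.records}
        return [by_rsid[rsid] for rsid in wanted]

    def record(self, rsid: str) -> SummaryRecord:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        raise KeyError(rsid)


def table1_fixture() -> Table1:
    """The packaged table of exposure instruments for morning plasma cortisol."""
    with resources.files("mrshape.data").joinpath("table1.tsv").open("rb") as handle:
        printed = pd.read_csv(handle, sep="\t")
    records: list[SummaryRecord] = []
    groups: dict[str, list[str]] = {}
    for _, row in printed.iterrows():
        rec = SummaryRecord(
            rsid=row["rsid"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            beta=float(row["beta"]),
            se=float(row["se"]),
            eaf=float(row["eaf"]),
            pvalue=float(row["pvalue"]),
            cadd=float(row["cadd"]),
            gene=row["gene"],
        )
        rec.validate()
        records.append(rec)
        for group in str(row["groups"]).split(";"):
            groups.setdefault(group, []).append(rec.rsid)
    return Table1(records=records, groups=groups, printed=printed)
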