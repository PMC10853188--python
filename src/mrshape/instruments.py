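"""Instrument selection: two-step LD clumping, locus merging and strength.

Lead-SNP selection follows the two-step clumping algorithm used by
FUMA-style pipelines:

1. *Independent significant SNPs*: scan variants below the lead p-value
   threshold in order of increasing p and keep each one that is in weak
   LD (``r^2 < r2_indep``) with every SNP kept so far.
2. *Lead SNPs*: apply the same greedy rule to the independent
   significant SNPs at the stricter threshold ``r2_lead``.

Each lead carries a *block* of candidate SNPs: variants nominally
associated with the exposure (``p < p_candidate``) and in LD
(``r^2 >= r2_indep``) with any independent significant SNP clumped to
that lead.  Blocks supply proxies and high-CADD analogues.  Lead SNPs
whose block boundaries lie closer than a gap (default 250 kb) are
merged into a single genetic locus.

Instrument strength is summarised by the approximation
``F = (beta/se)^2``; values above 10 are conventionally considered
acceptable.

Ties in the greedy scans (equal p) are broken by genomic position then
rsid, so the selection is deterministic and invariant to input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .exceptions import DomainError, LDLookupError
from .summary_io import LDMatrix, SummaryRecord

__all__ = [
    "ClumpConfig",
    "Instrument",
    "IV_A_PRESET",
    "IV_B_PRESET",
    "independent_significant",
    "lead_snps",
    "merge_loci",
    "high_cadd_analogue",
    "f_statistic",
    "is_weak_instrument",
    "WEAK_INSTRUMENT_F",
    "CADD_PATHOGENIC_CUTOFF",
]

#: Conventional threshold below which an instrument is considered weak.
WEAK_INSTRUMENT_F = 10.0

#: Conventional CADD deleteriousness cut-off.
CADD_PATHOGENIC_CUTOFF = 12.37


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds of the two-step clumping procedure."""

    p_lead: float = 5e-6
    r2_indep: float = 0.6
    r2_lead: float = 0.05
    p_candidate: float = 0.05
    locus_gap_bp: int = 250_000

    def __post_init__(self) -> None:
        if not (0.0 < self.p_lead <= self.p_candidate <= 1.0):
            raise ValueError("require 0 < p_lead <= p_candidate <= 1")
        if not (0.0 <= self.r2_lead <= self.r2_indep <= 1.0):
            raise ValueError("require 0 <= r2_lead <= r2_indep <= 1")
        if self.locus_gap_bp < 0:
            raise ValueError("locus_gap_bp must be >= 0")


#: Main instrument preset: genome-wide lenient significance, strict independence.
IV_A_PRESET = ClumpConfig(p_lead=5e-6, r2_indep=0.6, r2_lead=0.05)

#: Secondary preset: conservative significance, lenient independence
#: (recovers partially correlated SNPs within a single locus).
IV_B_PRESET = ClumpConfig(p_lead=5e-8, r2_indep=0.6, r2_lead=0.3)


@dataclass
class Instrument:
    """A lead SNP together with its LD block and strength statistics."""

    lead: SummaryRecord
    block: list[SummaryRecord] = field(default_factory=list)
    locus_id: int | None = None
    f_stat: float = 0.0
    high_cadd: SummaryRecord | None = None

    @property
    def block_range(self) -> tuple[str, int, int]:
        """(chromosome, min, max) position over the lead and its block."""
        positions = [self.lead.pos] + [rec.pos for rec in self.block]
        return self.lead.chrom, min(positions), max(positions)


def _sort_key(record: SummaryRecord):
    # p-value ascending; ties by chromosome, position, then rsid so the
    # greedy scan is order-independent.
    p = record.pvalue if record.pvalue is not None else 1.0
    return (p, _chrom_key(record.chrom), record.pos, record.rsid)


def _chrom_key(chrom: str):
    label = str(chrom).removeprefix("chr")
    return (0, int(label)) if label.isdigit() else (1, label)


def independent_significant(
    records: Sequence[SummaryRecord],
    ld: LDMatrix,
    cfg: ClumpConfig,
) -> list[SummaryRecord]:
    """First clumping step: greedy selection of weakly correlated significant SNPs."""
    for rec in records:
        if rec.rsid not in ld:
            raise LDLookupError(f"SNP {rec.rsid} absent from LD matrix")
    significant = sorted(
        (r for r in records if r.pvalue is not None and r.pvalue < cfg.p_lead),
        key=_sort_key,
    )
    kept: list[SummaryRecord] = []
    for rec in significant:
        if all(ld.r2_between(rec.rsid, other.rsid) < cfg.r2_indep for other in kept):
            kept.append(rec)
    return kept


def lead_snps(
    indep: Sequence[SummaryRecord],
    ld: LDMatrix,
    cfg: ClumpConfig,
    candidates: Sequence[SummaryRecord] | None = None,
) -> list[Instrument]:
    """Second clumping step: select lead SNPs and assemble their blocks.

    ``indep`` must come from :func:`independent_significant` under the
    same configuration.  ``candidates`` is the wider pool from which
    block members (``p < p_candidate``, ``r^2 >= r2_indep`` with any of
    the lead's independent significant SNPs) are drawn; when omitted,
    blocks contain the clumped independent significant SNPs only.
    """
    for rec in indep:
        if rec.rsid not in ld:
            raise LDLookupError(f"SNP {rec.rsid} absent from LD matrix")
    ordered = sorted(indep, key=_sort_key)
    leads: list[SummaryRecord] = []
    members: dict[str, list[SummaryRecord]] = {}
    for rec in ordered:
        blocking = [l for l in leads if ld.r2_between(rec.rsid, l.rsid) >= cfg.r2_lead]
        if not blocking:
            leads.append(rec)
            members[rec.rsid] = [rec]
        else:
            # assign to the most correlated lead
            best = max(blocking, key=lambda l: ld.r2_between(rec.rsid, l.rsid))
            members[best.rsid].append(rec)

    instruments: list[Instrument] = []
    pool = [] if candidates is None else [
        c for c in candidates
        if c.pvalue is not None and c.pvalue < cfg.p_candidate
    ]
    warned_missing = False
    for lead in leads:
        block: dict[str, SummaryRecord] = {m.rsid: m for m in members[lead.rsid]}
        for cand in pool:
            if cand.rsid in block:
                continue
            for member in members[lead.rsid]:
                if cand.rsid not in ld and not warned_missing:
                    warnings.warn(
                        "candidate SNP(s) absent from the LD matrix treated as r^2 = 0",
                        stacklevel=2,
                    )
                    warned_missing = True
                if ld.r2_between(cand.rsid, member.rsid, missing="zero") >= cfg.r2_indep:
                    block[cand.rsid] = cand
                    break
        instruments.append(
            Instrument(
                lead=lead,
                block=sorted(block.values(), key=lambda r: (_chrom_key(r.chrom), r.pos, r.rsid)),
                f_stat=f_statistic(lead.beta, lead.se),
            )
        )
    instruments.sort(key=lambda inst: (_chrom_key(inst.lead.chrom), inst.lead.pos, inst.lead.rsid))
    return instruments


def merge_loci(
    instruments: Sequence[Instrument],
    block_ranges: Sequence[tuple[str, int, int]] | None = None,
    gap_bp: int = 250_000,
) -> list[int]:
    """Assign locus ids, joining instruments whose block ranges are close.

    Two instruments on the same chromosome share a locus when their
    block intervals are separated by less than ``gap_bp`` (overlap
    counts as distance zero); the merge is transitive.  Ids are assigned
    in order of chromosome then leftmost block position and written back
    onto each instrument's ``locus_id``.
    """
    ranges = list(block_ranges) if block_ranges is not None else [
        inst.block_range for inst in instruments
    ]
    if len(ranges) != len(instruments):
        raise ValueError("one block range per instrument required")
    for chrom, start, end in ranges:
        if start > end:
            raise ValueError(f"malformed interval on chromosome {chrom}: {start} > {end}")

    parent = list(range(len(instruments)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(ranges)):
        for j in range(i + 1, len(ranges)):
            ci, si, ei = ranges[i]
            cj, sj, ej = ranges[j]
            if ci != cj:
                continue
            separation = max(0, max(si, sj) - min(ei, ej))
            if separation < gap_bp:
                union(i, j)

    # order roots by (chromosome, leftmost start) for stable ids
    root_extent: dict[int, tuple] = {}
    for i, (chrom, start, _end) in enumerate(ranges):
        root = find(i)
        key = (_chrom_key(chrom), start)
        if root not in root_extent or key < root_extent[root]:
            root_extent[root] = key
    ordered_roots = sorted(root_extent, key=root_extent.get)
    root_id = {root: k for k, root in enumerate(ordered_roots)}
    assignment = [root_id[find(i)] for i in range(len(instruments))]
    for inst, locus in zip(instruments, assignment):
        inst.locus_id = locus
    return assignment


def high_cadd_analogue(
    inst: Instrument,
    ld: LDMatrix,
    *,
    p_threshold: float = 5e-5,
    cadd_min: float = CADD_PATHOGENIC_CUTOFF,
    r2_min: float = 0.6,
) -> SummaryRecord | None:
    """The block member with the highest CADD above the pathogenicity cut-off.

    Qualifying members need exposure ``p < p_threshold``, ``r^2 >= r2_min``
    with the lead and ``CADD > cadd_min``.  Ties on CADD are broken by
    smaller p then position.  Returns ``None`` (and stores it) when the
    block holds no such variant.
    """
    best: SummaryRecord | None = None
    best_key: tuple | None = None
    for rec in inst.block:
        if rec.cadd is None or not (rec.cadd > cadd_min):
            continue
        if rec.pvalue is None or not (rec.pvalue < p_threshold):
            continue
        if ld.r2_between(inst.lead.rsid, rec.rsid, missing="zero") < r2_min:
            continue
        key = (-rec.cadd, rec.pvalue if rec.pvalue is not None else 1.0, rec.pos)
        if best_key is None or key < best_key:
            best, best_key = rec, key
    inst.high_cadd = best
    return best


def f_statistic(beta: float, se: float) -> float:
    """Instrument strength approximated as the squared z-score (beta/se)^2."""
    if not se > 0:
        raise DomainError(f"standard error must be > 0, got {se}")
    return (beta / se) ** 2


def is_weak_instrument(f: float, threshold: float = WEAK_INSTRUMENT_F) -> bool:
    """True when the F statistic fails the acceptable-strength criterion (F > threshold)."""
    return not (f > threshold)
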