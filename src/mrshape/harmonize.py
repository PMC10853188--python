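"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR combines per-SNP estimates from two independent GWAS, which
may report effects on different alleles and even on different strands.
The convention implemented here orients every outcome record to its
*minor* allele (effect-allele frequency <= 0.5) and then aligns the
exposure estimate to that same allele, irrespective of the exposure's
own allele frequency.  After harmonization the signs of ``beta_x`` and
``beta_y`` both refer to the outcome's minor allele, so their ratio is
a well-defined causal estimate.

Palindromic variants (A/T or C/G) are strand-ambiguous: allele labels
cannot distinguish the two strands, so they are resolved by allele
frequency alone (and rejected when either frequency is too close to
0.5 to be informative).  Such pairs are always flagged so the risk is
visible downstream.

The module also substitutes LD proxies for instruments missing from an
outcome panel: the proxy must itself be strongly associated with the
exposure (p below the instrument threshold) and in high LD with the
lead SNP (r^2 >= 0.6), and the best-correlated qualifying candidate is
chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .exceptions import (
    AlignmentError,
    LDLookupError,
    OrientationError,
    PalindromeAmbiguityError,
)
from .summary_io import LDMatrix, SummaryRecord

__all__ = [
    "HarmonizedPair",
    "ProxyChoice",
    "complement",
    "is_palindromic",
    "orient_to_minor_allele",
    "align_pair",
    "substitute_proxy",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default half-width of the EAF band around 0.5 inside which palindromic
#: pairs are considered unresolvable.
DEFAULT_PALINDROME_BAND = 0.08


def complement(allele: str) -> str:
    """Reverse-strand representation of an allele string."""
    try:
        return "".join(_COMPLEMENT[base] for base in allele.upper())
    except KeyError as exc:
        raise AlignmentError(f"cannot complement allele {allele!r}") from exc


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, which look identical on both strands."""
    try:
        return complement(effect_allele) == other_allele.upper()
    except AlignmentError:
        return False


@dataclass
class HarmonizedPair:
    """One SNP's exposure and outcome estimates on a shared effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    flags: frozenset[str] = frozenset()
    proxy_rsid: str | None = None
    proxy_r2: float | None = None

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(f"{self.rsid}: standard errors must be > 0")
        self.flags = frozenset(self.flags)

    def flipped(self) -> "HarmonizedPair":
        """The same pair expressed on the opposite allele (both betas negated)."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta_x=-self.beta_x,
            beta_y=-self.beta_y,
        )


def orient_to_minor_allele(record: SummaryRecord) -> tuple[SummaryRecord, bool]:
    """Express a record on its minor allele (EAF <= 0.5).

    Returns ``(record, flipped)``.  When the stored effect allele is the
    major allele the alleles are swapped, ``eaf`` becomes ``1 - eaf``
    and ``beta`` changes sign.  Orientation is idempotent.
    """
    if record.eaf is None:
        raise OrientationError(f"{record.rsid}: cannot orient without an allele frequency")
    if record.eaf <= 0.5:
        return record, False
    return (
        replace(
            record,
            effect_allele=record.other_allele,
            other_allele=record.effect_allele,
            eaf=1.0 - record.eaf,
            beta=-record.beta,
        ),
        True,
    )


def align_pair(
    exposure: SummaryRecord,
    outcome: SummaryRecord,
    *,
    palindromic_band: float = DEFAULT_PALINDROME_BAND,
) -> HarmonizedPair:
    """Harmonize one exposure/outcome record pair onto the outcome's minor allele.

    The outcome is first oriented to its minor allele (skipped, without a
    flag, when its EAF is unavailable).  The exposure is then matched by
    allele labels, complementing for strand mismatches; its beta changes
    sign iff its effect allele corresponds to the outcome's other allele.
    Palindromic pairs are resolved by allele frequency and flagged.

    Raises
    ------
    AlignmentError
        When the two allele sets cannot be reconciled.
    PalindromeAmbiguityError
        For palindromic pairs whose exposure or outcome EAF lies within
        ``palindromic_band`` of 0.5 (or is missing).
    """
    if exposure.rsid != outcome.rsid:
        raise AlignmentError(f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}")
    flags: set[str] = set()

    if outcome.eaf is not None:
        outcome, out_flipped = orient_to_minor_allele(outcome)
        if out_flipped:
            flags.add("outcome_flipped")

    out_ea = outcome.effect_allele.upper()
    out_oa = outcome.other_allele.upper()
    exp_ea = exposure.effect_allele.upper()
    exp_oa = exposure.other_allele.upper()
    palindromic = is_palindromic(out_ea, out_oa)

    if palindromic:
        if {exp_ea, exp_oa} != {out_ea, out_oa}:
            raise AlignmentError(
                f"{exposure.rsid}: palindromic outcome alleles {out_ea}/{out_oa} vs "
                f"exposure {exp_ea}/{exp_oa}"
            )
        flags.add("palindromic")
        # Strand is unidentifiable from labels; rescue by frequency
        # concordance.  The exposure allele matching the outcome's minor
        # allele is taken to be the exposure's own minor allele.
        if exposure.eaf is None or outcome.eaf is None:
            raise PalindromeAmbiguityError(
                f"{exposure.rsid}: palindromic pair without both allele frequencies"
            )
        if (
            abs(exposure.eaf - 0.5) <= palindromic_band
            or abs(outcome.eaf - 0.5) <= palindromic_band
        ):
            raise PalindromeAmbiguityError(
                f"{exposure.rsid}: palindromic pair with EAF too close to 0.5 "
                f"(exposure {exposure.eaf:.3f}, outcome {outcome.eaf:.3f})"
            )
        flip_exposure = exposure.eaf > 0.5
    else:
        if {exp_ea, exp_oa} == {out_ea, out_oa}:
            pass
        elif {complement(exp_ea), complement(exp_oa)} == {out_ea, out_oa}:
            exp_ea, exp_oa = complement(exp_ea), complement(exp_oa)
            flags.add("strand_complemented")
        else:
            raise AlignmentError(
                f"{exposure.rsid}: irreconcilable alleles exposure {exp_ea}/{exp_oa} "
                f"vs outcome {out_ea}/{out_oa}"
            )
        flip_exposure = exp_ea == out_oa

    beta_x = -exposure.beta if flip_exposure else exposure.beta
    if flip_exposure:
        flags.add("exposure_flipped")

    return HarmonizedPair(
        rsid=outcome.rsid,
        effect_allele=out_ea,
        other_allele=out_oa,
        beta_x=beta_x,
        se_x=exposure.se,
        beta_y=outcome.beta,
        se_y=outcome.se,
        flags=frozenset(flags),
    )


@dataclass
class ProxyChoice:
    """A proxy SNP substituted for a lead instrument, with provenance."""

    record: SummaryRecord
    lead_rsid: str
    r2: float


def substitute_proxy(
    lead: SummaryRecord,
    candidates: Sequence[SummaryRecord],
    ld: LDMatrix,
    *,
    p_threshold: float = 5e-6,
    r2_threshold: float = 0.6,
) -> ProxyChoice | None:
    """Pick a replacement for a lead SNP missing from an outcome panel.

    Among ``candidates`` (the lead's LD-block members available in the
    outcome panel) the proxy must have exposure ``p < p_threshold`` and
    ``r^2 >= r2_threshold`` with the lead; the candidate maximising r^2
    wins, with ties broken by smaller p then lower position.  Returns
    ``None`` when no candidate qualifies.
    """
    if lead.rsid not in ld:
        raise LDLookupError(f"lead SNP {lead.rsid} absent from LD matrix")
    best: tuple[float, float, int] | None = None
    chosen: SummaryRecord | None = None
    chosen_r2 = 0.0
    for cand in candidates:
        if cand.pvalue is None or not (cand.pvalue < p_threshold):
            continue
        r2 = ld.r2_between(lead.rsid, cand.rsid, missing="zero")
        if r2 < r2_threshold:
            continue
        key = (-r2, cand.pvalue, cand.pos)
        if best is None or key < best:
            best = key
            chosen = cand
            chosen_r2 = r2
    if chosen is None:
        return None
    return ProxyChoice(record=chosen, lead_rsid=lead.rsid, r2=chosen_r2)
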