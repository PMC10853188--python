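"""End-to-end orchestration: selection -> harmonization -> estimation.

One :func:`run_analysis` call reproduces the full analysis for a set of
outcome panels against one exposure panel: two-step clumping of the
exposure (IV_A- or IV_B-style preset), minor-allele harmonization with
LD-proxy substitution for instruments missing from an outcome panel,
the complete estimator battery per outcome x sex (per-SNP Wald ratios,
fixed- and random-effects IVW, weighted median, MR-Egger with the
NOME diagnostic, MR-PRESSO), and delimited-text outputs plus a run log
recording every harmonization and omission decision.

Everything is seeded from a single integer, and a run is deterministic
given its configuration: each number in the forest table can be
recomputed by calling the module operations directly with the logged
inputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mr_core, mr_presso
from .exceptions import AlignmentError, ConfigError, MRShapeError
from .harmonize import HarmonizedPair, align_pair, substitute_proxy
from .instruments import (
    IV_A_PRESET,
    IV_B_PRESET,
    ClumpConfig,
    Instrument,
    high_cadd_analogue,
    independent_significant,
    is_weak_instrument,
    lead_snps,
    merge_loci,
)
from .summary_io import (
    LDMatrix,
    SummaryRecord,
    filter_by_n,
    read_ld_matrix,
    read_summary_table,
)

__all__ = ["OutcomeSpec", "AnalysisConfig", "AnalysisResult", "run_analysis"]

_PRESETS = {"IV_A": IV_A_PRESET, "IV_B": IV_B_PRESET}

FOREST_COLUMNS = [
    "outcome", "sex", "method", "rsid", "n_snps", "theta", "se",
    "ci_low", "ci_high", "pvalue", "Q", "p_het", "i2", "primary",
]


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    sex: str
    path: str


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    exposure_path: str
    ld_path: str
    outcomes: list[OutcomeSpec]
    preset: str = "IV_A"
    n_min: int = 20_000
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    alpha: float = 0.05
    palindromic_band: float = 0.08
    output_dir: str = "results"
    dialect: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.exposure_path or not self.ld_path:
            raise ConfigError("exposure_path and ld_path must be nonempty")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if isinstance(self.preset, str) and self.preset not in _PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; use one of {sorted(_PRESETS)}")

    @property
    def clump_config(self) -> ClumpConfig:
        return _PRESETS[self.preset] if isinstance(self.preset, str) else self.preset

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        outcomes = [OutcomeSpec(**spec) for spec in raw.pop("outcomes", [])]
        clump = raw.pop("clump", None)
        cfg = cls(outcomes=outcomes, **raw)
        if clump is not None:
            cfg.preset = ClumpConfig(**clump)
        return cfg


@dataclass
class AnalysisResult:
    status: str
    instrument_table: pd.DataFrame
    forest_table: pd.DataFrame
    presso: dict[tuple[str, str], mr_presso.PressoResult]
    log: list[str] = field(default_factory=list)


def _child_seed(base: int, *stream: int) -> int:
    """Deterministic per-purpose seed below 2^31."""
    seq = np.random.SeedSequence([int(base), *map(int, stream)])
    return int(seq.generate_state(1)[0] % 2**31)


def _estimate_row(outcome: str, sex: str, est: mr_core.MREstimate, *, rsid: str = "",
                  primary: bool = False) -> dict:
    d = est.diagnostics
    return {
        "outcome": outcome, "sex": sex, "method": est.method, "rsid": rsid,
        "n_snps": est.n_snps, "theta": est.theta, "se": est.se,
        "ci_low": est.ci_low, "ci_high": est.ci_high, "pvalue": est.pvalue,
        "Q": d.get("Q", np.nan), "p_het": d.get("p_heterogeneity", np.nan),
        "i2": d.get("i2", np.nan), "primary": primary,
    }


def _instrument_rows(instruments: list[Instrument]) -> pd.DataFrame:
    rows = []
    for inst in instruments:
        lead = inst.lead
        rows.append({
            "rsid": lead.rsid, "chrom": lead.chrom, "pos": lead.pos,
            "gene": lead.gene, "EA": lead.effect_allele, "NEA": lead.other_allele,
            "EAF": lead.eaf, "beta": lead.beta, "se": lead.se, "pvalue": lead.pvalue,
            "F": inst.f_stat, "weak": is_weak_instrument(inst.f_stat),
            "CADD": lead.cadd, "locus": inst.locus_id,
            "block_size": len(inst.block),
            "high_cadd_rsid": inst.high_cadd.rsid if inst.high_cadd else None,
            "high_cadd_score": inst.high_cadd.cadd if inst.high_cadd else None,
        })
    return pd.DataFrame(rows)


def _harmonize_outcome(
    instruments: list[Instrument],
    outcome_by_rsid: dict[str, SummaryRecord],
    ld: LDMatrix,
    cfg: AnalysisConfig,
    log: list[str],
    label: str,
) -> list[HarmonizedPair]:
    pairs: list[HarmonizedPair] = []
    p_lead = cfg.clump_config.p_lead
    for inst in instruments:
        lead = inst.lead
        exposure_rec, outcome_rec = lead, outcome_by_rsid.get(lead.rsid)
        proxy = None
        if outcome_rec is None:
            candidates = [rec for rec in inst.block
                          if rec.rsid != lead.rsid and rec.rsid in outcome_by_rsid]
            proxy = substitute_proxy(lead, candidates, ld, p_threshold=p_lead)
            if proxy is None:
                log.append(
                    f"{label}: {lead.rsid} absent from outcome panel and no "
                    f"suitable replacement; instrument omitted"
                )
                continue
            exposure_rec = proxy.record
            outcome_rec = outcome_by_rsid[proxy.record.rsid]
            log.append(
                f"{label}: replaced {lead.rsid} with {proxy.record.rsid} "
                f"(r^2 = {proxy.r2:.3f})"
            )
        try:
            pair = align_pair(exposure_rec, outcome_rec,
                              palindromic_band=cfg.palindromic_band)
        except AlignmentError as exc:
            log.append(f"{label}: {lead.rsid} dropped at harmonization: {exc}")
            continue
        if proxy is not None:
            pair = dataclasses.replace(
                pair,
                flags=pair.flags | {"proxy_used"},
                proxy_rsid=proxy.record.rsid,
                proxy_r2=proxy.r2,
            )
        if pair.flags:
            log.append(f"{label}: {pair.rsid} flags: {sorted(pair.flags)}")
        pairs.append(pair)
    return pairs


def run_analysis(cfg: AnalysisConfig, *, write: bool = True) -> AnalysisResult:
    """Run the full analysis described by ``cfg``.

    Returns the result bundle and, unless ``write=False``, writes
    ``instruments.tsv``, ``forest.tsv``, ``presso.tsv``,
    ``presso_snps.tsv`` and ``run_log.txt`` into ``cfg.output_dir``.
    """
    log: list[str] = [f"seed = {cfg.seed}; preset = {cfg.preset}"]
    exposure, diags = read_summary_table(cfg.exposure_path, cfg.dialect)
    for d in diags:
        log.append(f"exposure read [{d.severity}] row {d.row} ({d.rsid}): {d.message}")
    n_before = len(exposure)
    have_n = any(rec.n is not None for rec in exposure)
    if cfg.n_min > 0 and have_n:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exposure = filter_by_n(exposure, cfg.n_min)
        log.append(f"sample-size filter n >= {cfg.n_min}: kept {len(exposure)}/{n_before}")
    elif cfg.n_min > 0:
        log.append("sample-size filter skipped: exposure table carries no n column")

    ld = read_ld_matrix(cfg.ld_path)
    clump = cfg.clump_config
    indep = independent_significant(exposure, ld, clump)
    instruments = lead_snps(indep, ld, clump, candidates=exposure)
    merge_loci(instruments, gap_bp=clump.locus_gap_bp)
    for inst in instruments:
        high_cadd_analogue(inst, ld)
    log.append(
        f"selected {len(instruments)} lead SNP(s) from {len(indep)} independent "
        f"significant SNP(s): {[i.lead.rsid for i in instruments]}"
    )
    if not instruments:
        log.append("no instruments survive selection; analysis not run")
        result = AnalysisResult(
            status="no_instruments",
            instrument_table=pd.DataFrame(),
            forest_table=pd.DataFrame(columns=FOREST_COLUMNS),
            presso={},
            log=log,
        )
        if write:
            _write_outputs(cfg, result)
        return result

    lead_rsids = [inst.lead.rsid for inst in instruments]
    if len(lead_rsids) > 1:
        off_diag = [
            ld.r2_between(a, b, missing="zero")
            for i, a in enumerate(lead_rsids) for b in lead_rsids[i + 1:]
        ]
        max_r2 = max(off_diag)
        if max_r2 > 0.05:
            log.append(
                f"warning: instruments are correlated (max pairwise r^2 = {max_r2:.3f}); "
                "IVW treats them as independent"
            )

    primary_mode = "random" if clump.r2_lead <= 0.05 else "fixed"
    forest_rows: list[dict] = []
    presso_results: dict[tuple[str, str], mr_presso.PressoResult] = {}

    for k, spec in enumerate(cfg.outcomes):
        label = f"{spec.name}/{spec.sex}"
        outcome_records, odiags = read_summary_table(spec.path, cfg.dialect)
        for d in odiags:
            log.append(f"{label} read [{d.severity}] row {d.row} ({d.rsid}): {d.message}")
        outcome_by_rsid = {rec.rsid: rec for rec in outcome_records}
        pairs = _harmonize_outcome(instruments, outcome_by_rsid, ld, cfg, log, label)
        if not pairs:
            log.append(f"{label}: no harmonized pairs; outcome skipped")
            continue
        log.append(f"{label}: {len(pairs)} harmonized instrument(s)")

        for pair in pairs:
            forest_rows.append(
                _estimate_row(spec.name, spec.sex, mr_core.wald_ratio(pair), rsid=pair.rsid)
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for mode in ("random", "fixed"):
                est = mr_core.ivw(pairs, mode=mode)
                forest_rows.append(
                    _estimate_row(spec.name, spec.sex, est, primary=(mode == primary_mode))
                )
        if len(pairs) >= 3:
            wm = mr_core.weighted_median(
                pairs, n_boot=cfg.n_boot, seed=_child_seed(cfg.seed, k, 1)
            )
            forest_rows.append(_estimate_row(spec.name, spec.sex, wm))
            slope, intercept = mr_core.egger(pairs)
            gx = mr_core.i2_gx(pairs)
            for est in (slope, intercept):
                row = _estimate_row(spec.name, spec.sex, est)
                row["i2"] = gx if est.method == "egger_slope" else np.nan
                forest_rows.append(row)
            if mr_core.violates_nome(gx):
                log.append(
                    f"{label}: I^2_GX = {gx:.3f} < {mr_core.NOME_I2_GX_THRESHOLD}: "
                    "NOME violated; MR-Egger unreliable"
                )
        else:
            log.append(f"{label}: fewer than 3 instruments; weighted median and MR-Egger skipped")
        if len(pairs) >= 4:
            presso_results[(spec.name, spec.sex)] = mr_presso.run_presso(
                pairs, n_sim=cfg.n_sim, seed=_child_seed(cfg.seed, k, 2),
                outlier_alpha=cfg.alpha,
            )
        else:
            log.append(f"{label}: fewer than 4 instruments; MR-PRESSO skipped")

    result = AnalysisResult(
        status="ok",
        instrument_table=_instrument_rows(instruments),
        forest_table=pd.DataFrame(forest_rows, columns=FOREST_COLUMNS),
        presso=presso_results,
        log=log,
    )
    if write:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: AnalysisConfig, result: AnalysisResult) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.instrument_table.to_csv(out / "instruments.tsv", sep="\t", index=False)
    result.forest_table.to_csv(out / "forest.tsv", sep="\t", index=False)
    presso_rows, snp_rows = [], []
    for (name, sex), pres in result.presso.items():
        presso_rows.append({
            "outcome": name, "sex": sex, "rss_observed": pres.rss_observed,
            "global_p": pres.global_p,
            "outliers": ";".join(sorted(pres.outliers)) or None,
            "theta_raw": pres.theta_raw.theta,
            "theta_corrected": pres.theta_corrected.theta if pres.theta_corrected else None,
            "distortion_p": pres.distortion_p, "n_sim": pres.n_sim, "seed": pres.seed,
        })
        for rsid, p in pres.outlier_pvalues.items():
            snp_rows.append({
                "outcome": name, "sex": sex, "rsid": rsid, "p": p,
                "p_bonferroni": pres.outlier_pvalues_adjusted[rsid],
                "outlier": rsid in pres.outliers,
            })
    pd.DataFrame(presso_rows).to_csv(out / "presso.tsv", sep="\t", index=False)
    pd.DataFrame(snp_rows).to_csv(out / "presso_snps.tsv", sep="\t", index=False)
    (out / "run_log.txt").write_text("\n".join(result.log) + "\n")
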