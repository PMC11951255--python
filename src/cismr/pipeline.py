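"""Config-driven orchestration: exposure panels, mediation panels, reports.

A YAML analysis config names the exposure / mediator / outcome summary-stat
files, the gene regions and selection thresholds, the estimators to run, and
bootstrap settings.  The panel runners reproduce the skeleton of a drug-target
mediation study: per-exposure instrument selection, harmonization against each
trait, univariable (and optional robust) MR, the with/without-mediator
adjustment contrast, and the bootstrap mediation decomposition.  All estimates
can be reported per 1 SD *lower* exposure (mimicking pharmacological
inhibition of the target) via a final sign flip.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (MREstimate, conmix, egger, ivw, ivw_ld, mvmr_ivw,
                         presso, weighted_median)
from .instruments import (ConsequenceTable, GeneRegion, clump, exclude_coding,
                          select_cis)
from .mediation import (MediationInputs, MediationResult, adjusted_outcome_mr,
                        bootstrap_mediation)
from .summary_stats import (LOG_ODDS, HarmonizedSet, LDMatrix, SummaryStatSet,
                            harmonize, harmonize_multi, read_ld_matrix,
                            read_sumstats)

logger = logging.getLogger("cismr")

REPORT_COLUMNS = ["exposure", "outcome_or_mediator", "adjustment", "method",
                  "n_snps", "estimate", "se", "ci_low", "ci_high", "pval",
                  "odds_ratio", "or_ci_low", "or_ci_high"]

KNOWN_METHODS = ("ivw", "ivw_ld", "egger", "weighted_median", "conmix",
                 "presso")


class ConfigError(ValueError):
    """Invalid analysis configuration."""


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "ld_matrix", "consequences", "methods",
         "report_per_sd_lower", "exposures", "traits", "mediators", "outcome",
         "bootstrap"},
    "exposures": {"name", "sumstats", "region", "maf_min", "p_max",
                  "clump_r2", "clump_window"},
    "region": {"gene_name", "chrom", "start", "end", "flank"},
    "traits": {"name", "sumstats", "trait_scale"},
    "mediators": {"name", "sumstats", "gw_p_max", "gw_clump_r2",
                  "gw_clump_window", "maf_min"},
    "outcome": {"name", "sumstats", "trait_scale"},
    "bootstrap": {"n_boot", "guard", "theta_my_override"},
}


def _check_keys(section: str, mapping: Mapping[str, Any]) -> None:
    unknown = set(mapping) - _SCHEMA[section]
    if unknown:
        raise ConfigError(f"unknown config keys in {section or 'top level'}: "
                          f"{sorted(unknown)}")


def validate_config(config: Mapping[str, Any],
                    base_dir: Path | None = None) -> dict[str, Any]:
    """Validate structure, required fields and path existence; unknown keys
    are errors (fail-fast).  Returns a normalized copy with resolved paths."""
    cfg = dict(config)
    _check_keys("", cfg)
    for required in ("exposures", "outcome", "methods"):
        if required not in cfg:
            raise ConfigError(f"missing required config field: {required!r}")
    if not cfg["methods"]:
        raise ConfigError("methods list is empty")
    bad = set(cfg["methods"]) - set(KNOWN_METHODS)
    if bad:
        raise ConfigError(f"unknown methods: {sorted(bad)}")
    base = Path(base_dir) if base_dir else Path(".")

    def resolve(p: str, what: str) -> str:
        path = Path(p)
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise ConfigError(f"{what}: file not found: {path}")
        return str(path)

    for exp in cfg["exposures"]:
        _check_keys("exposures", exp)
        for req in ("name", "sumstats", "region"):
            if req not in exp:
                raise ConfigError(f"exposure missing field {req!r}")
        _check_keys("region", exp["region"])
        exp["sumstats"] = resolve(exp["sumstats"], f"exposure {exp['name']}")
    for section in ("traits", "mediators"):
        for item in cfg.get(section, []):
            _check_keys(section, item)
            for req in ("name", "sumstats"):
                if req not in item:
                    raise ConfigError(f"{section} entry missing field {req!r}")
            item["sumstats"] = resolve(item["sumstats"],
                                       f"{section} {item['name']}")
    _check_keys("outcome", cfg["outcome"])
    if "sumstats" not in cfg["outcome"]:
        raise ConfigError("outcome missing field 'sumstats'")
    cfg["outcome"]["sumstats"] = resolve(cfg["outcome"]["sumstats"], "outcome")
    if "ld_matrix" in cfg:
        cfg["ld_matrix"] = resolve(cfg["ld_matrix"], "ld_matrix")
    if "consequences" in cfg:
        cfg["consequences"] = resolve(cfg["consequences"], "consequences")
    if "bootstrap" in cfg:
        _check_keys("bootstrap", cfg["bootstrap"])
    cfg.setdefault("seed", 0)
    cfg.setdefault("report_per_sd_lower", True)
    return cfg


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw, base_dir=Path(path).parent)


def config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def select_instruments(stats: SummaryStatSet, region: GeneRegion,
                       ld: LDMatrix, maf_min: float = 0.01,
                       p_max: float = 5e-8, clump_r2: float = 0.1,
                       clump_window: int = 10_000_000,
                       consequences: ConsequenceTable | None = None,
                       log: list | None = None) -> SummaryStatSet:
    """cis window -> coding exclusion -> LD clump, with a selection log."""
    log = [] if log is None else log
    out = select_cis(stats, region, maf_min=maf_min, p_max=p_max, log=log)
    if consequences is not None:
        out = exclude_coding(out, consequences, log=log)
    out = clump(out, ld, r2_max=clump_r2, window_bp=clump_window, log=log)
    logger.info("select_instruments(%s): %d instruments", region.gene_name,
                len(out))
    return out


def select_genome_wide(stats: SummaryStatSet, ld: LDMatrix,
                       maf_min: float = 0.01, p_max: float = 5e-8,
                       clump_r2: float = 0.01, clump_window: int = 1_000_000,
                       exclude_region: GeneRegion | None = None,
                       log: list | None = None) -> SummaryStatSet:
    """Genome-wide instrument selection for a mediator: MAF/p filters then
    stringent clumping, optionally excluding the drug-target cis region."""
    d = stats.df
    maf = np.minimum(d["eaf"], 1.0 - d["eaf"])
    keep = (maf > maf_min) & (d["pval"] < p_max)
    if exclude_region is not None:
        lo, hi = exclude_region.window
        in_region = (d["chrom"].astype(str) == exclude_region.chrom) \
            & (d["pos"] >= lo) & (d["pos"] <= hi)
        keep &= ~in_region
    filtered = SummaryStatSet(stats.trait_name, stats.trait_scale,
                              d[keep].reset_index(drop=True))
    if len(filtered) == 0:
        raise ConfigError(f"no genome-wide instruments for {stats.trait_name}")
    return clump(filtered, ld, r2_max=clump_r2, window_bp=clump_window, log=log)


def _run_methods(h: HarmonizedSet, methods: Sequence[str],
                 seed: int) -> list[MREstimate]:
    out: list[MREstimate] = []
    for m in methods:
        if m == "ivw":
            out.append(ivw(h))
        elif m == "ivw_ld":
            out.append(ivw_ld(h))
        elif m == "egger":
            out.extend(egger(h))
        elif m == "weighted_median":
            out.append(weighted_median(h, seed=seed))
        elif m == "conmix":
            out.append(conmix(h))
        elif m == "presso":
            _, _, corrected = presso(h, seed=seed)
            out.append(corrected)
        else:
            raise ConfigError(f"unknown method {m!r}")
    return out


def _report_row(exposure: str, target: str, adjustment: str,
                est: MREstimate, per_sd_lower: bool) -> dict[str, Any]:
    e = est.flipped() if per_sd_lower else est
    row = {
        "exposure": exposure, "outcome_or_mediator": target,
        "adjustment": adjustment, "method": e.method, "n_snps": e.n_snps,
        "estimate": e.theta, "se": e.se, "ci_low": e.ci_low,
        "ci_high": e.ci_high, "pval": e.pval,
        "odds_ratio": np.nan, "or_ci_low": np.nan, "or_ci_high": np.nan,
    }
    if est.outcome_scale == LOG_ODDS:
        row["odds_ratio"] = e.odds_ratio
        row["or_ci_low"], row["or_ci_high"] = e.or_ci
    return row


def _na_row(exposure: str, target: str, adjustment: str,
            message: str) -> dict[str, Any]:
    return {"exposure": exposure, "outcome_or_mediator": target,
            "adjustment": adjustment, "method": f"NA ({message})",
            "n_snps": 0, "estimate": np.nan, "se": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "pval": np.nan, "odds_ratio": np.nan,
            "or_ci_low": np.nan, "or_ci_high": np.nan}


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def _load_inputs(cfg: Mapping[str, Any]):
    ld = read_ld_matrix(cfg["ld_matrix"]) if "ld_matrix" in cfg else None
    consequences = None
    if "consequences" in cfg:
        table = pd.read_csv(cfg["consequences"], sep="\t")
        consequences = ConsequenceTable(
            dict(zip(table["variant_id"], table["consequence"])))
    return ld, consequences


def _exposure_instruments(exp: Mapping[str, Any], ld: LDMatrix,
                          consequences: ConsequenceTable | None,
                          log: list) -> SummaryStatSet:
    stats = read_sumstats(exp["sumstats"], trait_name=exp["name"])
    region = GeneRegion(**exp["region"])
    return select_instruments(
        stats, region, ld, maf_min=exp.get("maf_min", 0.01),
        p_max=exp.get("p_max", 5e-8), clump_r2=exp.get("clump_r2", 0.1),
        clump_window=exp.get("clump_window", 10_000_000),
        consequences=consequences, log=log)


def run_exposure_panel(cfg: Mapping[str, Any]) -> pd.DataFrame:
    """Exposure x trait MR panel (lipid associations per 1 SD lower exposure
    by default).  Per-cell failures are logged and reported as NA rows."""
    per_lower = cfg.get("report_per_sd_lower", True)
    ld, consequences = _load_inputs(cfg)
    seed = int(cfg.get("seed", 0))
    rows = []
    targets = list(cfg.get("traits", [])) + [dict(cfg["outcome"])]
    for exp in cfg["exposures"]:
        log: list = []
        try:
            instruments = _exposure_instruments(exp, ld, consequences, log)
        except Exception as exc:  # noqa: BLE001
            for t in targets:
                rows.append(_na_row(exp["name"], t["name"], "none", str(exc)))
            continue
        for t in targets:
            target_stats = read_sumstats(
                t["sumstats"], trait_name=t["name"],
                trait_scale=t.get("trait_scale", "sd_units"))
            try:
                h = harmonize(instruments, target_stats)
                if ld is not None:
                    h.ld = ld.submatrix(h.variant_ids)
                for est in _run_methods(h, cfg["methods"], seed):
                    rows.append(_report_row(exp["name"], t["name"], "none",
                                            est, per_lower))
            except Exception as exc:  # noqa: BLE001
                logger.warning("panel cell %s x %s failed: %s", exp["name"],
                               t["name"], exc)
                rows.append(_na_row(exp["name"], t["name"], "none", str(exc)))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_mediation_panel(cfg: Mapping[str, Any]) \
        -> tuple[pd.DataFrame, dict[tuple[str, str], MediationResult]]:
    """Per exposure x mediator: unadjusted cis-MR, mediator-adjusted cis-MR,
    and the bootstrap mediation decomposition (proportions as percentages)."""
    if not cfg.get("mediators"):
        raise ConfigError("mediation panel requires a 'mediators' section")
    per_lower = cfg.get("report_per_sd_lower", True)
    ld, consequences = _load_inputs(cfg)
    seed = int(cfg.get("seed", 0))
    boot_cfg = cfg.get("bootstrap", {})
    n_boot = int(boot_cfg.get("n_boot", 1_000_000))
    guard = float(boot_cfg.get("guard", 1e-6))
    outcome = read_sumstats(cfg["outcome"]["sumstats"],
                            trait_name=cfg["outcome"]["name"],
                            trait_scale=cfg["outcome"].get("trait_scale",
                                                           LOG_ODDS))
    def cis_ivw(h: HarmonizedSet) -> MREstimate:
        # residual LD (clumping keeps r2 below, not at, zero) is accounted
        # for by GLS when the LD matrix is available
        if ld is not None:
            h.ld = ld.submatrix(h.variant_ids)
            return ivw_ld(h)
        return ivw(h)

    rows = []
    results: dict[tuple[str, str], MediationResult] = {}
    for exp in cfg["exposures"]:
        log: list = []
        instruments = _exposure_instruments(exp, ld, consequences, log)
        region = GeneRegion(**exp["region"])
        h_total = harmonize(instruments, outcome)
        theta_total = cis_ivw(h_total)
        rows.append(_report_row(exp["name"], cfg["outcome"]["name"], "none",
                                theta_total, per_lower))
        for med in cfg["mediators"]:
            med_stats = read_sumstats(med["sumstats"], trait_name=med["name"])
            h_xm = harmonize(instruments, med_stats)
            theta_xm = cis_ivw(h_xm)
            gw = select_genome_wide(
                med_stats, ld, maf_min=med.get("maf_min", 0.01),
                p_max=med.get("gw_p_max", 5e-8),
                clump_r2=med.get("gw_clump_r2", 0.01),
                clump_window=med.get("gw_clump_window", 1_000_000),
                exclude_region=region)
            h_my = harmonize(gw, outcome)
            theta_my = ivw(h_my)
            if "theta_my_override" in boot_cfg:
                # a fixed mediator-outcome constant (e.g. 0 to switch the
                # adjustment off) carries no sampling uncertainty
                ov = float(boot_cfg["theta_my_override"])
                theta_my = replace(theta_my, theta=ov, se=0.0,
                                   ci_low=ov, ci_high=ov)
            cis_set = harmonize_multi([instruments, med_stats], outcome, ld=ld)
            result = bootstrap_mediation(
                MediationInputs(theta_total, theta_xm, theta_my, cis_set),
                n_boot=n_boot, seed=seed, proportion_guard=guard)
            results[(exp["name"], med["name"])] = result
            rows.append(_report_row(exp["name"], cfg["outcome"]["name"],
                                    f"adjusted_for_{med['name']}",
                                    result.direct_variant_level, per_lower))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS), results


def rescale_per_unit(estimate: MREstimate, sd_in_units: float) -> MREstimate:
    """Re-express a per-SD estimate per natural unit of the trait (e.g.
    per mg/dL given the trait SD in mg/dL); OR per unit = exp(theta_unit)."""
    if sd_in_units <= 0:
        raise ValueError("sd_in_units must be positive")
    return estimate.rescaled(sd_in_units)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_report(table: pd.DataFrame, path, cfg: Mapping[str, Any]) -> None:
    """Write a report TSV with provenance header lines (config hash, seed,
    package version); reruns with an identical config are byte-identical."""
    header = (f"# cismr_version={__version__} "
              f"config_sha256={config_hash(cfg)} seed={cfg.get('seed', 0)}\n")
    with open(path, "w") as fh:
        fh.write(header)
        table.to_csv(fh, sep="\t", index=False)


def mediation_to_json(result: MediationResult) -> dict[str, Any]:
    return {
        "total": result.total,
        "indirect": result.indirect_product,
        "direct": result.direct_difference,
        "proportion": result.proportion_mediated,
        "proportion_pct": 100.0 * result.proportion_mediated,
        "ci": {k: list(v) for k, v in result.ci.items()},
        "se": result.se,
        "n_boot": result.n_boot,
        "seed": result.seed,
        "guard_rejections": result.guard_rejections,
        "flags": result.flags,
    }
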