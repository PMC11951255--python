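"""GWAS summary statistics: containers, I/O, harmonization, SD standardization.

Per-variant association estimates are the raw material of two-sample Mendelian
randomization: each trait contributes a table of (variant, effect allele, beta,
standard error, p, allele frequency, sample size) rows, and causal estimation
only becomes possible once the exposure and outcome tables are expressed on a
common effect allele per variant.  This module owns that plumbing — validated
containers, tab-delimited readers/writers, allele harmonization (including
strand flips and the palindromic-SNP ambiguity rule), proxy-variant
substitution through an LD matrix, and the summary-statistic trait-SD
estimator used to put traits reported in natural units onto a 1-SD scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("cismr")

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SD_UNITS = "sd_units"
LOG_ODDS = "log_odds"


class SumstatsError(ValueError):
    """Fatal summary-statistic I/O or validation failure."""


class HarmonizationError(ValueError):
    """Fatal harmonization failure (e.g. no shared variants survive)."""


def _complement_allele(a: str) -> str:
    return "".join(COMPLEMENT[b] for b in a)


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and COMPLEMENT[ea] == oa


@dataclass(frozen=True)
class VariantAssociation:
    """A single variant-trait association estimate.

    beta is per copy of the effect allele, in SD units for quantitative traits
    and log-odds for binary traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: nonpositive_se")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.variant_id}: eaf_out_of_range")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical_alleles")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.variant_id}: pval_out_of_range")
        if self.n <= 0:
            raise ValueError(f"{self.variant_id}: nonpositive_n")


@dataclass
class SummaryStatSet:
    """One trait's GWAS summary statistics as a validated table.

    ``df`` uses the canonical column names; variant ids are unique and every
    row satisfies the `VariantAssociation` invariants.
    """

    trait_name: str
    trait_scale: str
    df: pd.DataFrame
    ancestry_tag: str = ""
    fasting_tag: str | None = None
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_scale not in (SD_UNITS, LOG_ODDS):
            raise SumstatsError(f"unknown trait_scale {self.trait_scale!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise SumstatsError(f"duplicate variant ids: {sorted(set(dups))[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    @property
    def records(self) -> list[VariantAssociation]:
        return [
            VariantAssociation(
                variant_id=r.variant_id, chrom=str(r.chrom), pos=int(r.pos),
                effect_allele=r.effect_allele, other_allele=r.other_allele,
                eaf=float(r.eaf), beta=float(r.beta), se=float(r.se),
                pval=float(r.pval), n=float(r.n),
            )
            for r in self.df.itertuples(index=False)
        ]

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStatSet":
        keep = self.df[self.df["variant_id"].isin(set(variant_ids))]
        # preserve requested order
        order = {v: i for i, v in enumerate(variant_ids)}
        keep = keep.sort_values("variant_id", key=lambda s: s.map(order))
        return SummaryStatSet(self.trait_name, self.trait_scale,
                              keep.reset_index(drop=True),
                              self.ancestry_tag, self.fasting_tag)


@dataclass
class LDMatrix:
    """Signed correlation matrix among variants, relative to each variant's
    stated effect allele."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        j = len(self.variant_ids)
        if self.r.shape != (j, j):
            raise ValueError("LD matrix shape does not match variant ids")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal not unit")
        if np.any(np.abs(self.r) > 1.0 + 1e-10):
            raise ValueError("LD |r| > 1")
        if np.linalg.eigvalsh(self.r).min() < -1e-8:
            raise ValueError("LD matrix not PSD within tolerance")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.corr(a, b) ** 2

    def submatrix(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


@dataclass
class HarmonizedSet:
    """Exposure(s) and outcome effects aligned to common effect alleles."""

    variant_ids: list[str]
    exposure_names: list[str]
    beta_exposure: np.ndarray   # (J, K)
    se_exposure: np.ndarray     # (J, K)
    beta_outcome: np.ndarray    # (J,)
    se_outcome: np.ndarray      # (J,)
    ld: LDMatrix | None = None
    drop_log: list[tuple[str, str]] = field(default_factory=list)
    outcome_scale: str = SD_UNITS

    def __post_init__(self) -> None:
        j = len(self.variant_ids)

        def as_matrix(a):
            a = np.atleast_2d(np.asarray(a, float))
            return a.T if (a.shape[0] == 1 and j > 1) else a

        self.beta_exposure = as_matrix(self.beta_exposure)
        self.se_exposure = as_matrix(self.se_exposure)
        self.beta_outcome = np.asarray(self.beta_outcome, float).ravel()
        self.se_outcome = np.asarray(self.se_outcome, float).ravel()
        k = len(self.exposure_names)
        if self.beta_exposure.shape != (j, k) or self.se_exposure.shape != (j, k):
            raise ValueError("exposure matrix shape mismatch")
        if self.beta_outcome.shape != (j,) or self.se_outcome.shape != (j,):
            raise ValueError("outcome vector length mismatch")
        if self.ld is not None and self.ld.variant_ids != self.variant_ids:
            self.ld = self.ld.submatrix(self.variant_ids)

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    @classmethod
    def from_arrays(cls, beta_exposure, se_exposure, beta_outcome, se_outcome,
                    ld: LDMatrix | None = None,
                    exposure_names: Sequence[str] | None = None,
                    variant_ids: Sequence[str] | None = None,
                    outcome_scale: str = SD_UNITS) -> "HarmonizedSet":
        bx = np.atleast_2d(np.asarray(beta_exposure, float))
        if bx.shape[0] == 1 and np.asarray(beta_outcome).size > 1:
            bx = bx.T
        j, k = bx.shape
        if variant_ids is None:
            variant_ids = [f"v{i + 1}" for i in range(j)]
        if exposure_names is None:
            exposure_names = [f"exposure{m + 1}" for m in range(k)]
        return cls(list(variant_ids), list(exposure_names), bx,
                   se_exposure, beta_outcome, se_outcome, ld=ld,
                   outcome_scale=outcome_scale)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ROW_CHECKS = (
    ("nonpositive_se", lambda d: ~(d["se"] > 0)),
    ("eaf_out_of_range", lambda d: ~((d["eaf"] > 0) & (d["eaf"] < 1))),
    ("identical_alleles", lambda d: d["effect_allele"] == d["other_allele"]),
    ("pval_out_of_range", lambda d: ~((d["pval"] > 0) & (d["pval"] <= 1))),
    ("nonpositive_n", lambda d: ~(d["n"] > 0)),
    ("non_snp", lambda d: ~(
        d["effect_allele"].isin(VALID_BASES) & d["other_allele"].isin(VALID_BASES)
    )),
)


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  trait_scale: str = SD_UNITS,
                  trait_name: str | None = None) -> SummaryStatSet:
    """Read a tab-delimited summary-statistics file into a validated set.

    ``column_map`` maps canonical names to source header names. Rows violating
    the per-variant invariants (nonpositive SE, out-of-range eaf/p, indels,
    multi-allelic records) are dropped and recorded in ``drop_log``. A missing
    p-value column is recomputed from z = beta/se under a standard normal.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if raw.empty:
        raise SumstatsError(f"{path}: empty summary-statistics file")
    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon == "pval":
            continue  # recomputed from z below
        else:
            raise SumstatsError(f"{path}: missing mapped column {src!r} for {canon!r}")
    df = raw.rename(columns=rename)
    if "pval" not in df.columns:
        df["pval"] = 2.0 * sps.norm.sf(np.abs(df["beta"] / df["se"]))
    df = df[CANONICAL_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    drop_log: list[tuple[str, str]] = []
    bad = df[["eaf", "beta", "se", "pval", "n"]].isna().any(axis=1)
    for vid in df.loc[bad, "variant_id"]:
        drop_log.append((str(vid), "missing_value"))
    df = df[~bad]
    for reason, check in _ROW_CHECKS:
        bad = check(df)
        for vid in df.loc[bad, "variant_id"]:
            drop_log.append((str(vid), reason))
        df = df[~bad]
    if trait_name is None:
        trait_name = str(path)
    out = SummaryStatSet(trait_name, trait_scale, df.reset_index(drop=True))
    out.drop_log = drop_log
    if drop_log:
        logger.info("read_sumstats(%s): dropped %d rows", path, len(drop_log))
    return out


def write_sumstats(stats: SummaryStatSet, path) -> None:
    """Write the canonical tab-delimited representation (round-trip exact)."""
    stats.df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix: square whitespace-delimited with a one-line header
    of variant ids, or long-format triplets (id1, id2, r)."""
    with open(path) as fh:
        header = fh.readline().split()
    ncol = len(header)
    body = pd.read_csv(path, sep=r"\s+", skiprows=1, header=None)
    if body.shape[1] == ncol and body.shape[0] == ncol and ncol > 3:
        return LDMatrix(header, body.to_numpy(float))
    if ncol == 3 and body.shape[1] == 3 and not _is_number(header[2]):
        # long format with header id1 id2 r
        tri = pd.read_csv(path, sep=r"\s+")
        tri.columns = ["id1", "id2", "r"]
        ids = sorted(set(tri["id1"]) | set(tri["id2"]))
        idx = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        for row in tri.itertuples(index=False):
            i, j = idx[row.id1], idx[row.id2]
            r[i, j] = r[j, i] = float(row.r)
        return LDMatrix(ids, r)
    if body.shape[1] == ncol and body.shape[0] == ncol:
        return LDMatrix(header, body.to_numpy(float))
    raise SumstatsError(f"{path}: unrecognized LD matrix layout")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ld.variant_ids) + "\n")
        for row in ld.r:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def write_drop_log(drop_log: Iterable[tuple[str, str, str]], path) -> None:
    """Write a (variant_id, stage, reason) TSV."""
    pd.DataFrame(list(drop_log), columns=["variant_id", "stage", "reason"]) \
        .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _align_row(ea: str, oa: str, eaf: float, o_ea: str, o_oa: str,
               o_eaf: float, palindrome_eaf_limit: float):
    """Decide the alignment action for one shared variant.

    Returns ("keep" | "flip" | drop-reason-string).  "flip" means the other
    study's beta sign must be reversed and its eaf complemented.
    """
    if _is_palindromic(ea, oa):
        if not _is_palindromic(o_ea, o_oa) or {o_ea, o_oa} != {ea, oa}:
            return "allele_mismatch"
        action = "keep" if (o_ea, o_oa) == (ea, oa) else "flip"
        f = o_eaf if action == "keep" else 1.0 - o_eaf
        informative = (min(eaf, 1 - eaf) < palindrome_eaf_limit
                       and min(f, 1 - f) < palindrome_eaf_limit)
        same_side = (eaf - 0.5) * (f - 0.5) > 0
        if not (informative and same_side):
            return "palindromic_ambiguous"
        return action
    if (o_ea, o_oa) == (ea, oa):
        return "keep"
    if (o_ea, o_oa) == (oa, ea):
        return "flip"
    try:
        c_ea, c_oa = _complement_allele(o_ea), _complement_allele(o_oa)
    except KeyError:
        return "allele_mismatch"
    if (c_ea, c_oa) == (ea, oa):
        return "keep"
    if (c_ea, c_oa) == (oa, ea):
        return "flip"
    return "allele_mismatch"


def _aligned_frame(ref: pd.DataFrame, other: pd.DataFrame,
                   palindrome_eaf_limit: float):
    """Align ``other`` onto ``ref``'s effect alleles for shared variants.

    Returns (aligned other frame indexed like ref's shared subset, drop log).
    """
    o = other.set_index("variant_id")
    shared = [v for v in ref["variant_id"] if v in o.index]
    drop: list[tuple[str, str]] = [
        (v, "missing_in_other") for v in ref["variant_id"] if v not in o.index
    ]
    rows = []
    kept_ids = []
    ref_idx = ref.set_index("variant_id")
    for vid in shared:
        r = ref_idx.loc[vid]
        s = o.loc[vid]
        action = _align_row(r["effect_allele"], r["other_allele"], float(r["eaf"]),
                            s["effect_allele"], s["other_allele"], float(s["eaf"]),
                            palindrome_eaf_limit)
        if action == "keep":
            rows.append((float(s["beta"]), float(s["se"]), float(s["eaf"]),
                         float(s["pval"]), float(s["n"])))
            kept_ids.append(vid)
        elif action == "flip":
            rows.append((-float(s["beta"]), float(s["se"]), 1.0 - float(s["eaf"]),
                         float(s["pval"]), float(s["n"])))
            kept_ids.append(vid)
        else:
            drop.append((vid, action))
    aligned = pd.DataFrame(rows, columns=["beta", "se", "eaf", "pval", "n"],
                           index=kept_ids)
    return aligned, drop


def harmonize(exposure: SummaryStatSet, outcome: SummaryStatSet,
              palindrome_eaf_limit: float = 0.42) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    Swapped alleles flip the outcome beta sign and eaf; strand flips
    (complement alleles) are resolved silently; palindromic variants are kept
    only when the allele frequency is informative on both sides
    (min(eaf, 1-eaf) < ``palindrome_eaf_limit``) and agrees in direction,
    otherwise dropped with reason ``palindromic_ambiguous``.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise HarmonizationError("empty summary-statistic set")
    aligned, drop = _aligned_frame(exposure.df, outcome.df, palindrome_eaf_limit)
    kept = [v for v in exposure.variant_ids if v in aligned.index]
    if not kept:
        raise HarmonizationError(
            f"no shared variants survive harmonization "
            f"(exposure {len(exposure)}, outcome {len(outcome)}, "
            f"dropped {len(drop)})")
    e = exposure.df.set_index("variant_id").loc[kept]
    a = aligned.loc[kept]
    return HarmonizedSet(
        variant_ids=kept,
        exposure_names=[exposure.trait_name],
        beta_exposure=e["beta"].to_numpy(float)[:, None],
        se_exposure=e["se"].to_numpy(float)[:, None],
        beta_outcome=a["beta"].to_numpy(float),
        se_outcome=a["se"].to_numpy(float),
        drop_log=[(v, r) for v, r in drop if r != "missing_in_other"],
        outcome_scale=outcome.trait_scale,
    )


def harmonize_multi(exposures: Sequence[SummaryStatSet], outcome: SummaryStatSet,
                    palindrome_eaf_limit: float = 0.42,
                    ld: LDMatrix | None = None) -> HarmonizedSet:
    """Align several exposures plus the outcome onto the first exposure's
    effect alleles (multivariable MR input)."""
    if not exposures:
        raise HarmonizationError("no exposures supplied")
    ref = exposures[0].df
    frames = []
    drop: list[tuple[str, str]] = []
    for other in list(exposures[1:]) + [outcome]:
        aligned, d = _aligned_frame(ref, other.df, palindrome_eaf_limit)
        frames.append(aligned)
        drop.extend(x for x in d if x[1] != "missing_in_other")
    kept = [v for v in ref["variant_id"]
            if all(v in f.index for f in frames)]
    if not kept:
        raise HarmonizationError("no shared variants across all datasets")
    e0 = ref.set_index("variant_id").loc[kept]
    bx = [e0["beta"].to_numpy(float)]
    sx = [e0["se"].to_numpy(float)]
    for f in frames[:-1]:
        bx.append(f.loc[kept, "beta"].to_numpy(float))
        sx.append(f.loc[kept, "se"].to_numpy(float))
    out = frames[-1].loc[kept]
    return HarmonizedSet(
        variant_ids=kept,
        exposure_names=[e.trait_name for e in exposures],
        beta_exposure=np.column_stack(bx),
        se_exposure=np.column_stack(sx),
        beta_outcome=out["beta"].to_numpy(float),
        se_outcome=out["se"].to_numpy(float),
        ld=ld.submatrix(kept) if ld is not None else None,
        drop_log=sorted(set(drop)),
        outcome_scale=outcome.trait_scale,
    )


# ---------------------------------------------------------------------------
# Proxies
# ---------------------------------------------------------------------------

def find_proxies(missing: Sequence[str], outcome: SummaryStatSet, ld: LDMatrix,
                 r2_min: float = 0.8) -> dict[str, str]:
    """Map each missing instrument to the best available proxy (r² >= r2_min).

    Ties on r² are broken by smaller outcome p-value, then lexicographic id.
    Variants with no adequate proxy are omitted from the mapping (and logged).
    """
    present = [v for v in outcome.variant_ids if v in ld]
    pvals = dict(zip(outcome.df["variant_id"], outcome.df["pval"]))
    mapping: dict[str, str] = {}
    unproxied = []
    for vid in missing:
        if vid not in ld:
            unproxied.append(vid)
            continue
        best = None
        for cand in present:
            if cand == vid:
                continue
            r2 = ld.r2(vid, cand)
            if r2 < r2_min:
                continue
            key = (-r2, pvals.get(cand, 1.0), cand)
            if best is None or key < best[0]:
                best = (key, cand)
        if best is None:
            unproxied.append(vid)
        else:
            mapping[vid] = best[1]
    if unproxied:
        logger.info("find_proxies: %d unproxied variants: %s",
                    len(unproxied), unproxied)
    return mapping


def substitute_proxies(outcome: SummaryStatSet, mapping: Mapping[str, str],
                       ld: LDMatrix) -> SummaryStatSet:
    """Return an outcome set in which each missing instrument id carries its
    proxy's statistics, with the beta sign flipped when the LD correlation
    between instrument and proxy is negative (effect-allele re-alignment)."""
    df = outcome.df.copy()
    extra = []
    for vid, proxy in mapping.items():
        row = df[df["variant_id"] == proxy].iloc[0].copy()
        sign = 1.0 if ld.corr(vid, proxy) >= 0 else -1.0
        row["variant_id"] = vid
        row["beta"] = sign * row["beta"]
        if sign < 0:
            row["eaf"] = 1.0 - row["eaf"]
        extra.append(row)
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return SummaryStatSet(outcome.trait_name, outcome.trait_scale, df,
                          outcome.ancestry_tag, outcome.fasting_tag)


# ---------------------------------------------------------------------------
# Trait-SD standardization
# ---------------------------------------------------------------------------

def estimate_trait_sd(stats: SummaryStatSet) -> float:
    """Estimate the phenotype SD from summary statistics.

    Under a quantitative-trait GWAS, se_j^2 ~ var(Y) / (2 n eaf_j (1-eaf_j)),
    so regressing 2 n eaf (1-eaf) on 1/se^2 through the origin gives var(Y)
    as the slope.  Deterministic; requires at least two usable variants.
    """
    d = stats.df
    usable = d[(d["se"] > 0) & (d["n"] > 0) & (d["eaf"] > 0) & (d["eaf"] < 1)]
    if len(usable) < 2:
        raise SumstatsError("estimate_trait_sd: fewer than 2 usable variants")
    x = 1.0 / usable["se"].to_numpy(float) ** 2
    y = 2.0 * usable["n"].to_numpy(float) * usable["eaf"].to_numpy(float) \
        * (1.0 - usable["eaf"].to_numpy(float))
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        raise SumstatsError("estimate_trait_sd: nonpositive variance estimate")
    return math.sqrt(slope)


def rescale_to_sd(stats: SummaryStatSet, sd: float) -> SummaryStatSet:
    """Divide betas and SEs by ``sd`` (z-scores and p-values are unchanged)."""
    if sd <= 0:
        raise SumstatsError("rescale_to_sd: sd must be positive")
    df = stats.df.copy()
    df["beta"] = df["beta"] / sd
    df["se"] = df["se"] / sd
    return SummaryStatSet(stats.trait_name, SD_UNITS, df,
                          stats.ancestry_tag, stats.fasting_tag)
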