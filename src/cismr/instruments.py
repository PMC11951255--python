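"""Genetic-instrument selection and strength diagnostics.

Drug-target MR instruments are common variants in the cis region of the gene
encoding the target protein, genome-wide significant for circulating protein
levels, pruned to approximate linkage-equilibrium, and stripped of
protein-altering variants (which can create epitope-binding artefacts in
aptamer-based protein assays).  Instrument strength is summarised by
per-variant F statistics, the Cragg-Donald F in the univariable setting, and
conditional F statistics in the multivariable setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .summary_stats import HarmonizedSet, LDMatrix, SummaryStatSet

logger = logging.getLogger("cismr")

CODING_CONSEQUENCES = frozenset({
    "missense_variant", "stop_gained", "stop_lost",
    "start_gained", "start_lost", "frameshift_variant",
})

CONSEQUENCE_VOCABULARY = CODING_CONSEQUENCES | frozenset({
    "synonymous_variant", "intron_variant", "intergenic_variant",
    "upstream_gene_variant", "downstream_gene_variant",
    "3_prime_UTR_variant", "5_prime_UTR_variant",
    "regulatory_region_variant", "splice_region_variant",
    "non_coding_transcript_variant", "TF_binding_site_variant",
})


class SelectionError(ValueError):
    """Fatal instrument-selection failure (no survivors)."""


@dataclass(frozen=True)
class GeneRegion:
    """A gene locus plus flanking window; positions are 1-based and the
    window is the closed interval [start - flank, end + flank]."""

    gene_name: str
    chrom: str
    start: int
    end: int
    flank: int = 100_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if self.flank < 0:
            raise ValueError("negative flank")

    @property
    def window(self) -> tuple[int, int]:
        return self.start - self.flank, self.end + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return str(chrom) == self.chrom and lo <= pos <= hi


@dataclass
class ConsequenceTable:
    """variant_id -> predicted functional consequence label."""

    consequences: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.consequences.values()) - CONSEQUENCE_VOCABULARY
        if unknown:
            raise ValueError(f"unknown consequence labels: {sorted(unknown)}")

    def get(self, variant_id: str) -> str | None:
        return self.consequences.get(variant_id)


@dataclass
class InstrumentSet:
    """A validated instrument panel with strength summaries."""

    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    eaf: np.ndarray
    per_variant_F: np.ndarray = field(init=False)
    r2_explained: float = field(init=False)
    mean_F: float = field(init=False)
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, float).ravel()
        self.se_exposure = np.asarray(self.se_exposure, float).ravel()
        self.eaf = np.asarray(self.eaf, float).ravel()
        self.per_variant_F = (self.beta_exposure / self.se_exposure) ** 2
        self.r2_explained = variance_explained_arrays(self.eaf, self.beta_exposure)
        self.mean_F = float(self.per_variant_F.mean())

    def __len__(self) -> int:
        return len(self.variant_ids)

    @classmethod
    def from_sumstats(cls, stats: SummaryStatSet,
                      selection_log: Sequence[tuple[str, str, str]] = ()) \
            -> "InstrumentSet":
        d = stats.df
        return cls(d["variant_id"].tolist(), d["beta"].to_numpy(float),
                   d["se"].to_numpy(float), d["eaf"].to_numpy(float),
                   selection_log=list(selection_log))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_cis(stats: SummaryStatSet, region: GeneRegion,
               maf_min: float = 0.01, p_max: float = 5e-8,
               log: list | None = None) -> SummaryStatSet:
    """Keep common (MAF > maf_min), genome-wide-significant (p < p_max)
    variants inside the flanked gene window (closed interval, strict
    inequalities on MAF and p)."""
    d = stats.df
    lo, hi = region.window
    maf = np.minimum(d["eaf"], 1.0 - d["eaf"])
    in_window = (d["chrom"].astype(str) == region.chrom) \
        & (d["pos"] >= lo) & (d["pos"] <= hi)
    common = maf > maf_min
    significant = d["pval"] < p_max

    drop = [] if log is None else log
    for vid, w, c, s in zip(d["variant_id"], in_window, common, significant):
        if not w:
            drop.append((vid, "select_cis", "outside_window"))
        elif not c:
            drop.append((vid, "select_cis", "maf"))
        elif not s:
            drop.append((vid, "select_cis", "pval"))
    keep = d[in_window & common & significant]
    if keep.empty:
        n = len(d)
        raise SelectionError(
            f"select_cis: no variants survive (input {n}, in-window "
            f"{int(in_window.sum())}, common {int(common.sum())}, "
            f"significant {int(significant.sum())})")
    out = SummaryStatSet(stats.trait_name, stats.trait_scale,
                         keep.reset_index(drop=True),
                         stats.ancestry_tag, stats.fasting_tag)
    logger.info("select_cis(%s): %d -> %d variants", region.gene_name,
                len(d), len(out))
    return out


def exclude_coding(stats: SummaryStatSet, consequences: ConsequenceTable,
                   log: list | None = None) -> SummaryStatSet:
    """Remove variants annotated with protein-altering consequences
    (missense, stop gained/lost, start gained/lost, frameshift); variants
    absent from the annotation table are retained."""
    d = stats.df
    labels = d["variant_id"].map(consequences.consequences)
    bad = labels.isin(CODING_CONSEQUENCES)
    if log is not None:
        for vid in d.loc[bad, "variant_id"]:
            log.append((vid, "exclude_coding", "coding_consequence"))
    return SummaryStatSet(stats.trait_name, stats.trait_scale,
                          d[~bad].reset_index(drop=True),
                          stats.ancestry_tag, stats.fasting_tag)


def clump(stats: SummaryStatSet, ld: LDMatrix, r2_max: float = 0.1,
          window_bp: int = 10_000_000, log: list | None = None) \
        -> SummaryStatSet:
    """Greedy LD clumping to the lowest p-value.

    Repeatedly keep the remaining variant with the smallest p (ties broken by
    larger |beta/se|, then lexicographic id) and discard remaining variants
    with r² >= r2_max within ``window_bp`` of it.  Variants without LD
    information are dropped first with reason ``no_ld``.  Returns the kept
    variants in selection order; the result is invariant to input row order.
    """
    d = stats.df
    drop = [] if log is None else log
    have_ld = d["variant_id"].apply(lambda v: v in ld)
    for vid in d.loc[~have_ld, "variant_id"]:
        drop.append((vid, "clump", "no_ld"))
    d = d[have_ld]

    rows = {r.variant_id: r for r in d.itertuples(index=False)}
    # deterministic priority: p asc, |z| desc, id asc
    order = sorted(rows, key=lambda v: (rows[v].pval,
                                        -abs(rows[v].beta / rows[v].se), v))
    kept: list[str] = []
    remaining = set(order)
    for vid in order:
        if vid not in remaining:
            continue
        kept.append(vid)
        remaining.discard(vid)
        row = rows[vid]
        for other in list(remaining):
            o = rows[other]
            if str(o.chrom) == str(row.chrom) \
                    and abs(int(o.pos) - int(row.pos)) <= window_bp \
                    and ld.r2(vid, other) >= r2_max:
                drop.append((other, "clump", f"r2_with_{vid}"))
                remaining.discard(other)
    keep_df = d.set_index("variant_id").loc[kept].reset_index()
    return SummaryStatSet(stats.trait_name, stats.trait_scale, keep_df,
                          stats.ancestry_tag, stats.fasting_tag)


# ---------------------------------------------------------------------------
# Strength statistics
# ---------------------------------------------------------------------------

def per_variant_f(beta: float, se: float) -> float:
    """Single-variant F statistic, (beta/se)^2."""
    if se <= 0:
        raise ValueError("per_variant_f: se must be positive")
    return (beta / se) ** 2


def variance_explained_arrays(eaf: np.ndarray, beta: np.ndarray) -> float:
    r2 = float(np.sum(2.0 * eaf * (1.0 - eaf) * beta ** 2))
    return min(max(r2, 0.0), 1.0 - 1e-12)


def variance_explained(instruments: InstrumentSet) -> float:
    """Fraction of trait variance explained, sum_j 2 eaf_j (1-eaf_j) beta_j^2
    (betas in SD units; instruments assumed independent after clumping)."""
    return variance_explained_arrays(instruments.eaf, instruments.beta_exposure)


def cragg_donald_f(instruments: InstrumentSet, n: int) -> float:
    """Cragg-Donald F from summary data: R^2 (n - J - 1) / (J (1 - R^2))."""
    j = len(instruments)
    if n <= j + 1:
        raise ValueError("cragg_donald_f: n must exceed J + 1")
    r2 = instruments.r2_explained
    return r2 * (n - j - 1) / (j * (1.0 - r2))


def conditional_f(harmonized: HarmonizedSet, exposure_index: int,
                  max_iter: int = 10, tol: float = 1e-10) -> float:
    """Conditional instrument-strength statistic for one exposure in a
    multivariable design (summary-data Sanderson-Windmeijer construction).

    The indexed exposure's instrument associations are regressed on all other
    exposures' associations (no intercept); the F statistic is built from the
    weighted residual sum of squares with residual-variance weights
    w_j = 1 / (se_xj^2 + sum_m delta_m^2 se_mj^2), iterated to convergence:

        F = sum_j w_j (x_j - Z_j delta)^2 / (J - k + 1)

    where J is the instrument count and k the number of exposures.  Two-sample
    zero cross-GWAS covariance is assumed.
    """
    bx = harmonized.beta_exposure
    sx = harmonized.se_exposure
    j, k = bx.shape
    if k < 2:
        raise ValueError("conditional_f: needs at least 2 exposures")
    if j < k + 1:
        raise ValueError("conditional_f: needs more instruments than exposures")
    e = exposure_index
    x = bx[:, e]
    z = np.delete(bx, e, axis=1)
    se_x = sx[:, e]
    se_z = np.delete(sx, e, axis=1)

    w = 1.0 / se_x ** 2
    delta = np.zeros(k - 1)
    for _ in range(max_iter):
        zw = z * w[:, None]
        gram = z.T @ zw
        if np.linalg.cond(gram) > 1e12:
            raise ValueError("conditionally_weak: collinear exposure associations")
        new_delta = np.linalg.solve(gram, zw.T @ x)
        w = 1.0 / (se_x ** 2 + (se_z ** 2) @ new_delta ** 2)
        if np.max(np.abs(new_delta - delta)) < tol:
            delta = new_delta
            break
        delta = new_delta
    resid = x - z @ delta
    if np.sum(resid ** 2) < 1e-16 * max(np.sum(x ** 2), 1e-300):
        raise ValueError("conditionally_weak: indexed exposure collinear "
                         "with the others")
    return float(np.sum(w * resid ** 2) / (j - k + 1))
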