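"""Hierarchical AMOVA on codominant genotypes and standardized indices.

Each individual contributes two allele copies per locus; the molecular
distance between two copies is allele identity (0 if the codes match,
1 otherwise — infinite-allele style, not repeat-length). Sums of squared
differences are partitioned among regions, among populations within
regions, and within populations, and the three variance components are
solved from the expected-mean-square equations with sample-size
coefficients that accommodate unequal population and region sizes.
Components are summed across loci before forming

    F_RT = s2_a / (s2_a + s2_b + s2_c)
    F_SR = s2_b / (s2_b + s2_c)
    F_ST = (s2_a + s2_b) / (s2_a + s2_b + s2_c)

Standardized indices divide each raw F by the maximum it could attain
given the observed within-population variation. The maximum is obtained
by recoding alleles so that groups at the relevant level share none
(populations for F'_ST and F'_SR; regions for F'_RT, with populations
inside a region keeping shared codes) and recomputing the AMOVA.
Hedrick's G'_ST is the closed-form analogue computed from multi-locus
G_ST and the mean within-population gene diversity H_S.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GenotypeTable, ValidationError

__all__ = [
    "AmovaResult",
    "StandardizedIndices",
    "amova_hierarchical",
    "standardize",
    "fst",
    "gst_hedrick",
]

log = logging.getLogger("hierqst")


@dataclass
class AmovaResult:
    """Hierarchical AMOVA variance components and F-statistics."""

    sigma2_a: float  # among regions
    sigma2_b: float  # among populations within regions
    sigma2_c: float  # within populations
    f_rt: float
    f_sr: float
    f_st: float
    f_rt_raw: float
    f_sr_raw: float
    f_st_raw: float
    n_loci: int
    per_locus: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    copies_per_population: dict[str, int] = field(default_factory=dict)


@dataclass
class StandardizedIndices:
    """Standardized differentiation indices and their maxima."""

    f_rt_std: float
    f_sr_std: float
    f_st_std: float
    g_st_hedrick: float
    max_f_rt: float
    max_f_sr: float
    max_f_st: float


def _region_codes(table: GenotypeTable, pops: list[str]) -> np.ndarray:
    regions = [table.design.region_of(p) for p in pops]
    order = list(dict.fromkeys(regions))
    return np.array([order.index(r) for r in regions])


def _locus_components(counts: np.ndarray, region_of: np.ndarray):
    """Variance components at one locus from a populations x alleles count matrix.

    Returns ``None`` when the locus carries no usable hierarchical signal
    (monomorphic, or fewer than 2 regions / populations after per-locus
    deletion of unscored populations).
    """
    scored = counts.sum(axis=1) > 0
    counts = counts[scored]
    region_of = region_of[scored]
    n_p = counts.sum(axis=1).astype(float)
    n_total = float(n_p.sum())
    regions = np.unique(region_of)
    n_pops = len(n_p)
    if n_pops < 2 or n_total <= n_pops:
        return None
    if (counts.sum(axis=0) > 0).sum() < 2:
        return None  # monomorphic after deletion

    # identity-distance sums of squares via allele counts:
    # SS within a group of n copies with allele counts m_a is (n - sum m_a^2 / n) / 2
    def _ss_within(group_counts: np.ndarray) -> float:
        n = group_counts.sum()
        return 0.5 * (n - (group_counts.astype(float) ** 2).sum() / n)

    ss_wp = sum(_ss_within(counts[i]) for i in range(n_pops))
    region_counts = {g: counts[region_of == g].sum(axis=0) for g in regions}
    ss_wr = sum(_ss_within(region_counts[g]) for g in regions)
    ss_tot = _ss_within(counts.sum(axis=0))
    ss_ap = ss_wr - ss_wp
    ss_ag = ss_tot - ss_wr

    r = len(regions)
    df_ag, df_ap, df_wp = r - 1, n_pops - r, n_total - n_pops
    n_g = np.array([n_p[region_of == g].sum() for g in regions])
    sigma2_c = ss_wp / df_wp

    if r == 1:
        # single region: two-level AMOVA among populations; no region component
        n_prime = (n_total - (n_p**2).sum() / n_total) / (n_pops - 1)
        sigma2_b = (ss_ap / (n_pops - 1) - sigma2_c) / n_prime
        return 0.0, sigma2_b, sigma2_c
    if df_ap == 0:
        # every region holds one population: two-level AMOVA among regions
        n_tprime = (n_total - (n_g**2).sum() / n_total) / df_ag
        sigma2_a = (ss_ag / df_ag - sigma2_c) / n_tprime
        return sigma2_a, 0.0, sigma2_c

    sum_np2_over_ng = sum(
        (n_p[region_of == g] ** 2).sum() / n_g[i] for i, g in enumerate(regions)
    )
    n_prime = (n_total - sum_np2_over_ng) / df_ap
    n_dprime = (sum_np2_over_ng - (n_p**2).sum() / n_total) / df_ag
    n_tprime = (n_total - (n_g**2).sum() / n_total) / df_ag

    ms_ap = ss_ap / df_ap
    ms_ag = ss_ag / df_ag
    sigma2_b = (ms_ap - sigma2_c) / n_prime
    sigma2_a = (ms_ag - sigma2_c - n_dprime * sigma2_b) / n_tprime
    return sigma2_a, sigma2_b, sigma2_c


def amova_hierarchical(table: GenotypeTable) -> AmovaResult:
    """Three-level AMOVA (region / population / allele copy) over all loci.

    Missing allele copies are excluded per locus, with the sample-size
    coefficients recomputed; loci that are monomorphic (or lose the
    hierarchy) after deletion contribute nothing. Raw negative components
    are retained in the across-locus sums; the reported F values are
    clamped to [0, 1] with the unclamped value kept alongside.
    """
    pops = table.populations
    if len(pops) < 2:
        raise ValidationError("hierarchical AMOVA needs >= 2 populations")
    region_of = _region_codes(table, pops)
    copies: dict[str, int] = {p: 0 for p in pops}
    rows = []
    for locus in table.loci:
        counts, _, _ = table.allele_counts(locus)
        for p, c in zip(pops, counts.sum(axis=1)):
            copies[p] += int(c)
        comps = _locus_components(counts, region_of)
        if comps is None:
            log.info("locus %s: no usable variation, contributes zero", locus)
            continue
        rows.append({"locus": locus, "sigma2_a": comps[0], "sigma2_b": comps[1], "sigma2_c": comps[2]})
    zero = [p for p, c in copies.items() if c == 0]
    if zero:
        raise ValidationError(f"population(s) {zero!r} have no scored allele copies at any locus")
    if not rows:
        raise ValidationError("no variation: every locus is monomorphic or degenerate")
    per_locus = pd.DataFrame(rows)
    a = float(per_locus["sigma2_a"].sum())
    b = float(per_locus["sigma2_b"].sum())
    c = float(per_locus["sigma2_c"].sum())
    tot = a + b + c
    if tot <= 0:
        raise ValidationError("no variation: total molecular variance is zero")
    f_rt_raw = a / tot
    f_sr_raw = b / (b + c) if (b + c) > 0 else 0.0
    f_st_raw = (a + b) / tot
    clamp = lambda v: float(min(max(v, 0.0), 1.0))
    return AmovaResult(
        sigma2_a=a, sigma2_b=b, sigma2_c=c,
        f_rt=clamp(f_rt_raw), f_sr=clamp(f_sr_raw), f_st=clamp(f_st_raw),
        f_rt_raw=f_rt_raw, f_sr_raw=f_sr_raw, f_st_raw=f_st_raw,
        n_loci=len(per_locus), per_locus=per_locus, copies_per_population=copies,
    )


def fst(table: GenotypeTable) -> float:
    """Convenience scalar: clamped multi-locus F_ST."""
    return amova_hierarchical(table).f_st


def _recode(table: GenotypeTable, level: str) -> GenotypeTable:
    """Relabel alleles so no two groups at ``level`` share a code.

    ``level`` is ``"population"`` or ``"region"``. Within-group genotype
    structure is preserved: the map allele -> group-specific allele is a
    bijection per group. Missing copies (0) stay missing.
    """
    df = table.data.copy()
    group = df[level].astype(str)
    group_idx = pd.Categorical(group).codes.astype(np.int64)
    for locus in table.loci:
        offset = int(max(df[f"{locus}_1"].max(), df[f"{locus}_2"].max())) + 1
        for slot in (1, 2):
            col = f"{locus}_{slot}"
            vals = df[col].to_numpy()
            df[col] = np.where(vals > 0, group_idx * offset + vals, 0)
    return GenotypeTable(df, table.design, list(table.loci))


def gst_hedrick(table: GenotypeTable) -> tuple[float, float, float]:
    """Multi-locus (G_ST, G'_ST, H_S) over populations.

    Per locus, H_S is the unweighted mean within-population expected
    heterozygosity and H_T the expected heterozygosity of the unweighted
    mean allele-frequency vector; locus values are averaged before forming
    G_ST = (H_T - H_S) / H_T and Hedrick's standardization
    G'_ST = G_ST (s - 1 + H_S) / ((s - 1)(1 - H_S)) with s populations.
    """
    s = len(table.populations)
    if s < 2:
        raise ValidationError("G'_ST needs >= 2 populations")
    hs_vals, ht_vals = [], []
    for locus in table.loci:
        counts, _, _ = table.allele_counts(locus)
        scored = counts.sum(axis=1) > 0
        counts = counts[scored]
        if len(counts) < 2:
            continue
        freqs = counts / counts.sum(axis=1, keepdims=True)
        hs_vals.append(float(np.mean(1.0 - (freqs**2).sum(axis=1))))
        mean_freq = freqs.mean(axis=0)
        ht_vals.append(float(1.0 - (mean_freq**2).sum()))
    if not ht_vals or sum(ht_vals) == 0:
        raise ValidationError("no variation: G_ST undefined")
    h_s = float(np.mean(hs_vals))
    h_t = float(np.mean(ht_vals))
    g_st = (h_t - h_s) / h_t
    if h_s >= 1.0:
        raise ValidationError("H_S = 1: standardization undefined")
    g_prime = g_st * (s - 1 + h_s) / ((s - 1) * (1.0 - h_s))
    return g_st, float(min(max(g_prime, 0.0), 1.0)), h_s


def standardize(table: GenotypeTable, raw: AmovaResult | None = None) -> StandardizedIndices:
    """Standardized F'_RT, F'_SR, F'_ST plus Hedrick's G'_ST.

    ``raw`` may be passed to avoid recomputing the observed-data AMOVA; it
    must come from the same table.
    """
    if raw is None:
        raw = amova_hierarchical(table)
    pop_max = amova_hierarchical(_recode(table, "population"))
    reg_max = amova_hierarchical(_recode(table, "region"))

    def ratio(value: float, maximum: float, name: str) -> float:
        # a level already at its (zero) ceiling carries no differentiation
        if maximum <= 0:
            if value <= 0:
                return 0.0
            raise ValidationError(f"standardization undefined: recoded-data {name} is zero")
        return float(min(max(value / maximum, 0.0), 1.0))

    _, g_prime, _ = gst_hedrick(table)
    return StandardizedIndices(
        f_rt_std=ratio(raw.f_rt, reg_max.f_rt, "F_RT"),
        f_sr_std=ratio(raw.f_sr, pop_max.f_sr, "F_SR"),
        f_st_std=ratio(raw.f_st, pop_max.f_st, "F_ST"),
        g_st_hedrick=g_prime,
        max_f_rt=reg_max.f_rt,
        max_f_sr=pop_max.f_sr,
        max_f_st=pop_max.f_st,
    )
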