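"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorised code paths of the package: sums
of squares are accumulated over explicit pairwise allele comparisons, the
expected-mean-square system is solved numerically, and the balanced
nested ANOVA follows the textbook coefficient formulas directly.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_amova(table) -> dict[str, float]:
    """Hierarchical AMOVA from explicit pairwise identity distances.

    Returns the summed-over-loci components and F statistics. Only the
    general case (>= 2 regions, more populations than regions at every
    locus) is handled; monomorphic loci contribute nothing.
    """
    tot = {"a": 0.0, "b": 0.0, "c": 0.0}
    for locus in table.loci:
        copies, pops, regs = [], [], []
        for _, row in table.data.iterrows():
            for slot in (1, 2):
                allele = int(row[f"{locus}_{slot}"])
                if allele > 0:
                    copies.append(allele)
                    pops.append(str(row["population"]))
                    regs.append(table.design.region_of(str(row["population"])))
        copies = np.array(copies)
        if len(np.unique(copies)) < 2:
            continue
        pops_arr, regs_arr = np.array(pops), np.array(regs)

        def ss_group(mask):
            idx = np.flatnonzero(mask)
            n = len(idx)
            s = 0.0
            for i, j in itertools.combinations(idx, 2):
                s += copies[i] != copies[j]
            return s / n

        n_total = len(copies)
        pop_ids = sorted(set(pops))
        reg_ids = sorted(set(regs))
        ss_tot = ss_group(np.ones(n_total, bool))
        ss_wp = sum(ss_group(pops_arr == p) for p in pop_ids)
        ss_wr = sum(ss_group(regs_arr == g) for g in reg_ids)
        ss_ap, ss_ag = ss_wr - ss_wp, ss_tot - ss_wr

        r, n_pops = len(reg_ids), len(pop_ids)
        n_p = {p: (pops_arr == p).sum() for p in pop_ids}
        n_g = {g: (regs_arr == g).sum() for g in reg_ids}
        region_of_pop = {p: regs_arr[pops_arr == p][0] for p in pop_ids}
        sum_np2_over_ng = sum(
            sum(n_p[p] ** 2 for p in pop_ids if region_of_pop[p] == g) / n_g[g] for g in reg_ids
        )
        df_ag, df_ap, df_wp = r - 1, n_pops - r, n_total - n_pops
        coeff = np.array(
            [
                [
                    (n_total - sum(v**2 for v in n_g.values()) / n_total) / df_ag,
                    (sum_np2_over_ng - sum(v**2 for v in n_p.values()) / n_total) / df_ag,
                    1.0,
                ],
                [0.0, (n_total - sum_np2_over_ng) / df_ap, 1.0],
                [0.0, 0.0, 1.0],
            ]
        )
        ms = np.array([ss_ag / df_ag, ss_ap / df_ap, ss_wp / df_wp])
        a, b, c = np.linalg.solve(coeff, ms)
        tot["a"] += a
        tot["b"] += b
        tot["c"] += c
    total = tot["a"] + tot["b"] + tot["c"]
    bc = tot["b"] + tot["c"]
    return {
        "sigma2_a": tot["a"],
        "sigma2_b": tot["b"],
        "sigma2_c": tot["c"],
        "f_rt": tot["a"] / total if total else float("nan"),
        "f_sr": tot["b"] / bc if bc else float("nan"),
        "f_st": (tot["a"] + tot["b"]) / total if total else float("nan"),
    }


def balanced_nested_anova(y: np.ndarray) -> dict[str, float]:
    """Textbook EMS solution for a balanced 4-level nested array.

    ``y`` has shape (regions, pops/region, families/pop, plants/family).
    """
    a, b, c, n = y.shape
    grand = y.mean()
    reg_m = y.mean(axis=(1, 2, 3))
    pop_m = y.mean(axis=(2, 3))
    fam_m = y.mean(axis=3)
    ms_r = b * c * n * ((reg_m - grand) ** 2).sum() / (a - 1)
    ms_p = c * n * ((pop_m - reg_m[:, None]) ** 2).sum() / (a * (b - 1))
    ms_f = n * ((fam_m - pop_m[:, :, None]) ** 2).sum() / (a * b * (c - 1))
    ms_e = ((y - fam_m[:, :, :, None]) ** 2).sum() / (a * b * c * (n - 1))
    s_e = ms_e
    s_f = (ms_f - ms_e) / n
    s_p = (ms_p - ms_f) / (c * n)
    s_r = (ms_r - ms_p) / (b * c * n)
    return {"region": s_r, "population": s_p, "family": s_f, "residual": s_e}
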