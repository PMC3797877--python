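"""Nested random-model variance components for one trait.

The model is the fully nested Gaussian random-effects model

    y_ijkl = mu + R_i + P_ij + F_ijk + e_ijkl

with regions i, populations j within regions, seed families k within
populations and plants l within families, all effects independent
zero-mean Gaussians. Two estimators are provided:

``estimate_anova``
    Method of moments: nested sums of squares are equated to their exact
    expected values under the random model (Henderson Method I style
    coefficients, valid under any imbalance and reducing to the textbook
    coefficients for balanced data). Negative solutions are truncated to 0
    and flagged.

``estimate_reml``
    Restricted maximum likelihood via EM on the mixed-model equations,
    warm-started at the (floored) ANOVA solution. For balanced data with an
    interior ANOVA solution the two estimators coincide, because the ANOVA
    solution is then the REML optimum and a fixed point of the EM map.

The initial-size covariate is handled by pre-residualisation
(``adjust_covariate``): the trait is replaced by the residuals of an OLS
fit on the covariate, re-centred at the trait grand mean so that the
measurement scale is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .design import PhenotypeTable, ValidationError

__all__ = [
    "VarianceComponents",
    "RemlNonConvergence",
    "adjust_covariate",
    "estimate_anova",
    "estimate_reml",
    "estimate",
]

LEVELS = ("region", "population", "family", "residual")


class RemlNonConvergence(RuntimeError):
    """EM-REML failed to converge; carries the last iterate."""

    def __init__(self, last: dict[str, float], iterations: int):
        super().__init__(f"REML did not converge in {iterations} iterations; last iterate {last}")
        self.last = last
        self.iterations = iterations


@dataclass
class VarianceComponents:
    """Estimated variances at each level of the nested design."""

    sigma2_region: float
    sigma2_population: float
    sigma2_family: float
    sigma2_residual: float
    method: str
    n_plants: int
    truncated: dict[str, bool] = field(default_factory=dict)
    trait: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "region": self.sigma2_region,
            "population": self.sigma2_population,
            "family": self.sigma2_family,
            "residual": self.sigma2_residual,
        }

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


def _usable(table: PhenotypeTable, trait: str, columns: tuple[str, ...]) -> pd.DataFrame:
    if trait not in table.traits:
        raise ValidationError(f"unknown trait {trait!r}")
    df = table.data[["region", "population", "family", *columns, trait]].copy()
    return df.dropna(subset=[*columns, trait] if columns else [trait])


def adjust_covariate(table: PhenotypeTable, trait: str, covariate: str = "initial_diameter") -> PhenotypeTable:
    """Residualise ``trait`` on ``covariate``, preserving the grand mean.

    Rows missing either value are dropped (their count is reflected in the
    returned table's length). Raises on a constant covariate or fewer than
    3 usable rows.
    """
    if covariate not in table.data.columns:
        raise ValidationError(f"unknown covariate {covariate!r}")
    df = table.data.dropna(subset=[trait, covariate]).reset_index(drop=True)
    if len(df) < 3:
        raise ValidationError(f"covariate adjustment needs >= 3 usable rows, got {len(df)}")
    x = df[covariate].to_numpy(dtype=float)
    y = df[trait].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError(f"covariate {covariate!r} is constant; adjustment undefined")
    slope, intercept = np.polyfit(x, y, 1)
    adjusted = y - (intercept + slope * x) + y.mean()
    out = df.copy()
    out[trait] = adjusted
    return PhenotypeTable(out, table.design, list(table.traits))


def _nested_ss(df: pd.DataFrame, trait: str):
    """Sequential nested sums of squares and the group-size functionals."""
    y = df[trait].to_numpy(dtype=float)
    n_total = len(y)
    grand = y.mean()

    fam_g = df.groupby(["region", "population", "family"], observed=True)[trait]
    pop_g = df.groupby(["region", "population"], observed=True)[trait]
    reg_g = df.groupby("region", observed=True)[trait]

    fam = fam_g.agg(["mean", "count"])
    pop = pop_g.agg(["mean", "count"])
    reg = reg_g.agg(["mean", "count"])

    # within-family residual SS
    fam_mean_per_row = fam_g.transform("mean").to_numpy()
    ss_e = float(((y - fam_mean_per_row) ** 2).sum())
    # families within populations
    fam_pop_mean = fam.join(pop["mean"].rename("pmean"), on=["region", "population"])
    ss_f = float((fam["count"] * (fam["mean"] - fam_pop_mean["pmean"]) ** 2).sum())
    # populations within regions
    pop_reg_mean = pop.join(reg["mean"].rename("rmean"), on="region")
    ss_p = float((pop["count"] * (pop["mean"] - pop_reg_mean["rmean"]) ** 2).sum())
    # regions
    ss_r = float((reg["count"] * (reg["mean"] - grand) ** 2).sum())

    a = len(reg)
    b = len(pop)
    c = len(fam)
    df_r, df_p, df_f, df_e = a - 1, b - a, c - b, n_total - c
    for name, v in (("region", df_r), ("population", df_p), ("family", df_f), ("plant", df_e)):
        if v <= 0:
            raise ValidationError(
                f"degenerate nesting: level {name!r} has no replication (df = {v})"
            )

    n_ijk = fam["count"].to_numpy(dtype=float)
    n_ij = pop["count"].to_numpy(dtype=float)
    n_i = reg["count"].to_numpy(dtype=float)
    # size functionals entering the expected sums of squares
    fam_by_pop = fam["count"].groupby(level=[0, 1], observed=True)
    fam_by_reg = fam["count"].groupby(level=0, observed=True)
    pop_by_reg = pop["count"].groupby(level=0, observed=True)
    k_f_pop = float((fam_by_pop.apply(lambda s: (s**2).sum()) / pop["count"]).sum())
    k_f_reg = float((fam_by_reg.apply(lambda s: (s**2).sum()) / reg["count"]).sum())
    k_f_tot = float((n_ijk**2).sum() / n_total)
    k_p_reg = float((pop_by_reg.apply(lambda s: (s**2).sum()) / reg["count"]).sum())
    k_p_tot = float((n_ij**2).sum() / n_total)
    k_r_tot = float((n_i**2).sum() / n_total)

    # E[SS] coefficient matrix for (sigma2_R, sigma2_P, sigma2_F, sigma2_e)
    ems = np.array(
        [
            [n_total - k_r_tot, k_p_reg - k_p_tot, k_f_reg - k_f_tot, df_r],
            [0.0, n_total - k_p_reg, k_f_pop - k_f_reg, df_p],
            [0.0, 0.0, n_total - k_f_pop, df_f],
            [0.0, 0.0, 0.0, df_e],
        ]
    )
    ss = np.array([ss_r, ss_p, ss_f, ss_e])
    return ss, ems, n_total


def estimate_anova(table: PhenotypeTable, trait: str) -> VarianceComponents:
    """Method-of-moments nested variance components.

    Equates the four sequential sums of squares to their exact expectations
    under the random model and solves the (triangular) system; negative
    solutions are truncated to 0 and flagged. Rows with a missing trait
    value are dropped.
    """
    df = _usable(table, trait, ())
    if df.empty:
        raise ValidationError(f"no usable rows for trait {trait!r}")
    y = df[trait].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, "anova", len(df), {}, trait)
    ss, ems, n_total = _nested_ss(df, trait)
    raw = linalg.solve_triangular(ems, ss, lower=False)
    truncated = {lvl: bool(v < 0) for lvl, v in zip(LEVELS, raw)}
    est = np.maximum(raw, 0.0)
    return VarianceComponents(
        float(est[0]), float(est[1]), float(est[2]), float(est[3]),
        "anova", n_total, truncated, trait,
    )


def _incidence(codes: np.ndarray, n_levels: int) -> np.ndarray:
    z = np.zeros((len(codes), n_levels))
    z[np.arange(len(codes)), codes] = 1.0
    return z


def estimate_reml(
    table: PhenotypeTable,
    trait: str,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> VarianceComponents:
    """EM-REML estimates of the four nested variance components.

    The trait is standardised internally (centred, unit variance) so the
    iteration is scale-free, and estimates are returned on the original
    scale. Components that converge to the boundary (below 1e-8 of the
    trait variance) are reported as 0 and flagged.
    """
    df = _usable(table, trait, ())
    if df.empty:
        raise ValidationError(f"no usable rows for trait {trait!r}")
    y_raw = df[trait].to_numpy(dtype=float)
    n = len(y_raw)
    if np.ptp(y_raw) == 0:
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, "reml", n, {}, trait)
    scale = y_raw.std()
    y = (y_raw - y_raw.mean()) / scale

    keys = {
        "region": df["region"].astype(str),
        "population": df["region"].astype(str) + "/" + df["population"].astype(str),
        "family": (
            df["region"].astype(str) + "/" + df["population"].astype(str) + "/" + df["family"].astype(str)
        ),
    }
    z_blocks, q_sizes = [], []
    for key in keys.values():
        codes, levels = pd.factorize(key)
        z_blocks.append(_incidence(codes, len(levels)))
        q_sizes.append(len(levels))
    z = np.hstack(z_blocks)
    x = np.ones((n, 1))
    w = np.hstack([x, z])
    wtw = w.T @ w
    wty = w.T @ y
    yty = float(y @ y)
    slices = []
    start = 1
    for q in q_sizes:
        slices.append(slice(start, start + q))
        start += q

    start_vals = estimate_anova(table, trait)
    floor = 1e-10
    sig = np.array(
        [
            max(start_vals.sigma2_region / scale**2, 1e-3),
            max(start_vals.sigma2_population / scale**2, 1e-3),
            max(start_vals.sigma2_family / scale**2, 1e-3),
            max(start_vals.sigma2_residual / scale**2, 1e-3),
        ]
    )
    q_total = sum(q_sizes)

    def neg2_loglik(sigma: np.ndarray) -> float:
        """-2 restricted log-likelihood (+const) via the MME identity."""
        m = wtw.copy()
        for k, sl in enumerate(slices):
            m[sl, sl] += np.eye(q_sizes[k]) * (sigma[3] / sigma[k])
        cho = linalg.cho_factor(m, lower=True)
        sol = linalg.cho_solve(cho, wty)
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        quad = (yty - float(sol @ wty)) / sigma[3]
        return (
            (n - q_total - 1) * np.log(sigma[3])
            + sum(q * np.log(sigma[k]) for k, q in enumerate(q_sizes))
            + logdet_m
            + quad
        )

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        m = wtw.copy()
        for k, sl in enumerate(slices):
            lam = sig[3] / max(sig[k], floor)
            m[sl, sl] += np.eye(q_sizes[k]) * lam
        cho = linalg.cho_factor(m, lower=True)
        sol = linalg.cho_solve(cho, wty)
        minv = linalg.cho_solve(cho, np.eye(m.shape[0]))
        new = sig.copy()
        for k, sl in enumerate(slices):
            u = sol[sl]
            new[k] = (float(u @ u) + sig[3] * float(np.trace(minv[sl, sl]))) / q_sizes[k]
        new[3] = (yty - float(sol @ wty)) / (n - 1)
        new = np.maximum(new, floor)
        # EM approaches a zero boundary at a vanishing rate; once a
        # component is negligible (<0.1% of the trait variance) and still
        # shrinking, pin it to the boundary instead of crawling
        for k in range(3):
            if new[k] < 1e-3 and new[k] <= sig[k]:
                new[k] = floor
        delta = np.max(np.abs(new - sig) / np.maximum(sig, 1e-12))
        sig = new
        if delta < tol:
            converged = True
            break
    if not converged:
        # EM stalls when a component drifts slowly near the boundary;
        # finish with bounded quasi-Newton on the log-variances
        from scipy import optimize

        res = optimize.minimize(
            lambda x: neg2_loglik(np.exp(x)),
            np.log(np.maximum(sig, floor)),
            method="L-BFGS-B",
            bounds=[(np.log(floor), np.log(1e3))] * 4,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if not res.success and res.status != 2:  # 2: precision loss at optimum
            last = {lvl: float(v * scale**2) for lvl, v in zip(LEVELS, np.exp(res.x))}
            raise RemlNonConvergence(last, iterations)
        sig = np.exp(res.x)

    est = sig * scale**2
    var_y = y_raw.var()
    truncated = {}
    out = []
    for lvl, v in zip(LEVELS, est):
        boundary = lvl != "residual" and v < 1e-8 * var_y
        truncated[lvl] = boundary
        out.append(0.0 if boundary else float(v))
    return VarianceComponents(out[0], out[1], out[2], out[3], "reml", n, truncated, trait)


def estimate(
    table: PhenotypeTable,
    trait: str,
    method: str = "anova",
    *,
    treatment: str | None = "control",
    covariate: str | None = None,
    transform_exponent: float | None = None,
) -> VarianceComponents:
    """One-stop estimation with the pipeline's standard preprocessing.

    Subsets to ``treatment`` (the differentiation analyses use unclipped
    plants only), optionally applies a power transform and covariate
    pre-adjustment, then dispatches on ``method``.
    """
    work = table
    if treatment is not None:
        work = work.subset_treatment(treatment)
    if transform_exponent is not None:
        from .stats import power_transform

        data = work.data.copy()
        data[trait] = power_transform(data[trait].to_numpy(dtype=float), transform_exponent)
        work = PhenotypeTable(data, work.design, list(work.traits))
    if covariate is not None:
        work = adjust_covariate(work, trait, covariate)
    if method == "anova":
        return estimate_anova(work, trait)
    if method == "reml":
        return estimate_reml(work, trait)
    raise ValidationError(f"unknown variance method {method!r}")
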