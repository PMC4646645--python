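"""Scale, variable-set and topology effects on model quality.

Cross-validated AUCs are arcsine-square-root transformed and analysed with
a linear mixed model

    arcsin(sqrt(AUC)) ~ alpha + beta_D + beta_TV + beta_AV + a_Species

with the distance class as a categorical fixed effect (four dummies against
the 0 m baseline), dummies for topology inclusion and for the assessed
variable set against the measured one, and a species random intercept with
standard deviation ``a_Species``.  The variance components are estimated by
REML, profiling the likelihood over the single variance ratio, which makes
each fit cheap enough for dense parametric bootstrapping (percentile
confidence intervals from refits on responses simulated from the fitted
model).  Companion statistics: paired t-tests on the transformed values,
the one-tailed variance-ratio F test between variable sets, and the
conventional five-class AUC performance labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "transform_auc",
    "LMMResult",
    "fit_scale_lmm",
    "bootstrap_ci",
    "compare_paired",
    "variance_ratio",
    "classify_auc",
]

COEF_NAMES = ("intercept", "D200", "D1000", "D2500", "D4000", "TV", "AV")


def transform_auc(x):
    """Arcsine-square-root transform (radians) of an AUC in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("AUC values must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class LMMResult:
    """REML fit of the transformed-AUC mixed model."""

    coefficients: dict[str, float]
    sigma_species: float  # random-intercept SD (transformed scale)
    sigma_resid: float
    loglik: float
    converged: bool
    singular: bool
    n_obs: int
    design: "LMMDesign" = field(repr=False, default=None)
    ci: dict[str, tuple[float, float]] | None = None


class LMMDesign:
    """Fixed-effect design matrix and species grouping for the AUC model."""

    def __init__(self, table: pd.DataFrame) -> None:
        df = table.copy()
        if "converged" in df.columns:
            df = df[df["converged"].astype(bool)]
        df = df.dropna(subset=["auc"])
        required = {"species", "distance_m", "varset", "topo", "auc"}
        missing = required - set(df.columns)
        if missing:
            raise KeyError(f"AUC table lacks columns: {sorted(missing)}")
        if df["species"].nunique() < 2:
            raise ValueError("need at least 2 species for a random intercept")
        dist = df["distance_m"].astype(float)
        # dummies only for levels present (baseline: 0 m, no topo, measured)
        cols = [np.ones(len(df))]
        names = ["intercept"]
        for level in sorted(dist.unique()):
            if level == 0:
                continue
            cols.append((dist == level).to_numpy(float))
            names.append(f"D{int(level)}")
        if (df["topo"].astype(str) == "yes").any() and (df["topo"].astype(str) == "no").any():
            cols.append((df["topo"].astype(str) == "yes").to_numpy(float))
            names.append("TV")
        if (df["varset"].astype(str) == "AV").any() and (df["varset"].astype(str) == "MV").any():
            cols.append((df["varset"].astype(str) == "AV").to_numpy(float))
            names.append("AV")
        self.X = np.column_stack(cols)
        self.names = names
        self.y = transform_auc(df["auc"].to_numpy(float))
        codes, self.group_labels = pd.factorize(df["species"].to_numpy(), sort=True)
        self.groups = codes
        self.n_groups = len(self.group_labels)
        self.n, self.p = self.X.shape

    def with_response(self, y: np.ndarray) -> "LMMDesign":
        new = object.__new__(LMMDesign)
        new.__dict__ = {**self.__dict__, "y": y}
        return new


def _profiled_fit(design: LMMDesign, lam: float, reml: bool):
    """GLS quantities for variance ratio lam = sigma_a^2 / sigma_e^2.

    With a single random intercept, V_i^{-1} = I - lam/(1 + lam n_i) J per
    group, so all GLS cross-products reduce to per-group sums.
    """
    X, y, g = design.X, design.y, design.groups
    q = design.n_groups
    n, p = design.n, design.p
    ng = np.bincount(g, minlength=q).astype(float)
    Gx = np.zeros((q, p))
    np.add.at(Gx, g, X)
    Gy = np.bincount(g, weights=y, minlength=q)
    w = lam / (1.0 + lam * ng)
    XtVX = X.T @ X - (Gx * w[:, None]).T @ Gx
    XtVy = X.T @ y - Gx.T @ (w * Gy)
    yVy = y @ y - w @ (Gy * Gy)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = yVy - beta @ XtVy
    logdetV = float(np.sum(np.log1p(lam * ng)))
    if reml:
        dof = n - p
        sign, logdetXVX = np.linalg.slogdet(XtVX)
        crit = logdetV + dof * math.log(max(rss, 1e-300) / dof) + logdetXVX
    else:
        dof = n
        crit = logdetV + n * math.log(max(rss, 1e-300) / n)
    return beta, rss / dof, crit, XtVX


def fit_scale_lmm(table: pd.DataFrame, reml: bool = True) -> LMMResult:
    """Fit the transformed-AUC mixed model with a species random intercept.

    ``table`` is the long AUC record table (``species``, ``distance_m``,
    ``varset`` in {MV, AV}, ``topo`` in {no, yes}, ``auc``; non-converged
    rows are excluded).  The profiled (RE)ML criterion is optimised over the
    log variance ratio; a boundary solution (zero species variance) is
    flagged as singular.
    """
    design = table if isinstance(table, LMMDesign) else LMMDesign(table)

    def crit_of(u: float) -> float:
        return _profiled_fit(design, math.exp(u), reml)[2]

    res = optimize.minimize_scalar(crit_of, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = math.exp(res.x)
    beta, sigma2_e, crit, _ = _profiled_fit(design, lam, reml)
    # compare against the boundary lam -> 0 (no species variance)
    beta0, s2_0, crit0, _ = _profiled_fit(design, 0.0, reml)
    singular = False
    if crit0 <= crit:
        lam, beta, sigma2_e, crit = 0.0, beta0, s2_0, crit0
        singular = True
        log.warning("fit_scale_lmm: singular fit (species variance estimated at zero)")
    coefs = dict(zip(design.names, beta))
    return LMMResult(
        coefficients=coefs,
        sigma_species=math.sqrt(lam * sigma2_e),
        sigma_resid=math.sqrt(sigma2_e),
        loglik=-0.5 * crit,
        converged=bool(res.success),
        singular=singular,
        n_obs=design.n,
        design=design,
    )


def bootstrap_ci(
    result: LMMResult,
    n_sim: int = 1000,
    seed: int = 0,
    reml_refit: bool = False,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap percentile CIs for all model parameters.

    Responses are simulated from the fitted model (new species intercepts
    and residuals), refit by ML (the conventional choice inside a
    parametric bootstrap; ``reml_refit`` switches to REML), and the
    ``level`` percentile interval is taken per coefficient and for the
    random-intercept SD.  Reproducible given ``seed``; refit failures are
    dropped and counted, with a warning above 5 %.
    """
    design = result.design
    rng = np.random.default_rng(seed)
    names = design.names
    fixed = design.X @ np.array([result.coefficients[k] for k in names])
    draws = {k: [] for k in (*names, "sigma_species")}
    failures = 0
    for _ in range(n_sim):
        a = rng.normal(0.0, result.sigma_species, design.n_groups)
        y = fixed + a[design.groups] + rng.normal(0.0, result.sigma_resid, design.n)
        try:
            refit = fit_scale_lmm(design.with_response(y), reml=reml_refit)
        except np.linalg.LinAlgError:
            failures += 1
            continue
        for k in names:
            draws[k].append(refit.coefficients[k])
        draws["sigma_species"].append(refit.sigma_species)
    if failures > 0.05 * n_sim:
        log.warning("bootstrap_ci: %d/%d refits failed", failures, n_sim)
    alpha = 100 * (1 - level) / 2
    ci = {
        k: (float(np.percentile(v, alpha)), float(np.percentile(v, 100 - alpha)))
        for k, v in draws.items()
    }
    result.ci = ci
    return ci


def compare_paired(table: pd.DataFrame, factor: str = "topo"):
    """Paired t-test on transformed AUCs between the two levels of a factor.

    Pairs are formed over all combinations of the remaining factors;
    combinations missing either member are excluded.  Returns
    ``(t, df, p, means)`` where ``means`` are the raw-scale group means of
    the complete pairs.
    """
    if factor not in ("topo", "varset"):
        raise ValueError("factor must be 'topo' or 'varset'")
    df = table.copy()
    if "converged" in df.columns:
        df = df[df["converged"].astype(bool)]
    df = df.dropna(subset=["auc"])
    others = [c for c in ("species", "distance_m", "varset", "topo") if c != factor]
    wide = df.pivot_table(index=others, columns=factor, values="auc", aggfunc="first").dropna()
    if len(wide) < 2:
        raise ValueError("fewer than 2 complete pairs")
    levels = ("no", "yes") if factor == "topo" else ("MV", "AV")
    a, b = wide[levels[0]].to_numpy(), wide[levels[1]].to_numpy()
    diffs = transform_auc(b) - transform_auc(a)
    if np.allclose(diffs, 0.0):
        t, p = 0.0, 1.0  # identical pairs: no evidence either way
    else:
        t, p = stats.ttest_rel(transform_auc(b), transform_auc(a))
    means = {levels[0]: float(a.mean()), levels[1]: float(b.mean())}
    return float(t), len(wide) - 1, float(p), means


def variance_ratio(table: pd.DataFrame, factor: str = "varset"):
    """One-tailed variance-ratio F test between factor levels (MV over AV,
    or without-topology over with) on transformed AUCs."""
    df = table.copy()
    if "converged" in df.columns:
        df = df[df["converged"].astype(bool)]
    df = df.dropna(subset=["auc"])
    levels = ("MV", "AV") if factor == "varset" else ("no", "yes")
    a = transform_auc(df.loc[df[factor].astype(str) == levels[0], "auc"].to_numpy(float))
    b = transform_auc(df.loc[df[factor].astype(str) == levels[1], "auc"].to_numpy(float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in a group")
    F = va / vb
    df1, df2 = len(a) - 1, len(b) - 1
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


AUC_CLASSES = ((0.6, "fail"), (0.7, "poor"), (0.8, "fair"), (0.9, "good"))


def classify_auc(x: float) -> str:
    """Five-class AUC performance label with half-open bins:
    <0.6 fail, [0.6,0.7) poor, [0.7,0.8) fair, [0.8,0.9) good, >=0.9 excellent."""
    if not 0 <= x <= 1:
        raise ValueError("AUC must lie in [0, 1]")
    for bound, label in AUC_CLASSES:
        if x < bound:
            return label
    return "excellent"
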