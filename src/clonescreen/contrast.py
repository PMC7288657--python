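"""The causal-vs-rest contrast test.

The scientific question is whether one targeted SNP (guide) shifts target
gene expression relative to the other guides in the credible interval.  The
model is a mixed linear model

    y_{gjk} = mu + beta_g + c_{gj} + b_{B(g)} + eps_{gjk}

with guide ``g`` fixed, clone ``c`` (and batch ``b`` when present) random,
and the tested quantity is the contrast

    (mean of causal guides) - (mean of non-causal guides),

two-sided.  Under the balanced designs produced by
:mod:`clonescreen.simulate`, clone-level aggregation yields exact t-tests,
which is what the fast vectorised engine uses:

``ols``
    No random effects declared: ordinary fixed-effects contrast with the
    pooled within-guide residual, df = N - G.
``clone_means``
    Clone random effects, one clone per guide: the clone means are analysed
    with a two-group model (causal vs rest); the between-guide scatter is
    the error term, df = G_used - 2.
``nested``
    Within-guide clone replication exists: the error term is the
    between-clone-within-guide mean square, df = n_clones - n_guides.  This
    is the proper (conservative) yardstick for a guide effect when clones
    vary, and with a single duplicated guide it leaves just one error df.
``mixed``
    REML fit via :class:`statsmodels.regression.mixed_linear_model.MixedLM`
    with a Satterthwaite-type denominator df; falls back to the
    clone-aggregated tests (flagged) when the clone variance is confounded
    with the guide fixed effects or the fit is singular.

``method="auto"`` resolves to ``ols``, ``clone_means`` or ``nested`` from
the declared design structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign

__all__ = [
    "CausalContrastModel",
    "CausalContrastResults",
    "test_causal_contrast",
    "estimate_variance_components",
]


def _contrast_groups(design: ExperimentDesign, contrast: str) -> tuple[np.ndarray, np.ndarray]:
    """Guide indices of the causal group A and the reference group B."""
    causal = sorted(design.causal_guides)
    if contrast == "causal_group":
        a = np.array(causal, dtype=int)
    elif contrast == "first_causal":
        a = np.array(causal[:1], dtype=int)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    b = np.array(
        [g for g in range(design.n_guides) if g not in design.causal_guides], dtype=int
    )
    if a.size == 0 or b.size == 0:
        raise ValueError("both contrast groups must be non-empty")
    return a, b


def resolve_method(design: ExperimentDesign, method: str = "auto") -> str:
    if method != "auto":
        return method
    if design.has_clone_replication:
        return "nested"
    if design.has_random_effects:
        return "clone_means"
    return "ols"


def contrast_arrays(
    values: np.ndarray,
    design: ExperimentDesign,
    method: str = "auto",
    contrast: str = "causal_group",
) -> dict:
    """Vectorised contrast test over a ``(n_sims, n_clones, replicates)`` array.

    Returns a dict of per-simulation arrays ``est``, ``se``, ``t``, ``p``
    plus the scalar ``df`` and the resolved ``method``.
    """
    method = resolve_method(design, method)
    if values.ndim == 2:
        values = values[None]
    S, C, r = values.shape
    if C != design.n_clones or r != design.replicates:
        raise ValueError("value array shape does not match the design")

    guides, _ = design.clone_table()
    G = design.n_guides
    a_idx, b_idx = _contrast_groups(design, contrast)

    clone_means = values.mean(axis=2)
    # equal-weight guide means from clone means (balanced replicates)
    gmat = np.zeros((C, G))
    gmat[np.arange(C), guides] = 1.0
    gmat /= gmat.sum(axis=0, keepdims=True)
    guide_means = clone_means @ gmat  # (S, G)

    est = guide_means[:, a_idx].mean(axis=1) - guide_means[:, b_idx].mean(axis=1)
    c_g = np.array([design.clones_of(g) for g in range(G)], dtype=float)

    if method == "ols":
        resid = values - guide_means[:, guides][:, :, None]
        df = C * r - G
        s2 = (resid**2).sum(axis=(1, 2)) / df
        w = (1.0 / a_idx.size**2) * (1.0 / (c_g[a_idx] * r)).sum() + (
            1.0 / b_idx.size**2
        ) * (1.0 / (c_g[b_idx] * r)).sum()
    elif method == "clone_means":
        ga = guide_means[:, a_idx]
        gb = guide_means[:, b_idx]
        ss = ((ga - ga.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (gb - gb.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        df = a_idx.size + b_idx.size - 2
        if df < 1:
            raise ValueError("clone-means test needs at least 3 guides in the contrast")
        s2 = ss / df
        w = 1.0 / a_idx.size + 1.0 / b_idx.size
    elif method == "nested":
        df = C - G
        if df < 1:
            raise ValueError(
                "nested test requires within-guide clone replication "
                "(more clones than guides)"
            )
        resid = clone_means - guide_means[:, guides]
        s2 = (resid**2).sum(axis=1) / df
        w = (1.0 / a_idx.size**2) * (1.0 / c_g[a_idx]).sum() + (
            1.0 / b_idx.size**2
        ) * (1.0 / c_g[b_idx]).sum()
    else:
        raise ValueError(f"unknown method {method!r}")

    se = np.sqrt(s2 * w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.inf * np.sign(est))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return {"est": est, "se": se, "t": t, "p": p, "df": df, "method": method}


@dataclass
class CausalContrastResults:
    """Fitted causal-vs-rest contrast.

    Attributes
    ----------
    estimate : float
        Contrast estimate (causal minus reference guide means) in sdu.
    se, df, tvalue, pvalue : float
        Standard error, denominator degrees of freedom, t statistic and
        two-sided p-value.
    method : str
        The test actually used ("ols", "clone_means", "nested" or "mixed").
    fallback : bool
        True when a requested mixed fit was singular or unidentifiable and
        the clone-aggregated test was substituted.
    """

    estimate: float
    se: float
    df: float
    tvalue: float
    pvalue: float
    method: str
    contrast: str
    fallback: bool = False
    variance_components: dict | None = None

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        half = stats.t.ppf(1 - alpha / 2, self.df) * self.se
        return (self.estimate - half, self.estimate + half)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Causal-vs-rest contrast",
            "=" * 47,
            f"method:        {self.method}" + ("  (fallback)" if self.fallback else ""),
            f"contrast:      {self.contrast}",
            f"estimate:      {self.estimate: .4f} sdu",
            f"std err:       {self.se: .4f}",
            f"df:            {self.df:g}",
            f"t value:       {self.tvalue: .4f}",
            f"p value:       {self.pvalue: .4g}",
            f"95% CI:        [{lo: .4f}, {hi: .4f}]",
        ]
        if self.variance_components:
            lines.append("variance components: " + ", ".join(
                f"{k}={v:.4f}" for k, v in self.variance_components.items()
            ))
        return "\n".join(lines)


class CausalContrastModel:
    """Model for testing a causal guide against the rest of a credible interval.

    Parameters
    ----------
    data
        Tidy measurements with columns ``guide, clone, batch, replicate,
        value`` (the output of :func:`clonescreen.simulate.simulate_experiment`).
    design
        The :class:`~clonescreen.design.ExperimentDesign` the data follow.

    Examples
    --------
    >>> from clonescreen import ExperimentDesign, simulate_experiment
    >>> design = ExperimentDesign(effect_sdu=1.0, replicates=8)
    >>> data = simulate_experiment(design, seed=1)
    >>> res = CausalContrastModel(data, design).fit()
    >>> 0 < res.pvalue < 1
    True
    """

    def __init__(self, data: pd.DataFrame, design: ExperimentDesign):
        missing = {"guide", "clone", "value"} - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        self.design = design
        self.data = data
        self._values = self._to_array(data, design)

    @staticmethod
    def _to_array(data: pd.DataFrame, design: ExperimentDesign) -> np.ndarray:
        C, r = design.n_clones, design.replicates
        if len(data) != C * r:
            raise ValueError(
                f"expected {C * r} measurements for this design, got {len(data)}"
            )
        ordered = data.sort_values(["clone", "replicate"] if "replicate" in data else ["clone"])
        counts = ordered.groupby("clone").size()
        if not (counts == r).all():
            raise ValueError("every clone must have exactly `replicates` measurements")
        return ordered["value"].to_numpy().reshape(C, r)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, design: ExperimentDesign
    ) -> "CausalContrastModel":
        return cls(data, design)

    def fit(
        self, method: str = "auto", contrast: str = "causal_group"
    ) -> CausalContrastResults:
        if method == "mixed":
            return self._fit_mixed(contrast)
        out = contrast_arrays(self._values, self.design, method, contrast)
        return CausalContrastResults(
            estimate=float(out["est"][0]),
            se=float(out["se"][0]),
            df=float(out["df"]),
            tvalue=float(out["t"][0]),
            pvalue=float(out["p"][0]),
            method=out["method"],
            contrast=contrast,
        )

    # ----- REML mixed model with Satterthwaite-type df ----------------------

    def _fit_mixed(self, contrast: str) -> CausalContrastResults:
        design = self.design
        if not design.has_clone_replication:
            # clone intercepts are confounded with the guide fixed effects:
            # the clone variance is unidentifiable, use the aggregated test
            res = self.fit(method="auto", contrast=contrast)
            res.fallback = True
            res.method = res.method
            return res

        import statsmodels.api as sm

        guides, _ = design.clone_table()
        C, r = design.n_clones, design.replicates
        y = self._values.ravel()
        guide_of_obs = np.repeat(guides, r)
        clone_of_obs = np.repeat(np.arange(C), r)
        X = np.zeros((y.size, design.n_guides))
        X[np.arange(y.size), guide_of_obs] = 1.0

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=clone_of_obs)
            try:
                fit = model.fit(reml=True, method="lbfgs")
                singular = not np.isfinite(fit.cov_re.iloc[0, 0]) or fit.cov_re.iloc[0, 0] <= 1e-10
            except Exception:
                fit, singular = None, True
        if singular or fit is None:
            res = self.fit(method="nested", contrast=contrast)
            res.fallback = True
            return res

        sigma2_c = float(fit.cov_re.iloc[0, 0])
        sigma2_e = float(fit.scale)
        a_idx, b_idx = _contrast_groups(design, contrast)
        L = np.zeros(design.n_guides)
        L[a_idx] = 1.0 / a_idx.size
        L[b_idx] = -1.0 / b_idx.size
        est = float(L @ fit.fe_params)
        c_g = np.array([design.clones_of(g) for g in range(design.n_guides)], dtype=float)
        kappa = (1.0 / a_idx.size**2) * (1.0 / c_g[a_idx]).sum() + (
            1.0 / b_idx.size**2
        ) * (1.0 / c_g[b_idx]).sum()
        term_c = kappa * sigma2_c
        term_e = kappa * sigma2_e / r
        se = float(np.sqrt(term_c + term_e))
        df_c, df_e = C - design.n_guides, C * (r - 1)
        df = (term_c + term_e) ** 2 / (term_c**2 / df_c + term_e**2 / df_e)
        tval = est / se
        pval = float(2 * stats.t.sf(abs(tval), df))
        return CausalContrastResults(
            estimate=est,
            se=se,
            df=float(df),
            tvalue=float(tval),
            pvalue=pval,
            method="mixed",
            contrast=contrast,
            variance_components={"clone": sigma2_c, "residual": sigma2_e},
        )


def estimate_variance_components(
    data: pd.DataFrame, design: ExperimentDesign
) -> dict[str, float]:
    """Method-of-moments variance-component estimates for a balanced design.

    Uses the classical nested-ANOVA expected mean squares: the residual
    from within-clone scatter, the clone component from between-clone
    within-guide scatter (requires >= 2 clones for some guide), and the
    batch component from between-batch scatter of clone means (requires
    >= 2 batches).  Assumes no fixed guide effects contaminate the batch
    stratum, i.e. run on null data (effect 0); negative estimates are
    truncated at zero.  Components that are not identifiable in the design
    are reported as ``nan``.
    """
    model = CausalContrastModel(data, design)
    values = model._values
    C, r = design.n_clones, design.replicates
    guides, batches = design.clone_table()
    clone_means = values.mean(axis=1)

    sigma2_e = float(((values - clone_means[:, None]) ** 2).sum() / (C * (r - 1)))

    out = {"residual": sigma2_e, "clone": float("nan"), "batch": float("nan")}
    if design.has_clone_replication:
        guide_means = np.array([clone_means[guides == g].mean() for g in range(design.n_guides)])
        ss = float(((clone_means - guide_means[guides]) ** 2).sum())
        ms = r * ss / (C - design.n_guides)
        out["clone"] = max(0.0, (ms - sigma2_e) / r)
    if design.n_batches >= 2:
        sigma2_c = out["clone"] if np.isfinite(out["clone"]) else design.sigma_clone**2
        B = design.n_batches
        n_b = C // B
        batch_means = np.array([clone_means[batches == b].mean() for b in range(B)])
        ms_b = n_b * float(((batch_means - clone_means.mean()) ** 2).sum()) / (B - 1)
        out["batch"] = max(0.0, (ms_b - sigma2_c - sigma2_e / r) / n_b)
    return out


def test_causal_contrast(
    data: pd.DataFrame,
    design: ExperimentDesign,
    method: str = "auto",
    contrast: str = "causal_group",
) -> float:
    """Two-sided p-value of the causal-vs-rest contrast (convenience wrapper)."""
    return CausalContrastModel(data, design).fit(method=method, contrast=contrast).pvalue
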