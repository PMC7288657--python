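"""Principal variance component analysis (PVCA).

PVCA attributes overall expression variance to labelled experimental
factors (cell type, clone, batch, ...) by (1) projecting the expression
matrix onto its leading principal components, (2) decomposing each PC's
scores into per-factor random-effect variance components, and (3) summing
the per-factor shares weighted by each PC's share of variance.  The result
is one proportion per factor plus a residual, summing to 1.

Per-PC components are estimated by REML (each factor a random effect, no
interactions) with a method-of-moments fallback; negative estimates are
truncated at zero before weighting, standard PVCA practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PVCA", "VarianceDecomposition", "run_pvca"]


@dataclass
class VarianceDecomposition:
    """Per-factor variance proportions from a PVCA fit.

    ``proportions`` includes every declared factor (possibly 0) plus
    ``"residual"`` and sums to 1.  ``pc_variance_captured`` is the fraction
    of total expression variance carried by the PCs that were analysed.
    Factors whose label partitions were identical are reported merged under
    a joint ``"a/b"`` name and listed in ``aliased``.
    """

    proportions: dict[str, float]
    n_pcs_used: int
    pc_variance_captured: float
    aliased: list[tuple[str, ...]] = field(default_factory=list)
    per_pc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"proportions must sum to 1, got {total}")

    def summary(self) -> str:
        lines = [
            "Principal variance component analysis",
            "=" * 45,
            f"PCs analysed:        {self.n_pcs_used}"
            f"  ({100 * self.pc_variance_captured:.1f}% of total variance)",
        ]
        for name, p in sorted(self.proportions.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {name:<18s} {100 * p:6.1f}%")
        for group in self.aliased:
            lines.append(f"aliased factors merged: {' = '.join(group)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            **{k: float(v) for k, v in self.proportions.items()},
            "n_pcs_used": self.n_pcs_used,
            "pc_variance_captured": float(self.pc_variance_captured),
        }


def _partition_key(labels: pd.Series) -> tuple:
    codes, _ = pd.factorize(labels, use_na_sentinel=False)
    return tuple(codes)


def _vc_one_pc(score: np.ndarray, factors: pd.DataFrame) -> dict[str, float]:
    """Variance components of one PC's scores, all factors as random effects."""
    import statsmodels.api as sm

    df = factors.copy()
    rename = {c: f"f{i}" for i, c in enumerate(factors.columns)}
    df = df.rename(columns=rename)
    df["score"] = score
    df["_all"] = 1
    vcf = {c: f"0 + C({c})" for c in rename.values()}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                "score ~ 1", groups="_all", vc_formula=vcf, re_formula="0", data=df
            )
            fit = model.fit(reml=True, method="lbfgs")
        comps = {
            orig: max(0.0, float(fit.vcomp[list(vcf).index(new)]))
            for orig, new in rename.items()
        }
        comps["residual"] = max(0.0, float(fit.scale))
        if np.isfinite(sum(comps.values())) and sum(comps.values()) > 0:
            return comps
    except Exception:
        pass
    return _vc_mom(score, factors)


def _vc_mom(score: np.ndarray, factors: pd.DataFrame) -> dict[str, float]:
    """Method-of-moments fallback via balanced-ANOVA expected mean squares.

    The residual mean square comes from the additive main-effects fit (so
    one factor's spread does not leak into another's error term, as it
    would with a one-way within-group MS in a crossed design); each
    factor's component is then ``(MS_factor - MS_resid) / n0``, truncated
    at zero.
    """
    n = len(score)
    grand = score.mean()
    fitted = np.full(n, grand)
    df_model = 0
    for col in factors.columns:
        labels = factors[col].to_numpy()
        levels = np.unique(labels)
        if len(levels) < 2:
            continue
        means = {lv: score[labels == lv].mean() for lv in levels}
        fitted += np.array([means[lv] for lv in labels]) - grand
        df_model += len(levels) - 1
    df_resid = max(n - 1 - df_model, 1)
    ms_resid = float(((score - fitted) ** 2).sum() / df_resid)

    comps: dict[str, float] = {}
    for col in factors.columns:
        labels = factors[col].to_numpy()
        levels, counts = np.unique(labels, return_counts=True)
        k = len(levels)
        if k < 2:
            comps[col] = 0.0
            continue
        means = np.array([score[labels == lv].mean() for lv in levels])
        msb = (counts * (means - grand) ** 2).sum() / (k - 1)
        n0 = (n - (counts**2).sum() / n) / (k - 1)
        comps[col] = max(0.0, (msb - ms_resid) / n0)
    comps["residual"] = ms_resid
    return comps


class PVCA:
    """PVCA model: expression matrix plus per-sample factor labels.

    Parameters
    ----------
    values
        Samples x probes matrix (an :class:`~clonescreen.fluidigm.ExpressionMatrix`
        or a plain DataFrame).
    factors
        DataFrame of per-sample labels, one column per factor, index
        aligned with the samples.
    n_pcs
        Number of leading PCs to analyse (default 5).  Alternatively set
        ``var_explained`` to pick the smallest PC count capturing that
        fraction of total variance.
    scale
        Scale probes to unit variance before PCA (default: centred only).
    weighting
        ``"selected"`` weights each PC by its variance share *within the
        selected PCs* (default): proportions describe the captured
        subspace, so diffuse residual variance outside the leading PCs is
        under-represented.  ``"total"`` weights by each PC's share of
        total variance and books the uncaptured remainder as residual,
        which recovers absolute shares on synthetic data.
    """

    def __init__(
        self,
        values,
        factors: pd.DataFrame,
        n_pcs: int = 5,
        var_explained: float | None = None,
        scale: bool = False,
        weighting: str = "selected",
    ):
        if hasattr(values, "values") and not isinstance(values, pd.DataFrame):
            values = values.values  # ExpressionMatrix
        self.values = pd.DataFrame(values)
        self.factors = pd.DataFrame(factors)
        if len(self.factors) != len(self.values):
            raise ValueError("factors must have one row per sample")
        if weighting not in ("selected", "total"):
            raise ValueError("weighting must be 'selected' or 'total'")
        if self.values.shape[0] < n_pcs + 1:
            raise ValueError("need at least n_pcs + 1 samples")
        self.n_pcs = int(n_pcs)
        self.var_explained = var_explained
        self.scale = scale
        self.weighting = weighting

    def fit(self) -> VarianceDecomposition:
        X = self.values.to_numpy(dtype=float)
        X = X - X.mean(axis=0, keepdims=True)
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            X = X / np.where(sd > 0, sd, 1.0)

        # PCA of the sample covariance via SVD
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        evals = s**2 / (X.shape[0] - 1)
        total_var = evals.sum()
        if total_var <= 0:
            raise ValueError("expression matrix has zero variance")
        if self.var_explained is not None:
            cum = np.cumsum(evals) / total_var
            k = int(np.searchsorted(cum, self.var_explained) + 1)
        else:
            k = self.n_pcs
        k = min(k, int((evals > 1e-12 * evals[0]).sum()))
        scores = U[:, :k] * s[:k]

        # degenerate single-level factors get proportion 0 by construction
        single = [c for c in self.factors.columns if self.factors[c].nunique() < 2]
        active = self.factors.drop(columns=single)

        # detect aliased factors (identical sample partitions) and merge them
        aliased: list[tuple[str, ...]] = []
        merged = active.copy()
        keys: dict[tuple, list[str]] = {}
        for col in active.columns:
            keys.setdefault(_partition_key(active[col]), []).append(col)
        for cols in keys.values():
            if len(cols) > 1:
                aliased.append(tuple(cols))
                joint = "/".join(cols)
                merged = merged.drop(columns=cols)
                merged[joint] = active[cols[0]].astype(str)

        if self.weighting == "selected":
            weights = evals[:k] / evals[:k].sum()
        else:
            # weight by share of total variance; the variance not captured
            # by the selected PCs is unattributable and counts as residual
            weights = evals[:k] / total_var
        names = list(merged.columns) + ["residual"]
        acc = {name: 0.0 for name in names}
        rows = []
        for j in range(k):
            comps = (
                _vc_one_pc(scores[:, j], merged)
                if merged.shape[1]
                else {"residual": float(np.var(scores[:, j], ddof=1))}
            )
            tot = sum(comps.values())
            shares = {name: comps.get(name, 0.0) / tot if tot > 0 else 0.0 for name in names}
            rows.append({"pc": j + 1, "weight": weights[j], **shares})
            for name in names:
                acc[name] += weights[j] * shares[name]
        if self.weighting == "total":
            acc["residual"] += 1.0 - float(evals[:k].sum() / total_var)
        norm = sum(acc.values())
        proportions = {name: acc[name] / norm for name in names}
        for col in single:
            proportions[col] = 0.0
        return VarianceDecomposition(
            proportions=proportions,
            n_pcs_used=k,
            pc_variance_captured=float(evals[:k].sum() / total_var),
            aliased=aliased,
            per_pc=pd.DataFrame(rows),
        )


def run_pvca(
    matrix,
    factors: pd.DataFrame,
    n_pcs: int = 5,
    **kwargs,
) -> VarianceDecomposition:
    """Convenience wrapper: ``PVCA(matrix, factors, n_pcs, **kwargs).fit()``."""
    return PVCA(matrix, factors, n_pcs=n_pcs, **kwargs).fit()
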