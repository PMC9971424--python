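"""Mutation-selection diagnostics: ENC plot, neutrality plot, grouping.

The ENC plot compares each gene's observed ENC against the value expected
if third-position composition alone drove codon usage,

    ENC_exp = 2 + GC3s + 29 / (GC3s^2 + (1 - GC3s)^2),

genes falling clearly below the curve indicate selection on codon usage.
The neutrality plot regresses GC12 (mean of GC1 and GC2) on GC3; a slope
near 1 indicates dominant mutational pressure, flatter slopes indicate
selection or conservation of GC at the first two positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RegressionFit:
    """Polynomial or linear fit summary. ``coefficients`` are in increasing
    order (intercept first). ``r``/``p_value`` are Pearson on observed vs
    fitted; Spearman rank statistics are carried alongside."""

    coefficients: tuple[float, ...]
    r: float
    p_value: float
    n: int
    residual_sd: float
    spearman_r: float = math.nan
    spearman_p: float = math.nan

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    @property
    def slope(self) -> float:
        return self.coefficients[1]

    def to_dict(self) -> dict:
        return {
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "slope": self.slope if len(self.coefficients) > 1 else math.nan,
            "r": self.r,
            "p_value": self.p_value,
            "spearman_r": self.spearman_r,
            "spearman_p": self.spearman_p,
            "n": self.n,
            "residual_sd": self.residual_sd,
        }


@dataclass
class GroupAssignment:
    labels: pd.Series          # gene -> group label
    boundaries: tuple[float, ...]
    sizes: dict[str, int]


def enc_expected(gc3s):
    """Expected ENC under pure third-position compositional bias."""
    x = np.asarray(gc3s, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("gc3s must lie in [0, 1]")
    val = 2.0 + x + 29.0 / (x * x + (1.0 - x) * (1.0 - x))
    return float(val) if np.isscalar(gc3s) else val


def _polyfit(x: np.ndarray, y: np.ndarray, degree: int) -> RegressionFit:
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    resid = y - fitted
    if np.std(fitted) > 0 and np.std(y) > 0:
        r, p = stats.pearsonr(y, fitted)
    else:
        r, p = math.nan, math.nan
    rho, rho_p = stats.spearmanr(x, y)
    return RegressionFit(tuple(float(c) for c in coeffs), float(r), float(p),
                         len(x), float(np.std(resid)), float(rho), float(rho_p))


def enc_plot(enc_obs, gc3s, groups=None, degree: int = 2):
    """Per-gene deviation from the expected ENC curve plus per-group fits.

    Returns ``(deviations, fits, below_fraction)``: *deviations* is
    ENC_obs − ENC_exp(GC3s) aligned to the input index; *fits* maps group
    label -> polynomial RegressionFit of ENC on GC3s (None when a group has
    fewer than 3 genes); *below_fraction* maps group -> fraction of genes
    strictly below the theoretical curve.
    """
    enc_obs = pd.Series(enc_obs).astype(float)
    gc3s = pd.Series(gc3s).astype(float)
    expected = pd.Series(enc_expected(gc3s.to_numpy()), index=gc3s.index)
    deviations = enc_obs - expected
    if groups is None:
        groups = pd.Series("all", index=enc_obs.index)
    else:
        groups = pd.Series(groups)
    fits: dict[str, RegressionFit | None] = {}
    below: dict[str, float] = {}
    for label, idx in groups.groupby(groups).groups.items():
        x = gc3s.loc[idx]
        y = enc_obs.loc[idx]
        ok = x.notna() & y.notna()
        x, y = x[ok].to_numpy(), y[ok].to_numpy()
        below[label] = float((y < enc_expected(x)).mean()) if len(y) else math.nan
        fits[label] = _polyfit(x, y, degree) if len(y) >= 3 else None
    return deviations, fits, below


def neutrality_fit(gc12_values, gc3_values) -> RegressionFit:
    """OLS of GC12 on GC3 with Spearman rank correlation alongside."""
    x = np.asarray(gc3_values, dtype=float)
    y = np.asarray(gc12_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        rho, rho_p = math.nan, math.nan
    else:
        rho, rho_p = stats.spearmanr(x, y)
    if np.std(x) == 0:
        return RegressionFit((float(np.mean(y)), math.nan), math.nan, math.nan,
                             len(x), float(np.std(y)), float(rho), float(rho_p))
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return RegressionFit((float(res.intercept), float(res.slope)),
                         float(res.rvalue), float(res.pvalue), len(x),
                         float(np.std(resid)), float(rho), float(rho_p))


def compare_slopes(x_a, y_a, x_b, y_b) -> float:
    """Two-sided p for equal slopes via the interaction term of a pooled OLS
    (y ~ x * group)."""
    import statsmodels.api as sm

    x_a, y_a = np.asarray(x_a, float), np.asarray(y_a, float)
    x_b, y_b = np.asarray(x_b, float), np.asarray(y_b, float)
    if len(x_a) < 3 or len(x_b) < 3:
        raise ValueError("each group needs at least 3 points")
    x = np.concatenate([x_a, x_b])
    g = np.concatenate([np.zeros(len(x_a)), np.ones(len(x_b))])
    y = np.concatenate([y_a, y_b])
    X = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[3])


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, p)."""
    rho, p = stats.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(rho), float(p)


def make_groups(values, thresholds, matched_sizes=None) -> GroupAssignment:
    """Band values by strictly decreasing thresholds (upper edges closed:
    the first band is ``>= t0``, then ``t0 > v >= t1`` ... last ``< t_last``).

    With *matched_sizes*, values are instead rank-ordered (descending,
    stable) and cut so group sizes equal the template exactly; the template
    must sum to the number of values.
    """
    values = pd.Series(values).astype(float)
    thresholds = tuple(float(t) for t in thresholds)
    if any(a <= b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    names = [f">={thresholds[0]:g}"]
    names += [f"{a:g}-{b:g}" for a, b in zip(thresholds, thresholds[1:])]
    names += [f"<{thresholds[-1]:g}"]

    if matched_sizes is not None:
        matched_sizes = [int(s) for s in matched_sizes]
        if len(matched_sizes) != len(names):
            raise ValueError("matched_sizes length must equal number of bands")
        if sum(matched_sizes) != len(values):
            raise ValueError(
                f"matched_sizes sum {sum(matched_sizes)} != n values {len(values)}")
        order = values.sort_values(ascending=False, kind="stable").index
        labels = pd.Series(index=values.index, dtype=object)
        start = 0
        for name, size in zip(names, matched_sizes):
            labels.loc[order[start : start + size]] = name
            start += size
    else:
        # ties at a boundary go to the higher band (>= comparison)
        def band(v: float) -> str:
            for name, t in zip(names, thresholds):
                if v >= t:
                    return name
            return names[-1]

        labels = values.map(band)

    sizes = labels.value_counts().to_dict()
    return GroupAssignment(labels, thresholds, {n: sizes.get(n, 0) for n in names})
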