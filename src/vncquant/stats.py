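"""The statistical policy of the pipeline as a small, test-covered layer.

Two-group comparisons are gated on normality: each group is tested with
Shapiro-Wilk at ``alpha_normality``; if both pass, a two-tailed unpaired
t-test is used, otherwise a two-tailed Mann-Whitney U. More than two groups
use Kruskal-Wallis with Dunn's pairwise z-tests under a Bonferroni family
correction. File-name blinding is deterministic given a seed and losslessly
reversible via the key table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = [
    "TestReport",
    "LinearFit",
    "blind_labels",
    "unblind_labels",
    "compare_two_groups",
    "compare_multi_groups",
    "linear_fit",
]


@dataclass
class TestReport:
    """Outcome of one statistical comparison, with the normality gate that
    selected the test recorded alongside the result."""

    test_name: str  # t_test_two_tailed | mann_whitney | kruskal_wallis_dunn
    statistic: float
    p_value: float
    n_per_group: list[int]
    gate: dict = field(default_factory=dict)  # shapiro p per group + alpha used
    dunn: pd.DataFrame | None = None  # pairwise table for multi-group tests

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": self.n_per_group,
            "gate": self.gate,
        }
        if self.dunn is not None:
            d["dunn"] = self.dunn.to_dict(orient="records")
        return d


def blind_labels(file_names: list[str], seed: int) -> tuple[list[str], pd.DataFrame]:
    """Assign deterministic shuffled pseudonyms to file names.

    Pseudonyms carry no substring of any original name, the assignment order
    is a seeded permutation, and the returned key table maps back losslessly.
    """
    names = list(file_names)
    if len(set(names)) != len(names):
        raise ConfigurationError("file names must be unique for blinding")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    codes = []
    seen = set()
    while len(codes) < len(names):
        code = "blind_" + "".join(rng.choice(list("0123456789abcdef"), size=8))
        if code in seen or any(orig in code for orig in names):
            continue
        seen.add(code)
        codes.append(code)
    blinded = [codes[int(order[i])] for i in range(len(names))]
    key = pd.DataFrame({"original": names, "blinded": blinded})
    return blinded, key


def unblind_labels(blinded: list[str], key: pd.DataFrame) -> list[str]:
    mapping = dict(zip(key["blinded"], key["original"]))
    return [mapping[b] for b in blinded]


def _as_samples(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if len(arr) < 3:
        raise ConfigurationError(f"insufficient samples for normality gate in group {name} (n >= 3 required)")
    return arr


def compare_two_groups(a, b, alpha_normality: float = 0.05) -> TestReport:
    """Normality-gated two-group comparison (see module docstring)."""
    a = _as_samples(a, "a")
    b = _as_samples(b, "b")
    gate: dict = {"alpha": alpha_normality}
    normal = True
    for label, sample in (("a", a), ("b", b)):
        if np.ptp(sample) == 0:
            # Shapiro-Wilk is undefined on constant data; constants are
            # trivially non-normal for gating purposes
            gate[f"shapiro_p_{label}"] = 0.0
            normal = False
            continue
        p = float(sps.shapiro(sample).pvalue)
        gate[f"shapiro_p_{label}"] = p
        normal = normal and (p > alpha_normality)
    if normal:
        res = sps.ttest_ind(a, b)
        name = "t_test_two_tailed"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return TestReport(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=[len(a), len(b)],
        gate=gate,
    )


def _dunn_table(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction and
    Bonferroni family adjustment."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "z": float(z),
                    "p_unadjusted": float(p),
                    "p_adjusted": float(min(1.0, p * m)),
                }
            )
    return pd.DataFrame(rows)


def compare_multi_groups(groups: list) -> TestReport:
    """Kruskal-Wallis omnibus test with Dunn's pairwise comparisons."""
    if len(groups) < 3:
        raise ConfigurationError("fewer than 3 groups: use compare_two_groups")
    arrs = [_as_samples(g, str(i)) for i, g in enumerate(groups)]
    h, p = sps.kruskal(*arrs)
    return TestReport(
        test_name="kruskal_wallis_dunn",
        statistic=float(h),
        p_value=float(p),
        n_per_group=[len(g) for g in arrs],
        dunn=_dunn_table(arrs),
    )


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    conf_band: pd.DataFrame  # x, fit, ci_low, ci_high (95% on the mean)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares with R² and a 95% confidence band on the mean."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ConfigurationError("linear_fit requires >= 3 paired points")
    if np.ptp(x) == 0:
        raise ConfigurationError("x is constant: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    xs = np.sort(x)
    pred = model.get_prediction(sm.add_constant(xs))
    ci = pred.conf_int(alpha=0.05)
    band = pd.DataFrame(
        {"x": xs, "fit": pred.predicted_mean, "ci_low": ci[:, 0], "ci_high": ci[:, 1]}
    )
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        conf_band=band,
    )
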