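"""qPCR relative expression (ΔCt), microarray/qPCR concordance, and post-ANOVA
95% LSD letter grouping.

Relative expression follows the plain ΔCt method with an assumed amplification
efficiency of 2 per cycle: 2**-(Ct_target - Ct_reference) against a
constitutive reference gene (olive actin in the study).  Technical triplicates
are averaged at the Ct level; biological replicates are summarized after the
transform on the log2 scale.

Concordance between platform log2 ratios uses Pearson r with the analytic
critical value r_c = t / sqrt(t^2 + df), df = n - 2, where t is the Student
quantile at the chosen alpha (single-tailed by default, which reproduces the
conventional table value 0.708 at n = 12, alpha = 0.005).

Per-seedling group comparisons run a one-way ANOVA followed, when significant,
by Fisher's least-significant-difference multiple range test at 95%, reported
as compact letters: groups sharing a letter are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_expression",
    "summarize_ct_table",
    "pearson_critical_value",
    "concordance",
    "ConcordanceReport",
    "LsdGrouping",
    "anova_lsd",
]


def relative_expression(ct_target: float | Sequence[float], ct_reference: float | Sequence[float]) -> float:
    """ΔCt relative expression 2**-(mean Ct_target - mean Ct_reference).

    Sequences are technical replicates and are averaged at the Ct level first.
    """
    ct_t = np.atleast_1d(np.asarray(ct_target, dtype=float))
    ct_r = np.atleast_1d(np.asarray(ct_reference, dtype=float))
    if ct_r.size == 0:
        raise ValueError("missing reference Ct values")
    if ct_t.size == 0:
        raise ValueError("missing target Ct values")
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r))):
        raise ValueError("Ct values must be finite")
    if np.any(ct_t <= 0) or np.any(ct_r <= 0):
        raise ValueError("Ct values must be positive")
    delta = float(ct_t.mean() - ct_r.mean())
    return float(2.0 ** (-delta))


def summarize_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, gene): biological-replicate mean log2 relative expression.

    Input columns: sample, biological_rep, gene, tech_rep, ct_target,
    ct_reference.  Technical replicates average at Ct level within each
    biological replicate; biological replicates then average on the log2
    scale (preserving the geometric structure of ratios).
    """
    required = {"sample", "biological_rep", "gene", "tech_rep", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for (sample, gene, bio), sub in ct.groupby(["sample", "gene", "biological_rep"], sort=True):
        rel = relative_expression(sub["ct_target"], sub["ct_reference"])
        rows.append((sample, gene, bio, rel, np.log2(rel), len(sub)))
    per_bio = pd.DataFrame(
        rows, columns=["sample", "gene", "biological_rep", "relative_expression", "log2_rel", "n_technical"]
    )
    agg = (
        per_bio.groupby(["sample", "gene"], sort=True)
        .agg(
            mean_log2_rel=("log2_rel", "mean"),
            sd_log2_rel=("log2_rel", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            n_biological=("log2_rel", "size"),
        )
        .reset_index()
    )
    agg.attrs["per_biological"] = per_bio
    return agg


def pearson_critical_value(n: int, alpha: float = 0.005, tails: int = 1) -> float:
    """Analytic Pearson critical value r_c = t/sqrt(t^2 + df), df = n - 2."""
    if n < 3:
        raise ValueError("need n >= 3 for a defined critical value")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 2
    t = stats.t.ppf(1.0 - alpha / tails, df)
    return float(t / np.sqrt(t * t + df))


@dataclass(frozen=True)
class ConcordanceReport:
    n: int
    r: float
    r_critical: float
    alpha: float
    tails: int
    significant: bool

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.r,
            "r_critical": self.r_critical,
            "alpha": self.alpha,
            "tails": self.tails,
            "significant": self.significant,
        }


def concordance(
    log2_ratios_qpcr: Sequence[float],
    log2_ratios_array: Sequence[float],
    alpha: float = 0.005,
    tails: int = 1,
) -> ConcordanceReport:
    """Pearson concordance of paired platform log2 ratios against the analytic
    critical value; significant iff |r| > r_critical."""
    x = np.asarray(log2_ratios_qpcr, dtype=float)
    y = np.asarray(log2_ratios_array, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-d lists of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one platform's ratios; r undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r_c = pearson_critical_value(x.size, alpha=alpha, tails=tails)
    return ConcordanceReport(n=x.size, r=r, r_critical=r_c, alpha=alpha, tails=tails, significant=abs(r) > r_c)


@dataclass(frozen=True)
class LsdGrouping:
    groups: tuple[str, ...]  # ordered by descending mean
    means: tuple[float, ...]
    ns: tuple[int, ...]
    f_statistic: float
    p_value: float
    alpha: float
    mse: float
    df_error: int
    letters: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "mean": self.means,
                "n": self.ns,
                "letters": [self.letters[g] for g in self.groups],
            }
        )


def _lsd_threshold(alpha: float, df_error: int, mse: float, n_i: int, n_j: int) -> float:
    t = stats.t.ppf(1.0 - alpha / 2.0, df_error)
    return float(t * np.sqrt(mse * (1.0 / n_i + 1.0 / n_j)))


def anova_lsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> LsdGrouping:
    """One-way ANOVA with Fisher LSD letter grouping at 1 - alpha.

    If the ANOVA is not significant at ``alpha`` all groups share one letter.
    Otherwise pairwise differences are declared where |mean_i - mean_j|
    exceeds LSD = t_{alpha/2, df_err} * sqrt(MSE*(1/n_i + 1/n_j)), and letters
    are assigned by a descending-mean sweep so that groups sharing a letter
    are mutually non-significant.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    n_total = sum(v.size for v in data.values())
    k = len(names)
    df_error = n_total - k
    if df_error <= 0:
        raise ValueError("zero error degrees of freedom")

    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    ms_between = ss_between / (k - 1)
    mse = ss_within / df_error
    if mse == 0.0 and ms_between == 0.0:
        f_stat, p = 0.0, 1.0
    elif mse == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = float(ms_between / mse)
        p = float(stats.f.sf(f_stat, k - 1, df_error))

    order = sorted(names, key=lambda g: -data[g].mean())
    means = {g: float(data[g].mean()) for g in names}
    ns = {g: int(data[g].size) for g in names}

    if p >= alpha:
        letters = {g: "a" for g in names}
    else:
        def differs(g1: str, g2: str) -> bool:
            lsd = _lsd_threshold(alpha, df_error, mse, ns[g1], ns[g2])
            return abs(means[g1] - means[g2]) > lsd

        # descending-mean sweep: each maximal run of mutually non-different
        # groups gets the next letter
        letter_sets: list[set[str]] = []
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and all(
                not differs(order[m], order[j + 1]) for m in range(i, j + 1)
            ):
                j += 1
            run = set(order[i:j + 1])
            if not letter_sets or not run <= letter_sets[-1]:
                letter_sets.append(run)
            if j == len(order) - 1:
                break
            i += 1
        letters = {
            g: "".join(
                chr(ord("a") + idx) for idx, s in enumerate(letter_sets) if g in s
            )
            for g in names
        }

    return LsdGrouping(
        groups=tuple(order),
        means=tuple(means[g] for g in order),
        ns=tuple(ns[g] for g in order),
        f_statistic=f_stat,
        p_value=p,
        alpha=alpha,
        mse=float(mse),
        df_error=df_error,
        letters=letters,
    )
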