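"""Normality-gated group comparisons for embryo features.

Each feature is first tested for normality per group with the Lilliefors
test (5% significance); a feature counts as normal only if *every* group
passes.  Non-normal features are compared with a Kruskal–Wallis omnibus
test (0.1% significance) followed by Dunn's pairwise test with Holm
p-value adjustment; normal features get a Levene variance check, one-way
ANOVA and pairwise Student t-tests with Holm adjustment.  The TE-vs-ICM
dry-mass-density comparison uses Kruskal–Wallis at α = 1e−4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors
from statsmodels.stats.multitest import multipletests

ALPHA_NORMALITY = 0.05
ALPHA_KRUSKAL = 0.001
ALPHA_ANOVA = 0.001
ALPHA_TE_ICM = 1e-4


@dataclass
class GroupComparison:
    feature: str
    groups: list[str]
    normality_pvalues: dict[str, float]
    all_normal: bool
    branch: str  # "KW+Dunn-Holm" or "ANOVA+t-Holm"
    levene_p: float | None
    omnibus_stat: float
    omnibus_p: float
    alpha: float
    significant: bool
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: group_a, group_b, raw_p, adjusted_p, significant


def normality_gate(
    samples: dict[str, np.ndarray], alpha: float = ALPHA_NORMALITY
) -> tuple[dict[str, float], bool]:
    """Per-group Lilliefors verdicts; normal iff every group passes.

    Constant (zero-variance) samples are degenerate and reported with
    p = 0 (rejected).
    """
    pvals: dict[str, float] = {}
    for name, x in samples.items():
        x = np.asarray(x, dtype=float)
        if len(x) < 4:
            raise ValueError(f"group {name!r} too small for a normality test")
        if np.ptp(x) == 0.0:
            pvals[name] = 0.0
            continue
        _, p = _lilliefors(x, dist="norm")
        pvals[name] = float(p)
    return pvals, all(p > alpha for p in pvals.values())


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-test on mean ranks with tie-corrected variance, Holm-adjusted."""
    names = list(samples)
    values = np.concatenate([np.asarray(samples[g], float) for g in names])
    sizes = {g: len(samples[g]) for g in names}
    ranks = sps.rankdata(values)
    n = len(values)
    mean_ranks = {}
    pos = 0
    for g in names:
        mean_ranks[g] = ranks[pos : pos + sizes[g]].mean()
        pos += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(dict(group_a=a, group_b=b, statistic=z, raw_p=p))
    return pd.DataFrame(rows)


def _t_pairwise(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for a, b in combinations(list(samples), 2):
        t, p = sps.ttest_ind(samples[a], samples[b])
        rows.append(dict(group_a=a, group_b=b, statistic=float(t), raw_p=float(p)))
    return pd.DataFrame(rows)


def _kruskal_safe(*groups):
    """Kruskal–Wallis with a guard for fully tied (constant) data."""
    if np.ptp(np.concatenate(groups)) == 0.0:
        return 0.0, 1.0
    return sps.kruskal(*groups)


def compare_groups(
    samples: dict[str, np.ndarray],
    feature: str = "feature",
    alpha_nonnormal: float = ALPHA_KRUSKAL,
    alpha_normal: float = ALPHA_ANOVA,
    alpha_normality: float = ALPHA_NORMALITY,
    branch: str = "auto",
) -> GroupComparison:
    """Normality-gated omnibus + post-hoc comparison across ≥ 2 groups.

    ``branch`` may force ``"kw"`` (Kruskal–Wallis + Dunn-Holm) or
    ``"anova"`` (Levene + ANOVA + t-Holm) instead of the Lilliefors gate.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for g, x in samples.items():
        if len(np.asarray(x)) == 0:
            raise ValueError(f"group {g!r} is empty")
    arrays = {g: np.asarray(x, dtype=float) for g, x in samples.items()}
    pvals, all_normal = normality_gate(arrays, alpha_normality)
    if branch == "kw":
        all_normal = False
    elif branch == "anova":
        all_normal = True
    elif branch != "auto":
        raise ValueError("branch must be 'auto', 'kw' or 'anova'")

    if all_normal:
        branch = "ANOVA+t-Holm"
        alpha = alpha_normal
        levene_p = float(sps.levene(*arrays.values())[1])
        stat, p = sps.f_oneway(*arrays.values())
        pairwise = _t_pairwise(arrays)
    else:
        branch = "KW+Dunn-Holm"
        alpha = alpha_nonnormal
        levene_p = None
        stat, p = _kruskal_safe(*arrays.values())
        pairwise = _dunn_pairwise(arrays)

    if len(pairwise):
        _, adj, _, _ = multipletests(pairwise["raw_p"], method="holm")
        pairwise = pairwise.assign(
            adjusted_p=adj, significant=adj < alpha
        )
    return GroupComparison(
        feature=feature,
        groups=list(arrays),
        normality_pvalues=pvals,
        all_normal=all_normal,
        branch=branch,
        levene_p=levene_p,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
        pairwise=pairwise,
    )


def te_icm_test(records: pd.DataFrame, alpha: float = ALPHA_TE_ICM) -> GroupComparison:
    """Kruskal–Wallis comparison of nuclear dry-mass density, TE vs ICM.

    ``records`` needs ``compartment`` and ``dmd_pg_um3`` columns.  An
    empty compartment is reported as not-testable (omnibus p = NaN).
    """
    te = records.loc[records.compartment == "TE", "dmd_pg_um3"].to_numpy()
    icm = records.loc[records.compartment == "ICM", "dmd_pg_um3"].to_numpy()
    if len(te) == 0 or len(icm) == 0:
        return GroupComparison(
            feature="dmd_pg_um3",
            groups=["TE", "ICM"],
            normality_pvalues={},
            all_normal=False,
            branch="KW+Dunn-Holm",
            levene_p=None,
            omnibus_stat=float("nan"),
            omnibus_p=float("nan"),
            alpha=alpha,
            significant=False,
        )
    stat, p = _kruskal_safe(te, icm)
    return GroupComparison(
        feature="dmd_pg_um3",
        groups=["TE", "ICM"],
        normality_pvalues={},
        all_normal=False,
        branch="KW+Dunn-Holm",
        levene_p=None,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
    )


def comparison_report(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flat report table: feature, branch, omnibus p, pairwise adjusted p."""
    rows = []
    for c in comparisons:
        base = dict(
            feature=c.feature,
            branch=c.branch,
            omnibus_stat=c.omnibus_stat,
            omnibus_p=c.omnibus_p,
            alpha=c.alpha,
            significant=c.significant,
        )
        if len(c.pairwise):
            for _, pr in c.pairwise.iterrows():
                rows.append(
                    base
                    | dict(
                        pair=f"{pr.group_a}-{pr.group_b}",
                        raw_p=pr.raw_p,
                        adjusted_p=pr.adjusted_p,
                        pair_significant=bool(pr.significant),
                    )
                )
        else:
            rows.append(base)
    return pd.DataFrame(rows)
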