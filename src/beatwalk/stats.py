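"""Extreme-group construction and group comparisons.

The ten songs with the highest mean normalized walking speed form the
"activating" group, the ten lowest the "relaxing" group, and the ten
ranks centered on the median form the "neutral" group.  Group effects on
speed are tested with one-way ANOVA plus Scheffe post-hoc contrasts;
sonic features are compared between the activating and relaxing groups
with two-sample t-tests, and bipolar-adjective ratings with Mann-Whitney
U tests.  Raw p-values are reported as primary (matching the analysis
style of small-n music-and-movement studies); a Holm-adjusted column is
added alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InsufficientDataError

#: The nine bipolar adjective pairs (rated 0-100, first adjective = 0).
ADJECTIVE_PAIRS = (
    "good-bad",
    "happy-sad",
    "tender-aggressive",
    "soft-loud",
    "slow-fast",
    "moving-static",
    "stuttering-flowing",
    "easy-difficult",
    "known-unknown",
)

GROUP_SIZE = 10


@dataclass
class GroupAssignment:
    """Disjoint activating / relaxing / neutral groups of 10 songs each.

    ``activating`` is ranked fastest first (the analog of a1..a10) and
    ``relaxing`` slowest first (r1..r10).
    """

    activating: list
    relaxing: list
    neutral: list

    def __post_init__(self) -> None:
        sets = [set(self.activating), set(self.relaxing), set(self.neutral)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("groups must be pairwise disjoint")


def extreme_groups(speeds: pd.Series | pd.DataFrame) -> GroupAssignment:
    """Select the 10 fastest, 10 slowest, and 10 most middle-ranked songs.

    ``speeds`` is a per-song v_s Series (or a SpeedTable DataFrame with a
    ``v_s`` column).  Ties across boundaries are broken deterministically
    by song id.  The neutral group is the 10 ranks centered on the median
    rank (ranks 22-31 of 52).
    """
    if isinstance(speeds, pd.DataFrame):
        speeds = speeds["v_s"]
    if len(speeds) < 3 * GROUP_SIZE:
        raise InsufficientDataError(
            f"need at least {3 * GROUP_SIZE} songs, got {len(speeds)}"
        )
    # ascending by v_s, deterministic tie-break on song id
    order = speeds.iloc[np.lexsort((speeds.index.astype(str), speeds.to_numpy()))]
    ids = list(order.index)
    n = len(ids)
    relaxing = ids[:GROUP_SIZE]
    activating = ids[-GROUP_SIZE:][::-1]
    start = (n - GROUP_SIZE) // 2
    neutral = ids[start : start + GROUP_SIZE]
    return GroupAssignment(activating=activating, relaxing=relaxing, neutral=neutral)


def _group_values(table, groups: GroupAssignment):
    if isinstance(table, pd.DataFrame) and "v_s" in table.columns:
        table = table["v_s"]
    a = table.loc[groups.activating]
    r = table.loc[groups.relaxing]
    n = table.loc[groups.neutral]
    return a, r, n


def speed_anova(speeds, groups: GroupAssignment) -> dict:
    """One-way ANOVA on v_s over the three groups plus Scheffe contrasts.

    Returns F, its degrees of freedom, p, per-group means, and a
    ``scheffe`` dict of pairwise contrast p-values.  Zero within-group
    variance is flagged rather than raising.
    """
    a, r, n = _group_values(speeds, groups)
    samples = {"activating": a.to_numpy(), "relaxing": r.to_numpy(), "neutral": n.to_numpy()}
    k = len(samples)
    N = sum(len(v) for v in samples.values())
    degenerate = all(np.ptp(v) == 0 for v in samples.values())
    if degenerate:
        return {
            "F": 0.0, "p": 1.0, "df": (k - 1, N - k),
            "means": {g: float(v.mean()) for g, v in samples.items()},
            "scheffe": {}, "degenerate_variance": True,
        }
    F, p = sps.f_oneway(*samples.values())
    grand = np.concatenate(list(samples.values()))
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    ms_within = ss_within / (N - k)
    scheffe = {}
    names = list(samples)
    for i in range(k):
        for j in range(i + 1, k):
            v1, v2 = samples[names[i]], samples[names[j]]
            diff = v1.mean() - v2.mean()
            if ms_within > 0:
                t2 = diff**2 / (ms_within * (1 / len(v1) + 1 / len(v2)))
                f_contrast = t2 / (k - 1)
                p_pair = float(sps.f.sf(f_contrast, k - 1, N - k))
            else:
                p_pair = 0.0 if diff != 0 else 1.0
            scheffe[f"{names[i]}_vs_{names[j]}"] = {
                "diff": float(diff),
                "p": p_pair,
            }
    return {
        "F": float(F),
        "p": float(p),
        "df": (k - 1, N - k),
        "means": {g: float(v.mean()) for g, v in samples.items()},
        "scheffe": scheffe,
        "degenerate_variance": False,
    }


def feature_ttests(
    song_features: pd.DataFrame, groups: GroupAssignment,
    feature_names: list | None = None,
) -> pd.DataFrame:
    """Two-sample t-tests (activating vs relaxing) per sonic feature.

    Returns a DataFrame with t, raw p, Holm-adjusted p, the group means,
    and a ``degenerate`` flag for features with zero pooled variance.
    """
    cols = feature_names if feature_names is not None else list(song_features.columns)
    a = song_features.loc[groups.activating, cols]
    r = song_features.loc[groups.relaxing, cols]
    rows = []
    for c in cols:
        x, z = a[c].to_numpy(), r[c].to_numpy()
        if np.ptp(x) == 0 and np.ptp(z) == 0:
            rows.append({"feature": c, "t": 0.0, "p": 1.0,
                         "mean_activating": float(x.mean()),
                         "mean_relaxing": float(z.mean()), "degenerate": True})
            continue
        t, p = sps.ttest_ind(x, z)
        rows.append({"feature": c, "t": float(t), "p": float(p),
                     "mean_activating": float(x.mean()),
                     "mean_relaxing": float(z.mean()), "degenerate": False})
    out = pd.DataFrame(rows).set_index("feature")
    out["p_holm"] = multipletests(out["p"].to_numpy(), method="holm")[1]
    return out


def ratings_tests(
    ratings: pd.DataFrame, groups: GroupAssignment, method: str = "auto"
) -> pd.DataFrame:
    """Mann-Whitney U per adjective pair, activating vs relaxing groups.

    ``method`` is passed to scipy ("exact", "asymptotic" or "auto").
    All-tied ratings are flagged.  For two n=10 groups U + U' = 100.
    """
    a = ratings.loc[ratings.index.isin(groups.activating)]
    r = ratings.loc[ratings.index.isin(groups.relaxing)]
    rows = []
    for adj in ratings.columns:
        x, z = a[adj].to_numpy(), r[adj].to_numpy()
        if np.ptp(np.concatenate([x, z])) == 0:
            rows.append({"adjective": adj, "U": len(x) * len(z) / 2.0,
                         "p": 1.0, "all_tied": True})
            continue
        U, p = sps.mannwhitneyu(x, z, alternative="two-sided", method=method)
        rows.append({"adjective": adj, "U": float(U), "p": float(p),
                     "all_tied": False})
    out = pd.DataFrame(rows).set_index("adjective")
    out["p_holm"] = multipletests(out["p"].to_numpy(), method="holm")[1]
    return out
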