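"""Group-comparison statistics: the decile-based TF DNA-binding variability
index, Kruskal-Wallis with a Dunn post-hoc compact letter display, and the
two-way ANOVA used for rhythm-amplitude (max/min) comparisons.

The variability index summarizes how differently a transcription factor
binds across the four transcriptional-output groups: for each decile
d = 0.1..0.9 of the within-group signal distributions, the standard
deviation of the group deciles is divided by their mean (dispersion grows
with signal level, so each decile is normalized by its own scale), and the
nine normalized dispersions are summed.  Identical group distributions
give index 0; the index is invariant to a global rescaling of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VariabilityResult",
    "variability_index",
    "dunn_test",
    "compact_letter_display",
    "kruskal_letters",
    "amplitude_anova",
    "core_clock_genes",
]

DEFAULT_DECILES = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass(frozen=True)
class VariabilityResult:
    tf_name: str
    deciles: tuple[float, ...]
    group_deciles: pd.DataFrame      # rows = deciles, columns = groups
    decile_sd: np.ndarray            # sample SD (ddof=1) across groups per decile
    decile_mean: np.ndarray
    normalized_dispersion: np.ndarray
    variability_index: float
    undefined: bool = False          # any decile mean was 0


def variability_index(
    grouped: Mapping[str, Sequence[float]],
    deciles: Sequence[float] = DEFAULT_DECILES,
    tf_name: str = "",
) -> VariabilityResult:
    """Decile-dispersion variability index across signal groups.

    ``grouped`` maps group name -> per-peak signal values (each group needs
    >= 10 values so the deciles are meaningful).  Deciles use the linear-
    interpolation quantile; the across-group spread is the sample (n-1)
    standard deviation.
    """
    if len(grouped) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in grouped.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
        if len(vals) < 10:
            raise ValueError(f"group {name!r} has {len(vals)} values; >= 10 required")

    q = pd.DataFrame(
        {
            name: np.quantile(np.asarray(vals, dtype=float), deciles)
            for name, vals in grouped.items()
        },
        index=list(deciles),
    )
    sd = q.std(axis=1, ddof=1).to_numpy()
    mean = q.mean(axis=1).to_numpy()
    undefined = bool(np.any(mean == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean == 0, np.nan, sd / mean)
    vi = float(np.nan) if undefined else float(disp.sum())
    return VariabilityResult(
        tf_name, tuple(deciles), q, sd, mean, disp, vi, undefined
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn post-hoc + compact letter display
# ---------------------------------------------------------------------------

def dunn_test(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's pairwise rank-sum z tests after Kruskal-Wallis, with the
    tie-corrected pooled variance; returns one row per pair with the raw
    two-sided p-value."""
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    i = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[i : i + v.size].mean()
        sizes[name] = v.size
        i += v.size
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "pvalue": p})
    return pd.DataFrame(rows)


def compact_letter_display(
    names: Sequence[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display: groups sharing a letter are
    not significantly different."""
    sig = {frozenset(p) for p in significant_pairs}
    letter_sets: list[set[str]] = []
    seen: list[str] = []
    for name in names:
        placed = False
        for s in letter_sets:
            if all(frozenset((name, other)) not in sig for other in s):
                s.add(name)
                placed = True
        if not placed:
            # start a new set seeded with every earlier group compatible
            # with this one (plain insertion would orphan those pairs)
            new = {name} | {
                g for g in seen if frozenset((name, g)) not in sig
            }
            letter_sets.append(new)
        seen.append(name)
    # absorb subsets
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, s in zip(alphabet, letter_sets):
        for name in names:
            if name in s:
                out[name] += letter
    return out


def kruskal_letters(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[float, dict[str, str], pd.DataFrame]:
    """Kruskal-Wallis omnibus test with Dunn/Benjamini-Hochberg post-hoc
    letters.  Returns (omnibus p, per-group letters, pairwise table).

    When the omnibus test does not reject at ``alpha`` (or every value is
    tied) all groups share the letter 'a'.
    """
    from statsmodels.stats.multitest import multipletests

    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")

    values = [np.asarray(groups[n], dtype=float) for n in names]
    if np.unique(np.concatenate(values)).size == 1:
        pairs = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "z": 0.0, "pvalue": 1.0, "pvalue_adj": 1.0}
                for a, b in combinations(names, 2)
            ]
        )
        return 1.0, {n: "a" for n in names}, pairs

    omnibus = float(sps.kruskal(*values).pvalue)
    pairs = dunn_test(groups)
    pairs["pvalue_adj"] = multipletests(pairs["pvalue"], method="fdr_bh")[1]

    if omnibus >= alpha:
        letters = {n: "a" for n in names}
    else:
        sig = {
            (r.group_a, r.group_b)
            for r in pairs.itertuples()
            if r.pvalue_adj < alpha
        }
        letters = compact_letter_display(names, sig)
    return omnibus, letters, pairs


def amplitude_anova(table: pd.DataFrame) -> pd.Series:
    """Two-way ANOVA of per-replicate rhythm extrema.

    ``table`` has columns (group, extremum, value) where extremum is
    'max'/'min' per replicate rhythm.  Returns p-values indexed
    'group', 'extremum', 'group:extremum' from the type-II ANOVA table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"group", "extremum", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    cells = table.groupby(["group", "extremum"]).size()
    if (cells < 1).any() or cells.empty:
        raise ValueError("every (group, extremum) cell needs >= 1 observation")

    model = smf.ols("value ~ C(group) * C(extremum)", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return pd.Series(
        {
            "group": float(anova.loc["C(group)", "PR(>F)"]),
            "extremum": float(anova.loc["C(extremum)", "PR(>F)"]),
            "group:extremum": float(anova.loc["C(group):C(extremum)", "PR(>F)"]),
        }
    )


def core_clock_genes() -> list[str]:
    """The editable exclusion list of core and core-associated clock genes
    shipped with the package (used for 'non-core-clock' re-analyses)."""
    text = resources.files("circout.data").joinpath("core_clock_genes.txt").read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
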