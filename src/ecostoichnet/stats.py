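"""Treatment-level statistics: one-way ANOVA, protected Fisher LSD letters, PCA.

Group differences are tested variable by variable with a one-way ANOVA over
the four stand types followed, only when the omnibus F is significant, by
Fisher's least-significant-difference pairwise comparisons at the same alpha
("protected" LSD). Results are rendered as compact letter displays: groups
sharing a letter are not significantly different, and letters start at 'a'
on the group with the highest mean.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float


def _split_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    out = {g: values[groups == g] for g in pd.unique(groups)}
    if len(out) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g, v in out.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return out


def one_way_anova(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA from explicit sums of squares."""
    by_group = _split_groups(values, groups)
    all_vals = np.concatenate(list(by_group.values()))
    grand = all_vals.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in by_group.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    dfb = len(by_group) - 1
    dfw = all_vals.size - len(by_group)
    if ssw == 0:
        raise ValueError("zero within-group variance: F undefined")
    msb, msw = ssb / dfb, ssw / dfw
    F = msb / msw
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(F=float(F), p=p, df_between=dfb, df_within=dfw, ms_within=float(msw))


def _compact_letters(order: list[str], distinct: set[frozenset]) -> dict[str, str]:
    """Compact letter display from the set of significantly different pairs.

    Letters are the maximal cliques of the non-significance graph, ordered by
    their best-ranked member so the highest-mean group receives 'a'.
    """
    g = nx.Graph()
    g.add_nodes_from(order)
    for a in order:
        for b in order:
            if a < b and frozenset((a, b)) not in distinct:
                g.add_edge(a, b)
    rank = {name: i for i, name in enumerate(order)}
    cliques = [sorted(c, key=rank.get) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: min(rank[m] for m in c))
    letters: dict[str, str] = {name: "" for name in order}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for member in clique:
            letters[member] += letter
    return {name: "".join(sorted(lets)) for name, lets in letters.items()}


def fisher_lsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Protected Fisher LSD with compact letter display.

    Pairwise comparisons use the pooled within-group mean square from the
    omnibus ANOVA: groups i, j differ when |mean_i - mean_j| exceeds
    t(1-alpha/2, df_within) * sqrt(MSW (1/n_i + 1/n_j)). If the omnibus test
    is not significant at ``alpha`` all groups share the letter 'a'.

    Returns a DataFrame indexed by group with columns mean, sd, n, letter,
    plus the omnibus F and p repeated on every row.
    """
    by_group = _split_groups(values, groups)
    anova = one_way_anova(values, groups)
    order = sorted(by_group, key=lambda g: -by_group[g].mean())
    distinct: set[frozenset] = set()
    if anova.p < alpha:
        tcrit = sps.t.ppf(1 - alpha / 2, anova.df_within)
        for i, a in enumerate(order):
            for b in order[i + 1 :]:
                va, vb = by_group[a], by_group[b]
                lsd = tcrit * np.sqrt(anova.ms_within * (1 / va.size + 1 / vb.size))
                if abs(va.mean() - vb.mean()) > lsd:
                    distinct.add(frozenset((a, b)))
    letters = _compact_letters(order, distinct)
    out = pd.DataFrame(
        {
            "mean": {g: by_group[g].mean() for g in order},
            "sd": {g: by_group[g].std(ddof=1) for g in order},
            "n": {g: by_group[g].size for g in order},
            "letter": letters,
        }
    )
    out.index.name = "group"
    out["F"] = anova.F
    out["p"] = anova.p
    return out


def group_comparison_table(
    wide: pd.DataFrame, treatments: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """ANOVA + LSD letters for every column of a samples x variables table.

    Output is long-format: one row per (variable, treatment) carrying the
    group mean, sd, letter and the variable's omnibus F and p — mirroring the
    conventional "mean ± sd letter" table layout.
    """
    rows = []
    labels = treatments.reindex(wide.index)
    if labels.isna().any():
        missing = sorted(wide.index[labels.isna()])
        raise ValueError(f"samples without treatment labels: {missing}")
    for var in wide.columns:
        res = fisher_lsd(wide[var].to_numpy(), labels.to_numpy(), alpha=alpha)
        res = res.reset_index().rename(columns={"group": "treatment"})
        res.insert(0, "variable", var)
        rows.append(res)
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # variables x components
    variance_fraction: np.ndarray


def pca(matrix: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA by SVD of the centered (optionally standardized) data matrix.

    Component signs are fixed by making the largest-magnitude loading of each
    component positive. Variance fractions sum to 1 over all computed
    components.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            dead = list(matrix.columns[sd == 0])
            raise ValueError(f"zero-variance variables under standardization: {dead}")
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip = np.where(flip == 0, 1.0, flip)
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    var = s**2
    frac = var / var.sum()
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=comp),
        variance_fraction=frac,
    )
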