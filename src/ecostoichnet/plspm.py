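"""Partial least squares path modeling (PLS-PM), statsmodels-style.

A :class:`PLSPathModel` is built from a samples-by-indicators DataFrame, a
block map (latent variable -> its reflective indicators) and a directed
acyclic inner path matrix; :meth:`PLSPathModel.fit` runs the Lohmöller
alternating algorithm and returns a :class:`PLSPathResults` carrying outer
weights, loadings, latent scores, path coefficients, R², communalities and
the goodness-of-fit index, with ``summary()``, ``total_effects()``,
``bootstrap()`` and loading-based pruning hanging off the two objects.

Estimation (mode A, reflective blocks throughout):

1. standardize all indicators; initialize outer weights equal within block;
2. outer step: latent score = standardized weighted sum of its indicators;
3. inner step: each latent's inner estimate is the standardized weighted sum
   of its adjacent latents, with inner weights by scheme — ``centroid``
   (sign of score correlation), ``factorial`` (score correlation) or
   ``path`` (regression coefficients on predecessors, correlations with
   successors);
4. mode-A outer update: weight of indicator x_k on latent j proportional to
   corr(x_k, inner estimate of j);
5. iterate 2-4 until the largest absolute outer-weight change falls below
   ``tol``.

Path coefficients are then the OLS coefficients of each endogenous latent
score on its predecessors' scores; loadings are indicator-score
correlations; communality is the squared loading; GoF is
sqrt(mean communality x mean R²).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

Scheme = Literal["centroid", "factorial", "path"]


@dataclass(frozen=True)
class PLSPMSpec:
    """Block structure and inner path matrix of a PLS path model.

    ``path_matrix`` is a 0/1 DataFrame over latent names, lower-triangular in
    the given latent order: entry (row i, column j) = 1 means latent j is a
    direct predecessor of latent i (arrow j -> i).
    """

    blocks: Mapping[str, Sequence[str]]
    path_matrix: pd.DataFrame
    scheme: Scheme = "path"
    tol: float = 1e-6
    max_iter: int = 300

    def __post_init__(self) -> None:
        latents = list(self.blocks)
        pm = self.path_matrix
        if list(pm.index) != latents or list(pm.columns) != latents:
            raise ValueError("path_matrix index/columns must equal block names, in order")
        arr = pm.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("path_matrix entries must be 0/1")
        if np.triu(arr).any():
            raise ValueError(
                "path_matrix must be strictly lower-triangular in block order (acyclic)"
            )
        seen: dict[str, str] = {}
        for lv, inds in self.blocks.items():
            if len(inds) == 0:
                raise ValueError(f"block {lv!r} has no indicators")
            for ind in inds:
                if ind in seen:
                    raise ValueError(
                        f"indicator {ind!r} appears in blocks {seen[ind]!r} and {lv!r}"
                    )
                seen[ind] = lv
        if self.scheme not in ("centroid", "factorial", "path"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def latents(self) -> list[str]:
        return list(self.blocks)

    @property
    def indicators(self) -> list[str]:
        return [ind for inds in self.blocks.values() for ind in inds]

    @property
    def endogenous(self) -> list[str]:
        pm = self.path_matrix.to_numpy()
        return [lv for i, lv in enumerate(self.latents) if pm[i].any()]

    def predecessors(self, latent: str) -> list[str]:
        row = self.path_matrix.loc[latent]
        return [lv for lv in self.latents if row[lv] == 1]


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column cannot be standardized")
    return (X - X.mean(axis=0)) / sd


class PLSPathModel:
    """PLS path model specification bound to data.

    Parameters
    ----------
    data : DataFrame, samples x indicators (complete, non-constant columns)
    blocks : mapping latent name -> list of indicator columns (mode A)
    path_matrix : lower-triangular 0/1 inner relations (row depends on column)
    scheme : inner weighting scheme, default "path"
    """

    def __init__(
        self,
        data: pd.DataFrame,
        blocks: Mapping[str, Sequence[str]],
        path_matrix: pd.DataFrame,
        scheme: Scheme = "path",
        tol: float = 1e-6,
        max_iter: int = 300,
    ) -> None:
        self.spec = PLSPMSpec(
            blocks={k: list(v) for k, v in blocks.items()},
            path_matrix=path_matrix.astype(int),
            scheme=scheme,
            tol=tol,
            max_iter=max_iter,
        )
        missing = [c for c in self.spec.indicators if c not in data.columns]
        if missing:
            raise ValueError(f"indicators absent from data: {missing}")
        frame = data[self.spec.indicators].astype(float)
        if frame.isna().any().any():
            bad = list(frame.columns[frame.isna().any()])
            raise ValueError(f"indicators with missing values: {bad}")
        n_min = max(len(v) for v in self.spec.blocks.values()) + 2
        if len(frame) < n_min:
            raise ValueError(f"need at least {n_min} samples, got {len(frame)}")
        self.data = frame

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        blocks: Mapping[str, Sequence[str]],
        paths: Sequence[tuple[str, str]],
        **kwargs,
    ) -> "PLSPathModel":
        """Build from an edge list of (source, target) inner paths.

        Latent order is the block order; edges must all point forward in it.
        """
        latents = list(blocks)
        pm = pd.DataFrame(0, index=latents, columns=latents, dtype=int)
        for src, dst in paths:
            if src not in latents or dst not in latents:
                raise ValueError(f"path ({src!r}, {dst!r}) references unknown latent")
            pm.loc[dst, src] = 1
        return cls(data, blocks, pm, **kwargs)

    # -- estimation ---------------------------------------------------------

    def fit(self) -> "PLSPathResults":
        spec = self.spec
        latents = spec.latents
        X = _standardize(self.data.to_numpy())
        n = X.shape[0]
        blocks_idx = {}
        pos = 0
        for lv, inds in spec.blocks.items():
            blocks_idx[lv] = np.arange(pos, pos + len(inds))
            pos += len(inds)
        pm = spec.path_matrix.to_numpy()
        adjacent = pm + pm.T  # symmetric inner adjacency

        weights = {lv: np.ones(len(idx)) for lv, idx in blocks_idx.items()}

        def scores_from(w: dict[str, np.ndarray]) -> np.ndarray:
            Y = np.column_stack(
                [X[:, blocks_idx[lv]] @ w[lv] for lv in latents]
            )
            return _standardize(Y)

        Y = scores_from(weights)
        converged = False
        iterations = 0
        for iterations in range(1, spec.max_iter + 1):
            R = np.corrcoef(Y, rowvar=False)
            if R.ndim == 0:  # single latent
                R = np.array([[1.0]])
            E = np.zeros_like(R)
            for i, lv in enumerate(latents):
                if spec.scheme == "centroid":
                    E[i] = np.sign(R[i]) * adjacent[i]
                elif spec.scheme == "factorial":
                    E[i] = R[i] * adjacent[i]
                else:  # path scheme
                    preds = np.flatnonzero(pm[i])
                    succs = np.flatnonzero(pm[:, i])
                    if preds.size:
                        coefs = np.linalg.solve(
                            R[np.ix_(preds, preds)], R[preds, i]
                        )
                        E[i, preds] = coefs
                    E[i, succs] = R[i, succs]
            Z = Y @ E.T
            # latents with no neighbours keep their own score as inner estimate
            lonely = adjacent.sum(axis=1) == 0
            if lonely.any():
                Z[:, lonely] = Y[:, lonely]
            Z = _standardize(Z)
            new_weights = {}
            for i, lv in enumerate(latents):
                Xb = X[:, blocks_idx[lv]]
                w = Xb.T @ Z[:, i] / (n - 1)  # mode A: corr(indicator, inner est.)
                new_weights[lv] = w
            Y_new = scores_from(new_weights)
            delta = max(
                np.max(np.abs(np.abs(new_weights[lv]) - np.abs(weights[lv])))
                for lv in latents
            )
            weights, Y = new_weights, Y_new
            if delta < spec.tol:
                converged = True
                break

        # sign convention: each latent correlates positively with the sum of
        # its block's indicators (flips are propagated to weights and scores)
        for i, lv in enumerate(latents):
            block_sum = X[:, blocks_idx[lv]].sum(axis=1)
            c = block_sum @ Y[:, i]
            if c < 0:
                Y[:, i] *= -1
                weights[lv] = -weights[lv]

        loadings = {}
        communalities = {}
        for i, lv in enumerate(latents):
            Xb = X[:, blocks_idx[lv]]
            lam = Xb.T @ Y[:, i] / (n - 1)
            for ind, l in zip(spec.blocks[lv], lam):
                loadings[ind] = float(l)
                communalities[ind] = float(l**2)

        path_coefs = pd.DataFrame(
            0.0, index=latents, columns=latents
        )
        r_squared: dict[str, float] = {}
        for i, lv in enumerate(latents):
            preds = np.flatnonzero(pm[i])
            if preds.size == 0:
                continue
            Xp = Y[:, preds]
            gram = Xp.T @ Xp
            if np.linalg.matrix_rank(gram) < preds.size:
                raise ValueError(
                    f"singular predecessor score matrix for latent {lv!r}"
                )
            beta = np.linalg.solve(gram, Xp.T @ Y[:, i])
            for j, b in zip(preds, beta):
                path_coefs.iloc[i, j] = float(b)
            fitted = Xp @ beta
            r_squared[lv] = float(
                1 - ((Y[:, i] - fitted) ** 2).sum() / ((Y[:, i]) ** 2).sum()
            )

        outer_weights = {
            ind: float(w)
            for lv in latents
            for ind, w in zip(spec.blocks[lv], weights[lv])
        }
        scores = pd.DataFrame(Y, index=self.data.index, columns=latents)
        return PLSPathResults(
            model=self,
            spec=spec,
            outer_weights=pd.Series(outer_weights, name="weight"),
            loadings=pd.Series(loadings, name="loading"),
            communalities=pd.Series(communalities, name="communality"),
            scores=scores,
            path_coefficients=path_coefs,
            r_squared=pd.Series(r_squared, name="r_squared"),
            converged=converged,
            iterations=iterations,
        )


def total_effects(path_coefficients: pd.DataFrame) -> pd.DataFrame:
    """Total (direct + indirect) effects of an acyclic path-coefficient matrix.

    For strictly lower-triangular B this is the finite series sum_{k>=1} B^k,
    i.e. the sum over all directed paths of the product of their coefficients.
    """
    B = path_coefficients.to_numpy(dtype=float)
    if np.triu(B).any():
        raise ValueError("path coefficient matrix must be strictly lower-triangular")
    total = np.zeros_like(B)
    power = np.eye(B.shape[0])
    for _ in range(B.shape[0]):
        power = power @ B
        total += power
    return pd.DataFrame(
        total, index=path_coefficients.index, columns=path_coefficients.columns
    )


@dataclass
class PLSPathResults:
    """Fitted PLS path model: estimates, diagnostics and resampling."""

    model: PLSPathModel
    spec: PLSPMSpec
    outer_weights: pd.Series
    loadings: pd.Series
    communalities: pd.Series
    scores: pd.DataFrame
    path_coefficients: pd.DataFrame
    r_squared: pd.Series
    converged: bool
    iterations: int
    _boot: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def gof(self) -> float:
        """Goodness of fit: sqrt(mean communality x mean R² over endogenous latents)."""
        if len(self.r_squared) == 0:
            raise ValueError("GoF undefined: model has no endogenous latent")
        return float(np.sqrt(self.communalities.mean() * self.r_squared.mean()))

    def total_effects(self) -> pd.DataFrame:
        return total_effects(self.path_coefficients)

    def direct_effects(self) -> pd.DataFrame:
        return self.path_coefficients.copy()

    def paths(self) -> pd.DataFrame:
        """Long-format table of the model's direct and total path effects."""
        rows = []
        tot = self.total_effects()
        pm = self.spec.path_matrix
        for dst in self.spec.latents:
            for src in self.spec.latents:
                if pm.loc[dst, src] == 1 or tot.loc[dst, src] != 0:
                    rows.append(
                        {
                            "source": src,
                            "target": dst,
                            "direct": self.path_coefficients.loc[dst, src],
                            "total": tot.loc[dst, src],
                        }
                    )
        return pd.DataFrame(rows)

    def prune(self, loading_min: float = 0.6) -> PLSPMSpec:
        """Spec with indicators whose loading falls below ``loading_min`` removed.

        Strict "below": a loading exactly at the threshold is retained. A
        block losing all indicators raises, naming the latent. The pruned
        spec must be refitted (``PLSPathModel(data, ...).fit()``).
        """
        new_blocks = {}
        for lv, inds in self.spec.blocks.items():
            kept = [ind for ind in inds if self.loadings[ind] >= loading_min]
            if not kept:
                raise ValueError(
                    f"pruning at loading >= {loading_min} empties block {lv!r}"
                )
            new_blocks[lv] = kept
        return replace(self.spec, blocks=new_blocks)

    def refit_pruned(self, loading_min: float = 0.6) -> "PLSPathResults":
        spec = self.prune(loading_min)
        return PLSPathModel(
            self.model.data,
            spec.blocks,
            spec.path_matrix,
            scheme=spec.scheme,
            tol=spec.tol,
            max_iter=spec.max_iter,
        ).fit()

    def bootstrap(self, n_boot: int = 999, seed: int = 0, ci: float = 0.95) -> pd.DataFrame:
        """Percentile bootstrap CIs and two-sided sign-based p per direct path.

        Rows are resampled with replacement; each replicate is refitted and
        its latent signs aligned with the original fit via the loading
        vectors. p is twice the smaller tail proportion of replicates on
        either side of zero (lower-bounded by 1/(n_boot+1)).
        """
        if n_boot < 100:
            raise ValueError(f"n_boot must be >= 100, got {n_boot}")
        rng = np.random.default_rng(seed)
        n = len(self.model.data)
        pm = self.spec.path_matrix
        edges = [
            (dst, src)
            for dst in self.spec.latents
            for src in self.spec.latents
            if pm.loc[dst, src] == 1
        ]
        draws = np.full((n_boot, len(edges)), np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            sample = self.model.data.iloc[idx].reset_index(drop=True)
            try:
                res = PLSPathModel(
                    sample,
                    self.spec.blocks,
                    self.spec.path_matrix,
                    scheme=self.spec.scheme,
                    tol=self.spec.tol,
                    max_iter=self.spec.max_iter,
                ).fit()
            except ValueError:
                continue  # degenerate resample (constant column / singularity)
            signs = {}
            for lv, inds in self.spec.blocks.items():
                a = np.array([self.loadings[i] for i in inds])
                bvec = np.array([res.loadings[i] for i in inds])
                signs[lv] = -1.0 if float(a @ bvec) < 0 else 1.0
            for k, (dst, src) in enumerate(edges):
                draws[b, k] = (
                    res.path_coefficients.loc[dst, src] * signs[dst] * signs[src]
                )
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        rows = []
        for k, (dst, src) in enumerate(edges):
            col = draws[:, k]
            col = col[~np.isnan(col)]
            neg = (col <= 0).mean()
            posi = (col >= 0).mean()
            p = max(2 * min(neg, posi), 1.0 / (len(col) + 1))
            rows.append(
                {
                    "source": src,
                    "target": dst,
                    "estimate": self.path_coefficients.loc[dst, src],
                    "boot_mean": col.mean(),
                    "ci_low": np.quantile(col, lo),
                    "ci_high": np.quantile(col, hi),
                    "p": min(p, 1.0),
                    "n_boot_ok": len(col),
                }
            )
        out = pd.DataFrame(rows)
        self._boot = out
        return out

    def summary(self) -> str:
        """Human-readable fit summary (outer model, inner model, GoF)."""
        lines = []
        lines.append("PLS Path Model Results (mode A, scheme=%s)" % self.spec.scheme)
        lines.append(
            "n=%d  converged=%s  iterations=%d  GoF=%.4f"
            % (len(self.scores), self.converged, self.iterations, self.gof)
        )
        lines.append("")
        lines.append("Outer model (weights / loadings / communality):")
        for lv, inds in self.spec.blocks.items():
            lines.append(f"  {lv}:")
            for ind in inds:
                lines.append(
                    "    %-20s w=%+.4f  loading=%+.4f  h2=%.4f"
                    % (
                        ind,
                        self.outer_weights[ind],
                        self.loadings[ind],
                        self.communalities[ind],
                    )
                )
        lines.append("")
        lines.append("Inner model (direct paths):")
        pm = self.spec.path_matrix
        for dst in self.spec.latents:
            for src in self.spec.latents:
                if pm.loc[dst, src] == 1:
                    lines.append(
                        "  %-18s -> %-18s beta=%+.4f"
                        % (src, dst, self.path_coefficients.loc[dst, src])
                    )
        if len(self.r_squared):
            lines.append("")
            lines.append("R² (endogenous latents):")
            for lv, r2 in self.r_squared.items():
                lines.append("  %-18s R²=%.4f" % (lv, r2))
        return "\n".join(lines)


def goodness_of_fit(fit: PLSPathResults) -> float:
    return fit.gof
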