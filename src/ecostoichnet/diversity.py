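"""Rarefaction and alpha-diversity indices on OTU count tables.

Sequencing depth varies between samples, so each kingdom's table is rarefied
(subsampled without replacement) to the minimum depth that retains every
sample before computing indices: observed richness, bias-corrected Chao1,
Shannon-Wiener (natural log) and Simpson. Simpson defaults to the
Gini-Simpson form 1 - sum(p_i^2); the classical dominance D and inverse 1/D
are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .datatypes import OTUTable


@dataclass(frozen=True)
class AlphaDiversity:
    observed: int
    chao1: float
    shannon: float
    simpson: float


SimpsonVariant = Literal["gini", "dominance", "inverse"]


def min_depth(table: OTUTable) -> int:
    """Minimum per-sample sequencing depth (smallest column sum)."""
    if table.counts.empty:
        raise ValueError("empty OTU table has no sequencing depth")
    return int(table.depths().min())


def rarefy(counts: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Subsample one sample's count vector to ``depth`` reads without replacement.

    Equivalent to drawing ``depth`` reads from the urn of sum(counts) reads;
    marginally each taxon follows a (multivariate) hypergeometric law. The
    identity rarefaction (depth equal to the full depth) returns the input
    unchanged.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("counts must be a 1-D non-negative vector")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample depth {total}")
    if depth == total:
        return counts.astype(np.int64).copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth).astype(
        np.int64
    )


def rarefy_table(table: OTUTable, depth: int | None = None, seed: int = 42) -> OTUTable:
    """Rarefy every sample of an OTU table to a common depth (default min_depth).

    Each sample gets an independent substream spawned from ``seed`` so the
    result is reproducible and independent of column order.
    """
    if depth is None:
        depth = min_depth(table)
    ss = np.random.SeedSequence(seed)
    out = {}
    for child, sid in zip(ss.spawn(len(table.sample_ids)), table.sample_ids):
        rng = np.random.default_rng(child)
        col = table.counts[sid].to_numpy()
        total = int(col.sum())
        if depth > total:
            raise ValueError(
                f"rarefaction depth {depth} exceeds depth {total} of sample {sid!r}"
            )
        if depth == total:
            out[sid] = col.astype(np.int64)
        else:
            out[sid] = rng.multivariate_hypergeometric(
                col.astype(np.int64), depth
            ).astype(np.int64)
    rarefied = pd.DataFrame(out, index=table.counts.index)[table.sample_ids]
    return OTUTable(rarefied, table.kingdom)


def alpha_diversity(
    counts: np.ndarray, simpson_variant: SimpsonVariant = "gini"
) -> AlphaDiversity:
    """Alpha-diversity indices of one sample's count vector.

    observed = number of taxa with positive counts; chao1 uses the
    bias-corrected estimator S + F1(F1-1)/(2(F2+1)) from singleton (F1) and
    doubleton (F2) counts; shannon = -sum p ln p; simpson per the selected
    variant.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("counts must be a 1-D non-negative vector")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count vector has undefined diversity")
    pos = counts[counts > 0]
    observed = int(pos.size)
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = pos / total
    shannon = float(-(p * np.log(p)).sum())
    d = float((p**2).sum())
    if simpson_variant == "gini":
        simpson = 1.0 - d
    elif simpson_variant == "dominance":
        simpson = d
    elif simpson_variant == "inverse":
        simpson = 1.0 / d
    else:
        raise ValueError(f"unknown simpson variant {simpson_variant!r}")
    return AlphaDiversity(observed, chao1, shannon, simpson)


def diversity_table(
    table: OTUTable,
    rarefaction_seed: int = 42,
    rarefaction_repeats: int = 1,
    simpson_variant: SimpsonVariant = "gini",
) -> pd.DataFrame:
    """Per-sample alpha diversity after rarefaction to the minimum depth.

    With ``rarefaction_repeats > 1`` the indices are averaged over that many
    independent rarefactions (observed richness then need not be integral).
    """
    if rarefaction_repeats < 1:
        raise ValueError("rarefaction_repeats must be >= 1")
    depth = min_depth(table)
    reps = []
    for r in range(rarefaction_repeats):
        rt = rarefy_table(table, depth, seed=rarefaction_seed + r)
        rows = {
            sid: vars(alpha_diversity(rt.counts[sid].to_numpy(), simpson_variant))
            for sid in rt.sample_ids
        }
        reps.append(pd.DataFrame.from_dict(rows, orient="index"))
    out = sum(reps) / len(reps)
    if rarefaction_repeats == 1:
        out["observed"] = out["observed"].astype(int)
    out.insert(0, "kingdom", table.kingdom)
    out.index.name = "sample_id"
    return out
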