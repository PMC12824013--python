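"""Core data containers shared across the pipeline.

The pipeline operates on three tabular artifacts — a sample frame (design
metadata), long-format measurement tables, and taxa-by-sample count tables —
plus the co-occurrence network graph. Containers are thin wrappers around
pandas/networkx objects that enforce the invariants the downstream stages
rely on (unique ids, non-negative integer counts, one treatment per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

#: The four stand types: pure Pinus sylvestris (EcM), pure Ulmus pumila (AM),
#: and each species sampled inside the 1:1 mixed stand.
TREATMENTS = ("Ps.P", "Up.P", "Ps.M", "Up.M")

#: Stand prefix determines the mycorrhizal type of the sampled tree:
#: Ulmus pumila hosts arbuscular mycorrhiza, Pinus sylvestris ectomycorrhiza.
MYCORRHIZAL_TYPE = {"Ps": "EcM", "Up": "AM"}

KINGDOMS = ("fungi", "bacteria")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class SampleFrame:
    """Design metadata: one row per composite rhizosphere sample.

    Columns: sample_id, treatment, plot, species, mycorrhizal_type.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "treatment", "plot", "species"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"sample frame missing columns: {sorted(missing)}")
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dupes}")
        bad = set(self.frame["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatments: {sorted(bad)}")
        if "mycorrhizal_type" not in self.frame.columns:
            self.frame = self.frame.assign(
                mycorrhizal_type=self.frame["treatment"].str[:2].map(MYCORRHIZAL_TYPE)
            )
        else:
            expected = self.frame["treatment"].str[:2].map(MYCORRHIZAL_TYPE)
            mism = self.frame.loc[
                self.frame["mycorrhizal_type"] != expected, "sample_id"
            ]
            if len(mism):
                raise ValidationError(
                    "mycorrhizal_type inconsistent with treatment for samples: "
                    f"{sorted(mism)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def treatment_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["treatment"]

    def samples_in(self, treatment: str) -> list[str]:
        sel = self.frame["treatment"] == treatment
        return list(self.frame.loc[sel, "sample_id"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class MeasurementTable:
    """Long-format measurements: (sample_id, variable, value, unit).

    Units are carried verbatim as labels and never interpreted; all math in
    the pipeline is dimension-agnostic.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "variable", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"measurement table missing columns: {sorted(missing)}")
        if "unit" not in self.frame.columns:
            self.frame = self.frame.assign(unit="")
        key = self.frame[["sample_id", "variable"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].drop_duplicates().values.tolist()
            raise ValidationError(f"duplicate (sample_id, variable) pairs: {dupes}")
        vals = pd.to_numeric(self.frame["value"], errors="coerce")
        if not np.isfinite(vals).all():
            bad = self.frame.loc[~np.isfinite(vals), ["sample_id", "variable"]]
            raise ValidationError(
                f"non-finite measurement values at: {bad.values.tolist()}"
            )
        self.frame = self.frame.assign(value=vals.astype(float))

    def wide(self, variables: Iterable[str] | None = None) -> pd.DataFrame:
        """Pivot to samples x variables; optionally restrict to ``variables``."""
        w = self.frame.pivot(index="sample_id", columns="variable", values="value")
        if variables is not None:
            variables = list(variables)
            missing = [v for v in variables if v not in w.columns]
            if missing:
                raise ValidationError(f"variables absent from measurements: {missing}")
            w = w[variables]
        return w

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class OTUTable:
    """Taxa-by-sample integer count matrix for one kingdom (ITS or 16S)."""

    counts: pd.DataFrame  # rows: taxa, columns: samples
    kingdom: str

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValidationError(
                f"kingdom must be one of {KINGDOMS}, got {self.kingdom!r}"
            )
        if self.counts.index.duplicated().any():
            dupes = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise ValidationError(f"duplicate taxa ids: {dupes}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric values")
        if (arr < 0).any():
            raise ValidationError("negative counts in OTU table")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("non-integral counts in OTU table")
        self.counts = self.counts.astype(np.int64)

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OTUTable":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"samples absent from OTU table: {missing}")
        return OTUTable(self.counts[sample_ids].copy(), self.kingdom)

    def relative_abundance(self) -> pd.DataFrame:
        depths = self.counts.sum(axis=0)
        if (depths == 0).any():
            empty = list(depths.index[depths == 0])
            raise ValidationError(f"samples with zero total counts: {empty}")
        return self.counts / depths


@dataclass
class CorrelationNetwork:
    """Undirected weighted co-occurrence network over retained taxa.

    Edge weight is the Spearman rho of the pair; provenance records the
    thresholds and sample set that produced the network.
    """

    graph: nx.Graph
    r_min: float
    alpha: float
    sample_ids: list[str] = field(default_factory=list)

    @property
    def node_number(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_number(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": u, "taxon_b": v, "rho": d["rho"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho"])
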