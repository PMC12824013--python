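"""End-to-end pipeline: configuration, orchestration, result bundle.

``run_pipeline`` ties the stages together on a (design, measurements, OTU
tables) bundle: biomass conversion, per-sample stoichiometry vectors,
rarefied alpha diversity per kingdom, ANOVA + LSD letters per variable,
per-treatment co-occurrence networks with topology metrics, PCA of enzyme
activities, and the PLS path model over the study's latent structure.
Everything stochastic is seeded through :class:`PipelineConfig`, so a run is
a pure function of (inputs, config).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .datatypes import (
    CorrelationNetwork,
    MeasurementTable,
    OTUTable,
    SampleFrame,
    TREATMENTS,
    ValidationError,
)
from .diversity import diversity_table
from .network import build_network, filter_taxa, spearman_matrix, topology_table
from .plspm import PLSPathModel, PLSPathResults
from .stats import group_comparison_table, pca
from .stoichiometry import biomass_table, vector_group_summary, vector_table

SOIL_VARS = ["pH", "TC", "TN", "TP", "SOC", "AN", "AP"]
ENZYME_VARS = ["BG", "NAG", "LAP", "ALP"]
BIOMASS_VARS = ["MBC", "MBN", "MBP"]

#: Numeric coding of stand type for the "mycorrhizal dominance" latent: an
#: AM-influence gradient with the mixed stands intermediate. The coding is
#: configurable because it is a modelling choice, not a measurement.
DEFAULT_DOMINANCE_CODING = {"Ps.P": 0.0, "Ps.M": 0.5, "Up.M": 0.5, "Up.P": 1.0}

#: Inner path structure of the study's latent model: stand dominance drives
#: pH, nutrients and the communities; everything upstream may act on the two
#: limitation responses (vector length and angle).
DEFAULT_PLSPM_PATHS = [
    ("dominance", "pH"),
    ("dominance", "nutrients"),
    ("dominance", "fungi"),
    ("dominance", "bacteria"),
    ("dominance", "biomass"),
    ("dominance", "vector_length"),
    ("dominance", "vector_angle"),
    ("pH", "nutrients"),
    ("pH", "biomass"),
    ("pH", "vector_length"),
    ("pH", "vector_angle"),
    ("nutrients", "fungi"),
    ("nutrients", "bacteria"),
    ("nutrients", "biomass"),
    ("nutrients", "vector_length"),
    ("nutrients", "vector_angle"),
    ("fungi", "vector_length"),
    ("fungi", "vector_angle"),
    ("bacteria", "vector_length"),
    ("bacteria", "vector_angle"),
    ("biomass", "vector_length"),
    ("biomass", "vector_angle"),
]


@dataclass
class PipelineConfig:
    """All pipeline thresholds, seeds and method switches in one place."""

    # taxa filtering / network construction
    min_mean_relabund: float = 0.0001
    min_prevalence: float = 0.5
    r_min: float = 0.9
    alpha: float = 0.05
    network_scope: str = "per_treatment"  # or "global"
    combine_kingdoms: bool = True
    pvalue_method: str = "t"              # or "permutation"
    bh_correct: bool = False
    community_seed: int = 0
    # diversity
    rarefaction_seed: int = 42
    rarefaction_repeats: int = 1
    simpson_variant: str = "gini"
    # stoichiometry
    vector_method: str = "log_ratio"
    atan2_order: str = "math"
    # group statistics
    anova_alpha: float = 0.05
    # PLS-PM
    plspm_scheme: str = "path"
    plspm_tol: float = 1e-6
    plspm_max_iter: int = 300
    loading_min: float = 0.6
    n_boot: int = 299
    bootstrap: bool = True
    bootstrap_seed: int = 7
    dominance_coding: dict = field(
        default_factory=lambda: dict(DEFAULT_DOMINANCE_CODING)
    )
    # output
    output_dir: str = "results"
    network_formats: tuple = ("graphml", "edgelist")

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= 1):
            raise ValueError(f"r_min must be in (0, 1], got {self.r_min}")
        for name in ("alpha", "anova_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("min_mean_relabund", "min_prevalence"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.network_scope not in ("per_treatment", "global"):
            raise ValueError(f"unknown network_scope {self.network_scope!r}")
        missing = [t for t in TREATMENTS if t not in self.dominance_coding]
        if missing:
            raise ValueError(f"dominance_coding lacks treatments: {missing}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "network_formats" in raw:
            raw["network_formats"] = tuple(raw["network_formats"])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = dataclasses.asdict(self)
        data["network_formats"] = list(self.network_formats)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class ResultBundle:
    """In-memory results of one pipeline run (plus where they were written)."""

    vectors: pd.DataFrame
    vector_groups: pd.DataFrame
    diversity: pd.DataFrame
    comparisons: pd.DataFrame
    networks: dict[str, CorrelationNetwork]
    topology: pd.DataFrame
    pca_variance: np.ndarray
    plspm: PLSPathResults
    plspm_report: pd.DataFrame
    output_dir: Path | None = None


def _check_sample_consistency(
    design: SampleFrame, measurements: MeasurementTable, tables: dict[str, OTUTable]
) -> None:
    design_ids = set(design.sample_ids)
    offenders = sorted(set(measurements.frame["sample_id"]) - design_ids)
    if offenders:
        raise ValidationError(f"measurement samples not in design: {offenders}")
    for kingdom, tab in tables.items():
        off = sorted(set(tab.sample_ids) - design_ids)
        if off:
            raise ValidationError(f"{kingdom} OTU samples not in design: {off}")


def _network_inputs(
    tables: dict[str, OTUTable], design: SampleFrame, config: PipelineConfig
) -> dict[str, OTUTable]:
    """Assemble the count tables each network is built from."""
    if config.combine_kingdoms:
        merged = pd.concat([t.counts for t in tables.values()])
        pools = {"combined": OTUTable(merged, "bacteria")}
    else:
        pools = dict(tables)
    out = {}
    if config.network_scope == "global":
        for name, tab in pools.items():
            out[name if not config.combine_kingdoms else "global"] = tab
        return out
    for tr in TREATMENTS:
        sids = [s for s in design.samples_in(tr)]
        for name, tab in pools.items():
            present = [s for s in sids if s in tab.sample_ids]
            label = tr if config.combine_kingdoms else f"{tr}.{name}"
            out[label] = tab.subset_samples(present)
    return out


def build_networks(
    tables: dict[str, OTUTable], design: SampleFrame, config: PipelineConfig
) -> dict[str, CorrelationNetwork]:
    """Per-treatment (or global) co-occurrence networks with the configured filters."""
    nets = {}
    for name, tab in _network_inputs(tables, design, config).items():
        filtered = filter_taxa(tab, config.min_mean_relabund, config.min_prevalence)
        rho, p = spearman_matrix(filtered, pvalue_method=config.pvalue_method)
        nets[name] = build_network(
            rho,
            p,
            r_min=config.r_min,
            alpha=config.alpha,
            sample_ids=tab.sample_ids,
            bh_correct=config.bh_correct,
        )
    return nets


def assemble_plspm_data(
    design: SampleFrame,
    wide: pd.DataFrame,
    diversity: pd.DataFrame,
    vectors: pd.DataFrame,
    coding: dict,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Samples-by-indicators table and block map for the latent path model."""
    treatments = design.treatment_of()
    data = pd.DataFrame(index=wide.index)
    data["dominance"] = treatments.reindex(wide.index).map(coding)
    data["pH"] = wide["pH"]
    for v in ["TC", "TN", "TP", "SOC", "AN", "AP"]:
        data[v] = wide[v]
    for kingdom, tag in (("fungi", "fungal"), ("bacteria", "bacterial")):
        sub = diversity[diversity["kingdom"] == kingdom]
        for idx_var in ("observed", "chao1", "shannon", "simpson"):
            data[f"{tag}_{idx_var}"] = sub[idx_var].reindex(wide.index)
    for v in BIOMASS_VARS:
        data[v] = wide[v]
    data["vector_length"] = vectors["vector_length"].reindex(wide.index)
    data["vector_angle"] = vectors["vector_angle_deg"].reindex(wide.index)
    blocks = {
        "dominance": ["dominance"],
        "pH": ["pH"],
        "nutrients": ["TC", "TN", "TP", "SOC", "AN", "AP"],
        "fungi": ["fungal_observed", "fungal_chao1", "fungal_shannon", "fungal_simpson"],
        "bacteria": [
            "bacterial_observed",
            "bacterial_chao1",
            "bacterial_shannon",
            "bacterial_simpson",
        ],
        "biomass": BIOMASS_VARS,
        "vector_length": ["vector_length"],
        "vector_angle": ["vector_angle"],
    }
    return data, blocks


def run_pipeline(
    config: PipelineConfig,
    design: SampleFrame,
    measurements: MeasurementTable,
    tables: dict[str, OTUTable],
    write: bool = True,
) -> ResultBundle:
    """Run every stage on an in-memory bundle and (optionally) write TSV outputs."""
    _check_sample_consistency(design, measurements, tables)
    wide = measurements.wide()
    if "MBC" not in wide.columns and "C_fum" in wide.columns:
        wide = wide.join(biomass_table(wide))
    treatments = design.treatment_of()

    vectors = vector_table(
        wide[ENZYME_VARS], method=config.vector_method, atan2_order=config.atan2_order
    )
    vector_groups = vector_group_summary(vectors, treatments)

    diversity = pd.concat(
        [
            diversity_table(
                tab,
                rarefaction_seed=config.rarefaction_seed,
                rarefaction_repeats=config.rarefaction_repeats,
                simpson_variant=config.simpson_variant,
            )
            for tab in tables.values()
        ]
    )

    stat_vars = [v for v in SOIL_VARS + ENZYME_VARS + BIOMASS_VARS if v in wide.columns]
    stat_table = wide[stat_vars].join(
        vectors[["vector_length", "vector_angle_deg"]]
    )
    for kingdom in tables:
        sub = diversity[diversity["kingdom"] == kingdom]
        for idx_var in ("observed", "chao1", "shannon", "simpson"):
            stat_table[f"{kingdom}_{idx_var}"] = sub[idx_var].reindex(stat_table.index)
    comparisons = group_comparison_table(stat_table, treatments, alpha=config.anova_alpha)

    enzyme_pca = pca(wide[ENZYME_VARS], standardize=True)

    nets = build_networks(tables, design, config)
    topo = topology_table(nets, seed=config.community_seed)

    plspm_data, blocks = assemble_plspm_data(
        design, wide, diversity, vectors, config.dominance_coding
    )
    model = PLSPathModel(
        plspm_data,
        blocks,
        _path_matrix(blocks),
        scheme=config.plspm_scheme,
        tol=config.plspm_tol,
        max_iter=config.plspm_max_iter,
    )
    fit = model.fit()
    try:
        fit = fit.refit_pruned(config.loading_min)
    except ValueError:
        pass  # pruning would empty a block; keep the unpruned fit
    report = fit.paths()
    report["gof"] = fit.gof
    if config.bootstrap:
        boot = fit.bootstrap(n_boot=config.n_boot, seed=config.bootstrap_seed)
        report = report.merge(
            boot[["source", "target", "ci_low", "ci_high", "p"]],
            on=["source", "target"],
            how="left",
        )

    bundle = ResultBundle(
        vectors=vectors,
        vector_groups=vector_groups,
        diversity=diversity,
        comparisons=comparisons,
        networks=nets,
        topology=topo,
        pca_variance=enzyme_pca.variance_fraction,
        plspm=fit,
        plspm_report=report,
        output_dir=None,
    )
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        vectors.to_csv(outdir / "vector_metrics.tsv", sep="\t")
        vector_groups.to_csv(outdir / "vector_groups.tsv", sep="\t")
        diversity.to_csv(outdir / "diversity.tsv", sep="\t")
        comparisons.to_csv(outdir / "group_comparisons.tsv", sep="\t", index=False)
        topo.to_csv(outdir / "network_topology.tsv", sep="\t")
        report.to_csv(outdir / "plspm_report.tsv", sep="\t", index=False)
        (outdir / "plspm_summary.txt").write_text(fit.summary() + "\n")
        for name, net in nets.items():
            if "graphml" in config.network_formats:
                eio.write_network(net, outdir / f"network_{name}.graphml", "graphml")
            if "edgelist" in config.network_formats:
                eio.write_network(net, outdir / f"network_{name}.edgelist.tsv", "edgelist")
        bundle.output_dir = outdir
    return bundle


def _path_matrix(blocks: dict) -> pd.DataFrame:
    latents = list(blocks)
    pm = pd.DataFrame(0, index=latents, columns=latents, dtype=int)
    for src, dst in DEFAULT_PLSPM_PATHS:
        pm.loc[dst, src] = 1
    return pm


def run_from_paths(config: PipelineConfig, input_dir: str | os.PathLike, write: bool = True) -> ResultBundle:
    """Run the pipeline from a directory of TSV inputs (as written by simulate)."""
    d = Path(input_dir)
    design = eio.read_sample_frame(d / "design.tsv")
    measurements = eio.read_measurements(d / "measurements.tsv")
    tables = {}
    for kingdom in ("fungi", "bacteria"):
        path = d / f"otu_{kingdom}.tsv"
        if path.exists():
            tables[kingdom] = eio.read_feature_table(path, kingdom)
    if not tables:
        raise FileNotFoundError(f"no OTU tables found under {d}")
    return run_pipeline(config, design, measurements, tables, write=write)
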