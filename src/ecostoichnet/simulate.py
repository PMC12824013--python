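"""Synthetic study bundles with known ground truth.

Emulates the field design this pipeline targets: four stand types (pure
Pinus sylvestris = Ps.P, pure Ulmus pumila = Up.P, and each species inside
the 1:1 mixed stand = Ps.M / Up.M), three replicate plots per stand, 15
standard trees per plot pooled 5-at-a-time into 3 composite rhizosphere
samples, hence 9 samples per treatment (36 total).

Generated artifacts:

* design table (sample -> treatment/plot/species/mycorrhizal type);
* measurement table — soil chemistry, enzyme activities, and
  fumigation-extraction concentration pairs whose flush / k reproduces the
  targeted microbial biomass — drawn per treatment from truncated-at-zero
  normals with configurable means and sds (sd = 0 reproduces means exactly);
* OTU count tables per kingdom: per-sample depth uniform within the
  kingdom's realistic range, compositions from a log-normal latent-factor
  model in which configured taxa cliques share a per-sample latent factor
  (inducing positive rank correlation = plantable co-occurrence edges),
  counts multinomial at the drawn depth;
* recursive linear SEM data with standardized latents and noisy single
  indicators for path-model recovery tests.

Every generator is a pure function of (config, seed). Default treatment
means are anchored to the magnitudes a semi-arid temperate plantation
rhizosphere study reports (soil chemistry, enzyme activities, biomass);
group means that such studies summarise only through derived vector metrics
are back-solved from those summaries so the default bundle reproduces the
published orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import OTUTable, SampleFrame, MeasurementTable, TREATMENTS
from .stoichiometry import K_EC, K_EN, K_EP

# per-variable, per-treatment (mean, sd); order Ps.P, Up.P, Ps.M, Up.M
DEFAULT_VARIABLE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "pH":  {"Ps.P": (8.11, 0.12), "Up.P": (8.35, 0.16), "Ps.M": (8.17, 0.11), "Up.M": (7.76, 0.05)},
    "TC":  {"Ps.P": (7.75, 0.17), "Up.P": (3.80, 0.13), "Ps.M": (7.34, 0.13), "Up.M": (9.85, 0.18)},
    "TN":  {"Ps.P": (0.45, 0.01), "Up.P": (0.25, 0.01), "Ps.M": (0.43, 0.01), "Up.M": (0.58, 0.01)},
    "TP":  {"Ps.P": (0.14, 0.01), "Up.P": (0.09, 0.01), "Ps.M": (0.13, 0.01), "Up.M": (0.14, 0.01)},
    "SOC": {"Ps.P": (3.29, 0.14), "Up.P": (2.19, 0.11), "Ps.M": (3.77, 0.12), "Up.M": (4.05, 0.23)},
    "AN":  {"Ps.P": (100.87, 1.18), "Up.P": (54.54, 0.82), "Ps.M": (89.59, 1.08), "Up.M": (114.91, 1.61)},
    "AP":  {"Ps.P": (2.73, 0.10), "Up.P": (1.35, 0.08), "Ps.M": (2.38, 0.10), "Up.M": (2.32, 0.10)},
    # enzyme activities; N acquisition is split 60/40 between NAG and LAP
    "BG":  {"Ps.P": (19.37, 0.97), "Up.P": (29.60, 1.48), "Ps.M": (15.26, 0.76), "Up.M": (15.42, 0.77)},
    "NAG": {"Ps.P": (42.89, 2.14), "Up.P": (31.51, 1.58), "Ps.M": (37.17, 1.86), "Up.M": (38.82, 1.94)},
    "LAP": {"Ps.P": (28.60, 1.43), "Up.P": (21.01, 1.05), "Ps.M": (24.78, 1.24), "Up.M": (25.89, 1.29)},
    "ALP": {"Ps.P": (35.97, 1.80), "Up.P": (26.68, 1.33), "Ps.M": (43.37, 2.17), "Up.M": (43.57, 2.18)},
    # microbial biomass targets (mixed stands > pure; AM pure lowest)
    "MBC": {"Ps.P": (120.0, 3.6), "Up.P": (89.13, 2.7), "Ps.M": (140.0, 4.2), "Up.M": (158.91, 4.8)},
    "MBN": {"Ps.P": (6.00, 0.18), "Up.P": (4.81, 0.14), "Ps.M": (6.90, 0.21), "Up.M": (7.52, 0.23)},
    "MBP": {"Ps.P": (48.00, 1.44), "Up.P": (40.25, 1.21), "Ps.M": (54.00, 1.62), "Up.M": (59.53, 1.79)},
}

DEFAULT_UNITS = {
    "pH": "", "TC": "g/kg", "TN": "g/kg", "TP": "g/kg", "SOC": "g/kg",
    "AN": "mg/g", "AP": "mg/g",
    "BG": "umol/h", "NAG": "umol/h", "LAP": "umol/h", "ALP": "umol/h",
    "MBC": "mg/g", "MBN": "mg/g", "MBP": "mg/g",
}

#: Baseline non-fumigated extract concentrations used to synthesise
#: fumigation-extraction pairs consistent with the biomass targets.
NONFUM_BASE = {"C": 60.0, "N": 12.0, "P": 25.0}
BIOMASS_FACTORS = {"C": ("MBC", K_EC), "N": ("MBN", K_EN), "P": ("MBP", K_EP)}

DEFAULT_DEPTH_RANGE = {"fungi": (67329, 78875), "bacteria": (114221, 130978)}
DEFAULT_N_TAXA = {"fungi": 400, "bacteria": 800}

SPECIES = {"Ps": "Pinus sylvestris var. mongolica", "Up": "Ulmus pumila"}


@dataclass
class SimulationConfig:
    """Study-design and generating parameters of a synthetic bundle."""

    n_plots: int = 3
    trees_per_plot: int = 15
    composite_size: int = 5
    variable_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            v: dict(t) for v, t in DEFAULT_VARIABLE_PARAMS.items()
        }
    )
    n_taxa: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_TAXA))
    depth_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_RANGE)
    )
    n_cliques: int = 5
    clique_size: int = 5
    factor_loading: float = 2.0
    taxon_mean_sd: float = 1.5       # spread of baseline log-abundances
    taxon_noise_sd: float = 0.5      # per-sample log-abundance noise
    treatment_effect_sd: float = 0.3 # treatment-structured mean shifts
    seed: int = 20240901

    def __post_init__(self) -> None:
        if self.trees_per_plot % self.composite_size != 0:
            raise ValueError(
                f"trees_per_plot ({self.trees_per_plot}) must be divisible by "
                f"composite_size ({self.composite_size})"
            )
        for kingdom, (lo, hi) in self.depth_range.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid depth range for {kingdom}: ({lo}, {hi})")

    @property
    def samples_per_treatment(self) -> int:
        return self.n_plots * (self.trees_per_plot // self.composite_size)


@dataclass
class GroundTruth:
    """Generating parameters recorded alongside a synthetic artifact."""

    treatment_means: dict | None = None
    clique_edges: list[tuple[str, str]] | None = None
    cliques: list[list[str]] | None = None
    sem_coefficients: pd.DataFrame | None = None


def generate_design(cfg: SimulationConfig) -> SampleFrame:
    """Sample frame of the 4-treatment composite design."""
    rows = []
    per_plot = cfg.trees_per_plot // cfg.composite_size
    for tr in TREATMENTS:
        prefix = tr[:2]
        for plot in range(1, cfg.n_plots + 1):
            for s in range(1, per_plot + 1):
                rows.append(
                    {
                        "sample_id": f"{tr}.p{plot}.s{s}",
                        "treatment": tr,
                        "plot": f"{tr}.plot{plot}",
                        "species": SPECIES[prefix],
                    }
                )
    return SampleFrame(pd.DataFrame(rows))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at zero by rejection (sds here are << means)."""
    if sd < 0:
        raise ValueError(f"negative sd: {sd}")
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise ValueError(f"truncated normal rejection failed for mean={mean}, sd={sd}")


def generate_measurements(
    design: SampleFrame, cfg: SimulationConfig, seed: int | None = None
) -> tuple[MeasurementTable, GroundTruth]:
    """Per-sample measurement table drawn from the configured treatment means.

    Biomass variables (MBC/MBN/MBP) are emitted indirectly, as
    fumigation-extraction concentration pairs (``C_fum``/``C_nonfum`` etc.)
    constructed so that flush / k equals the drawn biomass value.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    rows = []
    drawn: dict[str, pd.Series] = {}
    for var in cfg.variable_params:
        params = cfg.variable_params[var]
        missing = [t for t in TREATMENTS if t not in params]
        if missing:
            raise ValueError(f"variable {var!r} lacks parameters for {missing}")
        vals = {}
        for tr in TREATMENTS:
            mean, sd = params[tr]
            sids = design.samples_in(tr)
            for sid, v in zip(sids, _truncated_normal(rng, mean, sd, len(sids))):
                vals[sid] = v
        drawn[var] = pd.Series(vals)
    for var, series in drawn.items():
        if var in ("MBC", "MBN", "MBP"):
            continue
        for sid, v in series.items():
            rows.append(
                {"sample_id": sid, "variable": var, "value": v,
                 "unit": DEFAULT_UNITS.get(var, "")}
            )
    # fumigation-extraction pairs consistent with the biomass targets
    for elem, (bio_var, k) in BIOMASS_FACTORS.items():
        if bio_var not in drawn:
            continue
        base = NONFUM_BASE[elem]
        for sid, biomass in drawn[bio_var].items():
            rows.append(
                {"sample_id": sid, "variable": f"{elem}_nonfum", "value": base,
                 "unit": "mg/kg extract"}
            )
            rows.append(
                {"sample_id": sid, "variable": f"{elem}_fum",
                 "value": base + biomass * k, "unit": "mg/kg extract"}
            )
    table = MeasurementTable(pd.DataFrame(rows))
    truth = GroundTruth(
        treatment_means={
            var: {t: p[0] for t, p in params.items()}
            for var, params in cfg.variable_params.items()
        }
    )
    return table, truth


def generate_community(
    design: SampleFrame,
    cfg: SimulationConfig,
    kingdom: str,
    seed: int | None = None,
) -> tuple[OTUTable, GroundTruth]:
    """OTU count table with planted co-occurrence cliques.

    Log-abundance of taxon i in sample s:

        log a_is = mu_i + delta_{i,tr(s)} + lambda * f_{c(i),s} + eps_is

    with mu_i ~ N(0, taxon_mean_sd), treatment shifts delta ~ N(0,
    treatment_effect_sd), one standard-normal factor f per clique per sample
    scaled by ``factor_loading`` for clique members, and residual noise
    eps ~ N(0, taxon_noise_sd). Compositions are softmax(log a); counts are
    multinomial at a depth drawn uniformly in the kingdom's range.
    """
    if seed is None:
        seed = cfg.seed + {"fungi": 1, "bacteria": 2}[kingdom]
    n_taxa = int(cfg.n_taxa[kingdom])
    if n_taxa < 10:
        raise ValueError("n_taxa must be >= 10")
    if cfg.n_cliques * cfg.clique_size > n_taxa:
        raise ValueError("clique configuration exceeds taxon count")
    rng = np.random.default_rng(seed)
    prefix = {"fungi": "F_OTU", "bacteria": "B_OTU"}[kingdom]
    taxa = [f"{prefix}{i + 1:04d}" for i in range(n_taxa)]
    sample_ids = design.sample_ids
    n_samples = len(sample_ids)
    treatments = design.treatment_of().reindex(sample_ids)

    mu = rng.normal(0.0, cfg.taxon_mean_sd, n_taxa)
    delta = {
        tr: rng.normal(0.0, cfg.treatment_effect_sd, n_taxa) for tr in TREATMENTS
    }
    clique_members: list[list[str]] = []
    member_idx = np.full(n_taxa, -1)
    for c in range(cfg.n_cliques):
        lo = c * cfg.clique_size
        idx = np.arange(lo, lo + cfg.clique_size)
        member_idx[idx] = c
        clique_members.append([taxa[i] for i in idx])

    lo, hi = cfg.depth_range[kingdom]
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        factors = rng.normal(0.0, 1.0, max(cfg.n_cliques, 1))
        log_a = mu + delta[treatments[sid]] + rng.normal(0, cfg.taxon_noise_sd, n_taxa)
        if cfg.factor_loading != 0 and cfg.n_cliques > 0:
            in_clique = member_idx >= 0
            log_a[in_clique] += cfg.factor_loading * factors[member_idx[in_clique]]
        log_a -= log_a.max()
        p = np.exp(log_a)
        p /= p.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[:, j] = rng.multinomial(depth, p)

    table = OTUTable(pd.DataFrame(counts, index=taxa, columns=sample_ids), kingdom)
    edges = []
    if cfg.factor_loading != 0:
        for members in clique_members:
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    edges.append((members[a], members[b]))
    truth = GroundTruth(clique_edges=edges, cliques=clique_members)
    return table, truth


def _implied_latent_sds(B: np.ndarray) -> np.ndarray:
    """Disturbance sds making every latent of the recursive SEM unit-variance."""
    k = B.shape[0]
    cov = np.zeros((k, k))
    sds = np.zeros(k)
    for i in range(k):
        preds = np.flatnonzero(B[i])
        explained = float(B[i, preds] @ cov[np.ix_(preds, preds)] @ B[i, preds])
        if explained >= 1.0:
            raise ValueError(
                f"SEM row {i} implies explained variance {explained:.3f} >= 1; "
                "shrink the coefficients"
            )
        sds[i] = np.sqrt(1.0 - explained)
        for j in range(i):
            cov[i, j] = cov[j, i] = float(B[i] @ cov[:, j])
        cov[i, i] = 1.0
    return sds


def generate_sem_data(
    B: pd.DataFrame, n: int, noise_sd: float, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Samples from a recursive linear SEM with standardized single indicators.

    ``B`` is a strictly lower-triangular coefficient DataFrame over latent
    names (row regressed on columns). Latents are generated recursively with
    disturbance variances chosen so each latent has unit variance, hence the
    entries of ``B`` are the standardized path coefficients. Each emitted
    indicator is (latent + noise_sd * e) / sqrt(1 + noise_sd^2), so columns
    are standardized in expectation.
    """
    arr = B.to_numpy(dtype=float)
    if np.triu(arr).any():
        raise ValueError("SEM coefficient matrix must be strictly lower-triangular")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    k = arr.shape[0]
    sds = _implied_latent_sds(arr)
    Z = np.zeros((n, k))
    for i in range(k):
        preds = np.flatnonzero(arr[i])
        Z[:, i] = Z[:, preds] @ arr[i, preds] + sds[i] * rng.normal(size=n)
    X = (Z + noise_sd * rng.normal(size=(n, k))) / np.sqrt(1 + noise_sd**2)
    frame = pd.DataFrame(X, columns=list(B.index))
    return frame, GroundTruth(sem_coefficients=B.copy())


def generate_bundle(cfg: SimulationConfig | None = None, seed: int | None = None):
    """Full synthetic study bundle: design, measurements, both OTU tables.

    Returns (design, measurements, {"fungi": OTUTable, "bacteria": OTUTable},
    {"measurements": GroundTruth, "fungi": ..., "bacteria": ...}).
    """
    if cfg is None:
        cfg = SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
    design = generate_design(cfg)
    measurements, m_truth = generate_measurements(design, cfg)
    tables, truths = {}, {"measurements": m_truth}
    for kingdom in ("fungi", "bacteria"):
        tables[kingdom], truths[kingdom] = generate_community(design, cfg, kingdom)
    return design, measurements, tables, truths
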