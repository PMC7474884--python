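"""Scenario-grid orchestration and scoring of variable selection.

A grid run crosses datasets x scenarios x absence mechanisms x replicates.
For each dataset the pipeline is: build the spatial eigenvector basis from
the site layout, fit per-species GLMs on the baseline community to get a
realistic coefficient matrix (done once and cached), then per replicate:
resample scenario coefficients C*, simulate a community, run both
selection methods, and score the selected set against the generating set K.

Scoring treats each of the m eigenvectors as a binary inclusion/exclusion
decision: accuracy is the fraction of correct decisions, false inclusions
are selected variables with zero true coefficient, false exclusions are
unselected variables with non-zero true coefficient, so
m * accuracy + false_inclusions + false_exclusions = m exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from memsel.coefficient_model import (
    CoefficientMatrix,
    ScenarioSpec,
    all_scenarios,
    build_design,
    coefficient_pool,
    fit_species_glms,
)
from memsel.community_simulator import replicate_rng, simulate_sam, simulate_spm
from memsel.glm_aic import forward_select_glm
from memsel.rda_forward import SelectionConfig, forward_select_rda, ochiai_transform
from memsel.spatial_basis import (
    EdgeList,
    EigenBasis,
    aem_basis,
    delaunay_edges,
    mem_basis,
    mst_edges,
    pairwise_distances,
    read_coordinates,
    weight_matrix,
)
from memsel.synthetic_data import SyntheticBaselineConfig, generate_baseline_community, generate_coordinates

__all__ = [
    "ScoreRecord",
    "DatasetSpec",
    "GridConfig",
    "PreparedDataset",
    "GridResult",
    "score_selection",
    "inclusion_table",
    "prepare_dataset",
    "run_grid",
    "read_network",
]

logger = logging.getLogger(__name__)

MECHANISMS = ("spm", "sam")
CONNECTIVITIES = ("mst", "delaunay", "aem")


@dataclass(frozen=True)
class ScoreRecord:
    """Inclusion/exclusion scoring of one selection against the truth."""

    m: int
    n_false_incl: int
    n_false_excl: int

    @property
    def accuracy(self) -> float:
        return (self.m - self.n_false_incl - self.n_false_excl) / self.m


def score_selection(selected, K, m: int) -> ScoreRecord:
    """Score a selected index set against the generating set K (1-based)."""
    sel = set(int(j) for j in selected)
    true = set(int(k) for k in getattr(K, "K", K))
    for s in sel | true:
        if not 1 <= s <= m:
            raise ValueError(f"index {s} out of range 1..{m}")
    return ScoreRecord(
        m=m,
        n_false_incl=len(sel - true),
        n_false_excl=len(true - sel),
    )


@dataclass(frozen=True)
class DatasetSpec:
    """One baseline dataset: either file-backed or synthetic.

    File-backed datasets give ``coords`` (site,x,y CSV), ``community``
    (site rows x species columns CSV, first column site id) and, for AEM,
    ``network`` (from,to,length CSV with the virtual origin coded -1).
    Synthetic datasets give a :class:`SyntheticBaselineConfig` instead.
    """

    name: str
    connectivity: str
    synthetic: SyntheticBaselineConfig | None = None
    coords: str | None = None
    community: str | None = None
    network: str | None = None
    transform: str = "linear"

    def __post_init__(self) -> None:
        if self.connectivity not in CONNECTIVITIES:
            raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
        if self.synthetic is None and (self.coords is None or self.community is None):
            raise ValueError("dataset needs either synthetic config or file paths")


@dataclass(frozen=True)
class GridConfig:
    """Full grid specification (datasets, scenarios, replication, seeds)."""

    datasets: tuple[DatasetSpec, ...]
    replicates: int = 100
    mechanisms: tuple[str, ...] = MECHANISMS
    levels: tuple[str, ...] | None = None  # None = all 14 scenarios
    scalings: tuple[int, ...] = (1, 2, 3)
    alpha: float = 0.05
    nperm: int = 999
    seed: int = 0
    table: str = "printed"

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = []
        for d in raw.pop("datasets"):
            synth = d.pop("synthetic", None)
            if synth is not None:
                synth = SyntheticBaselineConfig(**synth)
            datasets.append(DatasetSpec(synthetic=synth, **d))
        for key in ("mechanisms", "levels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "scalings" in raw:
            raw["scalings"] = tuple(raw["scalings"])
        return cls(datasets=tuple(datasets), **raw)


@dataclass(frozen=True)
class PreparedDataset:
    """Dataset after basis construction and baseline coefficient fitting."""

    name: str
    connectivity: str
    basis: EigenBasis
    X: np.ndarray  # design: ones column + eigenvectors
    baseline: np.ndarray  # baseline presence/absence matrix
    C: CoefficientMatrix
    pool: np.ndarray


def read_network(path) -> EdgeList:
    """Read a directed network CSV (columns from,to,length; origin = -1)."""
    df = pd.read_csv(path)
    missing = {"from", "to"} - set(df.columns)
    if missing:
        raise ValueError(f"network file lacks columns: {sorted(missing)}")
    lengths = df["length"].to_numpy(float) if "length" in df.columns else None
    return EdgeList(
        edges=df[["from", "to"]].to_numpy(int), lengths=lengths, directed=True
    )


def _site_weighting(coords, network: EdgeList, transform: str):
    """Symmetric site weighting from the real-site edges of a network."""
    d = pairwise_distances(coords)
    real = network.edges[(network.edges >= 0).all(axis=1)]
    und = np.array(sorted({(min(a, b), max(a, b)) for a, b in real}), dtype=int)
    return weight_matrix(EdgeList(edges=und), d, transform)


def build_basis(coords, connectivity: str, network: EdgeList | None = None,
                transform: str = "linear") -> EigenBasis:
    """Build the MEM or AEM basis for a site layout."""
    if connectivity == "aem":
        if network is None:
            raise ValueError("AEM connectivity needs a directed network")
        w_sym = _site_weighting(coords, network, transform)
        return aem_basis(network, w_sym)
    d = pairwise_distances(coords)
    edges = mst_edges(d) if connectivity == "mst" else delaunay_edges(coords)
    return mem_basis(weight_matrix(edges, d, transform))


def prepare_dataset(spec: DatasetSpec) -> PreparedDataset:
    """Build basis, baseline community, and baseline coefficients."""
    if spec.synthetic is not None:
        coords, network = generate_coordinates(spec.synthetic)
        basis = build_basis(coords, spec.connectivity, network, spec.transform)
        Y0 = generate_baseline_community(spec.synthetic, basis)
    else:
        coords = read_coordinates(spec.coords)
        network = read_network(spec.network) if spec.network else None
        basis = build_basis(coords, spec.connectivity, network, spec.transform)
        Y0 = pd.read_csv(spec.community, index_col=0).to_numpy()
    X = build_design(basis)
    C = fit_species_glms(Y0, X)
    logger.info(
        "dataset %s: n=%d, p=%d, m=%d retained %s vectors",
        spec.name, basis.n, Y0.shape[1], basis.m, basis.kind,
    )
    return PreparedDataset(
        name=spec.name,
        connectivity=spec.connectivity,
        basis=basis,
        X=X,
        baseline=np.asarray(Y0),
        C=C,
        pool=coefficient_pool(C),
    )


@dataclass
class GridResult:
    """Tidy per-replicate results plus the raw selections."""

    results: pd.DataFrame
    selections: list[dict] = field(default_factory=list)

    def cell_means(self) -> pd.DataFrame:
        """Mean and sd of scores per (dataset, scenario, mechanism, method)."""
        keys = ["dataset", "ev", "scaling", "modelling", "method"]
        g = self.results.groupby(keys, sort=False)
        out = g.agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            accuracy_se=("accuracy", "sem"),
            false_incl_rate=("false_incl_rate", "mean"),
            false_excl_rate=("false_excl_rate", "mean"),
            coef_det_mean=("coef_det", "mean"),
            n=("accuracy", "size"),
        ).reset_index()
        return out


def inclusion_table(grid: GridResult) -> pd.DataFrame:
    """Per-variable TRUE/FALSE table of selected vs true status.

    One row per (dataset, scenario, mechanism, method, replicate) plus a
    matching ``truth`` row per replicate, with one boolean column per
    eigenvector.
    """
    rows = []
    for rec in grid.selections:
        m = rec["m"]
        key = {k: rec[k] for k in ("dataset", "ev", "scaling", "modelling", "replicate")}
        truth = {f"V{j}": (j in rec["K"]) for j in range(1, m + 1)}
        rows.append({**key, "method": "truth", **truth})
        for method in ("GLM/AIC", "RDA/FW"):
            sel = rec[method]
            rows.append(
                {**key, "method": method,
                 **{f"V{j}": (j in sel) for j in range(1, m + 1)}}
            )
    return pd.DataFrame(rows)


def _scenarios_for(cfg: GridConfig, m: int) -> list[ScenarioSpec]:
    scen = all_scenarios(m, cfg.table)
    if cfg.levels is not None:
        scen = [s for s in scen if s.level in cfg.levels]
    scen = [s for s in scen if s.scaling in cfg.scalings or s.level in ("0", "m")]
    return scen


def run_grid(
    cfg: GridConfig,
    out_dir: str | Path | None = None,
    prepared: dict[str, PreparedDataset] | None = None,
) -> GridResult:
    """Run the full scenario grid and score both selection methods.

    Every replicate draws from its own RNG substream keyed by (dataset,
    scenario, mechanism, replicate), so runs are reproducible and
    independent of execution order. A failing replicate is logged and
    recorded with NaN scores; it does not abort the grid. When ``out_dir``
    is given, results are written incrementally to ``results.csv``.
    """
    sel_cfg = SelectionConfig(alpha=cfg.alpha, nperm=cfg.nperm)
    rows: list[dict] = []
    selections: list[dict] = []
    writer = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        writer = (out_dir / "results.csv").open("w")
    try:
        for d_idx, dspec in enumerate(cfg.datasets):
            prep = (prepared or {}).get(dspec.name) or prepare_dataset(dspec)
            m = prep.basis.m
            scen = _scenarios_for(cfg, m)
            for s_idx, scenario in enumerate(scen):
                for mech_idx, mech in enumerate(cfg.mechanisms):
                    for rep in range(cfg.replicates):
                        rec = _one_replicate(
                            cfg, sel_cfg, prep, scenario,
                            d_idx, s_idx, mech_idx, mech, rep,
                        )
                        row_pair, sel_rec = rec
                        rows.extend(row_pair)
                        if sel_rec is not None:
                            selections.append(sel_rec)
                        if writer is not None:
                            frame = pd.DataFrame(row_pair)
                            frame.to_csv(
                                writer, header=writer.tell() == 0, index=False
                            )
                            writer.flush()
    finally:
        if writer is not None:
            writer.close()
    return GridResult(results=pd.DataFrame(rows), selections=selections)


def _one_replicate(cfg, sel_cfg, prep, scenario, d_idx, s_idx, mech_idx, mech, rep):
    from memsel.coefficient_model import sample_coefficients

    key = {
        "dataset": prep.name,
        "ev": scenario.n_var,
        "level": scenario.level,
        "scaling": scenario.scaling,
        "modelling": mech.upper(),
        "replicate": rep,
    }
    rng = replicate_rng(cfg.seed, d_idx, s_idx, mech_idx, rep)
    try:
        cstar = sample_coefficients(prep.C, scenario.K, rng, prep.pool)
        simulate = simulate_spm if mech == "spm" else simulate_sam
        Y = simulate(prep.X, cstar, rng)
        glm_res = forward_select_glm(Y, prep.X)
        Yt = ochiai_transform(Y)
        rda_res = forward_select_rda(Yt, prep.basis.vectors, sel_cfg, rng)
    except Exception:  # noqa: BLE001 - a bad replicate must not kill the grid
        logger.exception("replicate failed: %s", key)
        nan_row = {**key, "accuracy": np.nan, "n_false_incl": np.nan,
                   "n_false_excl": np.nan, "false_incl_rate": np.nan,
                   "false_excl_rate": np.nan, "coef_det": np.nan,
                   "n_selected": np.nan, "error": True}
        return (
            [{**nan_row, "method": "GLM/AIC"}, {**nan_row, "method": "RDA/FW"}],
            None,
        )
    m = scenario.m
    out_rows = []
    for method, res in (("GLM/AIC", glm_res), ("RDA/FW", rda_res)):
        sc = score_selection(res.selected, scenario.K, m)
        out_rows.append(
            {
                **key,
                "method": method,
                "accuracy": sc.accuracy,
                "n_false_incl": sc.n_false_incl,
                "n_false_excl": sc.n_false_excl,
                "false_incl_rate": sc.n_false_incl / m,
                "false_excl_rate": sc.n_false_excl / m,
                "coef_det": res.coef_det,
                "n_selected": len(res.selected),
                "error": False,
            }
        )
    logger.info(
        "%s ev=%d s=%d %s rep=%d: GLM=%s RDA=%s",
        prep.name, scenario.n_var, scenario.scaling, mech, rep,
        glm_res.selected, rda_res.selected,
    )
    sel_rec = {
        "dataset": prep.name, "ev": scenario.n_var, "scaling": scenario.scaling,
        "modelling": mech.upper(), "replicate": rep, "m": m, "K": set(scenario.K),
        "GLM/AIC": set(glm_res.selected), "RDA/FW": set(rda_res.selected),
    }
    return out_rows, sel_rec
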