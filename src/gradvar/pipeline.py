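"""End-to-end pipeline: simulate -> embed -> disperse -> score -> model ->
graph -> report, with a reproducibility manifest.

Every stage reads its inputs from and writes its outputs to plain-text
files (TSV/JSON) under the run directory — except raw time series, which
are dense binary arrays. A manifest records parameter values, library
versions, and a SHA-256 digest of every output file; two runs with the same
configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import cohort as coh
from . import dispersion as disp
from . import embedding as emb
from . import inference as inf
from . import topology as top
from .mesh import MeshTopology

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "embed", "disperse", "score", "model", "graph", "report")

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Single configuration object for the full pipeline."""

    # cohort
    n_subjects: int = 120
    mesh_rows: int = 20
    mesh_cols: int = 25
    edge_length_mm: float = 4.0
    runs: tuple[int, ...] = (150, 150, 150, 150)
    behavior_effect: float = -0.4
    noise_sd: float = 2.0
    # embedding
    k: int = 3
    rank: int | str = "auto"
    max_rank: int = 20
    # dispersion
    percentile: float = 95.0
    min_area_mm2: float = 200.0
    # inference
    folds: int = 10
    perms: int = 1000
    holdout_perms: int = 10000
    holdout_fraction: float = 0.25
    pairs: tuple[tuple[int, int], ...] = ()
    min_rho: float = 0.6
    # graph
    density: float = 0.10
    n_parcels: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.holdout_fraction < 0.9:
            raise ValueError("holdout_fraction must be in (0, 0.9)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "runs" in raw:
            raw["runs"] = tuple(raw["runs"])
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _seeds(config: PipelineConfig) -> dict[str, int]:
    ss = np.random.SeedSequence(config.seed)
    names = ("cohort", "split", "folds", "cv", "holdout")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, ss.spawn(len(names)))
    }


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    from .mesh import build_mesh

    mesh = build_mesh(config.mesh_rows, config.mesh_cols, config.edge_length_mm)
    cc = coh.CohortConfig(
        n_subjects=config.n_subjects,
        runs=config.runs,
        behavior_effect=config.behavior_effect,
        noise_sd=config.noise_sd,
        seed=_seeds(config)["cohort"],
    )
    subjects, table, truth = coh.simulate_cohort(mesh, cc)
    cdir = out / "cohort"
    coh.write_cohort(cdir, mesh, subjects, table, truth, config=cc)
    atlas = coh.synthetic_atlas(mesh, config.n_parcels)
    atlas.to_csv(out / "atlas.tsv", sep="\t", index=False)
    files = sorted(cdir.iterdir()) + [out / "atlas.tsv"]
    return files


def _stage_embed(config: PipelineConfig, out: Path) -> list[Path]:
    mesh, subjects, _, truth = coh.read_cohort(out / "cohort")
    group, embeddings, _, profile = emb.embed_cohort(
        subjects,
        k=config.k,
        rank=config.rank,
        max_rank=config.max_rank,
        template=truth.gradient_maps,
    )
    edir = out / "embed"
    edir.mkdir(parents=True, exist_ok=True)
    cols = [f"g{j + 1}" for j in range(config.k)]
    pd.DataFrame(group.gradients, columns=cols).to_csv(
        edir / "group_gradients.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    for e in embeddings:
        pd.DataFrame(e.coords, columns=cols).to_csv(
            edir / f"coords_{e.subject_id}.tsv",
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
        )
    pd.DataFrame(
        {
            "individual_fraction": profile.individual_fraction,
            "weighted_fraction": profile.weighted_fraction,
        }
    ).to_csv(edir / "variance_profile.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return sorted(edir.iterdir())


def _load_embeddings(out: Path) -> tuple[list[emb.SubjectEmbedding], emb.GroupEmbedding]:
    edir = out / "embed"
    grad = pd.read_csv(edir / "group_gradients.tsv", sep="\t").to_numpy()
    svals = np.linspace(1.0, 0.5, grad.shape[1])  # ordering placeholder; spectrum not persisted
    group = emb.GroupEmbedding(
        gradients=grad, group_singular_values=svals, k=grad.shape[1]
    )
    embeddings = []
    for path in sorted(edir.glob("coords_*.tsv")):
        sid = path.stem.replace("coords_", "")
        embeddings.append(
            emb.SubjectEmbedding(subject_id=sid, coords=pd.read_csv(path, sep="\t").to_numpy())
        )
    return embeddings, group


def _stage_disperse(config: PipelineConfig, out: Path) -> list[Path]:
    mesh = MeshTopology.from_json(out / "cohort" / "mesh.json")
    embeddings, group = _load_embeddings(out)
    dmap = disp.vertex_dispersion(embeddings)
    clusters = disp.extract_clusters(
        dmap, mesh, percentile=config.percentile, min_area_mm2=config.min_area_mm2
    )
    ddir = out / "disperse"
    ddir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({"vertex": np.arange(mesh.n_vertices), "total": dmap.total})
    for j in range(config.k):
        frame[f"axis_{j + 1}"] = dmap.per_axis[:, j]
        frame[f"centroid_{j + 1}"] = dmap.centroids[:, j]
    frame.to_csv(ddir / "dispersion.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        {"vertex": np.arange(mesh.n_vertices), "label": clusters.labels}
    ).to_csv(ddir / "clusters.tsv", sep="\t", index=False)
    with open(ddir / "cluster_summary.json", "w") as fh:
        json.dump(
            {
                "threshold_value": clusters.threshold_value,
                "clusters": [
                    {"id": c.id, "n_vertices": int(c.vertices.size), "area_mm2": c.area_mm2}
                    for c in clusters.clusters
                ],
            },
            fh,
            indent=1,
        )
    corr = disp.axis_dispersion_correlation(dmap, group)
    corr.to_csv(ddir / "axis_correlations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    if clusters.clusters:
        table = disp.cluster_coordinates(embeddings, clusters)
        table.to_csv(ddir / "cluster_gradients.tsv", sep="\t", float_format=_FLOAT_FMT)
    else:
        raise RuntimeError("no dispersion clusters survived thresholding")
    return sorted(ddir.iterdir())


def _stage_score(config: PipelineConfig, out: Path) -> list[Path]:
    table = pd.read_csv(out / "cohort" / "behavior.tsv", sep="\t")
    scored = bhv.score_table(table)
    scored.to_csv(out / "scored.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return [out / "scored.tsv"]


def _stage_model(config: PipelineConfig, out: Path) -> list[Path]:
    seeds = _seeds(config)
    scored = pd.read_csv(out / "scored.tsv", sep="\t")
    grads = pd.read_csv(out / "disperse" / "cluster_gradients.tsv", sep="\t").set_index(
        "subject_id"
    )
    grads, pair_log = inf.bilateral_average(
        grads, list(config.pairs), min_rho=config.min_rho, n_axes=config.k
    )

    n = len(scored)
    rng = np.random.default_rng(seeds["split"])
    perm = rng.permutation(n)
    n_hold = int(round(config.holdout_fraction * n))
    hold_idx, est_idx = perm[:n_hold], perm[n_hold:]

    cov = bhv.encode_covariates(scored)
    results = {}
    models = []
    for measure in ("CI", "FI", "G"):
        for axis in range(1, config.k + 1):
            cols = [c for c in grads.columns if c.endswith(f"_g{axis}")]
            X = grads[cols].to_numpy()
            y = scored[measure].to_numpy()
            # residualize estimation and hold-out samples separately
            y_est = bhv.residualize_confounds(y[est_idx], cov[est_idx])
            X_est = bhv.residualize_confounds(X[est_idx], cov[est_idx])
            folds = inf.stratified_folds(
                y_est, config.folds, seed=seeds["folds"] + axis
            )
            res = inf.cv_permutation_model(
                y_est,
                X_est,
                folds,
                n_perm=config.perms,
                seed=seeds["cv"] + 13 * axis,
                predictors=cols,
            )
            models.append((measure, axis, res, y, X))
    p_Fs = [m[2].p_F for m in models]
    q_Fs = inf.fdr_adjust(np.asarray(p_Fs))
    for (measure, axis, res, _, _), qF in zip(models, q_Fs):
        res.q_F = float(qF)
        res.q_t = inf.fdr_adjust(res.p_t)
        results[f"{measure}_g{axis}"] = {
            "measure": measure,
            "axis": axis,
            "predictors": res.predictors,
            "fold_betas": res.fold_betas.tolist(),
            "mean_F": res.mean_F,
            "mean_t": res.mean_t.tolist(),
            "p_F": res.p_F,
            "q_F": res.q_F,
            "p_t": res.p_t.tolist(),
            "q_t": res.q_t.tolist(),
            "significant": bool(qF < 0.05),
        }

    holdout_out = {}
    if n_hold > 0:
        for measure, axis, res, y, X in models:
            y_hold = bhv.residualize_confounds(y[hold_idx], cov[hold_idx])
            X_hold = bhv.residualize_confounds(X[hold_idx], cov[hold_idx])
            hres = inf.holdout_validation(
                res, y_hold, X_hold, n_perm=config.holdout_perms, seed=seeds["holdout"]
            )
            holdout_out[f"{measure}_g{axis}"] = {
                "beta": hres.beta.tolist(),
                "F": hres.F,
                "t": hres.t.tolist(),
                "p_F": hres.p_F,
                "p_t": hres.p_t.tolist(),
                "q_t": hres.q_t.tolist(),
            }

    mdir = out / "model"
    mdir.mkdir(parents=True, exist_ok=True)
    with open(mdir / "model_results.json", "w") as fh:
        json.dump({"models": results, "pair_log": pair_log}, fh, indent=1)
    with open(mdir / "holdout_results.json", "w") as fh:
        json.dump(holdout_out, fh, indent=1)

    # per-task screen: first cluster's principal-gradient column vs the
    # fluid-subset task scores, over the estimation sample
    g1_cols = [c for c in grads.columns if c.endswith("_g1")]
    x = bhv.residualize_confounds(
        grads[g1_cols[0]].to_numpy()[est_idx], cov[est_idx]
    )
    tasks = scored.loc[scored.index[est_idx], list(coh.FLUID_TASKS)]
    screen = inf.spearman_screen(x, tasks)
    screen.to_csv(mdir / "task_screen.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return sorted(mdir.iterdir())


def _stage_graph(config: PipelineConfig, out: Path) -> list[Path]:
    mesh, subjects, _, _ = coh.read_cohort(out / "cohort")
    atlas = pd.read_csv(out / "atlas.tsv", sep="\t")
    labels = pd.read_csv(out / "disperse" / "clusters.tsv", sep="\t")["label"].to_numpy()
    with open(out / "disperse" / "cluster_summary.json") as fh:
        summary = json.load(fh)
    clusters = disp.ClusterSet(
        labels=labels,
        clusters=[
            disp.Cluster(
                id=c["id"],
                vertices=np.flatnonzero(labels == c["id"]),
                area_mm2=c["area_mm2"],
            )
            for c in summary["clusters"]
        ],
        threshold_value=summary["threshold_value"],
    )
    parc = top.augment_parcellation(atlas, clusters)
    gdir = out / "graph"
    gdir.mkdir(parents=True, exist_ok=True)
    parc.overlap.to_csv(gdir / "overlap.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    cluster_nodes = [n for n in parc.parcel_names if n.startswith("cluster_")]
    metrics_all = []
    for ts in subjects:
        node_ts = top.parcel_timeseries(ts, parc)
        graph = top.correlation_graph(
            node_ts,
            density=config.density,
            communities=parc.communities,
            node_names=parc.parcel_names,
        )
        pd.DataFrame(
            graph.weights, index=parc.parcel_names, columns=parc.parcel_names
        ).to_csv(gdir / f"adjacency_{ts.subject_id}.tsv", sep="\t", float_format=_FLOAT_FMT)
        metrics_all.append(top.node_metrics(graph))
    long = pd.concat(
        metrics_all, keys=[ts.subject_id for ts in subjects], names=["subject_id", "node"]
    )
    long.to_csv(gdir / "metrics.tsv", sep="\t", float_format=_FLOAT_FMT)

    zprof = top.metric_zprofile(metrics_all, cluster_nodes)
    zprof.to_csv(gdir / "zprofile.tsv", sep="\t", float_format=_FLOAT_FMT)

    grads = pd.read_csv(out / "disperse" / "cluster_gradients.tsv", sep="\t").set_index(
        "subject_id"
    )
    first = cluster_nodes[0]
    cid = first.replace("cluster_", "")
    axis = grads[f"c{cid}_g1"].to_numpy()
    cl_metrics = pd.DataFrame(
        [m.loc[first] for m in metrics_all],
        index=[ts.subject_id for ts in subjects],
    )
    assoc = top.gradient_topology_association(axis, cl_metrics)
    assoc.to_csv(gdir / "topology_association.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return sorted(gdir.iterdir())


def _stage_report(config: PipelineConfig, out: Path) -> list[Path]:
    with open(out / "model" / "model_results.json") as fh:
        model = json.load(fh)
    with open(out / "disperse" / "cluster_summary.json") as fh:
        summary = json.load(fh)
    zprof = pd.read_csv(out / "graph" / "zprofile.tsv", sep="\t", index_col=0)
    assoc = pd.read_csv(out / "graph" / "topology_association.tsv", sep="\t")
    significant = {
        name: m for name, m in model["models"].items() if m["significant"]
    }
    report = {
        "n_clusters": len(summary["clusters"]),
        "cluster_areas_mm2": [c["area_mm2"] for c in summary["clusters"]],
        "significant_models": sorted(significant),
        "model_p_F": {name: m["p_F"] for name, m in model["models"].items()},
        "cluster_zprofile": zprof.to_dict(orient="index"),
        "topology_association": assoc.to_dict(orient="records"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return [out / "summary.json"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "embed": _stage_embed,
    "disperse": _stage_disperse,
    "score": _stage_score,
    "model": _stage_model,
    "graph": _stage_graph,
    "report": _stage_report,
}

_STAGE_OUTPUTS = {
    "simulate": ["cohort/behavior.tsv", "atlas.tsv"],
    "embed": ["embed/group_gradients.tsv", "embed/variance_profile.tsv"],
    "disperse": ["disperse/dispersion.tsv", "disperse/cluster_gradients.tsv"],
    "score": ["scored.tsv"],
    "model": ["model/model_results.json", "model/holdout_results.json"],
    "graph": ["graph/metrics.tsv", "graph/topology_association.tsv"],
    "report": ["summary.json"],
}


def run_pipeline(
    config: PipelineConfig, out_dir, resume: bool = False, logger=None
) -> dict:
    """Execute all stages; return (and write) the run manifest.

    With ``resume=True`` a stage is skipped when its sentinel outputs
    already exist *and* no upstream stage has been re-run.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "versions": _versions(),
        "stages": {},
    }
    prior = {}
    if resume and (out / "manifest.json").exists():
        with open(out / "manifest.json") as fh:
            prior = json.load(fh).get("stages", {})
    dirty = False
    for stage in STAGES:
        sentinels = [out / f for f in _STAGE_OUTPUTS[stage]]
        if resume and not dirty and all(s.exists() for s in sentinels):
            if logger:
                logger(f"skip {stage} (outputs exist)")
            files = [out / f for f in prior.get(stage, {})] or sentinels
        else:
            dirty = True
            if logger:
                logger(f"run {stage}")
            try:
                files = _STAGE_FN[stage](config, out)
            except Exception as exc:  # noqa: BLE001 - annotate failing stage
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            str(f.relative_to(out)): _sha256(f) for f in files if f.is_file()
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["runs"] = list(d["runs"])
    d["pairs"] = [list(p) for p in d["pairs"]]
    return d


def _versions() -> dict:
    import networkx
    import scipy
    import statsmodels

    from . import __version__

    return {
        "gradvar": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "statsmodels": statsmodels.__version__,
    }
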