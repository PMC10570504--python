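"""End-to-end pipeline: generate -> solve -> decompose -> embed -> train -> evaluate.

A :class:`RunConfig` (loadable from YAML) drives the whole run; a master seed
deterministically derives one sub-seed per randomised stage (geometry draws,
t-SNE, train/test split, forests), so any stage can be rerun in isolation and
a rerun with the same seed reproduces every table bit for bit.  Stage outputs
land in a run directory; the expensive stages (flow ensemble, embedding) are
cached there keyed by a hash of the configuration, so downstream stages can
be recomputed without re-solving.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from .embedding import ShapeEmbedding, shape_vectors
from .geometry import (
    MeshResolution,
    PerturbationBounds,
    VesselGeometry,
    default_reference_vessels,
    generate_dataset,
    perturbation_log,
)
from .metrics import ErrorReport, evaluate_test_set, field_range
from .pod import CommonBasePOD, assemble
from .regression import ChainedForestRegressor, coefficient_rmse_percent
from .solver import RheologyParams, SolverConfig, get_solver

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "predict_unseen", "load_run"]

STAGES = ("generate", "solve", "decompose", "embed", "train", "evaluate")
FIELDS = ("pressure", "wss")


@dataclass(frozen=True)
class RunConfig:
    """Every knob of one pipeline run; defaults are the full-scale study."""

    n_perturb: int = 200
    n_axial: int = 101
    n_circ: int = 32
    n_radial: int = 4
    a_max: float = 0.08
    d_max: float = 0.03
    f_min: float = 0.5
    f_max: float = 2.5
    inlet_speed_cm_s: float = 100.0
    density_kg_m3: float = 1060.0
    solver: str = "quasi1d"
    n_modes: int = 10                      # POD truncation (modes)
    energy_threshold: float | None = None  # alternative: energy fraction
    perplexity: float = 30.0
    knn_neighbors: int = 5
    n_trees: int = 70
    max_depth: int = 20
    cascade: str = "predicted"
    train_fraction: float = 0.8
    n_split_repeats: int = 10              # seeded split repeats for metrics
    chain_order_check: bool = False        # also log reversed-order metrics
    fields: tuple[str, ...] = FIELDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        bad = set(self.fields) - set(FIELDS)
        if bad:
            raise ValueError(f"unknown fields {sorted(bad)}")

    # -- sub-configs -------------------------------------------------------

    @property
    def resolution(self) -> MeshResolution:
        return MeshResolution(self.n_axial, self.n_circ, self.n_radial)

    @property
    def bounds(self) -> PerturbationBounds:
        return PerturbationBounds(self.a_max, self.d_max, self.f_min, self.f_max)

    @property
    def solver_config(self) -> SolverConfig:
        return SolverConfig(self.inlet_speed_cm_s, self.density_kg_m3)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fields"] = list(self.fields)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fields" in d:
            d["fields"] = tuple(d["fields"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Derive the per-stage seed from the master seed (documented, stable).

        SeedSequence(master).spawn(len(STAGES)) in stage order; each child's
        first generated state word, folded below 2^31.
        """
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        idx = STAGES.index(stage)
        return int(children[idx].generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    """In-memory artefacts of one run (also persisted to the run directory)."""

    config: RunConfig
    geometries: list[VesselGeometry]
    solutions_by_field: dict[str, np.ndarray]       # field -> (M, N) matrix
    pods: dict[str, CommonBasePOD]
    embedding: ShapeEmbedding | None
    chains: dict[str, ChainedForestRegressor]
    reports: dict[str, ErrorReport]
    pod_reports: dict[str, ErrorReport]             # truncation-only errors
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    @property
    def mesh_ids(self) -> list[str]:
        return [g.id for g in self.geometries]


# ---------------------------------------------------------------------------


def _split_indices(m: int, train_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    n_train = int(round(train_fraction * m))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def run_pipeline(
    cfg: RunConfig,
    outdir: str | Path,
    until: str = "evaluate",
    progress: bool = False,
) -> PipelineResult:
    """Execute the pipeline up to (and including) stage ``until``.

    Writes tables, models and a manifest into ``outdir``; returns the
    in-memory result.  Failures abort with the stage name attached.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "stages").mkdir(exist_ok=True)
    chash = cfg.config_hash()
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": chash,
        "stages": {},
    }
    last = STAGES.index(until)
    t_all = time.perf_counter()

    def _stage(name):
        return STAGES.index(name) <= last

    def _log(name, t0, **info):
        manifest["stages"][name] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
            **info,
        }
        if progress:
            print(f"[{name}] {manifest['stages'][name]}")

    # -- generate ----------------------------------------------------------
    t0 = time.perf_counter()
    refs = default_reference_vessels(cfg.n_axial)
    try:
        geoms = generate_dataset(
            refs,
            cfg.n_perturb,
            seed=cfg.stage_seed("generate"),
            resolution=cfg.resolution,
            bounds=cfg.bounds,
        )
    except Exception as e:
        raise RuntimeError(f"stage 'generate' failed: {e}") from e
    perturbation_log(geoms).to_csv(outdir / "perturbation_params.csv", index=False)
    _log("generate", t0, n_meshes=len(geoms))
    result = PipelineResult(cfg, geoms, {}, {}, None, {}, {}, {})
    if not _stage("solve"):
        _finish(manifest, outdir, t_all)
        return result

    # -- solve (cached) ----------------------------------------------------
    t0 = time.perf_counter()
    cache = outdir / "stages" / f"fields_{chash}.npz"
    if cache.exists():
        with np.load(cache) as z:
            result.solutions_by_field = {f: z[f] for f in cfg.fields}
        cached = True
    else:
        solver = get_solver(cfg.solver)
        scfg, rheo = cfg.solver_config, RheologyParams()
        sols = []
        for g in geoms:
            try:
                sols.append(solver(g, scfg, rheo))
            except Exception as e:
                raise RuntimeError(f"stage 'solve' failed on mesh {g.id!r}: {e}") from e
        result.solutions_by_field = {f: assemble(sols, f) for f in cfg.fields}
        np.savez_compressed(cache, **result.solutions_by_field)
        cached = False
    _log("solve", t0, cached=cached)
    if not _stage("decompose"):
        _finish(manifest, outdir, t_all)
        return result

    # -- decompose ---------------------------------------------------------
    t0 = time.perf_counter()
    mode_info = {}
    for f in cfg.fields:
        pod = CommonBasePOD(
            n_modes=None if cfg.energy_threshold else cfg.n_modes,
            energy_threshold=cfg.energy_threshold,
        ).fit(result.solutions_by_field[f])
        result.pods[f] = pod
        sigma = pod.singular_values_
        pd.DataFrame(
            {
                "mode": np.arange(1, sigma.size + 1),
                "sigma": sigma,
                "energy_fraction_sum": np.cumsum(sigma) / sigma.sum(),
                "energy_fraction_sq": np.cumsum(sigma**2) / (sigma**2).sum(),
            }
        ).to_csv(outdir / f"singular_values_{f}.csv", index=False)
        coeffs = pd.DataFrame(
            pod.coefficients_[:, : pod.n_modes_],
            columns=[f"c{j + 1}" for j in range(pod.n_modes_)],
        )
        coeffs.insert(0, "mesh_id", result.mesh_ids)
        coeffs.to_csv(outdir / f"coefficients_{f}.csv", index=False)
        np.savez_compressed(
            outdir / f"pod_{f}.npz",
            modes=pod.components_[: pod.n_modes_],
            singular_values=pod.singular_values_,
            coefficients=pod.coefficients_[:, : pod.n_modes_],
            n_modes=pod.n_modes_,
            field=f,
            mesh_ids=np.array(result.mesh_ids),
        )
        mode_info[f] = {
            "k": pod.n_modes_,
            "energy_fraction_pct": round(100 * pod.energy_fraction(pod.n_modes_), 3),
        }
    _log("decompose", t0, **mode_info)
    if not _stage("embed"):
        _finish(manifest, outdir, t_all)
        return result

    # -- embed (cached) ----------------------------------------------------
    t0 = time.perf_counter()
    emb_cache = outdir / "stages" / f"embedding_{chash}.joblib"
    if emb_cache.exists():
        result.embedding = joblib.load(emb_cache)
        cached = True
    else:
        X = shape_vectors(geoms)
        result.embedding = ShapeEmbedding(
            perplexity=cfg.perplexity,
            n_neighbors=cfg.knn_neighbors,
            random_state=cfg.stage_seed("embed"),
        ).fit(X)
        joblib.dump(result.embedding, emb_cache)
        cached = False
    emb = pd.DataFrame(result.embedding.embedding_, columns=["tsne_x", "tsne_y"])
    emb.insert(0, "parent_id", [g.parent_id for g in geoms])
    emb.insert(0, "mesh_id", result.mesh_ids)
    emb.to_csv(outdir / "embedding.csv", index=False)
    _log("embed", t0, cached=cached)
    if not _stage("train"):
        _finish(manifest, outdir, t_all)
        return result

    # -- train -------------------------------------------------------------
    t0 = time.perf_counter()
    split_seed = cfg.stage_seed("train")
    tr, te = _split_indices(len(geoms), cfg.train_fraction, split_seed)
    result.train_idx, result.test_idx = tr, te
    E = result.embedding.embedding_
    coef_rows = []
    for f in cfg.fields:
        pod = result.pods[f]
        C = pod.coefficients_[:, : pod.n_modes_]
        chain = ChainedForestRegressor(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            cascade=cfg.cascade,
            random_state=cfg.stage_seed("train"),
        ).fit(E[tr], C[tr])
        result.chains[f] = chain
        joblib.dump(chain, outdir / f"chain_{f}.joblib")
        # per-mode coefficient RMSE%, averaged over seeded split repeats
        for rep in range(cfg.n_split_repeats):
            rtr, rte = _split_indices(len(geoms), cfg.train_fraction, split_seed + rep)
            mdl = chain if rep == 0 else ChainedForestRegressor(
                n_estimators=cfg.n_trees,
                max_depth=cfg.max_depth,
                cascade=cfg.cascade,
                random_state=cfg.stage_seed("train") + rep,
            ).fit(E[rtr], C[rtr])
            pred = mdl.predict(E[rte])
            for j in range(C.shape[1]):
                rng_j = float(C[rtr, j].max() - C[rtr, j].min())
                coef_rows.append(
                    {
                        "field": f,
                        "mode": j + 1,
                        "rmse_percent": coefficient_rmse_percent(
                            pred, C[rte], j, training_range=rng_j
                        ),
                        "split_seed": split_seed + rep,
                        "chain_order": "default",
                    }
                )
        if cfg.chain_order_check:
            rev = ChainedForestRegressor(
                n_estimators=cfg.n_trees,
                max_depth=cfg.max_depth,
                order=list(range(C.shape[1]))[::-1],
                cascade=cfg.cascade,
                random_state=cfg.stage_seed("train"),
            ).fit(E[tr], C[tr])
            pred = rev.predict(E[te])
            for j in range(C.shape[1]):
                rng_j = float(C[tr, j].max() - C[tr, j].min())
                coef_rows.append(
                    {
                        "field": f,
                        "mode": j + 1,
                        "rmse_percent": coefficient_rmse_percent(
                            pred, C[te], j, training_range=rng_j
                        ),
                        "split_seed": split_seed,
                        "chain_order": "reversed",
                    }
                )
    coef_df = pd.DataFrame(coef_rows)
    means = (
        coef_df[coef_df.chain_order == "default"]
        .groupby(["field", "mode"], as_index=False)["rmse_percent"]
        .mean()
        .assign(split_seed="mean", chain_order="default")
    )
    pd.concat([coef_df, means], ignore_index=True).to_csv(
        outdir / "metrics_coefficients.csv", index=False
    )
    _log("train", t0, n_train=len(tr), n_test=len(te), repeats=cfg.n_split_repeats)
    if not _stage("evaluate"):
        _finish(manifest, outdir, t_all)
        return result

    # -- evaluate ----------------------------------------------------------
    t0 = time.perf_counter()
    frames = []
    err_info = {}
    ids = np.array(result.mesh_ids)
    for f in cfg.fields:
        A = result.solutions_by_field[f]
        pod = result.pods[f]
        rng_f = field_range(A)
        pred_coef = result.chains[f].predict(E[te])
        rec_ml = pod.inverse_transform(pred_coef)
        rec_pod = pod.inverse_transform(pod.transform(A[te]))
        rep_ml = evaluate_test_set(A[te], rec_ml, list(ids[te]), f, rng_f)
        rep_pod = evaluate_test_set(A[te], rec_pod, list(ids[te]), f, rng_f)
        result.reports[f] = rep_ml
        result.pod_reports[f] = rep_pod
        frames.append(rep_ml.to_frame().assign(source="ml_prediction"))
        frames.append(rep_pod.to_frame().assign(source="pod_truncation"))
        err_info[f] = {
            "ml_nmae_pct": round(rep_ml.nmae_mean, 4),
            "ml_nrmse_pct": round(rep_ml.nrmse_mean, 4),
            "pod_nrmse_pct": round(rep_pod.nrmse_mean, 4),
        }
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "metrics_fields.csv", index=False
    )
    _log("evaluate", t0, **err_info)
    _finish(manifest, outdir, t_all)
    return result


def _finish(manifest: dict, outdir: Path, t_all: float) -> None:
    manifest["total_wall_time_s"] = round(time.perf_counter() - t_all, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------


def load_run(outdir: str | Path) -> tuple[RunConfig, dict, ShapeEmbedding, dict]:
    """Load the persisted models of a completed run (for prediction)."""
    outdir = Path(outdir)
    cfg = RunConfig.from_dict(json.loads((outdir / "manifest.json").read_text())["config"])
    pods = {}
    for f in cfg.fields:
        with np.load(outdir / f"pod_{f}.npz", allow_pickle=False) as z:
            pod = CommonBasePOD(n_modes=int(z["n_modes"]))
            pod.components_ = z["modes"]
            pod.singular_values_ = z["singular_values"]
            pod.coefficients_ = z["coefficients"]
            pod.mean_ = np.zeros(z["modes"].shape[1])
            pod.n_features_in_ = z["modes"].shape[1]
            pod.n_modes_ = int(z["n_modes"])
            pods[f] = pod
    embedding = joblib.load(outdir / "stages" / f"embedding_{cfg.config_hash()}.joblib")
    chains = {f: joblib.load(outdir / f"chain_{f}.joblib") for f in cfg.fields}
    return cfg, pods, embedding, chains


def predict_unseen(
    run: PipelineResult | str | Path, geom: VesselGeometry
) -> dict[str, dict]:
    """Reconstruct pressure and WSS for an unseen geometry and report errors.

    Embeds the new mesh (out-of-sample), predicts its POD coefficients with
    the trained chains, reconstructs both fields, and compares against a
    fresh surrogate solve of the same geometry (NMAE/NRMSE on the run's
    dataset-wide range).
    """
    if isinstance(run, PipelineResult):
        cfg, pods, embedding, chains = run.config, run.pods, run.embedding, run.chains
        ranges = {f: field_range(run.solutions_by_field[f]) for f in cfg.fields}
    else:
        cfg, pods, embedding, chains = load_run(run)
        ranges = None
    if geom.resolution != cfg.resolution:
        raise ValueError("geometry resolution does not match the run's resolution")
    coords = embedding.transform(geom.shape_vector()[None, :])
    truth = get_solver(cfg.solver)(geom, cfg.solver_config, RheologyParams())
    out: dict[str, dict] = {}
    from .metrics import nmae as _nmae, nrmse as _nrmse

    for f in cfg.fields:
        coef = chains[f].predict(coords)
        rec = pods[f].inverse_transform(coef)[0]
        gt = getattr(truth, f)
        entry = {
            "coefficients": coef[0],
            "reconstruction": rec,
            "ground_truth": gt,
            "tsne_coordinate": coords[0],
        }
        if ranges is not None:
            entry["nmae_pct"] = _nmae(rec, gt, ranges[f])
            entry["nrmse_pct"] = _nrmse(rec, gt, ranges[f])
        out[f] = entry
    return out
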