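"""End-to-end orchestration: data -> innovations -> proximity -> tree ->
order regression -> compactness, with a reproducible artifact manifest.

Every stage writes its artifact(s) under the run directory; a stage
failure renames that stage's partially written files to ``*.partial``
and aborts with the stage name. The manifest records the configuration,
its hash, the seed, library versions, and a checksum for every artifact,
so two runs of one config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AreaAtlas, load_atlas, load_reference_atlas
from .synthetic import RawDataset, SynthConfig, simulate_dataset
from .prewhiten import InnovationsDataset, prewhiten_dataset
from .connectivity import ProximityMatrix, build_proximity
from .clustering import leaf_order, profile_distance_matrix, upgma
from .regression import fit_order_on_coordinates
from .compactness import (
    LayoutSequence,
    adjacency_test,
    metamodule_test,
    size_law_curve,
    subset_analysis,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    seed: int = 0
    atlas_path: str | None = None        # None -> packaged 52-area atlas
    input_csv: str | None = None         # external long-format raw data
    synth: SynthConfig = field(default_factory=SynthConfig)
    arima_order: tuple[int, int, int] = (15, 1, 1)
    estimation_method: str = "hannan_rissanen"
    trim: int = 3
    max_cv: float = 0.05
    lb_lags: int = 20
    leaf_order_policy: str = "seriate"
    rectify_lr: bool = True
    n_perms: int = 1000
    subset_sizes: tuple[int, ...] = (12, 20, 30, 40, 51)
    subset_sizes_hemisphere: tuple[int, ...] = (10, 15, 20, 25)
    n_subsets: int = 1000
    subset_n_perms: int = 1000
    per_hemisphere: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = self.synth.asdict()
        d["arima_order"] = list(self.arima_order)
        d["subset_sizes"] = list(self.subset_sizes)
        d["subset_sizes_hemisphere"] = list(self.subset_sizes_hemisphere)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        synth_raw = dict(raw.pop("synth", {}))
        for key in ("ar_coefs", "ma_coefs"):
            if key in synth_raw:
                synth_raw[key] = tuple(synth_raw[key])
        known = {f.name for f in dataclasses.fields(SynthConfig)}
        bad = set(synth_raw) - known
        if bad:
            raise PipelineError(f"unknown synth config keys: {sorted(bad)}")
        synth = SynthConfig(**synth_raw)
        for key in ("arima_order", "subset_sizes", "subset_sizes_hemisphere"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)} - {"synth"}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        return cls(synth=synth, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


class _Stage:
    """Context manager renaming a failed stage's outputs to *.partial."""

    def __init__(self, name: str, files: list[Path]):
        self.name = name
        self.files = files

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            for f in self.files:
                if f.exists():
                    f.rename(f.with_suffix(f.suffix + ".partial"))
            raise PipelineError(f"stage '{self.name}' failed: {exc}") from exc
        return False


def _analyze_sequence(seq: LayoutSequence, cfg: RunConfig, sizes: tuple[int, ...]) -> dict:
    adjacency = adjacency_test(seq, n_perms=cfg.n_perms, seed=cfg.seed)
    sizes = tuple(L for L in sizes if L <= len(seq))
    windows = subset_analysis(
        seq, list(sizes), n_subsets=cfg.n_subsets,
        n_perms=cfg.subset_n_perms, seed=cfg.seed,
    )
    size_law = size_law_curve(seq, list(sizes), windows=windows)
    meta = metamodule_test(seq, list(sizes), windows=windows)
    return {
        "rectified": seq.rectified,
        "n_areas": len(seq),
        "adjacency": adjacency.to_dict(),
        "size_law": size_law.to_dict(orient="records"),
        "metamodule": meta.to_dict(orient="records"),
        "n_subsets": cfg.n_subsets,
        "subset_n_perms": cfg.subset_n_perms,
    }


def _cluster(proximity: ProximityMatrix, cfg: RunConfig, atlas: AreaAtlas):
    dist = profile_distance_matrix(proximity)
    tree = upgma(dist, labels=proximity.labels)
    pa = atlas.frame.set_index("label").loc[proximity.labels, "y"].to_numpy(dtype=float)
    order = leaf_order(
        tree,
        policy=cfg.leaf_order_policy,
        dist=dist,
        orient_by=pa if cfg.leaf_order_policy == "seriate" else None,
    )
    return tree, order


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict[str, str]] = {}

    def register(stage: str, *files: Path) -> None:
        artifacts[stage] = {f.name: _sha256(f) for f in files}

    # -- atlas -------------------------------------------------------------
    with _Stage("atlas", []):
        atlas = load_atlas(cfg.atlas_path) if cfg.atlas_path else load_reference_atlas()

    # -- raw data ----------------------------------------------------------
    with _Stage("data", []):
        if cfg.input_csv:
            raw = RawDataset.from_csv(cfg.input_csv, atlas)
        else:
            raw = simulate_dataset(atlas, cfg.synth)

    # -- prewhitening ------------------------------------------------------
    diag_path = out / "innovations_diagnostics.json"
    with _Stage("prewhiten", [diag_path]):
        innovations = prewhiten_dataset(
            raw, order=cfg.arima_order, trim=cfg.trim, max_cv=cfg.max_cv,
            method=cfg.estimation_method, lb_lags=cfg.lb_lags,
        )
        diag = innovations.diagnostics
        ok = diag[diag["status"] == "ok"]
        _write_json(
            diag_path,
            {
                "order": list(cfg.arima_order),
                "estimation_method": cfg.estimation_method,
                "trend": "drift (t) for d >= 1",
                "n_voxels_ok": int(len(ok)),
                "n_voxels_excluded": int(len(diag) - len(ok)),
                "ljung_box_pass_rate_p01": float((ok["lb_p"] > 0.01).mean()),
                "durbin_watson_in_1p5_2p5": float(ok["dw"].between(1.5, 2.5).mean()),
                "voxels": json.loads(diag.to_json(orient="records")),
            },
        )
        register("prewhiten", diag_path)

    # -- proximity ---------------------------------------------------------
    prox_path, prox_meta = out / "proximity.csv", out / "proximity_meta.json"
    with _Stage("proximity", [prox_path, prox_meta]):
        proximity = build_proximity(innovations, atlas)
        proximity.to_csv(prox_path, sidecar=prox_meta)
        register("proximity", prox_path, prox_meta)

    # -- tree --------------------------------------------------------------
    newick_path, merges_path = out / "tree.nwk", out / "tree_merges.csv"
    with _Stage("tree", [newick_path, merges_path]):
        tree, order = _cluster(proximity, cfg, atlas)
        newick_path.write_text(tree.to_newick() + "\n")
        tree.to_merge_csv(merges_path)
        register("tree", newick_path, merges_path)

    # -- leaf order --------------------------------------------------------
    order_path = out / "leaf_order.csv"
    with _Stage("leaf_order", [order_path]):
        order.to_csv(order_path, atlas=atlas)
        register("leaf_order", order_path)

    # -- regression --------------------------------------------------------
    reg_path, scatter_path = out / "regression.json", out / "observed_vs_predicted.csv"
    with _Stage("regression", [reg_path, scatter_path]):
        reg = fit_order_on_coordinates(order, atlas, rectify_lr=False)
        reg.to_json(reg_path)
        reg.observed_vs_predicted().to_csv(scatter_path, index=False)
        register("regression", reg_path, scatter_path)

    # -- compactness -------------------------------------------------------
    compact_path = out / "compactness.json"
    with _Stage("compactness", [compact_path]):
        seq = LayoutSequence.from_leaf_order(order, atlas, rectify_lr=cfg.rectify_lr)
        payload = {"bilateral": _analyze_sequence(seq, cfg, cfg.subset_sizes)}
        if cfg.per_hemisphere and atlas.is_bilateral():
            for hemi in ("left", "right"):
                sub_atlas = atlas.subset(hemi)
                keep = [i for i, l in enumerate(proximity.labels) if l in set(sub_atlas.labels)]
                sub_prox = ProximityMatrix(
                    labels=[proximity.labels[i] for i in keep],
                    values=proximity.values[np.ix_(keep, keep)],
                    n_subjects=proximity.n_subjects,
                )
                _, sub_order = _cluster(sub_prox, cfg, sub_atlas)
                sub_seq = LayoutSequence.from_leaf_order(sub_order, sub_atlas, rectify_lr=False)
                payload[hemi] = _analyze_sequence(sub_seq, cfg, cfg.subset_sizes_hemisphere)
        _write_json(compact_path, payload)
        register("compactness", compact_path)

    manifest = {
        "package": "cortical-layout",
        "version": __version__,
        "python": sys.version.split()[0],
        "library_versions": _library_versions(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "artifacts": artifacts,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def _library_versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def render_report(run_dir: str | Path) -> list[Path]:
    """Render the observed-vs-predicted scatter and size-law curve as SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    written: list[Path] = []

    scatter_csv = run / "observed_vs_predicted.csv"
    if scatter_csv.exists():
        frame = pd.read_csv(scatter_csv)
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(frame["predicted"], frame["observed"], s=18)
        lims = [frame[["observed", "predicted"]].min().min(),
                frame[["observed", "predicted"]].max().max()]
        ax.plot(lims, lims, lw=0.8, color="gray")
        ax.set_xlabel("predicted tree order")
        ax.set_ylabel("observed tree order")
        out = run / "observed_vs_predicted.svg"
        fig.savefig(out)
        plt.close(fig)
        written.append(out)

    compact_json = run / "compactness.json"
    if compact_json.exists():
        payload = json.loads(compact_json.read_text())
        curve = pd.DataFrame(payload["bilateral"]["size_law"])
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(curve["L"], curve["c_geometric_mean"], marker="o")
        ax.set_xlabel("subset size L")
        ax.set_ylabel("geometric mean compactness index")
        out = run / "size_law.svg"
        fig.savefig(out)
        plt.close(fig)
        written.append(out)
    return written
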