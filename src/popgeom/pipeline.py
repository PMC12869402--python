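"""End-to-end synthetic-study pipeline.

``run_pipeline(config_path)`` drives the full workflow — simulate two
populations, build decoding manifolds/trajectories, encoding manifolds,
tubularity scores with a between-system comparison, and the alignment
battery — writing every artifact plus a manifest and a log into a run
directory. One global seed deterministically derives one sub-seed per stage
(via ``numpy.random.SeedSequence([global_seed, stage_index])``), so a single
number reproduces the whole run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .alignment import AlignmentModel
from .core import ResponseTensor
from .decoding import DecodingModel, ablate_neurons, selectivity_indices
from .encoding import EncodingModel
from .errors import SchemaError
from .synthetic import (
    EnsembleConfig,
    PopulationConfig,
    make_stimulus_ensemble,
    simulate_population,
)
from .tubularity import TubularityModel, compare_scores

__all__ = ["run_pipeline", "export_psth_figure_data", "PipelineConfig", "stage_seed"]

_STAGES = ("simulate_a", "simulate_b", "decode", "encode", "tubularity", "align")

_TOP_KEYS = {"seed", "ensemble", "population", "population_b", "decoding",
             "encoding", "tubularity", "alignment"}
_SECTION_KEYS = {
    "ensemble": {"classes", "n_directions"},
    "population": {
        "neurons_per_class", "kappa_range", "profiles", "noise_model", "noise_scale",
        "n_time", "bin_width", "cross_affinity", "gain_range", "periodic_cycles",
        "sustained_tau", "nonselective_tau", "transient_peak", "class_profiles",
    },
    "decoding": {"n_dims", "grouping"},
    "encoding": {"rank", "normalization", "k_neighbors", "n_dims", "diffusion_time",
                 "n_restarts"},
    "tubularity": {"n_boot", "n_comparisons"},
    "alignment": {"cca_components", "cca_pca_dim", "lp_folds", "lp_ridge", "dsa_rank",
                  "dsa_restarts"},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, documented derivation."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring)."""

    seed: int = 0
    ensemble: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    population_b: dict | None = None
    decoding: dict = field(default_factory=dict)
    encoding: dict = field(default_factory=dict)
    tubularity: dict = field(default_factory=dict)
    alignment: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        for section, allowed in _SECTION_KEYS.items():
            body = raw.get(section) or {}
            bad = set(body) - allowed
            if bad:
                raise SchemaError(
                    f"unknown key(s) in section {section!r}: {sorted(bad)}"
                )
        pb = raw.get("population_b")
        if pb is not None:
            bad = set(pb) - _SECTION_KEYS["population"]
            if bad:
                raise SchemaError(f"unknown key(s) in section 'population_b': {sorted(bad)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            ensemble=raw.get("ensemble") or {},
            population=raw.get("population") or {},
            population_b=pb,
            decoding=raw.get("decoding") or {},
            encoding=raw.get("encoding") or {},
            tubularity=raw.get("tubularity") or {},
            alignment=raw.get("alignment") or {},
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError("pipeline config must be a mapping")
        return cls.from_mapping(raw)


def _pop_config(body: dict) -> PopulationConfig:
    kw = dict(body)
    for key in ("kappa_range", "gain_range", "profiles"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    return PopulationConfig(**kw)


def run_pipeline(config_path, out_dir) -> Path:
    """Run the full synthetic study; returns the run directory.

    Every stage logs its parameters and derived seed; ``manifest.json``
    records each stage's status and artifacts, so a partial failure leaves a
    manifest marking the completed stages.
    """
    cfg = PipelineConfig.from_yaml(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("popgeom.pipeline")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)

    manifest: dict = {"global_seed": cfg.seed, "stages": {}}

    def record(stage, artifacts, seed=None):
        manifest["stages"][stage] = {
            "status": "ok",
            "artifacts": [str(Path(a).name) for a in artifacts],
            "seed": seed,
        }
        pio.write_json_report(manifest, out / "manifest.json")

    (out / "config_used.yaml").write_text(Path(config_path).read_text())

    try:
        # --- simulate -----------------------------------------------------
        ensemble = make_stimulus_ensemble(EnsembleConfig(**cfg.ensemble))
        tensors: dict[str, ResponseTensor] = {}
        for name, body, stage in (
            ("a", cfg.population, "simulate_a"),
            ("b", cfg.population_b if cfg.population_b is not None else cfg.population,
             "simulate_b"),
        ):
            seed = stage_seed(cfg.seed, stage)
            log.info("stage=%s seed=%d config=%s", stage, seed, body)
            tensor, truth = simulate_population(ensemble, _pop_config(body), seed=seed)
            tensors[name] = tensor
            pio.write_response_tensor(tensor, out / f"tensor_{name}.h5")
            truth.to_frame().to_csv(out / f"ground_truth_{name}.csv", index=False)
            record(stage, [f"tensor_{name}.h5", f"ground_truth_{name}.csv"], seed)

        # --- decode -------------------------------------------------------
        n_dims = int(cfg.decoding.get("n_dims", 3))
        grouping = cfg.decoding.get("grouping", "class-direction")
        log.info("stage=decode n_dims=%d grouping=%s", n_dims, grouping)
        dec = {}
        artifacts = []
        report = {}
        for name, tensor in tensors.items():
            res = DecodingModel(tensor, grouping=grouping).fit(n_dims=n_dims)
            dec[name] = res
            artifacts += [
                pio.write_manifold_csv(res.manifold, out / f"manifold_{name}.csv"),
                pio.write_trajectories_csv(res.trajectories, out / f"trajectories_{name}.csv"),
            ]
            sel = selectivity_indices(tensor)
            sel.to_csv(out / f"selectivity_{name}.csv")
            artifacts.append(out / f"selectivity_{name}.csv")
            report[name] = {
                "n_points": res.manifold.n_points,
                "explained_variance_ratio": res.manifold.explained_variance_ratio,
                "accuracy_nearest_centroid_loo": res.accuracy(),
                "mean_osi": float(sel["osi"].mean()),
                "mean_dsi": float(sel["dsi"].mean()),
            }
        pio.write_json_report(report, out / "decoding_report.json")
        record("decode", artifacts + [out / "decoding_report.json"])

        # --- encode -------------------------------------------------------
        seed = stage_seed(cfg.seed, "encode")
        log.info("stage=encode seed=%d config=%s", seed, cfg.encoding)
        enc_report = {}
        artifacts = []
        for name, tensor in tensors.items():
            enc = EncodingModel(tensor, seed=seed, **cfg.encoding).fit()
            artifacts.append(
                pio.write_embedding_csv(enc.manifold, out / f"embedding_{name}.csv")
            )
            enc_report[name] = {
                "rank": enc.ntf.rank,
                "rel_error": enc.ntf.rel_error,
                "eigenvalues": enc.manifold.eigenvalues,
                "topology": enc.topology(),
            }
        pio.write_json_report(enc_report, out / "encoding_report.json")
        record("encode", artifacts + [out / "encoding_report.json"], seed)

        # --- tubularity ---------------------------------------------------
        seed = stage_seed(cfg.seed, "tubularity")
        n_boot = int(cfg.tubularity.get("n_boot", 500))
        n_comp = int(cfg.tubularity.get("n_comparisons", 2))
        log.info("stage=tubularity seed=%d n_boot=%d", seed, n_boot)
        tub_report = {}
        for name in tensors:
            tub = TubularityModel(dec[name].trajectories).fit()
            tub_report[name] = tub.scores.to_dict()
        for metric in ("tight", "cross"):
            delta, p, p_bonf = compare_scores(
                dec["a"].trajectories, dec["b"].trajectories,
                metric=metric, n_boot=n_boot, seed=seed, n_comparisons=n_comp,
            )
            tub_report[f"compare_{metric}"] = {
                "delta": delta, "p": p, "p_bonferroni": p_bonf,
                "n_boot": n_boot, "n_comparisons": n_comp,
            }
        pio.write_json_report(tub_report, out / "tubularity.json")
        record("tubularity", [out / "tubularity.json"], seed)

        # --- align --------------------------------------------------------
        seed = stage_seed(cfg.seed, "align")
        log.info("stage=align seed=%d config=%s", seed, cfg.alignment)
        feats = {
            name: _unit_features(tensors[name], grouping) for name in tensors
        }
        align_cfg = dict(cfg.alignment)
        align_cfg["seed"] = seed
        res = AlignmentModel(
            feats["a"], feats["b"], dec["a"].trajectories, dec["b"].trajectories,
            config=align_cfg,
        ).fit()
        pio.write_json_report(res.report.to_dict(), out / "alignment.json")
        record("align", [out / "alignment.json"], seed)
    except Exception:
        log.exception("pipeline stage failed")
        pio.write_json_report(manifest, out / "manifest.json")
        raise
    finally:
        handler.close()
        log.removeHandler(handler)
    return out


def _unit_features(tensor: ResponseTensor, grouping: str) -> np.ndarray:
    """Conditions x neurons feature matrix (time-averaged analysis units)."""
    from .decoding import _analysis_units

    units, _, _ = _analysis_units(tensor, grouping)
    return units.mean(axis=2)


def export_psth_figure_data(
    tensor: ResponseTensor, neuron_ids, out_path, image: bool = False
) -> Path:
    """Export per-neuron direction x time PSTH grids as long-format CSV.

    One row per (neuron, class, variant, direction, time bin); re-importing
    reproduces :func:`popgeom.core.psth_grid` exactly. With ``image=True`` a
    PNG raster (brightness = activity) is written next to the CSV.
    """
    import pandas as pd

    from .core import psth_grid

    rows = []
    grids = []
    for nid in neuron_ids:
        for cls in tensor.ensemble.class_names:
            for var in tensor.ensemble.variants_of(cls):
                grid = psth_grid(tensor, nid, cls, var)
                grids.append(grid)
                for di, d in enumerate(grid.directions):
                    for ti in range(grid.matrix.shape[1]):
                        rows.append(
                            (nid, cls, var, float(d), ti, grid.matrix[di, ti])
                        )
    out_path = Path(out_path)
    pd.DataFrame(
        rows,
        columns=["neuron_id", "base_class", "variant_id", "direction", "time_bin",
                 "activity"],
    ).to_csv(out_path, index=False, float_format="%.17g")  # exact re-import

    if image and grids:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(grids)
        ncol = min(4, n)
        nrow = (n + ncol - 1) // ncol
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2 * nrow), squeeze=False)
        for ax, grid in zip(axes.ravel(), grids):
            ax.imshow(grid.matrix, aspect="auto", cmap="gray", origin="lower")
            ax.set_title(f"{grid.neuron_id} {grid.base_class}/{grid.variant_id}", fontsize=7)
            ax.set_xlabel("time bin", fontsize=6)
            ax.set_ylabel("direction", fontsize=6)
        for ax in axes.ravel()[n:]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(out_path.with_suffix(".png"), dpi=100)
        plt.close(fig)
    return out_path
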