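"""End-to-end experiment orchestration.

A single YAML config describes the data source (synthetic ensembles or
directories of WAV/image files), preprocessing, the models to train (LCA,
rectified LCA, SAILnet, signed-spike SAILnet), and which reports to emit.
``run_experiment`` executes every stage with seeds derived deterministically
from one root seed, writes dictionaries, activations, lifetime/population
statistic reports, random-direction controls, dictionary-match tables and GMM
cluster labels, and finishes with a manifest listing every output file with a
checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import lca as lca_mod
from . import preprocess as pp
from . import sailnet as sn
from . import stats as st
from . import synth

__all__ = ["ExperimentConfig", "run_experiment", "StageError"]

DATA_SOURCES = ("synthetic_symmetric", "synthetic_skewed", "wav_directory",
                "image_directory")
MODEL_KINDS = ("lca", "lca_rectified", "sailnet", "sailnet_signed")

_KNOWN_KEYS = {
    "schema_version", "data_source", "source_path", "n_dims", "n_elements_gen",
    "n_samples", "overcompleteness", "n_components", "models", "statistics",
    "seed", "spectrogram", "patch_side", "segment_hop",
}
_KNOWN_MODEL_KEYS = {
    "kind", "n_epochs", "minibatch", "learning_rate", "lam", "n_steps",
    "step_size", "snr_target_db", "lambda_gain", "target_rate", "sim_steps",
    "alpha_phi", "alpha_w", "alpha_theta",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ExperimentConfig:
    data_source: str = "synthetic_symmetric"
    source_path: str | None = None
    n_dims: int = 64
    n_elements_gen: int = 64
    n_samples: int = 20000
    overcompleteness: float = 1.0
    n_components: int | None = None  # PCA dims for wav/image sources
    models: list[dict] = field(default_factory=lambda: [{"kind": "lca"}])
    statistics: dict = field(
        default_factory=lambda: {"lifetime": True, "population": True,
                                 "controls": True, "clusters": True}
    )
    seed: int = 0
    patch_side: int = 16
    segment_hop: int = 5

    def __post_init__(self):
        if self.data_source not in DATA_SOURCES:
            raise ValueError(
                f"unknown data_source {self.data_source!r}; choose from {DATA_SOURCES}"
            )
        for m in self.models:
            kind = m.get("kind")
            if kind not in MODEL_KINDS:
                raise ValueError(f"unknown model kind {kind!r}")
            extra = set(m) - _KNOWN_MODEL_KEYS
            if extra:
                raise ValueError(f"unknown model config keys: {sorted(extra)}")
        if self.data_source.endswith("_directory") and not self.source_path:
            raise ValueError(f"{self.data_source} requires source_path")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        extra = set(raw) - _KNOWN_KEYS
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        raw.pop("schema_version", None)
        raw.pop("spectrogram", None)  # handled by preprocessing defaults
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "data_source": self.data_source,
            "source_path": self.source_path,
            "n_dims": self.n_dims,
            "n_elements_gen": self.n_elements_gen,
            "n_samples": self.n_samples,
            "overcompleteness": self.overcompleteness,
            "models": self.models,
            "statistics": self.statistics,
            "seed": self.seed,
        }


def _substream(root_seed: int, stage: str) -> int:
    # named, deterministic substreams below 2**31
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _load_data(config: ExperimentConfig):
    seed = _substream(config.seed, "data")
    if config.data_source == "synthetic_symmetric":
        x, a, spec = synth.symmetric_ensemble(
            config.n_dims, config.n_elements_gen, config.n_samples, seed=seed)
        return x, {"truth": spec.dictionary}
    if config.data_source == "synthetic_skewed":
        x, a, spec = synth.skewed_ensemble(
            config.n_dims, config.n_elements_gen, config.n_samples, seed=seed)
        return x, {"truth": spec.dictionary}
    if config.data_source == "wav_directory":
        segs = []
        for wav_path in sorted(Path(config.source_path).glob("*.wav")):
            wav, rate = pp.read_wav(wav_path)
            wav = pp.normalize_waveform(wav)
            spec = pp.compute_log_spectrogram(wav, rate)
            spec = pp.trim_silence(spec)
            segs.append(pp.segment_spectrogram(spec, segment_hop=config.segment_hop))
        if not segs:
            raise FileNotFoundError(f"no WAV files in {config.source_path}")
        raw = np.vstack(segs)
    else:  # image_directory
        from imageio.v3 import imread
        patches = []
        paths = sorted(p for p in Path(config.source_path).iterdir()
                       if p.suffix.lower() in (".png", ".pgm"))
        if not paths:
            raise FileNotFoundError(f"no PNG/PGM images in {config.source_path}")
        per = max(config.n_samples // len(paths), 1)
        for i, path in enumerate(paths):
            img = np.asarray(imread(path), dtype=float)
            if img.ndim == 3:
                img = img.mean(axis=2)
            patches.append(pp.extract_patches(img, side=config.patch_side,
                                              n_patches=per, seed=seed + i))
        raw = np.vstack(patches)
    n_comp = config.n_components or min(200, raw.shape[1] // 2)
    whitener = pp.fit_whitener(raw, n_comp)
    return pp.whiten(raw, whitener), {"whitener": whitener}


def _train_model(model_cfg: dict, data: np.ndarray, n_elements: int, seed: int):
    kind = model_cfg["kind"]
    if kind in ("lca", "lca_rectified"):
        cfg = lca_mod.LCAConfig(
            lam=model_cfg.get("lam", 0.1),
            n_steps=model_cfg.get("n_steps", 200),
            step_size=model_cfg.get("step_size", 0.1),
            rectified=(kind == "lca_rectified"),
            snr_target_db=model_cfg.get("snr_target_db", 15.0),
            lambda_gain=model_cfg.get("lambda_gain", 0.05),
        )
        phi, history = lca_mod.train_lca(
            data, n_elements, cfg,
            n_epochs=model_cfg.get("n_epochs", 10),
            learning_rate=model_cfg.get("learning_rate", 0.1),
            minibatch=model_cfg.get("minibatch", 100),
            seed=seed,
        )
        final_cfg = lca_mod.LCAConfig(
            lam=history.lam[-1], n_steps=cfg.n_steps, step_size=cfg.step_size,
            rectified=cfg.rectified)
        acts = lca_mod.lca_infer(data, phi, final_cfg)
        return phi, acts, history.as_dict()
    cfg = sn.SAILnetConfig(
        sim_steps=model_cfg.get("sim_steps", 50),
        alpha_phi=model_cfg.get("alpha_phi", 0.01),
        alpha_w=model_cfg.get("alpha_w", 0.1),
        alpha_theta=model_cfg.get("alpha_theta", 0.02),
        signed_spikes=(kind == "sailnet_signed"),
    )
    params, history = sn.train_sailnet(
        data, n_elements, cfg,
        target_rate=model_cfg.get("target_rate", 0.05),
        n_epochs=model_cfg.get("n_epochs", 10),
        minibatch=model_cfg.get("minibatch", 100),
        seed=seed,
    )
    acts = sn.sailnet_infer(data, params, cfg)
    return params.phi, acts, history.as_dict()


def _write_report(report: st.StatReport, out: Path, name: str, written: list):
    csv_path = out / f"{name}.csv"
    report.to_csv(csv_path)
    written.append(csv_path)
    rank = report.records.sort_values("sparseness_score", ascending=False)
    rank_path = out / f"{name}_rank.csv"
    rank_df = rank.reset_index().rename(columns={"index": "element_id"})
    rank_df.insert(0, "rank", np.arange(len(rank_df)))
    rank_df[["rank", "sparseness_score", "element_id"]].rename(
        columns={"sparseness_score": "score"}).to_csv(rank_path, index=False)
    written.append(rank_path)


def run_experiment(config: ExperimentConfig, output_dir) -> dict:
    """Run every configured stage and write the report bundle.

    Returns the manifest (also written as ``manifest.json``).  On stage
    failure, partial outputs are preserved next to a ``FAILED`` marker naming
    the stage.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"models": {}}
    try:
        stage = "data"
        data, extras = _load_data(config)
        np.savez(out / "data.npz", data=data)
        written.append(out / "data.npz")

        stage = "models"
        n_elements = int(round(config.overcompleteness * data.shape[1]))
        dictionaries, activations = {}, {}
        for i, mcfg in enumerate(config.models):
            name = f"{mcfg['kind']}_{i}"
            seed = _substream(config.seed, f"model:{name}")
            phi, acts, history = _train_model(mcfg, data, n_elements, seed)
            dictionaries[name], activations[name] = phi, acts
            np.savez(out / f"{name}.npz", dictionary=phi, activations=acts)
            written.append(out / f"{name}.npz")
            summary["models"][name] = {
                "n_elements": n_elements,
                "history_tail": {k: v[-1] for k, v in history.items() if v},
            }

        stage = "statistics"
        zero_tol = 0.0
        for name, acts in activations.items():
            tol = 0.0 if name.startswith("lca") else 1e-12
            if config.statistics.get("lifetime", True):
                rep = st.lifetime_report(acts, zero_tol=tol)
                _write_report(rep, out, f"{name}_lifetime", written)
                summary["models"][name]["lifetime"] = rep.summary
            if config.statistics.get("population", True):
                rep = st.population_report(acts, zero_tol=tol)
                _write_report(rep, out, f"{name}_population", written)
                summary["models"][name]["population"] = rep.summary
            if config.statistics.get("clusters", True):
                rec = st.lifetime_report(acts, zero_tol=tol).records
                ok = ~rec["skewness_magnitude"].isna()
                if ok.sum() >= 2:
                    labels, k = st.cluster_elements(
                        rec.loc[ok, "sparseness_score"],
                        rec.loc[ok, "skewness_magnitude"],
                        seed=_substream(config.seed, f"gmm:{name}"),
                    )
                    lab_path = out / f"{name}_clusters.csv"
                    np.savetxt(lab_path, labels, fmt="%d", header="cluster")
                    written.append(lab_path)
                    summary["models"][name]["n_clusters"] = int(k)

        if config.statistics.get("controls", True):
            stage = "controls"
            ctrl = st.random_direction_control(
                data.shape[1], n_elements, _substream(config.seed, "controls"))
            _, rep, _ = st.projection_stats(data, ctrl)
            _write_report(rep, out, "random_control_lifetime", written)
            summary["control"] = rep.summary

        if len(dictionaries) >= 2:
            stage = "matching"
            names = list(dictionaries)
            for a_name, b_name in zip(names[:-1], names[1:]):
                match = st.match_dictionaries(dictionaries[a_name],
                                              dictionaries[b_name])
                mpath = out / f"match_{a_name}_vs_{b_name}.csv"
                match.to_csv(mpath, index_label="element")
                written.append(mpath)
                summary[f"match_{a_name}_vs_{b_name}"] = {
                    "median_abs_cos": float(match["abs_cos"].median()),
                    "median_angle_deg": float(match["angle_deg"].median()),
                }
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc

    stage = "manifest"
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    written.append(spath)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
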