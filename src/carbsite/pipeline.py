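"""End-to-end pipeline: annotate → featurize → (optional select) → train the
three imbalance-strategy models → ensemble → evaluate.

The pipeline runs from a single structured config (YAML/JSON mapping).  At
desk scale the inputs are generated by the synthetic fixture module: toy
complexes drive the annotation and structural-feature stages, and
class-separable Gaussian matrices stand in for the pre-computed language-model
embeddings (conditioned on the annotation labels the pipeline itself
computed).  Every stage writes its outputs plus a manifest recording seeds and
SHA-256 checksums, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geometry import assemble_structural
from .imbalance import LabeledSet
from .metrics import evaluate
from .nn import NetConfig
from .sequence import ESM2_WIDTH, PROTT5_WIDTH, window_encode_all
from .structure import (
    CarbLexicon, annotate_binding, chain_filters, collect_carb_atoms,
    parse_structure, write_annotation,
)
from .synth import SynthSpec, make_toy_complex
from .training import build_ensemble

KNOWN_KEYS = {
    "seed", "out_dir", "cutoff", "min_binding", "lexicon",
    "synth", "train", "net", "threshold", "run_selection", "selection_folds",
}
KNOWN_SYNTH_KEYS = {"n_chains", "n_residues", "n_binding", "geometry", "d"}
KNOWN_TRAIN_KEYS = {"epochs", "batch_size", "lr", "seeds"}


class ConfigError(ValueError):
    """Unknown or inconsistent configuration."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults give a minutes-scale synthetic run."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    cutoff: float = 3.5
    min_binding: int = 5
    lexicon: str | None = None          # path; default = shipped lexicon
    synth: dict = field(default_factory=lambda: {
        "n_chains": 6, "n_residues": 40, "n_binding": 7,
        "geometry": "coil", "d": 4.0,
    })
    train: dict = field(default_factory=lambda: {
        "epochs": 8, "batch_size": 64, "lr": 1e-3,
    })
    net: dict = field(default_factory=dict)
    threshold: float = 0.5
    run_selection: bool = False
    selection_folds: int = 3

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for sub, allowed in (("synth", KNOWN_SYNTH_KEYS), ("train", KNOWN_TRAIN_KEYS)):
            extra = set(mapping.get(sub, {})) - allowed
            if extra:
                raise ConfigError(f"unknown {sub} config keys: {sorted(extra)}")
        base = cls()
        merged = {**asdict(base), **mapping}
        merged["synth"] = {**base.synth, **mapping.get("synth", {})}
        merged["train"] = {**base.train, **mapping.get("train", {})}
        return cls(**merged)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksums(directory: Path) -> dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(directory.iterdir()) if p.is_file()}


def run_pipeline(config: RunConfig | dict) -> Path:
    """Execute the full pipeline; returns the artifacts directory.

    Raises with the failing stage's name on any error.
    """
    if isinstance(config, dict):
        config = RunConfig.from_mapping(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    rng = np.random.default_rng(config.seed)
    stage = "setup"
    try:
        # ---------------- annotate ------------------------------------
        stage = "annotate"
        t0 = time.time()
        ann_dir = out / "annotate"
        ann_dir.mkdir(exist_ok=True)
        lexicon = (CarbLexicon.from_file(config.lexicon) if config.lexicon
                   else CarbLexicon.default())
        chains = []
        for k in range(config.synth["n_chains"]):
            spec = SynthSpec(
                n_residues=config.synth["n_residues"],
                n_binding=config.synth["n_binding"],
                geometry=config.synth["geometry"],
                seed=config.seed * 1000 + k,
            )
            toy = make_toy_complex(spec, out_dir=ann_dir / f"complex_{k}")
            parsed = parse_structure(toy.pdb_path)
            carbs = collect_carb_atoms(parsed, lexicon)
            chain = annotate_binding(parsed.chains[0], carbs, cutoff=config.cutoff)
            chain.chain_id = f"chain_{k}"
            keep, reason = chain_filters(chain, min_binding=config.min_binding)
            if keep:
                chains.append(chain)
        if not chains:
            raise RuntimeError("no chain survived the filters")
        write_annotation(chains, ann_dir / "annotations.cpb.tsv")
        manifest["stages"]["annotate"] = {
            "seconds": round(time.time() - t0, 2),
            "kept_chains": len(chains),
            "checksums": _checksums(ann_dir),
        }

        # ---------------- featurize -----------------------------------
        stage = "featurize"
        t0 = time.time()
        feat_dir = out / "featurize"
        feat_dir.mkdir(exist_ok=True)
        d = float(config.synth["d"])
        dir5 = rng.normal(size=PROTT5_WIDTH)
        dir5 /= np.linalg.norm(dir5)
        dir2 = rng.normal(size=ESM2_WIDTH)
        dir2 /= np.linalg.norm(dir2)
        windows, feats, labels = [], [], []
        for chain in chains:
            structural = assemble_structural(chain)
            win = window_encode_all(chain.full_sequence)
            lab = np.array([c == "1" for c in chain.labels], dtype=int)
            # surrogate embeddings: class-conditional Gaussians along a
            # shared direction per embedding space (stand-in for PLM output)
            sign = np.where(lab == 1, 0.5, -0.5)[:, None]
            prott5 = rng.normal(size=(len(lab), PROTT5_WIDTH)) + d * sign * dir5
            esm2 = rng.normal(size=(len(lab), ESM2_WIDTH)) + d * sign * dir2
            modeled = [i for i, a in enumerate(chain.alignment) if a is not None]
            feats.append(np.hstack([prott5, structural, esm2])[modeled])
            windows.append(win[modeled])
            labels.append(lab[modeled])
        dataset = LabeledSet(np.vstack(windows), np.vstack(feats),
                             np.concatenate(labels))
        np.save(feat_dir / "windows.npy", dataset.windows)
        np.save(feat_dir / "features.npy", dataset.features)
        np.save(feat_dir / "labels.npy", dataset.labels)
        manifest["stages"]["featurize"] = {
            "seconds": round(time.time() - t0, 2),
            "n_samples": len(dataset),
            "n_positive": int(dataset.labels.sum()),
            "checksums": _checksums(feat_dir),
        }

        # ---------------- select (optional) ---------------------------
        if config.run_selection:
            stage = "select"
            t0 = time.time()
            from sklearn.linear_model import LogisticRegression

            from .selection import FeatureGroup, cv_f1_scorer, ifs_greedy

            groups = {
                "prott5": FeatureGroup("prott5", 0, PROTT5_WIDTH),
                "structural": FeatureGroup("structural", PROTT5_WIDTH,
                                           PROTT5_WIDTH + 36),
                "esm2": FeatureGroup("esm2", PROTT5_WIDTH + 36,
                                     PROTT5_WIDTH + 36 + ESM2_WIDTH),
            }
            scorer = cv_f1_scorer(
                dataset.features, dataset.labels, groups,
                LogisticRegression(max_iter=500),
                folds=config.selection_folds, seed=config.seed,
            )
            result = ifs_greedy(list(groups), scorer)
            (out / "selection.json").write_text(json.dumps(
                {"chosen_groups": result.chosen_groups, "trace": result.trace},
                indent=2, default=float))
            manifest["stages"]["select"] = {
                "seconds": round(time.time() - t0, 2),
                "chosen_groups": result.chosen_groups,
            }

        # ---------------- train + ensemble ----------------------------
        stage = "train"
        t0 = time.time()
        model_dir = out / "models"
        seeds = tuple(config.train.get("seeds",
                                       (config.seed, config.seed + 1,
                                        config.seed + 2)))
        net_config = NetConfig(**config.net) if config.net else None
        ensemble = build_ensemble(
            dataset, config=net_config, seeds=seeds,
            epochs=config.train["epochs"],
            batch_size=config.train["batch_size"],
            lr=config.train["lr"],
        )
        ensemble.save(model_dir)
        manifest["stages"]["train"] = {
            "seconds": round(time.time() - t0, 2),
            "seeds": list(seeds),
            "checksums": _checksums(model_dir),
        }

        # ---------------- evaluate ------------------------------------
        stage = "evaluate"
        t0 = time.time()
        probs = ensemble.predict(dataset.windows, dataset.features)
        np.savetxt(out / "predictions.tsv", probs, fmt="%.6f")
        report = evaluate(probs, dataset.labels, threshold=config.threshold)
        (out / "metrics.json").write_text(
            json.dumps(report.as_dict(), indent=2))
        manifest["stages"]["evaluate"] = {
            "seconds": round(time.time() - t0, 2),
            "metrics": report.as_dict(),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=float))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return out
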