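"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — (optional) corpus synthesis → sentence
tagging → (probability mode only: embedding + sentence-classifier training) →
patient vectors → cohort split → classifier bank → evaluation — writing every
intermediate artifact plus a run manifest into a report directory.  The run
is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .corpus import read_corpus, write_corpus
from .embeddings import EmbeddingCache, get_backend
from .mlp import (
    TrainConfig,
    build_sentence_dataset,
    evaluate_sentence_classifier,
    save_model,
    train_mlp,
)
from .phenotype import (
    SplitSpec,
    evaluate,
    make_splits,
    render_report_tsv,
    train_bank,
)
from .synthetic import GeneratorConfig, generate_corpus, write_truth_tsv
from .tagger import load_lexicons, load_triggers, tag_corpus
from .vectors import binary_vector, probability_vector

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("phenopipe")


@dataclass
class PipelineConfig:
    """Everything one run needs; all randomness is derived from ``seed``."""

    out_dir: str = "phenopipe_run"
    corpus: str | None = None  # JSONL path; None -> synthesize
    lexicons: str | None = None
    triggers: str | None = None
    mode: str = "binary"  # "binary" | "probability"
    backend: str = "hashing"
    backend_dim: int = 768
    seed: int = 0
    generator: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    mlp: dict = field(default_factory=dict)
    menu: list | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured pipeline; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.corpus is None:
        _stage("generate")
        gen_cfg = GeneratorConfig(**{"seed": config.seed, **config.generator})
        records, truth = generate_corpus(gen_cfg)
        write_corpus(records, out / "corpus.jsonl")
        write_truth_tsv(truth, out / "truth.tsv")
    else:
        _stage("read-corpus")
        records = read_corpus(config.corpus)
    labels = {r.patient_id: r.label for r in records}
    if any(v is None for v in labels.values()):
        raise ValueError("all patients must be labeled for training/evaluation")

    _stage("tag")
    lexicons = load_lexicons(config.lexicons)
    triggers = load_triggers(config.triggers)
    tagged = tag_corpus(records, lexicons, triggers)

    _stage("build-vectors")
    if config.mode == "binary":
        vectors = {
            pid: binary_vector(pid, sents).values for pid, sents in tagged.items()
        }
    elif config.mode == "probability":
        backend = get_backend(
            config.backend,
            **({"dim": config.backend_dim, "seed": config.seed}
               if config.backend == "hashing" else {}),
        )
        cache = EmbeddingCache(out / "emb_cache")
        emb = lambda texts: cache.embed(backend, texts)  # noqa: E731
        _stage("train-sentence-classifiers")
        classifiers = {}
        model_dir = out / "models"
        model_dir.mkdir(exist_ok=True)
        sc_report = []
        for cat in range(1, 9):
            ds = build_sentence_dataset(
                tagged, cat, emb, seed=int(rng.integers(2**31)),
            )
            cfg = TrainConfig(**{"seed": int(rng.integers(2**31)), **config.mlp})
            model = train_mlp(ds.X_train, ds.y_train, cfg)
            acc = evaluate_sentence_classifier(model, ds.X_test, ds.y_test)
            sc_report.append((cat, len(ds.y_train), len(ds.y_test), acc))
            classifiers[cat] = model
            save_model(model, model_dir / f"category_{cat}.npz")
        with (out / "sentence_classifiers.tsv").open("w") as fh:
            fh.write("Classifier\tTrain\tTest\tAccuracy\n")
            for cat, ntr, nte, acc in sc_report:
                fh.write(f"{cat}\t{ntr}\t{nte}\t{acc:.4f}\n")
        vectors = {
            r.patient_id: probability_vector(r, classifiers, backend,
                                             embeddings_of=emb).values
            for r in records
        }
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    with (out / "vectors.tsv").open("w") as fh:
        fh.write("patient_id\t" + "\t".join(f"v{i}" for i in range(1, 9))
                 + "\tmode\n")
        for pid in sorted(vectors):
            fh.write(pid + "\t" + "\t".join(f"{v:.6g}" for v in vectors[pid])
                     + f"\t{config.mode}\n")

    _stage("split")
    split = make_splits(labels, SplitSpec(**{"seed": config.seed, **config.split}))

    _stage("train-phenotyper")
    X_train = np.array([vectors[p] for p in split.train])
    y_train = np.array([labels[p] for p in split.train], dtype=int)
    menu = tuple(config.menu) if config.menu else None
    bank = train_bank(X_train, y_train, seed=config.seed,
                      **({"menu": menu} if menu else {}))

    _stage("evaluate")
    report = evaluate(
        bank,
        {"balanced_test": split.balanced_test,
         "unbalanced_test": split.unbalanced_test},
        vectors,
        labels,
    )
    for set_name, per_model in report.items():
        (out / f"report_{config.mode}_{set_name}.tsv").write_text(
            render_report_tsv(per_model)
        )

    manifest = {
        "phenopipe_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "chosen_hyperparameters": bank.chosen_params,
        "split_sizes": {
            "train": len(split.train),
            "balanced_test": len(split.balanced_test),
            "unbalanced_test": len(split.unbalanced_test),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
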