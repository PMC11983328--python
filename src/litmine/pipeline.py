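"""End-to-end pipeline orchestration under a single YAML-serializable config.

``run_pipeline`` chains the stages -- read corpus, annotate, count per type
pair, score, build network -- and writes every intermediate artifact plus a
run manifest (config hash, input checksums, package version) into the output
directory.  Re-running on identical inputs reproduces identical association
tables; the manifest makes that checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .assoc import ScoringParams, score_table, write_association_tsv
from .cooccur import MINED_TYPE_PAIRS, count_cooccurrences, write_counts
from .corpus import read_annotations, read_jsonl_corpus, read_medline_xml, write_annotations
from .network import build_network, export_graph
from .vocab import (
    DEFAULT_LINK_K,
    DEFAULT_LINK_THRESHOLD,
    EntityType,
    annotate_corpus,
    read_vocabulary_jsonl,
    read_vocabulary_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_vocabulary", "load_corpus"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name."""


@dataclass
class RunConfig:
    corpus_paths: list[str]
    vocabulary_path: str
    out_dir: str
    corpus_format: str = "jsonl"  # "jsonl" | "medline-xml"
    include_titles: bool = False
    link_threshold: float = DEFAULT_LINK_THRESHOLD
    link_k: int = DEFAULT_LINK_K
    type_pairs: list[str] = field(default_factory=list)  # e.g. ["GENE-DISEASE"]; empty = all
    a: float = 0.6
    p_adj_threshold: float = 0.05
    seed: int = 17
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must be in [0, 1]")
        if self.corpus_format not in ("jsonl", "medline-xml"):
            raise ValueError(f"unknown corpus format {self.corpus_format!r}")

    def validate_paths(self) -> None:
        missing = [
            p for p in (*self.corpus_paths, self.vocabulary_path) if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def resolved_type_pairs(self) -> list[tuple[EntityType, EntityType]]:
        if not self.type_pairs:
            return list(MINED_TYPE_PAIRS)
        out = []
        for spec in self.type_pairs:
            tx, ty = spec.split("-", 1)
            out.append((EntityType(tx), EntityType(ty)))
        return out


def load_vocabulary(path: str | Path):
    path = Path(path)
    if path.suffix == ".jsonl":
        return read_vocabulary_jsonl(path)
    return read_vocabulary_tsv(path)


def load_corpus(paths: list[str], corpus_format: str, include_titles: bool = False):
    docs = []
    for path in paths:
        if corpus_format == "medline-xml":
            docs.extend(read_medline_xml(path, include_titles=include_titles))
        else:
            docs.extend(read_jsonl_corpus(path))
    return docs


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run every stage and return a mapping of artifact names to paths."""
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    vocab = _stage("vocabulary")(load_vocabulary, config.vocabulary_path)
    docs = _stage("corpus")(
        load_corpus, config.corpus_paths, config.corpus_format, config.include_titles
    )
    if not docs:
        logger.warning("empty corpus: association tables will be empty")

    sentences = _stage("annotate")(
        lambda: list(
            annotate_corpus(docs, vocab, threshold=config.link_threshold, k=config.link_k)
        )
    )
    ann_path = out / "annotations.jsonl"
    write_annotations(sentences, ann_path)
    artifacts["annotations"] = str(ann_path)

    names = {cui: c.name for cui, c in vocab.concepts.items()}
    vocab_types = vocab.entity_types()
    all_records = []
    for tx, ty in config.resolved_type_pairs():
        if tx not in vocab_types or ty not in vocab_types:
            continue
        label = f"{tx.value}-{ty.value}"
        table = _stage(f"count:{label}")(count_cooccurrences, sentences, (tx, ty))
        counts_dir = out / "counts" / label
        write_counts(table, counts_dir)
        artifacts[f"counts:{label}"] = str(counts_dir)
        records = _stage(f"score:{label}")(
            score_table, table, ScoringParams(a=config.a), names
        )
        assoc_path = out / f"associations_{label}.tsv"
        write_association_tsv(records, assoc_path)
        artifacts[f"associations:{label}"] = str(assoc_path)
        all_records.append(records)

    graph = _stage("network")(build_network, all_records, config.p_adj_threshold)
    net_path = out / "network.graphml"
    export_graph(graph, net_path, format="graphml")
    artifacts["network"] = str(net_path)

    config_dict = asdict(config)
    manifest = {
        "package_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "input_checksums": {
            p: _sha256_file(p) for p in (*config.corpus_paths, config.vocabulary_path)
        },
        "n_documents": len(docs),
        "n_sentences": len(sentences),
        "n_edges": graph.number_of_edges(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = str(manifest_path)
    return artifacts
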