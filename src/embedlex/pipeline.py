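"""End-to-end orchestration of the synthetic-data demonstration.

Six stages, each a pure function of (inputs, config, seed), writing
tabular artifacts to an output directory with a JSON manifest of
parameters and checksums:

simulate -> planted embedding spaces (word2vec text) + truth tables
query    -> top-k candidate lists per (source, seed term)
agree    -> simulated annotations + pairwise kappa reports + matrices
profile  -> frequency weights, cross-source cosines, semantic
            distributions, modifier contrasts
lexicon  -> expanded concept lexicon (seeds + consensus synonyms)
cohort   -> planted note corpus, match table, per-cohort feature
            proportions, severity-group summary

Rerunning any stage with the same config and seed reproduces
byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import seeds as seed_lists
from .agreement import (
    matrix_to_frame,
    disagreement_matrix,
    pairwise_agreement,
    read_annotations,
    reports_to_frame,
    write_annotations,
)
from .embeddings import read_embedding, write_embedding
from .lexicon import (
    Lexicon,
    build_expanded_lexicon,
    default_severity_map,
    feature_proportions,
    match_features,
    proportions_to_frame,
    read_lexicon,
    read_notes,
    severity_rollup,
    write_lexicon,
    write_notes,
)
from .neighbors import (
    cross_source_cosines,
    read_candidates,
    top_k_neighbors,
    write_candidates,
)
from .profiling import (
    contrasts_to_frame,
    distributions_to_frame,
    frequency_weights,
    modifier_contrast,
    semantic_type_distribution,
    weights_to_frame,
    write_frame,
)
from .synthetic import (
    PlantedTruth,
    SynthCohortConfig,
    SynthEmbeddingConfig,
    annotate_candidates,
    generate_cohort_notes,
    generate_embedding_space,
    write_truth,
)

logger = logging.getLogger(__name__)

STAGES: tuple[str, ...] = ("simulate", "query", "agree", "profile", "lexicon", "cohort")

DEFAULT_SEED_TERMS: tuple[str, ...] = (
    "fever",
    "cough",
    "dry cough",
    "sore throat",
    "malaise",
    "headache",
    "muscle pain",
    "nasal congestion",
    "shortness of breath",
    "dyspnea",
    "tachypnea",
    "respiratory distress",
    "hypoxia",
)

#: Per-cohort planted documentation prevalences for the demonstration,
#: emulating the spread reported for pneumonia / ARDS / COVID-19 cohorts
#: (fever and hypoxia widely documented; dry cough rare but highest in
#: the COVID-19 cohort).
DEFAULT_PREVALENCE: dict[str, dict[str, float]] = {
    "pneumonia": {
        "fever": 0.61, "cough": 0.41, "dry cough": 0.05, "sore throat": 0.10,
        "malaise": 0.15, "headache": 0.10, "muscle pain": 0.12,
        "nasal congestion": 0.08, "shortness of breath": 0.40, "dyspnea": 0.35,
        "tachypnea": 0.20, "respiratory distress": 0.25, "hypoxia": 0.51,
    },
    "ards": {
        "fever": 0.68, "cough": 0.46, "dry cough": 0.03, "sore throat": 0.08,
        "malaise": 0.12, "headache": 0.09, "muscle pain": 0.10,
        "nasal congestion": 0.06, "shortness of breath": 0.47, "dyspnea": 0.50,
        "tachypnea": 0.30, "respiratory distress": 0.60, "hypoxia": 0.56,
    },
    "covid19": {
        "fever": 0.84, "cough": 0.55, "dry cough": 0.07, "sore throat": 0.22,
        "malaise": 0.20, "headache": 0.25, "muscle pain": 0.30,
        "nasal congestion": 0.18, "shortness of breath": 0.59, "dyspnea": 0.45,
        "tachypnea": 0.25, "respiratory distress": 0.35, "hypoxia": 0.53,
    },
}


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    out_dir: str = "embedlex_run"
    seed_terms: tuple[str, ...] = DEFAULT_SEED_TERMS
    n_sources: int = 7
    dimension: int = 50
    synonyms_per_seed: int = 5
    related_per_seed: int = 5
    distractor_count: int = 40
    target_cos_synonym: float = 0.9
    target_cos_related: float = 0.4
    cos_jitter: float = 0.05
    k: int = 20
    phrase_strategy: str = "key_then_average"
    annotator_ids: tuple[str, ...] = ("a1", "a2", "a3")
    agreement_prob: float = 0.9
    include_rule: str = "consensus"
    cohorts: tuple[tuple[str, int], ...] = (
        ("pneumonia", 400),
        ("ards", 400),
        ("covid19", 400),
    )
    concept_prevalence: dict = field(default_factory=lambda: DEFAULT_PREVALENCE)
    notes_per_patient: int = 3
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed_terms" in doc:
            doc["seed_terms"] = tuple(doc["seed_terms"])
        if "annotator_ids" in doc:
            doc["annotator_ids"] = tuple(doc["annotator_ids"])
        if "cohorts" in doc:
            doc["cohorts"] = tuple((str(c), int(n)) for c, n in doc["cohorts"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed_terms"] = list(self.seed_terms)
        d["annotator_ids"] = list(self.annotator_ids)
        d["cohorts"] = [list(c) for c in self.cohorts]
        return d


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    ss = np.random.SeedSequence([config.rng_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _source_names(config: PipelineConfig) -> list[str]:
    return [f"source{i + 1}" for i in range(config.n_sources)]


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the {producer!r} stage first"
        )
    return path


def _read_truth(path: Path) -> PlantedTruth:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    role = dict(zip(frame["term"], frame["role"]))
    seed_of = {t: s for t, s in zip(frame["term"], frame["seed"]) if s}
    intended = {t: float(c) for t, c in zip(frame["term"], frame["intended_cos"])}
    return PlantedTruth(role=role, seed_of=seed_of, intended_cos=intended)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    emb_dir = out / "embeddings"
    truth_dir = out / "truth"
    emb_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    base = _stage_seed(config, "simulate")
    written = []
    for i, name in enumerate(_source_names(config)):
        cfg = SynthEmbeddingConfig(
            seed_terms=config.seed_terms,
            dimension=config.dimension,
            synonyms_per_seed=config.synonyms_per_seed,
            related_per_seed=config.related_per_seed,
            distractor_count=config.distractor_count,
            target_cos_synonym=config.target_cos_synonym,
            target_cos_related=config.target_cos_related,
            cos_jitter=config.cos_jitter,
            rng_seed=(base + i) % (2**31),
            name=name,
        )
        source, truth = generate_embedding_space(cfg)
        written.append(write_embedding(source, emb_dir / f"{name}.vec", "word2vec_text"))
        written.append(write_truth(truth, truth_dir / f"{name}.tsv"))
    return written


def _load_sources(config: PipelineConfig, out: Path):
    sources = []
    for name in _source_names(config):
        path = _require(out / "embeddings" / f"{name}.vec", "simulate")
        sources.append(
            read_embedding(
                path,
                "word2vec_text",
                name=name,
                case_policy="lowercase",
                phrase_policy="multiword_keys",
            )
        )
    return sources


def stage_query(config: PipelineConfig, out: Path) -> list[Path]:
    sources = _load_sources(config, out)
    candidates = []
    for source in sources:
        for term in config.seed_terms:
            candidates.extend(
                top_k_neighbors(source, term, k=config.k, phrase_strategy=config.phrase_strategy)
            )
    return [write_candidates(candidates, out / "candidates.tsv")]


def stage_agree(config: PipelineConfig, out: Path) -> list[Path]:
    candidates = read_candidates(_require(out / "candidates.tsv", "query"))
    truths = {
        name: _read_truth(_require(out / "truth" / f"{name}.tsv", "simulate"))
        for name in _source_names(config)
    }
    annotations = annotate_candidates(
        candidates,
        truths,
        annotator_ids=config.annotator_ids,
        agreement_prob=config.agreement_prob,
        rng_seed=_stage_seed(config, "agree"),
    )
    written = [write_annotations(annotations, out / "annotations.tsv")]

    category_map = {**seed_lists.query_category_map()}
    for term in config.seed_terms:
        category_map.setdefault(term, "symptom")
    for strata, fname in (
        ("by_category", "agreement_by_category.tsv"),
        ("by_query_term", "agreement_by_query.tsv"),
    ):
        reports = pairwise_agreement(annotations, strata, category_map=category_map)
        written.append(write_frame(reports_to_frame(reports), out / fname))

    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    annotators = sorted(config.annotator_ids)
    for i, a in enumerate(annotators):
        for b in annotators[i + 1 :]:
            frame = matrix_to_frame(disagreement_matrix(annotations, (a, b)))
            path = mat_dir / f"{a}_{b}.csv"
            frame.to_csv(path)
            written.append(path)
    return written


def _candidates_by_source_query(candidates):
    nested: dict[str, dict[str, list]] = {}
    for c in candidates:
        nested.setdefault(c.source_name, {}).setdefault(c.query, []).append(c)
    return nested


def stage_profile(config: PipelineConfig, out: Path) -> list[Path]:
    candidates = read_candidates(_require(out / "candidates.tsv", "query"))
    annotations = read_annotations(_require(out / "annotations.tsv", "agree"))
    nested = _candidates_by_source_query(candidates)
    source_names = sorted(nested)

    weight_frames = []
    cosine_rows = []
    for query in config.seed_terms:
        per_source = {s: nested[s][query] for s in source_names if query in nested[s]}
        if not per_source:
            continue
        frame = weights_to_frame(frequency_weights(per_source))
        frame.insert(0, "query", query)
        weight_frames.append(frame)
        terms = sorted({row.term for row in frequency_weights(per_source)})
        for term in terms:
            record = cross_source_cosines(term, per_source)
            row = {"query": query, "term": term}
            row.update({s: f"{record.values.get(s, -1.0):.6f}" for s in source_names})
            cosine_rows.append(row)

    written = [
        write_frame(pd.concat(weight_frames, ignore_index=True), out / "weights.tsv"),
        write_frame(
            pd.DataFrame(cosine_rows, columns=["query", "term"] + source_names),
            out / "cosines.tsv",
        ),
    ]

    distributions = semantic_type_distribution(annotations, nested)
    written.append(write_frame(distributions_to_frame(distributions), out / "distributions.tsv"))

    present = set(config.seed_terms)
    pairs = {
        unmod: tuple(v for v in variants if v in present)
        for unmod, variants in seed_lists.MODIFIER_PAIRS.items()
        if unmod in present
    }
    pairs = {u: vs for u, vs in pairs.items() if vs}
    if pairs:
        contrasts = modifier_contrast(distributions, pairs)
        written.append(write_frame(contrasts_to_frame(contrasts), out / "contrasts.tsv"))
    return written


def stage_lexicon(config: PipelineConfig, out: Path) -> list[Path]:
    annotations = read_annotations(_require(out / "annotations.tsv", "agree"))
    seed_concepts = {t: {t} for t in config.seed_terms}
    lexicon = build_expanded_lexicon(seed_concepts, annotations, include_rule=config.include_rule)
    return [write_lexicon(lexicon, out / "lexicon.tsv")]


def stage_cohort(config: PipelineConfig, out: Path) -> list[Path]:
    lexicon = read_lexicon(_require(out / "lexicon.tsv", "lexicon"))
    cohort_cfg = SynthCohortConfig(
        cohorts=config.cohorts,
        concept_prevalence=config.concept_prevalence,
        notes_per_patient=config.notes_per_patient,
        rng_seed=_stage_seed(config, "cohort"),
    )
    notes = generate_cohort_notes(cohort_cfg, lexicon)
    written = [write_notes(notes, out / "notes.tsv")]

    matches = match_features(notes, lexicon)
    matches_out = matches.reset_index()
    written.append(write_frame(matches_out, out / "matches.tsv"))

    props = feature_proportions(matches)
    written.append(write_frame(proportions_to_frame(props), out / "proportions.tsv"))

    severity_map = default_severity_map()
    needed = {f for g in severity_map.groups for f in g.features()}
    if needed <= (set(matches.columns) - {"cohort"}):
        flags = severity_rollup(matches, severity_map)
        summary = (
            flags.groupby("cohort")[[g.name for g in severity_map.groups]]
            .mean()
            .round(4)
            .reset_index()
        )
        written.append(write_frame(summary, out / "severity_summary.tsv"))
    else:
        logger.info("severity rollup skipped: features missing from lexicon")
    return written


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "query": stage_query,
    "agree": stage_agree,
    "profile": stage_profile,
    "lexicon": stage_lexicon,
    "cohort": stage_cohort,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] = STAGES
) -> dict:
    """Run the requested stages in canonical order; returns the manifest.

    The manifest (also written to <out>/manifest.json) records the config,
    the seed, the stages run, and a sha256 checksum per artifact.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; expected subset of {STAGES}")
    ordered = [s for s in STAGES if s in set(stages)]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest_path = out / "manifest.json"
    manifest = {"config": config.to_dict(), "seed": config.rng_seed, "stages": [], "checksums": {}}
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            prior = json.load(fh)
        manifest["stages"] = prior.get("stages", [])
        manifest["checksums"] = prior.get("checksums", {})

    for stage in ordered:
        logger.info("running stage %s", stage)
        written = _STAGE_FUNCS[stage](config, out)
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)
        for path in written:
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)

    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
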