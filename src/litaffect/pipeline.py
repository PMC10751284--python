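"""Pipeline orchestration: configured stages, deterministic seeding, manifest.

Stages run in dependency order — simulate (or ingest) -> stylometry ->
wordtest -> semantic -> affect — reading and writing plain-text artifacts in
the output directory, and a ``manifest.json`` records the configuration,
seeds and a SHA-256 hash of every output file, so a rerun with an identical
config can be verified bit-for-bit. Each stage is also callable on its own
against a directory produced by an earlier run (permutation testing is the
slow stage and must be re-runnable alone).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import affect as aff
from . import corpus as cio
from . import semantic_map as smap
from . import stylometry as styl
from . import synthdata as syn
from . import wordtest as wt

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "output_dir": None,
    "seed": 0,
    "stages": ["simulate", "stylometry", "wordtest", "semantic", "affect"],
    "simulate": {
        "preset": "paper-shape",
        "vocab_size": 2000,
        "n_authors": 1365,
        "tokens_per_author": 180_000,
    },
    "corpus": {"metadata": None, "text_dir": None},
    "prevalence_threshold": 0.10,
    "stoplist": None,
    "n_perm": 10_000,
    "alpha": 0.05,
    "geography_level": "continent",
    "tail": {"threshold": 0.10, "fraction": 0.10},
    "window": {"width": 50.0, "step": 10.0, "n_boot": 1000},
    "stylometry": {"target_degree": 20.0},
    "embeddings": {"enabled": False, "size": 512, "window": 5, "alpha": 0.05,
                   "sample": 1e-3, "epochs": 10, "perplexity": 40.0},
}


def make_config(overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Merge user overrides into the defaults, rejecting unknown keys."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in (overrides or {}).items():
        if key not in config:
            raise ValueError(f"unknown config key: {key!r}")
        if isinstance(config[key], dict) and isinstance(value, dict):
            for sub, subval in value.items():
                if sub not in config[key]:
                    raise ValueError(f"unknown config key: {key}.{sub}")
                config[key][sub] = subval
        else:
            config[key] = value
    if not config.get("output_dir"):
        raise ValueError("config requires output_dir")
    return config


def load_config(path: str | Path) -> dict[str, Any]:
    import yaml

    with open(path) as fh:
        return make_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def simulate_stage(config: dict[str, Any], outdir: Path) -> dict[str, Path]:
    """Generate and write the synthetic corpus plus its lexicons."""
    sim = config["simulate"]
    seed = int(config["seed"])
    preset = sim.get("preset", "paper-shape")
    overrides = {k: v for k, v in sim.items() if k != "preset"}
    if preset == "paper-shape":
        spec = syn.paper_shape_spec(seed=seed, **overrides)
    elif preset == "null":
        overrides.setdefault("n_authors", 500)
        overrides.setdefault("vocab_size", 1000)
        spec = syn.EffectSpec(seed=seed, **overrides)
    else:
        raise ValueError(f"unknown simulate preset: {preset!r}")
    corpus = syn.generate_corpus(spec)
    cio.write_metadata(corpus.authors, outdir / "metadata.tsv")
    cio.write_rates(corpus.rates, outdir)
    vocab = list(corpus.rates.words)
    norms = syn.generate_affective_norms(vocab, seed=seed + 11, rater_sex_gap=(0.2, -0.2))
    aff.write_norms(norms, outdir / "norms.tsv")
    n_pos, n_neg = min(620, len(vocab) // 3), min(743, len(vocab) // 3)
    pos, neg = syn.generate_category_lexicon(vocab, n_pos, n_neg, seed=seed + 12)
    aff.write_category_lexicon(aff.CategoryLexicon.from_sets(pos, neg),
                               outdir / "category_lexicon.tsv")
    domains = syn.generate_domain_lexicon(vocab, smap.DOMAINS, seed=seed + 13)
    domains.to_csv(outdir / "domain_lexicon.tsv", sep="\t", index=False)
    truth = {
        "sex_effect_words": {vocab[w]: d for w, d in spec.sex_effect_words.items()},
        "interaction_words": {vocab[w]: s for w, s in spec.interaction_words.items()},
        "n_null_words": len(spec.null_words),
        "seed": spec.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {p.name: p for p in
            [outdir / "metadata.tsv", outdir / "rates.mtx", outdir / "rates.rows.tsv",
             outdir / "rates.cols.tsv", outdir / "norms.tsv",
             outdir / "category_lexicon.tsv", outdir / "domain_lexicon.tsv",
             outdir / "truth.json"]}


def ingest_stage(config: dict[str, Any], outdir: Path) -> dict[str, Path]:
    """Read a real corpus, build and filter the rate matrix, write artifacts."""
    paths = config["corpus"]
    authors, streams = cio.read_corpus(paths["metadata"], paths["text_dir"])
    matrix = cio.compute_rates({a: streams[a] for a in authors["author_id"]})
    matrix = cio.filter_vocabulary(matrix, authors, threshold=config["prevalence_threshold"])
    if config.get("stoplist"):
        stop = Path(config["stoplist"]).read_text().split()
        matrix = cio.apply_stoplist(matrix, stop)
    cio.write_metadata(authors, outdir / "metadata.tsv")
    cio.write_rates(matrix, outdir)
    return {p.name: p for p in
            [outdir / "metadata.tsv", outdir / "rates.mtx",
             outdir / "rates.rows.tsv", outdir / "rates.cols.tsv"]}


def load_data(data_dir: str | Path) -> tuple[pd.DataFrame, cio.RateMatrix]:
    data_dir = Path(data_dir)
    authors = cio.read_metadata(data_dir / "metadata.tsv")
    matrix = cio.read_rates(data_dir)
    return authors, matrix


def stylometry_stage(config, outdir: Path, authors, matrix) -> dict[str, Path]:
    graph = styl.stylometric_backbone(
        matrix, authors, target_degree=config["stylometry"]["target_degree"]
    )
    gexf = outdir / "backbone.gexf"
    edges = outdir / "backbone_edges.tsv"
    styl.export_graph(graph, gexf_path=gexf, edgelist_path=edges)
    _strip_gexf_timestamp(gexf)
    return {"backbone.gexf": gexf, "backbone_edges.tsv": edges}


def _strip_gexf_timestamp(path: Path) -> None:
    # networkx stamps the file with the write date; remove it so reruns are
    # bit-identical
    text = path.read_text(encoding="utf-8")
    path.write_text(re.sub(r'\s*lastmodifieddate="[^"]*"', "", text), encoding="utf-8")


def wordtest_stage(config, outdir: Path, authors, matrix) -> dict[str, Path]:
    results = wt.run_word_tests(
        matrix,
        authors,
        n_perm=int(config["n_perm"]),
        seed=int(config["seed"]) + 1,
        alpha=config["alpha"],
        geography=config["geography_level"],
        tail_threshold=config["tail"]["threshold"],
        tail_fraction=config["tail"]["fraction"],
    )
    path = outdir / "word_tests.tsv"
    results.to_csv(path, sep="\t", index=False)
    return {"word_tests.tsv": path}


def semantic_stage(config, outdir: Path, authors, matrix) -> dict[str, Path]:
    results = pd.read_csv(outdir / "word_tests.tsv", sep="\t",
                          dtype={"word": str}, keep_default_na=False,
                          na_values=[""])
    sig = results.loc[results["significant"].astype(str).isin(["True", "1"]), "word"]
    if sig.empty:
        warnings.warn("no significant words; tracing the 50 largest-F words instead")
        sig = results.nlargest(50, "F")["word"]
    out: dict[str, Path] = {}
    lex_path = outdir / "domain_lexicon.tsv"
    if lex_path.exists():
        lexicon = smap.read_domain_lexicon(lex_path)
        labels, coverage = smap.assign_domains(list(sig), lexicon)
        labels.to_csv(outdir / "domain_labels.tsv", sep="\t", index=False)
        out["domain_labels.tsv"] = outdir / "domain_labels.tsv"
        log.info("domain coverage of significant words: %.1f%%", 100 * coverage)
        series = smap.domain_timecourses(
            matrix, authors, labels,
            width=config["window"]["width"], step=config["window"]["step"],
            n_boot=config["window"]["n_boot"], seed=int(config["seed"]) + 2,
        )
    else:
        series = smap.sliding_effect(
            matrix, authors, list(sig),
            width=config["window"]["width"], step=config["window"]["step"],
            n_boot=config["window"]["n_boot"], seed=int(config["seed"]) + 2,
        )
        series.insert(0, "domain", "all-significant")
    series.to_csv(outdir / "domain_timecourses.tsv", sep="\t", index=False)
    out["domain_timecourses.tsv"] = outdir / "domain_timecourses.tsv"
    return out


def affect_stage(config, outdir: Path, authors, matrix) -> dict[str, Path]:
    seed = int(config["seed"]) + 3
    norms = aff.read_norms(outdir / "norms.tsv")
    out: dict[str, Path] = {}

    results_path = outdir / "word_tests.tsv"
    contrasts: dict[str, Any] = {}
    if results_path.exists():
        results = pd.read_csv(results_path, sep="\t", dtype={"word": str}, keep_default_na=False,
                              na_values=[""])
        sig = results[results["significant"].astype(str).isin(["True", "1"])]
        if len(sig):
            try:
                matched = aff.sex_matched_ratings(sig, norms)
                for dim in ("valence", "arousal"):
                    contrasts[dim] = aff.compare_groups(
                        matched[dim]["male_preferred"], matched[dim]["female_preferred"],
                        seed=seed,
                    )
                contrasts["n_matched"] = matched["n_matched"]
            except ValueError as exc:
                warnings.warn(f"sex-matched contrast skipped: {exc}")

    scores = aff.score_authors(matrix, authors, norms)
    scores.to_csv(outdir / "author_scores.tsv", sep="\t", index=False)
    out["author_scores.tsv"] = outdir / "author_scores.tsv"

    model = aff.valence_arousal_model(scores)
    model_json = {
        "coefficients": model["coefficients"].to_dict(orient="index"),
        "adj_r2": model["adj_r2"], "df_resid": model["df_resid"], "n": model["n"],
    }

    tc = pd.concat([
        aff.affect_timecourse(scores, "valence_score", width=config["window"]["width"],
                              step=config["window"]["step"], n_boot=config["window"]["n_boot"],
                              seed=seed).assign(dimension="valence"),
        aff.affect_timecourse(scores, "arousal_score", width=config["window"]["width"],
                              step=config["window"]["step"], n_boot=config["window"]["n_boot"],
                              seed=seed).assign(dimension="arousal"),
    ])
    tc.to_csv(outdir / "affect_timecourse.tsv", sep="\t", index=False)
    out["affect_timecourse.tsv"] = outdir / "affect_timecourse.tsv"

    lex_path = outdir / "category_lexicon.tsv"
    if lex_path.exists():
        lexicon = aff.read_category_lexicon(lex_path)
        table, cat_contrasts = aff.category_frequencies(matrix, authors, lexicon, seed=seed)
        table.to_csv(outdir / "category_frequencies.tsv", sep="\t", index=False)
        out["category_frequencies.tsv"] = outdir / "category_frequencies.tsv"
        contrasts["categories"] = cat_contrasts

    summary = {"contrasts": contrasts, "valence_arousal_model": model_json}
    (outdir / "affect_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    out["affect_summary.json"] = outdir / "affect_summary.json"
    return out


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: dict[str, Any]) -> dict[str, Any]:
    """Execute the configured stages and write ``manifest.json``.

    A stage failure aborts the run with the stage named in the error;
    outputs of completed stages are preserved on disk.
    """
    config = make_config(config)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    authors = matrix = None
    executed = []
    for stage in config["stages"]:
        log.info("stage: %s", stage)
        try:
            if stage == "simulate":
                files.update(simulate_stage(config, outdir))
            elif stage == "ingest":
                files.update(ingest_stage(config, outdir))
            elif stage in ("stylometry", "wordtest", "semantic", "affect"):
                if authors is None:
                    authors, matrix = load_data(outdir)
                impl = {"stylometry": stylometry_stage, "wordtest": wordtest_stage,
                        "semantic": semantic_stage, "affect": affect_stage}[stage]
                files.update(impl(config, outdir, authors, matrix))
            else:
                raise ValueError(f"unknown stage: {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        executed.append(stage)
    manifest = {
        "config": {k: v for k, v in config.items() if k != "output_dir"},
        "stages_executed": executed,
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
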