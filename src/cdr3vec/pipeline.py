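"""End-to-end repertoire analysis: curate → tokenize → train → embed →
per-cohort PCA + clustering → dispersion statistics.

The embedding model is trained on one designated cohort (by convention
the pooled healthy controls); every cohort is then embedded with that
model and analyzed separately — PCA at a 90% explained-variance
threshold, a KMeans scan over k = 2..15 with silhouette-based selection
and the trivial-partition guard, and per-sequence centroid distances.
Group dispersion is finally compared across cohorts with Levene's test.

A run is fully described by a :class:`RunConfig`; one global seed expands
deterministically into per-stage seeds, and a run writes a
machine-readable ``summary.json`` plus per-cohort TSV outputs under the
output directory. Identical config + inputs give byte-identical
summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .cluster import fit_pca, kfold_stability, kmeans, scan_k, select_k
from .embed import SkipGramConfig, embed_corpus, save_model, train_skipgram
from .simulate import generate_presets
from .stats import centroid_distances, group_dispersion_report
from .tokenize import build_vocab, corpus_stats, kmerize

logger = logging.getLogger("cdr3vec")

_STAGE_NAMES = ("simulate", "embed_init", "kmeans", "kfold")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into named per-stage seeds (all < 2^31)."""
    states = np.random.SeedSequence(seed).generate_state(len(_STAGE_NAMES))
    return {name: int(s % (2 ** 31)) for name, s in zip(_STAGE_NAMES, states)}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``input_csv`` points at a clonotype table or ``simulate=True``
    generates the three preset cohorts. The defaults are the study
    profile: trigrams, 100-dimensional skip-gram over window 5 for 10
    epochs at min_count 1, 90% PCA variance, k scanned over 2..15 with
    the trivial-partition guard on.
    """

    outdir: str = "cdr3vec_run"
    input_csv: str | None = None
    simulate: bool = False
    train_group: str = "control"
    kmer_k: int = 3
    min_count: int = 1
    vector_size: int = 100
    window: int = 5
    epochs: int = 10
    negatives: int = 5
    var_threshold: float = 0.90
    k_min: int = 2
    k_max: int = 15
    trivial_guard: bool = True
    n_folds: int = 5
    kmeans_n_init: int = 10
    seed: int = 0
    save_embedding_model: bool = False

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class CohortResult:
    name: str
    n_sequences: int
    n_skipped: int
    n_components: int
    selected_k: int
    selection_rule: str
    best_silhouette: float
    selected_silhouette: float
    kfold_mean_silhouette: float | None
    mean_distance: float
    var_distance: float
    distances: np.ndarray = field(repr=False)


def _records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame({
        "sequence_id": [r.sequence_id for r in records],
        "cdr3_aa": [r.cdr3_aa for r in records],
        "sample_id": [r.sample_id for r in records],
        "group": [r.group for r in records],
    })


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return (and write) the run summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = derive_stage_seeds(config.seed)
    try:
        summary = _run_stages(config, outdir, seeds)
    except Exception as exc:
        raise PipelineError(f"pipeline aborted: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _run_stages(config: RunConfig, outdir: Path, seeds: dict[str, int]) -> dict:
    # --- input ---
    if config.simulate:
        records = generate_presets(seeds["simulate"])
        logger.info("simulate: generated %d records", len(records))
    elif config.input_csv:
        records = rio.read_clonotype_table(config.input_csv)
        logger.info("read: %d records from %s", len(records), config.input_csv)
    else:
        raise ValueError("config needs input_csv or simulate=True")

    # --- curation ---
    kept, report = rio.curate(records, min_length=config.kmer_k)
    logger.info("curate: %d in, %d kept, dropped %s",
                report.n_input, report.n_kept, report.dropped)
    if not kept:
        raise ValueError("curation removed every record")
    rio.write_clonotype_table(kept, outdir / "curated.csv")

    # --- tokenization ---
    frame = _records_to_frame(kept)
    corpus = [kmerize(r.cdr3_aa, config.kmer_k) for r in kept]
    stats_all = corpus_stats(corpus, config.kmer_k)
    groups = sorted(frame["group"].unique())
    if config.train_group not in groups:
        raise ValueError(f"training group {config.train_group!r} absent "
                         f"from data (groups: {groups})")
    train_mask = (frame["group"] == config.train_group).to_numpy()
    train_corpus = [toks for toks, m in zip(corpus, train_mask) if m]
    vocab = build_vocab(train_corpus, min_count=config.min_count)
    logger.info("tokenize: %d sequences, %d tokens, vocabulary %d",
                stats_all["n_sequences"], stats_all["n_tokens"], len(vocab))

    # --- embedding model (trained on the pooled training cohort) ---
    sg_config = SkipGramConfig(vector_size=config.vector_size,
                               window=config.window, epochs=config.epochs,
                               negatives=config.negatives,
                               seed=seeds["embed_init"])
    model = train_skipgram(train_corpus, vocab, sg_config)
    logger.info("embed: trained on %d %s sequences, %d parameters",
                len(train_corpus), config.train_group, model.param_count())
    if config.save_embedding_model:
        save_model(model, outdir / "model.json")

    # --- per-cohort analysis ---
    cohort_results: list[CohortResult] = []
    for gname in groups:
        mask = (frame["group"] == gname).to_numpy()
        sub_corpus = [toks for toks, m in zip(corpus, mask) if m]
        sub_meta = frame[mask].reset_index(drop=True)
        emb = embed_corpus(model, sub_corpus, sub_meta, on_unknown="skip")
        if emb.n_skipped:
            logger.info("embed[%s]: skipped %d unembeddable sequences",
                        gname, emb.n_skipped)
        pca_model, scores = fit_pca(emb.X, config.var_threshold)
        k_max = min(config.k_max, len(scores) - 1)
        scan = scan_k(scores, config.k_min, k_max, seed=seeds["kmeans"],
                      n_init=config.kmeans_n_init)
        k, rule = select_k(scan, trivial_guard=config.trivial_guard)
        result = kmeans(scores, k, seed=seeds["kmeans"],
                        n_init=config.kmeans_n_init)
        dists = centroid_distances(scores, result)
        kfold_mean = None
        if config.n_folds >= 2:
            _, kfold_mean = kfold_stability(scores, k, config.n_folds,
                                            seed=seeds["kfold"],
                                            n_init=config.kmeans_n_init)
        logger.info("cluster[%s]: n=%d, L=%d, k=%d (%s), silhouette %.3f",
                    gname, len(scores), pca_model.n_retained, k, rule,
                    scan.silhouettes[k])
        _write_cohort_outputs(outdir, gname, emb.meta, scores, result, scan)
        cohort_results.append(CohortResult(
            name=gname, n_sequences=len(scores), n_skipped=emb.n_skipped,
            n_components=pca_model.n_retained, selected_k=k,
            selection_rule=rule,
            best_silhouette=max(scan.silhouettes.values()),
            selected_silhouette=scan.silhouettes[k],
            kfold_mean_silhouette=kfold_mean,
            mean_distance=float(dists.mean()),
            var_distance=float(dists.var(ddof=1)) if len(dists) > 1 else 0.0,
            distances=dists))

    # --- between-group dispersion ---
    all_dists = np.concatenate([c.distances for c in cohort_results])
    all_groups = np.concatenate([[c.name] * len(c.distances)
                                 for c in cohort_results])
    report_disp = group_dispersion_report(all_dists, all_groups)
    for pw in report_disp.pairwise:
        logger.info("levene[%s vs %s]: W=%.3f p=%.3g",
                    pw.group_a, pw.group_b, pw.statistic, pw.pvalue)

    summary = {
        "config": config.as_dict(),
        "stage_seeds": seeds,
        "curation": report.as_dict(),
        "corpus_stats": stats_all,
        "vocab_size": len(vocab),
        "param_count": model.param_count(),
        "cohorts": {
            c.name: {
                "n_sequences": c.n_sequences,
                "n_skipped": c.n_skipped,
                "n_components": c.n_components,
                "selected_k": c.selected_k,
                "selection_rule": c.selection_rule,
                "best_silhouette": c.best_silhouette,
                "selected_silhouette": c.selected_silhouette,
                "kfold_mean_silhouette": c.kfold_mean_silhouette,
                "mean_distance": c.mean_distance,
                "var_distance": c.var_distance,
            } for c in cohort_results
        },
        "dispersion": report_disp.as_dict(),
    }
    return summary


def _write_cohort_outputs(outdir: Path, gname: str, meta: pd.DataFrame,
                          scores: np.ndarray, result, scan) -> None:
    """Per-cohort TSVs: PCA coordinates, cluster labels, the k-scan curves."""
    pca_df = pd.DataFrame(scores,
                          columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    pca_df.insert(0, "sequence_id", meta["sequence_id"].to_numpy())
    pca_df.to_csv(outdir / f"{gname}.pca.tsv", sep="\t", index=False)
    pd.DataFrame({"sequence_id": meta["sequence_id"],
                  "cluster": result.labels}).to_csv(
        outdir / f"{gname}.labels.tsv", sep="\t", index=False)
    pd.DataFrame({"k": scan.k_values,
                  "inertia": [scan.inertias[k] for k in scan.k_values],
                  "silhouette": [scan.silhouettes[k] for k in scan.k_values]}
                 ).to_csv(outdir / f"{gname}.scan.tsv", sep="\t", index=False)
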