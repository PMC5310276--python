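"""End-to-end pipeline: simulate → preprocess → select-k → fit → qi → map.

Each stage reads the previous stage's files from the output directory, writes
its own, and appends an entry to ``manifest.json`` (stage, inputs, outputs,
seed, wall time).  A failing stage leaves its partial outputs in place next
to a ``FAILED`` marker naming the stage.  Identical config and seed give bit
identical artifacts.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, OtuTopicsError, ValidationError
from .io_otu import OtuTable, read_labels, read_otu_table, to_corpus, write_otu_table
from .lda_core import Hyperparams, fit_lda_gibbs
from .model_selection import FitSettings, cross_validate_k, select_k
from .preprocess import preprocess_table
from .qi_stats import qi_permutation_pvalues, quetelet_index, topic_presence
from .synthetic import PRESETS, generate_labeled_corpus
from .topic_analysis import dominant_taxa, mds_topics, topic_distance, topic_overlap

log = logging.getLogger("otutopics")

STAGE_ORDER = ["simulate", "preprocess", "select_k", "fit", "qi", "map"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the package defaults.

    Loaded from a flat YAML file; unknown keys are rejected before any stage
    runs, and the effective config is always written next to the outputs.
    """

    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0
    otu_path: Optional[str] = None
    labels_path: Optional[str] = None
    delimiter: Optional[str] = None
    # simulate
    sim_preset: str = "oral-like"
    sim_k: int = 10
    sim_d: Optional[int] = None
    sim_v: Optional[int] = None
    sim_tokens: Optional[int] = None
    sim_groups: list[str] = field(default_factory=lambda: ["control", "case"])
    sim_enrich: Optional[str] = None      # "group:topic:multiplier[,...]" (1-based topic)
    sim_alpha: float = 1.0
    sim_beta: float = 0.1
    # preprocess
    min_taxa: int = 2
    min_prevalence: int = 2
    min_abundance: float = 1e-4
    vocab_mode: Optional[str] = "top_n"
    vocab_value: Optional[float] = 100
    # select_k
    k_grid: str = "2:12:2"
    folds: int = 5
    select_rule: str = "min_mean_perplexity"
    # fit
    k: Optional[int] = None               # None -> use select_k result
    alpha: Optional[float] = None         # None -> 50/K
    beta: float = 0.1
    n_iter: int = 2000
    burn_in: int = 1000
    sample_lag: int = 10
    foldin_iter: int = 200
    # qi
    presence_threshold: float = 0.05
    permutations: int = 0
    # map
    phi_display_threshold: float = 0.01

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if not self.stages:
            raise ConfigError("no stages requested")
        order = {s: i for i, s in enumerate(STAGE_ORDER)}
        if sorted(self.stages, key=order.get) != self.stages:
            raise ConfigError(f"stages must follow the order {STAGE_ORDER}")
        if "simulate" not in self.stages:
            if self.otu_path is None:
                raise ConfigError("otu_path required when not simulating")
            if not Path(self.otu_path).exists():
                raise ConfigError(f"otu_path does not exist: {self.otu_path}")
            if self.labels_path is not None and not Path(self.labels_path).exists():
                raise ConfigError(f"labels_path does not exist: {self.labels_path}")
        if self.sim_preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.sim_preset!r}; options {sorted(PRESETS)}")
        if "select_k" not in self.stages and "fit" in self.stages and self.k is None:
            raise ConfigError("fit without select_k requires an explicit k")

    def parsed_k_grid(self) -> list[int]:
        return parse_k_grid(self.k_grid)

    def parsed_enrich(self) -> dict[str, tuple[int, float]]:
        out: dict[str, tuple[int, float]] = {}
        if not self.sim_enrich:
            return out
        for part in str(self.sim_enrich).split(","):
            bits = part.strip().split(":")
            if len(bits) != 3:
                raise ConfigError(f"bad enrichment spec {part!r}; want group:topic:multiplier")
            out[bits[0]] = (int(bits[1]) - 1, float(bits[2]))
        return out


def parse_k_grid(spec: str | list[int]) -> list[int]:
    """Parse a candidate-K grid: explicit list, comma list, or start:stop:step
    (stop inclusive)."""
    if isinstance(spec, list):
        grid = [int(k) for k in spec]
    elif ":" in str(spec):
        bits = [int(b) for b in str(spec).split(":")]
        if len(bits) not in (2, 3):
            raise ConfigError(f"bad k grid {spec!r}")
        start, stop = bits[0], bits[1]
        step = bits[2] if len(bits) == 3 else 1
        grid = list(range(start, stop + 1, step))
    else:
        grid = [int(b) for b in str(spec).split(",")]
    if not grid or any(k < 1 for k in grid):
        raise ConfigError(f"bad k grid {spec!r}")
    return grid


def _write_theta(theta: np.ndarray, doc_ids: list[str], path: Path) -> None:
    K = theta.shape[1]
    pd.DataFrame(theta, index=pd.Index(doc_ids, name="id"),
                 columns=[f"topic_{k + 1}" for k in range(K)]).to_csv(path, sep="\t")


def _write_phi(phi: np.ndarray, vocab: list[str], path: Path) -> None:
    K = phi.shape[0]
    pd.DataFrame(phi, index=pd.Index([f"topic_{k + 1}" for k in range(K)], name="topic"),
                 columns=vocab).to_csv(path, sep="\t")


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.values.astype(float), [str(i) for i in df.index], [str(c) for c in df.columns]


class _Run:
    """One pipeline execution over a config and output directory."""

    def __init__(self, config: RunConfig, out_dir: Path | str):
        self.cfg = config
        self.out = Path(out_dir)
        self.manifest: list[dict] = []

    # -- helpers -------------------------------------------------------------
    def _table_path(self) -> Path:
        filtered = self.out / "filtered.tsv"
        if filtered.exists():
            return filtered
        if self.cfg.otu_path is not None and "simulate" not in self.cfg.stages:
            return Path(self.cfg.otu_path)
        return self.out / "otu.tsv"

    def _load_table(self) -> OtuTable:
        return read_otu_table(self._table_path(), label_path=self.cfg.labels_path,
                              delimiter=self.cfg.delimiter)

    def _stage_files(self, stage: str) -> tuple[list[str], list[str]]:
        table = str(self._table_path())
        files = {
            "simulate": ([], ["otu.tsv", "otu.labels.tsv", "truth.json"]),
            "preprocess": ([table], ["filtered.tsv", "filtered.labels.tsv", "report.json"]),
            "select_k": ([table], ["cv.tsv", "cv_summary.tsv", "selected_k.json"]),
            "fit": ([table], ["theta.tsv", "phi.tsv", "trace.tsv", "params.json"]),
            "qi": ([str(self.out / "theta.tsv")], ["qi.tsv"]),
            "map": ([str(self.out / "phi.tsv")],
                    ["dominant.tsv", "overlap.tsv", "dist.tsv", "coords.tsv", "eigs.json"]),
        }
        inputs, outputs = files[stage]
        return inputs, [str(self.out / f) for f in outputs if (self.out / f).exists()]

    def _record(self, stage: str, t0: float) -> None:
        inputs, outputs = self._stage_files(stage)
        self.manifest.append({"stage": stage, "inputs": inputs, "outputs": outputs,
                              "seed": self.cfg.seed, "config": str(self.out / "config.yaml"),
                              "wall_time_s": round(time.time() - t0, 3)})
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    # -- stages --------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.cfg
        preset = PRESETS[cfg.sim_preset]
        D = cfg.sim_d or preset["D"]
        V = cfg.sim_v or preset["V"]
        tokens = cfg.sim_tokens or preset["tokens_per_doc"]
        table, truth = generate_labeled_corpus(
            cfg.sim_k, V, D, tokens, cfg.sim_groups, cfg.parsed_enrich(),
            alpha=cfg.sim_alpha, beta=cfg.sim_beta, seed=cfg.seed)
        write_otu_table(table, self.out / "otu.tsv")
        (self.out / "truth.json").write_text(truth.to_json())

    def preprocess(self) -> None:
        table = self._load_table()
        filtered, report = preprocess_table(
            table, min_taxa=self.cfg.min_taxa, min_prevalence=self.cfg.min_prevalence,
            min_mean_rel_abundance=self.cfg.min_abundance,
            vocab_mode=self.cfg.vocab_mode, vocab_value=self.cfg.vocab_value)
        write_otu_table(filtered, self.out / "filtered.tsv")
        (self.out / "report.json").write_text(report.to_json())

    def select_k(self) -> None:
        cfg = self.cfg
        corpus = to_corpus(self._load_table())
        settings = FitSettings(n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                               sample_lag=cfg.sample_lag, alpha=cfg.alpha,
                               beta=cfg.beta, foldin_iter=cfg.foldin_iter)
        cv = cross_validate_k(corpus, cfg.parsed_k_grid(), cfg.folds,
                              settings, seed=cfg.seed)
        cv.to_frame().to_csv(self.out / "cv.tsv", sep="\t", index=False)
        cv.summary_frame().to_csv(self.out / "cv_summary.tsv", sep="\t", index=False)
        chosen = select_k(cv, cfg.select_rule)
        (self.out / "selected_k.json").write_text(
            json.dumps({"selected_k": chosen, "rule": cfg.select_rule}))
        log.info("selected K=%d by %s", chosen, cfg.select_rule)

    def _resolve_k(self) -> int:
        if self.cfg.k is not None:
            return int(self.cfg.k)
        sel = self.out / "selected_k.json"
        if not sel.exists():
            raise ConfigError("no k configured and no select_k stage output found")
        return int(json.loads(sel.read_text())["selected_k"])

    def fit(self) -> None:
        cfg = self.cfg
        corpus = to_corpus(self._load_table())
        K = self._resolve_k()
        hyper = Hyperparams.with_defaults(K, cfg.alpha, cfg.beta)
        fit = fit_lda_gibbs(corpus, hyper, n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                            sample_lag=cfg.sample_lag, seed=cfg.seed)
        _write_theta(fit.theta, fit.doc_ids, self.out / "theta.tsv")
        _write_phi(fit.phi, fit.vocab, self.out / "phi.tsv")
        pd.DataFrame({"iteration": np.arange(1, len(fit.trace) + 1),
                      "joint_log_likelihood": fit.trace}).to_csv(
            self.out / "trace.tsv", sep="\t", index=False)
        params = {"K": K, "alpha": hyper.alpha, "beta": hyper.beta, **fit.settings}
        (self.out / "params.json").write_text(json.dumps(params, indent=2))

    def qi(self) -> None:
        cfg = self.cfg
        theta, doc_ids, _ = _read_matrix(self.out / "theta.tsv")
        if cfg.labels_path is not None:
            labels = read_labels(cfg.labels_path)
        else:
            table = self._load_table()
            if table.labels is None:
                raise ValidationError("qi stage needs sample labels (labels_path or sidecar)")
            labels = table.labels
        presence = topic_presence(theta, cfg.presence_threshold, doc_ids)
        qi = quetelet_index(presence, labels)
        frame = qi.to_frame()
        if cfg.permutations:
            p = qi_permutation_pvalues(presence, labels, n_perm=cfg.permutations,
                                       seed=cfg.seed)
            frame["p_perm"] = [p[k, g] for k in range(p.shape[0])
                               for g in range(p.shape[1])]
        frame.to_csv(self.out / "qi.tsv", sep="\t", index=False)

    def map(self) -> None:
        cfg = self.cfg
        phi, _, vocab = _read_matrix(self.out / "phi.tsv")
        summary = dominant_taxa(phi, vocab, cfg.phi_display_threshold)
        rows = [{"topic": k + 1, "taxon": name, "probability": prob}
                for k, entries in enumerate(summary.dominant)
                for name, prob in entries]
        pd.DataFrame(rows, columns=["topic", "taxon", "probability"]).to_csv(
            self.out / "dominant.tsv", sep="\t", index=False)
        overlap = topic_overlap(summary)
        labels_k = [f"topic_{k + 1}" for k in range(phi.shape[0])]
        pd.DataFrame(overlap, index=labels_k, columns=labels_k).to_csv(
            self.out / "overlap.tsv", sep="\t")
        dist = topic_distance(phi)
        pd.DataFrame(dist, index=labels_k, columns=labels_k).to_csv(
            self.out / "dist.tsv", sep="\t")
        tmap = mds_topics(dist)
        tmap.coords_frame().to_csv(self.out / "coords.tsv", sep="\t", index=False)
        (self.out / "eigs.json").write_text(tmap.eigs_json())

    def run(self) -> Path:
        self.cfg.validate()
        self.out.mkdir(parents=True, exist_ok=True)
        (self.out / "config.yaml").write_text(self.cfg.to_yaml())
        failed_marker = self.out / "FAILED"
        if failed_marker.exists():
            failed_marker.unlink()
        for stage in self.cfg.stages:
            t0 = time.time()
            log.info("stage %s started", stage)
            try:
                getattr(self, stage)()
            except Exception as exc:
                failed_marker.write_text(f"stage {stage} failed: {exc}\n")
                raise OtuTopicsError(f"stage {stage!r} failed: {exc}") from exc
            self._record(stage, t0=t0)
            log.info("stage %s finished in %.2fs", stage, time.time() - t0)
        return self.out


def run_pipeline(config: RunConfig, out_dir: Path | str) -> Path:
    """Validate the config, then execute its stages in order under ``out_dir``.

    Returns the output directory; raises :class:`OtuTopicsError` naming the
    failing stage (partial outputs are kept next to a ``FAILED`` marker).
    """
    return _Run(config, out_dir).run()
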