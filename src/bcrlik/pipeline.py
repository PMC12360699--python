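"""End-to-end orchestration: simulate -> ingest -> score -> trees -> shm -> stats.

Configuration is a single YAML mapping (see :class:`PipelineConfig`); every
stage writes plain-text artifacts into the run directory and the run ends
with a manifest listing each output with its SHA-256 content hash, the
resolved configuration, and the seed, so re-running an identical
configuration is auditable byte-for-byte for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .io import (
    filter_cells,
    read_filtered_repertoire,
    read_repertoire,
    write_repertoire,
)
from .likelihood import (
    DirichletColumnProvider,
    GermlineAnchoredProvider,
    InputSource,
    LikelihoodProvider,
    UniformProvider,
    score_repertoire,
)
from .lineage import build_forest, write_forest
from .records import Repertoire
from .shm import (
    conserved_vs_mutating,
    edge_records_to_frame,
    forest_edge_substitutions,
    matrix_evenness,
    mean_substitution_rank,
)
from .simulate import (
    SimulationConfig,
    simulate_affinity_table,
    simulate_frequency_table,
    simulate_repertoire,
)
from .stats import (
    affinity_association,
    correlate,
    frequency_association,
    group_compare,
    results_to_frame,
    sp_feature_table,
)

logger = logging.getLogger(__name__)

DEFAULT_SOURCES = ["full_vdj", "cdr3_from_vdj", "cdr3_only", "paired"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``simulate`` (a :class:`SimulationConfig` parameter mapping) or
    ``input`` (path + dialect of an existing contig table) must be present.
    """

    seed: int = 0
    simulate: SimulationConfig | None = None
    input_path: str | None = None
    input_dialect: str = "airr_tsv"
    provider: str = "germline_anchored"
    provider_params: dict = field(default_factory=lambda: {"q": 0.7})
    sources: list[str] = field(default_factory=lambda: list(DEFAULT_SOURCES))
    tree_chains: str = "heavy"
    include_germline_edges: bool = True
    adjust: str = "holm"
    log_base: str = "e"
    frequency_table: str | None = None
    affinity_table: str | None = None

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        known = {
            "seed", "simulate", "input", "provider", "sources",
            "trees", "stats", "frequency_table", "affinity_table",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        cfg.seed = int(raw.get("seed", 0))
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", cfg.seed)
            if "cdr3_span" in sim:
                sim["cdr3_span"] = tuple(sim["cdr3_span"])
            try:
                cfg.simulate = SimulationConfig(**sim)
            except TypeError as exc:
                raise ConfigError(f"bad simulate section: {exc}") from None
        if "input" in raw and raw["input"] is not None:
            inp = raw["input"]
            cfg.input_path = inp.get("path")
            cfg.input_dialect = inp.get("dialect", "airr_tsv")
        if cfg.simulate is None and cfg.input_path is None:
            raise ConfigError("config needs a 'simulate' section or an 'input' path")
        prov = raw.get("provider", {"name": "germline_anchored", "q": 0.7})
        if isinstance(prov, str):
            prov = {"name": prov}
        prov = dict(prov)
        cfg.provider = prov.pop("name", "germline_anchored")
        cfg.provider_params = prov
        cfg.sources = list(raw.get("sources", DEFAULT_SOURCES))
        for s in cfg.sources:
            InputSource.parse(s)
        trees = raw.get("trees", {}) or {}
        cfg.tree_chains = trees.get("chains", "heavy")
        if cfg.tree_chains not in ("heavy", "paired"):
            raise ConfigError(f"trees.chains must be heavy|paired, got {cfg.tree_chains!r}")
        cfg.include_germline_edges = bool(trees.get("include_germline_edges", True))
        stats = raw.get("stats", {}) or {}
        cfg.adjust = stats.get("adjust", "holm")
        cfg.log_base = str(stats.get("log_base", "e"))
        cfg.frequency_table = raw.get("frequency_table")
        cfg.affinity_table = raw.get("affinity_table")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML: {exc}") from None
        return cls.from_mapping(raw)


def make_provider(name: str, params: dict, rep: Repertoire) -> LikelihoodProvider:
    """Instantiate a provider by name; germline-anchored registers the repertoire."""
    if name == "germline_anchored":
        return GermlineAnchoredProvider.from_cells(rep.cells, q=params.get("q", 0.7))
    if name == "uniform":
        return UniformProvider()
    if name == "dirichlet":
        return DirichletColumnProvider(
            seed=params.get("seed", 0), concentration=params.get("concentration", 0.3)
        )
    raise ConfigError(f"unknown provider {name!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage; returns the run directory.

    Stage failure aborts with the failing stage named; artifacts written by
    earlier stages are retained.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        # -- simulate / ingest ------------------------------------------------
        sim = None
        if config.simulate is not None:
            stage = "simulate"
            sim = simulate_repertoire(config.simulate)
            artifacts.update(sim.write(out_dir / "repertoire"))
            stage = "ingest"
            records = read_repertoire(artifacts["airr"], dialect="airr_tsv")
            clone_map = {cid: t.clone_id for cid, t in sim.truth.items()}
            rep = filter_cells(records, clonotype="existing", existing_clones=clone_map)
        else:
            stage = "ingest"
            records = read_repertoire(config.input_path, dialect=config.input_dialect)
            rep = filter_cells(records)
        artifacts.update(write_repertoire(rep, out_dir / "repertoire"))
        if not rep.cells:
            raise DataError("no cells retained after filtering")

        # -- score ------------------------------------------------------------
        stage = "score"
        provider = make_provider(config.provider, config.provider_params, rep)
        sources = [InputSource.parse(s) for s in config.sources]
        if InputSource.PAIRED in sources and not provider.paired_scoring:
            sources = [s for s in sources if s != InputSource.PAIRED]
            logger.info("provider %s lacks paired scoring; PAIRED dropped", provider.name)
        scores = score_repertoire(rep, provider, sources, log_base=config.log_base)
        score_dir = out_dir / "scores"
        score_dir.mkdir(exist_ok=True)
        artifacts["scored"] = score_dir / "scored.csv"
        scores.to_frame().to_csv(artifacts["scored"], index=False)

        # -- trees ------------------------------------------------------------
        stage = "trees"
        forest = build_forest(rep, chains=config.tree_chains)
        artifacts.update(write_forest(forest, out_dir / "trees"))

        # -- shm --------------------------------------------------------------
        stage = "shm"
        shm_dir = out_dir / "shm"
        shm_dir.mkdir(exist_ok=True)
        heavy_forest = forest if config.tree_chains == "heavy" else build_forest(rep, "heavy")
        edge_records = forest_edge_substitutions(
            heavy_forest, provider,
            include_germline_edges=config.include_germline_edges, sample_id="sample1",
        )
        artifacts["edges"] = shm_dir / "edge_substitutions.csv"
        edge_records_to_frame(edge_records).to_csv(artifacts["edges"], index=False)
        shm_summary: dict = {"n_edges_scored": len(edge_records)}
        if edge_records:
            per_sample, grand = mean_substitution_rank(edge_records)
            cvm = conserved_vs_mutating(
                heavy_forest, provider,
                include_germline_edges=config.include_germline_edges,
            )
            shm_summary.update(
                mean_substitution_rank=grand,
                mean_rl_mutating=cvm.mean_rl_mutating,
                mean_rl_conserved=cvm.mean_rl_conserved,
                conserved_vs_mutating_p=cvm.p_value,
            )
        # evenness over a bounded sample of unique heavy sequences
        unique_heavy = sorted({c.heavy.sequence_aa for c in rep.cells})[:50]
        ev_rows = []
        for seq in unique_heavy:
            for pos, ev in enumerate(matrix_evenness(provider.residue_probabilities(seq))):
                ev_rows.append({"sequence": seq, "position": pos, "evenness": ev})
        artifacts["evenness"] = shm_dir / "evenness.csv"
        pd.DataFrame(ev_rows).to_csv(artifacts["evenness"], index=False)
        if ev_rows:
            shm_summary["mean_evenness"] = float(
                np.mean([r["evenness"] for r in ev_rows])
            )
        artifacts["shm_summary"] = shm_dir / "summary.json"
        artifacts["shm_summary"].write_text(json.dumps(shm_summary, indent=2))

        # -- stats ------------------------------------------------------------
        stage = "stats"
        stats_dir = out_dir / "stats"
        stats_dir.mkdir(exist_ok=True)
        table = sp_feature_table(scores, rep, trees=heavy_forest)
        heavy_full = table[
            (table["locus"] == "heavy") & (table["source"] == "full_vdj")
        ].dropna(subset=["sp"])
        results = []
        sub = heavy_full.dropna(subset=["hamming_shm"])
        if len(sub) >= 3:
            results.append(
                correlate(sub["sp"], sub["hamming_shm"], "pearson", analysis="sp_vs_shm")
            )
        sub = heavy_full.dropna(subset=["normalized_expansion"])
        if len(sub) >= 3:
            results.append(
                correlate(sub["sp"], sub["normalized_expansion"], "pearson",
                          analysis="sp_vs_expansion")
            )
        sub = heavy_full.dropna(subset=["root_path_length"])
        if len(sub) >= 3:
            results.append(
                correlate(sub["sp"], sub["root_path_length"], "pearson",
                          analysis="sp_vs_root_distance")
            )
        isotypes = [i for i in ("IgG", "IgA") if (heavy_full["isotype"] == i).sum() >= 2]
        results.extend(
            group_compare(
                heavy_full, "sp", "isotype",
                pairs=[("IgM", iso) for iso in isotypes], adjust=config.adjust,
            )
        )
        if config.frequency_table:
            freq = pd.read_csv(config.frequency_table)
            mean_sp = (
                heavy_full.groupby("v_family")["sp"].mean()
                .rename_axis("group").reset_index(name="mean_sp")
            )
            try:
                results.append(frequency_association(mean_sp, freq))
            except DataError as exc:
                logger.info("frequency_association skipped: %s", exc)
        else:
            logger.info("no frequency table supplied; frequency_association skipped")
        affinity = None
        if config.affinity_table:
            affinity = pd.read_csv(config.affinity_table)
        elif sim is not None and config.simulate.affinity_coupling:
            affinity = simulate_affinity_table(
                sim, coupling=config.simulate.affinity_coupling,
                noise_sd=0.3, seed=config.seed + 1,
            )
            artifacts["affinity_table"] = stats_dir / "affinity_table.csv"
            affinity.to_csv(artifacts["affinity_table"], index=False)
        if affinity is not None and not affinity.empty:
            try:
                results.append(affinity_association(heavy_full, affinity))
            except DataError as exc:
                logger.info("affinity_association skipped: %s", exc)
        if sim is not None:
            artifacts["frequency_table"] = stats_dir / "frequency_table.csv"
            simulate_frequency_table(sim, "v_family").to_csv(
                artifacts["frequency_table"], index=False
            )
        artifacts["associations"] = stats_dir / "associations.csv"
        results_to_frame(results).to_csv(artifacts["associations"], index=False)
        artifacts["stats_summary"] = stats_dir / "summary.json"
        artifacts["stats_summary"].write_text(
            json.dumps([r.as_dict() for r in results], indent=2)
        )
    except (ConfigError, DataError) as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    # -- manifest -------------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "provider": config.provider,
        "outputs": {
            name: {"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def demo_config(seed: int = 0, n_cells: int = 300) -> PipelineConfig:
    """Bundled one-command synthetic demonstration configuration."""
    return PipelineConfig.from_mapping(
        {"seed": seed, "simulate": {"n_cells": n_cells}}
    )
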