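"""End-to-end orchestration with a structured config and one global seed.

The pipeline chains: gene scoring -> consensus co-expression inference ->
prior-network construction and filtering -> hub ranking -> drug feature
tables -> genetic optimization -> stability analysis, writing every
intermediate artifact plus a machine-readable run manifest into the output
directory. Each stage is individually re-runnable through the CLI
subcommands; any stage error aborts the run and names the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import DEFAULT_GRID, ensemble_consensus, rank_hub_genes
from .expression import DISEASE, ExpressionMatrix, score_genes
from .features import DrugRecord, build_feature_tables, build_moa_networks
from .networks import WeightedNetwork
from .optimizer import GAConfig, run_optimizer, stability_analysis
from .prior import PriorLayer, build_prior_network, filter_disease_network

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "load_drug_library",
    "load_layers",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class StageParams:
    """Tunable stage parameters (defaults are the published design)."""

    top_fraction: float = 0.10
    min_pairs: int = 10
    min_replicates: int = 6
    bins: int | None = None
    consensus_keep_top: int | None = None  # default 2N inside consensus
    algorithms: list[str] = field(default_factory=lambda: list(DEFAULT_GRID["algorithms"]))
    estimators: list[str] = field(default_factory=lambda: list(DEFAULT_GRID["estimators"]))
    discretizers: list[str] = field(default_factory=lambda: list(DEFAULT_GRID["discretizers"]))
    stability_runs: int = 10


@dataclass
class PipelineConfig:
    """Validated description of one pipeline run."""

    expression: str
    sample_meta: str
    drug_table: str
    moa_manifest: str
    layer_manifest: str
    output_dir: str
    seed: int = 0
    params: StageParams = field(default_factory=StageParams)
    ga: GAConfig = field(default_factory=GAConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        params = _from_mapping(StageParams, data.pop("params", {}), "params")
        ga = _from_mapping(GAConfig, data.pop("ga", {}), "ga")
        cfg = _from_mapping(cls, {**data, "params": params, "ga": ga}, "pipeline")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        base = Path(path).parent
        for key in ("expression", "sample_meta", "drug_table", "moa_manifest",
                    "layer_manifest", "output_dir"):
            if key in data and not Path(data[key]).is_absolute():
                data[key] = str(base / data[key])
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def parameter_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input loaders
# ---------------------------------------------------------------------------

def load_drug_library(
    drug_table: str | Path, moa_manifest: str | Path | None = None
) -> list[DrugRecord]:
    """Read the drug table TSV and attach per-drug MOA replicate profiles."""
    df = pd.read_csv(drug_table, sep="\t", dtype=str)
    profiles: dict[str, pd.DataFrame] = {}
    if moa_manifest is not None:
        manifest = pd.read_csv(moa_manifest, sep="\t", dtype=str)
        base = Path(moa_manifest).parent
        for _, row in manifest.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            prof = pd.read_csv(p, sep="\t", index_col=0)
            prof.index = prof.index.astype(str)
            profiles[row["drug_id"]] = prof
    drugs = []
    for _, row in df.iterrows():
        targets = {t for t in str(row["targets"]).split(",") if t}
        drugs.append(
            DrugRecord(
                drug_id=row["drug_id"],
                smiles=row["smiles"],
                targets=targets,
                moa_profiles=profiles.get(row["drug_id"]),
            )
        )
    return drugs


def load_layers(layer_manifest: str | Path) -> list[PriorLayer]:
    """Read the layer manifest (YAML) and its per-source TSV files."""
    with open(layer_manifest) as fh:
        manifest = yaml.safe_load(fh)
    base = Path(layer_manifest).parent
    layers = []
    for entry in manifest["layers"]:
        p = Path(entry["file"])
        if not p.is_absolute():
            p = base / p
        layers.append(
            PriorLayer.read_tsv(
                p,
                source_name=entry.get("source_name", p.stem),
                category=entry["category"],
                kind=entry["type"],
            )
        )
    return layers


# ---------------------------------------------------------------------------
# main pipeline
# ---------------------------------------------------------------------------

def _combined_ss(table: pd.DataFrame) -> pd.Series:
    """Per-gene overall significance: the larger of the two test SS values."""
    return table[["SS_wilcoxon", "SS_ftest"]].max(axis=1)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("netcombo")
    root.addHandler(handler)
    try:
        return _run_stages(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path) -> Path:
    p = config.params
    grid = dict(
        algorithms=p.algorithms,
        estimators=p.estimators,
        discretizers=p.discretizers,
        bins=p.bins,
    )

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("load_expression")
    try:
        expr = ExpressionMatrix.read_tsv(config.expression, config.sample_meta)
        if expr.n_pairs < p.min_pairs:
            raise ValueError(
                f"{expr.n_pairs} matched pairs < required minimum {p.min_pairs}"
            )

        current = stage("expression_scoring")
        table = score_genes(expr, fraction=p.top_fraction)
        table.to_csv(out / "gene_scores.tsv", sep="\t", float_format="%.10g")
        selected = sorted(table.index[table["selected"] == 1])

        current = stage("coexpression_inference")
        disease_cols = expr.sample_meta.loc[
            expr.sample_meta["condition"] == DISEASE, "sample_id"
        ]
        log_sub = np.log2(expr.values.loc[selected, disease_cols] + 1.0)
        consensus = ensemble_consensus(log_sub, keep_top=p.consensus_keep_top, **grid)
        consensus.write_tsv(out / "consensus_network.tsv")

        current = stage("prior_knowledge")
        layers = load_layers(config.layer_manifest)
        prior = build_prior_network(layers)
        prior.write_tsv(out / "prior_network.tsv")
        filtered = filter_disease_network(consensus, prior)
        filtered.write_tsv(out / "filtered_network.tsv")

        current = stage("hub_ranking")
        ranking = rank_hub_genes(filtered, _combined_ss(table.loc[selected]))
        ranking.to_csv(out / "hub_ranking.tsv", sep="\t", float_format="%.10g")

        current = stage("drug_features")
        drugs = load_drug_library(config.drug_table, config.moa_manifest)
        feats = build_feature_tables(
            drugs, filtered, ranking, min_replicates=p.min_replicates, **grid
        )
        feats.him.to_csv(out / "him.tsv", sep="\t", float_format="%.10g")
        feats.lev.to_csv(out / "lev.tsv", sep="\t")
        feats.sp.to_csv(out / "sp.tsv", sep="\t", float_format="%.10g")
        feats.es.to_csv(out / "es.tsv", sep="\t", float_format="%.10g")
        with open(out / "excluded_drugs.json", "w") as fh:
            json.dump(feats.excluded, fh, indent=2)

        current = stage("pareto_optimizer")
        state = run_optimizer(feats, config.ga, seed=config.seed)
        state.write_hof_json(out / "hof.json")
        state.write_traces_tsv(out / "traces.tsv")

        current = stage("stability_analysis")
        stability = stability_analysis(
            feats, config.ga, n_runs=p.stability_runs, seed=config.seed
        )
        stability.write_frequency_tsv(out / "frequency_network.tsv")
        np.savetxt(out / "stability_jaccard.tsv", stability.jaccard, delimiter="\t")

        current = stage("manifest")
        with open(out / "manifest.json", "w") as fh:
            json.dump(
                {
                    "netcombo_version": __version__,
                    "seed": config.seed,
                    "parameter_hash": config.parameter_hash(),
                    "config": config.to_dict(),
                    "n_selected_genes": len(selected),
                    "n_drugs": feats.n_drugs,
                    "excluded_drugs": feats.excluded,
                },
                fh,
                indent=2,
            )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        logger.error("pipeline aborted at stage %s: %s", current, exc)
        raise PipelineStageError(current, exc) from exc
    return out
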