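"""End-to-end orchestration: config, staged execution, reproducibility manifest.

Stage order: load (or simulate) -> subsample to common depth -> identify and
remove contaminants using negative controls -> alpha diversity + group
comparisons | taxon aggregation + group-mean abundances | CLR -> Aitchison
distances -> PCoA + pairwise ANOSIM -> matched home-stable transfer ranking.
Every random stage derives its seed from the single top-level seed, and a
rerun with the same config reproduces all outputs byte-identically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alpha_diversity import alpha_frame, alpha_metrics, compare_groups_alpha
from .beta_diversity import aitchison_distance, clr_transform, pairwise_anosim, pcoa
from .preprocess import (
    aggregate_taxa,
    contaminant_frame,
    group_mean_relative_abundance,
    prevalence_contaminant_scores,
    remove_contaminants,
    subsample_to_depth,
)
from .synthetic_data import generate_study, preset_study_shape
from .tables_io import (
    HOME_ENVIRONMENT,
    Metadata,
    ValidationError,
    derive_seed,
    join_metadata,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)
from .transfer_linkage import matched_pair_distances, ranking_frame, transfer_test

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Either ``simulate_preset`` ("study") or the three input paths must be
    given.  All tunables are recorded in the output manifest.
    """

    out_dir: str = "aerotransfer_out"
    simulate_preset: str | None = None
    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    depth: int = 20_000
    pseudocount: float = 0.5
    decontam_threshold: float = 0.1
    presence_min: int = 1
    n_permutations: int = 999
    n_null_draws: int = 999
    ranking_mode: str = "row_wise"
    aggregate_level: str = "phylum"
    min_mean_abundance: float = 0.0001
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output plus the manifest."""

    alpha: pd.DataFrame
    alpha_comparisons: pd.DataFrame
    distance: "object"  # skbio DistanceMatrix
    ordination: "object"
    anosim: pd.DataFrame
    abundance: pd.DataFrame
    transfer: dict[str, dict]
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return run

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "aerotransfer_version": __version__,
        "config": asdict(config),
        "seeds": {},
    }

    # -- load or simulate ---------------------------------------------------
    @_stage("load")
    def _load():
        if config.simulate_preset is not None:
            if config.simulate_preset != "study":
                raise ValidationError(
                    f"unknown simulate preset {config.simulate_preset!r}"
                )
            sim_seed = derive_seed(config.seed, "simulate")
            manifest["seeds"]["simulate"] = sim_seed
            table, meta, tax, _truth = generate_study(preset_study_shape(seed=sim_seed))
            return join_metadata(table, meta, tax)
        if not (config.table_path and config.metadata_path):
            raise ValidationError("either simulate_preset or input paths are required")
        table = read_feature_table(config.table_path)
        meta = read_metadata(config.metadata_path)
        tax = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
        return join_metadata(table, meta, tax)

    bundle = _load()
    manifest["input_group_sizes"] = bundle.group_sizes()
    manifest["metadata_only_samples"] = bundle.extra_metadata_ids

    # -- subsample ----------------------------------------------------------
    @_stage("subsample")
    def _subsample():
        sub_seed = derive_seed(config.seed, "subsample_stage")
        manifest["seeds"]["subsample"] = sub_seed
        sub, dropped = subsample_to_depth(bundle.table, config.depth, sub_seed)
        if sub.n_samples == 0:
            raise ValidationError("no samples retained at the requested depth")
        return sub, dropped

    table, dropped = _subsample()
    meta = bundle.metadata.subset(table.sample_ids)
    manifest["dropped_samples"] = dropped
    manifest["retained_group_sizes"] = meta.group_sizes()

    # -- decontaminate ------------------------------------------------------
    @_stage("decontam")
    def _decontam():
        reports = prevalence_contaminant_scores(
            table, meta, threshold=config.decontam_threshold,
            presence_min=config.presence_min,
        )
        return reports, remove_contaminants(table, reports)

    reports, table_clean = _decontam()
    flagged = [r.feature_id for r in reports if r.is_contaminant]
    manifest["flagged_contaminants"] = flagged
    contaminants_df = contaminant_frame(reports)

    # true samples only, controls served their purpose
    true_ids = [s for s in table_clean.sample_ids if not meta[s].is_control]
    table_true = table_clean.select_samples(true_ids)
    meta_true = meta.subset(true_ids)
    envs = sorted(meta_true.group_sizes())
    pairs = list(itertools.combinations(envs, 2))

    # -- alpha diversity ----------------------------------------------------
    @_stage("alpha")
    def _alpha():
        records = alpha_metrics(table_true)
        comparisons = compare_groups_alpha(records, meta_true, pairs)
        return alpha_frame(records), comparisons

    alpha_df, alpha_cmp = _alpha()

    # -- abundance summary --------------------------------------------------
    @_stage("abundance")
    def _abundance():
        if bundle.taxonomy is None:
            return pd.DataFrame()
        agg = aggregate_taxa(table_true, bundle.taxonomy, config.aggregate_level)
        return group_mean_relative_abundance(
            agg, meta_true, min_mean_abundance=config.min_mean_abundance
        )

    abundance = _abundance()

    # -- beta diversity -----------------------------------------------------
    @_stage("beta")
    def _beta():
        clr = clr_transform(table_true, pseudocount=config.pseudocount)
        dm = aitchison_distance(clr)
        ord_res = pcoa(dm, n_axes=3)
        anosim_seed = derive_seed(config.seed, "anosim")
        manifest["seeds"]["anosim"] = anosim_seed
        anosim_df = pairwise_anosim(
            dm, meta_true, pairs, n_permutations=config.n_permutations, seed=anosim_seed
        )
        return dm, ord_res, anosim_df

    dm, ordination, anosim_df = _beta()

    # -- transfer ranking ---------------------------------------------------
    @_stage("transfer")
    def _transfer():
        results: dict[str, dict] = {}
        transfer_seed = derive_seed(config.seed, "transfer")
        manifest["seeds"]["transfer"] = transfer_seed
        for livestock in sorted(HOME_ENVIRONMENT):
            try:
                sub, matching, log = matched_pair_distances(dm, meta_true, livestock)
            except ValidationError:
                continue  # no matched farms of this type in the study
            summary, rankings = transfer_test(
                sub,
                matching,
                mode=config.ranking_mode,
                n_null_draws=config.n_null_draws,
                seed=transfer_seed,
            )
            results[livestock] = {
                "summary": asdict(summary),
                "rankings": ranking_frame(rankings),
                "log": log,
            }
        return results

    transfer = _transfer()

    # -- write outputs ------------------------------------------------------
    @_stage("write")
    def _write():
        write_feature_table(table_clean, out / "table_subsampled_decontaminated.tsv")
        write_metadata(meta, out / "metadata_retained.tsv")
        if bundle.taxonomy is not None:
            write_taxonomy(bundle.taxonomy, out / "taxonomy.tsv")
        _write_tsv(contaminants_df, out / "contaminant_scores.tsv")
        _write_tsv(alpha_df, out / "alpha.tsv")
        _write_tsv(alpha_cmp, out / "alpha_comparisons.tsv")
        _write_tsv(dm.to_data_frame(), out / "distance_matrix.tsv", index=True)
        coords = ordination.coordinates.copy()
        coords.index.name = "sample_id"
        _write_tsv(coords, out / "ordination.tsv", index=True)
        eig = pd.DataFrame(
            {
                "eigenvalue": ordination.eigenvalues,
                "proportion_explained": list(ordination.proportion_explained)
                + [float("nan")]
                * (len(ordination.eigenvalues) - len(ordination.proportion_explained)),
            }
        )
        _write_tsv(eig, out / "ordination_eigenvalues.tsv")
        _write_tsv(anosim_df, out / "anosim.tsv")
        if len(abundance):
            ab = abundance.copy()
            ab.index.name = "taxon"
            _write_tsv(ab, out / "abundance_group_means.tsv", index=True)
        transfer_summaries = {}
        for livestock, res in transfer.items():
            _write_tsv(res["rankings"], out / f"transfer_rankings_{livestock}.tsv")
            transfer_summaries[livestock] = {"summary": res["summary"], "log": res["log"]}
        _write_json(transfer_summaries, out / "transfer_summary.json")
        _write_json(manifest, out / "manifest.json")

    _write()
    return PipelineResult(
        alpha=alpha_df,
        alpha_comparisons=alpha_cmp,
        distance=dm,
        ordination=ordination,
        anosim=anosim_df,
        abundance=abundance,
        transfer=transfer,
        manifest=manifest,
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
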