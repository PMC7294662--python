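"""End-to-end pipeline: simulate/ingest -> clean -> MODERN -> fit -> score
-> threshold -> compare -> differential statistics -> report.

A run is driven by a :class:`PipelineConfig` (round-trippable through a
versioned YAML file) and a master seed from which every stage derives
its own seed, so reruns are reproducible and no stage consumes global
randomness.  Each stage writes its artifacts under the output directory;
a rerun without ``force`` skips stages whose outputs already exist and
reloads them instead.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diffnet, features, inference, modern, preprocess, simulate
from .matrix import (
    CHANNEL_CONDITION,
    CHANNELS,
    ChromatogramMatrix,
    read_chromatogram_matrix,
)

log = logging.getLogger("cofracnet")

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """All pipeline knobs, with defaults matching the analysis recipe.

    Either simulation parameters (the default) or explicit input paths
    drive the run: set ``input_dir`` to a directory holding chromatogram
    TSVs named ``rep{r}_{channel}.tsv`` plus ``complexes.tsv`` to skip
    simulation.
    """

    # simulation inputs
    n_proteins: int = 100
    n_complexes: int = 15
    complex_size_min: int = 3
    complex_size_max: int = 5
    rewired_fraction: float = 0.3
    n_fractions: int = 60
    n_replicates: int = 3
    noise_sd: float = 0.05
    missing_rate: float = 0.2
    spike_rate: float = 0.002
    spike_magnitude: float = 50.0
    # or: pre-existing data
    input_dir: str | None = None
    gene_sets_gmt: str | None = None
    fold_changes_tsv: str | None = None
    # analysis parameters
    target_precision: float = 0.70
    fwer: float = 0.05
    n_perm: int = 1000
    n_iter_factor: float = 6.9
    min_obs: int = 5
    smooth_width: int = 5
    max_components: int = 5
    n_folds: int = 10
    jaccard_min: float = 0.33
    fdr_report: float = 0.20
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise PipelineError(
                f"config schema_version {self.schema_version} != {SCHEMA_VERSION}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunManifest:
    """Counts, timings, and seed derivations for one pipeline run."""

    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    stage_seeds: dict[str, int] = field(default_factory=dict)
    counts: dict[str, object] = field(default_factory=dict)
    skipped_stages: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _matrix_name(m: ChromatogramMatrix) -> str:
    return f"rep{m.replicate}_{m.channel}"


def _load_matrices(directory: Path, n_replicates: int) -> list[ChromatogramMatrix]:
    out = []
    for rep in range(1, n_replicates + 1):
        for channel in CHANNELS:
            path = directory / f"rep{rep}_{channel}.tsv"
            if not path.exists():
                raise PipelineError(f"stage simulate: missing input matrix {path}")
            out.append(read_chromatogram_matrix(path, replicate=rep, channel=channel))
    return out


def run_pipeline(
    config: PipelineConfig, out_dir, force: bool = False
) -> RunManifest:
    """Execute every stage in order, writing all intermediate artifacts.

    Reruns with the same config and seed reproduce integer outputs
    bit-identically.  A stage whose outputs already exist is skipped
    (and reloaded) unless ``force``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))

    def timed(stage):
        manifest.stage_seeds[stage] = stage_seed(config.seed, stage)
        return time.perf_counter()

    def done(stage, t0):
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %-12s %.2fs  %s", stage, manifest.stage_seconds[stage],
                 {k: v for k, v in manifest.counts.items() if k.startswith(stage)})

    # -- stage: simulate (or ingest) ------------------------------------
    t0 = timed("simulate")
    chrom_dir = out / "chromatograms"
    chrom_dir.mkdir(exist_ok=True)
    truth_path = out / "truth.tsv"
    if config.input_dir is not None:
        matrices = _load_matrices(Path(config.input_dir), config.n_replicates)
        complexes = inference.read_complexes_tsv(Path(config.input_dir) / "complexes.tsv")
        truth = None
        spikes = None
    else:
        expected = [chrom_dir / f"rep{r}_{c}.tsv"
                    for r in range(1, config.n_replicates + 1) for c in CHANNELS]
        if not force and truth_path.exists() and all(p.exists() for p in expected):
            manifest.skipped_stages.append("simulate")
            log.info("stage simulate: outputs exist, skipping")
            truth = simulate.read_truth_tsv(truth_path)
            # rebuild the full protein universe from any matrix
            matrices = _load_matrices(chrom_dir, config.n_replicates)
            truth = simulate.ComplexTruth(
                truth.complexes, truth.condition_membership,
                truth.rewired_fraction, tuple(matrices[0].proteins),
            )
            spikes = simulate.read_spikes_tsv(out / "spikes.tsv")
        else:
            truth = simulate.generate_complex_truth(
                config.n_proteins, config.n_complexes,
                (config.complex_size_min, config.complex_size_max),
                config.rewired_fraction, seed=stage_seed(config.seed, "truth"),
            )
            sim_config = simulate.SimulationConfig(
                n_proteins=config.n_proteins, n_fractions=config.n_fractions,
                n_replicates=config.n_replicates, noise_sd=config.noise_sd,
                missing_rate=config.missing_rate, spike_rate=config.spike_rate,
                spike_magnitude=config.spike_magnitude,
                seed=stage_seed(config.seed, "simulate"),
            )
            matrices, spikes = simulate.simulate_chromatograms(truth, sim_config)
            simulate.write_truth_tsv(truth, truth_path)
            simulate.write_spikes_tsv(spikes, out / "spikes.tsv")
            for m in matrices:
                m.to_tsv(chrom_dir / f"{_matrix_name(m)}.tsv")
        complexes = {cid: list(m) for cid, m in truth.complexes.items()}
    manifest.counts["simulate.proteins"] = len(matrices[0].proteins)
    manifest.counts["simulate.matrices"] = len(matrices)
    if spikes is not None:
        manifest.counts["simulate.spikes"] = len(spikes)
    done("simulate", t0)

    # -- stage: preprocess (impute + min-observation filter) -------------
    t0 = timed("preprocess")
    cleaned = []
    for m in matrices:
        try:
            cleaned.append(preprocess.clean_matrix(m, min_obs=config.min_obs))
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"stage preprocess: {_matrix_name(m)}: {exc}") from exc
    manifest.counts["preprocess.passing_qc"] = {
        _matrix_name(m): len(m.proteins) for m in cleaned
    }
    done("preprocess", t0)

    # -- stage: MODERN outlier removal -----------------------------------
    t0 = timed("modern")
    modern_dir = out / "modern"
    modern_dir.mkdir(exist_ok=True)
    removed_total = 0
    after_modern = []
    with open(modern_dir / "flags.tsv", "w") as fh:
        fh.write("matrix\tprotein\tfraction\tz\n")
        for m in cleaned:
            report = modern.detect_outliers(m, fwer=config.fwer)
            for protein, fraction in sorted(report.flagged):
                z = report.z_scores.loc[protein].iloc[fraction - 1]
                fh.write(f"{_matrix_name(m)}\t{protein}\t{fraction}\t{z:.4f}\n")
            removed_total += len(report.flagged)
            cleaned_m = modern.remove_outliers(m, report)
            cleaned_m.to_tsv(modern_dir / f"{_matrix_name(m)}.tsv")
            after_modern.append(cleaned_m)
    manifest.counts["modern.points_removed"] = removed_total
    manifest.counts["modern.points_observed"] = sum(m.n_observed for m in cleaned)
    done("modern", t0)

    # -- stage: smoothing and Gaussian mixture fitting --------------------
    t0 = timed("fit")
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    smoothed = []
    fits_by_matrix = {}
    for m in after_modern:
        sm = preprocess.smooth_matrix(m, width=config.smooth_width)
        smoothed.append(sm)
        fits, discarded = preprocess.fit_matrix(sm, max_components=config.max_components)
        fits_by_matrix[_matrix_name(m)] = fits
        preprocess.write_fits_tsv(fits, fits_dir / f"{_matrix_name(m)}.tsv")
        manifest.counts.setdefault("fit.discarded", {})[_matrix_name(m)] = len(discarded)
    done("fit", t0)

    # -- stage: pair features per channel ---------------------------------
    t0 = timed("features")
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    channel_features = {}
    for channel in CHANNELS:
        per_rep = {}
        for raw_m, sm in zip(after_modern, smoothed):
            if raw_m.channel != channel:
                continue
            frame = features.compute_pair_features(
                raw_m, sm, fits_by_matrix[_matrix_name(raw_m)]
            )
            per_rep[raw_m.replicate] = frame
        table = features.assemble_feature_table(per_rep)
        channel_features[channel] = table
        features.write_feature_table(table, feat_dir / f"{channel}.tsv")
        manifest.counts.setdefault("features.pairs", {})[channel] = len(table)
    done("features", t0)

    # -- stage: scoring and precision thresholding ------------------------
    t0 = timed("score")
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    gold_universe = set().union(*(set(t.index.get_level_values(0)) |
                                  set(t.index.get_level_values(1))
                                  for t in channel_features.values()))
    gold = inference.build_gold_standard(complexes, gold_universe)
    networks = {}
    for channel, table in channel_features.items():
        model = inference.CoComplexModel(table, gold)
        try:
            results = model.fit(
                n_folds=config.n_folds, seed=stage_seed(config.seed, f"score_{channel}")
            )
        except ValueError as exc:
            raise PipelineError(f"stage score: channel {channel}: {exc}") from exc
        condition = CHANNEL_CONDITION[channel]
        net = results.network(config.target_precision, condition=condition)
        networks[condition] = net
        net.to_tsv(net_dir / f"{condition}.tsv")
        net.to_graphml(net_dir / f"{condition}.graphml")
        results.table.reset_index().to_csv(
            net_dir / f"scored_{channel}.tsv", sep="\t", index=False
        )
        manifest.counts.setdefault("score.pairs_scored", {})[channel] = len(results.table)
        manifest.counts.setdefault("score.edges", {})[condition] = net.n_edges
    done("score", t0)

    # -- stage: network comparison ----------------------------------------
    t0 = timed("compare")
    comparison = inference.compare_networks(
        networks["stimulated"], networks["unstimulated"]
    )
    manifest.counts["compare.shared_edges"] = len(comparison.shared_edges)
    manifest.counts["compare.stimulated_only"] = len(comparison.a_only_edges)
    manifest.counts["compare.unstimulated_only"] = len(comparison.b_only_edges)
    manifest.counts["compare.shared_nodes"] = len(comparison.shared_nodes)
    manifest.counts["compare.condition_specific_nodes"] = len(
        comparison.a_only_nodes
    ) + len(comparison.b_only_nodes)
    done("compare", t0)

    # -- stage: differential network statistics ---------------------------
    t0 = timed("diffnet")
    diff_dir = out / "diffnet"
    diff_dir.mkdir(exist_ok=True)
    if config.gene_sets_gmt is not None:
        sets = diffnet.read_gmt(config.gene_sets_gmt).filter_sizes(max_size=100)
    else:
        # default for simulation-driven runs: each planted complex is a term
        sets = diffnet.GeneSetCollection(
            {cid: frozenset(m) for cid, m in complexes.items()}
        ).filter_sizes(max_size=100)
    nppi = diffnet.delta_nppi_test(
        networks["stimulated"], networks["unstimulated"], sets,
        n_perm=config.n_perm, seed=stage_seed(config.seed, "diffnet"),
    )
    nppi.to_frame().to_csv(diff_dir / "rewiring.tsv", sep="\t", index=False)
    sharing = diffnet.pair_annotation_sharing_enrichment(
        networks["stimulated"], sets, n_perm=min(config.n_perm, 200),
        seed=stage_seed(config.seed, "sharing"),
    )
    with open(diff_dir / "sharing.tsv", "w") as fh:
        fh.write("observed\tnull_mean\tp\tn_perm\n")
        fh.write(
            f"{sharing.observed:.4f}\t{sharing.null.mean():.4f}\t"
            f"{sharing.p:.4g}\t{sharing.n_perm}\n"
        )
    stim_mats = [m for m in after_modern if m.condition == "stimulated"]
    unstim_mats = [m for m in after_modern if m.condition == "unstimulated"]
    scores = diffnet.protein_autocorrelation(stim_mats, unstim_mats)
    diffnet.autocorrelation_frame(scores).to_csv(
        diff_dir / "autocorrelation.tsv", sep="\t"
    )
    with open(diff_dir / "enrichment_map.json", "w") as fh:
        json.dump(
            diffnet.enrichment_map_json(nppi, sets, config.jaccard_min), fh, indent=2
        )
    manifest.counts["diffnet.terms_tested"] = len(nppi.results)
    manifest.counts["diffnet.terms_skipped"] = len(nppi.skipped)
    manifest.counts["diffnet.significant_terms"] = len(
        nppi.significant(config.fdr_report)
    )
    done("diffnet", t0)

    # -- stage: report ------------------------------------------------------
    t0 = timed("report")
    generate_report(manifest, nppi, comparison, out / "report",
                    fdr=config.fdr_report,
                    fold_changes_tsv=config.fold_changes_tsv,
                    networks=networks)
    done("report", t0)

    manifest.to_json(out / "manifest.json")
    return manifest


def generate_report(
    manifest: RunManifest,
    nppi: diffnet.DeltaNPPITest,
    comparison,
    report_dir,
    fdr: float = 0.20,
    fold_changes_tsv: str | None = None,
    networks: dict | None = None,
) -> None:
    """Emit tabular summaries: network overlap, significant terms, abundance."""
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    props = comparison.edge_proportions
    with open(report_dir / "network_overlap.tsv", "w") as fh:
        fh.write("class\tn_edges\tproportion\n")
        for cls, edges in (
            ("shared", comparison.shared_edges),
            ("stimulated_only", comparison.a_only_edges),
            ("unstimulated_only", comparison.b_only_edges),
        ):
            key = {"shared": "shared", "stimulated_only": "a_only",
                   "unstimulated_only": "b_only"}[cls]
            fh.write(f"{cls}\t{len(edges)}\t{props[key]:.4f}\n")
    sig = nppi.significant(fdr)
    frame = nppi.to_frame()
    sig_frame = frame[frame["q"] <= fdr] if len(frame) else frame
    sig_frame.to_csv(report_dir / "significant_terms.tsv", sep="\t", index=False)
    if fold_changes_tsv is not None and networks:
        import pandas as pd

        fc = pd.read_csv(fold_changes_tsv, sep="\t", index_col=0).iloc[:, 0]
        ann = {
            cond: diffnet.annotate_edges_with_abundance(net, fc)
            for cond, net in networks.items()
        }
        summary = diffnet.abundance_by_overlap_class(
            comparison, ann["stimulated"], ann["unstimulated"]
        )
        summary.to_csv(report_dir / "abundance_by_class.tsv", sep="\t", index=False)
    manifest.counts["report.significant_terms"] = len(sig)
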