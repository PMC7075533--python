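"""End-to-end benchmark orchestration.

A JSON configuration names the compared tools — each either a real
annotation output already converted to AIRR Rearrangement TSV, or a
synthetic annotator profile emulated from simulated ground truth — plus a
germline reference (file or generated).  Stages run in dependency order:
harmonize -> preprocess -> accuracy metrics -> CDR3 overlap / Top-N ->
similarity networks and sub-network degree comparison.  Synthetic-profile
tools are materialized to AIRR TSV first, so real and emulated outputs
flow through identical code paths.  Every stage logs its input/output
record counts, and the whole run is a pure function of the configuration,
including its seeds.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
import pandas as pd

from . import airr_io, germline, metrics, network, preprocess, synthetic_data
from .models import (
    AnnotatorProfile,
    GroundTruthRearrangement,
    ReferenceSet,
    SimulationConfig,
)

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark", "write_report"]

ALL_STAGES = ("preprocess", "mishits", "overlap", "topn", "network", "speed")


class ConfigurationError(ValueError):
    """An invalid or internally inconsistent benchmark configuration."""


@dataclass
class ToolSpec:
    label: str
    path: str | None = None
    profile: dict | None = None
    cdr3_convention: str = "core"
    granularity: str = "allele"

    def __post_init__(self) -> None:
        if (self.path is None) == (self.profile is None):
            raise ConfigurationError(
                f"tool {self.label!r}: exactly one of 'path' or 'profile' required"
            )


@dataclass
class BenchmarkConfig:
    """Validated benchmark run configuration."""

    tools: list[ToolSpec]
    reference: dict
    truth: dict | None = None
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str | None = None
    top_n: int = 100
    seed: int = 0
    speed_inputs: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        labels = [t.label for t in self.tools]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"tool labels must be distinct: {labels}")
        if ("overlap" in self.stages or "network" in self.stages) and len(self.tools) < 2:
            raise ConfigurationError("overlap/network stages need at least 2 tools")
        if "mishits" in self.stages and self.truth is None:
            raise ConfigurationError("mishits stage requires ground truth")
        needs_truth = any(t.profile is not None for t in self.tools)
        if needs_truth and self.truth is None:
            raise ConfigurationError("synthetic annotator profiles require ground truth")

    @classmethod
    def from_dict(cls, raw: dict) -> "BenchmarkConfig":
        tools = [ToolSpec(**t) for t in raw.get("tools", [])]
        return cls(
            tools=tools,
            reference=raw.get("reference", {}),
            truth=raw.get("truth"),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            out_dir=raw.get("out_dir"),
            top_n=int(raw.get("top_n", 100)),
            seed=int(raw.get("seed", 0)),
            speed_inputs=raw.get("speed", []),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        blob = json.dumps(
            {
                "tools": [vars(t) for t in self.tools],
                "reference": self.reference,
                "truth": self.truth,
                "stages": list(self.stages),
                "top_n": self.top_n,
                "seed": self.seed,
                "speed": self.speed_inputs,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class BenchmarkReport:
    """Structured per-stage results of one benchmark run."""

    config_digest: str
    seed: int
    filter_reports: dict[str, preprocess.FilterReport] = field(default_factory=dict)
    alignment_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    mishit_summaries: dict[str, dict[str, metrics.MishitSummary]] = field(default_factory=dict)
    subgroup_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    confusion_matrices: dict[str, pd.DataFrame] = field(default_factory=dict)
    overlap_partitions: dict[str, metrics.OverlapPartition] = field(default_factory=dict)
    subnetwork_degrees: pd.DataFrame | None = None
    correlations: dict[str, network.CorrelationResult] = field(default_factory=dict)
    network_stats: dict[str, dict[str, float | str]] = field(default_factory=dict)
    speed_records: dict[str, metrics.SpeedRecord] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def _load_reference(config: BenchmarkConfig) -> ReferenceSet:
    spec = config.reference
    if "path" in spec:
        return airr_io.read_reference_fasta(spec["path"])
    if "generate" in spec:
        params = dict(spec["generate"])
        params.setdefault("seed", config.seed)
        return synthetic_data.generate_reference_set(**params)
    raise ConfigurationError("reference must provide 'path' or 'generate'")


def _truth_from_table(table: pd.DataFrame) -> list[GroundTruthRearrangement]:
    out = []
    for _, row in table.iterrows():
        junction = str(row.get("junction_aa", "") or "")
        cdr3 = str(row.get("cdr3_aa", "") or "")
        if not junction:
            junction = "C" + cdr3 + "W"
        out.append(GroundTruthRearrangement(
            sequence_id=str(row["sequence_id"]),
            true_v_gene=str(row["v_call"]),
            true_d_gene=str(row["d_call"]),
            true_j_gene=str(row["j_call"]),
            nt_sequence="AAA",  # placeholder; sequence content unused downstream
            junction_aa=junction,
            cdr3_aa=junction[1:-1],
            productive=bool(row.get("productive", True)),
            lineage_id=str(row.get("lineage_id", row["sequence_id"])),
        ))
    return out


def _load_truth(
    config: BenchmarkConfig, reference: ReferenceSet
) -> list[GroundTruthRearrangement] | None:
    if config.truth is None:
        return None
    if "path" in config.truth:
        table = airr_io.read_rearrangement_tsv(config.truth["path"])
        return _truth_from_table(table)
    if "simulate" in config.truth:
        params = dict(config.truth["simulate"])
        params.setdefault("seed", config.seed)
        sim = SimulationConfig(**params)
        return synthetic_data.generate_repertoire(reference, sim)
    raise ConfigurationError("truth must provide 'path' or 'simulate'")


def _materialize_tools(
    config: BenchmarkConfig,
    reference: ReferenceSet,
    truth: list[GroundTruthRearrangement] | None,
    inputs_dir: Path | None,
) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    for i, tool in enumerate(config.tools):
        if tool.path is not None:
            table = airr_io.read_rearrangement_tsv(tool.path)
        else:
            assert truth is not None
            raw = dict(tool.profile or {})
            raw.setdefault("tool_label", tool.label)
            raw.setdefault("seed", (config.seed + 17 * (i + 1)) % 2**31)
            raw.setdefault("cdr3_convention", tool.cdr3_convention)
            raw.setdefault("granularity", tool.granularity)
            profile = AnnotatorProfile(**raw)
            tool.cdr3_convention = profile.cdr3_convention
            tool.granularity = profile.granularity
            table = synthetic_data.emulate_annotator(truth, profile, reference)
            if inputs_dir is not None:
                airr_io.write_rearrangement_tsv(table, inputs_dir / f"{tool.label}.tsv")
        logger.info("tool %s: %d annotation records", tool.label, len(table))
        tables[tool.label] = table
    return tables


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Run all requested stages and return a structured report."""
    digest = config.digest()
    inputs_dir = None
    if config.out_dir is not None:
        inputs_dir = Path(config.out_dir) / "inputs"
        inputs_dir.mkdir(parents=True, exist_ok=True)

    reference = _load_reference(config)
    truth = _load_truth(config, reference)
    if truth is not None and inputs_dir is not None:
        airr_io.write_rearrangement_tsv(airr_io.truth_to_table(truth),
                                        inputs_dir / "ground_truth.tsv")
    raw_tables = _materialize_tools(config, reference, truth, inputs_dir)

    synonyms = germline.build_synonym_map(reference, level="gene")
    orphons = {a.gene_name for a in reference.alleles if a.orphon}

    report = BenchmarkReport(config_digest=digest, seed=config.seed)

    # harmonize everything once (gene granularity: the common denominator)
    harmonized: dict[str, pd.DataFrame] = {}
    for tool in config.tools:
        res = preprocess.harmonize(
            raw_tables[tool.label],
            cdr3_convention=tool.cdr3_convention,
            synonyms=synonyms,
            granularity="gene",
        )
        if res.n_flagged:
            logger.warning("tool %s: %d records with unexpected CDR3 anchors",
                           tool.label, res.n_flagged)
        harmonized[tool.label] = res.table

    preprocessed: dict[str, pd.DataFrame] = {}
    if "preprocess" in config.stages or {"overlap", "topn", "network"} & set(config.stages):
        for label, table in harmonized.items():
            filtered, filt_report = preprocess.preprocess_filter(table, orphons)
            preprocessed[label] = filtered
            report.filter_reports[label] = filt_report
            for gt in ("V", "D", "J"):
                key = f"{label}_{gt}"
                report.alignment_tables[key] = preprocess.alignment_counts(
                    table, filtered, gt)
            logger.info("tool %s: %d -> %d records after preprocessing",
                        label, filt_report.input_count, filt_report.output_count)
    if "preprocess" not in config.stages:
        report.skipped.setdefault("preprocess", "stage not requested")

    if "mishits" in config.stages:
        assert truth is not None
        for label, table in harmonized.items():
            report.mishit_summaries[label] = {
                gt: metrics.mishit_frequency(table, truth, gt, synonyms)
                for gt in ("V", "D", "J")
            }
            report.subgroup_tables[label] = pd.DataFrame([
                {"gene_type": gt, "subgroup": row.subgroup, "W": row.W,
                 "X": row.X, "frequency": row.frequency}
                for gt in ("V", "D", "J")
                for row in metrics.subgroup_mishit_frequencies(table, truth, gt, synonyms)
            ])
            report.confusion_matrices[label] = metrics.confusion_matrix(
                table, truth, "V", synonyms)
    else:
        report.skipped["mishits"] = ("stage not requested" if config.truth is None
                                     else "stage not requested")

    cdr3_sets = {label: set(t["cdr3_aa"]) for label, t in preprocessed.items()}

    if "overlap" in config.stages:
        annotated_sets = {
            label: {c for c in t["cdr3_aa"].fillna("").astype(str) if c}
            for label, t in harmonized.items()
        }
        report.overlap_partitions["annotated"] = metrics.cdr3_overlap(
            annotated_sets, stage="annotated")
        report.overlap_partitions["preprocessed"] = metrics.cdr3_overlap(
            cdr3_sets, stage="preprocessed")
    else:
        report.skipped["overlap"] = "stage not requested"

    if "topn" in config.stages:
        # the deduplicated tables carry aggregated duplicate_count, so
        # Top-N frequency ranking is preserved after deduplication
        top_sets = {
            label: metrics.top_n_cdr3(table, config.top_n)
            for label, table in preprocessed.items()
        }
        if len(top_sets) >= 2:
            report.overlap_partitions["topN"] = metrics.cdr3_overlap(
                top_sets, stage="topN")
    else:
        report.skipped["topn"] = "stage not requested"

    if "network" in config.stages:
        networks = {label: network.build_network(s) for label, s in cdr3_sets.items()}
        for label, net in networks.items():
            report.network_stats[label] = {
                "n_nodes": net.n_nodes,
                "n_links": net.n_links,
                "average_degree": net.average_degree,
                "classification": (network.classify_diversity(net)
                                   if net.n_nodes else "empty"),
            }
        labels = list(networks)
        subset_defs: dict[str, tuple[list[str], set[str]]] = {}
        for r in range(2, len(labels) + 1):
            for group in combinations(labels, r):
                shared = set.intersection(*(cdr3_sets[l] for l in group))
                subset_defs["+".join(group)] = (list(group), shared)
        matrix = pd.DataFrame(index=labels, columns=list(subset_defs), dtype=float)
        for subset_label, (group, shared) in subset_defs.items():
            if not shared:
                continue
            cells = network.shared_subnetwork_degrees(
                {l: networks[l] for l in group}, {subset_label: shared})
            for l in group:
                matrix.loc[l, subset_label] = cells.loc[l, subset_label]
        report.subnetwork_degrees = matrix
        for a, b in combinations(labels, 2):
            shared = sorted(cdr3_sets[a] & cdr3_sets[b])
            if len(shared) < 3:
                report.correlations[f"{a}+{b}"] = network.CorrelationResult(
                    r=None, tau=None, n=len(shared), reason="fewer than 3 shared CDR3s")
                continue
            deg_a = networks[a].degree
            deg_b = networks[b].degree
            va = [deg_a[c] for c in shared]
            vb = [deg_b[c] for c in shared]
            if len(set(va)) == 1 or len(set(vb)) == 1:
                report.correlations[f"{a}+{b}"] = network.CorrelationResult(
                    r=None, tau=None, n=len(shared), reason="constant degree vector")
            else:
                report.correlations[f"{a}+{b}"] = network.degree_correlations(va, vb)
    else:
        report.skipped["network"] = "stage not requested"

    if "speed" in config.stages:
        if config.speed_inputs:
            for entry in config.speed_inputs:
                report.speed_records[entry["label"]] = metrics.processing_speed(
                    int(entry["n_sequences"]), float(entry["minutes"]),
                    int(entry["jobs"]))
        else:
            report.skipped["speed"] = "no timing inputs provided"
    else:
        report.skipped["speed"] = "stage not requested"

    return report


def write_report(report: BenchmarkReport, directory: str | Path) -> list[str]:
    """Write report tables as TSV plus a JSON summary; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _write(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = directory / name
        frame.to_csv(path, sep="\t", index=index)
        manifest.append(name)

    if report.filter_reports:
        rows = [
            {"tool": label, "input_count": fr.input_count,
             **{f"removed_{rule}": n for rule, n in fr.removed_per_rule.items()},
             "output_count": fr.output_count,
             "unique_cdr3_count": fr.unique_cdr3_count}
            for label, fr in report.filter_reports.items()
        ]
        _write(pd.DataFrame(rows), "filter_reports.tsv")
    if report.mishit_summaries:
        rows = [
            {"tool": label, "gene_type": gt, "K": s.K, "N": s.N,
             "frequency": s.frequency}
            for label, per_type in report.mishit_summaries.items()
            for gt, s in per_type.items()
        ]
        _write(pd.DataFrame(rows), "mishit_summaries.tsv")
    for label, table in report.subgroup_tables.items():
        _write(table, f"subgroup_mishits_{label}.tsv")
    for label, matrix in report.confusion_matrices.items():
        _write(matrix, f"confusion_{label}.tsv", index=True)
    for stage, part in report.overlap_partitions.items():
        _write(part.to_frame(), f"overlap_{stage}.tsv")
    if report.subnetwork_degrees is not None:
        _write(report.subnetwork_degrees, "subnetwork_degrees.tsv", index=True)
    if report.network_stats:
        rows = [{"tool": label, **stats_}
                for label, stats_ in report.network_stats.items()]
        _write(pd.DataFrame(rows), "network_stats.tsv")
    if report.correlations:
        rows = [
            {"pair": pair, "r": c.r, "tau": c.tau, "n": c.n, "reason": c.reason}
            for pair, c in report.correlations.items()
        ]
        _write(pd.DataFrame(rows), "degree_correlations.tsv")
    if report.speed_records:
        rows = [
            {"tool": label, "n_sequences": s.n_sequences, "minutes": s.minutes,
             "jobs": s.jobs, "speed": s.speed}
            for label, s in report.speed_records.items()
        ]
        _write(pd.DataFrame(rows), "speed.tsv")

    summary = {
        "config_digest": report.config_digest,
        "seed": report.seed,
        "written_at": _dt.datetime.now().isoformat(timespec="seconds"),
        "tables": sorted(manifest),
        "skipped": report.skipped,
        "network_stats": report.network_stats,
    }
    with open(directory / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    manifest.append("summary.json")
    manifest_path = directory / "manifest.txt"
    manifest_path.write_text("\n".join(sorted(manifest)) + "\n")
    manifest.append("manifest.txt")
    return sorted(manifest)
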