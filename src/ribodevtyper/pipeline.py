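"""End-to-end orchestration: config validation, staged run, run report.

A run is driven by a single YAML/JSON config (seed, input paths, thresholds
and mode flags). When the config carries a ``simulate`` block the inputs
are generated first with the synthetic module, so a fully self-contained
demo run needs nothing but a seed. Every stage logs a line, contributes a
block to the machine-readable run report, and any failure aborts the run
with a partial report naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from . import read_typing, sticky, synthetic, synthetic_refs, units, variants

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "k": 26,
    "min_read_length": {"5.8S": 100, "18S": 25, "28S": 25},
    "min_match": 5,
    "completeness_minima": dict(synthetic.COMPLETENESS_MINIMA),
    "identity_threshold": 97.0,
    "min_identity": 80.0,
    "min_hit_length": 100,
    "max_unit_span": 20000,
}
DEFAULT_MODES = {
    "sticky_mode": "complement",
    "allow_wobble": False,
    "fisher_alternative": "two-sided",
}
PATH_KEYS = ("genome", "refs", "annotations", "utrs", "tx2gene", "labels")


@dataclass
class RunConfig:
    seed: int = 0
    simulate: dict | None = None
    paths: dict = field(default_factory=dict)
    # fastq entries: {sample_id, stage_label, element, path}
    fastq: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    modes: dict = field(default_factory=lambda: dict(DEFAULT_MODES))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        config = cls(
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            paths=dict(raw.get("paths", {})),
            fastq=list(raw.get("fastq", [])),
        )
        config.thresholds.update(raw.get("thresholds", {}))
        config.modes.update(raw.get("modes", {}))
        return config

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": self.simulate,
            "paths": {k: str(v) for k, v in self.paths.items()},
            "fastq": self.fastq,
            "thresholds": self.thresholds,
            "modes": self.modes,
        }

    def digest(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return every problem found (empty list means the run may start)."""
    problems: list[str] = []
    thresholds = config.thresholds
    if thresholds.get("k", 0) < 1:
        problems.append(f"thresholds.k must be positive, got {thresholds.get('k')}")
    if thresholds.get("min_match", 0) < 1:
        problems.append(
            f"thresholds.min_match must be positive, got {thresholds.get('min_match')}"
        )
    for key in ("min_hit_length", "max_unit_span"):
        if thresholds.get(key, 0) <= 0:
            problems.append(f"thresholds.{key} must be positive")
    for element, value in thresholds.get("min_read_length", {}).items():
        if value < 0:
            problems.append(f"thresholds.min_read_length[{element}] negative")
    if config.simulate is None:
        for key in PATH_KEYS:
            path = config.paths.get(key)
            if not path:
                problems.append(f"paths.{key} missing")
            elif not Path(path).exists():
                problems.append(f"paths.{key} does not exist: {path}")
        for entry in config.fastq:
            path = entry.get("path")
            if not path or not Path(path).exists():
                problems.append(f"fastq path missing or absent: {entry}")
    return problems


def _write_tsv(frame: pd.DataFrame, path: Path, digest: str) -> None:
    with open(path, "w") as handle:
        handle.write(f"# config_digest={digest}\n")
        frame.to_csv(handle, sep="\t", index=False)


def _write_json(payload: dict, path: Path, digest: str) -> None:
    payload = {"_config_digest": digest, **payload}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def simulate_inputs(config: RunConfig, out_dir: Path) -> dict:
    """Generate the full synthetic input set declared by the simulate block."""
    block = config.simulate or {}
    seed = config.seed
    inputs = out_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    pairs = synthetic_refs.build_reference_pairs()

    genome_truth = synthetic.make_genome(
        pairs,
        units_per_type=block.get("units_per_type", {"maternal": 1, "somatic": 2}),
        spacer_length=block.get("spacer_length", 800),
        partial_spec=[tuple(p) for p in block.get("partial_spec", [])] or None,
        seed=seed,
    )
    _io.write_fasta(genome_truth.genome, inputs / "genome.fasta")

    refs = {
        f"{element}_{label}": pair.seq_of(label)
        for element, pair in pairs.items()
        for label in ("maternal", "somatic")
    }
    _io.write_fasta(refs, inputs / "refs.fasta")

    from .annotations import write_annotations

    ref_objects = [pair.somatic_ref() for pair in pairs.values()]
    for element, pair in pairs.items():
        maternal = pair.maternal_ref()
        for name, coords in synthetic_refs.STICKY_RANGES.get(element, {}).items():
            maternal.sticky_ranges.append((name, *coords["maternal"]))
        ref_objects.append(maternal)
    write_annotations(ref_objects, inputs / "annotations.tsv")

    stages = block.get(
        "stages",
        [
            ("egg", 1.0),
            ("64_cells", 0.95),
            ("epiboly", 0.7),
            ("prim-5", 0.4),
            ("protruding_mouth", 0.1),
            ("adult", 0.0),
        ],
    )
    n_reads = block.get("n_reads", 400)
    fastq_entries: list[dict] = []
    for element in ("5.8S", "18S", "28S"):
        length_range = (110, 155) if element == "5.8S" else (30, 150)
        for index, (stage, fraction) in enumerate(stages):
            reads, _ = synthetic.simulate_reads(
                pairs[element],
                maternal_fraction=float(fraction),
                n_reads=n_reads,
                read_length_range=length_range,
                error_rate=block.get("error_rate", 0.002),
                seed=seed + 101 * index + {"5.8S": 1, "18S": 2, "28S": 3}[element],
            )
            path = inputs / f"reads_{element.replace('.', '')}_{stage}.fastq"
            _io.write_fastq(reads, path)
            fastq_entries.append(
                {
                    "sample_id": f"{element}:{stage}",
                    "stage_label": stage,
                    "element": element,
                    "path": str(path),
                }
            )

    stretches = synthetic_refs.sticky_stretches(pairs)["range 6-I"]
    utrs, tx2gene, labels, _ = synthetic.make_utr_set(
        n_genes=block.get("n_genes", 120),
        maternal_gene_fraction=block.get("maternal_gene_fraction", 0.5),
        es_stretch_maternal=stretches["maternal"],
        es_stretch_somatic=stretches["somatic"],
        planted_length_range=tuple(block.get("planted_length_range", (10, 14))),
        seed=seed + 7,
    )
    _io.write_fasta(utrs, inputs / "utrs.fasta")
    pd.DataFrame(
        sorted(tx2gene.items()), columns=["transcript_id", "gene_id"]
    ).to_csv(inputs / "tx2gene.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(labels.items()), columns=["gene_id", "maternal"]
    ).to_csv(inputs / "labels.tsv", sep="\t", index=False)

    config.paths.update(
        genome=str(inputs / "genome.fasta"),
        refs=str(inputs / "refs.fasta"),
        annotations=str(inputs / "annotations.tsv"),
        utrs=str(inputs / "utrs.fasta"),
        tx2gene=str(inputs / "tx2gene.tsv"),
        labels=str(inputs / "labels.tsv"),
    )
    config.fastq = fastq_entries
    return {
        "n_units_planted": len(genome_truth.units),
        "n_fastq": len(fastq_entries),
        "n_genes": len(labels),
    }


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the whole pipeline; returns the run report (also written)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    report: dict = {"config_digest": digest, "seed": config.seed, "stages": {}}
    report_path = out_dir / "run_report.json"

    problems = validate_config(config)
    if problems:
        report["stages"]["validate"] = {"status": "failed", "problems": problems}
        _write_json(report, report_path, digest)
        raise ValueError("config validation failed: " + "; ".join(problems))
    report["stages"]["validate"] = {"status": "ok"}

    stage = "simulate"
    try:
        if config.simulate is not None:
            report["stages"][stage] = {
                "status": "ok",
                **simulate_inputs(config, out_dir),
            }
            logger.info("simulate: inputs generated under %s", out_dir / "inputs")
        else:
            report["stages"][stage] = {"status": "skipped"}

        stage = "find_units"
        genome = _io.read_fasta(config.paths["genome"])
        refs = _io.read_fasta(config.paths["refs"])
        element_refs = {
            name.rsplit("_", 1)[0]: seq
            for name, seq in refs.items()
            if name.endswith("_somatic")
        }
        thresholds = config.thresholds
        hits = units.find_element_hits(
            genome,
            element_refs,
            min_identity=thresholds["min_identity"],
            min_hit_length=thresholds["min_hit_length"],
        )
        unit_list = units.assemble_units(
            hits,
            max_unit_span=thresholds["max_unit_span"],
            minima=thresholds["completeness_minima"],
        )
        for unit in unit_list:
            units.extract_ets(unit, genome)
        unit_rows = [
            {
                "contig": u.contig_id,
                "start": min(s for s, _ in u.element_intervals.values()) - 1,
                "end": max(e for _, e in u.element_intervals.values()),
                "element": el,
                "unit_id": u.unit_id,
                "strand": u.strand,
                "el_start": u.element_intervals[el][0] - 1,
                "el_end": u.element_intervals[el][1],
                "completeness": u.completeness,
            }
            for u in unit_list
            for el in u.element_intervals
        ]
        _write_tsv(pd.DataFrame(unit_rows), out_dir / "units.tsv", digest)
        completeness = {
            c: sum(1 for u in unit_list if u.completeness == c)
            for c in ("Complete", "Partial")
        }
        cluster_info = {}
        if unit_list:
            clusters, _, min_identity = units.cluster_unit_types(
                unit_list, thresholds["identity_threshold"]
            )
            cluster_info = {
                "n_clusters": len(clusters),
                "min_pairwise_identity": round(min_identity, 2),
            }
        report["stages"][stage] = {
            "status": "ok",
            "units_by_completeness": completeness,
            **cluster_info,
        }
        logger.info("find_units: %s", completeness)

        stage = "markers"
        marker_sets: dict[str, list[read_typing.Marker]] = {}
        marker_rows = []
        for element in ("5.8S", "18S", "28S"):
            type_refs = {
                name.rsplit("_", 1)[1]: seq
                for name, seq in refs.items()
                if name.rsplit("_", 1)[0] == element
            }
            if len(type_refs) < 2:
                continue
            marker_sets[element] = read_typing.select_markers(
                type_refs, k=thresholds["k"], element=element
            )
            marker_rows += [
                {
                    "element": m.element,
                    "type_label": m.type_label,
                    "position": m.position,
                    "sequence": m.sequence,
                }
                for m in marker_sets[element]
            ]
        _write_tsv(pd.DataFrame(marker_rows), out_dir / "markers.tsv", digest)
        report["stages"][stage] = {
            "status": "ok",
            "n_markers": {el: len(ms) for el, ms in marker_sets.items()},
        }

        stage = "type_profile"
        profile_rows = []
        for entry in config.fastq:
            element = entry["element"]
            profile = read_typing.scan_reads(
                entry["path"],
                marker_sets[element],
                min_read_length=thresholds["min_read_length"][element],
                k=thresholds["k"],
                sample_id=entry["sample_id"],
                stage_label=entry.get("stage_label", ""),
            )
            row = {
                "sample_id": profile.sample_id,
                "stage_label": profile.stage_label,
                "element": element,
                **profile.counts,
                "percent_maternal": profile.percent_maternal,
                "percent_somatic": profile.percent_somatic,
            }
            if element == "5.8S":
                aln_profile = read_typing.type_profile(
                    entry["path"],
                    refs[f"{element}_maternal"],
                    refs[f"{element}_somatic"],
                    min_read_length=thresholds["min_read_length"][element],
                    sample_id=entry["sample_id"],
                    stage_label=entry.get("stage_label", ""),
                )
                row["percent_maternal_aligned"] = aln_profile.percent_maternal
            profile_rows.append(row)
        _write_tsv(pd.DataFrame(profile_rows), out_dir / "type_profiles.tsv", digest)
        report["stages"][stage] = {
            "status": "ok",
            "percent_maternal_by_sample": {
                r["sample_id"]: (
                    None
                    if r["percent_maternal"] is None
                    else round(r["percent_maternal"], 2)
                )
                for r in profile_rows
            },
        }

        stage = "variants"
        from .annotations import load_annotations

        sequences = {
            (name.rsplit("_", 1)[0], name.rsplit("_", 1)[1]): seq
            for name, seq in refs.items()
        }
        annotated = {
            (ref.element, ref.type_label): ref
            for ref in load_annotations(config.paths["annotations"], sequences)
        }
        variant_rows, stat_rows = [], []
        for element in ("5.8S", "18S", "28S"):
            somatic_ref = annotated.get((element, "somatic"))
            maternal_ref = annotated.get((element, "maternal"))
            if somatic_ref is None or maternal_ref is None:
                continue
            records, stats = variants.compare_refs(
                maternal_ref, somatic_ref, allow_wobble=config.modes["allow_wobble"]
            )
            variant_rows += [
                {
                    "element": element,
                    "name": r.name,
                    "kind": r.kind,
                    "somatic_pos": r.somatic_pos,
                    "maternal_pos": r.maternal_pos,
                    "domain": r.domain_name,
                    "es": r.es_name or "",
                    "sticky": r.sticky_name or "",
                    "region": r.region_name or "",
                    "covariation": r.is_covariation,
                }
                for r in records
            ]
            stat_rows += [
                {
                    "element": element,
                    "domain": s.domain_name,
                    "n_substitutions": s.n_substitutions,
                    "n_indel_events": s.n_indel_events,
                    "domain_length": s.domain_length,
                    "percent_variant": round(s.percent_variant, 2),
                }
                for s in stats
            ]
        _write_tsv(pd.DataFrame(variant_rows), out_dir / "variants.tsv", digest)
        _write_tsv(pd.DataFrame(stat_rows), out_dir / "domain_stats.tsv", digest)
        report["stages"][stage] = {
            "status": "ok",
            "n_variants": {
                el: sum(1 for r in variant_rows if r["element"] == el)
                for el in ("5.8S", "18S", "28S")
            },
        }

        stage = "sticky"
        utrs = _io.read_fasta(config.paths["utrs"])
        tx2gene = dict(
            pd.read_csv(config.paths["tx2gene"], sep="\t", comment="#").values
        )
        labels_frame = pd.read_csv(config.paths["labels"], sep="\t", comment="#")
        labels = dict(labels_frame.values)
        stretch_m, stretch_s = _resolve_stretches(config, annotated)
        counts = [
            sticky.stickiness(
                seq,
                stretch_m,
                stretch_s,
                min_length=thresholds["min_match"],
                mode=config.modes["sticky_mode"],
                transcript_id=tx_id,
                gene_id=tx2gene.get(tx_id, ""),
            )
            for tx_id, seq in utrs.items()
        ]
        ratios = sticky.gene_ms_ratios(counts, tx2gene)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": c.transcript_id,
                        "gene_id": c.gene_id,
                        "covered_nt_maternal": c.covered_nt_maternal,
                        "covered_nt_somatic": c.covered_nt_somatic,
                    }
                    for c in counts
                ]
            ),
            out_dir / "sticky_counts.tsv",
            digest,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "gene_id": r.gene_id,
                        "mean_maternal": r.mean_maternal,
                        "mean_somatic": r.mean_somatic,
                        "ms_ratio": r.ms_ratio,
                        "ratio_class": r.ratio_class,
                    }
                    for r in ratios
                ]
            ),
            out_dir / "gene_ms_ratios.tsv",
            digest,
        )
        report["stages"][stage] = {
            "status": "ok",
            "n_genes": len(ratios),
            "ratio_classes": {
                cls: sum(1 for r in ratios if r.ratio_class == cls)
                for cls in ("gt1", "lt1", "eq1", "undefined")
            },
        }

        stage = "enrich"
        result = sticky.enrichment_test(
            ratios, labels, alternative=config.modes["fisher_alternative"]
        )
        _write_json(
            {
                "contingency": result.contingency,
                "odds_ratio": result.odds_ratio,
                "p_value": result.p_value,
                "alternative": result.alternative,
                "n_excluded_eq1": result.n_excluded_eq1,
                "n_excluded_undefined": result.n_excluded_undefined,
            },
            out_dir / "enrichment.json",
            digest,
        )
        report["stages"][stage] = {
            "status": "ok",
            "p_value": result.p_value,
            "odds_ratio": result.odds_ratio,
        }
    except Exception as exc:
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_json(report, report_path, digest)
        raise
    _write_json(report, report_path, digest)
    return report


def _resolve_stretches(config: RunConfig, annotated: dict) -> tuple[str, str]:
    """Sticky stretch sequences: explicit in config, else from annotations."""
    modes = config.modes
    if "sticky_stretch_maternal" in modes and "sticky_stretch_somatic" in modes:
        return modes["sticky_stretch_maternal"], modes["sticky_stretch_somatic"]
    somatic_ref = annotated[("18S", "somatic")]
    if not somatic_ref.sticky_ranges:
        raise ValueError("no sticky ranges annotated on the somatic 18S reference")
    name = modes.get("sticky_range", somatic_ref.sticky_ranges[-1][0])
    lookup = {n: (s, e) for n, s, e in somatic_ref.sticky_ranges}
    start, end = lookup[name]
    stretch_s = somatic_ref.sequence[start - 1 : end]
    maternal_ref = annotated[("18S", "maternal")]
    # the maternal range may sit at shifted coordinates (indels upstream)
    maternal_lookup = {n: (s, e) for n, s, e in maternal_ref.sticky_ranges}
    ms, me = maternal_lookup.get(name, (start, end))
    stretch_m = maternal_ref.sequence[ms - 1 : me]
    return stretch_m, stretch_s


def demo_config(seed: int = 7) -> RunConfig:
    """The bundled all-synthetic demo configuration."""
    return RunConfig(
        seed=seed,
        simulate={
            "units_per_type": {"maternal": 1, "somatic": 2},
            "partial_spec": [[2, "5.8S", 100]],
            "n_reads": 300,
            "n_genes": 120,
        },
    )
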