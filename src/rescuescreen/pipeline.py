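"""End-to-end orchestration: simulate -> score -> call hits -> evaluate.

One master seed and one config drive every stage; identical config + seed
produce byte-identical output files. Every table carries a commented header
with the package version, config hash, and seed, and a manifest records the
file inventory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrich import AnalysisConfig, run_enrichment
from .hits import CLASS_ORDER, call_hits, evaluate_recovery
from .quantify import _write_table
from .simulate import SimConfig, simulate_counts, simulate_library, write_fixture

log = logging.getLogger("rescuescreen")


class ConfigError(ValueError):
    """Malformed pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "results"
    emit_fastq: bool = False
    seed: int | None = None  # overrides sim.seed when set

    def resolved_sim(self) -> SimConfig:
        return self.sim if self.seed is None else replace(self.sim, seed=self.seed)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "analysis": dataclasses.asdict(self.analysis),
            "out_dir": self.out_dir,
            "emit_fastq": self.emit_fastq,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        known = {"sim", "analysis", "out_dir", "emit_fastq", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for section, klass in (("sim", SimConfig), ("analysis", AnalysisConfig)):
            sub = raw.get(section) or {}
            fields = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - fields
            if bad:
                raise ConfigError(f"unknown {section} key(s): {sorted(bad)}")
            raw[section] = klass(**sub)
        return cls(
            sim=raw.get("sim", SimConfig()),
            analysis=raw.get("analysis", AnalysisConfig()),
            out_dir=raw.get("out_dir", "results"),
            emit_fastq=bool(raw.get("emit_fastq", False)),
            seed=raw.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        # covers the scientific parameters only, not I/O paths, so the same
        # screen written to two directories hashes identically
        d = self.to_dict()
        blob = json.dumps(
            {"sim": dataclasses.asdict(self.resolved_sim()),
             "analysis": d["analysis"]},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole synthetic-screen pipeline; returns the manifest dict."""
    sim = config.resolved_sim()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"rescuescreen {__version__} | config_sha256={config.config_hash()} "
        f"| seed={sim.seed}"
    )

    log.info("simulate: %d genes x %d guides + %d NTCs, %d replicates",
             sim.n_genes, sim.sgrnas_per_gene, sim.n_ntc, sim.n_replicates)
    library, truth = simulate_library(sim)
    counts = simulate_counts(library, truth, sim)
    files = write_fixture(library, counts, truth, out,
                          emit_fastq=config.emit_fastq, header=header)

    log.info("enrich: scoring %d guides x %d samples",
             len(library), counts.counts.shape[1])
    ratio_table = run_enrichment(counts, library, config.analysis)
    results = ratio_table.to_frame()
    files["sgrna_results"] = out / "sgrna_results.tsv"
    _write_table(results, files["sgrna_results"], header)
    n_valid = int(results["n_valid_empty"].ge(
        config.analysis.min_valid_replicates).sum())
    log.info("enrich: %d/%d guides with a valid YAP/Empty median",
             n_valid, len(results))

    hit_table = call_hits(ratio_table, library, config.analysis,
                          ntc_group_size=sim.sgrnas_per_gene,
                          ntc_partition_seed=sim.seed)
    files["gene_hits"] = out / "gene_hits.tsv"
    _write_table(hit_table, files["gene_hits"], header)
    log.info("hits: %s", hit_table["class"].value_counts().to_dict())

    report = evaluate_recovery(hit_table[~hit_table["is_ntc"]], truth)
    files["recovery"] = out / "recovery.json"
    files["recovery"].write_text(json.dumps(report.to_dict(), indent=2,
                                            sort_keys=True))

    manifest = {
        "package": "rescuescreen",
        "version": __version__,
        "seed": sim.seed,
        "config_sha256": config.config_hash(),
        "config": config.to_dict(),
        "files": {k: str(v) for k, v in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def summarize(results_dir: str | Path) -> str:
    """Human-readable markdown report over a pipeline results directory."""
    results_dir = Path(results_dir)
    hits_path = results_dir / "gene_hits.tsv"
    if not hits_path.exists():
        raise FileNotFoundError(hits_path)
    hit_table = pd.read_csv(hits_path, sep="\t", comment="#")

    lines = ["# Screen summary", ""]
    targeted = hit_table[~hit_table["is_ntc"]]
    lines.append("## Gene classes")
    for klass in CLASS_ORDER:
        lines.append(f"- {klass}: {int((targeted['class'] == klass).sum())}")
    ntc = hit_table[hit_table["is_ntc"]]
    if not ntc.empty:
        n_hit = int(ntc["class"].isin(
            ["effector", "effector_prioritized", "inhibitor"]).sum())
        lines.append("")
        lines.append(f"## Nontargeting pseudo-genes")
        lines.append(f"- classified as hits: {n_hit} of {len(ntc)}")

    sg_path = results_dir / "sgrna_results.tsv"
    if sg_path.exists():
        sg = pd.read_csv(sg_path, sep="\t", comment="#")
        top = sg.reindex(sg["zscore"].abs().sort_values(ascending=False).index)
        lines.append("")
        lines.append("## Top sgRNAs by |z| (YAP/Empty)")
        for _, row in top.head(10).iterrows():
            lines.append(
                f"- {row['sgrna_id']} ({row['gene']}): "
                f"median ratio {row['median_empty']:.3g}, z = {row['zscore']:+.2f}"
            )

    rec_path = results_dir / "recovery.json"
    if rec_path.exists():
        rec = json.loads(rec_path.read_text())
        lines.append("")
        lines.append("## Recovery vs simulation truth")
        for klass in ("effector", "inhibitor"):
            row = rec["per_class"][klass]
            fmt = lambda v: "n/a" if v is None else f"{v:.3f}"
            lines.append(
                f"- {klass}: precision {fmt(row['precision'])}, "
                f"recall {fmt(row['recall'])}, F1 {fmt(row['f1'])} "
                f"(tp={row['tp']}, fp={row['fp']}, fn={row['fn']})"
            )
    return "\n".join(lines) + "\n"
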