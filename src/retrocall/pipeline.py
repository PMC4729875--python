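"""Pipeline orchestration: validate -> simulate -> call -> filter -> annotate
-> sensitivity -> rate -> bias, with a reproducible run manifest.

Stages communicate through files under one output directory; every output
carries a provenance header (stage, configuration hash, seed) and the run
manifest records per-stage output checksums and wall-clock time, so two runs
with identical configuration and seeds produce identical checksums for the
deterministic stages.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import calling, denovo, io as rio, sensitivity as sens, simulate as sim
from .hallmarks import InsertionSequence, classify_structure
from .util import sha256_file, sha256_text

STAGES = ("simulate", "call", "denovo", "hallmarks", "sensitivity", "rate", "bias")


@dataclass
class ValidationIssue:
    path: str
    line: int | None
    message: str
    fatal: bool = False

    def __str__(self):
        where = f"{self.path}:{self.line}" if self.line else self.path
        return f"{'FATAL' if self.fatal else 'error'} {where}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def fatal(self) -> bool:
        return any(i.fatal for i in self.issues)


def _validate_fasta(path, report):
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        report.issues.append(ValidationIssue(str(path), None, str(exc), fatal=True))
        return
    name = None
    seqlen = 0
    offset = 0
    for i, line in enumerate(lines, start=1):
        if line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None and seqlen == 0:
                report.issues.append(ValidationIssue(
                    str(path), offset, f"record {name!r} truncated (no sequence)",
                    fatal=True))
            name = line[1:].strip()
            offset = i
            seqlen = 0
        else:
            if name is None and line.strip():
                report.issues.append(ValidationIssue(
                    str(path), i, "sequence before first header", fatal=True))
                return
            seqlen += len(line.strip())
    if name is not None and seqlen == 0:
        report.issues.append(ValidationIssue(
            str(path), offset, f"record {name!r} truncated (no sequence)", fatal=True))
    if name is None:
        report.issues.append(ValidationIssue(str(path), None, "no FASTA records",
                                             fatal=True))


def _validate_bed(path, report):
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        report.issues.append(ValidationIssue(str(path), None, str(exc), fatal=True))
        return
    for i, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            report.issues.append(ValidationIssue(str(path), i,
                                                 f"{len(fields)} columns, need 6"))
            continue
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            report.issues.append(ValidationIssue(str(path), i,
                                                 "non-integer coordinates"))
            continue
        if start > end or start < 0:
            report.issues.append(ValidationIssue(str(path), i,
                                                 f"start {start} > end {end}"))


_TSV_REQUIRED = {
    "reads": ["sample", "chrom", "start", "side", "family"],
    "calls": ["call_id", "sample", "chrom", "position", "family"],
    "tsv": [],
}


def _validate_tsv(path, kind, report):
    try:
        df = rio.read_tsv(path)
    except Exception as exc:
        report.issues.append(ValidationIssue(str(path), None, str(exc), fatal=True))
        return
    missing = [c for c in _TSV_REQUIRED.get(kind, []) if c not in df.columns]
    if missing:
        report.issues.append(ValidationIssue(
            str(path), 1, f"missing required columns: {', '.join(missing)}"))


def validate_inputs(paths: dict[str, str]) -> ValidationReport:
    """Structural validation of input files; ``paths`` maps path -> format
    ('fasta', 'bed', 'reads', 'calls', 'tsv')."""
    report = ValidationReport()
    for path, fmt in paths.items():
        if not Path(path).exists():
            report.issues.append(ValidationIssue(str(path), None, "unreadable file",
                                                 fatal=True))
            continue
        if fmt == "fasta":
            _validate_fasta(path, report)
        elif fmt == "bed":
            _validate_bed(path, report)
        else:
            _validate_tsv(path, fmt, report)
    return report


# ---------------------------------------------------------------------------


DEFAULT_PIPELINE_CONFIG = {
    "seed": 1,
    "outdir": "retrocall_out",
    "stages": {s: True for s in STAGES},
    "simulate": {"genome_length": 300_000, "n_chromosomes": 2, "n_genes": 30,
                 "gene_length_range": [2000, 8000], "gc_content": 0.41,
                 "depth": 30, "duplicate_rate": 0.15, "vaf": 1.0},
    "cohort": {"n_germline": 12, "n_parental_private": 4,
               "n_pluripotent_private": 3, "n_recurrent": 1},
    "call": {"window": 200, "min_unique": 2, "min_separation": 5,
             "match_window": 100},
    "sensitivity": {"grid_step": 0.05, "reps": 10},
    "rate": {"vaf_floor": 0.05},
    "bias": {"permutations": 100_000},
}


def load_pipeline_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(config.get(key), dict):
            config[key].update(val)
        else:
            config[key] = val
    return config


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p): sha256_file(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "config": self.config,
                       "stages": self.stages}, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: dict) -> RunManifest:
    """Execute the enabled stages in dependency order.

    A stage failure raises and halts its dependents; outputs of completed
    stages remain on disk.
    """
    from . import __version__

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    # hash the run parameters, not the output location
    hashed = {k: v for k, v in config.items() if k != "outdir"}
    chash = sha256_text(json.dumps(hashed, sort_keys=True))[:12]
    stages_on = config["stages"]
    manifest = RunManifest(version=__version__, config=config)

    def meta(stage):
        return dict(stage=stage, config_hash=chash, seed=seed)

    sim_cfg = sim.SimConfig(seed=seed, **{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in config["simulate"].items()})
    call_cfg = config["call"]

    cohort = None
    calls_all = None
    verdicts = None

    if stages_on.get("simulate"):
        t0 = time.perf_counter()
        rng = np.random.default_rng(seed)
        cohort = sim.simulate_cohort(sim_cfg, rng=rng, **config["cohort"])
        outputs = []
        rio.write_fasta(cohort.genome.chromosomes, outdir / "genome.fa", **meta("simulate"))
        outputs.append(outdir / "genome.fa")
        rio.write_bed6(rio.genes_to_bed(cohort.genome.genes),
                       outdir / "genes.bed", **meta("simulate"))
        outputs.append(outdir / "genes.bed")
        truth = sim.truth_table(list(cohort.truths.values()))
        truth["class"] = [cohort.truth_class[i] for i in truth["id"]]
        rio.write_tsv(truth, outdir / "truth.tsv", **meta("simulate"))
        outputs.append(outdir / "truth.tsv")
        rio.write_bed6(cohort.catalog, outdir / "catalog.bed", **meta("simulate"))
        outputs.append(outdir / "catalog.bed")
        for sample, reads in cohort.reads.items():
            p = outdir / f"reads_{sample}.tsv"
            rio.write_tsv(reads, p, **meta("simulate"))
            outputs.append(p)
        manifest.record("simulate", outputs, time.perf_counter() - t0)
    elif any(stages_on.get(s) for s in STAGES[1:]):
        raise ValueError("downstream stages require the simulate stage outputs "
                         "in this demo pipeline")

    if stages_on.get("call"):
        t0 = time.perf_counter()
        frames = []
        for sample, reads in cohort.reads.items():
            calls = calling.run_caller(
                reads, window=call_cfg["window"],
                min_unique=call_cfg["min_unique"],
                min_separation=call_cfg["min_separation"],
                catalog=cohort.catalog, match_window=call_cfg["match_window"],
                library=cohort.library)
            calls["call_id"] = sample + ":" + calls["call_id"].astype(str)
            frames.append(calls)
        calls_all = pd.concat(frames, ignore_index=True)
        rio.write_tsv(calls_all, outdir / "calls.tsv", **meta("call"))
        rio.write_bed6(rio.calls_to_bed(calls_all), outdir / "calls.bed",
                       **meta("call"))
        manifest.record("call", [outdir / "calls.tsv", outdir / "calls.bed"],
                        time.perf_counter() - t0)

    if stages_on.get("denovo"):
        t0 = time.perf_counter()
        verdicts = denovo.annotate_de_novo(calls_all, cohort.catalog,
                                           cohort.design,
                                           match_window=call_cfg["match_window"])
        rio.write_tsv(verdicts, outdir / "denovo.tsv", **meta("denovo"))
        manifest.record("denovo", [outdir / "denovo.tsv"], time.perf_counter() - t0)

    if stages_on.get("hallmarks"):
        t0 = time.perf_counter()
        rows = []
        dn = verdicts[verdicts["de_novo"]]
        seen = set()
        for _, v in dn.iterrows():
            truth = _nearest_truth(cohort, v, call_cfg["match_window"] + 100)
            if truth is None or truth.id in seen:
                continue
            seen.add(truth.id)
            left, insert, right = sim.truth_triplet(truth, cohort.genome,
                                                    cohort.library)
            rep = classify_structure(
                InsertionSequence(left, insert, right, truth.family),
                cohort.library)
            rows.append({
                "truth_id": truth.id, "family": rep.family,
                "subfamily": rep.subfamily, "orientation": rep.orientation,
                "tsd": rep.tsd, "tsd_length": rep.tsd_length,
                "en_mismatches": rep.en_mismatches,
                "en_dependent": rep.en_dependent,
                "polya_length": rep.polya_length,
                "five_prime_truncation": rep.five_prime_truncation,
                "three_prime_truncation": rep.three_prime_truncation,
                "inversion": rep.inversion is not None,
                "inverted_length": rep.inverted_length,
                "spacer_length": rep.inversion[1] if rep.inversion else 0,
                "microcomplementarity": rep.microcomplementarity,
                "untemplated_5p": rep.untemplated_5p,
                "full_length": rep.full_length,
            })
        rio.write_tsv(pd.DataFrame(rows), outdir / "hallmarks.tsv",
                      **meta("hallmarks"))
        manifest.record("hallmarks", [outdir / "hallmarks.tsv"],
                        time.perf_counter() - t0)

    fn_model = None
    if stages_on.get("sensitivity"):
        t0 = time.perf_counter()
        rng = np.random.default_rng(seed + 1)
        step = config["sensitivity"]["grid_step"]
        grid = np.round(np.arange(step, 1.0 + 1e-9, step), 6)
        germline = pd.DataFrame({"family": cohort.catalog["name"],
                                 "chrom": cohort.catalog["chrom"],
                                 "position": cohort.catalog["start"]})
        sample = cohort.design.pluripotent_samples()[0]
        curve = sens.subsample_detection(cohort.reads[sample], germline,
                                         grid=grid,
                                         reps=config["sensitivity"]["reps"],
                                         rng=rng)
        rio.write_tsv(curve.to_frame(), outdir / "detection_curve.tsv",
                      **meta("sensitivity"))
        # recompute weights and baseline detection from the simulated cohort
        weights = germline["family"].value_counts().to_dict()
        parent = cohort.design.samples[sample].parent_sample
        if parent is not None:
            early = calls_all[calls_all["sample"] == parent]
            late = calls_all[calls_all["sample"] == sample]
            baseline = sens.germline_concordance(early, late,
                                                 call_cfg["match_window"])
        else:
            baseline = {f: 1.0 for f in weights}
        baseline = {f: baseline.get(f, 1.0) for f in weights}
        fn_model = sens.FNModel(baseline_detection=baseline,
                                weights={f: float(w) for f, w in weights.items()})
        fn_model.from_curve(curve)
        with open(outdir / "fn_model.json", "w") as fh:
            fh.write(rio.provenance_line("sensitivity", chash, seed) + "\n")
            json.dump({"baseline_fn": fn_model.baseline_fn,
                       "weights": fn_model.weights,
                       "baseline_detection": fn_model.baseline_detection,
                       "vaf_grid": [float(v) for v in curve.grid],
                       "fn_curve": [float(v) for v in fn_model.fn_curve]},
                      fh, indent=2)
            fh.write("\n")
        manifest.record("sensitivity",
                        [outdir / "detection_curve.tsv", outdir / "fn_model.json"],
                        time.perf_counter() - t0)

    if stages_on.get("rate"):
        t0 = time.perf_counter()
        rng = np.random.default_rng(seed + 2)
        dn = verdicts[verdicts["de_novo"]]
        sample = cohort.design.pluripotent_samples()[0]
        own = dn[dn["sample"] == sample]
        result = {"observed": 0, "corrected_per_line": 0.0, "per_cell": 0.0}
        if len(own):
            obs = own.rename(columns={"position": "position"}).copy()
            obs["vaf"] = [
                (t.vaf if (t := _nearest_truth(cohort, row, 300)) else 1.0)
                for _, row in obs.iterrows()]
            step = config["sensitivity"]["grid_step"]
            grid = np.round(np.arange(step, 1.0 + 1e-9, step), 6)
            curves = sens.insertion_detection_curves(
                cohort.reads[sample], obs, grid,
                config["sensitivity"]["reps"], rng)
            est = sens.estimate_insertion_rate(
                obs, curves,
                baseline_fn=(fn_model.baseline_fn if fn_model else 0.0),
                vaf_floor=config["rate"]["vaf_floor"])
            result = {"observed": est.observed,
                      "corrected_per_line": est.corrected_per_line,
                      "mean_vaf": est.mean_vaf, "per_cell": est.per_cell,
                      "vaf_floor": est.vaf_floor}
        with open(outdir / "rate.json", "w") as fh:
            fh.write(rio.provenance_line("rate", chash, seed) + "\n")
            json.dump(result, fh, indent=2)
            fh.write("\n")
        manifest.record("rate", [outdir / "rate.json"], time.perf_counter() - t0)

    if stages_on.get("bias"):
        t0 = time.perf_counter()
        rng = np.random.default_rng(seed + 3)
        dn_truth = [t for i, t in cohort.truths.items()
                    if cohort.truth_class[i] == "pluripotent_private"]
        ins = pd.DataFrame({"id": [t.id for t in dn_truth],
                            "chrom": [t.chrom for t in dn_truth],
                            "position": [t.position for t in dn_truth]})
        pcts = bias_mod.intragenic_percentiles(ins, cohort.genome.genes)
        outputs = []
        rio.write_tsv(pcts, outdir / "percentiles.tsv", **meta("bias"))
        outputs.append(outdir / "percentiles.tsv")
        result = {"n_intragenic": int(len(pcts))}
        if len(pcts):
            res = bias_mod.permutation_test(ins, cohort.genome.genes,
                                            config["bias"]["permutations"], rng)
            result.update({"observed_mean": res.observed_mean,
                           "permutations": res.permutations,
                           "exceedances": res.exceedances, "p": res.pvalue})
        with open(outdir / "bias.json", "w") as fh:
            fh.write(rio.provenance_line("bias", chash, seed) + "\n")
            json.dump(result, fh, indent=2)
            fh.write("\n")
        outputs.append(outdir / "bias.json")
        manifest.record("bias", outputs, time.perf_counter() - t0)

    manifest.write(outdir / "manifest.json")
    return manifest


def _nearest_truth(cohort, row, window):
    best = None
    for t in cohort.truths.values():
        if t.chrom != row["chrom"] or t.family != row["family"]:
            continue
        d = abs(t.position - int(row["position"]))
        if d <= window and (best is None or d < best[0]):
            best = (d, t)
    return best[1] if best else None
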