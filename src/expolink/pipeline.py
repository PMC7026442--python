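"""End-to-end orchestration: normalize -> DE -> diseasome -> enrichment -> survival.

A single YAML config names the exposure study, the disease studies, the
thresholds, the GMT libraries and the survival cohorts; ``run_pipeline``
executes the stages in order, writes every artifact under the output
directory and returns a manifest with per-stage timings, warnings and a
SHA-256 checksum per produced file.  ``make_demo`` writes a complete
synthetic study set with known planted structure plus a ready-to-run config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time as _time
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import (DiseaseGeneSet, Thresholds, de_table, select_significant,
                       write_gene_set, write_gene_stats)
from .diseasome import build_diseasome, export_network
from .enrichment import fisher_enrichment, load_gmt, write_enrichment
from .studies import read_clinical, read_expression, read_labels
from .survival import SurvivalCohort, gene_survival_screen, write_km_curve, \
    write_screen_report
from .synthetic import (DEFAULT_CLINICAL_FACTORS, CohortSpec, StudySpec,
                        derive_seed, generate_linked_studies,
                        generate_survival_cohort, write_cohort_clinical,
                        write_cohort_z, write_ground_truth)
from .studies import write_expression, write_labels

DEFAULT_FACTOR_NAMES = tuple(DEFAULT_CLINICAL_FACTORS)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class StudyEntry:
    study_id: str
    expression: Path
    labels: Path
    already_log2: bool = True


@dataclass(frozen=True)
class CohortEntry:
    disease_id: str
    clinical: Path
    expression_z: Path
    factors: tuple


@dataclass(eq=False)
class RunConfig:
    """Validated run configuration (paths resolved against the config file)."""

    seed: int
    output_dir: Path
    exposure: StudyEntry
    diseases: list
    thresholds: Thresholds
    ttest_variant: str
    gmt_libraries: list
    enrichment_background: int | None
    enrichment_top_k: int | None
    survival_alpha: float
    survival_z_threshold: float
    survival_ties: str
    cohorts: list
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        base = path.parent
        problems: list[str] = []

        def _resolve(p: str) -> Path:
            rp = Path(p)
            return rp if rp.is_absolute() else base / rp

        def _study(entry: dict, what: str) -> StudyEntry | None:
            for key in ("study_id", "expression", "labels"):
                if key not in entry:
                    problems.append(f"{what}: missing key {key!r}")
                    return None
            e = StudyEntry(str(entry["study_id"]), _resolve(entry["expression"]),
                           _resolve(entry["labels"]),
                           bool(entry.get("already_log2", True)))
            for p in (e.expression, e.labels):
                if not p.exists():
                    problems.append(f"{what}: missing file {p}")
            return e

        exposure = _study(raw.get("exposure", {}), "exposure")
        diseases = [_study(d, f"diseases[{i}]")
                    for i, d in enumerate(raw.get("diseases", []))]
        if not raw.get("diseases"):
            problems.append("no disease studies declared")

        thr = raw.get("thresholds", {})
        try:
            thresholds = Thresholds(
                p_cutoff=float(thr.get("p_cutoff", 0.01)),
                lfc_cutoff=float(thr.get("lfc_cutoff", 1.0)),
                use_adjusted=bool(thr.get("use_adjusted", True)),
            )
        except ValueError as exc:
            problems.append(str(exc))
            thresholds = Thresholds()
        variant = str(thr.get("ttest", "welch"))
        if variant not in ("welch", "student"):
            problems.append(f"unknown t-test variant {variant!r}")

        enr = raw.get("enrichment", {}) or {}
        libraries = [_resolve(p) for p in enr.get("libraries", [])]
        for p in libraries:
            if not p.exists():
                problems.append(f"enrichment: missing library {p}")

        surv = raw.get("survival", {}) or {}
        cohorts = []
        for i, c in enumerate(surv.get("cohorts", [])):
            missing = [k for k in ("disease_id", "clinical", "expression_z") if k not in c]
            if missing:
                problems.append(f"survival.cohorts[{i}]: missing keys {missing}")
                continue
            entry = CohortEntry(str(c["disease_id"]), _resolve(c["clinical"]),
                                _resolve(c["expression_z"]),
                                tuple(c.get("factors", [])))
            for p in (entry.clinical, entry.expression_z):
                if not p.exists():
                    problems.append(f"survival.cohorts[{i}]: missing file {p}")
            cohorts.append(entry)
        ties = str(surv.get("ties", "efron"))
        if ties not in ("efron", "breslow"):
            problems.append(f"unknown ties method {ties!r}")

        if problems:
            raise ConfigError(f"{path}: " + "; ".join(problems))
        out_dir = raw.get("output_dir", "run_output")
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=_resolve(out_dir),
            exposure=exposure,
            diseases=diseases,
            thresholds=thresholds,
            ttest_variant=variant,
            gmt_libraries=libraries,
            enrichment_background=enr.get("background"),
            enrichment_top_k=enr.get("top_k"),
            survival_alpha=float(surv.get("alpha", 0.05)),
            survival_z_threshold=float(surv.get("z_threshold", 2.0)),
            survival_ties=ties,
            cohorts=cohorts,
            raw=raw,
        )


@dataclass(eq=False)
class RunManifest:
    config: dict
    version: str
    stages: list = field(default_factory=list)
    files: dict = field(default_factory=dict)
    status: str = "ok"

    def to_json(self, path) -> None:
        payload = {"version": self.version, "status": self.status,
                   "config": self.config, "stages": self.stages,
                   "files": self.files}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; abort on failure naming the stage, keeping partial outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.raw, version=__version__)

    def record(stage: str, elapsed: float, outputs: list, warn: list) -> None:
        rels = []
        for p in outputs:
            digest = _sha256(p)
            rel = str(Path(p).relative_to(out))
            manifest.files[rel] = digest
            rels.append(rel)
        manifest.stages.append({"name": stage, "seconds": round(elapsed, 3),
                                "outputs": sorted(rels), "warnings": warn})

    gene_sets: dict[str, DiseaseGeneSet] = {}
    overlap_by_disease: dict[str, dict] = {}
    networks = {}

    def _run_stage(name, fn):
        t0 = _time.perf_counter()
        outputs: list[Path] = []
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            try:
                fn(outputs)
            except Exception as exc:
                record(name, _time.perf_counter() - t0, outputs,
                       [str(w.message) for w in caught])
                manifest.status = f"failed at stage {name}"
                manifest.to_json(out / "manifest.json")
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        record(name, _time.perf_counter() - t0, outputs,
               [str(w.message) for w in caught])

    # --- stage 1: per-study normalization + differential expression
    def _stage_de(outputs):
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        for entry in [config.exposure] + config.diseases:
            study = read_expression(entry.expression, read_labels(entry.labels),
                                    study_id=entry.study_id)
            table = de_table(study, variant=config.ttest_variant,
                             thresholds=config.thresholds)
            gene_sets[entry.study_id] = select_significant(
                table, entry.study_id, config.thresholds)
            stats_path = de_dir / f"{entry.study_id}_stats.tsv"
            set_path = de_dir / f"{entry.study_id}_genes.tsv"
            write_gene_stats(table, stats_path)
            write_gene_set(gene_sets[entry.study_id], set_path)
            outputs += [stats_path, set_path]

    _run_stage("differential_expression", _stage_de)

    # --- stage 2: direction-stratified diseasome networks
    def _stage_network(outputs):
        net_dir = out / "network"
        net_dir.mkdir(exist_ok=True)
        exposure_set = gene_sets[config.exposure.study_id]
        disease_sets = [gene_sets[d.study_id] for d in config.diseases]
        for direction in ("up", "down"):
            net = build_diseasome(exposure_set, disease_sets, direction)
            networks[direction] = net
            for fmt, suffix in (("graphml", "graphml"), ("tsv", "edges.tsv"),
                                ("sif", "sif")):
                p = net_dir / f"diseasome_{direction}.{suffix}"
                export_network(net, p, fmt)
                outputs.append(p)
        for d in config.diseases:
            ds = gene_sets[d.study_id]
            overlap_by_disease[d.study_id] = {
                "up": frozenset(exposure_set.up & ds.up),
                "down": frozenset(exposure_set.down & ds.down),
            }
            rows = [(g, "up") for g in sorted(overlap_by_disease[d.study_id]["up"])]
            rows += [(g, "down") for g in sorted(overlap_by_disease[d.study_id]["down"])]
            p = net_dir / f"overlap_{d.study_id}.tsv"
            pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
                p, sep="\t", index=False)
            outputs.append(p)

    _run_stage("diseasome", _stage_network)

    # --- stage 3: enrichment of each exposure-disease overlap set
    def _stage_enrichment(outputs):
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        libraries = [load_gmt(p, name=Path(p).stem) for p in config.gmt_libraries]
        for did, overlap in overlap_by_disease.items():
            query = overlap["up"] | overlap["down"]
            if not query:
                _warnings.warn(f"{did}: empty overlap set, enrichment skipped")
                continue
            for lib in libraries:
                table = fisher_enrichment(query, lib,
                                          background_n=config.enrichment_background)
                p = enr_dir / f"{did}_{lib.name}.tsv"
                write_enrichment(table, p, top_k=config.enrichment_top_k)
                outputs.append(p)

    if config.gmt_libraries:
        _run_stage("enrichment", _stage_enrichment)

    # --- stage 4: survival screen per cohort on the overlap genes
    def _stage_survival(outputs):
        surv_dir = out / "survival"
        surv_dir.mkdir(exist_ok=True)
        for entry in config.cohorts:
            if entry.disease_id not in overlap_by_disease:
                _warnings.warn(f"cohort {entry.disease_id}: no matching disease study")
                continue
            clin = read_clinical(entry.clinical,
                                 factor_cols=list(entry.factors) or None)
            zmat = pd.read_csv(entry.expression_z, sep="\t", index_col=0)
            cohort = SurvivalCohort.from_clinical(
                clin, zmat, z_threshold=config.survival_z_threshold)
            overlap = overlap_by_disease[entry.disease_id]
            genes = sorted((overlap["up"] | overlap["down"])
                           & set(cohort.status.columns))
            report = gene_survival_screen(cohort, genes,
                                          alpha=config.survival_alpha,
                                          ties=config.survival_ties)
            p = surv_dir / f"{entry.disease_id}_screen.tsv"
            write_screen_report(report, p)
            outputs.append(p)
            for gene, curves in sorted(report.km_curves.items()):
                for grp, curve in sorted(curves.items()):
                    cp = surv_dir / f"{entry.disease_id}_{gene}_{grp}_km.tsv"
                    write_km_curve(curve, cp)
                    outputs.append(cp)

    if config.cohorts:
        _run_stage("survival", _stage_survival)

    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Demo scenario

# Planted DE structure: (n_up, n_down) per study and per-disease shared
# (up, down) counts with the exposure; the shared sets overlap across
# diseases so that a handful of genes touch several cancers.
_DEMO_PLANS = {
    "full": {
        "n_genes": 3000, "n_case": 20, "n_control": 20, "n_patients": 250,
        "exposure": (392, 511),
        "diseases": {
            "CC": {"de": (503, 436), "shared": (20, 16)},
            "PC": {"de": (323, 230), "shared": (8, 5)},
            "LC": {"de": (673, 217), "shared": (15, 10)},
            "GC": {"de": (463, 228), "shared": (10, 7)},
        },
        # slices of the exposure's planted up genes reused across diseases
        "multi_up": {"PC": 2, "LC": 1, "GC": 3},
    },
    "small": {
        "n_genes": 400, "n_case": 12, "n_control": 12, "n_patients": 120,
        "exposure": (40, 50),
        "diseases": {
            "CC": {"de": (30, 25), "shared": (5, 4)},
            "PC": {"de": (20, 15), "shared": (3, 2)},
            "LC": {"de": (25, 20), "shared": (4, 3)},
            "GC": {"de": (22, 18), "shared": (3, 2)},
        },
        "multi_up": {"PC": 1, "LC": 1, "GC": 1},
    },
}

EXPOSURE_ID = "WF"


def demo_scenario(seed: int = 0, scale: str = "full",
                  effect_size: float = 2.0, noise_sd: float = 0.5):
    """Build the demo's linked studies + cohort specs with planted overlaps.

    Returns ``(linked, cohort_specs)`` where ``linked.true_overlap`` gives the
    planted per-disease shared-gene counts.
    """
    if scale not in _DEMO_PLANS:
        raise ValueError(f"unknown demo scale {scale!r}")
    plan = _DEMO_PLANS[scale]
    rng = np.random.default_rng(derive_seed(seed, "demo-plan"))
    universe = tuple(f"G{i:05d}" for i in range(plan["n_genes"]))
    perm = rng.permutation(plan["n_genes"])
    n_up, n_down = plan["exposure"]
    exp_up = [universe[i] for i in perm[:n_up]]
    exp_down = [universe[i] for i in perm[n_up:n_up + n_down]]
    pool = [universe[i] for i in perm[n_up + n_down:]]

    exposure_spec = StudySpec(
        study_id=EXPOSURE_ID, n_genes=plan["n_genes"], n_case=plan["n_case"],
        n_control=plan["n_control"], de_up=frozenset(exp_up),
        de_down=frozenset(exp_down), effect_size=effect_size, noise_sd=noise_sd,
        seed=derive_seed(seed, "study", EXPOSURE_ID), gene_ids=universe,
    )

    # shared sets: CC takes the leading slices; a few of those same exposure
    # genes are re-shared to PC/LC/GC so they touch several diseases
    diseases = plan["diseases"]
    cc_up_n, cc_down_n = diseases["CC"]["shared"]
    shared_up = {"CC": set(exp_up[:cc_up_n])}
    shared_down = {"CC": set(exp_down[:cc_down_n])}
    up_cursor, down_cursor = cc_up_n, cc_down_n
    multi_cursor = 0
    for did in ("PC", "LC", "GC"):
        s_up, s_down = diseases[did]["shared"]
        n_multi = min(plan["multi_up"].get(did, 0), s_up)
        take_multi = exp_up[multi_cursor:multi_cursor + n_multi]
        multi_cursor += n_multi
        fresh = exp_up[up_cursor:up_cursor + (s_up - n_multi)]
        up_cursor += s_up - n_multi
        shared_up[did] = set(take_multi) | set(fresh)
        shared_down[did] = set(exp_down[down_cursor:down_cursor + s_down])
        down_cursor += s_down

    disease_specs = []
    pool_rng = np.random.default_rng(derive_seed(seed, "private-pool"))
    for did, info in diseases.items():
        de_up_n, de_down_n = info["de"]
        s_up, s_down = info["shared"]
        n_private = (de_up_n - s_up) + (de_down_n - s_down)
        picks = pool_rng.choice(len(pool), size=n_private, replace=False)
        private = [pool[i] for i in picks]
        disease_specs.append(StudySpec(
            study_id=did, n_genes=plan["n_genes"], n_case=plan["n_case"],
            n_control=plan["n_control"],
            de_up=frozenset(private[:de_up_n - s_up]),
            de_down=frozenset(private[de_up_n - s_up:]),
            effect_size=effect_size, noise_sd=noise_sd,
            seed=derive_seed(seed, "study", did), gene_ids=universe,
        ))

    linked = generate_linked_studies(exposure_spec, disease_specs,
                                     shared_up, shared_down)

    cohort_specs = {}
    for did in diseases:
        genes = sorted(shared_up[did] | shared_down[did])
        beta_true = {g: math.log(2.0) for g in genes[:2]}
        cohort_specs[did] = CohortSpec(
            n_patients=plan["n_patients"], gene_ids=tuple(genes),
            beta_true=beta_true, baseline_scale=60.0, censor_rate=0.3,
            alteration_rate=0.25, seed=derive_seed(seed, "cohort", did),
        )
    return linked, cohort_specs


def _demo_gmt(linked, cohort_specs, seed: int, path: Path) -> None:
    """Synthetic GMT library: overlap-derived terms plus random filler terms."""
    rng = np.random.default_rng(derive_seed(seed, "gmt"))
    universe = list(linked.exposure_spec.universe)
    lines = []
    for did in sorted(cohort_specs):
        genes = sorted(linked.shared_up.get(did, frozenset())
                       | linked.shared_down.get(did, frozenset()))
        if genes:
            lines.append("\t".join([f"OVERLAP_{did}", f"demo:{did}", *genes]))
    for i in range(25):
        size = int(rng.integers(5, 30))
        members = sorted(universe[j] for j in rng.choice(len(universe), size, replace=False))
        lines.append("\t".join([f"RANDOM_TERM_{i:02d}", f"demo:rand{i}", *members]))
    path.write_text("\n".join(lines) + "\n")


def make_demo(outdir, seed: int = 0, scale: str = "full") -> Path:
    """Write a complete synthetic study set plus a ready-to-run config.

    Returns the path to the written ``config.yaml``.
    """
    outdir = Path(outdir)
    (outdir / "studies").mkdir(parents=True, exist_ok=True)
    (outdir / "cohorts").mkdir(exist_ok=True)
    (outdir / "libraries").mkdir(exist_ok=True)

    linked, cohort_specs = demo_scenario(seed=seed, scale=scale)
    for study in [linked.exposure] + linked.diseases:
        write_expression(study, outdir / "studies" / f"{study.study_id}.tsv")
        write_labels(study, outdir / "studies" / f"{study.study_id}_labels.tsv")

    factors = list(DEFAULT_FACTOR_NAMES)
    for did, spec in cohort_specs.items():
        cohort = generate_survival_cohort(spec)
        write_cohort_clinical(cohort, outdir / "cohorts" / f"{did}_clinical.tsv")
        write_cohort_z(cohort, outdir / "cohorts" / f"{did}_expr_z.tsv")

    _demo_gmt(linked, cohort_specs, seed, outdir / "libraries" / "demo_library.gmt")
    write_ground_truth(linked, cohort_specs, outdir / "ground_truth.json")

    cfg = {
        "seed": int(seed),
        "output_dir": "demo_out",
        "thresholds": {"p_cutoff": 0.01, "lfc_cutoff": 1.0,
                       "use_adjusted": True, "ttest": "welch"},
        "exposure": {"study_id": linked.exposure.study_id,
                     "expression": f"studies/{linked.exposure.study_id}.tsv",
                     "labels": f"studies/{linked.exposure.study_id}_labels.tsv"},
        "diseases": [
            {"study_id": s.study_id, "expression": f"studies/{s.study_id}.tsv",
             "labels": f"studies/{s.study_id}_labels.tsv"}
            for s in linked.diseases
        ],
        "enrichment": {"libraries": ["libraries/demo_library.gmt"],
                       "background": None, "top_k": None},
        "survival": {
            "alpha": 0.05, "z_threshold": 2.0, "ties": "efron",
            "cohorts": [
                {"disease_id": did,
                 "clinical": f"cohorts/{did}_clinical.tsv",
                 "expression_z": f"cohorts/{did}_expr_z.tsv",
                 "factors": factors}
                for did in sorted(cohort_specs)
            ],
        },
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return config_path
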