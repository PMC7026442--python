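"""Synthetic expression studies and survival cohorts with planted structure.

The generators stand in for public microarray studies and clinical cohorts:
expression is drawn on a log2-like scale (Gaussian noise around per-gene
baselines) with planted up/down shifts, so that a planted gene's expected
case-control mean difference equals its log2 fold change; survival times are
drawn from an exponential baseline hazard scaled by exp(beta' x) — exactly
the proportional-hazards model the downstream estimators assume — with
independent exponential censoring whose rate is solved to hit a target
censoring fraction.  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .studies import CASE, CONTROL, ExpressionStudy
from .survival import SurvivalCohort


class InvalidSpecError(ValueError):
    """Generator spec violates its invariants."""


def derive_seed(seed: int, *keys) -> int:
    """Deterministic sub-stream seed (< 2^31) from a global seed plus labels."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


def default_gene_universe(n_genes: int) -> tuple:
    return tuple(f"G{i:05d}" for i in range(n_genes))


DEFAULT_CLINICAL_FACTORS = {
    "ethnicity": ("hispanic", "non_hispanic"),
    "histological_grade": ("g1", "g2", "g3"),
    "primary_site": ("left", "right"),
    "neoplasm_status": ("tumor_free", "with_tumor"),
}


@dataclass(frozen=True)
class StudySpec:
    """Specification of one synthetic expression study."""

    study_id: str
    n_genes: int
    n_case: int
    n_control: int
    de_up: frozenset = frozenset()
    de_down: frozenset = frozenset()
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    gene_ids: tuple | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "de_up", frozenset(self.de_up))
        object.__setattr__(self, "de_down", frozenset(self.de_down))
        if self.n_genes < 1 or self.n_case < 1 or self.n_control < 1:
            raise InvalidSpecError("counts must be positive")
        if self.effect_size <= 0:
            raise InvalidSpecError("effect_size must be > 0")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be > 0")
        if self.de_up & self.de_down:
            raise InvalidSpecError(
                f"{self.study_id}: genes planted both up and down: "
                f"{sorted(self.de_up & self.de_down)[:5]}"
            )
        universe = set(self.universe)
        stray = (self.de_up | self.de_down) - universe
        if stray:
            raise InvalidSpecError(f"{self.study_id}: planted genes outside universe: "
                                   f"{sorted(stray)[:5]}")

    @property
    def universe(self) -> tuple:
        if self.gene_ids is not None:
            if len(self.gene_ids) != self.n_genes:
                raise InvalidSpecError("gene_ids length != n_genes")
            return tuple(self.gene_ids)
        return default_gene_universe(self.n_genes)


def generate_expression_study(spec: StudySpec) -> ExpressionStudy:
    """Draw a genes x samples log2-scale matrix with the planted shifts."""
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.universe)
    n = spec.n_case + spec.n_control
    baseline = rng.uniform(6.0, 12.0, size=spec.n_genes)
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    shift = np.zeros(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in spec.de_up:
        shift[gene_pos[g]] = spec.effect_size
    for g in spec.de_down:
        shift[gene_pos[g]] = -spec.effect_size
    values[:, :spec.n_case] += shift[:, None]
    samples = [f"{spec.study_id}_case_{i}" for i in range(spec.n_case)] + \
              [f"{spec.study_id}_ctrl_{i}" for i in range(spec.n_control)]
    group = pd.Series([CASE] * spec.n_case + [CONTROL] * spec.n_control,
                      index=samples)
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionStudy(spec.study_id, df, group)


@dataclass(eq=False)
class LinkedStudies:
    """An exposure study plus disease studies with known shared planted genes."""

    exposure: ExpressionStudy
    diseases: list
    exposure_spec: StudySpec
    disease_specs: list
    shared_up: dict
    shared_down: dict

    @property
    def true_overlap(self) -> dict:
        """Planted per-disease total overlap with the exposure (up + down)."""
        return {d: len(self.shared_up.get(d, frozenset()))
                   + len(self.shared_down.get(d, frozenset()))
                for d in (s.study_id for s in self.disease_specs)}


def generate_linked_studies(exposure: StudySpec, diseases: list,
                            shared_up: dict, shared_down: dict) -> LinkedStudies:
    """Generate an exposure study plus disease studies with planted overlaps.

    ``shared_up``/``shared_down`` map disease id -> genes that must be
    dysregulated (same direction) in both the exposure and that disease.
    Each disease spec's own de_up/de_down are its disease-private genes and
    may not touch the exposure's planted sets.
    """
    ids = [d.study_id for d in diseases]
    if len(set(ids)) != len(ids):
        raise InvalidSpecError(f"duplicate disease ids: {ids}")
    exposure_planted = exposure.de_up | exposure.de_down
    for name, shared, planted in (("shared_up", shared_up, exposure.de_up),
                                  ("shared_down", shared_down, exposure.de_down)):
        for did, genes in shared.items():
            if did not in ids:
                raise InvalidSpecError(f"{name}: unknown disease {did!r}")
            stray = frozenset(genes) - planted
            if stray:
                raise InvalidSpecError(
                    f"{name}[{did}]: genes not planted in exposure ({name.split('_')[1]}):"
                    f" {sorted(stray)[:5]}"
                )
    effective_specs = []
    for spec in diseases:
        private = spec.de_up | spec.de_down
        clash = private & exposure_planted
        if clash:
            raise InvalidSpecError(
                f"{spec.study_id}: private genes collide with exposure planted set: "
                f"{sorted(clash)[:5]}"
            )
        up = spec.de_up | frozenset(shared_up.get(spec.study_id, frozenset()))
        down = spec.de_down | frozenset(shared_down.get(spec.study_id, frozenset()))
        effective_specs.append(StudySpec(
            study_id=spec.study_id, n_genes=spec.n_genes, n_case=spec.n_case,
            n_control=spec.n_control, de_up=up, de_down=down,
            effect_size=spec.effect_size, noise_sd=spec.noise_sd,
            seed=spec.seed, gene_ids=spec.gene_ids,
        ))
    return LinkedStudies(
        exposure=generate_expression_study(exposure),
        diseases=[generate_expression_study(s) for s in effective_specs],
        exposure_spec=exposure,
        disease_specs=effective_specs,
        shared_up={d: frozenset(g) for d, g in shared_up.items()},
        shared_down={d: frozenset(g) for d, g in shared_down.items()},
    )


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic survival cohort."""

    n_patients: int
    gene_ids: tuple
    beta_true: dict = field(default_factory=dict)
    clinical_factors: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_FACTORS))
    baseline_scale: float = 60.0
    censor_rate: float = 0.3
    alteration_rate: float = 0.25
    seed: int = 0
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g).upper() for g in self.gene_ids))
        object.__setattr__(self, "beta_true",
                           {str(g).upper(): float(b) for g, b in self.beta_true.items()})
        if self.n_patients < 1:
            raise InvalidSpecError("n_patients must be positive")
        if not 0 <= self.censor_rate < 1:
            raise InvalidSpecError("censor_rate must lie in [0, 1)")
        if not 0 < self.alteration_rate < 1:
            raise InvalidSpecError("alteration_rate must lie in (0, 1)")
        if self.baseline_scale <= 0:
            raise InvalidSpecError("baseline_scale must be > 0")
        stray = set(self.beta_true) - set(self.gene_ids)
        if stray:
            raise InvalidSpecError(f"beta_true for genes not in cohort: {sorted(stray)[:5]}")


def _censoring_rate(lam: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate mu with mean_i mu/(mu+lam_i) = censor_rate."""
    def f(log_mu):
        mu = np.exp(log_mu)
        return float(np.mean(mu / (mu + lam))) - censor_rate
    lo, hi = np.log(lam.mean()) - 30, np.log(lam.mean()) + 30
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12)))


def generate_survival_cohort(spec: CohortSpec) -> SurvivalCohort:
    """Draw a cohort from h(t|x) = h0 exp(beta' x), h0 = 1/baseline_scale."""
    rng = np.random.default_rng(spec.seed)
    n, genes = spec.n_patients, list(spec.gene_ids)
    status = rng.random((n, len(genes))) < spec.alteration_rate
    beta = np.array([spec.beta_true.get(g, 0.0) for g in genes])
    lam = np.exp(status @ beta) / spec.baseline_scale
    event_time = rng.exponential(1.0 / lam)
    if spec.censor_rate == 0:
        censor_time = np.full(n, np.inf)
    else:
        mu = _censoring_rate(lam, spec.censor_rate)
        censor_time = rng.exponential(1.0 / mu, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clinical = pd.DataFrame({
        name: rng.choice(levels, size=n)
        for name, levels in spec.clinical_factors.items()
    })
    patient_ids = pd.Index([f"P{i:04d}" for i in range(n)])
    clinical.index = patient_ids

    # z-scores consistent with the planted status at the cohort's threshold
    zstar = spec.z_threshold
    z = np.clip(rng.normal(0.0, zstar / 2.5, size=(len(genes), n)),
                -0.999 * zstar, 0.999 * zstar)
    sign = rng.choice([-1.0, 1.0], size=(len(genes), n))
    magnitude = zstar + rng.exponential(0.5, size=(len(genes), n))
    z = np.where(status.T, sign * magnitude, z)
    expression_z = pd.DataFrame(z, index=genes, columns=patient_ids)

    return SurvivalCohort(
        patient_ids=patient_ids,
        time=time,
        event=event,
        status=pd.DataFrame(status, index=patient_ids, columns=genes),
        clinical=clinical,
        expression_z=expression_z,
        z_threshold=zstar,
    )


# ---------------------------------------------------------------------------
# Writers (same layouts the ingestion side reads)

def write_cohort_clinical(cohort: SurvivalCohort, path) -> None:
    df = pd.DataFrame({"patient_id": cohort.patient_ids,
                       "time_months": cohort.time,
                       "event": cohort.event})
    df = pd.concat([df, cohort.clinical.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cohort_z(cohort: SurvivalCohort, path) -> None:
    if cohort.expression_z is None:
        raise ValueError("cohort has no expression z matrix")
    cohort.expression_z.to_csv(path, sep="\t", index_label="gene",
                               float_format="%.10g")


def write_ground_truth(linked: LinkedStudies, cohort_specs: dict, path) -> None:
    """Sidecar JSON with planted sets, true betas and true overlap counts."""
    payload = {
        "exposure": {
            "study_id": linked.exposure_spec.study_id,
            "de_up": sorted(linked.exposure_spec.de_up),
            "de_down": sorted(linked.exposure_spec.de_down),
        },
        "diseases": {
            s.study_id: {"de_up": sorted(s.de_up), "de_down": sorted(s.de_down)}
            for s in linked.disease_specs
        },
        "shared_up": {d: sorted(g) for d, g in linked.shared_up.items()},
        "shared_down": {d: sorted(g) for d, g in linked.shared_down.items()},
        "true_overlap": linked.true_overlap,
        "cohorts": {
            d: {"beta_true": spec.beta_true, "n_patients": spec.n_patients,
                "censor_rate": spec.censor_rate,
                "alteration_rate": spec.alteration_rate}
            for d, spec in cohort_specs.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
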