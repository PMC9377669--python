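"""Synthetic compound screens with the statistical structure the analysis assumes.

The generator emulates the downstream-visible properties of a summarized
microarray screen: log2 probe-set intensities with per-probe baselines,
additive per-(batch, probe) shifts, batch-wise vehicle controls, a fixed
number of treated replicates per condition, compound-specific sets of
deregulated probe sets with prescribed log2 fold-change magnitudes, and
cytotoxic conditions that contribute *no* expression samples (a cytotoxic
exposure yields no usable RNA; the condition exists only in the compound
annotation table).

It also ships the packaged screen-count fixture (per-condition up/down
deregulated probe-set counts plus cytotoxicity flags for 16 non-teratogens
and 23 teratogens) used by the SPS classifier, and a random toy ontology
generator for exercising the elim enrichment on small DAGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import OntologyDAG
from .preprocess import validate_sample_sheet, write_expression_matrix, write_sample_sheet

__all__ = [
    "EffectSpec",
    "CompoundSpec",
    "SyntheticConfig",
    "generate_screen",
    "recovery_screen_config",
    "write_screen",
    "table2_fixture",
    "generate_toy_ontology",
]


@dataclass(frozen=True)
class EffectSpec:
    """Log2 fold-change distribution of a compound's affected probe sets."""

    mean_abs_log2fc: float = 0.0  # mean effect magnitude, log2 units
    sd_log2fc: float = 0.0  # spread of the magnitude across probes
    frac_up: float = 0.5  # fraction of affected probes shifted upward

    def __post_init__(self) -> None:
        if self.mean_abs_log2fc < 0 or self.sd_log2fc < 0:
            raise ValueError("effect magnitudes must be nonnegative")
        if not 0.0 <= self.frac_up <= 1.0:
            raise ValueError("frac_up must lie in [0, 1]")


def _per_tier(value, tiers: Sequence[str], default):
    """Normalize a scalar-or-dict field to one value per tier."""
    if isinstance(value, Mapping):
        return {t: value.get(t, default) for t in tiers}
    return {t: (value if value is not None else default) for t in tiers}


@dataclass(frozen=True)
class CompoundSpec:
    """One test compound: label, tiers, effect sizes, cytotoxicity."""

    compound_id: str
    label: str  # "teratogen" | "non_teratogen"
    concentration_tiers: tuple[str, ...] = ("1x",)
    n_affected_probesets: int | Mapping[str, int] = 0
    effect_log2fc: EffectSpec | Mapping[str, EffectSpec] = field(default_factory=EffectSpec)
    cytotoxic: bool | Mapping[str, bool] = False
    vehicle: str = "DMSO_0.1pct"
    #: fraction of affected probes drawn from the screen-wide shared response
    #: program (see ``SyntheticConfig.signature_pool_size``); the remainder is
    #: compound-specific, chosen uniformly outside the pool
    signature_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("teratogen", "non_teratogen"):
            raise ValueError(f"unknown label {self.label!r}")
        if not self.concentration_tiers:
            raise ValueError("compound needs at least one concentration tier")
        if not 0.0 <= self.signature_frac <= 1.0:
            raise ValueError("signature_frac must lie in [0, 1]")

    def tier_n_affected(self) -> dict[str, int]:
        return _per_tier(self.n_affected_probesets, self.concentration_tiers, 0)

    def tier_effects(self) -> dict[str, EffectSpec]:
        return _per_tier(self.effect_log2fc, self.concentration_tiers, EffectSpec())

    def tier_cytotoxic(self) -> dict[str, bool]:
        return _per_tier(self.cytotoxic, self.concentration_tiers, False)


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of a synthetic screen.

    Defaults mirror the study layout: three biological replicates per
    condition and log2-scale intensities.  ``n_batches=None`` distributes
    the conditions round-robin over ``ceil(n_conditions / 6)`` batches,
    each with its own vehicle controls.
    """

    compounds: tuple[CompoundSpec, ...]
    n_probesets: int = 5000
    replicates_per_condition: int = 3
    control_samples_per_batch: int = 3
    batch_effect_sd: float = 0.3  # log2 units, per (batch, probe)
    residual_sd: float = 0.25  # log2 units, per measurement
    baseline_mean: float = 7.0  # log2 units, centre of probe baselines
    baseline_sd: float = 1.5
    n_batches: int | None = None
    #: size of the shared "response program" probe pool that compounds with
    #: ``signature_frac > 0`` draw part of their affected sets from; emulates
    #: the common developmental program that makes compound-level
    #: classification generalize across held-out compounds
    signature_pool_size: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValueError("config must declare at least one compound")
        if self.n_probesets < 1:
            raise ValueError("n_probesets must be >= 1")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if self.control_samples_per_batch < 1:
            raise ValueError("every batch needs at least one control sample")
        for sd in (self.batch_effect_sd, self.residual_sd, self.baseline_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")
        if not 0 <= self.signature_pool_size <= self.n_probesets:
            raise ValueError("signature_pool_size must lie in [0, n_probesets]")
        for spec in self.compounds:
            if spec.signature_frac > 0 and self.signature_pool_size == 0:
                raise ValueError(
                    f"{spec.compound_id}: signature_frac > 0 requires a "
                    "nonzero signature_pool_size"
                )
            for tier, n_aff in spec.tier_n_affected().items():
                if n_aff > self.n_probesets:
                    raise ValueError(
                        f"{spec.compound_id} @ {tier}: n_affected_probesets "
                        f"{n_aff} exceeds n_probesets {self.n_probesets}"
                    )


def generate_screen(
    config: SyntheticConfig, return_truth: bool = False
) -> tuple[pd.DataFrame, ...]:
    """Simulate (expression matrix, sample sheet, compound annotations).

    Expression model, all on the log2 scale: per-probe baseline
    N(baseline_mean, baseline_sd²), plus a per-(batch, probe) shift
    N(0, batch_effect_sd²) shared by every sample of the batch, plus the
    condition's additive effect on its affected probe sets (treated samples
    only), plus i.i.d. residual noise N(0, residual_sd²).  Cytotoxic tiers
    emit no samples.  Deterministic for a fixed config (seed included).

    With ``return_truth=True`` a fourth element is appended: the ground
    truth as a dict mapping ``(compound_id, tier)`` to a Series of the true
    log2 fold changes indexed by the affected probe ids.
    """
    rng = np.random.default_rng(config.seed)
    probes = pd.Index(
        [f"ps{i:05d}_at" for i in range(config.n_probesets)], name="probe_id"
    )
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_probesets)
    all_idx = np.arange(config.n_probesets)
    if config.signature_pool_size > 0:
        pool = rng.choice(all_idx, size=config.signature_pool_size, replace=False)
        # the shared program is directionally coherent: every compound that
        # hits a pool probe shifts it the same way
        pool_sign = {int(i): s for i, s in zip(pool, np.where(rng.random(pool.size) < 0.5, 1.0, -1.0))}
    else:
        pool = np.empty(0, dtype=int)
        pool_sign = {}
    outside_pool = np.setdiff1d(all_idx, pool)

    conditions = []  # (spec, tier) for non-cytotoxic tiers, in declaration order
    annotations = []
    for spec in config.compounds:
        cyto = spec.tier_cytotoxic()
        for tier in spec.concentration_tiers:
            annotations.append(
                {
                    "compound_id": spec.compound_id,
                    "label": spec.label,
                    "tier": tier,
                    "cytotoxic": bool(cyto[tier]),
                }
            )
            if not cyto[tier]:
                conditions.append((spec, tier))
    if not conditions:
        raise ValueError("every condition is cytotoxic: nothing to simulate")

    n_batches = config.n_batches or -(-len(conditions) // 6)
    batch_of = {
        (spec.compound_id, tier): f"b{i % n_batches:02d}"
        for i, (spec, tier) in enumerate(conditions)
    }
    batches = [f"b{i:02d}" for i in range(n_batches)]
    batch_shift = {
        b: rng.normal(0.0, config.batch_effect_sd, config.n_probesets) for b in batches
    }

    vehicles_in_batch: dict[str, set[str]] = {b: set() for b in batches}
    for spec, tier in conditions:
        vehicles_in_batch[batch_of[(spec.compound_id, tier)]].add(spec.vehicle)

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []

    def noise() -> np.ndarray:
        return rng.normal(0.0, config.residual_sd, config.n_probesets)

    for b in batches:
        for vehicle in sorted(vehicles_in_batch[b]) or []:
            for r in range(config.control_samples_per_batch):
                sid = f"ctrl_{b}_{vehicle}_r{r + 1}"
                columns[sid] = baseline + batch_shift[b] + noise()
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "compound_id": "control",
                        "tier": "none",
                        "batch": b,
                        "role": "control",
                        "vehicle": vehicle,
                        "replicate": r + 1,
                        "excluded": False,
                    }
                )

    truth: dict[tuple[str, str], pd.Series] = {}
    for spec, tier in conditions:
        b = batch_of[(spec.compound_id, tier)]
        n_aff = spec.tier_n_affected()[tier]
        eff = spec.tier_effects()[tier]
        effect = np.zeros(config.n_probesets)
        if n_aff > 0:
            n_shared = min(int(round(spec.signature_frac * n_aff)), pool.size)
            shared = rng.choice(pool, size=n_shared, replace=False)
            n_own = n_aff - n_shared
            own_source = outside_pool if n_own <= outside_pool.size else np.setdiff1d(all_idx, shared)
            own = rng.choice(own_source, size=n_own, replace=False)
            affected = np.concatenate([shared, own])
            signs = np.where(rng.random(n_aff) < eff.frac_up, 1.0, -1.0)
            signs[:n_shared] = [pool_sign[int(i)] for i in shared]
            if eff.sd_log2fc > 0:
                magnitude = np.abs(rng.normal(eff.mean_abs_log2fc, eff.sd_log2fc, n_aff))
            else:
                magnitude = np.full(n_aff, eff.mean_abs_log2fc)
            effect[affected] = signs * magnitude
        nz = np.flatnonzero(effect)
        truth[(spec.compound_id, tier)] = pd.Series(effect[nz], index=probes[nz])
        for r in range(config.replicates_per_condition):
            sid = f"{spec.compound_id}_{tier}_r{r + 1}"
            columns[sid] = baseline + batch_shift[b] + effect + noise()
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "compound_id": spec.compound_id,
                    "tier": tier,
                    "batch": b,
                    "role": "treated",
                    "vehicle": spec.vehicle,
                    "replicate": r + 1,
                    "excluded": False,
                }
            )

    matrix = pd.DataFrame(columns, index=probes)
    sheet = validate_sample_sheet(pd.DataFrame(sheet_rows))
    ann = pd.DataFrame(annotations)
    if return_truth:
        return matrix, sheet, ann, truth
    return matrix, sheet, ann


def recovery_screen_config(n_probesets: int = 5000, seed: int = 0) -> SyntheticConfig:
    """Standard parameter-recovery screen for validating the classifiers.

    Five teratogen-like compounds, each deregulating 300 probe sets at
    |log2FC| 1.5 (sd 0.3) with 80% of them drawn from a directionally
    coherent 300-probe shared response program, against five near-null
    non-teratogens (5 affected probes at |log2FC| 0.5); three replicates per
    condition, residual sd 0.25 log2 units.  The strong sharing emulates the
    common developmental program real screens exhibit, which is what lets a
    classifier generalize to held-out compounds.
    """
    effect = EffectSpec(mean_abs_log2fc=1.5, sd_log2fc=0.3)
    compounds = tuple(
        CompoundSpec(
            compound_id=f"tox{i}", label="teratogen",
            n_affected_probesets=300, effect_log2fc=effect, signature_frac=0.8,
        )
        for i in range(5)
    ) + tuple(
        CompoundSpec(
            compound_id=f"neg{i}", label="non_teratogen",
            n_affected_probesets=5,
            effect_log2fc=EffectSpec(mean_abs_log2fc=0.5),
        )
        for i in range(5)
    )
    return SyntheticConfig(
        compounds=compounds, n_probesets=n_probesets,
        signature_pool_size=300, seed=seed,
    )


def write_screen(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    annotations: pd.DataFrame,
    outdir: str | Path,
    prefix: str = "screen",
) -> dict[str, Path]:
    """Write matrix (TSV), sheet and annotations (CSV) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}_expression.tsv",
        "sheet": outdir / f"{prefix}_samples.csv",
        "annotations": outdir / f"{prefix}_compounds.csv",
    }
    write_expression_matrix(matrix, paths["matrix"])
    write_sample_sheet(sheet, paths["sheet"])
    annotations.to_csv(paths["annotations"], index=False)
    return paths


def table2_fixture() -> pd.DataFrame:
    """The packaged per-condition screen counts.

    One row per compound × tested tier with the printed up/down deregulated
    probe-set counts and cytotoxicity flags: 16 non-teratogens, 23
    teratogens; compounds whose high concentration had to be substituted
    keep their substituted tier name (``10x`` carbamazepine, ``1.67x``
    valproic acid) and the four compounds tested only at the therapeutic
    concentration have a single ``1x`` row.  Cytotoxic rows carry no counts.
    """
    with resources.files("teratoclass.data").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"up": "Int64", "down": "Int64"})
    df["cytotoxic"] = df["cytotoxic"].astype(bool)
    return df


def generate_toy_ontology(seed: int, n_terms: int, n_genes: int) -> OntologyDAG:
    """Random single-root is-a DAG with every gene annotated to >= 1 term.

    Term ``T000`` is the root; each later term attaches to 1–2 uniformly
    chosen earlier terms, which guarantees acyclicity and a single root.
    Genes are directly annotated to 1–3 random terms; ancestor propagation
    is left to :class:`OntologyDAG`.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(2, i) + 1))
        chosen = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = {terms[j] for j in chosen}
    annotations: dict[str, set[str]] = {t: set() for t in terms}
    for g in range(n_genes):
        gene = f"g{g:04d}"
        k = int(rng.integers(1, min(3, n_terms) + 1))
        for j in rng.choice(n_terms, size=k, replace=False):
            annotations[terms[j]].add(gene)
    return OntologyDAG(parents, annotations=annotations)
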