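"""Synthetic inputs with planted, fully recorded ground truth.

Every pipeline stage consumes one of three input kinds; this module
generates all of them with controllable planted structure so the whole
analysis is testable without any database snapshot or cohort download:

* annotation/target tables whose induced network contains exactly the
  planted directed cycles as nontrivial strongly connected components
  (background host→target records respect a random topological order among
  non-core genes, so no accidental cycle can arise);
* an RPKM-like log-normal expression matrix with a planted gene set whose
  location is shifted up and whose dispersion is shrunk;
* four patient cohorts (training / two filtration / validation) with a
  planted discriminative gene set whose expression differs between the
  recurrence and recurrence-free classes by stated, possibly differently
  signed shifts, plus a grey zone and censored follow-up.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    LocationClass,
    MaturePrecursorMap,
    MirnaGeneAnnotation,
    Orientation,
    TargetInteraction,
)
from .signature_search import (
    COLORECTAL_SCHEME,
    RECURRED,
    RECURRENCE_FREE,
    CohortDataset,
    DichotomizationScheme,
)

__all__ = [
    "SyntheticGroundTruth",
    "SimulatedAnnotations",
    "simulate_annotations",
    "simulate_expression",
    "simulate_cohorts",
    "write_annotation_tables",
    "write_cohort_table",
]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """What was planted, and with which effect sizes and seeds."""

    seeds: dict = field(default_factory=dict)
    planted_core_components: tuple[frozenset[str], ...] = ()
    planted_high_expression_genes: frozenset[str] = frozenset()
    location_shift: float = 0.0
    dispersion_factor: float = 1.0
    planted_signature: tuple[str, ...] = ()
    class_shifts: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulatedAnnotations:
    """Synthetic host/target tables plus their ground truth."""

    annotations: list[MirnaGeneAnnotation]
    mature_map: MaturePrecursorMap
    targets_a: list[TargetInteraction]
    targets_b: list[TargetInteraction]
    truth: SyntheticGroundTruth


def _gene_universe(n_genes: int, planted: Sequence[str]) -> list[str]:
    filler = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    planted_set = set(planted)
    filler = [g for g in filler if g not in planted_set][: n_genes - len(planted)]
    return list(planted) + filler


def simulate_annotations(
    n_genes: int = 200,
    n_mirnas: int = 60,
    planted_cycles: Sequence[Sequence[str]] = (),
    background_edge_rate: float = 0.02,
    seed: int = 0,
) -> SimulatedAnnotations:
    """Host/target tables whose network core is exactly the planted cycles.

    Each planted cycle ``[g1, …, gk]`` is wired as gene ``gi`` hosting an
    intronic-sense miRNA that targets ``g(i+1)`` (cyclically).  Background
    hosts target only genes later in a random topological order of the
    non-core genes, so the only nontrivial SCCs are the planted ones.  Both
    target tables contain every emitted interaction (the two-database
    intersection preserves all of them); each table additionally carries a
    few source-unique decoy rows that the intersection must discard.
    """
    rng = np.random.default_rng(seed)
    planted_flat: list[str] = []
    for cycle in planted_cycles:
        if len(cycle) < 2:
            raise ValueError("planted cycles must contain at least two genes")
        for g in cycle:
            gene = str(g).upper()
            if gene in planted_flat:
                raise ValueError(f"gene {gene!r} appears in more than one planted cycle")
            planted_flat.append(gene)
    if len(planted_flat) > n_genes:
        raise ValueError("planted cycles exceed the gene universe size")
    universe = _gene_universe(n_genes, planted_flat)
    non_core = [g for g in universe if g not in set(planted_flat)]

    annotations: list[MirnaGeneAnnotation] = []
    mature_map: dict[str, frozenset[str]] = {}
    interactions: list[tuple[str, str]] = []

    def add_host(gene: str, target_genes: Sequence[str], intronic_sense: bool = True) -> None:
        pre = f"pre-{gene.lower()}"
        mature = f"mat-{gene.lower()}"
        loc = LocationClass.INTRONIC if intronic_sense else LocationClass.EXONIC
        ori = Orientation.SENSE if intronic_sense else Orientation.ANTISENSE
        annotations.append(MirnaGeneAnnotation(pre, gene, loc, ori))
        mature_map[mature] = frozenset({pre})
        for t in target_genes:
            interactions.append((mature, t))

    for cycle in planted_cycles:
        cycle = [str(g).upper() for g in cycle]
        for i, gene in enumerate(cycle):
            add_host(gene, [cycle[(i + 1) % len(cycle)]])

    # Background hosts: early genes in a random topological order target a
    # sparse subset of strictly later genes (guaranteed acyclic).
    order = [non_core[i] for i in rng.permutation(len(non_core))]
    n_background = max(0, n_mirnas - len(planted_flat))
    host_positions = list(range(min(len(order) - 1, n_background)))
    for pos in host_positions:
        later = order[pos + 1 :]
        mask = rng.random(len(later)) < background_edge_rate
        targets = [t for t, m in zip(later, mask) if m]
        if not targets:
            targets = [later[int(rng.integers(len(later)))]]
        # one in five background miRNAs is exonic/antisense so that the
        # intronic-sense class filter is exercised
        add_host(order[pos], targets, intronic_sense=bool(rng.random() >= 0.2))

    targets_a = [TargetInteraction(m, t, "db_a") for m, t in interactions]
    targets_b = [TargetInteraction(m, t, "db_b") for m, t in interactions]
    # source-unique decoys: interactions towards genes nothing else targets,
    # present in one table only, so the validated intersection drops them
    real = set(interactions)
    matures = sorted(mature_map)
    for source, table in (("db_a", targets_a), ("db_b", targets_b)):
        for _ in range(3):
            m = matures[int(rng.integers(len(matures)))]
            t = universe[int(rng.integers(len(universe)))]
            if (m, t) not in real:
                table.append(TargetInteraction(m, t, source))

    truth = SyntheticGroundTruth(
        seeds={"annotations": seed},
        planted_core_components=tuple(
            frozenset(str(g).upper() for g in cycle) for cycle in planted_cycles
        ),
    )
    return SimulatedAnnotations(annotations, mature_map, targets_a, targets_b, truth)


def simulate_expression(
    n_transcripts: int = 5000,
    n_samples: int = 100,
    planted_genes: Sequence[str] = (),
    location_shift: float = 2.0,
    dispersion_factor: float = 0.5,
    seed: int = 0,
    base_location_mean: float = 1.0,
    base_location_sd: float = 0.75,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Log-normal transcripts × samples matrix with a planted gene set.

    Background transcript ``i`` has values ``exp(mu_i + s_i * z)`` with
    heterogeneous locations ``mu_i ~ N(base_location_mean, base_location_sd)``
    and scales ``s_i ~ U(0.5, 1.5)``.  Planted genes get ``mu_i`` shifted up
    by ``location_shift`` (log units) and ``s_i`` multiplied by
    ``dispersion_factor`` in (0, 1].
    """
    if not 0 < dispersion_factor <= 1:
        raise ValueError("dispersion_factor must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    planted = [str(g).upper() for g in planted_genes]
    names = _gene_universe(n_transcripts, planted)
    mu = rng.normal(base_location_mean, base_location_sd, size=n_transcripts)
    scale = rng.uniform(0.5, 1.5, size=n_transcripts)
    is_planted = np.zeros(n_transcripts, dtype=bool)
    is_planted[: len(planted)] = True
    mu = mu + location_shift * is_planted
    scale = scale * np.where(is_planted, dispersion_factor, 1.0)
    z = rng.standard_normal((n_transcripts, n_samples))
    values = np.exp(mu[:, None] + scale[:, None] * z)
    mat = pd.DataFrame(
        values,
        index=pd.Index(names, name="transcript"),
        columns=[f"S{j:04d}" for j in range(1, n_samples + 1)],
    )
    truth = SyntheticGroundTruth(
        seeds={"expression": seed},
        planted_high_expression_genes=frozenset(planted),
        location_shift=location_shift,
        dispersion_factor=dispersion_factor,
    )
    return mat, truth


def simulate_cohorts(
    n_per_cohort: Sequence[int] = (200, 150, 150, 150),
    genes: Sequence[str] = (),
    planted_signature: Sequence[str] = (),
    class_shifts: Sequence[float] = (),
    grey_fraction: float = 0.2,
    seed: int = 0,
    scheme: DichotomizationScheme = COLORECTAL_SCHEME,
    event_rate: float = 0.5,
    censoring_scale_months: float = 24.0,
) -> tuple[list[CohortDataset], SyntheticGroundTruth]:
    """Four cohorts (training, two filtration, validation) with planted signal.

    Event-class patients have the planted-signature genes shifted by
    ``class_shifts`` (in units of the per-gene standard deviation; signs may
    differ between genes, mirroring oppositely directed expression changes).
    All other genes are uninformative N(0, 1) noise.  Event times fall
    inside the dichotomization event window, control follow-up beyond the
    control minimum (plus exponential censoring spread); a ``grey_fraction``
    of patients gets times between the two rules and is therefore excluded
    by dichotomization.
    """
    if len(n_per_cohort) != 4:
        raise ValueError("n_per_cohort must list four cohort sizes")
    if not 0 <= grey_fraction < 1:
        raise ValueError("grey_fraction must lie in [0, 1)")
    genes = [str(g).upper() for g in genes]
    planted = [str(g).upper() for g in planted_signature]
    if len(planted) != len(class_shifts):
        raise ValueError("class_shifts must match planted_signature in length")
    missing = set(planted) - set(genes)
    if missing:
        raise ValueError(f"planted signature genes not in the gene list: {sorted(missing)}")
    shift_of = dict(zip(planted, class_shifts))
    roles = ["training", "filtration", "filtration", "validation"]
    cohorts: list[CohortDataset] = []
    for c, (n, role) in enumerate(zip(n_per_cohort, roles)):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(c,)))
        u = rng.random(n)
        grey = u < grey_fraction
        event = ~grey & (rng.random(n) < event_rate)
        expr = rng.standard_normal((n, len(genes)))
        for j, g in enumerate(genes):
            if g in shift_of:
                expr[event, j] += shift_of[g]
                expr[grey, j] += 0.5 * shift_of[g]  # grey zone sits between classes
        status = np.where(event, RECURRED, RECURRENCE_FREE)
        times = np.empty(n)
        lo = scheme.min_event_months
        hi = scheme.event_horizon_months
        times[event] = lo + (hi - lo) * rng.uniform(0.05, 1.0, size=int(event.sum()))
        ctrl = ~grey & ~event
        times[ctrl] = scheme.control_min_followup_months + rng.exponential(
            censoring_scale_months, size=int(ctrl.sum())
        )
        grey_recur = grey & (rng.random(n) < 0.5)
        status = np.where(grey_recur, RECURRED, status)
        times[grey_recur] = hi + rng.uniform(0.0, 36.0, size=int(grey_recur.sum()))
        grey_free = grey & ~grey_recur
        times[grey_free] = rng.uniform(
            lo + 1.0, scheme.control_min_followup_months, size=int(grey_free.sum())
        )
        idx = pd.Index([f"P{c+1}{i:04d}" for i in range(1, n + 1)], name="patient_id")
        cohorts.append(
            CohortDataset(
                expression=pd.DataFrame(expr, index=idx, columns=genes),
                status=pd.Series(status, index=idx, name="recurrence_status"),
                time_months=pd.Series(times, index=idx, name="time_months"),
                role=role,
            )
        )
    truth = SyntheticGroundTruth(
        seeds={"cohorts": seed},
        planted_signature=tuple(planted),
        class_shifts=shift_of,
    )
    return cohorts, truth


# ---------------------------------------------------------------------------
# TSV writers matching the formats the readers consume
# ---------------------------------------------------------------------------


def write_annotation_tables(sim: SimulatedAnnotations, out_dir: str | Path) -> dict[str, Path]:
    """Write hosts.tsv, mature_map.tsv, targets_a.tsv and targets_b.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hosts": out / "hosts.tsv",
        "mature_map": out / "mature_map.tsv",
        "targets_a": out / "targets_a.tsv",
        "targets_b": out / "targets_b.tsv",
    }
    with paths["hosts"].open("w", encoding="utf-8") as fh:
        fh.write("pre_mirna_id\thost_gene\tlocation_class\torientation\n")
        for r in sim.annotations:
            fh.write(f"{r.pre_mirna_id}\t{r.host_gene}\t{r.location_class.value}\t{r.orientation.value}\n")
    with paths["mature_map"].open("w", encoding="utf-8") as fh:
        fh.write("mature_mirna_id\tpre_mirna_id\n")
        for mature in sorted(sim.mature_map):
            for pre in sorted(sim.mature_map[mature]):
                fh.write(f"{mature}\t{pre}\n")
    for key, table in (("targets_a", sim.targets_a), ("targets_b", sim.targets_b)):
        with paths[key].open("w", encoding="utf-8") as fh:
            fh.write("mature_mirna_id\ttarget_gene\n")
            for t in table:
                fh.write(f"{t.mature_mirna_id}\t{t.target_gene}\n")
    return paths


def write_cohort_table(cohort: CohortDataset, path: str | Path) -> Path:
    """Write one cohort as the delimited table read_cohort consumes."""
    df = cohort.expression.copy()
    df["recurrence_status"] = cohort.status
    df["time_months"] = cohort.time_months
    df.to_csv(path, sep="\t", index_label="patient_id")
    return Path(path)
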