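"""End-to-end study orchestration and the permutation control.

``run_study`` wires the stages together: per-signature de novo motif
discovery, cross-signature similarity grouping and shared-motif calling
per cancer type, genome-wide PWM target scanning, motif-combination
target intersection, binomial enrichment against cancer-related gene
sets, and hypergeometric miRNA-target overlap with signature-level and
cancer-type-level common-miRNA calling.

``run_permutation_control`` re-runs discovery and shared-motif calling
on nucleotide-permuted copies of every signature's promoters, the
study's negative control: per-sequence shuffling preserves composition
but destroys motifs, so shared motifs called on shuffled input measure
the pipeline's false-positive behaviour.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .discovery import (
    DiscoveryParams,
    MotifCombination,
    build_combinations,
    discover_motifs,
    permute_sequences,
)
from .enrichment import (
    DEFAULT_MIRNA_ALPHA,
    EnrichmentResult,
    MirnaCall,
    binomial_overlap_test,
    common_mirnas,
    mirna_regulates_gs,
)
from .io import GeneSetCollection, GeneSignature, PromoterSet
from .pwm import Motif, PWM
from .scan import (
    DEFAULT_SCORE_CUTOFF,
    TargetGeneSet,
    combination_targets,
    target_genes,
)
from .shared import SharedMotif, call_shared, group_similar
from .similarity import (
    KNOWN_MATCH_E,
    NullCalibration,
    WITHIN_STUDY_E,
    default_calibration,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Thresholds, parameters and seed for one full analysis run."""

    similarity_e: float = WITHIN_STUDY_E  # within-study similar motifs
    known_match_e: float = KNOWN_MATCH_E  # annotation threshold
    scan_cutoff: float = DEFAULT_SCORE_CUTOFF  # target-gene score
    mirna_alpha: float = DEFAULT_MIRNA_ALPHA  # per-motif miRNA overlap
    enrichment_alpha: float = 0.01  # combination vs cancer sets
    annotated_only: bool = True  # downstream uses annotated shared motifs
    mirna_universe: str = "signature"  # or "scanned"
    control_reps: int = 100
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("similarity_e", "known_match_e", "mirna_alpha",
                     "enrichment_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.scan_cutoff < 1.0:
            raise ValueError("scan_cutoff must lie in (0, 1)")
        if self.control_reps < 1:
            raise ValueError("control_reps must be >= 1")
        if self.mirna_universe not in ("signature", "scanned"):
            raise ValueError("mirna_universe must be signature or scanned")


@dataclass
class StudyResult:
    """Everything the pipeline computes, stage by stage."""

    config: StudyConfig
    motifs_by_gs: dict[str, list[Motif]]
    combinations_by_gs: dict[str, list[MotifCombination]]
    shared_by_type: dict[str, list[SharedMotif]]
    targets_by_shared: dict[str, TargetGeneSet]
    combination_target_sets: dict[str, TargetGeneSet]
    cancer_enrichment: list[EnrichmentResult]
    mirna_calls: dict[str, dict[str, list[MirnaCall]]]
    # cancer type -> gs id -> calls (one per miRNA)
    common_mirnas_by_type: dict[str, list[str]]
    timings: dict[str, float]

    def summary(self) -> dict:
        """Plain-data summary (deterministic key order when dumped)."""
        return {
            "n_motifs": {g: len(v) for g, v in self.motifs_by_gs.items()},
            "n_combinations": {g: len(v)
                               for g, v in self.combinations_by_gs.items()},
            "shared_motifs": {
                t: [
                    {
                        "consensus": s.representative.consensus,
                        "gs_ids": sorted(s.group.gs_ids),
                        "known_match": s.known_match,
                        "annotated": s.annotated,
                    }
                    for s in v
                ]
                for t, v in self.shared_by_type.items()
            },
            "n_targets": {m: len(t.genes)
                          for m, t in self.targets_by_shared.items()},
            "significant_cancer_sets": sum(
                1 for r in self.cancer_enrichment
                if r.p_value < self.config.enrichment_alpha),
            "n_cancer_tests": len(self.cancer_enrichment),
            "common_mirnas": self.common_mirnas_by_type,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


@dataclass
class ControlReport:
    """Per-replicate motif and shared-motif counts on permuted input."""

    n_reps: int
    motifs_per_rep: list[int]
    shared_per_rep: list[int]

    @property
    def shared_motif_rate(self) -> float:
        return sum(1 for n in self.shared_per_rep if n > 0) / self.n_reps

    @property
    def motif_rate(self) -> float:
        return sum(1 for n in self.motifs_per_rep if n > 0) / self.n_reps


def run_study(
    signatures: list[GeneSignature],
    promoters: dict[str, PromoterSet],
    universe_promoters: PromoterSet,
    known_db: list[tuple[str, PWM]],
    cancer_sets: GeneSetCollection,
    mirna_sets: GeneSetCollection,
    config: StudyConfig | None = None,
    calibration: NullCalibration | None = None,
) -> StudyResult:
    """Execute the full analysis on in-memory inputs."""
    config = config or StudyConfig()
    calibration = calibration or default_calibration()
    timings: dict[str, float] = {}
    missing = [s.id for s in signatures if s.id not in promoters]
    if missing:
        raise ValueError(f"promoters missing for signatures {missing[:5]}")

    # 1. per-signature discovery (and combinations)
    t0 = time.perf_counter()
    motifs_by_gs: dict[str, list[Motif]] = {}
    combos_by_gs: dict[str, list[MotifCombination]] = {}
    for sig in signatures:
        mots = discover_motifs(promoters[sig.id], config.discovery,
                               calibration)
        motifs_by_gs[sig.id] = mots
        combos_by_gs[sig.id] = build_combinations(mots, promoters[sig.id],
                                                  config.discovery)
    timings["discovery"] = time.perf_counter() - t0

    # 2. shared motifs per cancer type
    t0 = time.perf_counter()
    by_type: dict[str, list[GeneSignature]] = {}
    for sig in signatures:
        by_type.setdefault(sig.cancer_type, []).append(sig)
    shared_by_type: dict[str, list[SharedMotif]] = {}
    for ctype, sigs in sorted(by_type.items()):
        if len(sigs) < 2:
            logger.warning("cancer type %s has fewer than 2 signatures; "
                           "skipped", ctype)
            shared_by_type[ctype] = []
            continue
        type_motifs = [m for s in sigs for m in motifs_by_gs[s.id]]
        groups = group_similar(type_motifs, config.similarity_e, calibration)
        shared_by_type[ctype] = call_shared(
            groups, len(sigs), known_db, cancer_type=ctype,
            threshold=config.known_match_e, calibration=calibration)
    timings["shared"] = time.perf_counter() - t0

    # 3. genome-wide scanning of shared-motif representatives
    t0 = time.perf_counter()
    targets_by_shared: dict[str, TargetGeneSet] = {}
    shared_ids: dict[int, str] = {}
    for ctype, shared in shared_by_type.items():
        for i, sm in enumerate(shared, 1):
            if config.annotated_only and not sm.annotated:
                continue
            sid = f"{ctype}_shared{i}"
            shared_ids[id(sm)] = sid
            targets_by_shared[sid] = target_genes(
                sm.representative.pwm, universe_promoters,
                cutoff=config.scan_cutoff, source_id=sid)
    timings["scan"] = time.perf_counter() - t0

    # 4. combination targets + cancer gene-set enrichment
    t0 = time.perf_counter()
    scanned_universe = frozenset(universe_promoters.entries)
    combination_target_sets: dict[str, TargetGeneSet] = {}
    cancer_enrichment: list[EnrichmentResult] = []
    for ctype, shared in shared_by_type.items():
        for sm in shared:
            sid = shared_ids.get(id(sm))
            if sid is None:
                continue
            gs_id = sm.representative.source_gs
            for combo in combos_by_gs.get(gs_id, []):
                if sm.representative.id not in combo.motif_ids:
                    continue
                member_sets = []
                for mid in sorted(combo.motif_ids):
                    motif = next(m for m in motifs_by_gs[gs_id]
                                 if m.id == mid)
                    member_sets.append(target_genes(
                        motif.pwm, universe_promoters,
                        cutoff=config.scan_cutoff, source_id=mid))
                cset = combination_targets(member_sets, source_id=combo.id)
                combination_target_sets[combo.id] = cset
                for set_name, genes in cancer_sets.sets.items():
                    cancer_enrichment.append(binomial_overlap_test(
                        cset.genes, genes & scanned_universe,
                        scanned_universe,
                        source_id=combo.id, set_name=set_name))
    timings["enrichment"] = time.perf_counter() - t0

    # 5. miRNA overlap per signature, common miRNAs per cancer type
    t0 = time.perf_counter()
    mirna_calls: dict[str, dict[str, list[MirnaCall]]] = {}
    common_by_type: dict[str, list[str]] = {}
    for ctype, sigs in sorted(by_type.items()):
        shared = [sm for sm in shared_by_type[ctype]
                  if id(sm) in shared_ids]
        per_gs: dict[str, list[MirnaCall]] = {}
        for sig in sigs:
            gs_genes = frozenset(sig.genes)
            motif_targets: dict[str, frozenset[str]] = {}
            for sm in shared:
                sid = shared_ids[id(sm)]
                in_gs = targets_by_shared[sid].genes & gs_genes
                motif_targets[sid] = in_gs
            universe = (gs_genes if config.mirna_universe == "signature"
                        else scanned_universe)
            calls = [
                mirna_regulates_gs(sig.id, motif_targets, name, genes,
                                   universe, alpha=config.mirna_alpha)
                for name, genes in sorted(mirna_sets.sets.items())
            ]
            per_gs[sig.id] = calls
        mirna_calls[ctype] = per_gs
        common_by_type[ctype] = common_mirnas(per_gs) if per_gs else []
    timings["mirna"] = time.perf_counter() - t0

    return StudyResult(
        config=config,
        motifs_by_gs=motifs_by_gs,
        combinations_by_gs=combos_by_gs,
        shared_by_type=shared_by_type,
        targets_by_shared=targets_by_shared,
        combination_target_sets=combination_target_sets,
        cancer_enrichment=cancer_enrichment,
        mirna_calls=mirna_calls,
        common_mirnas_by_type=common_by_type,
        timings=timings,
    )


def run_permutation_control(
    signatures: list[GeneSignature],
    promoters: dict[str, PromoterSet],
    known_db: list[tuple[str, PWM]],
    config: StudyConfig | None = None,
    n_reps: int | None = None,
    calibration: NullCalibration | None = None,
) -> ControlReport:
    """Discovery + shared-motif calling on shuffled promoters.

    Each replicate permutes the nucleotide order of every promoter
    independently (per-sequence composition preserved), re-runs
    discovery in every signature and shared-motif calling per cancer
    type, and records the motif and shared-motif counts.
    """
    config = config or StudyConfig()
    calibration = calibration or default_calibration()
    if n_reps is None:
        n_reps = config.control_reps
    by_type: dict[str, list[GeneSignature]] = {}
    for sig in signatures:
        by_type.setdefault(sig.cancer_type, []).append(sig)
    motifs_per_rep: list[int] = []
    shared_per_rep: list[int] = []
    for rep in range(n_reps):
        rep_motifs: dict[str, list[Motif]] = {}
        for i, sig in enumerate(signatures):
            perm = permute_sequences(
                promoters[sig.id],
                seed=(int(config.seed) % (2**31 - 1)) * 100003
                + rep * 1009 + i)
            rep_motifs[sig.id] = discover_motifs(perm, config.discovery,
                                                 calibration)
        n_motifs = sum(len(v) for v in rep_motifs.values())
        n_shared = 0
        for ctype, sigs in by_type.items():
            if len(sigs) < 2:
                continue
            type_motifs = [m for s in sigs for m in rep_motifs[s.id]]
            groups = group_similar(type_motifs, config.similarity_e,
                                   calibration)
            n_shared += len(call_shared(groups, len(sigs), known_db,
                                        cancer_type=ctype,
                                        threshold=config.known_match_e,
                                        calibration=calibration))
        motifs_per_rep.append(n_motifs)
        shared_per_rep.append(n_shared)
    return ControlReport(n_reps=n_reps, motifs_per_rep=motifs_per_rep,
                         shared_per_rep=shared_per_rep)


def write_study_report(result: StudyResult, outdir: str | Path) -> None:
    """Write the JSON summary and per-stage TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(result.to_json())
    lines = ["cancer_type\tconsensus\tgs_ids\tknown_match\tknown_e"]
    for ctype, shared in sorted(result.shared_by_type.items()):
        for sm in shared:
            km = sm.known_match or ("", float("nan"))
            lines.append("\t".join([
                ctype, sm.representative.consensus,
                ",".join(sorted(sm.group.gs_ids)), str(km[0]),
                f"{km[1]:.3g}",
            ]))
    (outdir / "shared_motifs.tsv").write_text("\n".join(lines) + "\n")
    lines = ["cancer_type\tmirna"]
    for ctype, mirnas in sorted(result.common_mirnas_by_type.items()):
        for m in mirnas:
            lines.append(f"{ctype}\t{m}")
    (outdir / "common_mirnas.tsv").write_text("\n".join(lines) + "\n")
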