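"""Synthetic study generation with planted ground truth.

A synthetic study emulates the statistical design the analysis assumes:
several cancer types, each with a handful of prognostic gene signatures
(5-7 per type, 30-80 genes each, nearly disjoint), 1.5 kb repeat-masked
promoters, one or more binding motifs planted into the promoters of a
majority of the signatures of a type, optional co-planted cofactor
motifs, a known-motif database containing noisy copies of the planted
matrices among decoys, cancer-related gene sets with controlled
enrichment for planted-motif targets, and per-miRNA target sets where
one designated miRNA per cancer type overlaps the true targets at a
controlled rate.

The generator is seeded and fully reproducible; every generated file
round-trips through :mod:`sigmotif.io`, and the returned
:class:`GroundTruth` records exactly what was planted where.

Background sequence is order-0 with configurable GC content: the real
promoters this stands in for have higher-order structure and repeat
families, so null rates measured here speak to the statistics of the
method, not to the false-positive rate on genomic sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import psi

from .io import (
    GeneSetCollection,
    GeneSignature,
    PromoterSet,
    write_fasta,
    write_gene_sets,
    write_motif_db,
    write_signatures,
)
from .pwm import MAX_PWM_LENGTH, MIN_PWM_LENGTH, PWM, revcomp

# ---------------------------------------------------------------------------
# PWM sampling


def _expected_ic(conc: float) -> float:
    """Expected per-column IC (bits) of a symmetric Dirichlet(conc) column."""
    # E[-sum p ln p] = psi(4c + 1) - psi(c + 1) for a symmetric Dirichlet.
    entropy_nats = psi(4 * conc + 1) - psi(conc + 1)
    return 2.0 - entropy_nats / np.log(2)


def sample_pwm(
    length: int,
    ic_target: float,
    rng: np.random.Generator | int,
    tol: float = 0.15,
    col_tol: float = 0.1,
    max_tries: int = 2000,
) -> PWM:
    """Sample a PWM with per-column information content near a target.

    Columns are symmetric-Dirichlet draws with the concentration solved
    so the expected column IC equals ``ic_target``; each column is
    redrawn until its own IC lies within ``col_tol`` bits of the target,
    so the matrix is homogeneous in information (every position carries
    comparable signal, as in standard planted-motif benchmarks).  The
    matrix mean IC then lands well within ``tol`` of the target.
    """
    if not MIN_PWM_LENGTH <= length <= MAX_PWM_LENGTH:
        raise ValueError(f"length {length} outside PWM bounds")
    if not 0.0 < ic_target <= 2.0:
        raise ValueError(f"ic_target {ic_target} outside (0, 2]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if ic_target > _expected_ic(1e-4):
        conc = 1e-4  # effectively one-hot columns
    elif ic_target < _expected_ic(50.0):
        raise ValueError(f"ic_target {ic_target} unattainable (too uniform)")
    else:
        conc = brentq(lambda c: _expected_ic(c) - ic_target, 1e-4, 50.0)
    eff_col_tol = min(col_tol, 2.0 - ic_target + 1e-9) if ic_target > 1.8 \
        else col_tol
    cols = []
    for _ in range(max_tries):
        col = rng.dirichlet([conc] * 4)
        c = np.clip(col, 1e-12, 1.0)
        ic = 2.0 + float((c * np.log2(c)).sum())
        if abs(ic - ic_target) <= eff_col_tol:
            cols.append(col)
            if len(cols) == length:
                pwm = PWM(np.array(cols))
                if abs(pwm.information_content().mean() - ic_target) <= tol:
                    return pwm
                cols = []
    raise RuntimeError(
        f"could not hit IC {ic_target} +/- {tol} in {max_tries} draws"
    )


# ---------------------------------------------------------------------------
# study specification


@dataclass(frozen=True)
class PlantedMotifSpec:
    """One motif planted across a majority of each cancer type's GSs."""

    name: str = "planted_1"
    length: int = 12
    ic: float = 1.3
    plant_rate: float = 0.6  # per-promoter probability within a carrier GS
    # every signature carries the motif by default: the designated
    # common miRNA must overlap motif targets in every signature, which
    # is impossible when some signatures have no planted sites at all;
    # majority-sharing designs (e.g. 4 of 6 carriers) are exercised by
    # setting this fraction explicitly
    fraction_of_gs: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate outside [0, 1]")
        if not 0.0 <= self.fraction_of_gs <= 1.0:
            raise ValueError("fraction_of_gs outside [0, 1]")
        if not MIN_PWM_LENGTH <= self.length <= MAX_PWM_LENGTH:
            raise ValueError("length outside PWM bounds")


@dataclass(frozen=True)
class CofactorSpec:
    """A cofactor motif co-planted in sequences carrying the primary."""

    length: int = 10
    ic: float = 1.6
    co_plant_rate: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.co_plant_rate <= 1.0:
            raise ValueError("co_plant_rate outside [0, 1]")


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full specification of a synthetic study.

    Defaults emulate the five-cancer-type study design: 7/5/6/6/5
    signatures with mean sizes 50/57/34/74/47, 1.5 kb promoters, one
    planted motif per type carried by two thirds of the signatures.
    """

    cancer_types: tuple[tuple[str, int, int], ...] = (
        ("breast", 7, 50),
        ("colorectal", 5, 57),
        ("leukemia", 6, 34),
        ("lymphoma", 6, 74),
        ("lung", 5, 47),
    )
    promoter_length: int = 1500
    gc_content: float = 0.45
    planted_motifs: tuple[PlantedMotifSpec, ...] = (PlantedMotifSpec(),)
    cofactor: CofactorSpec | None = None
    universe_size: int = 2000
    n_known_decoys: int = 20
    n_cancer_sets: int = 20
    cancer_set_enrichment: float = 4.0  # odds multiplier theta
    cancer_set_background: float = 0.1
    n_mirnas: int = 30
    mirna_target_overlap: float = 0.5  # rho for the designated miRNA
    mirna_background: float = 0.3
    max_pairwise_gs_overlap: int = 1
    mask_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n_gs, size in self.cancer_types:
            if n_gs < 2:
                raise ValueError(f"{name}: need at least 2 GSs")
        for frac in (self.gc_content, self.cancer_set_background,
                     self.mirna_target_overlap, self.mirna_background,
                     self.mask_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        needed = sum(n * s for _, n, s in self.cancer_types)
        if needed > self.universe_size:
            raise ValueError(
                f"universe_size {self.universe_size} cannot host "
                f"{needed} signature genes"
            )


@dataclass
class GroundTruth:
    """Everything that was planted, for downstream verification."""

    planted_pwms: dict[str, PWM]
    carrier_gs: dict[str, list[str]]  # motif name -> carrier signature ids
    plants: dict[str, list[dict]]
    # gene -> [{motif, position, strand, site}]; positions are 0-based
    # within the promoter, site given in motif orientation
    true_targets: dict[str, list[str]]  # motif name -> genes with a site
    true_enriched_sets: list[str]
    true_common_mirnas: dict[str, str]  # cancer type -> designated miRNA

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["planted_pwms"] = {
            name: pwm.matrix.tolist() for name, pwm in self.planted_pwms.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        payload["planted_pwms"] = {
            name: PWM(np.array(mat))
            for name, mat in payload["planted_pwms"].items()
        }
        return cls(**payload)


@dataclass
class SyntheticStudy:
    """In-memory bundle of all generated inputs plus the ground truth."""

    spec: SyntheticStudySpec
    signatures: list[GeneSignature]
    promoters: dict[str, PromoterSet]  # signature id -> promoters
    universe_promoters: PromoterSet
    known_db: list[tuple[str, PWM]]
    cancer_sets: GeneSetCollection
    mirna_sets: GeneSetCollection
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "promoters").mkdir(parents=True, exist_ok=True)
        write_signatures(self.signatures, outdir / "signatures.tsv")
        for sid, pset in self.promoters.items():
            write_fasta(pset.entries, outdir / "promoters" / f"{sid}.fa")
        write_fasta(self.universe_promoters.entries, outdir / "universe.fa")
        write_motif_db(self.known_db, outdir / "known_motifs.meme")
        write_gene_sets(self.cancer_sets, outdir / "cancer_sets.gmt")
        write_gene_sets(self.mirna_sets, outdir / "mirna_sets.gmt")
        (outdir / "ground_truth.json").write_text(self.truth.to_json())


# ---------------------------------------------------------------------------
# generation


def _background_promoter(length: int, gc: float,
                         rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")


def _mask_sequence(seq: str, mask_fraction: float,
                   rng: np.random.Generator) -> str:
    """Lowercase random runs (RepeatMasker convention) up to the fraction."""
    if mask_fraction <= 0:
        return seq
    chars = np.array(list(seq))
    masked = np.zeros(len(seq), dtype=bool)
    target = mask_fraction * len(seq)
    # cap attempts so pathological fractions cannot spin forever
    for _ in range(200):
        if masked.sum() >= target:
            break
        run = int(rng.integers(30, 81))
        start = int(rng.integers(0, max(1, len(seq) - run)))
        masked[start : start + run] = True
    chars[masked] = np.char.lower(chars[masked])
    return "".join(chars)


def _plant_site(seq: str, site: str, rng: np.random.Generator,
                occupied: list[tuple[int, int]]) -> tuple[str, int, str] | None:
    """Insert a site (random strand) at a clean window; None if impossible."""
    k = len(site)
    if len(seq) < k:
        return None
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    blocked = ~np.isin(codes, np.frombuffer(b"ACGT", dtype=np.uint8))
    for s, e in occupied:
        blocked[s:e] = True
    # windows of length k containing any blocked base are excluded
    bad = np.convolve(blocked.astype(int), np.ones(k, dtype=int), "valid") > 0
    candidates = np.flatnonzero(~bad)
    if candidates.size == 0:
        return None
    pos = int(rng.choice(candidates))
    strand = "+" if rng.random() < 0.5 else "-"
    inserted = site if strand == "+" else revcomp(site)
    new_seq = seq[:pos] + inserted + seq[pos + k :]
    occupied.append((pos, pos + k))
    return new_seq, pos, strand


def _assign_signature_genes(
    spec: SyntheticStudySpec, rng: np.random.Generator, universe: list[str]
) -> list[GeneSignature]:
    pool = list(universe)
    rng.shuffle(pool)
    cursor = 0
    signatures: list[GeneSignature] = []
    for ctype, n_gs, size in spec.cancer_types:
        type_sigs: list[GeneSignature] = []
        for i in range(n_gs):
            genes: list[str] = []
            # occasionally reuse one gene from an earlier GS of the same
            # type, so pairwise sharing looks like the near-disjoint
            # pattern of real signature collections
            if (
                spec.max_pairwise_gs_overlap >= 1
                and type_sigs
                and rng.random() < 0.3
            ):
                donor = type_sigs[int(rng.integers(len(type_sigs)))]
                genes.append(str(rng.choice(donor.genes)))
            while len(genes) < size:
                genes.append(pool[cursor])
                cursor += 1
            sid = f"{ctype}_GS{i + 1}"
            type_sigs.append(
                GeneSignature(id=sid, cancer_type=ctype, genes=tuple(genes))
            )
        signatures.extend(type_sigs)
    return signatures


def generate_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Generate a complete synthetic study from a seeded specification."""
    rng = np.random.default_rng(spec.seed)
    universe = [f"G{i:05d}" for i in range(spec.universe_size)]
    signatures = _assign_signature_genes(spec, rng, universe)

    # planted PWMs are shared across cancer types (the analysis looks for
    # motifs recurring across signatures; planting the same matrix in
    # every type also exercises the cross-type comparison)
    planted_pwms: dict[str, PWM] = {}
    cof_pwms: dict[str, PWM] = {}
    for mspec in spec.planted_motifs:
        planted_pwms[mspec.name] = sample_pwm(mspec.length, mspec.ic, rng)
        if spec.cofactor is not None:
            cof_pwms[mspec.name + "_cof"] = sample_pwm(
                spec.cofactor.length, spec.cofactor.ic, rng
            )

    # carrier signatures per motif, chosen per cancer type
    carrier_gs: dict[str, list[str]] = {m.name: [] for m in spec.planted_motifs}
    by_type: dict[str, list[GeneSignature]] = {}
    for s in signatures:
        by_type.setdefault(s.cancer_type, []).append(s)
    for mspec in spec.planted_motifs:
        for ctype, sigs in by_type.items():
            n_carriers = int(round(mspec.fraction_of_gs * len(sigs)))
            chosen = rng.choice(len(sigs), size=n_carriers, replace=False)
            carrier_gs[mspec.name].extend(sigs[i].id for i in sorted(chosen))

    # one promoter per gene (shared genes share their promoter)
    gene_promoters: dict[str, str] = {}
    for gene in universe:
        seq = _background_promoter(spec.promoter_length, spec.gc_content, rng)
        gene_promoters[gene] = _mask_sequence(seq, spec.mask_fraction, rng)

    plants: dict[str, list[dict]] = {}
    true_targets: dict[str, set[str]] = {m.name: set() for m in spec.planted_motifs}
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in universe}
    for mspec in spec.planted_motifs:
        pwm = planted_pwms[mspec.name]
        carrier_genes: set[str] = set()
        for s in signatures:
            if s.id in carrier_gs[mspec.name]:
                carrier_genes.update(s.genes)
        for gene in sorted(carrier_genes):
            if rng.random() >= mspec.plant_rate:
                continue
            site = pwm.sample_site(rng)
            planted = _plant_site(gene_promoters[gene], site, rng,
                                  occupied[gene])
            if planted is None:
                continue
            gene_promoters[gene], pos, strand = planted
            plants.setdefault(gene, []).append(
                {"motif": mspec.name, "position": pos, "strand": strand,
                 "site": site}
            )
            true_targets[mspec.name].add(gene)
            if spec.cofactor is not None and rng.random() < spec.cofactor.co_plant_rate:
                cof_name = mspec.name + "_cof"
                cof_site = cof_pwms[cof_name].sample_site(rng)
                planted = _plant_site(gene_promoters[gene], cof_site, rng,
                                      occupied[gene])
                if planted is not None:
                    gene_promoters[gene], pos, strand = planted
                    plants.setdefault(gene, []).append(
                        {"motif": cof_name, "position": pos, "strand": strand,
                         "site": cof_site}
                    )

    promoters = {
        s.id: PromoterSet(
            signature_id=s.id,
            entries={g: gene_promoters[g] for g in s.genes},
            nominal_length=spec.promoter_length,
        )
        for s in signatures
    }
    universe_promoters = PromoterSet(
        signature_id="universe",
        entries=dict(gene_promoters),
        nominal_length=spec.promoter_length,
    )

    # known-motif database: noisy re-estimates of the planted matrices
    # (30 sampled sites each) hidden among random decoys
    known_db: list[tuple[str, PWM]] = []
    for name, pwm in {**planted_pwms, **cof_pwms}.items():
        sites = [pwm.sample_site(rng) for _ in range(30)]
        known_db.append((f"KNOWN_{name}", PWM.from_sites(sites)))
    for i in range(spec.n_known_decoys):
        length = int(rng.integers(8, 13))
        known_db.append((f"DECOY_{i + 1}", sample_pwm(length, 1.2, rng)))

    # cancer-related gene sets: half enriched for true targets (odds
    # multiplied by theta), half pure background
    all_true = sorted(set().union(*true_targets.values())) if true_targets else []
    all_true_set = set(all_true)
    cancer_sets: dict[str, frozenset[str]] = {}
    true_enriched: list[str] = []
    p_bg = spec.cancer_set_background
    p_hi = min(1.0, p_bg * spec.cancer_set_enrichment)
    for i in range(spec.n_cancer_sets):
        enriched = i < spec.n_cancer_sets // 2 and bool(all_true)
        members = [
            g for g in universe
            if rng.random() < (p_hi if enriched and g in all_true_set else p_bg)
        ]
        name = f"CSET_{i + 1}"
        cancer_sets[name] = frozenset(members)
        if enriched:
            true_enriched.append(name)

    # miRNA target sets: one designated miRNA per cancer type overlaps
    # that type's true targets at rate rho (and never touches the other
    # signature genes); the rest are uniform background
    mirna_sets: dict[str, frozenset[str]] = {}
    true_common: dict[str, str] = {}
    gs_genes: set[str] = set()
    for s in signatures:
        gs_genes.update(s.genes)
    rho = spec.mirna_target_overlap
    if spec.planted_motifs:
        primary = spec.planted_motifs[0].name
        for ctype, sigs in by_type.items():
            name = f"MIR-TRUE-{ctype.upper()}"
            carrier_ids = {
                s.id for s in sigs if s.id in carrier_gs[primary]
            }
            type_true = set()
            for s in sigs:
                if s.id in carrier_ids:
                    type_true.update(g for g in s.genes
                                     if g in true_targets[primary])
            members = [g for g in sorted(type_true) if rng.random() < rho]
            members += [
                g for g in universe
                if g not in gs_genes and rng.random() < spec.mirna_background
            ]
            mirna_sets[name] = frozenset(members)
            true_common[ctype] = name
    for i in range(spec.n_mirnas - len(mirna_sets)):
        members = [g for g in universe if rng.random() < spec.mirna_background]
        mirna_sets[f"MIR-{i + 1}"] = frozenset(members)

    truth = GroundTruth(
        planted_pwms={**planted_pwms, **cof_pwms},
        carrier_gs=carrier_gs,
        plants=plants,
        true_targets={m: sorted(v) for m, v in true_targets.items()},
        true_enriched_sets=true_enriched,
        true_common_mirnas=true_common,
    )
    uni_frozen = frozenset(universe)
    return SyntheticStudy(
        spec=spec,
        signatures=signatures,
        promoters=promoters,
        universe_promoters=universe_promoters,
        known_db=known_db,
        cancer_sets=GeneSetCollection(
            name="cancer_sets", universe=uni_frozen, sets=cancer_sets
        ),
        mirna_sets=GeneSetCollection(
            name="mirna_sets", universe=uni_frozen, sets=mirna_sets
        ),
        truth=truth,
    )
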