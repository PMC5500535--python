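"""Input/output for signatures, promoters, gene sets and motif files.

File formats
------------
* signatures: TSV with columns ``cancer_type, signature_id, gene_symbol``
* coordinates: TSV with columns ``gene_id, chrom, strand, start`` where
  ``start`` is the 0-based translational start position
* promoters / genomes: FASTA (case preserved; lowercase and N = masked)
* gene sets and miRNA target sets: GMT
* motifs: MEME-style minimal motif format (letter-probability matrices)

Coordinates are 0-based half-open throughout.  The coordinate table
stores the translational start, not the transcription start; upstream
windows are taken relative to it.
"""

from __future__ import annotations

import io as _io
import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq

from .pwm import PWM, revcomp

logger = logging.getLogger(__name__)

SIGNATURE_COLUMNS = ("cancer_type", "signature_id", "gene_symbol")
COORDINATE_COLUMNS = ("gene_id", "chrom", "strand", "start")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class GeneSignature:
    """A named prognostic gene list for one cancer type."""

    id: str
    cancer_type: str
    genes: tuple[str, ...]  # ordered, deduplicated, uppercase

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.id!r} has duplicate genes")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneCoordinateTable:
    """Translational start coordinates, 0-based, one record per gene."""

    records: pd.DataFrame  # columns gene_id, chrom, strand, start

    def __post_init__(self) -> None:
        df = self.records
        missing = set(COORDINATE_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"coordinate table missing columns {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise FormatError(f"duplicate gene_ids in coordinates: {dupes[:5]}")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise FormatError("strand must be '+' or '-'")
        if (df["start"] < 0).any():
            raise FormatError("start positions must be >= 0")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.records["gene_id"])

    def lookup(self, gene_id: str) -> tuple[str, str, int]:
        row = self.records.loc[self.records["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return str(r["chrom"]), str(r["strand"]), int(r["start"])


@dataclass
class PromoterSet:
    """Upstream sequences for one signature (or a genome-wide universe)."""

    signature_id: str
    entries: dict[str, str]  # gene_id -> sequence, case preserved
    nominal_length: int = 1500

    def __post_init__(self) -> None:
        for gid, seq in self.entries.items():
            if len(seq) > self.nominal_length:
                raise ValueError(
                    f"{gid}: promoter length {len(seq)} exceeds "
                    f"nominal {self.nominal_length}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def gene_ids(self) -> list[str]:
        return list(self.entries)


@dataclass
class GeneSetCollection:
    """Named gene sets over a common gene universe (GMT semantics)."""

    name: str
    universe: frozenset[str]
    sets: dict[str, frozenset[str]]
    restriction_report: dict[str, tuple[int, int]] = field(default_factory=dict)
    # set_name -> (size before restriction, size after)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        for sname, genes in self.sets.items():
            if not genes <= self.universe:
                raise ValueError(f"set {sname!r} not within the universe")

    def restricted_gene_count(self) -> int:
        """Number of distinct genes across all sets after restriction."""
        return len(frozenset(itertools.chain.from_iterable(self.sets.values())))


# ---------------------------------------------------------------------------
# signatures


def read_signatures(path: str | Path) -> list[GeneSignature]:
    """Read a signatures TSV into a list of GeneSignature.

    Symbols are uppercased and whitespace-trimmed; duplicates within a
    signature are dropped with a warning; empty signatures are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SIGNATURE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"signature file missing columns {sorted(missing)}")
    df = df.dropna(subset=list(SIGNATURE_COLUMNS))
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    df = df[df["gene_symbol"] != ""]
    signatures: list[GeneSignature] = []
    for (ctype, sid), grp in df.groupby(["cancer_type", "signature_id"], sort=False):
        genes: list[str] = []
        seen: set[str] = set()
        for g in grp["gene_symbol"]:
            if g in seen:
                warnings.warn(
                    f"duplicate gene {g} in signature {sid}; deduplicated",
                    stacklevel=2,
                )
                continue
            seen.add(g)
            genes.append(g)
        if not genes:
            raise FormatError(f"signature {sid} has no genes")
        signatures.append(GeneSignature(id=str(sid), cancer_type=str(ctype),
                                        genes=tuple(genes)))
    ids = [s.id for s in signatures]
    if len(set(ids)) != len(ids):
        raise FormatError("signature_id values must be unique across the study")
    if not signatures:
        raise FormatError("no signatures in file")
    return signatures


def write_signatures(signatures: list[GeneSignature], path: str | Path) -> None:
    rows = [
        (s.cancer_type, s.id, g) for s in signatures for g in s.genes
    ]
    pd.DataFrame(rows, columns=list(SIGNATURE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_coordinates(path: str | Path) -> GeneCoordinateTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str,
                                            "strand": str, "start": int})
    return GeneCoordinateTable(df)


# ---------------------------------------------------------------------------
# promoters


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA preserving case (lowercase = repeat-masked)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(entries: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_promoters(path: str | Path, signature_id: str = "",
                   nominal_length: int = 1500) -> PromoterSet:
    return PromoterSet(signature_id=signature_id, entries=read_fasta(path),
                       nominal_length=nominal_length)


def extract_upstream(
    genome: dict[str, str],
    coords: GeneCoordinateTable,
    genes: list[str],
    length: int = 1500,
    signature_id: str = "",
) -> tuple[PromoterSet, list[str]]:
    """Extract ``length`` bases upstream of each gene's translational start.

    For + strand genes the window is ``[start - length, start)``; for -
    strand genes it is the reverse complement of ``[start, start + length)``.
    Windows are truncated at chromosome ends, never padded.  Case (and
    hence repeat masking) is preserved from the genome FASTA.

    Returns the promoter set and the list of genes skipped because they
    are absent from the coordinate table.  A missing chromosome is fatal.
    """
    entries: dict[str, str] = {}
    skipped: list[str] = []
    known = set(coords.records["gene_id"])
    for gene in genes:
        if gene not in known:
            skipped.append(gene)
            continue
        chrom, strand, start = coords.lookup(gene)
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} not in genome FASTA")
        seq = genome[chrom]
        if strand == "+":
            window = seq[max(0, start - length) : start]
        else:
            window = revcomp(seq[start : start + length])
        if window:
            entries[gene] = window
    if skipped:
        logger.warning("extract_upstream skipped %d genes absent from "
                       "coordinates: %s", len(skipped), skipped[:5])
    return (
        PromoterSet(signature_id=signature_id, entries=entries,
                    nominal_length=length),
        skipped,
    )


# ---------------------------------------------------------------------------
# pairwise gene sharing


def pairwise_share_stats(signatures: list[GeneSignature]) -> dict:
    """Gene-sharing statistics over within-cancer-type signature pairs.

    Pairs are unordered and formed only between signatures of the same
    cancer type.  Reports the fraction of pairs sharing zero genes, the
    fraction sharing at most one, the maximum shared count, and the
    per-pair counts.
    """
    by_type: dict[str, list[GeneSignature]] = {}
    for s in signatures:
        by_type.setdefault(s.cancer_type, []).append(s)
    pair_counts: dict[tuple[str, str], int] = {}
    for ctype, sigs in sorted(by_type.items()):
        for a, b in itertools.combinations(sorted(sigs, key=lambda s: s.id), 2):
            pair_counts[(a.id, b.id)] = len(a.gene_set & b.gene_set)
    if not pair_counts:
        warnings.warn("no cancer type has two or more signatures", stacklevel=2)
        return {
            "n_pairs": 0,
            "fraction_zero_share": float("nan"),
            "fraction_at_most_one": float("nan"),
            "max_shared": 0,
            "pair_counts": {},
        }
    counts = np.array(list(pair_counts.values()))
    return {
        "n_pairs": len(counts),
        "fraction_zero_share": float((counts == 0).mean()),
        "fraction_at_most_one": float((counts <= 1).mean()),
        "max_shared": int(counts.max()),
        "pair_counts": pair_counts,
    }


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(
    path: str | Path,
    universe: list[str] | None = None,
    name: str | None = None,
) -> GeneSetCollection:
    """Read a GMT file, optionally restricting every set to a universe.

    Without a universe the collection's universe is the union of all
    sets.  Empty post-restriction sets are kept (size 0) with a warning.
    """
    sets: dict[str, frozenset[str]] = {}
    report: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need name, description, genes"
                )
            sname = fields[0]
            if sname in sets:
                raise FormatError(f"duplicate gene set name {sname!r}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            before = len(genes)
            if universe is not None:
                genes = genes & frozenset(g.upper() for g in universe)
                if not genes:
                    warnings.warn(
                        f"gene set {sname!r} empty after universe restriction",
                        stacklevel=2,
                    )
            report[sname] = (before, len(genes))
            sets[sname] = genes
    if universe is not None:
        uni = frozenset(g.upper() for g in universe)
    else:
        uni = frozenset(itertools.chain.from_iterable(sets.values()))
    return GeneSetCollection(
        name=name or Path(path).stem,
        universe=uni,
        sets=sets,
        restriction_report=report,
    )


def write_gene_sets(collection: GeneSetCollection, path: str | Path,
                    description: str = "na") -> None:
    with open(path, "w") as fh:
        for sname, genes in collection.sets.items():
            fh.write("\t".join([sname, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# motif databases (MEME-style minimal format)


def read_motif_db(path: str | Path) -> list[tuple[str, PWM]]:
    """Read a MEME-style minimal motif file into (name, PWM) pairs.

    Rows are renormalized to sum to one (tolerance 1e-6 checked by the
    PWM constructor after renormalization); duplicate names, negative
    entries and zero-sum rows are format errors.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = bio_motifs.parse(_io.StringIO(text), "minimal")
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise FormatError(f"cannot parse {path} as MEME minimal: {exc}") from exc
    out: list[tuple[str, PWM]] = []
    seen: set[str] = set()
    for rec in records:
        name = rec.name
        if name in seen:
            raise FormatError(f"duplicate motif name {name!r}")
        seen.add(name)
        mat = np.array(
            [[rec.pwm[b][i] for b in "ACGT"] for i in range(rec.length)],
            dtype=float,
        )
        if (mat < 0).any():
            raise FormatError(f"motif {name!r} has negative entries")
        row_sums = mat.sum(axis=1)
        if (row_sums <= 0).any():
            raise FormatError(f"motif {name!r} has a zero-sum row")
        out.append((name, PWM(mat / row_sums[:, None])))
    return out


def write_motif_db(motifs: list[tuple[str, PWM]], path: str | Path,
                   background: tuple[float, float, float, float] | None = None,
                   nsites: int = 1000000) -> None:
    # large nsites: MEME readers reconstruct counts as probability*nsites,
    # so a small value would quantize the matrix on round-trip
    """Write (name, PWM) pairs in MEME minimal format."""
    bg = background or (0.25, 0.25, 0.25, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for name, pwm in motifs:
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alphabet= 4 w= {pwm.length} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
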