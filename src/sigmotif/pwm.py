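"""Position weight matrices and DNA sequence encoding.

A PWM is a ``k x 4`` matrix of per-position base probabilities in the
fixed column order A, C, G, T.  Everything downstream — de novo
discovery, similarity grouping, genome-wide scanning — moves PWMs
around, so the class lives here rather than in any one stage.

Sequences are encoded as ``int8`` arrays with A,C,G,T -> 0..3 and any
masked or ambiguous character (lowercase, N, ...) -> -1.  Masked
positions are never silently unmasked; windows touching them are
excluded from counting and scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}

# IUPAC degenerate letters keyed by the frozenset of base indices they cover.
IUPAC = {
    frozenset({0}): "A", frozenset({1}): "C",
    frozenset({2}): "G", frozenset({3}): "T",
    frozenset({0, 2}): "R", frozenset({1, 3}): "Y",
    frozenset({1, 2}): "S", frozenset({0, 3}): "W",
    frozenset({2, 3}): "K", frozenset({0, 1}): "M",
}

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i

MIN_PWM_LENGTH = 6
MAX_PWM_LENGTH = 30


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string; lowercase/N/other characters become -1 (masked)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("N" if c < 0 else BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement preserving case; N stays N."""
    table = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(table)[::-1]


@dataclass(frozen=True)
class PWM:
    """Probability matrix over A,C,G,T; rows are motif positions."""

    matrix: np.ndarray  # shape (k, 4), rows sum to 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PWM matrix must be (k, 4), got {m.shape}")
        if not MIN_PWM_LENGTH <= m.shape[0] <= MAX_PWM_LENGTH:
            raise ValueError(
                f"PWM length {m.shape[0]} outside "
                f"[{MIN_PWM_LENGTH}, {MAX_PWM_LENGTH}]"
            )
        if (m < 0).any():
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1 within 1e-6")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.length

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1].copy())

    def consensus(self) -> str:
        """IUPAC consensus.

        A base letter enters a column's degenerate set when its
        probability is >= 0.25 and >= half the column maximum; three or
        more qualifying bases collapse to N.
        """
        out = []
        for row in self.matrix:
            top = row.max()
            qual = frozenset(
                int(j) for j in range(4) if row[j] >= 0.25 and row[j] >= 0.5 * top
            )
            if len(qual) >= 3:
                out.append("N")
            else:
                out.append(IUPAC[qual])
        return "".join(out)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (2 - Shannon entropy)."""
        m = np.clip(self.matrix, 1e-12, 1.0)
        return 2.0 + (m * np.log2(m)).sum(axis=1)

    @classmethod
    def from_sites(cls, sites: list[str], pseudocount: float = 0.25) -> "PWM":
        """Estimate a PWM from aligned equal-length sites (A/C/G/T only)."""
        if not sites:
            raise ValueError("no sites")
        k = len(sites[0])
        counts = np.full((k, 4), pseudocount, dtype=float)
        for s in sites:
            codes = encode(s)
            if len(codes) != k or (codes < 0).any():
                raise ValueError(f"bad site {s!r}")
            counts[np.arange(k), codes] += 1.0
        return cls(counts / counts.sum(axis=1, keepdims=True))

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one site, each position independently from its column."""
        idx = [int(rng.choice(4, p=row)) for row in self.matrix]
        return "".join(BASES[i] for i in idx)


@dataclass
class Motif:
    """A discovered motif: PWM plus provenance and discovery statistics."""

    id: str
    pwm: PWM
    consensus: str
    support: int
    source_gs: str
    enrichment_p: float
    occurrences: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    # occurrences: gene_id -> [(position, strand)] at discovery time

    def __post_init__(self) -> None:
        if len(self.consensus) != self.pwm.length:
            raise ValueError("consensus length must match PWM length")
        if self.support < 0:
            raise ValueError("support must be non-negative")
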