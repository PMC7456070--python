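"""Core domain types shared by every pipeline stage.

All coordinates are 0-based, half-open. Sequences are held in the RNA
alphabet (A/C/G/U); DNA input is normalized on ingest (T -> U).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

RNA_ALPHABET = frozenset("ACGU")
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
PHE_CODONS = frozenset({"UUU", "UUC"})
LYS_CODONS = frozenset({"AAA", "AAG"})


def normalize_rna(seq: str) -> str:
    """Uppercase and map T to U. Does not validate the alphabet."""
    return seq.upper().replace("T", "U")


def validate_rna(seq: str, where: str = "sequence") -> None:
    for pos, base in enumerate(seq):
        if base not in RNA_ALPHABET:
            raise ValueError(
                f"{where}: invalid character {base!r} at position {pos} "
                "(only A/C/G/U allowed after normalization; ambiguity codes "
                "such as N are rejected)"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A coding transcript: CDS sequence plus exon-junction coordinates.

    Parameters
    ----------
    transcript_id
        Unique identifier.
    cds
        Coding sequence, RNA alphabet, length a positive multiple of 3.
    cds_offset
        Transcript coordinate (0-based) of the first CDS base; the length
        of the 5' UTR.
    junctions
        Sorted transcript coordinates; each records an exon-exon junction
        as the coordinate of the first base *after* the junction, so the
        junction between bases j-1 and j is stored as j.  Junctions may lie
        downstream of the CDS (in the 3' UTR).
    """

    transcript_id: str
    cds: str
    cds_offset: int = 0
    junctions: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if len(self.cds) < 3 or len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds)} must be "
                ">= 3 and a multiple of 3"
            )
        validate_rna(self.cds, where=f"{self.transcript_id} CDS")
        if self.cds_offset < 0:
            raise ValueError(f"{self.transcript_id}: cds_offset must be >= 0")
        object.__setattr__(self, "junctions", tuple(self.junctions))
        for j in self.junctions:
            if j < 0:
                raise ValueError(f"{self.transcript_id}: junction {j} < 0")
        if any(a >= b for a, b in zip(self.junctions, self.junctions[1:])):
            raise ValueError(
                f"{self.transcript_id}: junctions must be strictly increasing, "
                f"got {list(self.junctions)}"
            )

    @property
    def cds_end_transcript(self) -> int:
        """Transcript coordinate one past the last CDS base."""
        return self.cds_offset + len(self.cds)

    def codons(self):
        """Iterate over in-frame (frame 0) codons of the CDS."""
        for i in range(0, len(self.cds) - 2, 3):
            yield self.cds[i : i + 3]


@dataclass(frozen=True)
class DEThresholds:
    """Differential-expression calling thresholds (strict inequalities)."""

    log2fc: float = 1.0
    padj: float = 0.05


@dataclass(frozen=True)
class DERecord:
    transcript_id: str
    log2fc: float
    padj: float
    status: str  # "down" | "up" | "unchanged"

    def __post_init__(self):
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(
                f"{self.transcript_id}: padj {self.padj} outside [0, 1]"
            )
        if self.status not in ("down", "up", "unchanged"):
            raise ValueError(f"invalid DE status {self.status!r}")


@dataclass(frozen=True)
class ScanConfig:
    """Parameters for slippery-site scanning and stimulatory-element calling.

    phe_mode
        "a_site_suffix": a site is tRNA-Phe class iff heptamer positions
        4-7 are UUUU or UUUC (the literal UUUU/C reading); "any_codon":
        Phe class if either the P-site (N2N3N4) or A-site (N5N6N7) codon
        is UUU/UUC.
    require_frame
        Keep only sites whose heptamer starts at CDS position = 2 mod 3,
        so the slipping codons sit in the reading frame.
    min_spacer, max_spacer
        Range of nucleotides between the heptamer and the folded window.
    window_len
        Length of the downstream window scored for secondary structure.
    min_pairs
        Minimum base pairs for a stimulatory element.
    min_loop
        Minimum unpaired bases enclosed by any hairpin.
    n_perm
        Mononucleotide shuffles for the permutation null.
    z_cutoff
        Minimum permutation z-score (excess pairing over the null mean)
        for a signal to pass.
    """

    phe_mode: str = "a_site_suffix"
    require_frame: bool = True
    min_spacer: int = 5
    max_spacer: int = 9
    window_len: int = 70
    min_pairs: int = 15
    min_loop: int = 3
    n_perm: int = 100
    z_cutoff: float = 1.64
    seed: int = 0

    def __post_init__(self):
        if self.phe_mode not in ("a_site_suffix", "any_codon"):
            raise ValueError(f"invalid phe_mode {self.phe_mode!r}")
        if self.min_spacer > self.max_spacer:
            raise ValueError("min_spacer must be <= max_spacer")
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass(frozen=True)
class SlipperySite:
    """A detected X XXY YYZ slippery heptamer.

    start is the 0-based CDS coordinate of heptamer base N1; the heptamer
    occupies [start, start+7). p_codon is N2N3N4 (the codon the P-site tRNA
    occupies before the slip), a_codon is N5N6N7.
    """

    transcript_id: str
    start: int
    heptamer: str
    p_codon: str
    a_codon: str
    trna_class: str  # "phe" | "lys" | "other"
    site_of_action: str  # "P" | "A" | "both" | "none"
    in_frame: bool

    @property
    def end(self) -> int:
        return self.start + 7


@dataclass(frozen=True)
class StimulatoryElement:
    """Best-scoring downstream structure window for a slippery site."""

    window_start: int
    window_end: int
    spacer: int
    pair_score: int
    structure: str
    z: float
    p_perm: float
    degenerate: bool = False


@dataclass(frozen=True)
class PRFSignal:
    """A slippery site together with its stimulatory-element verdict."""

    site: SlipperySite
    element: Optional[StimulatoryElement]
    passes: bool


@dataclass(frozen=True)
class FrameshiftOutcome:
    """Result of simulating a -1 slip at one site."""

    transcript_id: str
    site_start: int
    ptc_start: Optional[int]
    ptc_found: bool
    dist_to_next_junction: Optional[int] = None
    nmd_predicted: bool = False


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = down vs comparator, cols = signal+/signal-."""

    a: int  # down & signal-positive
    b: int  # down & signal-negative
    c: int  # comparator & signal-positive
    d: int  # comparator & signal-negative

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class EnrichmentResult:
    signal_class: str  # "phe_uuuu_c" | "lys_aaaa_g" | "no_phe_codon"
    comparator: str  # "up_regulated" | "prfdb_background"
    table: ContingencyTable
    odds_ratio: float
    p: float
    sided: str  # "one_greater" | "two"


@dataclass(frozen=True)
class LuciferasePair:
    """One dual-luciferase replicate (firefly downstream of the slippery site)."""

    firefly: float
    renilla: float
    condition: str
    replicate: int = 0

    def __post_init__(self):
        if self.firefly < 0:
            raise ValueError("firefly luminescence must be >= 0")
        if self.renilla <= 0:
            raise ValueError("renilla luminescence must be > 0")


@dataclass(frozen=True)
class GstBands:
    """Band intensities from the dual-GST frameshift reporter."""

    dual_intensity: float
    single_intensity: float
    replicate: int = 0

    def __post_init__(self):
        if self.dual_intensity < 0 or self.single_intensity < 0:
            raise ValueError("band intensities must be >= 0")
        if self.dual_intensity + self.single_intensity <= 0:
            raise ValueError("at least one band intensity must be positive")
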