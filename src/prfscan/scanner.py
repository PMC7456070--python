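"""Slippery-heptamer detection and tRNA attribution.

A slippery heptamer X XXY YYZ (N1=N2=N3 and N4=N5=N6) lets the P- and
A-site tRNAs re-pair with the mRNA after a one-nucleotide backward slip.
Heptamers whose A-site-proximal tetramer (N4..N7) is UUUU or UUUC are
decoded by tRNA-Phe, whose position-37 hypermodification normally
suppresses the slip; AAAA/G is the analogous tRNA-Lys class.

The scanner is vectorized with numpy; the test suite checks it against a
naive position-by-position predicate.
"""
from __future__ import annotations

import numpy as np

from .model import (
    LYS_CODONS,
    PHE_CODONS,
    ScanConfig,
    SlipperySite,
    TranscriptModel,
)

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}

PHE_SUFFIXES = frozenset({"UUUU", "UUUC"})
LYS_SUFFIXES = frozenset({"AAAA", "AAAG"})


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA string as uint8 (A=0, C=1, G=2, U=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.shape, dtype=np.uint8)
    for base, code in _ENCODE.items():
        out[arr == ord(base)] = code
    return out


def is_slippery(heptamer: str) -> bool:
    """Pattern predicate: X XXY YYZ with N1=N2=N3 and N4=N5=N6."""
    if len(heptamer) != 7:
        return False
    return (
        heptamer[0] == heptamer[1] == heptamer[2]
        and heptamer[3] == heptamer[4] == heptamer[5]
    )


def classify_trna(heptamer: str, phe_mode: str = "a_site_suffix") -> tuple[str, str]:
    """Attribute a slippery heptamer to its decoding tRNA.

    Returns (trna_class, site_of_action) with trna_class in
    {"phe", "lys", "other"} and site_of_action in {"P", "A", "both", "none"}.

    In "a_site_suffix" mode classification follows the literal UUUU/C vs
    AAAA/G reading of the tetramer N4..N7 (the codon re-paired by the
    A-site tRNA). In "any_codon" mode a site is Phe (Lys) class if either
    the P-site codon N2N3N4 or the A-site codon N5N6N7 is UUU/UUC
    (AAA/AAG); this covers sites like the HIV heptamer UUUUUUA that slip
    via a P-site Phe.
    """
    if not is_slippery(heptamer):
        raise ValueError(f"{heptamer!r} is not a slippery heptamer")
    p_codon = heptamer[1:4]
    a_codon = heptamer[4:7]
    if phe_mode == "a_site_suffix":
        suffix = heptamer[3:7]
        if suffix in PHE_SUFFIXES:
            return "phe", "A"
        if suffix in LYS_SUFFIXES:
            return "lys", "A"
        return "other", "none"
    if phe_mode == "any_codon":
        for cls, codons in (("phe", PHE_CODONS), ("lys", LYS_CODONS)):
            at_p = p_codon in codons
            at_a = a_codon in codons
            if at_p and at_a:
                return cls, "both"
            if at_p:
                return cls, "P"
            if at_a:
                return cls, "A"
        return "other", "none"
    raise ValueError(f"unknown phe_mode {phe_mode!r}")


def _slippery_starts(enc: np.ndarray) -> np.ndarray:
    """All start positions matching X XXY YYZ, vectorized."""
    n = enc.shape[0]
    if n < 7:
        return np.empty(0, dtype=np.int64)
    m = n - 6
    hit = (
        (enc[0:m] == enc[1 : m + 1])
        & (enc[1 : m + 1] == enc[2 : m + 2])
        & (enc[3 : m + 3] == enc[4 : m + 4])
        & (enc[4 : m + 4] == enc[5 : m + 5])
    )
    return np.nonzero(hit)[0]


def find_slippery_sites(
    model: TranscriptModel, config: ScanConfig = ScanConfig()
) -> list[SlipperySite]:
    """Detect slippery heptamers in a CDS.

    With require_frame (the default), only sites whose heptamer starts at
    CDS position = 2 mod 3 are kept: N2 then begins a zero-frame codon, so
    the pre-slip P/A-site codons are in frame and the post-slip codons
    N1N2N3 / N4N5N6 are the -1 frame. Overlapping sites (homopolymeric
    runs) are all reported; output is sorted by start.
    """
    enc = encode_rna(model.cds)
    starts = _slippery_starts(enc)
    if config.require_frame:
        starts = starts[starts % 3 == 2]
    sites = []
    for start in starts.tolist():
        heptamer = model.cds[start : start + 7]
        trna_class, action = classify_trna(heptamer, config.phe_mode)
        sites.append(
            SlipperySite(
                transcript_id=model.transcript_id,
                start=start,
                heptamer=heptamer,
                p_codon=heptamer[1:4],
                a_codon=heptamer[4:7],
                trna_class=trna_class,
                site_of_action=action,
                in_frame=start % 3 == 2,
            )
        )
    return sites


def has_phe_codon(model: TranscriptModel) -> bool:
    """True iff any in-frame codon of the CDS is UUU or UUC.

    Out-of-frame UUU/UUC trinucleotides do not count: the question is
    whether tRNA-Phe ever decodes this message.
    """
    return any(codon in PHE_CODONS for codon in model.codons())
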