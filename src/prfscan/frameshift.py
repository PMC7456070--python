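"""Simulate the -1 slip, locate the premature termination codon (PTC) and
apply the exon-junction rule for nonsense-mediated decay (NMD).

After a -1 slip at an in-frame slippery heptamer X XXY YYZ the tRNAs
re-pair to codons N1N2N3 (P site) and N4N5N6 (A site), so -1-frame
translation resumes at CDS coordinate site.start + 3 and proceeds in steps
of three until a stop codon (the PTC) or the CDS end. A transcript whose
PTC lies sufficiently far (canonically >= 50 nt) upstream of a downstream
exon-exon junction is predicted to be degraded by NMD.
"""
from __future__ import annotations

from typing import Optional, Sequence

from .model import (
    FrameshiftOutcome,
    PRFSignal,
    STOP_CODONS,
    SlipperySite,
    TranscriptModel,
)

NMD_DISTANCE_THRESHOLD = 50  # canonical 50-55 nt exon-junction rule


def simulate_minus1(model: TranscriptModel, site: SlipperySite) -> FrameshiftOutcome:
    """Locate the first -1-frame stop codon downstream of a slip.

    Translation resumes at site.start + 3 (codon N4N5N6 of the heptamer)
    and the first UAA/UAG/UGA encountered in steps of 3 is the PTC.
    """
    if not site.in_frame:
        raise ValueError(
            f"{site.transcript_id}: site at {site.start} is not frame-anchored "
            "(start mod 3 must be 2); the -1 slip is undefined"
        )
    cds = model.cds
    ptc_start: Optional[int] = None
    for p in range(site.start + 3, len(cds) - 2, 3):
        if cds[p : p + 3] in STOP_CODONS:
            ptc_start = p
            break
    return FrameshiftOutcome(
        transcript_id=model.transcript_id,
        site_start=site.start,
        ptc_start=ptc_start,
        ptc_found=ptc_start is not None,
    )


def distance_to_next_junction(
    model: TranscriptModel, ptc_start: int
) -> Optional[int]:
    """Nucleotides between the PTC and the next exon-exon junction.

    The stop codon occupies transcript coordinates
    [cds_offset + ptc_start, cds_offset + ptc_start + 3); the distance is
    j - (cds_offset + ptc_start + 3) for the smallest junction j strictly
    downstream of the stop codon's last base, or None when the PTC lies in
    the last exon (no downstream junction).
    """
    stop_end = model.cds_offset + ptc_start + 3  # one past the last stop base
    for j in model.junctions:
        if j >= stop_end:
            return j - stop_end
    return None


def predict_nmd(
    outcome: FrameshiftOutcome, threshold: int = NMD_DISTANCE_THRESHOLD
) -> bool:
    """Exon-junction rule: NMD iff a PTC exists and sits at least
    ``threshold`` nt upstream of the next exon-exon junction (inclusive)."""
    return (
        outcome.ptc_found
        and outcome.dist_to_next_junction is not None
        and outcome.dist_to_next_junction >= threshold
    )


def frameshift_outcome(
    model: TranscriptModel,
    site: SlipperySite,
    threshold: int = NMD_DISTANCE_THRESHOLD,
) -> FrameshiftOutcome:
    """Full per-site outcome: PTC location, junction distance, NMD verdict."""
    out = simulate_minus1(model, site)
    dist = (
        distance_to_next_junction(model, out.ptc_start)
        if out.ptc_found
        else None
    )
    out = FrameshiftOutcome(
        transcript_id=out.transcript_id,
        site_start=out.site_start,
        ptc_start=out.ptc_start,
        ptc_found=out.ptc_found,
        dist_to_next_junction=dist,
    )
    return FrameshiftOutcome(
        transcript_id=out.transcript_id,
        site_start=out.site_start,
        ptc_start=out.ptc_start,
        ptc_found=out.ptc_found,
        dist_to_next_junction=dist,
        nmd_predicted=predict_nmd(out, threshold),
    )


def transcript_nmd_verdict(
    model: TranscriptModel,
    signals: Sequence[PRFSignal],
    threshold: int = NMD_DISTANCE_THRESHOLD,
) -> Optional[FrameshiftOutcome]:
    """Transcript-level NMD verdict from the 5'-most passing Phe signal.

    The first slip along the message dominates, so only the most upstream
    passing tRNA-Phe site determines the transcript's fate; returns None
    when no such signal exists. Per-site outcomes remain available via
    frameshift_outcome.
    """
    phe_passing = sorted(
        (s for s in signals if s.passes and s.site.trna_class == "phe"),
        key=lambda s: s.site.start,
    )
    if not phe_passing:
        return None
    return frameshift_outcome(model, phe_passing[0].site, threshold)
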