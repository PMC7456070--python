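"""Synthetic transcriptomes and DE tables with recorded ground truth.

The generator emulates the study design this pipeline targets: a
transcriptome of coding sequences in which a controlled fraction of
transcripts carries a complete, frame-anchored -1 PRF signal (slippery
heptamer of the tRNA-Phe or tRNA-Lys class, a spacer, a perfect
stem-loop), a known -1-frame premature stop, and a downstream exon-exon
junction at a recorded distance - plus a differential-expression table in
which down-regulation is enriched among Phe-signal transcripts with a
configurable odds ratio. Every planted quantity is recorded in a truth
table so each pipeline stage can be validated by exact round-trip.

Background sequence is drawn codon-wise from the 61 sense codons (no
internal stops; one terminal stop), and - unless disabled - resampled
until it contains no accidental frame-anchored heptamer of the planted
classes, so truth labels are unambiguous.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import DERecord, STOP_CODONS, TranscriptModel

_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_SENSE_CODONS = [
    "".join(c)
    for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]
_STOPS = sorted(STOP_CODONS)


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic transcriptome.

    CDS lengths span 90-300 nt (30-100 codons): short enough that a
    realistic minority of transcripts lacks UUU/UUC codons entirely (the
    second negative-control class needs members), long enough to host a
    full planted signal. The planted stem-loop uses a 24-bp perfect stem
    with a 4-nt loop - at the strong end of natural -1 PRF stimulators,
    whose stems and pseudoknots commonly involve some 20-30 bp of pairing -
    so that planted elements separate unambiguously from the permutation
    null and truth recovery is exact. The planted exon junction lies
    55-150 nt downstream of the premature stop, inside NMD-triggering
    range under the 50-nt rule.
    """

    n_transcripts: int = 2000
    cds_len_range: tuple[int, int] = (90, 300)
    junctions_per_transcript: tuple[int, int] = (2, 8)
    p_plant_phe_signal: float = 0.15
    p_plant_lys_signal: float = 0.15
    hairpin_stem_len: int = 24
    hairpin_loop_len: int = 4
    spacer: int = 6
    base_p_down: float = 0.1
    enrichment_odds_ratio: float = 3.0
    p_up: float = 0.1
    planted_junction_distance: tuple[int, int] = (55, 150)
    utr5_max: int = 150
    seed: int = 0
    reject_accidental_sites: bool = True

    def __post_init__(self):
        for name in ("p_plant_phe_signal", "p_plant_lys_signal", "base_p_down", "p_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_plant_phe_signal + self.p_plant_lys_signal > 1.0:
            raise ValueError("planting probabilities sum above 1")
        if self.enrichment_odds_ratio < 0:
            raise ValueError("enrichment_odds_ratio must be >= 0")
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")
        lo, hi = self.cds_len_range
        if lo % 3 or hi % 3 or lo < 3 or lo > hi:
            raise ValueError("cds_len_range must be multiples of 3 with lo <= hi")
        cassette = 7 + self.spacer + 2 * self.hairpin_stem_len + self.hairpin_loop_len
        # site start (>=2) + cassette + stop codon + terminal stop codon
        if 2 + cassette + 3 + 3 + 3 > lo:
            raise ValueError(
                "infeasible config: minimum CDS length cannot host the "
                f"planted cassette ({cassette} nt plus stops)"
            )


@dataclass
class TruthRecord:
    transcript_id: str
    planted_site_start: Optional[int] = None
    planted_class: Optional[str] = None
    planted_ptc_start: Optional[int] = None
    planted_junction_distance: Optional[int] = None
    down_assigned: Optional[bool] = None
    up_assigned: Optional[bool] = None


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def by_id(self) -> dict[str, TruthRecord]:
        return {r.transcript_id: r for r in self.records}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _has_frame_anchored_phe_lys(cds: str, skip_start: int = -1) -> bool:
    """Accidental-site predicate: any frame-anchored (start = 2 mod 3)
    slippery heptamer of the Phe UUUU/C or Lys AAAA/G class, other than
    the planted one. Intentionally naive and independent of the scanner."""
    for s in range(2, len(cds) - 6, 3):
        if s == skip_start:
            continue
        h = cds[s : s + 7]
        if h[0] == h[1] == h[2] and h[3] == h[4] == h[5]:
            if h[3:7] in ("UUUU", "UUUC", "AAAA", "AAAG"):
                return True
    return False


def _zero_frame_internal_stop(chars: list[str], n_codons: int) -> bool:
    for i in range(0, 3 * (n_codons - 1), 3):
        if "".join(chars[i : i + 3]) in STOP_CODONS:
            return True
    return False


def _first_minus1_stop(chars: list[str], begin: int, end: int) -> Optional[int]:
    """First -1-frame stop start in [begin, end), stepping by 3."""
    for p in range(begin, min(end, len(chars) - 2), 3):
        if "".join(chars[p : p + 3]) in STOP_CODONS:
            return p
    return None


def _plant_cassette(
    chars: list[str],
    n_codons: int,
    trna_class: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Optional[tuple[int, int]]:
    """Overwrite a planted signal into background codons.

    Returns (site_start, ptc_start) or None when the attempt violated a
    constraint (caller retries with fresh randomness).
    """
    stem, loop, spacer = cfg.hairpin_stem_len, cfg.hairpin_loop_len, cfg.spacer
    required = 7 + spacer + 2 * stem + loop
    pad = (-required) % 3  # align the planted stop to the -1 frame
    cds_len = 3 * n_codons
    # s = 2 mod 3; planted stop must end before the terminal stop codon
    s_max = cds_len - 3 - (required + pad + 3) - 2
    if s_max < 2:
        return None
    n_slots = (s_max - 2) // 3 + 1
    s = 2 + 3 * int(rng.integers(0, n_slots))

    if trna_class == "phe":
        x = "ACG"[rng.integers(0, 3)]
        z = "UC"[rng.integers(0, 2)]
        heptamer = x * 3 + "UUU" + z
    else:
        x = "CGU"[rng.integers(0, 3)]
        z = "AG"[rng.integers(0, 2)]
        heptamer = x * 3 + "AAA" + z

    stem_seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=stem))
    loop_seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=loop))
    spacer_seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=spacer))
    pad_seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=pad))
    cassette = heptamer + spacer_seq + stem_seq + loop_seq + revcomp(stem_seq) + pad_seq
    p = s + len(cassette)
    stop = _STOPS[rng.integers(0, 3)]
    chars[s : s + len(cassette)] = list(cassette)
    chars[p : p + 3] = list(stop)

    if _zero_frame_internal_stop(chars, n_codons):
        return None
    if _first_minus1_stop(chars, s + 3, p) is not None:
        return None
    return s, p


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], TruthTable]:
    """Generate CDSs, exon junctions and planted -1 PRF signals.

    Reproducible: the same config (including seed) yields byte-identical
    output. Raises RuntimeError if the rejection sampler cannot satisfy
    the constraints (an infeasible combination of lengths).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    models: list[TranscriptModel] = []
    truth = TruthTable()
    lo_c, hi_c = config.cds_len_range[0] // 3, config.cds_len_range[1] // 3
    width = len(str(max(config.n_transcripts, 1)))

    for idx in range(config.n_transcripts):
        tid = f"T{idx:0{width}d}"
        u = rng.random()
        if u < config.p_plant_phe_signal:
            plant = "phe"
        elif u < config.p_plant_phe_signal + config.p_plant_lys_signal:
            plant = "lys"
        else:
            plant = None

        planted = None
        accepted = False
        for _attempt in range(200):
            n_codons = int(rng.integers(lo_c, hi_c + 1))
            codon_idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
            chars = list(
                "".join(_SENSE_CODONS[i] for i in codon_idx)
                + _STOPS[rng.integers(0, 3)]
            )
            planted = None
            if plant is not None:
                planted = _plant_cassette(chars, n_codons, plant, config, rng)
                if planted is None:
                    continue
            cds = "".join(chars)
            skip = planted[0] if planted is not None else -1
            if config.reject_accidental_sites and _has_frame_anchored_phe_lys(
                cds, skip_start=skip
            ):
                continue
            accepted = True
            break
        if not accepted:
            raise RuntimeError(
                f"{tid}: rejection sampling failed; config likely infeasible"
            )

        cds_offset = int(rng.integers(0, config.utr5_max + 1))
        jlo, jhi = config.junctions_per_transcript
        n_extra = int(rng.integers(jlo, jhi + 1))
        rec = TruthRecord(transcript_id=tid)
        if planted is not None:
            s, p = planted
            d = int(
                rng.integers(
                    config.planted_junction_distance[0],
                    config.planted_junction_distance[1] + 1,
                )
            )
            j_planted = cds_offset + p + 3 + d
            # extra junctions stay upstream of the stop so the planted one
            # is the next junction after the PTC
            upstream_hi = max(cds_offset + p, 1)
            extras = sorted(
                {int(v) for v in rng.integers(0, upstream_hi, size=n_extra)}
            )
            junctions = tuple(extras + [j_planted])
            rec.planted_site_start = s
            rec.planted_class = plant
            rec.planted_ptc_start = p
            rec.planted_junction_distance = d
        else:
            span = cds_offset + len(cds) + 200
            junctions = tuple(
                sorted({int(v) for v in rng.integers(0, span, size=n_extra)})
            )
        models.append(
            TranscriptModel(
                transcript_id=tid,
                cds=cds,
                cds_offset=cds_offset,
                junctions=junctions,
            )
        )
        truth.records.append(rec)
    return models, truth


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_de_table(
    truth: TruthTable, config: SimulationConfig
) -> list[DERecord]:
    """Assign DE status with planted enrichment and emit matching values.

    A transcript is down-regulated with probability q where
    logit(q) = logit(base_p_down) + log(enrichment_odds_ratio) for
    Phe-signal transcripts and q = base_p_down otherwise; transcripts not
    drawn down are up-regulated with probability p_up independent of
    planting. log2fc/padj values are then emitted to satisfy the default
    calling thresholds deterministically (DE estimation itself is not the
    object under test, only the downstream classification).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    base = config.base_p_down
    records: list[DERecord] = []
    for rec in truth:
        if rec.planted_class == "phe" and base > 0:
            if config.enrichment_odds_ratio == 0:
                q = 0.0
            else:
                q = _expit(_logit(base) + math.log(config.enrichment_odds_ratio))
        else:
            q = base
        down = rng.random() < q
        up = (not down) and rng.random() < config.p_up
        rec.down_assigned = bool(down)
        rec.up_assigned = bool(up)
        if down:
            log2fc = -(1.2 + 2.8 * rng.random())
            padj = 1e-6 + 0.0489 * rng.random()
            status = "down"
        elif up:
            log2fc = 1.2 + 2.8 * rng.random()
            padj = 1e-6 + 0.0489 * rng.random()
            status = "up"
        else:
            log2fc = -0.9 + 1.8 * rng.random()
            padj = 0.06 + 0.93 * rng.random()
            status = "unchanged"
        records.append(
            DERecord(
                transcript_id=rec.transcript_id,
                log2fc=float(log2fc),
                padj=float(padj),
                status=status,
            )
        )
    return records
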