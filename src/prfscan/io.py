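"""Readers and writers for FASTA, transcript-model tables, DE tables and
site/report outputs.

All tabular formats are TSV. Output files begin with a commented header line
recording the tool version, a config hash and the seed, so every emitted
number can be traced back to a reproducible run.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .model import (
    DERecord,
    DEThresholds,
    PRFSignal,
    RNA_ALPHABET,
    ScanConfig,
    TranscriptModel,
    normalize_rna,
)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file of CDS sequences.

    Sequences are uppercased and DNA is converted to the RNA alphabet
    (T -> U). Record ids are the first whitespace-delimited token of each
    header. Duplicate ids, empty files and non-ACGT/U characters are
    reported as errors with the offending record and position.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_rna(str(rec.seq))
        for pos, base in enumerate(seq):
            if base not in RNA_ALPHABET:
                raise ValueError(
                    f"record {rec.id!r}: invalid character {base!r} at "
                    f"position {pos}"
                )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_transcript_models(fasta_path, table_path) -> list[TranscriptModel]:
    """Join a CDS FASTA with a transcript-model table.

    The table is TSV with columns transcript_id, cds_offset, junctions
    (comma-separated transcript coordinates, possibly empty).
    """
    seqs = dict(read_fasta(fasta_path))
    table = pd.read_csv(table_path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"transcript_id", "cds_offset", "junctions"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")
    models = []
    for row in table.itertuples(index=False):
        tid = row.transcript_id
        if tid not in seqs:
            raise ValueError(f"table id {tid!r} not found in FASTA")
        junctions = tuple(
            int(tok) for tok in str(row.junctions).split(",") if tok.strip()
        )
        models.append(
            TranscriptModel(
                transcript_id=tid,
                cds=seqs[tid],
                cds_offset=int(row.cds_offset),
                junctions=junctions,
            )
        )
    return models


def write_transcript_table(path, models: Sequence[TranscriptModel], meta: str = "") -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        fh.write("transcript_id\tcds_offset\tjunctions\n")
        for m in models:
            junc = ",".join(str(j) for j in m.junctions)
            fh.write(f"{m.transcript_id}\t{m.cds_offset}\t{junc}\n")


def read_de_table(path, thresholds: DEThresholds = DEThresholds()) -> list[DERecord]:
    """Read a TSV DE table (transcript_id, log2fc, padj) and call status.

    Row order is preserved; status is assigned with the configured
    thresholds (defaults: |log2FC| > 1.0 and padj < 0.05, both strict).
    """
    from .enrichment import classify_de_status

    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"transcript_id", "log2fc", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    records = []
    for row in table.itertuples(index=False):
        try:
            log2fc = float(row.log2fc)
            padj = float(row.padj)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric DE fields for {row.transcript_id!r}"
            ) from exc
        status = classify_de_status(log2fc, padj, thresholds)
        records.append(
            DERecord(
                transcript_id=str(row.transcript_id),
                log2fc=log2fc,
                padj=padj,
                status=status,
            )
        )
    return records


def write_de_table(path, records: Sequence[DERecord], meta: str = "") -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        fh.write("transcript_id\tlog2fc\tpadj\n")
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.log2fc:.6g}\t{r.padj:.6g}\n")


def config_hash(config: ScanConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def output_meta(config: ScanConfig) -> str:
    return (
        f"prfscan {__version__} config={config_hash(config)} seed={config.seed}"
    )


SITE_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "heptamer",
    "trna_class",
    "site_of_action",
    "in_frame",
    "spacer",
    "pair_score",
    "z",
    "p_perm",
    "passes",
]


def write_sites_tsv(path, signals: Sequence[PRFSignal], config: ScanConfig) -> None:
    """Write PRF signals as TSV; the first three columns are BED-compatible
    (transcript_id, start, end; 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f"# {output_meta(config)}\n")
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for sig in signals:
            s = sig.site
            if sig.element is not None:
                e = sig.element
                extra = [str(e.spacer), str(e.pair_score), f"{e.z:.4f}", f"{e.p_perm:.6g}"]
            else:
                extra = ["NA", "NA", "NA", "NA"]
            fh.write(
                "\t".join(
                    [
                        s.transcript_id,
                        str(s.start),
                        str(s.end),
                        s.heptamer,
                        s.trna_class,
                        s.site_of_action,
                        str(int(s.in_frame)),
                        *extra,
                        str(int(sig.passes)),
                    ]
                )
                + "\n"
            )


def read_sites_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sites table missing columns: {sorted(missing)}")
    return df
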