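"""Differential-expression classification and Fisher enrichment testing.

Builds the 2x2 tables asking whether down-regulated transcripts are
enriched for -1 PRF signals of a given tRNA class, with two comparators
(up-regulated transcripts, and the full scanned background) and a
negative-control panel (tRNA-Lys AAAA/G signals; transcripts lacking any
UUU/UUC codon).

The hypergeometric tail behind Fisher's exact test is implemented here via
log-factorials; the test suite cross-checks it against full-table
enumeration and against an independent library routine.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import replace
from typing import Iterable, Sequence

from .frameshift import transcript_nmd_verdict
from .model import (
    ContingencyTable,
    DERecord,
    DEThresholds,
    EnrichmentResult,
    PRFSignal,
    ScanConfig,
    TranscriptModel,
)
from .scanner import find_slippery_sites, has_phe_codon

SIGNAL_CLASSES = ("phe_uuuu_c", "lys_aaaa_g", "no_phe_codon")
COMPARATORS = ("up_regulated", "prfdb_background")


def classify_de_status(
    log2fc: float, padj: float, thresholds: DEThresholds = DEThresholds()
) -> str:
    """Call down/up/unchanged with strict inequalities.

    Defaults follow standard RNA-seq practice for this analysis:
    |log2FC| > 1.0 and adjusted p < 0.05.
    """
    if not 0.0 <= padj <= 1.0:
        raise ValueError(f"padj {padj} outside [0, 1]")
    if padj < thresholds.padj:
        if log2fc < -thresholds.log2fc:
            return "down"
        if log2fc > thresholds.log2fc:
            return "up"
    return "unchanged"


def summarize_de(records: Sequence[DERecord]) -> dict:
    """Counts per status plus the percentage of changed transcripts that
    are down-regulated."""
    counts = {"down": 0, "up": 0, "unchanged": 0}
    for r in records:
        counts[r.status] += 1
    changed = counts["down"] + counts["up"]
    counts["changed"] = changed
    counts["percent_down_of_changed"] = (
        100.0 * counts["down"] / changed if changed else float("nan")
    )
    return counts


def _log_comb(n: int, k: int) -> float:
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    )


def _log_pmf(x: int, r1: int, r2: int, c1: int) -> float:
    """log P(X = x) for X ~ Hypergeometric with row sums r1, r2 and first
    column sum c1 (x = top-left cell)."""
    return (
        _log_comb(r1, x)
        + _log_comb(r2, c1 - x)
        - _log_comb(r1 + r2, c1)
    )


def hypergeom_tail(a: int, b: int, c: int, d: int, sided: str = "one_greater") -> float:
    """Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    one_greater: P(X >= a) under the hypergeometric fixing all margins
    (enrichment of the top-left cell). two: the standard two-sided Fisher
    test, summing every table whose point probability does not exceed the
    observed one.

    A zero margin makes the table degenerate; p is defined as 1 and a
    warning is issued.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        warnings.warn(
            "degenerate contingency table (zero margin); p defined as 1",
            stacklevel=2,
        )
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_obs = _log_pmf(a, r1, r2, c1)
    if sided == "one_greater":
        total = 0.0
        for x in range(a, hi + 1):
            total += math.exp(_log_pmf(x, r1, r2, c1))
        return min(total, 1.0)
    if sided == "two":
        # include tables as extreme as observed, with a tiny relative
        # tolerance so float noise cannot drop the observed table itself
        cutoff = log_obs + 1e-7
        total = 0.0
        for x in range(lo, hi + 1):
            lp = _log_pmf(x, r1, r2, c1)
            if lp <= cutoff:
                total += math.exp(lp)
        return min(total, 1.0)
    raise ValueError(f"unknown sidedness {sided!r}")


def build_contingency(
    de_records: Sequence[DERecord],
    signal_positive_ids: Iterable[str],
    comparator: str = "up_regulated",
) -> ContingencyTable:
    """Count transcripts into the down-vs-comparator by signal+/- table.

    Each transcript is counted once (signal ids are a set: site-level
    results must be deduplicated to transcript level before this point).
    The comparator class is either the up-regulated transcripts or, for
    "prfdb_background", every scanned transcript that is not down-regulated.
    """
    if comparator not in COMPARATORS:
        raise ValueError(f"unknown comparator {comparator!r}")
    ids = [r.transcript_id for r in de_records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript ids in DE table: {dupes[:5]}")
    positive = set(signal_positive_ids)
    missing = positive - set(ids)
    if missing:
        raise ValueError(
            "signal-positive ids absent from DE table: "
            f"{sorted(missing)[:5]}"
        )
    down = [r for r in de_records if r.status == "down"]
    if comparator == "up_regulated":
        comp = [r for r in de_records if r.status == "up"]
    else:
        comp = [r for r in de_records if r.status != "down"]
    if not down:
        raise ValueError("empty down-regulated class")
    if not comp:
        raise ValueError(f"empty comparator class ({comparator})")
    a = sum(1 for r in down if r.transcript_id in positive)
    c = sum(1 for r in comp if r.transcript_id in positive)
    return ContingencyTable(a=a, b=len(down) - a, c=c, d=len(comp) - c)


def enrichment_test(
    de_records: Sequence[DERecord],
    signal_positive_ids: Iterable[str],
    signal_class: str,
    comparator: str = "up_regulated",
    sided: str = "one_greater",
) -> EnrichmentResult:
    table = build_contingency(de_records, signal_positive_ids, comparator)
    p = hypergeom_tail(table.a, table.b, table.c, table.d, sided)
    return EnrichmentResult(
        signal_class=signal_class,
        comparator=comparator,
        table=table,
        odds_ratio=table.odds_ratio,
        p=p,
        sided=sided,
    )


def scan_transcriptome(
    models: Sequence[TranscriptModel],
    config: ScanConfig = ScanConfig(),
    classes: tuple[str, ...] = ("phe", "lys"),
) -> list[PRFSignal]:
    """Scan every transcript and call PRF signals for sites of the
    requested tRNA classes (structure folding is skipped for the rest)."""
    from .fold import call_prf_signal

    signals: list[PRFSignal] = []
    for model in models:
        for site in find_slippery_sites(model, config):
            if site.trna_class in classes:
                signals.append(call_prf_signal(model, site, config))
            else:
                signals.append(PRFSignal(site=site, element=None, passes=False))
    return signals


def positive_sets(
    models: Sequence[TranscriptModel], signals: Sequence[PRFSignal]
) -> dict[str, set[str]]:
    """Transcript-level positive sets for the three tested classes.

    phe_uuuu_c / lys_aaaa_g: transcripts with at least one passing PRF
    signal of that class; no_phe_codon: transcripts whose CDS contains no
    in-frame UUU or UUC codon at all.
    """
    sets: dict[str, set[str]] = {
        "phe_uuuu_c": set(),
        "lys_aaaa_g": set(),
        "no_phe_codon": set(),
    }
    for sig in signals:
        if sig.passes and sig.site.trna_class == "phe":
            sets["phe_uuuu_c"].add(sig.site.transcript_id)
        elif sig.passes and sig.site.trna_class == "lys":
            sets["lys_aaaa_g"].add(sig.site.transcript_id)
    for model in models:
        if not has_phe_codon(model):
            sets["no_phe_codon"].add(model.transcript_id)
    return sets


def control_panel(
    models: Sequence[TranscriptModel],
    de_records: Sequence[DERecord],
    config: ScanConfig = ScanConfig(),
    comparators: tuple[str, ...] = COMPARATORS,
    sided: str = "one_greater",
    signals: Sequence[PRFSignal] | None = None,
) -> list[EnrichmentResult]:
    """The full enrichment panel: Phe UUUU/C signals plus the two negative
    controls (Lys AAAA/G signals; transcripts lacking UUU/UUC codons),
    tested against each comparator with identical machinery.

    Precomputed signals may be passed to avoid rescanning. No multiple-
    testing correction is applied across the panel by default.
    """
    if signals is None:
        signals = scan_transcriptome(models, config)
    sets = positive_sets(models, signals)
    results = []
    for comparator in comparators:
        for signal_class in SIGNAL_CLASSES:
            results.append(
                enrichment_test(
                    de_records,
                    sets[signal_class],
                    signal_class,
                    comparator,
                    sided,
                )
            )
    return results


def bonferroni(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Optional Bonferroni correction across a panel (off by default)."""
    k = len(results)
    return [replace(r, p=min(1.0, r.p * k)) for r in results]


__all__ = [
    "classify_de_status",
    "summarize_de",
    "hypergeom_tail",
    "build_contingency",
    "enrichment_test",
    "scan_transcriptome",
    "positive_sets",
    "control_panel",
    "bonferroni",
    "transcript_nmd_verdict",
]
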