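"""Downstream stimulatory-structure scoring for -1 PRF signal calling.

A -1 PRF signal is a slippery heptamer followed, after a short spacer, by
RNA secondary structure that pauses the ribosome over the heptamer. The
structure stage scores candidate windows by base-pair maximization
(Nussinov-style dynamic programming over nested Watson-Crick A.U/G.C plus
G.U wobble pairs, with a minimum hairpin-loop size) and assesses
significance against a mononucleotide-shuffle permutation null: the
z-score measures excess pairing over the null mean, so a stimulatory
element corresponds to z above the cutoff.

Base-pair maximization is used rather than a thermodynamic energy model:
it is self-contained, parameter-free apart from the loop constraint, and
exactly verifiable against brute-force enumeration. Energy-model folding
is an extension point, not a dependency.
"""
from __future__ import annotations

import zlib
from typing import NamedTuple

import numpy as np
from numba import njit

from .model import (
    PRFSignal,
    ScanConfig,
    SlipperySite,
    StimulatoryElement,
    TranscriptModel,
)
from .scanner import encode_rna

# Allowed pairs (A=0, C=1, G=2, U=3): A.U, G.C, G.U and reverses.
_PAIR = np.zeros((4, 4), dtype=np.uint8)
for _x, _y in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIR[_x, _y] = 1


@njit(cache=True)
def _fill(enc, min_loop):  # pragma: no cover - exercised via wrappers
    n = enc.shape[0]
    dp = np.zeros((n, n), dtype=np.int16)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            if _PAIR[enc[i], enc[j]]:
                v = dp[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


@njit(cache=True)
def _score_many(mat, min_loop):  # pragma: no cover - exercised via wrappers
    m = mat.shape[0]
    out = np.empty(m, dtype=np.int64)
    for r in range(m):
        dp = _fill(mat[r], min_loop)
        out[r] = dp[0, mat.shape[1] - 1] if mat.shape[1] > 0 else 0
    return out


def _traceback(dp: np.ndarray, enc: np.ndarray, min_loop: int) -> str:
    """One optimal structure as dot-bracket, deterministic tie-break.

    At each interval the options are tried in a fixed order: pair the ends,
    leave the 5' end unpaired, leave the 3' end unpaired, then the leftmost
    bifurcation. This makes the reported structure a pure function of the
    sequence.
    """
    n = enc.shape[0]
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        score = dp[i, j]
        if score == 0:
            continue
        if _PAIR[enc[i], enc[j]] and score == dp[i + 1, j - 1] + 1:
            structure[i] = "("
            structure[j] = ")"
            stack.append((i + 1, j - 1))
        elif score == dp[i + 1, j]:
            stack.append((i + 1, j))
        elif score == dp[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if score == dp[i, k] + dp[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return "".join(structure)


def max_basepair_fold(seq: str, min_loop: int = 3) -> tuple[int, str]:
    """Maximum nested base pairs (A.U, G.C, G.U) with hairpin loops of at
    least ``min_loop`` unpaired bases, plus one optimal dot-bracket
    traceback.

    A pair (i, j) is admissible iff j - i > min_loop. Deterministic.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    enc = encode_rna(seq)
    n = enc.shape[0]
    if n <= min_loop + 1:
        return 0, "." * n
    dp = _fill(enc, min_loop)
    score = int(dp[0, n - 1])
    return score, _traceback(dp, enc, min_loop)


class PermutationNull(NamedTuple):
    z: float
    p_perm: float
    degenerate: bool


def permutation_zscore(
    window: str,
    n_perm: int = 100,
    seed: int = 0,
    min_loop: int = 3,
) -> PermutationNull:
    """Permutation null for a window's pair score.

    The window is mononucleotide-shuffled n_perm times and each shuffle is
    refolded. z = (observed - mean) / sd of the permuted scores, so z > 0
    means more pairing than expected from composition alone.
    p_perm = (1 + #{perm score >= observed}) / (n_perm + 1).

    If the permuted scores have zero spread (e.g. a homopolymer window),
    the null is degenerate: z is defined as 0 and flagged.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    enc = encode_rna(window)
    n = enc.shape[0]
    if n <= min_loop + 1:
        return PermutationNull(0.0, 1.0, True)
    observed = int(_fill(enc, min_loop)[0, n - 1])
    rng = np.random.default_rng(seed)
    perms = np.tile(enc, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    scores = _score_many(perms, min_loop)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if n_perm > 1 else 0.0
    p_perm = float(1 + int((scores >= observed).sum())) / (n_perm + 1)
    if sd == 0.0:
        return PermutationNull(0.0, p_perm, True)
    return PermutationNull((observed - mean) / sd, p_perm, False)


def _site_seed(config: ScanConfig, site: SlipperySite) -> int:
    mix = (
        config.seed * 1000003
        + site.start * 7919
        + zlib.crc32(site.transcript_id.encode())
    )
    return mix % (2**31)


def call_prf_signal(
    model: TranscriptModel, site: SlipperySite, config: ScanConfig = ScanConfig()
) -> PRFSignal:
    """Score the downstream windows of a slippery site and call the signal.

    For each spacer in [min_spacer, max_spacer] the window starting at
    site.start + 7 + spacer of length window_len (truncated at the CDS end)
    is folded; the spacer maximizing pair_score is kept (ties -> smallest
    spacer) and reported as the stimulatory element.

    Significance, however, is assessed on the full candidate region - from
    site.start + 7 + min_spacer to the end of the max_spacer window - as a
    plain permutation test (observed fold of that region vs its shuffles).
    Testing the best-of-several overlapping windows against its own shuffle
    null would be selection-biased (the null pass rate roughly doubles);
    the region-level test keeps the false-positive rate at its nominal
    level. The signal passes iff the element exists, its pair_score >=
    min_pairs and the region z >= z_cutoff on a non-degenerate null.
    """
    cds = model.cds
    n = len(cds)
    best = None  # (score, spacer, wstart, wend)
    for spacer in range(config.min_spacer, config.max_spacer + 1):
        wstart = site.start + 7 + spacer
        if wstart >= n:
            continue
        wend = min(wstart + config.window_len, n)
        window = cds[wstart:wend]
        score, _ = max_basepair_fold(window, config.min_loop)
        if best is None or score > best[0]:
            best = (score, spacer, wstart, wend)
    if best is None:
        return PRFSignal(site=site, element=None, passes=False)
    score, spacer, wstart, wend = best
    window = cds[wstart:wend]
    _, structure = max_basepair_fold(window, config.min_loop)
    region_start = site.start + 7 + config.min_spacer
    region_end = min(site.start + 7 + config.max_spacer + config.window_len, n)
    null = permutation_zscore(
        cds[region_start:region_end],
        config.n_perm,
        _site_seed(config, site),
        config.min_loop,
    )
    element = StimulatoryElement(
        window_start=wstart,
        window_end=wend,
        spacer=spacer,
        pair_score=score,
        structure=structure,
        z=null.z,
        p_perm=null.p_perm,
        degenerate=null.degenerate,
    )
    passes = (
        score >= config.min_pairs
        and not null.degenerate
        and null.z >= config.z_cutoff
    )
    return PRFSignal(site=site, element=element, passes=passes)
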