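"""Independent brute-force oracles used only by the test suite.

Each oracle is deliberately naive and shares no code path with the
implementation it checks.
"""
from functools import lru_cache
from math import comb

_WC_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


def naive_slippery_starts(cds: str, require_frame: bool = True) -> list[int]:
    """Position-by-position X XXY YYZ predicate."""
    out = []
    for s in range(len(cds) - 6):
        h = cds[s : s + 7]
        if h[0] == h[1] == h[2] and h[3] == h[4] == h[5]:
            if not require_frame or s % 3 == 2:
                out.append(s)
    return out


def exhaustive_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum nested base pairs by exhaustive pair-first recursion.

    At interval [i, j] either i is unpaired or i pairs with some k with
    k - i > min_loop, splitting the interval; all choices are explored.
    """
    n = len(seq)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        top = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _WC_PAIRS:
                v = 1 + best(i + 1, k - 1) + best(k + 1, j)
                if v > top:
                    top = v
        return top

    return best(0, n - 1) if n else 0


def enum_fisher(a: int, b: int, c: int, d: int, sided: str) -> float:
    """Fisher p by full-table enumeration with exact integer binomials."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    pmf = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    if sided == "one_greater":
        return sum(v for x, v in pmf.items() if x >= a)
    obs = pmf[a]
    return sum(v for v in pmf.values() if v <= obs * (1 + 1e-9))


def dotbracket_pairs(structure: str) -> list[tuple[int, int]]:
    """Decode a dot-bracket string into its pair list (errors on imbalance)."""
    stack: list[int] = []
    pairs = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    assert not stack, "unbalanced structure"
    return pairs
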