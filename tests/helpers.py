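"""Independent brute-force oracles shared by the test modules.

These enumerate maximal exact matches by direct O(n^2 * l) scanning and
are deliberately kept free of any suffix-array machinery.
"""

from __future__ import annotations

import numpy as np

from mldkit import fitting, mems


def brute_cross_mems(a: str, b: str, minlen: int) -> list[tuple[int, int, int]]:
    """All maximal matches between a and b by quadratic scanning."""
    out = []
    la, lb = len(a), len(b)
    for i in range(la):
        for j in range(lb):
            if a[i] != b[j] or a[i] == "N":
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1] and a[i - 1] != "N":
                continue  # extendable to the left: not a match start
            length = 0
            while (
                i + length < la
                and j + length < lb
                and a[i + length] == b[j + length]
                and a[i + length] != "N"
            ):
                length += 1
            if length >= minlen:
                out.append((i, j, length))
    return sorted(out)


def brute_self_mems(s: str, minlen: int) -> list[tuple[int, int, int]]:
    """All maximal self-matches (unordered locus pairs, diagonal excluded)."""
    out = []
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n):
            if s[i] != s[j] or s[i] == "N":
                continue
            if i > 0 and s[i - 1] == s[j - 1] and s[i - 1] != "N":
                continue
            length = 0
            while j + length < n and s[i + length] == s[j + length] and s[i + length] != "N":
                length += 1
            if length >= minlen:
                out.append((i, j, length))
    return sorted(out)


def random_dna(rng: np.random.Generator, n: int, with_n: float = 0.0) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = None
    if with_n:
        p = [(1 - with_n) / 4] * 4 + [with_n]
    return "".join(rng.choice(list(alphabet), size=n, p=p))


def fitted_tail(pooled: mems.MLD, r_lo: float = 30.0, ratio: float = 1.25,
                start: int = 20) -> fitting.TailFit:
    """The standard tail-fit pipeline used for simulated MLDs."""
    return fitting.fit_tail_exponent(mems.log_bin(pooled, ratio, start=start), r_lo=r_lo)
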